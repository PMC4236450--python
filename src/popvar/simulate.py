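"""Seeded multi-population cohort simulator.

Generates the ground-truth fixtures every downstream stage consumes: a
Balding-Nichols genotype matrix over one focal population plus a panel of
reference populations (defaults mirror a 16-diploid focal cohort compared
against fourteen 16-sample reference panels), GWAS-style SNP subsets with
planted large frequency differences, population-confined rare/private
variants, synonymous/non-synonymous labels with a planted non-synonymous
excess among strict singletons, per-sample deletion callsets whose
breakpoints jitter around shared loci, a reference deletion catalogue for
novelty assessment, and an array-style gold-standard genotype table.

All stochastic draws flow from a single numpy Generator in the order the
functions document, so a seed fully determines every fixture.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError
from .rare_private import classify_all
from .variants import (
    MISSING,
    GenotypeMatrix,
    make_panel,
    make_variant_table,
)
from .deletions import DeletionCall

#: 1000 Genomes phase-1 population codes used as default reference panels
REFERENCE_POPULATIONS = (
    "CEU", "TSI", "GBR", "FIN", "IBS",
    "CHB", "JPT", "CHS",
    "YRI", "LWK", "ASW",
    "MXL", "PUR", "CLM",
)
#: default pooled comparison group (the European panels)
EUROPEAN_GROUP = ("CEU", "TSI", "GBR", "FIN", "IBS")

_TRAITS = (
    "pigmentation", "total cholesterol", "height", "type 2 diabetes",
    "blood pressure", "body mass index", "rheumatoid arthritis",
)


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    The defaults are the cohort design the downstream analyses assume: one
    focal population and 14 reference populations of 16 diploid samples
    each, Balding-Nichols differentiated allele frequencies at Fst 0.1
    around Beta(0.5, 0.5) ancestral frequencies, a 2000-SNP GWAS panel with
    2 planted outliers at |delta f| 0.8 (large enough to stand above the
    background differentiation the Fst default produces), planted
    population-confined variants (200 singletons, 20 at 2-3 copies, 7 at
    >3 copies), a
    non-synonymous fraction of 0.6 among strict singletons vs 0.4 elsewhere,
    and 500 deletion loci (sizes strictly inside 50 bp - 100 kbp) of which a
    fraction 0.1 is planted to violate the heterozygous-SNP validation rule.
    """

    # cohort layout
    n_populations: int = 15            # reference panels + 1 focal
    samples_per_population: int = 16
    focal_population: str = "TUR"
    # genome coordinate space
    n_chroms: int = 22
    chrom_length: int = 10_000_000
    # SNP frequency model
    n_snps: int = 20_000
    fst: float = 0.1
    beta_a: float = 0.5
    beta_b: float = 0.5
    missing_frac: float = 0.0
    # GWAS panel and planted frequency outliers
    n_gwas_snps: int = 2_000
    n_planted_outliers: int = 2
    planted_diff: float = 0.8
    # planted population-confined variants (focal alt chromosome counts
    # 1 / 2-3 / >3)
    n_rare: int = 200
    n_low_count_private: int = 20
    n_private: int = 7
    # functional labels
    rare_nonsyn_frac: float = 0.6
    common_nonsyn_frac: float = 0.4
    labeled_frac: float = 1.0
    known_frac_shared: float = 0.92
    known_frac_confined: float = 0.3
    # deletion callsets
    n_deletion_sites: int = 500
    deletion_carrier_rate: float = 0.1
    false_deletion_frac: float = 0.1
    deletion_min_size: int = 51
    deletion_max_size: int = 99_999
    jitter_frac: float = 0.02
    deletion_hom_rate: float = 0.2
    genotyped_frac: float = 0.9
    known_deletion_frac: float = 0.5
    n_extra_reference_deletions: int = 100
    # array-style gold standard
    n_array_sites: int = 5_000
    array_discord_frac: float = 0.002
    # geography (focal bounding box: Anatolia)
    focal_lat_range: tuple[float, float] = (36.0, 42.0)
    focal_lon_range: tuple[float, float] = (26.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "missing_frac": self.missing_frac,
            "rare_nonsyn_frac": self.rare_nonsyn_frac,
            "common_nonsyn_frac": self.common_nonsyn_frac,
            "labeled_frac": self.labeled_frac,
            "known_frac_shared": self.known_frac_shared,
            "known_frac_confined": self.known_frac_confined,
            "false_deletion_frac": self.false_deletion_frac,
            "deletion_carrier_rate": self.deletion_carrier_rate,
            "deletion_hom_rate": self.deletion_hom_rate,
            "genotyped_frac": self.genotyped_frac,
            "known_deletion_frac": self.known_deletion_frac,
            "array_discord_frac": self.array_discord_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ContractError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ContractError("fst must lie in (0, 1)")
        if not (
            50 < self.deletion_min_size
            and self.deletion_max_size < 100_000
            and self.deletion_min_size <= self.deletion_max_size
        ):
            raise ContractError(
                "deletion sizes must lie strictly inside (50, 100000) bp"
            )
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ContractError("need at least one population and sample")
        n_special = (
            self.n_rare + self.n_low_count_private + self.n_private
            + self.n_gwas_snps
        )
        if n_special > self.n_snps:
            raise ContractError(
                "planted variant counts exceed the number of SNPs"
            )
        if self.n_planted_outliers > self.n_gwas_snps:
            raise ContractError("more planted outliers than GWAS SNPs")
        if 4 > 2 * self.samples_per_population and self.n_private > 0:
            raise ContractError(
                "private plant needs > 3 chromosomes but the focal "
                "population is too small"
            )

    @property
    def populations(self) -> list[str]:
        refs = list(REFERENCE_POPULATIONS)
        while len(refs) < self.n_populations - 1:
            refs.append(f"REF{len(refs) + 1:02d}")
        return [self.focal_population] + refs[: self.n_populations - 1]

    @property
    def comparison_group(self) -> list[str]:
        """Pooled comparison group: the European panels present in the run."""
        pops = set(self.populations)
        group = [p for p in EUROPEAN_GROUP if p in pops]
        if not group:
            group = [p for p in self.populations if p != self.focal_population][:1]
        return group

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["focal_lat_range"] = list(self.focal_lat_range)
        d["focal_lon_range"] = list(self.focal_lon_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("focal_lat_range", "focal_lon_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GenotypeTruth:
    """Ground truth planted by :func:`simulate_genotypes`."""

    gwas_index: np.ndarray
    planted_outlier_index: np.ndarray
    comparison_group: list[str]
    focal_population: str
    rare_index: np.ndarray
    low_count_private_index: np.ndarray
    private_index: np.ndarray
    planted_counts: dict[int, int]
    sharing_class: pd.Series
    population_freq: pd.DataFrame  # populations x snps


@dataclass
class DeletionTruth:
    """Ground truth planted by :func:`simulate_deletions`."""

    sites: pd.DataFrame  # chrom, start, end, carriers, is_false, is_known
    reference_intervals: list[tuple[str, int, int]]


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, GenotypeTruth]:
    """Simulate the multi-population genotype fixture.

    Draw order: variant positions, ancestral frequencies, per-population
    Balding-Nichols frequencies, planted GWAS outlier frequencies, planted
    confined-variant layout, per-population binomial dosages, missingness
    mask, functional labels, known flags, panel coordinates.

    Returns (matrix, variant table, panel, truth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps
    pops = config.populations
    spp = config.samples_per_population

    chroms, positions = _draw_positions(config, rng)

    p = rng.beta(config.beta_a, config.beta_b, size=n_snps)
    p = np.clip(p, 1e-6, 1 - 1e-6)
    f = config.fst
    shape_a = p * (1 - f) / f
    shape_b = (1 - p) * (1 - f) / f
    pop_freq = rng.beta(
        shape_a[None, :], shape_b[None, :], size=(len(pops), n_snps)
    )

    # disjoint special variant subsets
    special = rng.choice(
        n_snps,
        size=config.n_gwas_snps
        + config.n_rare
        + config.n_low_count_private
        + config.n_private,
        replace=False,
    )
    cut1 = config.n_gwas_snps
    cut2 = cut1 + config.n_rare
    cut3 = cut2 + config.n_low_count_private
    gwas_idx = np.sort(special[:cut1])
    rare_idx = np.sort(special[cut1:cut2])
    low_idx = np.sort(special[cut2:cut3])
    priv_idx = np.sort(special[cut3:])

    planted_idx = (
        np.sort(rng.choice(gwas_idx, size=config.n_planted_outliers,
                           replace=False))
        if config.n_planted_outliers
        else np.array([], dtype=int)
    )
    comparison = config.comparison_group
    comp_rows = [pops.index(c) for c in comparison]
    for j in planted_idx:
        lo, hi = 0.02, 0.98 - config.planted_diff
        f_comp = rng.uniform(lo, max(lo + 1e-6, hi))
        f_focal = f_comp + config.planted_diff
        if rng.random() < 0.5:
            f_comp, f_focal = f_focal, f_comp
        pop_freq[0, j] = f_focal
        for r in comp_rows:
            pop_freq[r, j] = f_comp

    # planted confined variants: chromosome counts per index
    planted_counts: dict[int, int] = {}
    for j in rare_idx:
        planted_counts[int(j)] = 1
    for j in low_idx:
        planted_counts[int(j)] = int(rng.integers(2, 4))
    for j in priv_idx:
        hi = min(8, 2 * spp)
        planted_counts[int(j)] = int(rng.integers(4, hi + 1))
    infeasible = [k for k, v in planted_counts.items() if v > 2 * spp]
    if infeasible:
        raise ContractError(
            f"planted chromosome count exceeds 2 x focal samples at "
            f"variants {infeasible}"
        )

    dosage = np.empty((len(pops) * spp, n_snps), dtype=np.int8)
    for i in range(len(pops)):
        dosage[i * spp : (i + 1) * spp] = rng.binomial(
            2, pop_freq[i], size=(spp, n_snps)
        ).astype(np.int8)

    confined = np.fromiter(planted_counts.keys(), dtype=int)
    if confined.size:
        dosage[:, confined] = 0
        for j, k in planted_counts.items():
            _assign_focal_chromosomes(dosage, int(j), k, spp, rng)

    # planted outliers carry the focal frequency exactly (chromosome counts
    # rounded), so the planted |delta f| is not washed out by focal-sample
    # binomial noise; focal samples occupy rows [0, spp)
    for j in planted_idx:
        k = int(round(pop_freq[0, j] * 2 * spp))
        dosage[:spp, j] = 0
        _assign_focal_chromosomes(dosage, int(j), k, spp, rng)

    if config.missing_frac > 0:
        mask = rng.random(dosage.shape) < config.missing_frac
        if confined.size:
            mask[:, confined] = False
        dosage[mask] = MISSING

    samples = [f"{pop}{i + 1:02d}" for pop in pops for i in range(spp)]
    panel = _draw_panel(config, rng, samples, pops, spp)

    matrix = GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(
            {"chrom": chroms, "pos": positions,
             "ref": ["A"] * n_snps, "alt": ["G"] * n_snps}
        ),
        dosage=dosage,
    )

    classes = classify_all(matrix, panel, config.focal_population)
    labeled = rng.random(n_snps) < config.labeled_frac
    nonsyn_p = np.where(
        classes.to_numpy() == "rare",
        config.rare_nonsyn_frac,
        config.common_nonsyn_frac,
    )
    nonsyn = rng.random(n_snps) < nonsyn_p
    functional = np.where(
        labeled, np.where(nonsyn, "nonsynonymous", "synonymous"), "other"
    )
    confined_mask = np.isin(
        classes.to_numpy(), ("rare", "low_count_private", "private")
    )
    known_p = np.where(
        confined_mask, config.known_frac_confined, config.known_frac_shared
    )
    known = rng.random(n_snps) < known_p

    table = make_variant_table(
        chroms,
        positions,
        ["A"] * n_snps,
        ["G"] * n_snps,
        functional.tolist(),
        known.tolist(),
        rsid=[f"rs{1_000_000 + j}" for j in range(n_snps)],
    )
    truth = GenotypeTruth(
        gwas_index=gwas_idx,
        planted_outlier_index=planted_idx,
        comparison_group=list(comparison),
        focal_population=config.focal_population,
        rare_index=rare_idx,
        low_count_private_index=low_idx,
        private_index=priv_idx,
        planted_counts=planted_counts,
        sharing_class=classes,
        population_freq=pd.DataFrame(pop_freq, index=pops),
    )
    return matrix, table, panel, truth


def _assign_focal_chromosomes(
    dosage: np.ndarray, j: int, k: int, spp: int, rng: np.random.Generator
) -> None:
    """Distribute exactly k alternate chromosomes over the focal samples
    (rows [0, spp)) at variant j, as heterozygotes where possible."""
    order = rng.permutation(spp)
    n_hom = max(0, k - spp)
    n_het = k - 2 * n_hom
    for s in order[:n_hom]:
        dosage[s, j] = 2
    for s in order[n_hom : n_hom + n_het]:
        dosage[s, j] = 1


def _draw_positions(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Sorted unique 1-based positions spread over the synthetic genome."""
    per_chrom = np.full(config.n_chroms, config.n_snps // config.n_chroms)
    per_chrom[: config.n_snps % config.n_chroms] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for ci in range(config.n_chroms):
        cnt = int(per_chrom[ci])
        draw = np.unique(rng.integers(1, config.chrom_length, size=cnt * 2 + 8))
        while draw.size < cnt:  # vanishingly unlikely at sane densities
            draw = np.unique(
                np.concatenate(
                    [draw, rng.integers(1, config.chrom_length, size=cnt)]
                )
            )
        take = np.sort(rng.choice(draw, size=cnt, replace=False))
        chroms.extend([str(ci + 1)] * cnt)
        positions.extend(int(x) for x in take)
    return chroms, np.array(positions, dtype=np.int64)


def _draw_panel(config, rng, samples, pops, spp) -> pd.DataFrame:
    lats, lons = [], []
    for pi, pop in enumerate(pops):
        if pop == config.focal_population:
            lo_lat, hi_lat = config.focal_lat_range
            lo_lon, hi_lon = config.focal_lon_range
            lats.extend(rng.uniform(lo_lat, hi_lat, size=spp))
            lons.extend(rng.uniform(lo_lon, hi_lon, size=spp))
        else:
            c_lat = rng.uniform(-55, 65)
            c_lon = rng.uniform(-170, 170)
            lats.extend(np.clip(rng.uniform(c_lat - 2, c_lat + 2, spp), -90, 90))
            lons.extend(np.clip(rng.uniform(c_lon - 2, c_lon + 2, spp), -180, 180))
    populations = [pop for pop in pops for _ in range(spp)]
    return make_panel(samples, populations, lats, lons)


def gwas_snp_list(
    table: pd.DataFrame, truth: GenotypeTruth
) -> pd.DataFrame:
    """GWAS SNP list TSV content for the simulated GWAS panel."""
    idx = truth.gwas_index
    sub = table.iloc[idx]
    traits = [_TRAITS[i % len(_TRAITS)] for i in range(len(idx))]
    return pd.DataFrame(
        {
            "rsid": sub["rsid"].to_numpy()
            if "rsid" in sub
            else [f"rs{j}" for j in idx],
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "trait": traits,
        }
    )


def simulate_deletions(
    config: SimConfig,
    matrix: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[DeletionCall]], pd.DataFrame, DeletionTruth]:
    """Simulate per-sample deletion callsets over the focal population.

    Loci are placed in pairwise-disjoint genomic windows. A true locus
    avoids (with a jitter-sized margin) every heterozygous SNP of its
    carriers, so no jittered call can contain one; a planted-false locus is
    centred on a heterozygous SNP of one carrier, deep enough inside the
    interval that every jittered call still contains it. Exactly
    ``round(false_deletion_frac * n_deletion_sites)`` loci are false.
    Per-carrier calls are whole-interval shifts of at most
    ``jitter_frac x length``, so same-locus calls reciprocally overlap at
    least ``1 - 2 x jitter_frac``.

    Returns (per-sample callsets, het-SNP site list, truth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    focal_samples = [
        s for s in matrix.samples if s.startswith(config.focal_population)
    ]
    if not focal_samples:
        focal_samples = list(matrix.samples)
    het_index = _het_position_index(matrix, focal_samples)

    n_sites = config.n_deletion_sites
    n_false = int(round(config.false_deletion_frac * n_sites))
    false_ids = set(
        rng.choice(n_sites, size=n_false, replace=False).tolist()
    )
    occupied: dict[str, list[tuple[int, int]]] = {}
    site_rows = []
    callsets: dict[str, list[DeletionCall]] = {s: [] for s in focal_samples}
    reference: list[tuple[str, int, int]] = []

    for sid in range(n_sites):
        carriers = [
            s for s in focal_samples
            if rng.random() < config.deletion_carrier_rate
        ]
        if not carriers:
            carriers = [focal_samples[int(rng.integers(len(focal_samples)))]]
        is_false = sid in false_ids
        chrom, start, length, het_pos0 = _place_locus(
            config, rng, carriers, het_index, occupied, is_false
        )
        end = start + length
        occupied.setdefault(chrom, []).append((start, end))
        margin = int(config.jitter_frac * length) + 1
        for s in carriers:
            delta = int(rng.integers(-(margin - 1), margin)) if margin > 1 else 0
            genotype = 2 if rng.random() < config.deletion_hom_rate else 1
            genotyped = bool(rng.random() < config.genotyped_frac)
            callsets[s].append(
                DeletionCall(
                    chrom=chrom,
                    start=start + delta,
                    end=end + delta,
                    sample=s,
                    genotype=genotype,
                    genotyped=genotyped,
                )
            )
        is_known = bool(rng.random() < config.known_deletion_frac)
        if is_known:
            shift = int(rng.integers(-length // 20 - 1, length // 20 + 2))
            reference.append((chrom, start + shift, end + shift))
        site_rows.append(
            (chrom, start, end, ",".join(sorted(carriers)), is_false, is_known)
        )

    # decoy reference intervals away from every simulated locus
    for _ in range(config.n_extra_reference_deletions):
        length = _draw_length(config, rng)
        for _ in range(200):
            chrom = str(int(rng.integers(1, config.n_chroms + 1)))
            start = int(rng.integers(0, config.chrom_length - length))
            if not _overlaps_occupied(occupied, chrom, start, start + length):
                reference.append((chrom, start, start + length))
                occupied.setdefault(chrom, []).append((start, start + length))
                break

    het_rows = [
        (s, chrom, int(p0 + 1))
        for (s, chrom), pos0 in het_index.items()
        for p0 in pos0
    ]
    het_sites = pd.DataFrame(het_rows, columns=["sample", "chrom", "pos"])
    truth = DeletionTruth(
        sites=pd.DataFrame(
            site_rows,
            columns=["chrom", "start", "end", "carriers", "is_false", "is_known"],
        ),
        reference_intervals=reference,
    )
    return callsets, het_sites, truth


def _het_position_index(matrix, samples) -> dict[tuple[str, str], np.ndarray]:
    """(sample, chrom) -> sorted 0-based het positions."""
    idx: dict[tuple[str, str], np.ndarray] = {}
    v = matrix.variants
    chrom_arr = v["chrom"].to_numpy()
    pos0_arr = v["pos"].to_numpy(np.int64) - 1
    for s in samples:
        row = matrix.dosage[matrix.samples.index(s)]
        het = row == 1
        for chrom in np.unique(chrom_arr[het]):
            sel = het & (chrom_arr == chrom)
            idx[(s, str(chrom))] = np.sort(pos0_arr[sel])
    return idx


def _draw_length(config, rng) -> int:
    lo, hi = config.deletion_min_size, config.deletion_max_size
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _overlaps_occupied(occupied, chrom, start, end, gap: int = 1000) -> bool:
    for s, e in occupied.get(chrom, []):
        if start < e + gap and s < end + gap:
            return True
    return False


def _carrier_hets_in(het_index, carriers, chrom, lo, hi) -> bool:
    for s in carriers:
        pos0 = het_index.get((s, chrom))
        if pos0 is None:
            continue
        a = np.searchsorted(pos0, lo, side="left")
        b = np.searchsorted(pos0, hi, side="left")
        if b > a:
            return True
    return False


def _place_locus(config, rng, carriers, het_index, occupied, is_false):
    """Choose (chrom, start, length, anchor het pos) for one locus."""
    length = _draw_length(config, rng)
    for _ in range(8):  # progressively shorten if placement keeps failing
        margin = int(config.jitter_frac * length) + 1
        if is_false:
            placed = _place_false(
                config, rng, carriers, het_index, occupied, length, margin
            )
        else:
            placed = _place_true(
                config, rng, carriers, het_index, occupied, length, margin
            )
        if placed is not None:
            return placed
        length = max(config.deletion_min_size + 1, length // 2)
    raise ContractError(
        "could not place a deletion locus; the genome is too crowded for "
        "the configured counts"
    )


def _place_true(config, rng, carriers, het_index, occupied, length, margin):
    for _ in range(200):
        chrom = str(int(rng.integers(1, config.n_chroms + 1)))
        start = int(rng.integers(margin, config.chrom_length - length - margin))
        if _overlaps_occupied(occupied, chrom, start - margin, start + length + margin):
            continue
        if _carrier_hets_in(
            het_index, carriers, chrom, start - margin, start + length + margin
        ):
            continue
        return chrom, start, length, None
    return None


def _place_false(config, rng, carriers, het_index, occupied, length, margin):
    if 2 * margin >= length:
        return None
    order = list(rng.permutation(len(carriers)))
    for ci in order:
        s = carriers[ci]
        keys = [k for k in het_index if k[0] == s]
        rng.shuffle(keys)
        for key in keys:
            chrom = key[1]
            pos0 = het_index[key]
            for p0 in rng.permutation(pos0)[:50]:
                offset = int(rng.integers(margin, length - margin))
                start = int(p0) - offset
                if start < 0 or start + length > config.chrom_length:
                    continue
                if _overlaps_occupied(occupied, chrom, start, start + length):
                    continue
                return chrom, start, length, int(p0)
    return None


def simulate_array_truth(
    config: SimConfig,
    matrix: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> dict[tuple, int]:
    """Array-style gold-standard genotypes at a random subset of sites.

    The truth genotype equals the matrix dosage except at a planted
    ``array_discord_frac`` of (sample, site) pairs, where it is replaced by
    a different genotype — emulating the small residual discordance between
    a sequencing callset and a genotyping-array gold standard.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = min(config.n_array_sites, matrix.n_variants)
    site_idx = np.sort(rng.choice(matrix.n_variants, size=n, replace=False))
    keys = matrix.variant_keys()
    g = matrix.dosage[:, site_idx].astype(np.int64)
    discord = rng.random(g.shape) < config.array_discord_frac
    shifted = (g + 1 + rng.integers(0, 2, size=g.shape)) % 3
    g = np.where(discord, shifted, g)
    truth: dict[tuple, int] = {}
    for i, s in enumerate(matrix.samples):
        row = matrix.dosage[i, site_idx]
        for jj, j in enumerate(site_idx):
            if row[jj] == MISSING:
                continue
            truth[(s, *keys[j])] = int(g[i, jj])
    return truth


def simulate_all(config: SimConfig):
    """Run all three simulators off one seeded stream.

    Returns a dict with matrix, variant table, panel, genotype truth,
    deletion callsets, het sites, deletion truth, and array truth.
    """
    rng = np.random.default_rng(config.seed)
    matrix, table, panel, gtruth = simulate_genotypes(config, rng)
    callsets, het_sites, dtruth = simulate_deletions(config, matrix, rng)
    array_truth = simulate_array_truth(config, matrix, rng)
    return {
        "matrix": matrix,
        "variant_table": table,
        "panel": panel,
        "genotype_truth": gtruth,
        "deletion_callsets": callsets,
        "het_sites": het_sites,
        "deletion_truth": dtruth,
        "array_truth": array_truth,
    }
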