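"""Genotype containers and per-variant operations.

The central object is :class:`GenotypeMatrix`: a samples x variants matrix of
alternate-allele dosages (0, 1, 2, or missing) for biallelic SNVs/indels,
paired with a variant table carrying functional-class labels and a
known/novel flag, and a population panel mapping samples to populations and
optional coordinates.

Coordinate conventions: variant positions are 1-based (VCF); all interval
work in :mod:`popvar.deletions` is 0-based half-open, converted at the
boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDataWarning, SampleLookupError

#: sentinel dosage for a missing ("./.") genotype
MISSING = -1

#: the three-level functional vocabulary consumed from VCF INFO
FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous", "other")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the bare dialect ("chr1" -> "1").

    GRCh37 resources mix "chr1" and "1" naming; every comparison in this
    package happens on normalized names.
    """
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


def autosome_whitelist() -> list[str]:
    """Default chromosome whitelist: human autosomes 1-22 (normalized)."""
    return [str(i) for i in range(1, 23)]


@dataclass
class AlleleCount:
    """Alternate-allele chromosome count within some sample set.

    ``alt`` alternate chromosomes out of ``total`` successfully called
    chromosomes (2 per non-missing diploid genotype).
    """

    alt: int
    total: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.alt <= self.total):
            raise ContractError(
                f"invalid allele count alt={self.alt} total={self.total}"
            )

    @property
    def frequency(self) -> float:
        """Alternate-allele frequency; NaN when no chromosome was called."""
        if self.total == 0:
            return float("nan")
        return self.alt / self.total

    @property
    def ref(self) -> int:
        return self.total - self.alt


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants alternate-allele dosage matrix.

    ``dosage[i, j]`` is 0/1/2 or :data:`MISSING` for sample ``samples[i]`` at
    variant ``j`` of ``variants`` (a DataFrame with columns chrom, pos, ref,
    alt; chrom stored normalized).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ContractError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ContractError("duplicate sample ids")
        keys = self.variant_keys()
        if len(set(keys)) != len(keys):
            raise ContractError("duplicate variant keys")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ContractError("dosage values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) key per variant, in column order."""
        v = self.variants
        return list(zip(v["chrom"], v["pos"].astype(int), v["ref"], v["alt"]))

    def sample_indices(self, sample_subset: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_subset if s not in pos]
        if missing:
            raise SampleLookupError(f"samples absent from matrix: {missing}")
        return np.array([pos[s] for s in sample_subset], dtype=int)

    def take_variants(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
        )

    def take_samples(self, sample_subset: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_subset)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.reset_index(drop=True),
            dosage=self.dosage[idx, :].copy(),
        )


@dataclass
class ConcordanceReport:
    """Callset-vs-gold-standard genotype concordance summary.

    ``fdr``: fraction of assayed calls contradicting the gold standard.
    ``fnr``: fraction of gold-standard variants missed by the callset.
    Either is NaN (``*_defined`` False) when its denominator is empty.
    """

    n_calls: int
    n_truth: int
    n_matching: int
    fdr: float
    fnr: float
    fdr_defined: bool = True
    fnr_defined: bool = True


def make_variant_table(
    chrom: Iterable,
    pos: Iterable[int],
    ref: Iterable[str],
    alt: Iterable[str],
    functional_class: Iterable[str] | None = None,
    known_flag: Iterable[bool] | None = None,
    rsid: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble a validated variant table (chrom names normalized)."""
    table = pd.DataFrame(
        {
            "chrom": [normalize_chrom(c) for c in chrom],
            "pos": np.asarray(list(pos), dtype=np.int64),
            "ref": list(ref),
            "alt": list(alt),
        }
    )
    n = len(table)
    table["functional_class"] = (
        list(functional_class) if functional_class is not None else ["other"] * n
    )
    bad = set(table["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if bad:
        raise ContractError(f"unknown functional classes: {sorted(bad)}")
    table["known_flag"] = (
        np.asarray(list(known_flag), dtype=bool) if known_flag is not None
        else np.zeros(n, dtype=bool)
    )
    if rsid is not None:
        table["rsid"] = list(rsid)
    return table


def make_panel(
    samples: Sequence[str],
    populations: Sequence[str],
    latitude: Sequence[float] | None = None,
    longitude: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assemble a validated sample panel (sample -> population [+ coords])."""
    panel = pd.DataFrame({"sample": list(samples), "population": list(populations)})
    if panel["sample"].duplicated().any():
        raise ContractError("duplicate sample ids in panel")
    panel["latitude"] = np.nan if latitude is None else np.asarray(latitude, float)
    panel["longitude"] = np.nan if longitude is None else np.asarray(longitude, float)
    lat = panel["latitude"].dropna()
    lon = panel["longitude"].dropna()
    if ((lat < -90) | (lat > 90)).any():
        raise ContractError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ContractError("longitude outside [-180, 180]")
    return panel


def panel_samples(panel: pd.DataFrame, population: str) -> list[str]:
    """Samples belonging to one population label."""
    sub = panel.loc[panel["population"] == population, "sample"]
    if sub.empty:
        raise SampleLookupError(f"population {population!r} absent from panel")
    return list(sub)


# ---------------------------------------------------------------------------
# per-variant operations


def allele_count(
    matrix: GenotypeMatrix,
    variant: int | tuple,
    sample_subset: Sequence[str] | None = None,
) -> AlleleCount:
    """Alternate-allele count of one variant within a sample subset.

    Missing genotypes are excluded: each non-missing diploid genotype
    contributes 2 to ``total``. An all-missing subset yields the degenerate
    count (0, 0).
    """
    if isinstance(variant, tuple):
        keys = matrix.variant_keys()
        try:
            j = keys.index(variant)
        except ValueError:
            raise SampleLookupError(f"variant {variant} absent from matrix")
    else:
        j = int(variant)
    if sample_subset is None:
        rows = matrix.dosage[:, j]
    else:
        if len(sample_subset) == 0:
            raise ContractError("empty sample subset")
        rows = matrix.dosage[matrix.sample_indices(sample_subset), j]
    called = rows != MISSING
    if not called.any():
        return AlleleCount(0, 0, degenerate=True)
    return AlleleCount(int(rows[called].sum()), int(2 * called.sum()))


def allele_counts_array(
    matrix: GenotypeMatrix, sample_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (alt, total) counts over all variants for a sample subset."""
    d = matrix.dosage if sample_subset is None else (
        matrix.dosage[matrix.sample_indices(sample_subset), :]
    )
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=0).astype(np.int64)
    total = 2 * called.sum(axis=0).astype(np.int64)
    return alt, total


def code_genotypes(matrix: GenotypeMatrix) -> np.ndarray:
    """Code dosages for structure analyses: 1 hom-ref, 2 het, 3 hom-alt.

    The coding has no missing state; submit a matrix with missingness
    filtered out (see :func:`drop_missing_variants`).
    """
    if (matrix.dosage == MISSING).any():
        raise ContractError(
            "coded matrices admit no missing genotypes; drop variants with "
            "missingness first (drop_missing_variants)"
        )
    return matrix.dosage.astype(np.int16) + 1


def drop_missing_variants(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove every variant with at least one missing genotype."""
    keep = ~(matrix.dosage == MISSING).any(axis=0)
    return matrix.take_variants(np.flatnonzero(keep))


def filter_biallelic_autosomal(
    matrix: GenotypeMatrix,
    table: pd.DataFrame,
    chrom_whitelist: Sequence[str] | None = None,
    normalize: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Restrict a matrix/table pair to whitelisted (autosomal) chromosomes.

    With ``normalize`` (default) both sides are compared on dialect-normalized
    names, so "chr1" and "1" match. With ``normalize=False`` a whitelist that
    matches nothing literally but would match after normalization raises,
    pointing at the dialect mismatch rather than silently emptying the data.
    """
    if chrom_whitelist is None:
        chrom_whitelist = autosome_whitelist()
    chroms = table["chrom"].astype(str)
    if normalize:
        wl = {normalize_chrom(c) for c in chrom_whitelist}
        keep = chroms.map(normalize_chrom).isin(wl).to_numpy()
    else:
        wl = set(map(str, chrom_whitelist))
        keep = chroms.isin(wl).to_numpy()
        if not keep.any():
            wl_norm = {normalize_chrom(c) for c in wl}
            if chroms.map(normalize_chrom).isin(wl_norm).any():
                raise SampleLookupError(
                    "chromosome naming dialect mismatch between whitelist and "
                    "data; pass normalize=True or harmonize names"
                )
    if not keep.any():
        warnings.warn(
            "chromosome filter removed every variant", DegenerateDataWarning
        )
    idx = np.flatnonzero(keep)
    return matrix.take_variants(idx), table.iloc[idx].reset_index(drop=True)


def concordance(
    call_genotypes: Mapping[tuple, int],
    truth_genotypes: Mapping[tuple, int],
) -> ConcordanceReport:
    """Genotype concordance of a callset against a gold standard.

    Both mappings are keyed by (sample, chrom, pos, ref, alt) with values in
    {0, 1, 2}. The truth mapping defines the assayed sites (a value of 0
    means assayed hom-ref). A call is true iff its site was assayed and the
    unphased genotype matches; truth variants (value > 0) without a matching
    call count toward the false-negative rate, whether or not the caller
    assayed them.
    """
    calls = {k: g for k, g in call_genotypes.items() if g > 0}
    truth_vars = {k: g for k, g in truth_genotypes.items() if g > 0}
    assayed_calls = {k: g for k, g in calls.items() if k in truth_genotypes}
    n_matching = sum(1 for k, g in assayed_calls.items() if truth_genotypes[k] == g)
    if assayed_calls:
        fdr = (len(assayed_calls) - n_matching) / len(assayed_calls)
        fdr_defined = True
    else:
        fdr, fdr_defined = float("nan"), False
    if truth_vars:
        missed = sum(1 for k, g in truth_vars.items() if call_genotypes.get(k) != g)
        fnr = missed / len(truth_vars)
        fnr_defined = True
    else:
        fnr, fnr_defined = float("nan"), False
    return ConcordanceReport(
        n_calls=len(calls),
        n_truth=len(truth_vars),
        n_matching=n_matching,
        fdr=fdr,
        fnr=fnr,
        fdr_defined=fdr_defined,
        fnr_defined=fnr_defined,
    )


def genotype_mapping(
    matrix: GenotypeMatrix, include_hom_ref: bool = False
) -> dict[tuple, int]:
    """Flatten a matrix into the (sample, chrom, pos, ref, alt) -> dosage
    mapping consumed by :func:`concordance`. Missing genotypes are dropped."""
    out: dict[tuple, int] = {}
    keys = matrix.variant_keys()
    if include_hom_ref:
        wanted = matrix.dosage != MISSING
    else:
        wanted = matrix.dosage > 0
    for i, s in enumerate(matrix.samples):
        for j in np.flatnonzero(wanted[i]):
            out[(s, *keys[j])] = int(matrix.dosage[i, j])
    return out
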