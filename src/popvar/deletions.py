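"""Deletion-callset algebra.

Per-sample deletion calls (0-based half-open intervals) are size-filtered,
merged across samples into non-redundant sites by reciprocal overlap,
flagged novel against reference callsets, validated in silico by counting
heterozygous SNPs of carrier samples inside each site (a real deletion
cannot contain a het call in a carrier), and summarised as deleted-allele
frequencies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .variants import normalize_chrom

#: size bounds (strict) for a usable deletion call, in bp
MIN_DELETION_SIZE = 50
MAX_DELETION_SIZE = 100_000


@dataclass(frozen=True, order=True)
class DeletionCall:
    """One deletion call: 0-based half-open [start, end) on chrom, from a
    sample or callset label, with optional deleted-allele dosage genotype
    and an external-genotyper success flag."""

    chrom: str
    start: int
    end: int
    sample: str
    genotype: int | None = field(default=None, compare=False)
    genotyped: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ContractError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MergedSite:
    """A non-redundant deletion site: the representative interval (first
    member call in canonical sort order), its member calls and carrier
    samples, plus novelty and het-SNP validation annotations filled in by
    the downstream operations."""

    chrom: str
    start: int
    end: int
    members: tuple[DeletionCall, ...]
    novel: bool | None = None
    het_snp_count: int | None = None

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(sorted({m.sample for m in self.members}))

    @property
    def genotyped(self) -> bool:
        """Site counts as genotyped when any member call was successfully
        genotyped by the external genotyper."""
        return any(m.genotyped for m in self.members)

    @property
    def length(self) -> int:
        return self.end - self.start


def size_filter(
    calls: Iterable[DeletionCall],
    min_size: int = MIN_DELETION_SIZE,
    max_size: int = MAX_DELETION_SIZE,
) -> list[DeletionCall]:
    """Keep calls strictly longer than ``min_size`` and strictly shorter
    than ``max_size``."""
    return [c for c in calls if min_size < c.length < max_size]


def reciprocal_overlap(a: DeletionCall | tuple, b: DeletionCall | tuple) -> float:
    """Reciprocal overlap fraction min(o/len(a), o/len(b)) in [0, 1];
    0 across chromosomes."""
    ca, sa, ea = _as_interval(a)
    cb, sb, eb = _as_interval(b)
    if ea <= sa or eb <= sb:
        raise ContractError("zero-length interval")
    if ca != cb:
        return 0.0
    o = min(ea, eb) - max(sa, sb)
    if o <= 0:
        return 0.0
    return min(o / (ea - sa), o / (eb - sb))


def _as_interval(x) -> tuple[str, int, int]:
    if isinstance(x, (DeletionCall, MergedSite)):
        return x.chrom, x.start, x.end
    chrom, start, end = x[0], int(x[1]), int(x[2])
    return normalize_chrom(chrom), start, end


def merge_callsets(
    callsets: Iterable[DeletionCall] | Iterable[Iterable[DeletionCall]],
    threshold: float = 0.8,
) -> list[MergedSite]:
    """Merge deletion calls across samples into non-redundant sites.

    Calls whose reciprocal overlap is >= ``threshold`` are joined by
    single-linkage (transitive closure). To keep chained clusters honest,
    each connected component is then split greedily: the first call in
    (chrom, start, end, sample) sort order seeds a site that absorbs every
    component member overlapping it >= threshold; the remainder re-seeds.
    Every emitted site therefore has all members at >= threshold overlap
    with its representative, the representative interval is the seed's, and
    the output is deterministic under permutation of the input. Re-merging
    an already merged set reproduces it (site representatives of one
    component pairwise overlap < threshold by construction).
    """
    calls = _flatten(callsets)
    calls.sort()
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # sweep: calls sorted by (chrom, start); a qualifying partner overlaps,
    # so only compare while the candidate's start precedes the current end
    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(calls):
        by_chrom.setdefault(c.chrom, []).append(i)
    for idx in by_chrom.values():
        active: list[int] = []
        for i in idx:
            ci = calls[i]
            active = [j for j in active if calls[j].end > ci.start]
            for j in active:
                if reciprocal_overlap(calls[j], ci) >= threshold:
                    union(i, j)
            active.append(i)
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)
    sites: list[MergedSite] = []
    for root in sorted(components):
        pending = sorted(components[root])  # index order == sort order
        while pending:
            seed = calls[pending[0]]
            member_idx = [
                i for i in pending
                if reciprocal_overlap(seed, calls[i]) >= threshold
            ]
            sites.append(
                MergedSite(
                    chrom=seed.chrom,
                    start=seed.start,
                    end=seed.end,
                    members=tuple(calls[i] for i in member_idx),
                )
            )
            taken = set(member_idx)
            pending = [i for i in pending if i not in taken]
    sites.sort(key=lambda s: (s.chrom, s.start, s.end))
    return sites


def _flatten(callsets) -> list[DeletionCall]:
    out: list[DeletionCall] = []
    for item in callsets:
        if isinstance(item, DeletionCall):
            out.append(item)
        else:
            out.extend(item)
    return out


def novelty_filter(
    sites: Sequence[MergedSite],
    reference_callsets: Iterable,
    threshold: float = 0.5,
) -> list[MergedSite]:
    """Flag each site known/novel against reference callsets.

    A site is known iff its reciprocal overlap with ANY reference interval is
    strictly greater than ``threshold``; otherwise novel. Reference entries
    may be DeletionCalls or (chrom, start, end) tuples. Returns new sites
    with ``novel`` set.
    """
    refs: dict[str, list[tuple[int, int]]] = {}
    for r in _flatten_intervals(reference_callsets):
        chrom, start, end = r
        refs.setdefault(chrom, []).append((start, end))
    ref_arrays = {
        c: (
            np.array([s for s, _ in iv], dtype=np.int64),
            np.array([e for _, e in iv], dtype=np.int64),
        )
        for c, iv in refs.items()
    }
    out = []
    for site in sites:
        known = False
        if site.chrom in ref_arrays:
            rs, re = ref_arrays[site.chrom]
            o = np.minimum(re, site.end) - np.maximum(rs, site.start)
            pos = o > 0
            if pos.any():
                ro = np.minimum(
                    o[pos] / (re[pos] - rs[pos]), o[pos] / site.length
                )
                known = bool((ro > threshold).any())
        out.append(replace_site(site, novel=not known))
    return out


def _flatten_intervals(reference_callsets) -> list[tuple[str, int, int]]:
    out = []
    for item in reference_callsets:
        if isinstance(item, (DeletionCall, MergedSite)):
            out.append((item.chrom, item.start, item.end))
        elif (
            isinstance(item, (tuple, list))
            and len(item) >= 3
            and isinstance(item[1], (int, np.integer))
        ):
            out.append(_as_interval(item))
        else:
            out.extend(_flatten_intervals(item))
    return out


def replace_site(site: MergedSite, **kw) -> MergedSite:
    return replace(site, **kw)


def het_snp_validation(
    sites: Sequence[MergedSite],
    het_sites: pd.DataFrame,
) -> tuple[list[MergedSite], dict[str, float]]:
    """Count heterozygous SNPs of carrier samples inside each site.

    ``het_sites`` has columns ``sample``, ``chrom``, ``pos`` with 1-based
    positions (converted to 0-based for half-open containment). A site
    passes validation when its count is zero. Returns annotated sites and a
    summary with the fractions of sites carrying zero and exactly one het
    SNP.
    """
    index: dict[tuple[str, str], np.ndarray] = {}
    for (sample, chrom), grp in het_sites.groupby(["sample", "chrom"]):
        pos0 = np.sort(grp["pos"].to_numpy(np.int64) - 1)
        index[(sample, normalize_chrom(chrom))] = pos0
    out = []
    for site in sites:
        count = 0
        for carrier in site.carriers:
            pos0 = index.get((carrier, site.chrom))
            if pos0 is None:
                continue
            lo = np.searchsorted(pos0, site.start, side="left")
            hi = np.searchsorted(pos0, site.end, side="left")
            count += int(hi - lo)
        out.append(replace_site(site, het_snp_count=count))
    n = len(out)
    counts = np.array([s.het_snp_count for s in out], dtype=int)
    summary = {
        "n_sites": n,
        "fraction_zero_het": float((counts == 0).mean()) if n else float("nan"),
        "fraction_one_het": float((counts == 1).mean()) if n else float("nan"),
    }
    return out, summary


def genotyped_filter(sites: Sequence) -> list:
    """Keep only calls/sites flagged as successfully genotyped by the
    external genotyper; order preserved."""
    return [s for s in sites if s.genotyped]


def deletion_frequency(site: MergedSite, n_genotyped_samples: int) -> float:
    """Deleted-allele frequency of a merged site.

    Sum of deleted-allele dosages over genotyped member calls divided by
    2 x ``n_genotyped_samples`` (the cohort size successfully genotyped at
    the site). Raises when no genotyped carrier remains — such a site should
    have been filtered out.
    """
    gts = [
        m.genotype for m in site.members if m.genotyped and m.genotype
    ]
    if not gts:
        raise ContractError(
            f"site {site.chrom}:{site.start}-{site.end} has no genotyped "
            "carriers"
        )
    if n_genotyped_samples <= 0:
        raise ContractError("n_genotyped_samples must be positive")
    return sum(gts) / (2 * n_genotyped_samples)


# ---------------------------------------------------------------------------
# BED interchange


def read_bed_callset(path: str | os.PathLike) -> list[DeletionCall]:
    """Read a BED4(+2) deletion callset:
    `chrom  start  end  sample  [genotype  genotyped_flag]`."""
    calls = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ContractError(
                    f"{path}:{line_no}: expected >= 4 BED columns"
                )
            genotype = int(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            genotyped = parts[5] == "1" if len(parts) > 5 else True
            calls.append(
                DeletionCall(
                    chrom=normalize_chrom(parts[0]),
                    start=int(parts[1]),
                    end=int(parts[2]),
                    sample=parts[3],
                    genotype=genotype,
                    genotyped=genotyped,
                )
            )
    return calls


def write_bed_callset(
    path: str | os.PathLike, calls: Iterable[DeletionCall]
) -> None:
    with open(path, "w") as fh:
        for c in calls:
            g = "." if c.genotype is None else str(c.genotype)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample}\t{g}\t"
                f"{1 if c.genotyped else 0}\n"
            )


def read_bed3(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read a reference callset as BED3 intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((normalize_chrom(parts[0]), int(parts[1]), int(parts[2])))
    return out


def write_bed3(
    path: str | os.PathLike, intervals: Iterable[tuple[str, int, int]]
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def sites_to_frame(sites: Sequence[MergedSite]) -> pd.DataFrame:
    """Tabular summary of merged sites for TSV output."""
    rows = []
    for s in sites:
        rows.append(
            (
                s.chrom,
                s.start,
                s.end,
                s.length,
                len(s.members),
                ",".join(s.carriers),
                "" if s.novel is None else ("novel" if s.novel else "known"),
                "" if s.het_snp_count is None else s.het_snp_count,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "n_calls", "carriers",
            "novelty", "het_snp_count",
        ],
    )
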