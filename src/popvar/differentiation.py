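"""Allele-frequency differentiation scan over a SNP panel.

Per-population and pooled-group allele frequencies for a list of SNPs (e.g.
GWAS-catalogue hits), the absolute frequency difference between a focal
population and a comparison group, and upper-tail percentile outlier
detection on those differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDataWarning
from .variants import GenotypeMatrix, allele_counts_array, panel_samples


@dataclass
class FrequencyTable:
    """Variant x population (and pooled group) allele-frequency table.

    ``alt`` / ``total`` are DataFrames indexed by variant row with one column
    per population; group columns are count-pooled over member populations,
    so a group frequency is sum(alt) / sum(total), not a mean of member
    frequencies.
    """

    variants: pd.DataFrame
    alt: pd.DataFrame
    total: pd.DataFrame
    groups: dict[str, list[str]] = field(default_factory=dict)
    unresolved: pd.DataFrame | None = None

    def frequency(self, column: str) -> pd.Series:
        """Allele frequency for a population or group column (NaN where no
        chromosome was called)."""
        if column in self.alt.columns:
            alt, tot = self.alt[column], self.total[column]
        elif column in self.groups:
            pops = self.groups[column]
            alt = self.alt[pops].sum(axis=1)
            tot = self.total[pops].sum(axis=1)
        else:
            raise ContractError(f"unknown population or group {column!r}")
        return alt / tot.replace(0, np.nan)

    def group_counts(self, column: str) -> tuple[pd.Series, pd.Series]:
        if column in self.alt.columns:
            return self.alt[column], self.total[column]
        pops = self.groups[column]
        return self.alt[pops].sum(axis=1), self.total[pops].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.variants.copy()
        for col in self.alt.columns:
            out[f"f_{col}"] = self.frequency(col).to_numpy()
        for g in self.groups:
            out[f"f_{g}"] = self.frequency(g).to_numpy()
        return out


@dataclass
class DiffScanResult:
    """Outcome of the percentile outlier scan on |delta f|."""

    diffs: pd.Series
    threshold: float
    top_percentile: float
    outliers: pd.Index

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"abs_diff": self.diffs})
        out["outlier"] = out.index.isin(self.outliers)
        return out


def population_frequencies(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    snp_list: pd.DataFrame | None = None,
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> FrequencyTable:
    """Per-population (and pooled-group) allele frequencies.

    ``snp_list`` (optional) restricts rows to the listed SNPs, matched by
    (chrom, pos); unmatched entries are recorded in ``unresolved`` rather
    than raised. ``grouping`` maps group name -> member populations; group
    counts are pooled sums over members.
    """
    pops = list(dict.fromkeys(panel["population"]))
    grouping = dict(grouping or {})
    for g, members in grouping.items():
        if len(members) == 0:
            raise ContractError(f"group {g!r} has no member populations")
        unknown = set(members) - set(pops)
        if unknown:
            raise ContractError(f"group {g!r} has unknown members {unknown}")
    variants = matrix.variants.copy()
    unresolved = None
    if snp_list is not None:
        key = pd.MultiIndex.from_frame(
            variants[["chrom", "pos"]].astype({"pos": np.int64})
        )
        wanted = pd.MultiIndex.from_frame(
            snp_list[["chrom", "pos"]].astype({"pos": np.int64})
        )
        locator = pd.Series(np.arange(len(variants)), index=key)
        hit = wanted.isin(key)
        unresolved = snp_list.loc[~hit].reset_index(drop=True)
        idx = locator.loc[wanted[hit]].to_numpy()
        matrix = matrix.take_variants(idx)
        variants = snp_list.loc[hit].reset_index(drop=True)
    alt_cols, tot_cols = {}, {}
    for pop in pops:
        alt, tot = allele_counts_array(matrix, panel_samples(panel, pop))
        alt_cols[pop] = alt
        tot_cols[pop] = tot
    return FrequencyTable(
        variants=variants.reset_index(drop=True),
        alt=pd.DataFrame(alt_cols),
        total=pd.DataFrame(tot_cols),
        groups={g: list(m) for g, m in grouping.items()},
        unresolved=unresolved,
    )


def abs_freq_diff(
    table: FrequencyTable, focal_group: str, comparison_group: str
) -> pd.Series:
    """Per-variant |f_focal - f_comparison|.

    Variants with zero called chromosomes in either group are excluded (and
    absent from the returned series).
    """
    fa, ta = table.group_counts(focal_group)
    fb, tb = table.group_counts(comparison_group)
    ok = (ta > 0) & (tb > 0)
    diff = (fa[ok] / ta[ok] - fb[ok] / tb[ok]).abs()
    diff.name = "abs_diff"
    return diff


def outlier_scan(
    diffs: pd.Series | np.ndarray, top_percentile: float = 0.1
) -> DiffScanResult:
    """Upper-tail percentile outlier scan on |delta f| values.

    The threshold is the (100 - top_percentile)-th percentile of the values
    (linear-interpolation quantile); outliers lie strictly above it. With
    fewer than 1000 values the tail quantile is poorly determined and a
    warning is emitted.
    """
    s = pd.Series(diffs).astype(float)
    if len(s) == 0:
        raise ContractError("empty |delta f| vector")
    if len(s) < 1000:
        warnings.warn(
            f"percentile threshold on only {len(s)} values is unstable",
            DegenerateDataWarning,
        )
    threshold = float(np.quantile(s.to_numpy(), 1.0 - top_percentile / 100.0))
    outliers = s.index[s > threshold]
    return DiffScanResult(
        diffs=s,
        threshold=threshold,
        top_percentile=top_percentile,
        outliers=outliers,
    )


def diff_histogram(
    diffs: pd.Series | np.ndarray, n_bins: int = 50
) -> pd.DataFrame:
    """Binned histogram of |delta f| on [0, 1], as a plain table."""
    counts, edges = np.histogram(np.asarray(diffs, float), bins=n_bins,
                                 range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
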