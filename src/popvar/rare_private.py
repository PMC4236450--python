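"""Sharing-class classification of focal-population variants and
non-synonymous enrichment testing.

A focal-population variant falls in exactly one class by its alternate-allele
counts in the focal sample and in all other populations pooled:

- ``monomorphic``: no alternate allele in the focal sample;
- ``shared``: alternate allele also present outside the focal population;
- ``rare``: exactly one focal chromosome, absent elsewhere (a strict
  population-confined singleton);
- ``low_count_private``: 2-3 focal chromosomes, absent elsewhere;
- ``private``: more than 3 focal chromosomes, absent elsewhere.

Enrichment of non-synonymous vs synonymous labels between two strata is
tested with a Yates-corrected chi-square on the 2x2 table. Two singleton
predicates are exposed because the field uses both: ``rare_strict``
(singleton AND absent elsewhere) and ``singleton`` (focal singleton
regardless of other populations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ContractError
from .variants import AlleleCount, GenotypeMatrix, allele_counts_array

SHARING_CLASSES = (
    "monomorphic",
    "shared",
    "rare",
    "low_count_private",
    "private",
)


@dataclass
class EnrichmentResult:
    """2x2 nonsynonymous/synonymous table with its Yates-corrected
    chi-square statistic and 1-df p-value."""

    table: np.ndarray  # rows: strata; cols: (nonsynonymous, synonymous)
    statistic: float
    p_value: float
    stratum_names: tuple[str, str] = ("a", "b")


def classify_sharing(focal: AlleleCount, others: AlleleCount) -> str:
    """Sharing class of one variant from focal and pooled-other counts."""
    if focal.alt == 0:
        return "monomorphic"
    if others.alt > 0:
        return "shared"
    if focal.alt == 1:
        return "rare"
    if focal.alt > 3:
        return "private"
    return "low_count_private"


def classify_all(
    matrix: GenotypeMatrix, panel: pd.DataFrame, focal_population: str
) -> pd.Series:
    """Vectorized sharing class for every variant in the matrix."""
    focal_samples = list(
        panel.loc[panel["population"] == focal_population, "sample"]
    )
    other_samples = list(
        panel.loc[panel["population"] != focal_population, "sample"]
    )
    if not focal_samples:
        raise ContractError(f"no samples in focal population {focal_population!r}")
    f_alt, _ = allele_counts_array(matrix, focal_samples)
    o_alt, _ = allele_counts_array(matrix, other_samples) if other_samples else (
        np.zeros_like(f_alt), None,
    )
    out = np.full(matrix.n_variants, "shared", dtype=object)
    out[f_alt == 0] = "monomorphic"
    confined = (f_alt > 0) & (o_alt == 0)
    out[confined & (f_alt == 1)] = "rare"
    out[confined & (f_alt > 1) & (f_alt <= 3)] = "low_count_private"
    out[confined & (f_alt > 3)] = "private"
    return pd.Series(out, name="sharing_class")


def stratum_mask(
    classes: pd.Series,
    table: pd.DataFrame,
    name: str,
    matrix: GenotypeMatrix | None = None,
    panel: pd.DataFrame | None = None,
    focal_population: str | None = None,
) -> np.ndarray:
    """Boolean mask for a named variant stratum.

    Supported names: any single sharing class; ``rare_strict`` (alias of
    ``rare``); ``singleton`` (focal alt count exactly 1, other populations
    ignored — needs matrix/panel/focal_population); ``novel_rare`` (rare and
    not known); ``all`` (everything polymorphic in the focal sample);
    ``non_rare`` (polymorphic, not rare).
    """
    cls = classes.to_numpy()
    poly = cls != "monomorphic"
    if name in SHARING_CLASSES:
        return cls == name
    if name == "rare_strict":
        return cls == "rare"
    if name == "novel_rare":
        return (cls == "rare") & ~table["known_flag"].to_numpy()
    if name == "all":
        return poly
    if name == "non_rare":
        return poly & (cls != "rare")
    if name == "singleton":
        if matrix is None or panel is None or focal_population is None:
            raise ContractError(
                "stratum 'singleton' needs matrix, panel and focal_population"
            )
        focal_samples = list(
            panel.loc[panel["population"] == focal_population, "sample"]
        )
        f_alt, _ = allele_counts_array(matrix, focal_samples)
        return f_alt == 1
    raise ContractError(f"unknown stratum {name!r}")


def enrichment_table(
    variant_table: pd.DataFrame,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    stratum_names: tuple[str, str] = ("a", "b"),
) -> np.ndarray:
    """2x2 table of (nonsynonymous, synonymous) counts for two strata.

    Variants with functional class "other" are excluded. Raises when a
    stratum is empty or a functional column is zero everywhere (the test is
    undefined on degenerate tables).
    """
    fc = variant_table["functional_class"].to_numpy()
    rows = []
    for name, mask in zip(stratum_names, (mask_a, mask_b)):
        if not np.asarray(mask).any():
            raise ContractError(f"stratum {name!r} is empty")
        rows.append(
            [
                int(((fc == "nonsynonymous") & mask).sum()),
                int(((fc == "synonymous") & mask).sum()),
            ]
        )
    table = np.array(rows, dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ContractError(
            f"degenerate 2x2 table (zero margin): {table.tolist()}"
        )
    return table


def chi_square_yates(table: np.ndarray) -> EnrichmentResult:
    """Yates-corrected chi-square test of association on a 2x2 table.

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), floored at 0 when
    |ad - bc| <= N/2; p from the chi-square survival function with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ContractError("chi_square_yates expects a 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ContractError("zero margin in 2x2 table")
    excess = abs(a * d - b * c) - n / 2.0
    stat = 0.0 if excess <= 0 else n * excess**2 / margins
    p = float(chi2.sf(stat, df=1))
    return EnrichmentResult(
        table=np.asarray(table, dtype=np.int64), statistic=float(stat), p_value=p
    )


def enrichment_test(
    variant_table: pd.DataFrame,
    classes: pd.Series,
    stratum_a: str,
    stratum_b: str,
    **stratum_kwargs,
) -> EnrichmentResult:
    """Convenience: build the 2x2 table for two named strata and test it."""
    ma = stratum_mask(classes, variant_table, stratum_a, **stratum_kwargs)
    mb = stratum_mask(classes, variant_table, stratum_b, **stratum_kwargs)
    table = enrichment_table(
        variant_table, ma, mb, stratum_names=(stratum_a, stratum_b)
    )
    result = chi_square_yates(table)
    result.stratum_names = (stratum_a, stratum_b)
    return result
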