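"""Nucleotide diversity (pi).

Per-site pi is the unbiased heterozygosity estimator
``(n / (n - 1)) * 2 * p * (1 - p)`` with ``n`` the number of called
chromosomes and ``p`` the alternate-allele frequency; it equals the mean
pairwise difference over all C(n, 2) chromosome pairs. Genome-wide pi for a
population is the per-site sum over its variable sites divided by the summed
ungapped chromosome lengths. Sites with any missing genotype in the focal
population are dropped from that population's sum, and no Hardy-Weinberg
filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .variants import (
    MISSING,
    AlleleCount,
    GenotypeMatrix,
    normalize_chrom,
    panel_samples,
)


@dataclass
class PiSummary:
    population: str
    sum_site_pi: float
    ungapped_length: int
    n_sites_used: int

    @property
    def genome_pi(self) -> float:
        return self.sum_site_pi / self.ungapped_length


def site_pi(count: AlleleCount) -> float:
    """Unbiased per-site nucleotide diversity from an allele count."""
    n = count.total
    if n < 2:
        raise ContractError(f"site pi undefined for {n} called chromosomes")
    p = count.alt / n
    return (n / (n - 1)) * 2.0 * p * (1.0 - p)


def _site_pi_vector(alt: np.ndarray, total: np.ndarray) -> np.ndarray:
    n = total.astype(float)
    p = np.divide(alt, n, out=np.zeros_like(n), where=n > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
    pi[n < 2] = 0.0
    return pi


def genome_pi(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    population: str,
    ungapped_lengths: Mapping[str, int],
) -> PiSummary:
    """Genome-wide pi for one population.

    Monomorphic sites contribute 0; sites with any missing genotype in the
    population are excluded. ``ungapped_lengths`` maps chromosome name to
    ungapped length in bp; its sum is the denominator.
    """
    samples = panel_samples(panel, population)
    d = matrix.dosage[matrix.sample_indices(samples), :]
    complete = ~(d == MISSING).any(axis=0)
    alt = np.where(d == MISSING, 0, d).sum(axis=0).astype(np.int64)
    total = np.full(matrix.n_variants, 2 * len(samples), dtype=np.int64)
    pi = _site_pi_vector(alt, total)
    pi[~complete] = 0.0
    length = sum(int(v) for v in ungapped_lengths.values())
    if length <= 0:
        raise ContractError("total ungapped length must be positive")
    variable = complete & (alt > 0) & (alt < total)
    return PiSummary(
        population=population,
        sum_site_pi=float(pi[variable].sum()),
        ungapped_length=length,
        n_sites_used=int(variable.sum()),
    )


def pi_by_population(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    ungapped_lengths: Mapping[str, int],
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-population pi table (one :func:`genome_pi` row per population)."""
    pops = (
        list(populations)
        if populations is not None
        else list(dict.fromkeys(panel["population"]))
    )
    rows = []
    for pop in pops:
        s = genome_pi(matrix, panel, pop, ungapped_lengths)
        rows.append(
            (pop, s.n_sites_used, s.sum_site_pi, s.ungapped_length, s.genome_pi)
        )
    return pd.DataFrame(
        rows,
        columns=["population", "n_sites", "sum_site_pi", "ungapped_length", "pi"],
    )
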