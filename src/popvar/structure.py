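"""Population-structure pipeline.

Stages, in the order a typical run applies them: the subset-polymorphism
filter (a SNP must be polymorphic within a fixed-size random subset of every
population, curbing ascertainment bias toward the largest panels), sliding-
window LD pruning, PCA on the 1/2/3-coded genotype matrix, individual-level
genetic and geographic distance matrices, a permutation Mantel test of their
association, and neighbor-joining trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDataWarning, SampleLookupError
from .variants import GenotypeMatrix, allele_counts_array, panel_samples

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labelled rows/columns."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ContractError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ContractError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ContractError("negative distances")
        if not np.allclose(np.diag(v), 0):
            raise ContractError("nonzero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PcaResult:
    """PCA scores (samples x components) and per-component explained
    variance fractions (non-increasing, summing to <= 1)."""

    sample_ids: list[str]
    scores: np.ndarray
    explained_fraction: np.ndarray
    degenerate: bool = False


def subset_polymorphic_filter(
    matrix: GenotypeMatrix,
    panel: pd.DataFrame,
    subset_size: int = 16,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Keep variants polymorphic within a random subset of every population.

    From each population a subset of ``subset_size`` samples is drawn without
    replacement (populations smaller than the subset size are used whole). A
    variant survives iff ``0 < alt_count < total_count`` within every subset.
    Returns the filtered matrix and the chosen subsets.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pops = list(dict.fromkeys(panel["population"]))
    subsets: dict[str, list[str]] = {}
    keep = np.ones(matrix.n_variants, dtype=bool)
    for pop in pops:
        samples = panel_samples(panel, pop)
        if len(samples) == 0:
            raise SampleLookupError(f"population {pop!r} has no samples")
        if len(samples) > subset_size:
            chosen = sorted(
                rng.choice(len(samples), size=subset_size, replace=False)
            )
            samples = [samples[i] for i in chosen]
        subsets[pop] = samples
        alt, total = allele_counts_array(matrix, samples)
        keep &= (alt > 0) & (alt < total)
    return matrix.take_variants(np.flatnonzero(keep)), subsets


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation between dosage columns; zero-variance
    columns correlate 0 with everything."""
    x = d.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    x[:, ok] = x[:, ok] / sd[ok]
    x[:, ~ok] = 0.0
    r = (x.T @ x) / x.shape[0]
    return r * r


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Sliding-window LD pruning of a complete (no-missing) dosage matrix.

    Within each window of ``window`` currently retained variants (per
    chromosome, position order), while any pair exceeds ``r2_max`` the later
    variant of the first offending pair is removed; the window then advances
    by ``step``. Returns the retained variant indices (original order).
    """
    if (matrix.dosage < 0).any():
        raise ContractError("ld_prune requires a matrix without missing data")
    chroms = matrix.variants["chrom"].to_numpy()
    order = np.lexsort(
        (matrix.variants["pos"].to_numpy(), chroms)
    )  # position within chromosome
    retained: list[int] = []
    for chrom in dict.fromkeys(chroms[order]):
        idx = [int(i) for i in order[chroms[order] == chrom]]
        alive = list(idx)
        start = 0
        while True:
            win = alive[start : start + window]
            if len(win) >= 2:
                removed_any = True
                while removed_any:
                    removed_any = False
                    r2 = _window_r2(matrix.dosage[:, win])
                    m = len(win)
                    for a in range(m):
                        for b in range(a + 1, m):
                            if r2[a, b] > r2_max:
                                # remove the later variant in position order
                                alive.remove(win[b])
                                win.pop(b)
                                removed_any = True
                                break
                        if removed_any:
                            break
            if start + window >= len(alive):
                # done only once the just-processed window reached the end
                # of the (possibly shrunk) list; otherwise reprocess here
                if not alive or not win or win[-1] == alive[-1]:
                    break
            else:
                start += step
        retained.extend(alive)
    return np.array(sorted(retained), dtype=int)


def pca(coded: np.ndarray, sample_ids: Sequence[str] | None = None) -> PcaResult:
    """PCA of a 1/2/3-coded genotype matrix after scaling to unit variance.

    Columns are centred and scaled (sd with n-1 denominator); zero-variance
    columns are dropped with a warning. Scores come from the SVD of the
    scaled matrix; explained fractions use all non-zero singular values as
    the denominator.
    """
    x = np.asarray(coded, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ContractError("pca needs >= 2 samples and >= 2 variants")
    ids = list(sample_ids) if sample_ids is not None else [
        f"S{i}" for i in range(x.shape[0])
    ]
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} zero-variance columns before PCA",
            DegenerateDataWarning,
        )
    if not usable.any():
        # identical rows: no sample-axis variation at all
        warnings.warn(
            "no variable columns; PCA is degenerate", DegenerateDataWarning
        )
        return PcaResult(
            sample_ids=ids,
            scores=np.zeros((x.shape[0], 1)),
            explained_fraction=np.zeros(1),
            degenerate=True,
        )
    if usable.sum() < 2:
        raise ContractError("fewer than 2 usable (variable) columns for PCA")
    x = x[:, usable] / sd[usable]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps if s.size else 0.0
    nonzero = s > tol
    degenerate = not nonzero.any()
    if degenerate:
        warnings.warn(
            "all singular values are zero (identical rows?)",
            DegenerateDataWarning,
        )
        explained = np.zeros(s.shape)
    else:
        lam = s**2
        explained = np.where(nonzero, lam / lam[nonzero].sum(), 0.0)
    scores = u * s
    return PcaResult(
        sample_ids=ids,
        scores=scores,
        explained_fraction=explained,
        degenerate=degenerate,
    )


def genetic_distance(
    coded: np.ndarray,
    sample_ids: Sequence[str],
    metric: str = "allele_sharing",
) -> DistanceMatrix:
    """Individual-level genetic distance from a coded (or dosage) matrix.

    ``allele_sharing`` (default): mean over variants of |dosage_i -
    dosage_j| / 2, in [0, 1]. ``euclidean``: Euclidean distance on the coded
    rows. The coded 1/2/3 and dosage 0/1/2 scales give identical results
    (the map is a shift).
    """
    from scipy.spatial.distance import pdist, squareform

    x = np.asarray(coded, dtype=float)
    if metric == "allele_sharing":
        d = squareform(pdist(x, metric="cityblock")) / (2.0 * x.shape[1])
    elif metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        raise ContractError(f"unknown genetic distance metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=list(sample_ids), values=d)


def geographic_distance(panel: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sample locations."""
    missing = panel.loc[
        panel["latitude"].isna() | panel["longitude"].isna(), "sample"
    ]
    if len(missing):
        raise ContractError(
            f"samples without coordinates: {list(missing)}"
        )
    lat = np.radians(panel["latitude"].to_numpy(float))
    lon = np.radians(panel["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=list(panel["sample"]), values=d)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    null is built by jointly permuting one matrix's row/column labels;
    p = (#{perm r >= observed} + 1) / (n_perm + 1), one-sided with positive
    association as the alternative.
    """
    if d1.ids != d2.ids:
        raise ContractError("distance matrices must share ids (same order)")
    if n_perm < 99:
        raise ContractError("n_perm must be at least 99")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if x.std() == 0 or d2.values[iu].std() == 0:
        raise ContractError("constant distance matrix; Mantel r undefined")
    xc = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float((xc * (y - y.mean())).mean() / y.std())

    r_obs = corr(d2.values)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou-Nei) as a newick string.

    Q-matrix agglomeration with the standard branch-length formulas; ties in
    Q are broken by the smaller (i, j) pair in input id order, so the result
    is deterministic. Negative inferred branch lengths are clamped to zero
    with a warning; negative input distances are an error. The tree is
    unrooted (trifurcating root node).
    """
    n = len(d.ids)
    if n < 3:
        raise ContractError("nj_tree needs at least 3 taxa")
    if (d.values < 0).any():
        raise ContractError("negative input distances")
    dist = d.values.astype(float).copy()
    labels = [_escape_newick(t) for t in d.ids]
    clamped = False

    def fmt(label: str, length: float) -> str:
        nonlocal clamped
        if length < 0:
            clamped = True
            length = 0.0
        return f"{label}:{length:.17g}"

    active = list(range(n))
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    dmat = {
        (i, j): dist[i, j] for i in range(n) for j in range(n) if i != j
    }
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dmat[(i, k)] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * dmat[(i, j)] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = dmat[(i, j)]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        nodes[u] = f"({fmt(nodes[i], li)},{fmt(nodes[j], lj)})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dmat[(i, k)] + dmat[(j, k)] - dij)
            dmat[(u, k)] = dmat[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    la = 0.5 * (dmat[(a, b)] + dmat[(a, c)] - dmat[(b, c)])
    lb = 0.5 * (dmat[(a, b)] + dmat[(b, c)] - dmat[(a, c)])
    lc = 0.5 * (dmat[(a, c)] + dmat[(b, c)] - dmat[(a, b)])
    newick = (
        f"({fmt(nodes[a], la)},{fmt(nodes[b], lb)},{fmt(nodes[c], lc)});"
    )
    if clamped:
        warnings.warn(
            "negative inferred branch lengths clamped to 0",
            DegenerateDataWarning,
        )
    return newick


def _escape_newick(label: str) -> str:
    if any(ch in label for ch in "(),:; \t"):
        return "'" + label.replace("'", "''") + "'"
    return label
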