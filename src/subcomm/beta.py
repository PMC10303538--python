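"""Beta diversity: Bray–Curtis, PCoA, PERMANOVA, ANOSIM and dispersion
homogeneity, implemented directly from their definitions.

All permutation tests report ``p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm)``
so a p-value of zero is impossible. Group dispersion follows the standard
betadisper treatment: samples are embedded by principal coordinates, squared
distances to the group centroid are the real-axis contribution minus the
imaginary-axis contribution (negative-eigenvalue axes), truncated at zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CommunityTable, DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "bray_curtis", "pcoa", "OrdinationResult",
    "permanova", "anosim", "dispersion_homogeneity", "GroupTestResult",
]


def bray_curtis(table: CommunityTable, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between sample columns.

    ``BC(j,k) = Σ_i |x_ij − x_ik| / Σ_i (x_ij + x_ik)``, computed on raw
    counts by default or on within-sample relative abundances with
    ``relative=True``.
    """
    x = table.relative_abundance() if relative else table.counts
    # vectorised over pairs: |a-b| sums via broadcasting (n_samples is small)
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    tot = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        bc = diff / tot
    np.fill_diagonal(bc, 0.0)
    return DistanceMatrix(list(table.sample_ids), bc)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    ids: list
    axes: np.ndarray  # samples × axes, scaled by sqrt(|eigenvalue|)
    eigenvalues: np.ndarray  # sorted descending, may contain negatives
    imaginary: np.ndarray  # bool per axis: negative-eigenvalue axis
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling (Gower-centred −½D² eigendecomposition).

    All axes are retained; axes from negative eigenvalues (non-Euclidean
    structure) are flagged ``imaginary``. Coordinates are eigenvectors
    scaled by sqrt(|eigenvalue|) and are centred at the origin.
    """
    n = d.n
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval[np.abs(eigval) < 1e-12] = 0.0
    axes = eigvec * np.sqrt(np.abs(eigval))[None, :]
    imaginary = eigval < 0
    pos = eigval[eigval > 0]
    prop = np.where(eigval > 0, eigval / pos.sum() if pos.size else 0.0, 0.0)
    return OrdinationResult(list(d.ids), axes, eigval, imaginary, prop)


@dataclass
class GroupTestResult:
    statistic_name: str
    statistic: float
    n_permutations: int
    p_value: float


def _group_arrays(d: DistanceMatrix, groups) -> np.ndarray:
    groups = np.asarray([str(g) for g in groups])
    if groups.size != d.n:
        raise ValidationError("group labels must match distance matrix samples")
    return groups


def _permanova_f(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    n = d2.shape[0]
    a = sizes.size
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g, ng in enumerate(sizes):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / (a - 1)) / denom


def permanova(d: DistanceMatrix, groups, n_perm: int = 9999,
              seed: int | None = 0) -> GroupTestResult:
    """One-way PERMANOVA (distance-based pseudo-F with label permutation).

    ``SS_total = Σ_{i<j} d²_ij / n``; ``SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g``;
    ``F = [SS_between/(a−1)] / [SS_within/(N−a)]``.
    """
    groups = _group_arrays(d, groups)
    levels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    if levels.size < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if np.any(sizes < 2):
        raise ValidationError("every group needs at least 2 samples")
    d2 = d.values**2
    f_obs = _permanova_f(d2, codes, sizes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        if _permanova_f(d2, perm_codes, sizes) >= f_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return GroupTestResult("pseudo_F", float(f_obs), n_perm, p)


def permanova_exact(d: DistanceMatrix, groups) -> GroupTestResult:
    """PERMANOVA p-value by exhaustive enumeration of label assignments
    (feasible only for very small designs; used as an oracle)."""
    groups = _group_arrays(d, groups)
    levels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    d2 = d.values**2
    f_obs = _permanova_f(d2, codes, sizes)
    n = len(codes)
    hits = total = 0
    for combo in itertools.combinations(range(n), int(sizes[0])):
        perm = np.ones(n, dtype=int)
        perm[list(combo)] = 0
        total += 1
        if _permanova_f(d2, perm, sizes) >= f_obs - 1e-12:
            hits += 1
    return GroupTestResult("pseudo_F", float(f_obs), total, hits / total)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = 0) -> GroupTestResult:
    """ANOSIM: R = (mean between-group rank − mean within-group rank) /
    (n(n−1)/4) on midranked pairwise distances, with label-permutation p."""
    from scipy.stats import rankdata

    groups = _group_arrays(d, groups)
    levels, codes = np.unique(groups, return_inverse=True)
    if levels.size < 2 or np.any(np.bincount(codes) < 2):
        raise ValidationError("ANOSIM needs >=2 groups of >=2 samples")
    n = d.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.values[iu])
    denom = n * (n - 1) / 4.0

    def r_stat(c):
        within = c[iu[0]] == c[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(codes)) >= r_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return GroupTestResult("anosim_R", float(r_obs), n_perm, p)


def dispersion_homogeneity(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = 0,
) -> tuple[pd.DataFrame, GroupTestResult]:
    """Multivariate homogeneity of group dispersions (betadisper analogue).

    Samples are embedded by PCoA; each sample's squared distance to its
    group centroid is the real-axis squared distance minus the
    imaginary-axis squared distance (truncated at zero with a warning). The
    statistic is the one-way ANOVA F on those distances; the p-value
    permutes the distances among groups. Returns the per-sample
    distance-to-centroid table and the test result.
    """
    groups = _group_arrays(d, groups)
    levels, codes = np.unique(groups, return_inverse=True)
    if levels.size < 2:
        raise ValidationError("need at least 2 groups")
    ord_res = pcoa(d)
    real = ord_res.axes[:, ~ord_res.imaginary]
    imag = ord_res.axes[:, ord_res.imaginary]

    z2 = np.empty(d.n)
    for g in range(levels.size):
        idx = np.flatnonzero(codes == g)
        if idx.size == 1:
            logger.warning("dispersion_homogeneity: group %s has a single "
                           "member; its distance is 0", levels[g])
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        dr2 = ((real[idx] - cr)**2).sum(axis=1)
        di2 = ((imag[idx] - ci)**2).sum(axis=1) if imag.size else 0.0
        z2[idx] = dr2 - di2
    if np.any(z2 < -1e-10):
        logger.warning("dispersion_homogeneity: negative squared distances "
                       "truncated at 0 (non-Euclidean correction)")
    dist = np.sqrt(np.clip(z2, 0.0, None))

    def anova_f(vals, c):
        grand = vals.mean()
        ss_b = sum(np.sum(c == g) * (vals[c == g].mean() - grand)**2
                   for g in range(levels.size))
        ss_w = sum(np.sum((vals[c == g] - vals[c == g].mean())**2)
                   for g in range(levels.size))
        dfb, dfw = levels.size - 1, len(vals) - levels.size
        if ss_w <= 0:
            return 0.0 if ss_b <= 0 else np.inf
        return (ss_b / dfb) / (ss_w / dfw)

    f_obs = anova_f(dist, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(dist, rng.permutation(codes)) >= f_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    per_sample = pd.DataFrame({"sample_id": d.ids, "group": groups,
                               "distance_to_centroid": dist})
    return per_sample, GroupTestResult("dispersion_F", float(f_obs), n_perm, p)
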