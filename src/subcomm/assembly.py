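"""Null-model inference of community assembly processes.

For every pair of samples the analysis computes the abundance-weighted
between-sample mean nearest taxon distance (βMNTD), standardises it against
a tip-shuffling phylogenetic null to obtain βNTI, and computes the
Bray–Curtis-based Raup–Crick metric (RC_bray) against a probabilistic
assembly null that preserves each sample's richness and total abundance.
Pairs are then classified:

* βNTI > +2           → variable (heterogeneous) selection
* βNTI < −2           → homogeneous selection
* |βNTI| ≤ 2, RC > 0.95  → dispersal limitation
* |βNTI| ≤ 2, RC < −0.95 → homogenizing dispersal
* |βNTI| ≤ 2, |RC| ≤ 0.95 → undominated

Boundary values fall to the stochastic/undominated side, which is
conservative toward selection claims. The βNTI null shuffles taxon
identities across the tips of the (pruned) tree, implemented as a shared
row/column permutation of the precomputed patristic matrix per null
replicate. All null draws derive from a single seed; per-pair RC child
seeds are derived deterministically so results are independent of
evaluation order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

from .beta import bray_curtis
from .containers import CommunityTable, DistanceMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "patristic_matrix", "beta_mntd", "beta_nti", "rc_bray",
    "classify_process", "process_fractions", "assembly_analysis",
    "PROCESSES",
]

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated")
SELECTION = ("variable_selection", "homogeneous_selection")


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sum of branch lengths along paths)."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError("tree has an edge with no branch length")
    dm = tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), dm.data)


def _pair_mntd(w_j: np.ndarray, w_k: np.ndarray, pdist: np.ndarray,
               rows: np.ndarray, cols: np.ndarray) -> float:
    """Abundance-weighted βMNTD for one pair.

    ``w_j``/``w_k`` are the two samples' relative abundances over their
    present taxa; ``rows``/``cols`` index those taxa into ``pdist`` (under a
    tip-shuffling null they are the permuted identities while the weights
    stay with the observed communities).
    """
    sub = pdist[np.ix_(rows, cols)]
    return 0.5 * (w_j @ sub.min(axis=1) + w_k @ sub.min(axis=0))


def beta_mntd(table: CommunityTable, pdm: DistanceMatrix,
              pair: tuple[str, str]) -> float:
    """Observed abundance-weighted βMNTD between two samples.

    βMNTD = ½ [ Σ_{i∈j} f_ij · min_{i′∈k} d(i,i′) + Σ_{i∈k} f_ik ·
    min_{i′∈j} d(i,i′) ] with f the within-sample relative abundances. A
    taxon present in both samples has nearest-neighbour distance zero.
    """
    order = {t: i for i, t in enumerate(pdm.ids)}
    missing = [t for t in table.taxon_ids if t not in order]
    if missing:
        raise ValidationError(f"taxa absent from patristic matrix: {missing[:5]}")
    rows = [order[t] for t in table.taxon_ids]
    pdist = pdm.values[np.ix_(rows, rows)]
    j = table.sample_ids.index(pair[0])
    k = table.sample_ids.index(pair[1])
    freq = table.relative_abundance()
    sup_j = np.flatnonzero(freq[:, j] > 0)
    sup_k = np.flatnonzero(freq[:, k] > 0)
    if sup_j.size == 0 or sup_k.size == 0:
        raise ValidationError("empty sample in βMNTD")
    return float(_pair_mntd(freq[sup_j, j], freq[sup_k, k], pdist, sup_j, sup_k))


def beta_nti(
    table: CommunityTable,
    pdm: DistanceMatrix,
    n_null: int = 999,
    seed: int | None = 0,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """βNTI for every (or the given) unordered sample pairs.

    The null shuffles taxon identities across tips: each replicate applies
    one random permutation to the rows and columns of the patristic matrix,
    shared by all pairs in that replicate. βNTI = (obs − null mean) / null
    sd; a zero null sd (e.g. a star phylogeny) yields NaN with an
    ``undefined`` flag.
    """
    if n_null < 2:
        raise ValidationError("n_null must be at least 2")
    if n_null < 100:
        logger.warning("beta_nti: n_null=%d is small; βNTI will be noisy", n_null)
    if table.n_samples < 2 or table.n_taxa < 2:
        raise ValidationError("need at least 2 samples and 2 taxa")

    order = {t: i for i, t in enumerate(pdm.ids)}
    missing = [t for t in table.taxon_ids if t not in order]
    if missing:
        raise ValidationError(f"taxa absent from patristic matrix: {missing[:5]}")
    rows = [order[t] for t in table.taxon_ids]
    pdist = pdm.values[np.ix_(rows, rows)]

    freq = table.relative_abundance()
    n_taxa = table.n_taxa
    supports = [np.flatnonzero(freq[:, j] > 0) for j in range(table.n_samples)]

    if pairs is None:
        pairs = [(table.sample_ids[j], table.sample_ids[k])
                 for j in range(table.n_samples)
                 for k in range(j + 1, table.n_samples)]
    sidx = {s: i for i, s in enumerate(table.sample_ids)}
    pair_idx = [(sidx[a], sidx[b]) for a, b in pairs]

    weights = [freq[supports[j], j] for j in range(table.n_samples)]
    obs = np.array([_pair_mntd(weights[j], weights[k], pdist,
                               supports[j], supports[k])
                    for j, k in pair_idx])

    rng = np.random.default_rng(seed)
    null = np.empty((n_null, len(pairs)))
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        for p, (j, k) in enumerate(pair_idx):
            null[r, p] = _pair_mntd(weights[j], weights[k], pdist,
                                    perm[supports[j]], perm[supports[k]])
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / sd, np.nan)
    return pd.DataFrame({
        "sample_1": [a for a, _ in pairs],
        "sample_2": [b for _, b in pairs],
        "beta_mntd_obs": obs,
        "null_mean": mean,
        "null_sd": sd,
        "beta_nti": bnti,
        "undefined": sd <= 0,
    })


def _null_community(rng: np.random.Generator, richness: int, total: int,
                    occ_p: np.ndarray, abun_p: np.ndarray) -> np.ndarray:
    """One Raup–Crick null community over the pool's taxon list."""
    n_pool = occ_p.size
    chosen = rng.choice(n_pool, size=richness, replace=False, p=occ_p)
    counts = np.zeros(n_pool)
    counts[chosen] = 1.0
    remaining = total - richness
    if remaining > 0:
        w = abun_p[chosen]
        wsum = w.sum()
        w = w / wsum if wsum > 0 else np.full(richness, 1.0 / richness)
        counts[chosen] += rng.multinomial(remaining, w)
    return counts


def rc_bray(
    table: CommunityTable,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int | None = 0,
    pool: list[str] | None = None,
) -> float:
    """Bray–Curtis-based Raup–Crick metric for one sample pair.

    Null communities preserve the observed richness S and total abundance N
    of each sample: S distinct taxa are drawn from the pool with probability
    proportional to occurrence frequency (number of pool samples containing
    the taxon), each receives one individual, and the remaining N−S
    individuals are distributed multinomially in proportion to the drawn
    taxa's pool-wide relative abundances. RC is the observed Bray–Curtis's
    position in the null distribution rescaled to [−1, 1]::

        RC = 2·[#(null < obs) + ½·#(null = obs)] / n_null − 1
    """
    pool_ids = list(table.sample_ids) if pool is None else list(pool)
    for s in pair:
        if s not in pool_ids:
            raise ValidationError(f"pair sample {s} not in pool")
    pool_table = table.select_samples(pool_ids)
    occ = (pool_table.counts > 0).sum(axis=1).astype(float)
    occ_p = occ / occ.sum()
    abun = pool_table.counts.sum(axis=1)
    abun_p = abun / abun.sum()

    j = table.sample_ids.index(pair[0])
    k = table.sample_ids.index(pair[1])
    xj = table.counts[:, j]
    xk = table.counts[:, k]
    obs = np.abs(xj - xk).sum() / (xj + xk).sum()

    params = []
    for x in (xj, xk):
        s_obs = int(np.sum(x > 0))
        n_tot = int(round(x.sum()))
        if s_obs == 0:
            raise ValidationError("empty sample in RC_bray")
        if s_obs > int(np.sum(occ > 0)):
            raise ValidationError("observed richness exceeds pool richness")
        params.append((s_obs, max(n_tot, s_obs)))

    rng = np.random.default_rng(seed)
    below = ties = 0
    for _ in range(n_null):
        a = _null_community(rng, *params[0], occ_p, abun_p)
        b = _null_community(rng, *params[1], occ_p, abun_p)
        bc = np.abs(a - b).sum() / (a + b).sum()
        if np.isclose(bc, obs, rtol=0.0, atol=1e-10):
            ties += 1
        elif bc < obs:
            below += 1
    return float(2.0 * (below + 0.5 * ties) / n_null - 1.0)


def classify_process(beta_nti_value: float, rc: float) -> str:
    """Five-way assembly-process classification from βNTI and RC_bray."""
    if not np.isfinite(beta_nti_value):
        return "undefined"
    if beta_nti_value > 2:
        return "variable_selection"
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if not np.isfinite(rc):
        return "undefined"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def assembly_analysis(
    table: CommunityTable,
    tree_or_pdm,
    n_null: int = 999,
    seed: int | None = 0,
    rc_all: bool = False,
) -> pd.DataFrame:
    """βNTI + RC_bray + process class for every sample pair of one table.

    ``tree_or_pdm`` may be a tree (patristic distances are computed) or a
    ready patristic DistanceMatrix; either is pruned/subset to the table's
    taxa. The RC pool is the table's full sample set. RC_bray is computed
    only for the pairs whose |βNTI| ≤ 2 (selection already decided
    otherwise) unless ``rc_all`` is set. Per-pair RC seeds are derived from
    ``seed`` and the pair index, so results do not depend on evaluation
    order.
    """
    if isinstance(tree_or_pdm, DistanceMatrix):
        pdm = tree_or_pdm
    else:
        tree = tree_or_pdm.shear(table.taxon_ids)
        tree.prune()
        pdm = patristic_matrix(tree)

    results = beta_nti(table, pdm, n_null=n_null, seed=seed)
    rcs = np.full(len(results), np.nan)
    for p, row in results.iterrows():
        if not rc_all and (not np.isfinite(row["beta_nti"])
                           or abs(row["beta_nti"]) > 2):
            continue
        child = np.random.SeedSequence(entropy=(0 if seed is None else seed),
                                       spawn_key=(int(p),))
        rcs[p] = rc_bray(table, (row["sample_1"], row["sample_2"]),
                         n_null=n_null, seed=child)
    results["rc_bray"] = rcs
    results["process"] = [classify_process(b, r)
                          for b, r in zip(results["beta_nti"], results["rc_bray"])]
    return results


def process_fractions(results: pd.DataFrame,
                      by: list[str] | None = None) -> pd.DataFrame:
    """Fractions of sample pairs per assembly process.

    ``results`` must carry a ``process`` column plus any grouping columns
    named in ``by`` (e.g. treatment group and abundance class). Undefined
    pairs are excluded from fractions and counted separately. Also reports
    deterministic (selection) and stochastic (dispersal + undominated)
    totals.
    """
    by = by or []
    grouped = results.groupby(by, sort=True) if by else [((), results)]
    rows = []
    for key, sub in grouped:
        defined = sub[sub["process"] != "undefined"]
        n = len(defined)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n_pairs"] = n
        row["n_undefined"] = len(sub) - n
        if n == 0:
            logger.warning("process_fractions: no classified pairs in cell %s", key)
            rows.append(row)
            continue
        for proc in PROCESSES:
            row[proc] = float((defined["process"] == proc).mean())
        row["deterministic"] = sum(row[p] for p in SELECTION)
        row["stochastic"] = 1.0 - row["deterministic"]
        rows.append(row)
    return pd.DataFrame(rows)
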