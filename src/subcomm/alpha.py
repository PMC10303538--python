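"""Per-sample alpha diversity (Chao1, Shannon) and rank-sum group comparison.

Chao1 uses the bias-corrected form ``S_obs + F1(F1-1) / (2(F2+1))`` (F1 =
singletons, F2 = doubletons) which stays defined when no doubletons are
observed. Shannon uses natural logarithms on within-sample relative
abundances. Group differences are tested with the two-sided Wilcoxon
rank-sum test: exact when both groups are small and untied, otherwise the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CommunityTable, ValidationError

__all__ = ["chao1", "shannon", "rarefy", "wilcoxon_rank_sum",
           "RankSumResult", "alpha_table", "compare_groups"]


def _check_counts(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("all-zero count vector")
    if np.any(counts < 0):
        raise ValidationError("negative counts")
    return counts


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate from integer counts."""
    counts = _check_counts(counts)
    if np.any(counts != np.floor(counts)):
        raise ValidationError("Chao1 requires integer counts")
    s_obs = int(np.sum(counts > 0))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon entropy H = −Σ p ln p over positive entries (natural log)."""
    counts = _check_counts(counts)
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-np.sum(p * np.log(p)))


def rarefy(counts, depth: int, seed: int | None = 0) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    counts = _check_counts(counts).astype(np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"rarefaction depth {depth} exceeds total {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first group (midranks for ties)
    p_value: float
    method: str  # "exact" or "normal"
    degenerate: bool = False


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p-value when min(n) ≤ 8 with no ties; otherwise the normal
    approximation with midrank tie correction and continuity correction.
    Identical values in both groups yield p = 1 with a degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:x.size].sum())
    if np.ptp(pooled) == 0:
        return RankSumResult(w, 1.0, "degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    exact = (min(x.size, y.size) <= 8) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True)
    return RankSumResult(w, float(res.pvalue), "exact" if exact else "normal")


def alpha_table(tables: dict, rarefy_depth: int | None = None,
                seed: int | None = 0) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon for each abundance-class sub-table.

    ``tables`` maps class → CommunityTable (None entries skipped). Optional
    rarefaction to a common depth before computing the indices.
    """
    rows = []
    for cls, table in tables.items():
        if table is None:
            continue
        for j, sample in enumerate(table.sample_ids):
            counts = table.counts[:, j]
            if rarefy_depth is not None:
                counts = rarefy(counts, rarefy_depth, seed)
                if counts.sum() == 0:
                    continue
            rows.append({"sample_id": sample, "class": cls,
                         "chao1": chao1(counts), "shannon": shannon(counts)})
    return pd.DataFrame(rows)


def compare_groups(alpha: pd.DataFrame, meta: pd.DataFrame,
                   metrics: tuple = ("chao1", "shannon")) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of alpha metrics between the two groups."""
    merged = alpha.merge(meta[["sample_id", "group"]].reset_index(drop=True),
                         on="sample_id")
    groups = sorted(merged["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    rows = []
    for cls, sub in merged.groupby("class", sort=True):
        for metric in metrics:
            x = sub.loc[sub["group"] == g1, metric].to_numpy()
            y = sub.loc[sub["group"] == g2, metric].to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            res = wilcoxon_rank_sum(x, y)
            rows.append({
                "class": cls, "metric": metric,
                f"mean_{g1}": x.mean(), f"mean_{g2}": y.mean(),
                "statistic": res.statistic, "p_value": res.p_value,
                "method": res.method,
            })
    return pd.DataFrame(rows)
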