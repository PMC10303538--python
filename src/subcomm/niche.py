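"""Levins' niche breadth and generalist/specialist classification.

For taxon *j*, with P_ij the share of the taxon's total abundance found in
sample *i*, the breadth is ``B_j = 1 / Σ_i P_ij²`` (the inverse Simpson
concentration of its occupancy distribution): B = 1 for a taxon confined to
one sample, B = N for perfectly even occupancy over N samples. Taxa with
B > 3 are classed as habitat generalists, B < 1.5 as specialists.
Breadth is computed within each treatment group by default since pooling
across habitats conflates occupancy with habitat preference.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CommunityTable, ValidationError
from .alpha import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["levins_breadth", "classify_habitat", "community_breadth"]


def levins_breadth(table: CommunityTable) -> pd.DataFrame:
    """Levins breadth per taxon over the table's samples.

    Returns a frame with columns ``taxon_id, B``; 1 ≤ B ≤ n_samples.
    """
    totals = table.counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = [t for t, s in zip(table.taxon_ids, totals) if s <= 0]
        raise ValidationError(f"taxa with zero total abundance: {bad[:5]}")
    shares = table.counts / totals[:, None]
    b = 1.0 / np.sum(shares**2, axis=1)
    return pd.DataFrame({"taxon_id": table.taxon_ids, "B": b})


def classify_habitat(breadths: pd.DataFrame, generalist_min: float = 3.0,
                     specialist_max: float = 1.5) -> pd.DataFrame:
    """Attach a habitat class: generalist (B > 3), specialist (B < 1.5),
    otherwise neither. Proportions use all taxa as the denominator."""
    if generalist_min <= specialist_max:
        raise ValidationError("generalist threshold must exceed specialist threshold")
    out = breadths.copy()
    out["habitat_class"] = np.select(
        [out["B"] > generalist_min, out["B"] < specialist_max],
        ["generalist", "specialist"], default="neither")
    return out


def community_breadth(
    tables_by_group_class: dict,
    generalist_min: float = 3.0,
    specialist_max: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-taxon breadths and per-(group, class) summaries.

    ``tables_by_group_class`` maps (group, class) → CommunityTable (or
    None, skipped with a warning). Returns ``(per_taxon, summary,
    comparisons)``: the per-taxon breadth/habitat table, per-cell mean
    breadth and generalist/specialist/neither proportions, and the rank-sum
    comparison of breadths between groups within each class.
    """
    frames = []
    for (group, cls), table in sorted(tables_by_group_class.items()):
        if table is None:
            logger.warning("community_breadth: empty cell (%s, %s) skipped", group, cls)
            continue
        b = classify_habitat(levins_breadth(table), generalist_min, specialist_max)
        b["group"] = group
        b["class"] = cls
        b["n_samples"] = table.n_samples
        frames.append(b)
    if not frames:
        raise ValidationError("no non-empty (group, class) cells")
    per_taxon = pd.concat(frames, ignore_index=True)

    summary_rows = []
    for (group, cls), sub in per_taxon.groupby(["group", "class"], sort=True):
        n = len(sub)
        summary_rows.append({
            "group": group, "class": cls, "n_taxa": n,
            "mean_B": sub["B"].mean(),
            "generalist_prop": (sub["habitat_class"] == "generalist").mean(),
            "specialist_prop": (sub["habitat_class"] == "specialist").mean(),
            "neither_prop": (sub["habitat_class"] == "neither").mean(),
        })
    summary = pd.DataFrame(summary_rows)

    comp_rows = []
    groups = sorted(per_taxon["group"].unique())
    if len(groups) == 2:
        g1, g2 = groups
        for cls, sub in per_taxon.groupby("class", sort=True):
            x = sub.loc[sub["group"] == g1, "B"].to_numpy()
            y = sub.loc[sub["group"] == g2, "B"].to_numpy()
            if x.size and y.size:
                res = wilcoxon_rank_sum(x, y)
                comp_rows.append({"class": cls, f"mean_B_{g1}": x.mean(),
                                  f"mean_B_{g2}": y.mean(),
                                  "statistic": res.statistic,
                                  "p_value": res.p_value})
    comparisons = pd.DataFrame(comp_rows)
    return per_taxon, summary, comparisons
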