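"""Abundance-class partitioning of taxa into abundant / intermediate / rare.

Taxa whose relative abundance exceeds 0.1% are "abundant", those below 0.01%
are "rare", everything in between (including values exactly at a threshold)
is "intermediate". The default statistic is the mean across samples of the
per-sample relative abundance; pooled (whole-matrix) and per-sample-maximum
bases are available. Classification is typically run separately within each
treatment group, mirroring per-group reporting of class percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PartitionLabels", "classify_taxa", "split_table", "CLASSES"]

CLASSES = ("abundant", "intermediate", "rare")


@dataclass
class PartitionLabels:
    """Taxon → abundance class, with the thresholds and statistic used."""

    labels: dict  # taxon_id -> class
    statistic: dict  # taxon_id -> relative-abundance statistic
    upper: float = 0.001
    lower: float = 0.0001
    basis: str = "mean"

    def taxa_in(self, cls: str) -> list[str]:
        return [t for t, c in self.labels.items() if c == cls]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon_id": list(self.labels),
            "class": [self.labels[t] for t in self.labels],
            "statistic": [self.statistic[t] for t in self.labels],
        })


def classify_taxa(
    table: CommunityTable,
    upper: float = 0.001,
    lower: float = 0.0001,
    basis: str = "mean",
) -> PartitionLabels:
    """Assign each taxon an abundance class.

    ``basis``: ``mean`` (mean of per-sample relative abundances, default),
    ``pooled`` (taxon total / grand total) or ``max`` (maximum per-sample
    relative abundance). Boundary values fall to ``intermediate``.
    """
    if upper <= lower:
        raise ValidationError(f"upper ({upper}) must exceed lower ({lower})")
    if lower <= 0:
        raise ValidationError("lower threshold must be positive")
    rel = table.relative_abundance()
    if basis == "mean":
        stat = rel.mean(axis=1)
    elif basis == "pooled":
        stat = table.counts.sum(axis=1) / table.counts.sum()
    elif basis == "max":
        stat = rel.max(axis=1)
    else:
        raise ValidationError(f"unknown basis {basis!r}")

    labels = {}
    for taxon, s in zip(table.taxon_ids, stat):
        if s > upper:
            labels[taxon] = "abundant"
        elif s < lower:
            labels[taxon] = "rare"
        else:
            labels[taxon] = "intermediate"
    return PartitionLabels(labels, dict(zip(table.taxon_ids, stat.astype(float))),
                           upper, lower, basis)


def split_table(table: CommunityTable, labels: PartitionLabels) -> dict:
    """Split a table into per-class sub-tables (map class → CommunityTable).

    Counts are preserved exactly (no renormalisation is stored); samples
    whose column sum becomes zero within a sub-table are dropped from that
    sub-table with a warning. Classes with zero taxa map to ``None``.
    """
    missing = [t for t in table.taxon_ids if t not in labels.labels]
    if missing:
        raise ValidationError(f"labels missing for taxa: {missing[:5]}")
    out = {}
    for cls in CLASSES:
        taxa = [t for t in table.taxon_ids if labels.labels[t] == cls]
        if not taxa:
            logger.warning("split_table: class %s has no taxa", cls)
            out[cls] = None
            continue
        try:
            sub = table.select_taxa(taxa, drop_empty_samples=True)
        except ValidationError:  # labelled taxa carry no counts at all
            logger.warning("split_table: class %s has no counts", cls)
            out[cls] = None
            continue
        dropped = set(table.sample_ids) - set(sub.sample_ids)
        if dropped:
            logger.warning("split_table: class %s drops empty samples %s",
                           cls, sorted(dropped))
        out[cls] = sub
    return out
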