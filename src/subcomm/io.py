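"""Readers and writers for on-disk artifacts.

Canonical formats are plain text: the OTU table and sample metadata are
tab-separated UTF-8 with a header row, the phylogeny is Newick with branch
lengths, run configuration is YAML, and results are TSV plus one JSON run
summary. Trees are represented in memory as :class:`skbio.TreeNode`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .containers import CommunityTable, ValidationError, validate_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "read_community_table", "write_community_table",
    "read_tree", "write_tree",
    "read_metadata", "write_metadata",
    "read_yaml", "align_inputs", "AlignmentReport",
]


def read_community_table(path: str | Path) -> CommunityTable:
    """Read a taxa × samples TSV (header: ``taxon_id<TAB>sample...``)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected taxon_id column plus sample columns")
    df = df.set_index(df.columns[0])
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric counts ({exc})") from exc
    return CommunityTable(list(df.index), list(df.columns), values)


def write_community_table(table: CommunityTable, path: str | Path) -> None:
    df = table.to_frame()
    # integer-valued tables round-trip bit-exactly as integers
    if np.all(df.to_numpy() == np.floor(df.to_numpy())):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; every edge must carry a branch length."""
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    _validate_tree(tree, where=str(path))
    return tree


def _validate_tree(tree: TreeNode, where: str = "tree") -> None:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValidationError(f"{where}: duplicate tip labels {dupes}")
    if any(t is None for t in tips):
        raise ValidationError(f"{where}: unlabeled tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(f"{where}: missing branch length on an edge")
        if node.length < 0:
            raise ValidationError(f"{where}: negative branch length {node.length}")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str, "group": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    return out


class AlignmentReport(dict):
    """Record of IDs dropped while aligning table, tree and metadata."""

    @property
    def dropped_taxa(self) -> list[str]:
        return self.get("dropped_taxa", [])

    @property
    def dropped_samples(self) -> list[str]:
        return self.get("dropped_samples", [])


def align_inputs(
    table: CommunityTable,
    tree: TreeNode | None,
    meta: pd.DataFrame,
) -> tuple[CommunityTable, TreeNode | None, pd.DataFrame, AlignmentReport]:
    """Restrict table/tree/metadata to their common taxa and samples.

    Taxa missing from the tree are dropped from the table with a logged
    warning (phylogenetic stages need tree coverage; other stages do not);
    the tree is pruned to the table's taxa. Orderings are canonicalised by
    lexicographic sort so downstream permutation seeds reproduce across
    platforms. Idempotent.
    """
    report = AlignmentReport(dropped_taxa=[], dropped_samples=[])
    meta = validate_metadata(meta)

    samples = sorted(set(table.sample_ids) & set(meta["sample_id"]))
    if not samples:
        raise ValidationError("no samples shared between table and metadata")
    dropped_samples = sorted(
        (set(table.sample_ids) | set(meta["sample_id"])) - set(samples))
    report["dropped_samples"] = dropped_samples
    if dropped_samples:
        logger.warning("align_inputs: dropping %d unmatched samples: %s",
                       len(dropped_samples), dropped_samples[:10])

    taxa = sorted(table.taxon_ids)
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        kept = [t for t in taxa if t in tip_names]
        if not kept:
            raise ValidationError("no taxa shared between table and tree")
        report["dropped_taxa"] = [t for t in taxa if t not in tip_names]
        if report["dropped_taxa"]:
            logger.warning("align_inputs: dropping %d taxa absent from tree",
                           len(report["dropped_taxa"]))
        taxa = kept
        tree = tree.shear(taxa)
        tree.prune()

    aligned = table.select_samples(samples).select_taxa(taxa)
    meta = meta.loc[samples].copy()
    return aligned, tree, meta, report
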