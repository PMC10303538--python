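"""Core in-memory containers for community ecology data.

The central observable is a taxa-by-samples count table (:class:`CommunityTable`).
Pairwise quantities (Bray–Curtis, patristic, geographic, environmental
distances) travel as :class:`DistanceMatrix`. Per-sample covariates (treatment
group, coordinates, soil chemistry) travel as a validated pandas DataFrame
(see :func:`validate_metadata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "ValidationError",
    "validate_metadata",
    "ENV_COLUMNS",
]

#: conventional soil-chemistry variable names (any numeric extra column is accepted)
ENV_COLUMNS = ("pH", "SOM", "TN", "TP", "AP", "TK", "AK")

REQUIRED_META_COLUMNS = ("sample_id", "group", "latitude", "longitude")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class CommunityTable:
    """Taxa × samples matrix of non-negative counts (or abundances).

    Parameters
    ----------
    taxon_ids : list of str
        Unique row identifiers (OTUs/ASVs).
    sample_ids : list of str
        Unique column identifiers.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative values; no sample column may sum to zero.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {kind} IDs: {sorted(dupes)}")
        if np.any(~np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts contain negative values")
        zero = np.flatnonzero(self.counts.sum(axis=0) == 0)
        if zero.size:
            names = [self.sample_ids[i] for i in zero]
            raise ValidationError(f"sample columns sum to zero: {names}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalised view; every column sums to 1."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))

    def select_taxa(self, taxa: list[str], drop_empty_samples: bool = False) -> "CommunityTable":
        """Sub-table restricted to ``taxa`` (kept in the given order).

        With ``drop_empty_samples`` samples whose column sum becomes zero in
        the sub-table are removed (their IDs are recoverable by comparing
        ``sample_ids``).
        """
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ValidationError(f"taxa not in table: {missing[:5]}")
        rows = [index[t] for t in taxa]
        counts = self.counts[rows, :]
        sample_ids = list(self.sample_ids)
        if drop_empty_samples:
            keep = counts.sum(axis=0) > 0
            counts = counts[:, keep]
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        if counts.size == 0 or counts.sum() == 0:
            raise ValidationError("sub-table is empty")
        return CommunityTable(list(taxa), sample_ids, counts)

    def select_samples(self, samples: list[str]) -> "CommunityTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return CommunityTable(list(self.taxon_ids), list(samples), self.counts[:, cols])


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal matrix of non-negative pairwise values."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if _duplicates(self.ids):
            raise ValidationError("duplicate IDs in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        # enforce exact symmetry and zero diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        if np.any(self.values < 0):
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(rows, rows)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.ids)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata frame.

    Requires columns ``sample_id, group, latitude, longitude``; any additional
    numeric columns are treated as environmental variables. Returns a copy
    indexed by ``sample_id``.
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    dupes = _duplicates(list(meta["sample_id"]))
    if dupes:
        raise ValidationError(f"duplicate sample IDs in metadata: {sorted(dupes)}")
    lat = meta["latitude"].to_numpy(dtype=float)
    lon = meta["longitude"].to_numpy(dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValidationError("longitude outside [-180, 180]")
    return meta.set_index("sample_id", drop=False)


def env_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the environmental (numeric, non-positional) metadata columns."""
    skip = set(REQUIRED_META_COLUMNS)
    return [c for c in meta.columns
            if c not in skip and pd.api.types.is_numeric_dtype(meta[c])]


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup
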