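"""Geographic distances, distance–decay regression, and Mantel tests.

Distance–decay is fit as ordinary least squares of ln(community similarity)
on ln(geographic distance) over unordered sample pairs; the slope is then a
scale-free decay exponent. Significance of matrix–matrix relationships uses
the Mantel permutation test (simultaneous row/column permutation of the
second matrix), one-sided greater by default as is conventional in the
distance-decay literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CommunityTable, DistanceMatrix, ValidationError, env_columns

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM", "haversine_km", "haversine_matrix",
    "DecayFit", "distance_decay",
    "MantelResult", "mantel", "env_mantel_panel",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise ValidationError("coordinates outside valid ranges")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2.0) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def haversine_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Great-circle distances between the samples of a metadata frame."""
    d = haversine_km(meta["latitude"].to_numpy(), meta["longitude"].to_numpy())
    return DistanceMatrix(list(meta["sample_id"]), d)


@dataclass
class DecayFit:
    """Log–log OLS fit of similarity against geographic distance."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    n_excluded: int
    transform: str = "lnboth"


def distance_decay(
    similarity: DistanceMatrix,
    geo: DistanceMatrix,
    transform: str = "lnboth",
    n_perm: int = 999,
    seed: int | None = 0,
) -> DecayFit:
    """Distance–decay regression over unordered sample pairs.

    ``similarity`` is community similarity (1 − Bray–Curtis). Pairs with
    zero similarity or zero distance are excluded (ln undefined) and
    counted. The p-value is a Mantel-style permutation test of the
    correlation on the same (log-transformed) pairs, one-sided for a
    negative slope.

    ``transform``: ``lnboth`` (default, log–log), ``lnsim`` (ln similarity
    vs raw distance), or ``none``.
    """
    if similarity.ids != geo.ids:
        raise ValidationError("similarity and geographic matrices must share IDs")
    if transform not in ("lnboth", "lnsim", "none"):
        raise ValidationError(f"unknown transform {transform!r}")
    n = similarity.n
    iu = np.triu_indices(n, k=1)
    sim_m = similarity.values.copy()
    geo_m = geo.values.copy()

    usable = np.ones_like(sim_m, dtype=bool)
    if transform in ("lnboth", "lnsim"):
        usable &= sim_m > 0
    if transform == "lnboth":
        usable &= geo_m > 0
    n_excluded = int((~usable[iu]).sum())
    if n_excluded:
        logger.warning("distance_decay: excluded %d pairs with zero similarity "
                       "or zero distance", n_excluded)

    with np.errstate(divide="ignore"):
        y_m = np.log(sim_m) if transform in ("lnboth", "lnsim") else sim_m
        x_m = np.log(geo_m) if transform == "lnboth" else geo_m

    mask_pairs = usable[iu]
    x, y = x_m[iu][mask_pairs], y_m[iu][mask_pairs]
    if x.size < 3:
        raise ValidationError("fewer than 3 usable pairs for distance decay")

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        slope, intercept = 0.0, float(np.mean(y))
        return DecayFit(slope, intercept, 0.0, 1.0, x.size, n_excluded, transform)

    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2)

    # permutation p on the matrix structure (sample-label permutations),
    # one-sided in the direction of decay (negative correlation)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp_m = y_m[np.ix_(perm, perm)]
        up_m = usable[np.ix_(perm, perm)]
        m = up_m[iu] & np.isfinite(x_m[iu])
        xs, ys = x_m[iu][m], yp_m[iu][m]
        if xs.size < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            hits += 1
            continue
        if np.corrcoef(xs, ys)[0, 1] <= r:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return DecayFit(float(slope), float(intercept), r2, float(p),
                    int(x.size), n_excluded, transform)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    method: str = "pearson"
    alternative: str = "greater"
    degenerate: bool = False


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = 0,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the Pearson (or Spearman, with midranks) correlation of
    the lower-triangle entries; the null distribution permutes the rows and
    columns of ``d2`` simultaneously. ``r`` is symmetric in the two
    matrices; the permutation p-value may differ slightly depending on which
    matrix is permuted. With ``exhaustive=True`` (n ≤ 7) every permutation
    is enumerated once and ``p = #{r_perm ≥ r_obs} / n!`` (the identity
    permutation guarantees p > 0).
    """
    if d1.ids != d2.ids:
        raise ValidationError("Mantel requires matching IDs")
    n = d1.n
    if n < 4:
        raise ValidationError("Mantel needs at least 4 samples")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")

    iu = np.triu_indices(n, k=1)
    a_m = d1.values
    b_m = d2.values
    if method == "spearman":
        # rank within each matrix's triangle; ranking is permutation-equivariant,
        # so pre-ranking b's triangle values then permuting labels is exact
        a_m = _rank_matrix(a_m, iu)
        b_m = _rank_matrix(b_m, iu)
    a = a_m[iu]
    if np.ptp(a) == 0 or np.ptp(b_m[iu]) == 0:
        return MantelResult(np.nan, np.nan, n_perm, method, alternative, degenerate=True)

    a = (a - a.mean()) / a.std()
    r_obs = float(np.mean(a * _standardized_triangle(b_m, iu)))

    if exhaustive:
        import itertools
        import math as _math
        if n > 7:
            raise ValidationError("exhaustive Mantel is limited to n <= 7")
        null = np.array([
            np.mean(a * _standardized_triangle(b_m[np.ix_(perm, perm)], iu))
            for perm in itertools.permutations(range(n))])
        if alternative == "greater":
            hits = int(np.sum(null >= r_obs - 1e-12))
        elif alternative == "less":
            hits = int(np.sum(null <= r_obs + 1e-12))
        else:
            hits = int(np.sum(np.abs(null) >= abs(r_obs) - 1e-12))
        return MantelResult(r_obs, hits / _math.factorial(n),
                            _math.factorial(n), method, alternative)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = np.mean(a * _standardized_triangle(b_m[np.ix_(perm, perm)], iu))
    if alternative == "greater":
        hits = int(np.sum(null >= r_obs))
    elif alternative == "less":
        hits = int(np.sum(null <= r_obs))
    else:
        hits = int(np.sum(np.abs(null) >= abs(r_obs)))
    p = (1.0 + hits) / (1.0 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, method, alternative)


def _standardized_triangle(m: np.ndarray, iu) -> np.ndarray:
    v = m[iu]
    return (v - v.mean()) / v.std()


def _rank_matrix(m: np.ndarray, iu) -> np.ndarray:
    ranks = stats.rankdata(m[iu])
    out = np.zeros_like(m)
    out[iu] = ranks
    out = out + out.T
    return out


def env_mantel_panel(
    community_d: DistanceMatrix,
    meta: pd.DataFrame,
    variables: list[str] | None = None,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable Mantel tests plus the Spearman matrix among variables.

    Each environmental distance is the Euclidean (absolute-difference)
    distance on the z-scored single variable. Constant variables are skipped
    with a warning. Returns ``(mantel_table, spearman_matrix)``.
    """
    if variables is None:
        variables = env_columns(meta)
    meta = meta.set_index("sample_id", drop=False).loc[community_d.ids]
    rows = []
    for var in variables:
        if var not in meta.columns:
            raise ValidationError(f"variable {var!r} missing from metadata")
        vals = meta[var].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            logger.warning("env_mantel_panel: variable %s constant, skipped", var)
            continue
        z = (vals - vals.mean()) / vals.std()
        envd = DistanceMatrix(community_d.ids, np.abs(z[:, None] - z[None, :]))
        res = mantel(community_d, envd, method=method, n_perm=n_perm, seed=seed)
        rows.append({"variable": var, "mantel_r": res.r, "p_value": res.p_value,
                     "n_permutations": res.n_permutations, "method": res.method})
    mantel_table = pd.DataFrame(rows)
    spearman = meta[variables].corr(method="spearman")
    return mantel_table, spearman
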