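"""Spot-level scoring and screen-level statistics.

Per spot, the nuclear integrated intensities of included cells are summed per
channel; pin normalization removes multiplicative per-pin intensity bias
using each pin's negative-control spots; the growth/survival readout is the
spot index

    index = log2( (cum_Ki67 + pseudo) / cum_DAPI
                  / ((cum_cPARP + pseudo) / cum_DAPI) ),

a DAPI-normalized log2 Ki-67/cPARP ratio (lower = growth-inhibited /
apoptotic).  Per array, sample indices are standardized to z-scores with the
global array mean and population s.d.; replicate arrays are combined by the
mean z and hits called at |z| >= 2 s.d.  Consistency of effects across
conditions (replicates or cell lines) is ranked with the rank-product
statistic with permutation p-values; samples are clustered with a
deterministic PAM (partitioning around medoids, BUILD + SWAP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError, PinNormalizationError
from .layout import CONTROL_ID

SPOT_CHANNELS = ("cum_dapi", "cum_ki67", "cum_cparp")


def aggregate_spots(cells: pd.DataFrame, min_cells: int = 10) -> pd.DataFrame:
    """Sum per-cell nuclear integrated intensities into spot measurements.

    Excluded cells (outside the spot perimeter) do not contribute.  Returns
    one row per spot with ``n_cells, cum_dapi, cum_ki67, cum_cparp,
    sample_id, pin_id`` and a ``scoreable`` flag (``n_cells >= min_cells``).
    """
    inc = cells[~cells["excluded"].astype(bool)] if "excluded" in cells else cells
    g = inc.groupby("spot_id", sort=True)
    spots = pd.DataFrame(
        {
            "n_cells": g.size(),
            "cum_dapi": g["dapi_int"].sum(),
            "cum_ki67": g["ki67_int"].sum(),
            "cum_cparp": g["cparp_int"].sum(),
            "sample_id": g["sample_id"].first(),
            "pin_id": g["pin_id"].first(),
        }
    ).reset_index()
    spots["scoreable"] = spots["n_cells"] >= min_cells
    spots["normalized"] = False
    return spots


def pin_normalize(
    spots: pd.DataFrame,
    control_ids: Iterable[str] = (CONTROL_ID,),
    min_cells: int = 10,
) -> pd.DataFrame:
    """Remove per-pin multiplicative channel bias against control spots.

    For every channel, each spot's cumulative value is divided by
    (median over the same pin's control spots / median over all control spots
    on the array), so per-pin control medians equalize across pins while the
    array-wide control level is preserved.  Raises
    :class:`PinNormalizationError` naming the first pin lacking a usable
    (``n_cells >= min_cells``) control spot.
    """
    control_ids = set(control_ids)
    spots = spots.copy()
    ctrl = spots[spots["sample_id"].isin(control_ids) & (spots["n_cells"] >= min_cells)]
    for pin in sorted(spots["pin_id"].unique()):
        if (ctrl["pin_id"] == pin).sum() == 0:
            raise PinNormalizationError(f"pin {pin} has no usable control spots")
    for ch in SPOT_CHANNELS:
        global_med = float(ctrl[ch].median())
        pin_med = ctrl.groupby("pin_id")[ch].median()
        factor = spots["pin_id"].map(pin_med) / global_med
        spots[ch] = spots[ch] / factor.to_numpy()
    spots["normalized"] = True
    return spots


def spot_index(
    spots: pd.DataFrame,
    min_cells: int = 10,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Attach the log2 Ki-67/cPARP spot index.

    ``pseudo`` guards the log against zero cPARP sums on fully viable spots;
    the default is 1% of the array-median ``cum_cparp``.  Spots with fewer
    than ``min_cells`` cells or zero cumulative DAPI are flagged and get an
    undefined (NaN) index.
    """
    spots = spots.copy()
    if pseudo is None:
        pseudo = 0.01 * float(spots["cum_cparp"].median())
    ki = spots["cum_ki67"].to_numpy(dtype=float)
    cp = spots["cum_cparp"].to_numpy(dtype=float)
    da = spots["cum_dapi"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.log2(((ki + pseudo) / da) / ((cp + pseudo) / da))
    bad = (spots["n_cells"].to_numpy() < min_cells) | (da <= 0)
    idx[bad] = np.nan
    spots["index"] = idx
    spots["index_defined"] = ~bad
    return spots


def zscore_array(indices: pd.Series) -> pd.Series:
    """Standardize one array's per-sample indices (population s.d.).

    NaN entries are ignored for the moments and stay NaN.  Raises
    :class:`DegenerateDataError` for < 3 defined values or zero s.d.
    """
    x = indices.astype(float)
    defined = x.dropna()
    if len(defined) < 3:
        raise DegenerateDataError(f"need >= 3 defined indices, got {len(defined)}")
    sd = float(defined.std(ddof=0))
    if sd == 0:
        raise DegenerateDataError("zero standard deviation across the array")
    return (x - float(defined.mean())) / sd


def combine_and_call(z_per_array: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Combine replicate-array z-scores and call hits at |z| >= threshold.

    ``z_per_array`` is samples x arrays.  The combined score is the
    arithmetic mean over arrays with a defined z; samples missing from some
    array are scored over the available ones and flagged.  Hit direction:
    ``inhibitory`` (combined z <= -threshold, lower Ki-67/cPARP index),
    ``promoting`` (>= +threshold) or ``none``.
    """
    combined = z_per_array.mean(axis=1, skipna=True)
    n_arrays = z_per_array.notna().sum(axis=1)
    hit = np.where(
        combined <= -threshold, "inhibitory", np.where(combined >= threshold, "promoting", "none")
    )
    hit = np.where(n_arrays == 0, "none", hit)
    return pd.DataFrame(
        {
            "combined_z": combined,
            "hit": hit,
            "n_arrays": n_arrays,
            "flagged_missing": n_arrays < z_per_array.shape[1],
        }
    )


def replicate_concordance(z_a: pd.Series, z_b: pd.Series) -> float:
    """Pearson correlation between two replicate arrays' z-scores."""
    a, b = z_a.align(z_b, join="inner")
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise DegenerateDataError("need >= 3 paired values")
    if float(a.std(ddof=0)) == 0 or float(b.std(ddof=0)) == 0:
        raise DegenerateDataError("zero variance in a replicate")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Rank product
# ---------------------------------------------------------------------------


def _exact_rp_pvalues(rp_obs: np.ndarray, n: int, k: int) -> np.ndarray:
    """P(RP <= observed) by exhaustive enumeration of independent rank tuples."""
    prod = np.arange(1, n + 1, dtype=float)
    for _ in range(k - 1):
        prod = np.multiply.outer(prod, np.arange(1, n + 1, dtype=float)).ravel()
    prod.sort()
    target = rp_obs**k
    # tolerance for float geometric-mean round-trip
    counts = np.searchsorted(prod, target * (1 + 1e-9), side="right")
    return counts / len(prod)


def rank_product(
    scores: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "down",
    exact_limit: int = 10**6,
) -> pd.DataFrame:
    """Rank-product meta-ranking of samples across conditions.

    ``scores`` is samples x conditions (e.g. combined z per cell line).
    Within each condition samples are ranked with average ranks for ties --
    ascending for ``direction='down'`` (rank 1 = most inhibitory, i.e. lowest
    score) or descending for ``'up'``.  A sample missing in one condition
    receives that condition's worst rank + 1 (conservative) and is flagged.
    RP is the geometric mean of the ranks; its p-value is P(RP_null <= RP)
    under independent uniform rankings, computed by exhaustive enumeration
    when ``n_samples ** n_conditions <= exact_limit`` and otherwise by seeded
    permutation of ranks within conditions.  Benjamini-Hochberg FDR is
    reported over samples.
    """
    if scores.shape[1] < 2:
        raise ValueError("rank product requires >= 2 conditions")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    n, k = scores.shape
    ranks = np.empty((n, k))
    flagged = np.zeros(n, dtype=bool)
    for j, col in enumerate(scores.columns):
        x = scores[col].to_numpy(dtype=float)
        if direction == "up":
            x = -x
        ok = ~np.isnan(x)
        r = np.full(n, float(ok.sum() + 1))  # missing -> worst rank + 1
        r[ok] = stats.rankdata(x[ok], method="average")
        flagged |= ~ok
        ranks[:, j] = r

    rp = np.exp(np.log(ranks).mean(axis=1))
    if n**k <= exact_limit and not flagged.any():
        p = _exact_rp_pvalues(rp, n, k)
    else:
        rng = np.random.default_rng(seed)
        base = np.arange(1, n + 1, dtype=float)
        null = np.empty((n_perm, n))
        for b in range(n_perm):
            perm_ranks = np.column_stack([rng.permutation(base) for _ in range(k)])
            null[b] = np.exp(np.log(perm_ranks).mean(axis=1))
        pooled = np.sort(null.ravel())
        counts = np.searchsorted(pooled, rp * (1 + 1e-9), side="right")
        p = (counts + 1.0) / (pooled.size + 1.0)

    fdr = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {"rp": rp, "rp_p": p, "rp_fdr": fdr, "rp_missing": flagged},
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# PAM clustering
# ---------------------------------------------------------------------------


@dataclass
class PAMResult:
    """Deterministic k-medoids clustering with a display ordering."""

    medoid_indices: np.ndarray
    labels: np.ndarray
    cost: float
    order: np.ndarray  # display ordering: by cluster, then distance to medoid


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = D[:, medoids].min(axis=1)
        gains = np.maximum(dist_to_near[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def pam_cluster(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    metric: str = "euclidean",
    max_iter: int = 300,
) -> PAMResult:
    """Partitioning around medoids with BUILD initialization and SWAP descent.

    ``metric`` is ``'euclidean'`` or ``'correlation'`` (1 - Pearson r).  The
    algorithm is fully deterministic: BUILD picks the greedy cost-minimizing
    medoids (ties to the lowest index) and SWAP accepts the single best
    cost-decreasing (medoid, non-medoid) exchange until none remains.  Total
    cost is the sum of distances of every point to its medoid.  The display
    ordering sorts clusters by an average-linkage hierarchy over the medoid
    profiles and, within a cluster, by distance to the medoid.
    """
    X = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, dtype=float)
    n = X.shape[0]
    if k >= n + 1 or k < 1:
        raise ValueError(f"k must be in [1, n]; got k={k}, n={n}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    D = squareform(pdist(X, metric=metric)) if n > 1 else np.zeros((1, 1))

    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        cost = D[:, medoids].min(axis=1).sum()
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = D[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]

    medoids_arr = np.array(sorted(medoids))
    assign = np.argmin(D[:, medoids_arr], axis=1)
    cost = float(D[np.arange(n), medoids_arr[assign]].sum())

    if k > 1:
        Z = average(pdist(X[medoids_arr], metric=metric))
        cluster_rank = {int(c): r for r, c in enumerate(leaves_list(Z))}
    else:
        cluster_rank = {0: 0}
    d_own = D[np.arange(n), medoids_arr[assign]]
    order = np.lexsort((d_own, np.array([cluster_rank[int(a)] for a in assign])))
    return PAMResult(medoid_indices=medoids_arr, labels=assign, cost=cost, order=order)
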