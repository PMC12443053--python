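"""Ancillary quantifications and nonparametric comparisons.

Covers the scalar endpoints around the behavioral and survival analyses:

* **Scutal index** — tick engorgement proxy: alloscutum length divided by
  scutum width (the scutum does not distend during feeding, so the ratio
  grows with feeding success).
* **Δ perfusion** — laser-speckle ROI signal minus image background,
  averaged over a 20-s time of interest, in perfusion units.
* **Hourly bout distributions** — bout counts per 1-h bin normalised to a
  probability distribution, with per-bin surprisal −ln p in nats.
* **Two-sample Kolmogorov-Smirnov** and **Mann-Whitney U** tests with
  exact/permutation and asymptotic p-values.
* A permutation test of group separation in the (scratch bouts, ticks
  remaining) plane, reported next to Pearson/Spearman correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "scutal_index",
    "delta_perfusion",
    "HourlyBoutDistribution",
    "hourly_distribution",
    "ks_two_sample",
    "mann_whitney_u",
    "AssociationResult",
    "scratch_tick_association",
]


def scutal_index(alloscutum_length, scutum_width):
    """Engorgement index: alloscutum length / scutum width (vectorized)."""
    length = np.asarray(alloscutum_length, float)
    width = np.asarray(scutum_width, float)
    if np.any(width <= 0):
        raise ValueError("scutum_width must be > 0")
    if np.any(length <= 0):
        raise ValueError("alloscutum_length must be > 0")
    out = length / width
    return float(out) if out.ndim == 0 else out


def delta_perfusion(roi_series, bg_series, sample_rate_hz: float,
                    toi: tuple[float, float] = (20.0, 40.0)) -> float:
    """Background-subtracted perfusion, averaged over the time of interest.

    ``mean(roi over TOI) - mean(bg over TOI)``; the default TOI is the
    middle 20 s of a 1-min recording. Common offsets and common drift
    cancel exactly.
    """
    roi = np.asarray(roi_series, float)
    bg = np.asarray(bg_series, float)
    if roi.shape != bg.shape:
        raise ValueError("roi and background series must have equal length")
    lo, hi = toi
    n = roi.size
    i0, i1 = int(round(lo * sample_rate_hz)), int(round(hi * sample_rate_hz))
    if not (0 <= i0 < i1 <= n):
        raise ValueError(f"TOI [{lo}, {hi}] s outside the {n / sample_rate_hz} s recording")
    return float(roi[i0:i1].mean() - bg[i0:i1].mean())


@dataclass
class HourlyBoutDistribution:
    """Hourly bout counts with normalised probabilities and surprisal.

    ``surprisal`` is −ln p in nats; NaN marks empty bins (undefined).
    ``defined`` is False when there were no bouts at all.
    """

    counts: np.ndarray
    p: np.ndarray
    surprisal: np.ndarray
    defined: bool


def hourly_distribution(bout_start_times_s: Sequence[float],
                        duration_h: int) -> HourlyBoutDistribution:
    """Tumbling 1-h bins over bout start times, normalised to probabilities."""
    if duration_h < 1:
        raise ValueError("duration_h must be >= 1")
    starts = np.asarray(bout_start_times_s, float) / 3600.0
    counts, _ = np.histogram(starts, bins=np.arange(0.0, duration_h + 1.0))
    total = counts.sum()
    if total == 0:
        nanv = np.full(duration_h, np.nan)
        return HourlyBoutDistribution(counts, nanv, nanv.copy(), defined=False)
    p = counts / total
    with np.errstate(divide="ignore"):
        surprisal = np.where(p > 0, -np.log(np.where(p > 0, p, 1.0)), np.nan)
    return HourlyBoutDistribution(counts, p, surprisal, defined=True)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup |F̂x − F̂y| evaluated at the pooled order statistics."""
    xs, ys = np.sort(x), np.sort(y)
    pooled = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, pooled, side="right") / xs.size
    fy = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.abs(fx - fy).max())


def ks_two_sample(x, y, method: str = "asymptotic", seed: int | None = None,
                  reps: int = 5000, enumeration_limit: int = 200_000,
                  ) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``method="asymptotic"`` uses the Kolmogorov limiting distribution at
    the effective sample size; ``method="permutation"`` permutes the
    pooled labels — enumerating *all* C(n+m, n) splits exactly when that
    count is within ``enumeration_limit``, otherwise sampling ``reps``
    seeded shuffles. Returns (D, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_d(x, y)
    n, m = x.size, y.size
    if method == "asymptotic":
        en = math.sqrt(n * m / (n + m))
        p = float(sstats.kstwobign.sf(en * d))
        return d, min(max(p, 0.0), 1.0)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    total = math.comb(n + m, n)
    if total <= enumeration_limit:
        hits = 0
        idx_all = np.arange(n + m)
        for comb in itertools.combinations(range(n + m), n):
            sel = np.zeros(n + m, bool)
            sel[list(comb)] = True
            if _ks_d(pooled[sel], pooled[~sel]) >= d - 1e-12:
                hits += 1
        return d, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        perm = rng.permutation(pooled)
        if _ks_d(perm[:n], perm[n:]) >= d - 1e-12:
            hits += 1
    return d, (1 + hits) / (1 + reps)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: pairs with x > y count 1, ties count 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Null counts of U = 0..nm over all C(n+m, n) rank arrangements.

    Uses the counting recurrence
    ``N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1)`` — equivalent to
    full enumeration of interleavings, computed without listing them.
    """
    nm = n * m
    A = np.zeros((n + 1, nm + 1))
    A[:, 0] = 1.0  # m = 0: U is forced to 0
    for j in range(1, m + 1):
        B = np.zeros_like(A)
        B[0, 0] = 1.0
        for i in range(1, n + 1):
            B[i] = A[i]
            B[i, j:] += B[i - 1, : nm + 1 - j]
        A = B
    return A[n]


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test, two-sided. Returns (U for x, p).

    ``method="exact"`` uses the exact null distribution of U (no ties
    allowed); ``"normal"`` the tie-corrected normal approximation with
    continuity correction; ``"auto"`` picks exact when there are no ties
    and n·m <= 10⁴.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (not has_ties and n * m <= 10_000) else "normal"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free samples")
        dist = _exact_u_distribution(n, m)
        total = dist.sum()
        k = int(round(u))
        p_le = dist[: k + 1].sum() / total
        p_ge = dist[k:].sum() / total
        return u, float(min(1.0, 2.0 * min(p_le, p_ge)))
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * (n + m + 1.0 - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sstats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Scratch-vs-ticks association
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    """Correlations plus a permutation test of group separation.

    ``separation`` is the mean pairwise squared distance between group
    centroids in the standardized (scratch, ticks) plane; ``permutation_p``
    is its label-permutation p-value.
    """

    pearson_r: float
    spearman_rho: float
    separation: float
    permutation_p: float
    n_permutations: int
    degenerate: bool = False


def _separation(z: np.ndarray, gidx: np.ndarray, k: int) -> float:
    cents = np.stack([z[gidx == g].mean(axis=0) for g in range(k)])
    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    return float(np.mean([((cents[a] - cents[b]) ** 2).sum() for a, b in pairs]))


def scratch_tick_association(scratch_totals, ticks_remaining, group_labels,
                             reps: int = 5000, seed: int | None = None,
                             ) -> AssociationResult:
    """Association between per-animal scratch totals and ticks remaining.

    Reports Pearson and Spearman correlations across all animals, and a
    seeded permutation test of group separation: group labels are shuffled
    against the standardized bivariate observations and the mean pairwise
    squared centroid distance is recomputed. Requires >= 3 animals per
    group; constant variables make the correlations undefined (NaN,
    ``degenerate=True``).
    """
    s = np.asarray(scratch_totals, float)
    t = np.asarray(ticks_remaining, float)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    k = groups.size
    gidx = np.searchsorted(groups, labels)
    for g, lab in enumerate(groups):
        if (gidx == g).sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 animals")
    degenerate = s.std() == 0 or t.std() == 0
    if degenerate:
        pr = rho = np.nan
    else:
        pr = float(sstats.pearsonr(s, t).statistic)
        rho = float(sstats.spearmanr(s, t).statistic)

    def z(v):
        sd = v.std(ddof=0)
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    zmat = np.column_stack([z(s), z(t)])
    obs = _separation(zmat, gidx, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        if _separation(zmat, rng.permutation(gidx), k) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + reps)
    return AssociationResult(pr, rho, obs, p, reps, degenerate)
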