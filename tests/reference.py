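"""Independent, deliberately naive reference implementations.

Everything here recomputes quantities frame-by-frame / record-by-record
with explicit loops, sharing no code path with the package, so tests can
assert agreement between the optimized implementations and a transparent
re-derivation.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Smoothing / channels
# ---------------------------------------------------------------------------


def naive_moving_average(x, window):
    x = np.asarray(x, float)
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - (window - 1) // 2)
        hi = min(n, i + window // 2 + 1)
        vals = [v for v in x[lo:hi] if np.isfinite(v)]
        out[i] = sum(vals) / len(vals) if vals else np.nan
        if not np.isfinite(x[i]):
            out[i] = np.nan
    return out


def naive_lowess_1d(y, window):
    y = np.asarray(y, float)
    n = len(y)
    h = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n, i + h + 1)
        xs = np.arange(lo, hi, dtype=float)
        ys = y[lo:hi]
        dmax = max(abs(xs - i)) if len(xs) > 1 else 0.0
        if dmax == 0:
            out[i] = y[i]
            continue
        w = np.clip(1 - (np.abs(xs - i) / dmax) ** 3, 0, None) ** 3
        if (w > 0).sum() < 2:
            out[i] = y[i]
            continue
        # weighted degree-1 polyfit (sqrt weights per numpy convention)
        coef = np.polyfit(xs, ys, 1, w=np.sqrt(w))
        out[i] = np.polyval(coef, i)
    return out


def naive_lowess_track(xy, window):
    xy = np.asarray(xy, float)
    return np.column_stack([naive_lowess_1d(xy[:, 0], window),
                            naive_lowess_1d(xy[:, 1], window)])


def naive_distance(xy, smoothed=False, window=9):
    xy = np.asarray(xy, float)
    if smoothed:
        xy = naive_lowess_track(xy, window)
    out = [0.0]
    for i in range(1, len(xy)):
        dx, dy = xy[i] - xy[i - 1]
        out.append((dx * dx + dy * dy) ** 0.5)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Frame-wise detection
# ---------------------------------------------------------------------------


def naive_detect(series, crit_a, crit_b, min_overlap=0.2):
    """Full detection chain recomputed with loops; returns validated
    (start_s, end_s, best_overlap) triples."""
    fr = series.frame_rate_hz
    events = {}
    for c in (crit_a, crit_b):
        elong = naive_moving_average(series.channel("elongation"),
                                     c.smoothing.get("elongation", 10))
        act = naive_moving_average(series.channel("activity"),
                                   c.smoothing.get("activity", 10))
        n = series.n_frames
        mask = []
        d_nose = d_cent = v_nose = v_cent = None
        if c.distance_max_nose is not None:
            d_nose = naive_distance(series.xy("nose"), True, c.lowess_window)
        if c.distance_max_center is not None:
            d_cent = naive_distance(series.xy("center"), True, c.lowess_window)
        vwin = c.smoothing.get("velocity", 10)
        if c.velocity_max_nose is not None:
            v_nose = naive_moving_average(naive_distance(series.xy("nose")) * fr, vwin)
        if c.velocity_max_center is not None:
            v_cent = naive_moving_average(naive_distance(series.xy("center")) * fr, vwin)
        inz = None
        if c.excluded_zone is not None:
            inz = series.frames[f"in_{c.excluded_zone}"].to_numpy(bool)
        for i in range(n):
            ok = (np.isfinite(elong[i]) and elong[i] < c.elongation_max
                  and np.isfinite(act[i]) and act[i] >= c.activity_min)
            if ok and d_nose is not None:
                ok = np.isfinite(d_nose[i]) and d_nose[i] < c.distance_max_nose
            if ok and d_cent is not None:
                ok = np.isfinite(d_cent[i]) and d_cent[i] < c.distance_max_center
            if ok and v_nose is not None:
                ok = np.isfinite(v_nose[i]) and v_nose[i] < c.velocity_max_nose
            if ok and v_cent is not None:
                ok = np.isfinite(v_cent[i]) and v_cent[i] < c.velocity_max_center
            if ok and inz is not None:
                ok = not inz[i]
            mask.append(bool(ok))
        # segment maximal runs, then duration-filter
        evs = []
        i = 0
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if (j - i) / fr >= c.min_duration_s - 1e-9:
                    evs.append((i / fr, j / fr))
                i = j
            else:
                i += 1
        events[c.name] = evs
    out = []
    for (sa, ea) in events[crit_a.name]:
        best = 0.0
        for (sb, eb) in events[crit_b.name]:
            inter = min(ea, eb) - max(sa, sb)
            if inter > 0:
                best = max(best, inter / min(ea - sa, eb - sb))
        if best >= min_overlap - 1e-9:
            out.append((sa, ea, best))
    return out


# ---------------------------------------------------------------------------
# Survival oracles
# ---------------------------------------------------------------------------


def km_redistribute(times, events):
    """Redistribute-to-the-right survival estimate.

    Each observation starts with mass 1/n; a censored observation passes
    its mass equally to all strictly later observations; survival drops by
    the (accumulated) mass of each event. Returns (event_times, S).
    """
    order = sorted(range(len(times)), key=lambda i: (times[i], events[i]), reverse=False)
    # at equal times process events before censorings (event=1 first)
    order = sorted(range(len(times)), key=lambda i: (times[i], -events[i]))
    mass = [1.0 / len(times)] * len(times)
    s = 1.0
    out_t, out_s = [], []
    for pos, i in enumerate(order):
        if events[i] == 1:
            s -= mass[i]
            out_t.append(times[i])
            out_s.append(s)
        else:
            later = [j for j in order[pos + 1:] if times[j] > times[i]]
            if later:
                share = mass[i] / len(later)
                for j in later:
                    mass[j] += share
            mass[i] = 0.0
    # collapse tied event times to the last (lowest) S
    coll = {}
    for t, s_ in zip(out_t, out_s):
        coll[t] = s_
    ts = sorted(coll)
    return np.asarray(ts), np.asarray([coll[t] for t in ts])


def peto_peto_direct(times, events, labels):
    """Direct summation of the Peto-Peto weighted log-rank chi-square for
    two groups, term by term."""
    groups = sorted(set(labels))
    assert len(groups) == 2
    ts = sorted({t for t, e in zip(times, events) if e == 1})
    w = 1.0
    U = 0.0
    V = 0.0
    for ti in ts:
        n = sum(1 for t in times if t >= ti)
        d = sum(1 for t, e in zip(times, events) if t == ti and e == 1)
        n1 = sum(1 for t, lab in zip(times, labels) if t >= ti and lab == groups[0])
        d1 = sum(1 for t, e, lab in zip(times, events, labels)
                 if t == ti and e == 1 and lab == groups[0])
        w *= (n - d + 1) / (n + 1)
        U += w * (d1 - d * n1 / n)
        if n > 1:
            V += w * w * d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return (U * U / V) if V > 0 else 0.0
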