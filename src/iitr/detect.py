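"""Rule-based scratch-bout detection.

A scratch bout — the behavioral proxy for itch directed at the tick
attachment site — is operationalised as a contiguous epoch that passes two
"multi-condition" frame-wise criteria and a set of event filters:

* **Criterion A** (broad): smoothed body elongation below 47 % (the animal
  is hunched) and smoothed activity at least 0.1 %.
* **Criterion B** (strict): elongation below 46.5 %, activity at least
  0.26 %, nose-/center-point distance moved below 0.58 / 0.3 cm per frame
  on the lowess-smoothed track, nose-/center-point velocity below
  12 / 5 cm/s (smoothed), and the nose point outside the feeder zone.

Frame masks are segmented into maximal runs of true frames; A-events
shorter than 1 s and B-events shorter than 0.66 s are discarded; an
A-event survives only if it overlaps some B-event by at least 20 % of the
shorter event's duration. Channels are smoothed first and thresholded
second, matching the per-clause smoothing windows of the tracking
software's condition editor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tracking import TrackingSeries, Zone, distance_moved, in_zone, moving_average, velocity

__all__ = [
    "DetectionCriterion",
    "BoutEvent",
    "CRITERION_A",
    "CRITERION_B",
    "evaluate_criterion",
    "segment_events",
    "filter_duration",
    "overlap_fraction",
    "cross_validate",
    "detect_bouts",
    "trim_preamble",
    "summarize",
    "score_detection",
    "events_to_frame",
]

#: Float slack for duration comparisons (durations are integer multiples of
#: the frame period; this only absorbs representation error).
_EPS = 1e-9


@dataclass(frozen=True)
class DetectionCriterion:
    """A named conjunction of thresholded, smoothed channel predicates.

    Thresholds are strict upper bounds except ``activity_min`` which is
    inclusive (">="), exactly as printed in tracking-software condition
    editors. Optional clauses are skipped when None. ``smoothing`` maps
    channel names to moving-average windows (samples); ``lowess_window``
    is the track-smoothing window used for the distance clauses.
    """

    name: str
    elongation_max: float
    activity_min: float
    min_duration_s: float
    distance_max_nose: float | None = None
    distance_max_center: float | None = None
    velocity_max_nose: float | None = None
    velocity_max_center: float | None = None
    excluded_zone: str | None = None
    smoothing: Mapping[str, int] = field(
        default_factory=lambda: {"elongation": 10, "activity": 10, "velocity": 10}
    )
    lowess_window: int = 9

    def __post_init__(self) -> None:
        for f in ("elongation_max", "activity_min", "min_duration_s"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{self.name}: {f} must be > 0")
        for f in ("distance_max_nose", "distance_max_center",
                  "velocity_max_nose", "velocity_max_center"):
            v = getattr(self, f)
            if v is not None and not v > 0:
                raise ValueError(f"{self.name}: {f} must be > 0 when present")


CRITERION_A = DetectionCriterion(
    name="A", elongation_max=47.0, activity_min=0.1, min_duration_s=1.0
)

CRITERION_B = DetectionCriterion(
    name="B", elongation_max=46.5, activity_min=0.26, min_duration_s=0.66,
    distance_max_nose=0.58, distance_max_center=0.3,
    velocity_max_nose=12.0, velocity_max_center=5.0,
    excluded_zone="feeder",
)


@dataclass(frozen=True)
class BoutEvent:
    """A contiguous interval classified under one criterion (or validated).

    Times are seconds from recording start; intervals are half-open
    ``[start_s, end_s)``. ``overlap_fraction`` is set only on validated
    bouts and carries the best cross-criterion overlap.
    """

    start_s: float
    end_s: float
    source: str
    overlap_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# Frame-wise evaluation
# ---------------------------------------------------------------------------


def evaluate_criterion(series: TrackingSeries, criterion: DetectionCriterion,
                       zones: Mapping[str, Zone] | None = None) -> np.ndarray:
    """Boolean mask: frame true iff every present clause holds.

    Channels are smoothed per the criterion's windows before thresholding.
    Missing-flagged (NaN) samples make their clause — hence the frame —
    false. The excluded-zone clause uses a precomputed ``in_<zone>``
    channel when the series carries one, otherwise computes membership
    from a geometry in ``zones``.
    """
    c = criterion
    elong = moving_average(series.channel("elongation"), c.smoothing.get("elongation", 10))
    act = moving_average(series.channel("activity"), c.smoothing.get("activity", 10))
    # NaN compares False, which is exactly the missing-frame rule.
    mask = (elong < c.elongation_max) & (act >= c.activity_min)

    if c.distance_max_nose is not None:
        d = distance_moved(series.xy("nose"), smoothed=True, lowess_window=c.lowess_window)
        mask &= d < c.distance_max_nose
    if c.distance_max_center is not None:
        d = distance_moved(series.xy("center"), smoothed=True, lowess_window=c.lowess_window)
        mask &= d < c.distance_max_center
    vwin = c.smoothing.get("velocity", 10)
    if c.velocity_max_nose is not None:
        v = moving_average(velocity(series.xy("nose"), series.frame_rate_hz), vwin)
        mask &= v < c.velocity_max_nose
    if c.velocity_max_center is not None:
        v = moving_average(velocity(series.xy("center"), series.frame_rate_hz), vwin)
        mask &= v < c.velocity_max_center
    if c.excluded_zone is not None:
        col = f"in_{c.excluded_zone}"
        if col in series.frames.columns:
            inz = series.frames[col].to_numpy(bool)
        elif zones is not None and c.excluded_zone in zones:
            inz = in_zone(series.xy("nose"), zones[c.excluded_zone])
        else:
            raise ValueError(
                f"criterion {c.name!r} requires channel {col!r} "
                f"(or a geometry for zone {c.excluded_zone!r})"
            )
        mask &= ~inz
    return mask


# ---------------------------------------------------------------------------
# Event segmentation and filtering
# ---------------------------------------------------------------------------


def segment_events(mask: np.ndarray, frame_rate_hz: float,
                   max_gap_frames: int = 0, source: str = "") -> list[BoutEvent]:
    """Maximal runs of true frames as half-open events.

    Runs separated by at most ``max_gap_frames`` false frames are merged.
    Event times are ``[first/fr, (last+1)/fr)``.
    """
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        raise ValueError("mask is empty")
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    if starts.size and max_gap_frames > 0:
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged_e[-1] <= max_gap_frames:
                merged_e[-1] = e
            else:
                merged_s.append(s)
                merged_e.append(e)
        starts, ends = np.asarray(merged_s), np.asarray(merged_e)
    fr = frame_rate_hz
    return [BoutEvent(s / fr, e / fr, source) for s, e in zip(starts, ends)]


def filter_duration(events: Iterable[BoutEvent], min_duration_s: float) -> list[BoutEvent]:
    """Drop events strictly shorter than the floor; boundary events stay."""
    if not min_duration_s > 0:
        raise ValueError("min_duration_s must be > 0")
    return [e for e in events if e.duration_s >= min_duration_s - _EPS]


def overlap_fraction(e1: BoutEvent, e2: BoutEvent) -> float:
    """Shared time as a fraction of the *shorter* event's duration.

    The symmetric, conservative choice of denominator: identical intervals
    give 1, disjoint give 0.
    """
    inter = min(e1.end_s, e2.end_s) - max(e1.start_s, e2.start_s)
    if inter <= 0:
        return 0.0
    return min(1.0, inter / min(e1.duration_s, e2.duration_s))


def cross_validate(events_a: Sequence[BoutEvent], events_b: Sequence[BoutEvent],
                   min_overlap: float = 0.2) -> list[BoutEvent]:
    """Retain A-events whose best overlap against any B-event is >= ``min_overlap``.

    The retained interval is the A-event (A is the broad detector, B the
    validator); many A-events may share one B-event. The result carries
    source "validated" and the best overlap fraction, sorted by start.
    """
    out = []
    for a in events_a:
        best = max((overlap_fraction(a, b) for b in events_b), default=0.0)
        if best >= min_overlap - _EPS:
            out.append(BoutEvent(a.start_s, a.end_s, "validated", best))
    out.sort(key=lambda e: (e.start_s, e.end_s))
    return out


def detect_bouts(series: TrackingSeries,
                 criterion_a: DetectionCriterion = CRITERION_A,
                 criterion_b: DetectionCriterion = CRITERION_B,
                 min_overlap: float = 0.2,
                 max_gap_frames: int = 0,
                 zones: Mapping[str, Zone] | None = None,
                 ) -> tuple[list[BoutEvent], dict]:
    """Full detection chain: evaluate → segment → duration filter → cross-validate.

    Returns the validated bouts and an audit trail of the counts surviving
    each stage — the machine-readable stand-in for the study's manual
    verification step.
    """
    audit: dict = {"n_frames": series.n_frames, "frame_rate_hz": series.frame_rate_hz}
    per_crit = {}
    for crit in (criterion_a, criterion_b):
        mask = evaluate_criterion(series, crit, zones)
        events = segment_events(mask, series.frame_rate_hz, max_gap_frames, source=crit.name)
        kept = filter_duration(events, crit.min_duration_s)
        audit[f"criterion_{crit.name}"] = {
            "true_frames": int(mask.sum()),
            "candidate_events": len(events),
            "after_duration_filter": len(kept),
            "min_duration_s": crit.min_duration_s,
        }
        per_crit[crit.name] = kept
    bouts = cross_validate(per_crit[criterion_a.name], per_crit[criterion_b.name], min_overlap)
    audit["min_overlap"] = min_overlap
    audit["validated"] = len(bouts)
    return bouts, audit


def trim_preamble(series: TrackingSeries, min_present_s: float = 5.0,
                  activity_min: float = 0.05) -> tuple[TrackingSeries, int]:
    """Trim frames before the session-start gate.

    The session starts at the first frame from which the center point is
    continuously detected for ``min_present_s`` and whose activity exceeds
    ``activity_min`` — the rule used to mark cage presence / anesthesia
    recovery. Returns the trimmed series and the number of frames dropped.
    """
    fr = series.frame_rate_hz
    need = int(round(min_present_s * fr))
    present = np.isfinite(series.xy("center")).all(axis=1)
    act = series.channel("activity")
    # forward run length of presence at each frame
    runlen = np.zeros(series.n_frames, dtype=np.int64)
    run = 0
    for i in range(series.n_frames - 1, -1, -1):
        run = run + 1 if present[i] else 0
        runlen[i] = run
    ok = (runlen >= need) & (act > activity_min)
    idx = np.flatnonzero(ok)
    start = int(idx[0]) if idx.size else series.n_frames
    return series.slice_frames(start), start


# ---------------------------------------------------------------------------
# Summaries and evaluation helpers
# ---------------------------------------------------------------------------


def summarize(bouts: Sequence[BoutEvent], window_s: float = 43200.0,
              duration_s: float | None = None) -> pd.DataFrame:
    """Bout frequency and total duration over tumbling windows from time 0.

    A bout is counted once, in the window containing its start; its full
    duration accrues to that window. ``duration_s`` fixes the number of
    windows (otherwise the span of the bouts, minimum one window).
    """
    if not window_s > 0:
        raise ValueError("window_s must be > 0")
    span = duration_s if duration_s is not None else max(
        (b.end_s for b in bouts), default=window_s)
    n_win = max(1, int(np.ceil(span / window_s - _EPS)))
    freq = np.zeros(n_win, dtype=int)
    total = np.zeros(n_win)
    for b in bouts:
        w = min(int(b.start_s / window_s), n_win - 1)
        freq[w] += 1
        total[w] += b.duration_s
    return pd.DataFrame({
        "window_start_s": np.arange(n_win) * window_s,
        "window_end_s": (np.arange(n_win) + 1) * window_s,
        "frequency": freq,
        "total_duration_s": total,
    })


def events_to_frame(events: Sequence[BoutEvent]) -> pd.DataFrame:
    """Tidy table of events (start_s, end_s, duration_s, source, overlap)."""
    return pd.DataFrame({
        "start_s": [e.start_s for e in events],
        "end_s": [e.end_s for e in events],
        "duration_s": [e.duration_s for e in events],
        "source": [e.source for e in events],
        "overlap_fraction": [e.overlap_fraction for e in events],
    })


def score_detection(detected: Sequence[BoutEvent],
                    truth: Sequence[tuple[float, float]],
                    min_cover: float = 0.5) -> dict:
    """Recall / precision of detected bouts against ground-truth intervals.

    A truth interval is recalled if some detected bout covers at least
    ``min_cover`` of it; a detected bout is a true positive if it overlaps
    some truth interval by at least ``min_cover`` of the shorter of the two.
    """
    truth_ev = [BoutEvent(s, e, "truth") for s, e in truth]
    recalled = 0
    for t in truth_ev:
        cover = max(((min(t.end_s, d.end_s) - max(t.start_s, d.start_s)) / t.duration_s
                     for d in detected), default=0.0)
        if cover >= min_cover:
            recalled += 1
    tp = sum(
        1 for d in detected
        if max((overlap_fraction(d, t) for t in truth_ev), default=0.0) >= min_cover
    )
    recall = recalled / len(truth_ev) if truth_ev else 1.0
    precision = tp / len(detected) if detected else 1.0
    return {"recall": recall, "precision": precision,
            "n_truth": len(truth_ev), "n_detected": len(detected)}
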