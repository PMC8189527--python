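"""Rule-based detection of multi-OGD gaze patterns.

When the distances from the gaze point to two AOIs are plotted together as a
multi-OGD time series, four recurring shapes emerge:

1. **glance** — the gaze darts onto one object (an AOI Hit, OGD = 0) while the
   distance to the other object grows, then reverts to a similar position as
   before the Hit; a quick status check.
2. **convergence** — both distances shrink together until both objects sit
   inside the foveal field, ending with a Hit on exactly one of them; the gaze
   has moved to the interconnection point of the two objects.
3. **joint excursion** — both distances rise out of the perifoveal field
   simultaneously and return within a few fixations.
4. **disappearance** — one distance climbs beyond the near-peripheral
   threshold (or the AOI stops being detected) while the other object stays
   close to the gaze point; the object has left the field of view.

The published descriptions of these shapes are qualitative; the quantitative
onset/offset rules here (tolerances, windows, the strict Hit requirement in
patterns 1-2) are this module's own operational definitions, exposed as
parameters so they can be tightened or relaxed.

Detectors operate on fixation-indexed series (one value per fixation, not
wall-clock time) and report events as fixation-id spans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .camera import VisionFieldSpec, TABLE_DEFAULT_THRESHOLDS_PX
from .core import OGDSeries

__all__ = [
    "PatternParams",
    "PatternEvent",
    "PATTERN_NAMES",
    "detect_glance",
    "detect_convergence",
    "detect_joint_excursion",
    "detect_disappearance",
    "detect_all",
    "paired_series",
    "summarize_patterns",
]

PATTERN_NAMES = ("glance", "convergence", "joint_excursion", "disappearance")


def _default_spec() -> VisionFieldSpec:
    return VisionFieldSpec(*TABLE_DEFAULT_THRESHOLDS_PX, source="table_defaults")


@dataclass(frozen=True)
class PatternParams:
    """Tunable thresholds of the pattern detectors.

    ``tolerance_px`` is the counter-movement allowed inside a "monotone"
    stretch and the minimum movement considered a real increase;
    ``return_window`` / ``return_tolerance_px`` define "reverts to a similar
    position as before" for the glance pattern.
    """

    field_spec: VisionFieldSpec = field(default_factory=_default_spec)
    min_len: int = 2
    tolerance_px: float = 5.0
    return_window: int = 3
    return_tolerance_px: float = 30.0

    def __post_init__(self) -> None:
        if self.min_len < 1 or self.tolerance_px <= 0 or self.return_window < 1 \
                or self.return_tolerance_px <= 0:
            raise ValidationError("all pattern thresholds must be positive")
        if self.tolerance_px >= self.field_spec.foveal_px:
            raise ValidationError(
                f"tolerance_px ({self.tolerance_px}) must be smaller than the "
                f"foveal threshold ({self.field_spec.foveal_px})"
            )


@dataclass(frozen=True)
class PatternEvent:
    """One detected gaze pattern, spanning fixations start_fix..end_fix."""

    pattern: str
    start_fix: int
    end_fix: int
    aois: tuple[str, str]
    hit_aoi: str | None = None
    notes: str = ""


def _prepare(
    a: Sequence[float], b: Sequence[float], fixation_ids: Sequence[int] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"series must be aligned 1-D arrays, got shapes {a.shape} and {b.shape}"
        )
    if fixation_ids is None:
        ids = np.arange(len(a))
    else:
        ids = np.asarray(fixation_ids)
        if ids.shape != a.shape:
            raise ValidationError("fixation_ids must align with the series")
    return a, b, ids


def detect_glance(
    a: Sequence[float],
    b: Sequence[float],
    params: PatternParams | None = None,
    fixation_ids: Sequence[int] | None = None,
    aois: tuple[str, str] = ("A", "B"),
) -> list[PatternEvent]:
    """Pattern 1: a Hit on AOI A while the OGD of B increases, then a revert.

    An event needs (i) a run of OGD(A) == 0, (ii) OGD(B) rising by more than
    ``tolerance_px`` above its pre-Hit value during the run, and (iii) OGD(A)
    returning to within ``return_tolerance_px`` of its pre-Hit value within
    ``return_window`` fixations after the run.  A Hit that never ends is a
    sustained fixation, not a glance.
    """
    params = params or PatternParams()
    a, b, ids = _prepare(a, b, fixation_ids)
    events: list[PatternEvent] = []
    n = len(a)
    i = 1
    while i < n:
        if a[i] != 0.0 or a[i - 1] == 0.0:
            i += 1
            continue
        i0 = i  # start of a Hit run with a pre-Hit baseline at i0-1
        i1 = i0
        while i1 + 1 < n and a[i1 + 1] == 0.0:
            i1 += 1
        pre = a[i0 - 1]
        rises = np.max(b[i0 : i1 + 1]) > b[i0 - 1] + params.tolerance_px
        returned_at = None
        if rises:
            for j in range(i1 + 1, min(i1 + params.return_window, n - 1) + 1):
                if a[j] > 0.0 and abs(a[j] - pre) <= params.return_tolerance_px:
                    returned_at = j
                    break
        if returned_at is not None:
            events.append(
                PatternEvent(
                    pattern="glance",
                    start_fix=int(ids[i0 - 1]),
                    end_fix=int(ids[returned_at]),
                    aois=aois,
                    hit_aoi=aois[0],
                )
            )
            i = returned_at + 1
        else:
            i = i1 + 1
    return events


def detect_convergence(
    a: Sequence[float],
    b: Sequence[float],
    params: PatternParams | None = None,
    fixation_ids: Sequence[int] | None = None,
    aois: tuple[str, str] = ("A", "B"),
) -> list[PatternEvent]:
    """Pattern 2: both OGDs decrease together into the foveal field, one Hit.

    Both series must be non-increasing (allowing ``tolerance_px`` of
    counter-movement per step) over at least ``min_len`` steps, both must end
    below the foveal threshold with a net decrease larger than the tolerance,
    and exactly one AOI must register a Hit (0 px) at the end.
    """
    params = params or PatternParams()
    a, b, ids = _prepare(a, b, fixation_ids)
    fov = params.field_spec.foveal_px
    tol = params.tolerance_px
    events: list[PatternEvent] = []
    n = len(a)
    e = 0
    while e < n:
        one_hit = (a[e] == 0.0) != (b[e] == 0.0)
        if not (one_hit and a[e] < fov and b[e] < fov):
            e += 1
            continue
        s = e
        while s > 0 and a[s] <= a[s - 1] + tol and b[s] <= b[s - 1] + tol:
            s -= 1
        long_enough = e - s >= params.min_len
        net_decrease = a[s] - a[e] > tol and b[s] - b[e] > tol
        if long_enough and net_decrease:
            hit = aois[0] if a[e] == 0.0 else aois[1]
            events.append(
                PatternEvent(
                    pattern="convergence",
                    start_fix=int(ids[s]),
                    end_fix=int(ids[e]),
                    aois=aois,
                    hit_aoi=hit,
                )
            )
            # skip the rest of this Hit run so one approach yields one event
            while e + 1 < n and ((a[e + 1] == 0.0) != (b[e + 1] == 0.0)):
                e += 1
        e += 1
    return events


def detect_joint_excursion(
    a: Sequence[float],
    b: Sequence[float],
    params: PatternParams | None = None,
    fixation_ids: Sequence[int] | None = None,
    aois: tuple[str, str] = ("A", "B"),
) -> list[PatternEvent]:
    """Pattern 3: both OGDs leave the perifoveal field together and return.

    Both series must cross the perifoveal threshold upward on the same
    fixation (both below it on the previous one), stay with at least one of
    them outside for one or more fixations, and both return below the
    threshold before the series ends; a rise without a return is not an event.
    """
    params = params or PatternParams()
    a, b, ids = _prepare(a, b, fixation_ids)
    peri = params.field_spec.perifoveal_px
    events: list[PatternEvent] = []
    n = len(a)
    i = 1
    while i < n:
        crossed_up = (
            a[i] >= peri and b[i] >= peri and a[i - 1] < peri and b[i - 1] < peri
        )
        if not crossed_up:
            i += 1
            continue
        j = i + 1
        while j < n and (a[j] >= peri or b[j] >= peri):
            j += 1
        if j < n:  # both back inside the perifoveal field
            events.append(
                PatternEvent(
                    pattern="joint_excursion",
                    start_fix=int(ids[i - 1]),
                    end_fix=int(ids[j]),
                    aois=aois,
                )
            )
            i = j + 1
        else:
            i = j
    return events


def detect_disappearance(
    a: Sequence[float],
    b: Sequence[float],
    params: PatternParams | None = None,
    fixation_ids: Sequence[int] | None = None,
    aois: tuple[str, str] = ("A", "B"),
) -> list[PatternEvent]:
    """Pattern 4: one OGD climbs beyond the near-peripheral threshold (or the
    AOI becomes undetected, i.e. sentinel-capped) while the other object stays
    inside the perifoveal field throughout.

    Checked in both role assignments, so either AOI may be the vanishing one.
    """
    params = params or PatternParams()
    a, b, ids = _prepare(a, b, fixation_ids)
    near = params.field_spec.near_peripheral_px
    peri = params.field_spec.perifoveal_px
    events: list[PatternEvent] = []
    n = len(a)
    for hi, lo, hi_label in ((a, b, aois[0]), (b, a, aois[1])):
        i = 1
        while i < n:
            rises = (
                hi[i] >= near
                and hi[i - 1] < near
                and lo[i] < peri
                and lo[i - 1] < peri
            )
            if not rises:
                i += 1
                continue
            j = i
            while j + 1 < n and hi[j + 1] >= near and lo[j + 1] < peri:
                j += 1
            events.append(
                PatternEvent(
                    pattern="disappearance",
                    start_fix=int(ids[i - 1]),
                    end_fix=int(ids[j]),
                    aois=aois,
                    notes=f"vanishing={hi_label}",
                )
            )
            i = j + 1
    return sorted(events, key=lambda ev: (ev.start_fix, ev.end_fix))


def paired_series(
    series: OGDSeries, aoi_a: str, aoi_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract aligned per-fixation OGD arrays for two AOIs of one trial."""
    rec_a = {r.fixation_id: r.ogd_px for r in series.for_aoi(aoi_a)}
    rec_b = {r.fixation_id: r.ogd_px for r in series.for_aoi(aoi_b)}
    if rec_a.keys() != rec_b.keys():
        raise ValidationError(
            f"series for {aoi_a!r} and {aoi_b!r} cover different fixations"
        )
    ids = np.array(series.fixation_ids)
    return (
        np.array([rec_a[i] for i in ids]),
        np.array([rec_b[i] for i in ids]),
        ids,
    )


_DETECTORS = {
    "glance": detect_glance,
    "convergence": detect_convergence,
    "joint_excursion": detect_joint_excursion,
    "disappearance": detect_disappearance,
}


def detect_all(
    series_map: Mapping[str, Sequence[float]] | OGDSeries,
    params: PatternParams | None = None,
    fixation_ids: Sequence[int] | None = None,
) -> list[PatternEvent]:
    """Run all four detectors over every AOI pair; deduplicated, time-sorted.

    ``series_map`` is either a mapping AOI label -> per-fixation OGD array, or
    an :class:`~ogd.core.OGDSeries` (pairs are extracted automatically).  The
    directional glance detector runs in both orientations per pair; the other
    three handle both roles internally.  Overlapping events of different types
    are all reported.
    """
    params = params or PatternParams()
    if isinstance(series_map, OGDSeries):
        labels = series_map.aoi_labels
        if len(labels) < 2:
            raise ValidationError(f"need >= 2 AOIs, got {labels}")
        pairs = {}
        for la, lb in itertools.combinations(labels, 2):
            a, b, ids = paired_series(series_map, la, lb)
            pairs[(la, lb)] = (a, b, ids)
    else:
        labels = sorted(series_map)
        if len(labels) < 2:
            raise ValidationError(f"need >= 2 AOIs, got {labels}")
        pairs = {
            (la, lb): (
                np.asarray(series_map[la], dtype=float),
                np.asarray(series_map[lb], dtype=float),
                None,
            )
            for la, lb in itertools.combinations(labels, 2)
        }
    events: set[PatternEvent] = set()
    for (la, lb), (a, b, ids) in pairs.items():
        if ids is None:
            ids = np.arange(len(a))
        events.update(detect_glance(a, b, params, ids, aois=(la, lb)))
        events.update(detect_glance(b, a, params, ids, aois=(lb, la)))
        events.update(detect_convergence(a, b, params, ids, aois=(la, lb)))
        events.update(detect_joint_excursion(a, b, params, ids, aois=(la, lb)))
        events.update(detect_disappearance(a, b, params, ids, aois=(la, lb)))
    return sorted(events, key=lambda ev: (ev.start_fix, ev.end_fix, ev.pattern))


def summarize_patterns(
    trials_events: Sequence[Sequence[PatternEvent]],
) -> pd.DataFrame:
    """Per-pattern total counts and per-trial mean +/- SD over trials.

    SD is the population standard deviation, so a single trial reports 0.
    """
    rows = []
    for pattern in PATTERN_NAMES:
        per_trial = np.array(
            [sum(ev.pattern == pattern for ev in evs) for evs in trials_events],
            dtype=float,
        )
        rows.append(
            {
                "pattern": pattern,
                "total_count": int(per_trial.sum()),
                "mean_per_trial": float(per_trial.mean()) if len(per_trial) else 0.0,
                "sd_per_trial": float(per_trial.std(ddof=0)) if len(per_trial) else 0.0,
            }
        )
    return pd.DataFrame(rows)
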