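"""Derived gaze metrics: AOI Hits, fixation rates, band occupancy, mask IoU.

The fixation rate (FR) of an AOI at a pixel threshold ``d`` is

    FR(d) = (number of fixations with OGD <= d) / (total number of fixations)

so FR(0) is the classical AOI-Hit rate and FR at the frame diagonal is 1
(sentinel records sit exactly at the cap).  Sweeping ``d`` from 0 to the frame
diagonal in 10 px steps yields the FR curve, a non-decreasing step function
that shows how much fixation data becomes interpretable as the accepted field
of vision widens from foveal toward near-peripheral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .camera import VisionBand, VisionFieldSpec, classify_vision_field, frame_diagonal_px
from .core import OGDSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FRCurve",
    "BandSummary",
    "fixation_rate",
    "fr_curve",
    "fr_curve_multi",
    "aoi_hits",
    "band_summary",
    "mask_iou",
]


@dataclass
class FRCurve:
    """Fixation-rate curve of one AOI over a grid of distance thresholds."""

    aoi_label: str
    distances_px: np.ndarray
    fr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aoi_label": self.aoi_label,
                "distance_px": self.distances_px,
                "fr": self.fr,
            }
        )


@dataclass
class BandSummary:
    """Per-visual-field-band fixation counts and fractions for one AOI."""

    aoi_label: str
    counts: dict[VisionBand, int]
    fractions: dict[VisionBand, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aoi_label": self.aoi_label,
                "band": [b.value for b in VisionBand],
                "count": [self.counts[b] for b in VisionBand],
                "fraction": [self.fractions[b] for b in VisionBand],
            }
        )


def _aoi_values(
    series: OGDSeries, aoi_label: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    recs = series.for_aoi(aoi_label)
    ids = np.array([r.fixation_id for r in recs])
    vals = np.array([r.ogd_px for r in recs], dtype=float)
    sent = np.array([r.sentinel for r in recs], dtype=bool)
    return ids, vals, sent


def fixation_rate(
    series: OGDSeries,
    aoi_label: str,
    threshold_px: float,
    durations_s: Mapping[int, float] | None = None,
) -> float:
    """Fraction of fixations whose OGD to ``aoi_label`` is <= ``threshold_px``.

    The comparison is inclusive, so a threshold of 0 reproduces the AOI-Hit
    rate.  Sentinel records count in the denominator and satisfy only the
    frame-diagonal cap.  With ``durations_s`` (fixation id -> seconds) the
    rate is dwell-time weighted instead of fixation-counted.
    """
    if threshold_px < 0:
        raise ValidationError(f"threshold must be non-negative, got {threshold_px}")
    ids, vals, _ = _aoi_values(series, aoi_label)
    within = vals <= threshold_px
    if durations_s is None:
        return float(np.count_nonzero(within) / len(vals))
    w = np.array([durations_s[int(i)] for i in ids], dtype=float)
    return float(w[within].sum() / w.sum())


def fr_curve(
    series: OGDSeries,
    aoi_label: str,
    step_px: float = 10.0,
    max_px: float | None = None,
    durations_s: Mapping[int, float] | None = None,
) -> FRCurve:
    """Fixation rate on the threshold grid {0, step, 2*step, ..., max}.

    Default grid: 0 to the frame diagonal in 10 px steps (161 points for the
    reference camera).
    """
    if step_px <= 0:
        raise ValidationError(f"step must be positive, got {step_px}")
    if max_px is None:
        max_px = frame_diagonal_px(series.camera)
    grid = np.arange(0.0, max_px + step_px / 2.0, step_px)
    _, vals, _ = _aoi_values(series, aoi_label)
    if durations_s is None:
        fr = np.count_nonzero(vals[None, :] <= grid[:, None], axis=1) / len(vals)
    else:
        fr = np.array(
            [fixation_rate(series, aoi_label, t, durations_s) for t in grid]
        )
    return FRCurve(aoi_label=aoi_label, distances_px=grid, fr=fr.astype(float))


def fr_curve_multi(
    trials: Sequence[OGDSeries],
    aoi_label: str,
    step_px: float = 10.0,
    max_px: float | None = None,
    mode: str = "per_trial",
) -> FRCurve:
    """FR curve across trials: per-trial curves averaged, or pooled counts.

    ``per_trial`` (default) computes one curve per trial and averages them, so
    every trial weighs equally regardless of its fixation count; ``pooled``
    concatenates all records into one denominator.
    """
    if not trials:
        raise ValidationError("need at least one trial")
    if mode == "per_trial":
        curves = [fr_curve(t, aoi_label, step_px, max_px) for t in trials]
        grid = curves[0].distances_px
        fr = np.mean([c.fr for c in curves], axis=0)
        return FRCurve(aoi_label=aoi_label, distances_px=grid, fr=fr)
    if mode == "pooled":
        from .core import OGDSeries as _S

        pooled = _S(
            records=[r for t in trials for r in t.records], camera=trials[0].camera
        )
        return fr_curve(pooled, aoi_label, step_px, max_px)
    raise ValidationError(f"unknown mode {mode!r}; expected 'per_trial' or 'pooled'")


def aoi_hits(series: OGDSeries, aoi_label: str) -> list[int]:
    """Fixation ids whose gaze lies inside the AOI mask (OGD == 0).

    This reproduces the traditional one-to-one AOI-Hit mapping when applied
    per AOI.
    """
    ids, vals, sent = _aoi_values(series, aoi_label)
    return [int(i) for i in ids[(vals == 0.0) & ~sent]]


def band_summary(
    series: OGDSeries, aoi_label: str, spec: VisionFieldSpec
) -> BandSummary:
    """Tabulate how many fixations fall in each visual-field band for an AOI."""
    _, vals, sent = _aoi_values(series, aoi_label)
    counts = {band: 0 for band in VisionBand}
    for v, s in zip(vals, sent):
        counts[classify_vision_field(v, spec, sentinel=bool(s))] += 1
    total = len(vals)
    fractions = {band: counts[band] / total for band in VisionBand}
    return BandSummary(aoi_label=aoi_label, counts=counts, fractions=fractions)


def mask_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    The area of overlap between the predicted and reference mask divided by
    the area of their union.  Two empty masks have IoU 0 by convention (logged,
    since neither area exists).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    union = np.count_nonzero(pred | truth)
    if union == 0:
        logger.warning("IoU of two empty masks defined as 0 by convention")
        return 0.0
    return float(np.count_nonzero(pred & truth) / union)
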