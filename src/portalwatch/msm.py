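"""Multiple-separate-metrics (MSM) threshold detector.

The comparator method: each of the four image-difference metrics gets its
own threshold, fitted from reference (error-free) deliveries as

    threshold = median + 2 * range

of the per-case maxima of the metric's absolute value.  During a delivery,
an error is declared at the first window where ANY metric exceeds its
threshold; the detection latches.  Undetected deliveries are reported at the
sentinel segment ``n_segments + 1`` (181 for a default arc).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import METRIC_NAMES, MetricStream
from .simulate import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-metric detection thresholds and the reference cases they came from."""

    cax: float
    mean_val: float
    rms_global: float
    rms_local: float
    provenance: tuple[str, ...] = ()

    def as_array(self) -> np.ndarray:
        return np.array([self.cax, self.mean_val, self.rms_global, self.rms_local])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {m: getattr(self, m) for m in METRIC_NAMES}
                | {"provenance": list(self.provenance)},
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(*(float(d[m]) for m in METRIC_NAMES), tuple(d.get("provenance", ())))


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of running a detector over one metric stream.

    ``first_index`` is the internal (post-exclusion) index of the first
    threshold crossing, or ``length + 1`` when no crossing occurred;
    ``reported_segment`` is on the original segment scale, with sentinel
    ``n_segments + 1`` (181 by default) when undetected.
    """

    method: str
    detected: bool
    first_index: int
    reported_segment: int


def _result(
    method: str, stream: MetricStream, first_index: int | None
) -> DetectionResult:
    if first_index is None:
        return DetectionResult(
            method=method,
            detected=False,
            first_index=len(stream) + 1,
            reported_segment=stream.n_segments + 1,
        )
    return DetectionResult(
        method=method,
        detected=True,
        first_index=first_index,
        reported_segment=int(stream.segment_map[first_index - 1]),
    )


def fit_thresholds(reference_streams: Sequence[MetricStream]) -> ThresholdSet:
    """Fit per-metric thresholds from error-free reference deliveries.

    For each metric, the maximum absolute value over the stream is taken per
    reference case; the threshold is ``median + 2 * (max - min)`` of those
    per-case maxima.  At least two references are required (the range of a
    single case is not a meaningful spread).
    """
    if len(reference_streams) < 2:
        raise ValidationError("need at least 2 reference streams to fit thresholds")
    maxima = np.array(
        [np.abs(s.values).max(axis=0) for s in reference_streams]
    )  # (n_cases, 4)
    thr = np.median(maxima, axis=0) + 2.0 * (maxima.max(axis=0) - maxima.min(axis=0))
    if np.all(maxima == maxima[0]):
        logger.warning("all reference cases identical; thresholds equal common maxima")
    if np.any(thr == 0):
        logger.warning("degenerate zero threshold fitted (all-zero references)")
    provenance = tuple(
        f"{s.patient_id}:{s.error.label}" for s in reference_streams
    )
    return ThresholdSet(*map(float, thr), provenance)


DEFAULT_PERSISTENCE = 2


def detect_msm(
    stream: MetricStream, thresholds: ThresholdSet, persistence: int = DEFAULT_PERSISTENCE
) -> DetectionResult:
    """First-crossing detection: any metric's |value| above its threshold.

    With ``persistence = k`` the exceedance must hold for k consecutive
    windows before detection latches (reported at the first window of the
    run).  The default of 2 rejects single-window statistical spikes, which
    would otherwise dominate false alarms on error-free deliveries; a real
    delivery error persists, so the cost in latency is one window.
    """
    if persistence < 1:
        raise ValidationError("persistence must be >= 1")
    exceed = (np.abs(stream.values) > thresholds.as_array()[None, :]).any(axis=1)
    run = 0
    for i, e in enumerate(exceed, start=1):
        run = run + 1 if e else 0
        if run >= persistence:
            return _result("MSM", stream, i - persistence + 1)
    return _result("MSM", stream, None)
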