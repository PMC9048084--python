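"""Image-difference metrics over running-sum windows of a VMAT arc.

Four measures of agreement between predicted and measured portal images are
computed at each retained segment, on the pixelwise sum of a running window
of 10 segments:

* ``cax`` — central-axis signal difference, % of the predicted value;
* ``mean_val`` — mean image difference, % of the predicted mean;
* ``rms_global`` — RMS difference as % of the global maximum of the
  predicted window;
* ``rms_local`` — RMS of the pixelwise relative difference (% of local
  prediction), over pixels where the prediction is at least
  ``mask_threshold`` of its maximum.

The first ~10% of segments (18 of 180 by default) are discarded as the
unstable start-up period, so a default delivery yields a stream of
162 metric vectors, indexed internally s = 1..162.

``cax`` and ``mean_val`` are signed; both RMS measures are non-negative.
All four vanish identically when measured equals predicted, and all four
are invariant to a common positive rescaling of both images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simulate import ErrorSpec, SegmentImagePair, ValidationError

METRIC_NAMES = ("cax", "mean_val", "rms_global", "rms_local")

DEFAULT_WINDOW = 10
DEFAULT_MASK_THRESHOLD = 0.05
DEFAULT_CAX_HALFWIDTH = 1  # 3x3 central region; 0 = single pixel


class MetricVector(NamedTuple):
    """The four image-agreement measures for one running-sum window."""

    cax: float
    mean_val: float
    rms_global: float
    rms_local: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass
class MetricStream:
    """Per-window metric vectors for one delivery, after start-up exclusion.

    ``values`` has shape (length, 4) with columns in :data:`METRIC_NAMES`
    order, internal index s = 1..length; ``segment_map[s-1]`` gives the
    original (1-based) segment number of internal index s.
    """

    values: np.ndarray
    segment_map: np.ndarray
    patient_id: str
    error: ErrorSpec = field(default_factory=ErrorSpec.none)
    n_segments: int = 180

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.segment_map = np.asarray(self.segment_map, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValidationError("values must be (length, 4)")
        if self.segment_map.shape != (self.values.shape[0],):
            raise ValidationError("segment_map length mismatch")
        if len(self.segment_map) > 1 and not (np.diff(self.segment_map) > 0).all():
            raise ValidationError("segment_map must be strictly increasing")

    def __len__(self) -> int:
        return self.values.shape[0]

    def metric(self, name: str) -> np.ndarray:
        return self.values[:, METRIC_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(METRIC_NAMES))
        df.insert(0, "original_segment", self.segment_map)
        df.insert(0, "internal_index", np.arange(1, len(self) + 1))
        df.insert(0, "magnitude", self.error.magnitude)
        df.insert(0, "error_kind", self.error.kind)
        df.insert(0, "patient_id", self.patient_id)
        return df


def window_sum(
    images: Sequence[np.ndarray], index: int, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Pixelwise sum of images for segments ``index - window + 1 .. index``.

    ``index`` is 1-based.  ``window = 1`` returns the segment's own image.
    """
    if index < window:
        raise ValidationError(f"index {index} precedes a full window of {window}")
    if index > len(images):
        raise ValidationError("index beyond delivery length")
    block = np.stack([np.asarray(images[i], dtype=float) for i in range(index - window, index)])
    return block.sum(axis=0)


def compute_metrics(
    pred_sum: np.ndarray,
    meas_sum: np.ndarray,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    cax_halfwidth: int = DEFAULT_CAX_HALFWIDTH,
) -> MetricVector:
    """The four agreement measures between summed predicted/measured windows.

    The central-axis signal is averaged over a ``(2h+1) x (2h+1)`` region
    around the beam axis (``h = cax_halfwidth``; 0 gives the single central
    pixel).  A degenerate aperture (zero predicted signal on the central
    axis) is rejected.
    """
    P = np.asarray(pred_sum, dtype=float)
    M = np.asarray(meas_sum, dtype=float)
    if P.shape != M.shape:
        raise ValidationError("window shapes differ")
    pmax = P.max()
    if pmax <= 0:
        raise ValidationError("predicted window has no positive signal")

    c = P.shape[0] // 2, P.shape[1] // 2
    h = cax_halfwidth
    p_c = P[c[0] - h : c[0] + h + 1, c[1] - h : c[1] + h + 1].mean()
    m_c = M[c[0] - h : c[0] + h + 1, c[1] - h : c[1] + h + 1].mean()
    if p_c <= 0:
        raise ValidationError("degenerate aperture: no predicted central-axis signal")

    diff = M - P
    cax = 100.0 * (m_c - p_c) / p_c
    mean_val = 100.0 * (M.mean() - P.mean()) / P.mean()
    rms_global = 100.0 * np.sqrt(np.mean(diff**2)) / pmax
    local_mask = P >= mask_threshold * pmax
    rel = diff[local_mask] / P[local_mask]
    rms_local = 100.0 * np.sqrt(np.mean(rel**2))
    return MetricVector(cax, mean_val, rms_global, rms_local)


def default_excluded(n_segments: int, fraction: float = 0.10) -> int:
    """Number of initial segments discarded as unstable (10% by default)."""
    return int(round(fraction * n_segments))


def metric_stream(
    delivery: Sequence[SegmentImagePair],
    excluded: int | None = None,
    window: int = DEFAULT_WINDOW,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    cax_halfwidth: int = DEFAULT_CAX_HALFWIDTH,
    patient_id: str = "",
    error: ErrorSpec | None = None,
    window_scope: str = "all",
) -> MetricStream:
    """Metric stream of a delivery: one MetricVector per retained segment.

    For each original segment ``excluded + 1 .. n`` the metrics of the
    running-sum window ending at that segment are computed; internal index 1
    maps to original segment ``excluded + 1``.

    With the default ``window_scope="all"`` every retained window is a full
    ``window``-segment sum; the first ``window - 1`` retained indices reach
    back into the tail of the excluded period (requires ``excluded >=
    window - 1``), which is safe because the exclusion is deliberately
    longer than the instability itself.  ``window_scope="post_exclusion"``
    instead restricts sums to retained segments, growing the window from a
    single segment at the first retained index — useful when the excluded
    period is shorter than a full window.
    """
    n = len(delivery)
    if excluded is None:
        excluded = default_excluded(n)
    if n < excluded + 1:
        raise ValidationError("delivery shorter than the excluded start-up period")
    if window_scope not in ("post_exclusion", "all"):
        raise ValidationError("window_scope must be 'post_exclusion' or 'all'")
    if window_scope == "all" and excluded < window - 1:
        raise ValidationError("excluded must be at least window - 1 for window_scope='all'")

    pred = [np.asarray(p.predicted, dtype=float) for p in delivery]
    meas = [np.asarray(p.measured, dtype=float) for p in delivery]

    # rolling window sums, updated in place segment by segment
    first = excluded + 1
    if window_scope == "all":
        wp = sum(pred[first - window : first - 1], np.zeros_like(pred[0]))
        wm = sum(meas[first - window : first - 1], np.zeros_like(meas[0]))
    else:
        wp = np.zeros_like(pred[0])
        wm = np.zeros_like(meas[0])

    rows = []
    seg_map = []
    for s_orig in range(first, n + 1):
        wp += pred[s_orig - 1]
        wm += meas[s_orig - 1]
        drop = s_orig - window  # 1-based index leaving the window
        if drop >= (first - window + 1 if window_scope == "all" else first):
            wp -= pred[drop - 1]
            wm -= meas[drop - 1]
        mv = compute_metrics(wp, wm, mask_threshold, cax_halfwidth)
        rows.append(mv.as_array())
        seg_map.append(s_orig)
    return MetricStream(
        values=np.array(rows),
        segment_map=np.array(seg_map),
        patient_id=patient_id or getattr(delivery[0], "patient_id", ""),
        error=error or ErrorSpec.none(),
        n_segments=n,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def save_streams(streams: Iterable[MetricStream], path: str | Path) -> Path:
    """Write one or more metric streams to a single CSV file."""
    df = pd.concat([s.to_frame() for s in streams], ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_streams(path: str | Path, n_segments: int = 180) -> list[MetricStream]:
    """Read metric streams written by :func:`save_streams`."""
    df = pd.read_csv(path)
    streams = []
    for (pid, kind, mag), g in df.groupby(
        ["patient_id", "error_kind", "magnitude"], sort=False
    ):
        g = g.sort_values("internal_index")
        streams.append(
            MetricStream(
                values=g[list(METRIC_NAMES)].to_numpy(),
                segment_map=g["original_segment"].to_numpy(),
                patient_id=str(pid),
                error=ErrorSpec(kind, float(mag)),
                n_segments=n_segments,
            )
        )
    return streams
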