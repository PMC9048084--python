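"""Scoring the detectors: latency, error counts, strata, relative benefit.

Detection timeliness is measured by the original segment index at which a
delivery error is first flagged; a delivery whose error is never flagged
during its 180 segments enters every average at the sentinel index 181.
Error cases are stratified by physical size:

* small  — 2% MU, 2 mm opening, 2 mm shift, 10 mm air gap (ranking 1)
* medium — 4-6% MU / mm, 20-30 mm air gap (rankings 2-3)
* large  — 8-10% MU / mm, 40-50 mm air gap (rankings 4-5)

The *relative benefit* of the recurrent detector is the quotient of RNN and
MSM mean detection indices (values below 1 favour the RNN); per-split
overall statistics are pooled across splits by the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricStream
from .msm import DetectionResult, _result
from .simulate import ErrorSpec, ValidationError

logger = logging.getLogger(__name__)

STRATA = ("small", "medium", "large")


def stratum_of(error: ErrorSpec) -> str:
    """Size stratum of an error case by its physical ranking."""
    if error.ranking == 0:
        raise ValidationError("error-free deliveries belong to no stratum")
    return {1: "small", 2: "medium", 3: "medium", 4: "large", 5: "large"}[error.ranking]


def detect_rnn(trace: np.ndarray, stream: MetricStream) -> DetectionResult:
    """First-crossing detection on the network output: y > 0 flags an error.

    The detection latches at the first internal index with positive output;
    an all-negative trace reports the undetected sentinel.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape != (len(stream),):
        raise ValidationError("output trace is not aligned with the stream")
    above = np.flatnonzero(trace > 0)
    if above.size == 0:
        return _result("RNN", stream, None)
    return _result("RNN", stream, int(above[0]) + 1)


@dataclass(frozen=True)
class OutcomeCounts:
    """False positives/negatives and their denominators for one result set."""

    false_positives: int
    false_negatives: int
    n_error_cases: int
    n_normal_cases: int

    @property
    def fn_ratio(self) -> float:
        return self.false_negatives / self.n_error_cases if self.n_error_cases else 0.0

    @property
    def fp_ratio(self) -> float:
        return self.false_positives / self.n_normal_cases if self.n_normal_cases else 0.0


def count_outcomes(
    results: Sequence[DetectionResult], is_error_case: Sequence[bool]
) -> OutcomeCounts:
    """Tally detections against case labels.

    A false positive is a detection on an error-free delivery; a false
    negative is an error delivery never flagged during its arc.
    """
    if len(results) != len(is_error_case):
        raise ValidationError("results and labels differ in length")
    fp = sum(r.detected for r, e in zip(results, is_error_case) if not e)
    fn = sum(not r.detected for r, e in zip(results, is_error_case) if e)
    n_err = sum(is_error_case)
    return OutcomeCounts(fp, fn, n_err, len(results) - n_err)


def stratified_means(
    results: Mapping[str, dict[ErrorSpec, DetectionResult]],
) -> pd.DataFrame:
    """Mean detection segment per size stratum and method, plus overall.

    ``results`` maps method name ("MSM", "RNN") to a dict of error case ->
    DetectionResult; undetected cases contribute the sentinel segment.
    Returns one row per stratum plus an "overall" row pooling all cases,
    with a ``relative_benefit`` column = RNN mean / MSM mean.
    """
    methods = list(results)
    rows = []
    for stratum in (*STRATA, "overall"):
        row: dict[str, float | str] = {"stratum": stratum}
        for method in methods:
            segs = [
                r.reported_segment
                for err, r in results[method].items()
                if stratum == "overall" or stratum_of(err) == stratum
            ]
            if not segs:
                logger.warning("stratum %s empty for %s; omitted", stratum, method)
                row[method] = np.nan
            else:
                row[method] = float(np.mean(segs))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("stratum")
    if {"MSM", "RNN"} <= set(methods):
        df["relative_benefit"] = df["RNN"] / df["MSM"]
    return df.dropna(how="all")


def pooled_summary(per_split: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Median across splits of each per-split overall statistic."""
    if not per_split:
        raise ValidationError("no split reports to pool")
    overall = pd.concat([df.loc[["overall"]] for df in per_split])
    return overall.median(axis=0).to_frame("median_overall").T
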