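"""End-to-end leave-two-out benchmark on the synthetic six-patient cohort.

This module wires the whole pipeline together: simulate every delivery of
the study design (3 patients with all 20 error cases, 3 with the four
representative ones, plus an error-free delivery each — 78 deliveries),
reduce each to its 162-window metric stream, then for each of the nine
leave-two-out splits fit MSM thresholds on the error-free training
deliveries, train the GRU detector by random search on all training
streams, and score both detectors on the held-out test streams.

The headline quantity is the relative earliness of RNN detection versus
MSM: the per-split overall relative benefit (quotient of mean detection
indices) pooled by the median across splits, and the percentage reduction
in the pooled median first-detection segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, metrics, msm, training
from .gru import RNNWeights, forward
from .simulate import (
    DeliverySpec,
    ErrorSpec,
    PanelGeometry,
    PatientCohortSpec,
    PhantomSpec,
    cohort_cases,
    simulate_delivery,
)

logger = logging.getLogger(__name__)


def _delivery_seed(master_seed: int, case_index: int) -> int:
    """Deterministic per-delivery seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, case_index]).generate_state(1)[0] % (2**31)
    )


def generate_cohort_streams(
    cohort: PatientCohortSpec | None = None,
    seed: int = 1,
    n_segments: int = 180,
    noise_sd: float = 0.01,
    geometry: PanelGeometry | None = None,
    phantom: PhantomSpec | None = None,
) -> dict[tuple[str, str], metrics.MetricStream]:
    """Simulate every delivery of the study design and return its streams.

    Keys are ``(patient_id, error_label)``.  The same measured deliveries
    are shared by all nine splits, as in a physical phantom study where each
    delivery is performed once.
    """
    cohort = cohort or PatientCohortSpec()
    streams: dict[tuple[str, str], metrics.MetricStream] = {}
    for idx, (pid, error) in enumerate(cohort_cases(cohort)):
        spec = DeliverySpec(
            patient_id=pid,
            n_segments=n_segments,
            error=error,
            seed=_delivery_seed(seed, idx),
            noise_sd=noise_sd,
        )
        delivery = simulate_delivery(spec, phantom, geometry)
        streams[(pid, error.label)] = metrics.metric_stream(
            delivery, patient_id=pid, error=error
        )
        logger.debug("simulated %s / %s", pid, error.label)
    return streams


def _patient_streams(
    streams: dict[tuple[str, str], metrics.MetricStream], pid: str
) -> list[metrics.MetricStream]:
    return [s for (p, _), s in streams.items() if p == pid]


@dataclass
class SplitResult:
    """Everything measured on one leave-two-out split."""

    split: training.Split
    thresholds: msm.ThresholdSet
    weights: RNNWeights
    objective_trace: np.ndarray
    report: pd.DataFrame                       # stratified means + relative benefit
    msm_results: dict[tuple[str, str], msm.DetectionResult] = field(default_factory=dict)
    rnn_results: dict[tuple[str, str], msm.DetectionResult] = field(default_factory=dict)
    msm_counts: evaluate.OutcomeCounts | None = None
    rnn_counts: evaluate.OutcomeCounts | None = None


@dataclass
class BenchmarkResult:
    """Aggregate outcome of the nine-split benchmark."""

    splits: list[SplitResult]
    pooled: pd.DataFrame                       # median across splits of overall stats
    median_relative_benefit: float             # median of per-split overall RNN/MSM
    pooled_median_msm: float                   # pooled median detection segment, MSM
    pooled_median_rnn: float
    reduction_pct: float                       # 100 * (1 - rnn/msm pooled medians)
    msm_counts: evaluate.OutcomeCounts         # totals over all splits
    rnn_counts: evaluate.OutcomeCounts

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for sr in self.splits:
            for stratum, row in sr.report.iterrows():
                rows.append(
                    {
                        "test_full": sr.split.test_full,
                        "test_partial": sr.split.test_partial,
                        "stratum": stratum,
                        **row.to_dict(),
                    }
                )
        return pd.DataFrame(rows)


def run_split(
    split: training.Split,
    streams: dict[tuple[str, str], metrics.MetricStream],
    objective_spec: training.ObjectiveSpec | None = None,
    search: training.SearchConfig | None = None,
) -> SplitResult:
    """Train and evaluate both detectors on one leave-two-out split."""
    objective_spec = objective_spec or training.ObjectiveSpec()
    search = search or training.SearchConfig()

    reference = [
        streams[(pid, "none")] for pid in split.train_patients
    ]
    thresholds = msm.fit_thresholds(reference)

    cases = [
        training.TrainingCase.from_stream(s)
        for pid in split.train_patients
        for s in _patient_streams(streams, pid)
    ]
    weights, trace = training.random_search(cases, objective_spec, search)

    msm_results: dict[tuple[str, str], msm.DetectionResult] = {}
    rnn_results: dict[tuple[str, str], msm.DetectionResult] = {}
    labels: list[bool] = []
    err_msm: dict[ErrorSpec, msm.DetectionResult] = {}
    err_rnn: dict[ErrorSpec, msm.DetectionResult] = {}
    for pid in split.test_patients:
        for stream in _patient_streams(streams, pid):
            key = (pid, stream.error.label)
            r_m = msm.detect_msm(stream, thresholds)
            y = forward(stream, weights, objective_spec.input_scale)
            r_r = evaluate.detect_rnn(y, stream)
            msm_results[key] = r_m
            rnn_results[key] = r_r
            labels.append(stream.error.kind != "none")
            if stream.error.kind != "none":
                # (patient, error) is unique within a split's test set
                err_msm[stream.error] = r_m
                err_rnn[stream.error] = r_r

    # stratified means are computed over (patient, error) test cases; the two
    # test patients contribute disjoint error sets (full vs representative),
    # so every test error case appears exactly once.
    report = evaluate.stratified_means({"MSM": err_msm, "RNN": err_rnn})
    msm_counts = evaluate.count_outcomes(list(msm_results.values()), labels)
    rnn_counts = evaluate.count_outcomes(list(rnn_results.values()), labels)
    return SplitResult(
        split=split,
        thresholds=thresholds,
        weights=weights,
        objective_trace=trace,
        report=report,
        msm_results=msm_results,
        rnn_results=rnn_results,
        msm_counts=msm_counts,
        rnn_counts=rnn_counts,
    )


def run_benchmark(
    seed: int = 1,
    cohort: PatientCohortSpec | None = None,
    iterations: int = 3000,
    noise_sd: float = 0.01,
    n_segments: int = 180,
    objective_spec: training.ObjectiveSpec | None = None,
    streams: dict[tuple[str, str], metrics.MetricStream] | None = None,
) -> BenchmarkResult:
    """The full nine-split leave-two-out benchmark.

    All randomness (delivery noise, weight initialisation, search
    perturbations) derives from ``seed``; each split trains with its own
    deterministic sub-seed, so per-split executions are order-independent.
    """
    cohort = cohort or PatientCohortSpec()
    if streams is None:
        streams = generate_cohort_streams(
            cohort, seed=seed, n_segments=n_segments, noise_sd=noise_sd
        )
    n_windows = len(next(iter(streams.values())))
    objective_spec = objective_spec or training.ObjectiveSpec(n_windows=n_windows)

    results: list[SplitResult] = []
    for k, split in enumerate(training.make_splits(cohort)):
        search = training.SearchConfig(
            iterations=iterations,
            seed=_delivery_seed(seed, 1000 + k),
            step_decay=0.7,
            decay_patience=40,
            min_step=3e-3,
            restarts=4,
            target_objective=4.0,
        )
        logger.info("split %d/9: test %s", k + 1, split.test_patients)
        results.append(run_split(split, streams, objective_spec, search))

    pooled = evaluate.pooled_summary([sr.report for sr in results])
    median_rb = float(
        np.median([sr.report.loc["overall", "relative_benefit"] for sr in results])
    )
    # pooled medians over test *error* cases only
    msm_segs = [
        r.reported_segment
        for sr in results
        for (pid, lbl), r in sr.msm_results.items()
        if lbl != "none"
    ]
    rnn_segs = [
        r.reported_segment
        for sr in results
        for (pid, lbl), r in sr.rnn_results.items()
        if lbl != "none"
    ]
    med_msm = float(np.median(msm_segs))
    med_rnn = float(np.median(rnn_segs))

    def _tot(counts: list[evaluate.OutcomeCounts]) -> evaluate.OutcomeCounts:
        return evaluate.OutcomeCounts(
            sum(c.false_positives for c in counts),
            sum(c.false_negatives for c in counts),
            sum(c.n_error_cases for c in counts),
            sum(c.n_normal_cases for c in counts),
        )

    return BenchmarkResult(
        splits=results,
        pooled=pooled,
        median_relative_benefit=median_rb,
        pooled_median_msm=med_msm,
        pooled_median_rnn=med_rnn,
        reduction_pct=100.0 * (1.0 - med_rnn / med_msm),
        msm_counts=_tot([sr.msm_counts for sr in results]),
        rnn_counts=_tot([sr.rnn_counts for sr in results]),
    )


def case_accounting(cohort: PatientCohortSpec | None = None) -> dict[str, int]:
    """Pooled error-case denominators of the nine-split design.

    Each split trains on 2 full-error + 2 partial-error patients (2x20 +
    2x4 = 48 error deliveries) and tests on one of each (20 + 4 = 24);
    pooling the nine splits gives the 432 training and 216 test error
    deliveries used as denominators for false-negative ratios.
    """
    cohort = cohort or PatientCohortSpec()
    errors_of = {
        pid: len([e for p, e in cohort_cases(cohort, include_error_free=False) if p == pid])
        for pid in cohort.patients
    }
    train_total = 0
    test_total = 0
    for split in training.make_splits(cohort):
        train_total += sum(errors_of[p] for p in split.train_patients)
        test_total += sum(errors_of[p] for p in split.test_patients)
    return {"train_error_cases": train_total, "test_error_cases": test_total}
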