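"""Synthetic VMAT deliveries for portal-dosimetry error detection.

This module emulates, per delivery, the sequence of predicted and measured
portal images that a forward-projection portal-dosimetry system sees during a
volumetric modulated arc therapy (VMAT) arc: one image pair per segment
(control point), 180 segments per arc by default.

The predicted image is a parametric fluence model: a smoothly modulated,
leaf-wise rectangular MLC aperture, rendered on the imaging panel, blurred
with a Gaussian penumbra and given a small out-of-field scatter floor.  The
measured image is the predicted image with an optional deliberate delivery
error applied (monitor-unit scaling, MLC retraction, MLC shift, or an air
gap in the phantom) plus multiplicative measurement noise.  All noise
components scale with ``noise_sd``:

* independent per-pixel noise (panel quantum/readout noise),
* a per-segment global gain fluctuation (linac output variation),
* a smooth gantry-angle-dependent gain drift — a random-phase low-harmonic
  modulation over the arc (angular response of the panel and its
  calibration), and
* an aperture-geometry jitter on the measured image: mm-scale offsets of
  the rendered aperture position and width, with an independent
  per-segment part (MLC positioning scatter, imperfect allocation of
  measured images to plan control points) and a smooth angle-dependent
  part (panel sag, which persists across neighbouring segments), and
* a penumbra-width mismatch: the measured edge blur differs from the
  predicted one by a smooth angle-dependent amount plus per-segment
  scatter (the prediction model's penumbra and the panel's glare/response
  are never exact).  This produces large edge-region RMS differences on
  error-free deliveries while leaving the mean signal and the central-axis
  signal untouched — the dominant benign residual of forward-projection
  dosimetry.  Without these components, edge-sensitive metrics on
  error-free deliveries would be unrealistically clean and any geometric
  error would be trivially detectable.

The first few percent of segments are unstable: the measured output is
depressed by an exponentially settling start-up ramp (linac servo settling)
and the noise components are inflated.  Downstream analysis discards the
first 10% of segments, comfortably covering this period.

Everything is deterministic given the specification and its seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

ERROR_KINDS = ("none", "mu_increase", "mlc_retraction", "mlc_shift", "air_gap")

#: valid magnitudes per error kind (percent for MU, mm otherwise)
_VALID_MAGNITUDES = {
    "mu_increase": (2, 4, 6, 8, 10),
    "mlc_retraction": (2, 4, 6, 8, 10),
    "mlc_shift": (2, 4, 6, 8, 10),
    "air_gap": (10, 20, 30, 40, 50),
}


class ValidationError(ValueError):
    """Raised when a specification or operation argument is invalid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Water-equivalent slab phantom with the isocentre at its centre."""

    length_mm: float = 300.0
    width_mm: float = 300.0
    height_mm: float = 200.0

    def __post_init__(self) -> None:
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise ValidationError("phantom dimensions must be positive")


@dataclass(frozen=True)
class PanelGeometry:
    """Imaging-panel geometry and fluence-model rendering parameters.

    The panel is square with the beam axis at pixel ``(n_pixels // 2,
    n_pixels // 2)``.  Leaf travel is along the image x-axis; leaves are
    indexed along y with width ``leaf_width_mm``.  ``pitch_mm`` is the
    effective pixel pitch at the isocentre plane.
    """

    n_pixels: int = 256
    pitch_mm: float = 1.0
    leaf_width_mm: float = 4.0
    penumbra_sigma_mm: float = 3.0
    scatter_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.n_pixels < 8 or self.pitch_mm <= 0:
            raise ValidationError("invalid panel geometry")

    @property
    def centre(self) -> int:
        return self.n_pixels // 2

    def axis_mm(self) -> np.ndarray:
        """Pixel-centre coordinates in mm relative to the beam axis."""
        return (np.arange(self.n_pixels) - self.centre) * self.pitch_mm


@dataclass(frozen=True)
class ErrorSpec:
    """A deliberate delivery error: kind, physical magnitude, and ranking.

    ``ranking`` is the physical ranking M_e of the error from 1 (smallest:
    2% MU, 2 mm MLC, 10 mm air gap) to 5 (largest: 10% MU, 10 mm MLC,
    50 mm air gap); it is 0 for an error-free delivery.
    """

    kind: str = "none"
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise ValidationError(f"unknown error kind {self.kind!r}")
        if self.kind == "none":
            if self.magnitude != 0:
                raise ValidationError("error-free delivery must have magnitude 0")
        elif self.magnitude not in _VALID_MAGNITUDES[self.kind]:
            raise ValidationError(
                f"magnitude {self.magnitude} invalid for {self.kind}; "
                f"allowed: {_VALID_MAGNITUDES[self.kind]}"
            )

    @property
    def ranking(self) -> int:
        """Physical ranking M_e in 1..5 (0 for no error)."""
        if self.kind == "none":
            return 0
        if self.kind == "air_gap":
            return int(self.magnitude // 10)
        return int(self.magnitude // 2)

    @classmethod
    def none(cls) -> "ErrorSpec":
        return cls("none", 0.0)

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        unit = "pct" if self.kind == "mu_increase" else "mm"
        return f"{self.kind}_{self.magnitude:g}{unit}"


@dataclass(frozen=True)
class DeliverySpec:
    """One synthetic VMAT delivery of a patient plan.

    ``noise_sd`` is the relative per-pixel measurement noise; every other
    noise component scales with it (per-segment gain ``gain_ratio *
    noise_sd``; angular gain response amplitude ``drift_ratio * noise_sd``;
    aperture scatter ``jitter_ratio * noise_sd`` mm and sag drift
    ``jitter_drift_ratio * noise_sd`` mm; penumbra mismatch ``blur_ratio *
    noise_sd`` mm), so ``noise_sd = 0`` yields a perfectly noise-free
    delivery.  The first ``startup_fraction`` of segments are unstable: the
    output is depressed by a settling ramp of depth ``startup_ramp`` and
    the gain/pixel noise is inflated by ``startup_noise_factor``.
    """

    patient_id: str
    n_segments: int = 180
    error: ErrorSpec = field(default_factory=ErrorSpec.none)
    seed: int = 0
    noise_sd: float = 0.01
    startup_fraction: float = 0.05
    startup_noise_factor: float = 5.0
    startup_ramp: float = 0.3  # initial output depression while the servo settles
    gain_ratio: float = 1.0
    drift_ratio: float = 6.0  # amplitude of the angular gain response
    jitter_ratio: float = 100.0  # mm of per-segment aperture scatter per unit noise_sd
    jitter_drift_ratio: float = 250.0  # mm of panel-sag geometry drift per unit noise_sd
    blur_ratio: float = 160.0  # mm of penumbra-width mismatch per unit noise_sd
    drift_amp_spread: float = 0.5  # delivery-to-delivery amplitude variation

    def __post_init__(self) -> None:
        if self.n_segments < 20:
            raise ValidationError("need at least 20 segments per delivery")
        if self.noise_sd < 0 or not (0 <= self.startup_fraction < 1):
            raise ValidationError("invalid noise specification")


@dataclass(frozen=True)
class SegmentImagePair:
    """Predicted and measured portal image for one VMAT segment."""

    segment_index: int  # 1-based
    predicted: np.ndarray
    measured: np.ndarray
    gantry_angle: float

    def __post_init__(self) -> None:
        if self.predicted.shape != self.measured.shape:
            raise ValidationError("predicted and measured shapes differ")
        if not (self.predicted > 0).any():
            raise ValidationError("predicted image has no positive pixel")


@dataclass(frozen=True)
class PatientCohortSpec:
    """The six-virtual-patient study cohort.

    Three patients carry the full set of 20 error cases (MU 2-10%, MLC
    retraction 2-10 mm, MLC shift 2-10 mm, air gap 10-50 mm); three carry
    only the four representative magnitude-2 errors (4% MU, 4 mm retraction,
    4 mm shift, 20 mm air gap).  Every patient also has an error-free
    delivery.
    """

    full_error_patients: tuple[str, ...] = ("P1", "P2", "P3")
    partial_error_patients: tuple[str, ...] = ("P4", "P5", "P6")

    def __post_init__(self) -> None:
        overlap = set(self.full_error_patients) & set(self.partial_error_patients)
        if overlap:
            raise ValidationError(f"patients in both groups: {overlap}")

    @property
    def patients(self) -> tuple[str, ...]:
        return self.full_error_patients + self.partial_error_patients


FULL_ERROR_CASES: tuple[ErrorSpec, ...] = tuple(
    ErrorSpec(kind, mag)
    for kind in ("mu_increase", "mlc_retraction", "mlc_shift", "air_gap")
    for mag in _VALID_MAGNITUDES[kind]
)

PARTIAL_ERROR_CASES: tuple[ErrorSpec, ...] = (
    ErrorSpec("mu_increase", 4),
    ErrorSpec("mlc_retraction", 4),
    ErrorSpec("mlc_shift", 4),
    ErrorSpec("air_gap", 20),
)


def cohort_cases(
    cohort: PatientCohortSpec, include_error_free: bool = True
) -> list[tuple[str, ErrorSpec]]:
    """Enumerate all (patient, error) deliveries of the study design."""
    cases: list[tuple[str, ErrorSpec]] = []
    for pid in cohort.full_error_patients:
        if include_error_free:
            cases.append((pid, ErrorSpec.none()))
        cases.extend((pid, e) for e in FULL_ERROR_CASES)
    for pid in cohort.partial_error_patients:
        if include_error_free:
            cases.append((pid, ErrorSpec.none()))
        cases.extend((pid, e) for e in PARTIAL_ERROR_CASES)
    return cases


# ---------------------------------------------------------------------------
# error injectors
# ---------------------------------------------------------------------------

def inject_mu_error(image: np.ndarray, pct: float) -> np.ndarray:
    """Scale every pixel by ``1 + pct/100`` (monitor-unit increase)."""
    if pct < 0:
        raise ValidationError("MU increase must be non-negative")
    return image * (1.0 + pct / 100.0)


def _px(mm: float, pitch_mm: float) -> int:
    return int(round(mm / pitch_mm))


def inject_aperture_opening(
    aperture_mask: np.ndarray, mm: float, pitch_mm: float = 1.0
) -> np.ndarray:
    """Retract all MLC leaves by ``mm``: dilate the opening along leaf travel.

    Each leaf-defined edge moves outward by ``mm`` along the x-axis
    (morphological dilation by ``mm / pitch`` pixels per side).  The open
    area never decreases; dilation reaching the panel edge is clipped there.
    """
    if mm < 0:
        raise ValidationError("retraction must be non-negative")
    k = _px(mm, pitch_mm)
    if k == 0:
        return aperture_mask.copy()
    mask = aperture_mask.astype(bool)
    struct = np.ones((1, 2 * k + 1), dtype=bool)
    out = ndimage.binary_dilation(mask, structure=struct)
    rows = mask.any(axis=1)
    if (out[rows, 0].any() or out[rows, -1].any()) and not (
        mask[rows, 0].any() or mask[rows, -1].any()
    ):
        logger.warning("aperture dilation clipped at panel edge")
    return out


def inject_aperture_shift(
    aperture_mask: np.ndarray, mm: float, pitch_mm: float = 1.0
) -> np.ndarray:
    """Shift all MLC leaves by ``mm`` along leaf travel (+x direction)."""
    if mm < 0:
        raise ValidationError("shift must be non-negative")
    k = _px(mm, pitch_mm)
    mask = aperture_mask.astype(bool)
    if k == 0:
        return mask.copy()
    out = np.zeros_like(mask)
    out[:, k:] = mask[:, :-k]
    if mask[:, -k:].any():
        logger.warning("aperture shift clipped at panel edge")
    return out


def inject_air_gap(
    predicted_fluence: np.ndarray,
    width_mm: float,
    phantom: PhantomSpec | None = None,
    geometry: PanelGeometry | None = None,
    mu_per_mm: float = 0.005,
    band_centre_mm: float = 30.0,
) -> np.ndarray:
    """Introduce an air gap of ``width_mm`` into the phantom (rectal gas).

    Within the horizontal band of the panel that projects through the gap
    (height ``width_mm``, centred ``band_centre_mm`` posterior of the beam
    axis) the path length through water is reduced by ``width_mm``, so the
    transmitted intensity rises by ``exp(mu_per_mm * width_mm)``; pixels
    outside the band are unchanged.  Default ``mu_per_mm`` is an effective
    linear attenuation coefficient for a 6 MV beam in water.
    """
    phantom = phantom or PhantomSpec()
    geometry = geometry or PanelGeometry()
    if width_mm < 0:
        raise ValidationError("air-gap width must be non-negative")
    if width_mm > phantom.height_mm:
        raise ValidationError("air gap cannot exceed the phantom height")
    if width_mm == 0:
        return predicted_fluence.copy()
    y = geometry.axis_mm()
    in_band = np.abs(y - band_centre_mm) <= width_mm / 2.0
    out = predicted_fluence.copy()
    out[in_band, :] *= float(np.exp(mu_per_mm * width_mm))
    return out


# ---------------------------------------------------------------------------
# aperture plan and image rendering
# ---------------------------------------------------------------------------

def plan_seed_for(patient_id: str) -> int:
    """Stable per-patient seed for the treatment-plan (aperture) trajectory."""
    return zlib.crc32(patient_id.encode("utf-8")) & 0x7FFFFFFF


@dataclass(frozen=True)
class _PlanParams:
    """Smooth per-patient aperture trajectory parameters (internal)."""

    phases: np.ndarray          # global modulation phases (5,)
    leaf_amp: np.ndarray        # per-leaf modulation amplitude, mm
    leaf_freq: np.ndarray       # per-leaf modulation frequency, cycles/arc
    leaf_phase: np.ndarray


_TEMPLATE_PHASES = np.array([0.7, 2.1, 4.0, 1.3, 5.2])


def _draw_plan(patient_id: str, geometry: PanelGeometry) -> _PlanParams:
    # all patients share one plan template (same treatment site and
    # complexity); patient individuality enters through small global phase
    # offsets and the per-leaf modulation pattern
    rng = np.random.default_rng(plan_seed_for(patient_id))
    n_leaves = int(np.ceil(geometry.n_pixels * geometry.pitch_mm / geometry.leaf_width_mm))
    phases = _TEMPLATE_PHASES + rng.uniform(-0.4, 0.4, size=5)
    template_rng = np.random.default_rng(20220404)
    template = np.abs(ndimage.gaussian_filter1d(template_rng.normal(0, 1, n_leaves), 2.0))
    own = np.abs(ndimage.gaussian_filter1d(rng.normal(0, 1, n_leaves), 2.0))
    leaf_amp = 3.0 * (0.6 * template + 0.4 * own)
    leaf_freq = rng.uniform(0.5, 2.0, size=n_leaves)
    leaf_phase = rng.uniform(0, 2 * np.pi, size=n_leaves)
    return _PlanParams(phases, leaf_amp, leaf_freq, leaf_phase)


def aperture_mask(
    plan: _PlanParams,
    segment_index: int,
    n_segments: int,
    geometry: PanelGeometry,
    dx_mm: float = 0.0,
    dw_mm: float = 0.0,
) -> np.ndarray:
    """Boolean MLC aperture for one segment of the arc.

    The opening translates, narrows and sweeps vertically as the gantry
    rotates, with smooth per-leaf modulation, emulating the aperture
    trajectory of a prostate VMAT plan.  ``dx_mm`` and ``dw_mm`` offset the
    aperture centre and half-width (used for measurement-side geometry
    jitter).
    """
    t = segment_index / n_segments
    p = plan.phases
    # the opening contracts strongly over the arc (broad fields early, small
    # boost-like segments late), so geometric-error visibility ramps up; the
    # beam axis (isocentre in the target) stays safely inside the opening
    cx = 5.0 * np.sin(2 * np.pi * 0.8 * t + p[0]) + dx_mm
    hw = max(52.0 * (1.0 - 0.45 * t) + 6.0 * np.sin(2 * np.pi * 1.7 * t + p[1]) + dw_mm, 16.0)
    cy = -8.0 + 18.0 * t + 4.0 * np.sin(2 * np.pi * 1.3 * t + p[2])
    vh = 42.0 - 20.0 * t + 4.0 * np.sin(2 * np.pi * 0.9 * t + p[3])

    x = geometry.axis_mm()
    y = geometry.axis_mm()
    n_leaves = plan.leaf_amp.size
    leaf_of_row = np.clip(
        ((y - y[0]) // geometry.leaf_width_mm).astype(int), 0, n_leaves - 1
    )
    delta = plan.leaf_amp * np.sin(2 * np.pi * plan.leaf_freq * t + plan.leaf_phase)
    leaf_centres = y[0] + (np.arange(n_leaves) + 0.5) * geometry.leaf_width_mm
    leaf_open = np.abs(leaf_centres - cy) <= vh
    left = np.where(leaf_open, cx - hw + delta, 0.0)
    right = np.where(leaf_open, cx + hw + delta, 0.0)
    lo = left[leaf_of_row][:, None]
    hi = right[leaf_of_row][:, None]
    open_row = leaf_open[leaf_of_row][:, None]
    return open_row & (x[None, :] >= lo) & (x[None, :] <= hi)


def segment_weight(plan: _PlanParams, segment_index: int, n_segments: int) -> float:
    """Relative monitor-unit weight of a segment (dose-rate modulation)."""
    t = segment_index / n_segments
    return 1.0 + 0.2 * np.sin(2 * np.pi * 1.1 * t + plan.phases[4])


def render_image(
    mask: np.ndarray,
    weight: float,
    geometry: PanelGeometry,
    sigma_mm: float | None = None,
) -> np.ndarray:
    """Panel image of an aperture: penumbra blur plus scatter floor.

    ``sigma_mm`` overrides the geometry's penumbra width (used to render
    measured images whose effective edge blur differs from the model's).
    """
    if sigma_mm is None:
        sigma_mm = geometry.penumbra_sigma_mm
    sigma_px = max(sigma_mm, 0.3) / geometry.pitch_mm
    blurred = ndimage.gaussian_filter(mask.astype(float), sigma_px)
    return weight * (blurred + geometry.scatter_floor)


def _measured_clean(
    mask: np.ndarray,
    base: np.ndarray,
    weight: float,
    error: ErrorSpec,
    phantom: PhantomSpec,
    geometry: PanelGeometry,
    sigma_mm: float | None = None,
) -> np.ndarray:
    """Noise-free measured image under the delivery error.

    ``base`` is the measurement-side rendering (with geometry jitter and
    penumbra mismatch already applied); ``mask`` is the corresponding
    aperture, transformed and re-rendered for the MLC error kinds.
    """
    if error.kind == "none":
        return base
    if error.kind == "mu_increase":
        return inject_mu_error(base, error.magnitude)
    if error.kind == "air_gap":
        return inject_air_gap(base, error.magnitude, phantom, geometry)
    if error.kind == "mlc_retraction":
        mask = inject_aperture_opening(mask, error.magnitude, geometry.pitch_mm)
    else:  # mlc_shift
        mask = inject_aperture_shift(mask, error.magnitude, geometry.pitch_mm)
    return render_image(mask, weight, geometry, sigma_mm)


def simulate_delivery(
    spec: DeliverySpec,
    phantom: PhantomSpec | None = None,
    geometry: PanelGeometry | None = None,
) -> list[SegmentImagePair]:
    """Simulate one VMAT delivery: a predicted/measured image pair per segment.

    The predicted images are the error-free fluence model of the patient's
    plan (deterministic given ``patient_id``).  The measured images apply the
    delivery error of ``spec.error`` and multiplicative measurement noise
    driven by ``spec.seed``.  Identical specs produce bitwise-identical
    output.
    """
    phantom = phantom or PhantomSpec()
    geometry = geometry or PanelGeometry()
    plan = _draw_plan(spec.patient_id, geometry)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_segments

    # correlated noise components, drawn up-front in a fixed order
    t = np.arange(1, n + 1) / n

    def _angular_response() -> np.ndarray:
        """Unit-scale smooth modulation over the arc (random phase/amplitude).

        Gantry-angle-dependent effects (panel sag, angular calibration
        response) are bounded smooth functions of arc position.  The
        realised amplitude is hard-bounded above by the system's full
        characteristic amplitude and follows a mixture across deliveries:
        most sessions show the full or three-quarter amplitude, a minority
        a substantially smaller one (partial compensation by the day's
        calibration state).  The hard upper bound is what makes zero false
        positives attainable; the spread below it is what keeps thresholds
        fitted as median + 2*range comfortably above the envelope.
        """
        phi = rng.uniform(0, 2 * np.pi)
        amp_max = 1.0 + 0.5 * spec.drift_amp_spread
        v = rng.uniform()
        w = rng.uniform()  # always drawn: keeps the stream position fixed
        if v < 0.40:
            a = 1.0
        elif v < 0.60:
            a = 0.75
        else:
            a = 0.20 + 0.35 * w
        return amp_max * a * np.sin(2 * np.pi * t + phi)

    drift = spec.drift_ratio * spec.noise_sd * _angular_response()
    seg_noise = rng.normal(0, 1, size=n)
    jitter_sd = spec.jitter_ratio * spec.noise_sd
    jitter_drift_sd = spec.jitter_drift_ratio * spec.noise_sd
    jx = rng.normal(0, 1, size=n)
    jw = rng.normal(0, 1, size=n)
    # smooth angle-dependent geometry drift: panel sag shifts the projected
    # aperture but preserves its area, so only the position drifts — the
    # aperture width has no comparable systematic error source
    gx = _angular_response()
    # penumbra-width mismatch between measured and predicted edges
    blur_sd = spec.blur_ratio * spec.noise_sd
    gb = _angular_response()
    jb = rng.normal(0, 1, size=n)

    n_startup = int(round(spec.startup_fraction * n))
    pairs: list[SegmentImagePair] = []
    for s in range(1, n + 1):
        mask = aperture_mask(plan, s, n, geometry)
        w = segment_weight(plan, s, n)
        predicted = render_image(mask, w, geometry)
        boost = spec.startup_noise_factor if s <= n_startup else 1.0
        # servo settling: measured output depressed early, recovering with a
        # time constant of a few segments
        ramp = 1.0 - spec.startup_ramp * np.exp(-(s - 1) / 2.5) if spec.noise_sd > 0 else 1.0
        # start-up instability is a beam-output/panel effect: it inflates the
        # gain and pixel noise below, not the MLC geometry jitter
        if spec.noise_sd > 0:
            # width (symmetric leaf-pair) calibration is tighter than the
            # positional sag/allocation error: half the jitter amplitude
            mask_m = aperture_mask(
                plan, s, n, geometry,
                dx_mm=jitter_sd * jx[s - 1] + jitter_drift_sd * gx[s - 1],
                dw_mm=0.5 * jitter_sd * jw[s - 1],
            )
            sigma_m = geometry.penumbra_sigma_mm + blur_sd * (
                gb[s - 1] + 0.25 * jb[s - 1]
            )
            base = render_image(mask_m, w, geometry, sigma_m)
        else:
            mask_m, base, sigma_m = mask, predicted, None
        clean = _measured_clean(
            mask_m, base, w, spec.error, phantom, geometry, sigma_m
        )
        gain = ramp * (1.0 + drift[s - 1]) * (
            1.0 + boost * spec.gain_ratio * spec.noise_sd * seg_noise[s - 1]
        )
        if spec.noise_sd > 0:
            pixel = 1.0 + boost * spec.noise_sd * rng.normal(0, 1, size=clean.shape)
            measured = np.clip(clean * gain * pixel, 0.0, None)
        else:
            measured = clean
        pairs.append(
            SegmentImagePair(
                segment_index=s,
                predicted=predicted,
                measured=measured,
                gantry_angle=-180.0 + (s - 1) * 360.0 / n,
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# delivery I/O (CSV matrices + JSON manifest)
# ---------------------------------------------------------------------------

def save_delivery(pairs: Sequence[SegmentImagePair], spec: DeliverySpec, out_dir: str | Path) -> Path:
    """Write a delivery as per-segment CSV matrices plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in pairs:
        np.savetxt(out / f"segment_{p.segment_index:03d}_predicted.csv", p.predicted, delimiter=",")
        np.savetxt(out / f"segment_{p.segment_index:03d}_measured.csv", p.measured, delimiter=",")
    manifest = {
        "patient_id": spec.patient_id,
        "n_segments": spec.n_segments,
        "error_kind": spec.error.kind,
        "error_magnitude": spec.error.magnitude,
        "error_ranking": spec.error.ranking,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "gantry_angles": [p.gantry_angle for p in pairs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_delivery(in_dir: str | Path) -> tuple[list[SegmentImagePair], dict]:
    """Read a delivery written by :func:`save_delivery`."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    pairs = []
    for s in range(1, manifest["n_segments"] + 1):
        pred = np.loadtxt(d / f"segment_{s:03d}_predicted.csv", delimiter=",")
        meas = np.loadtxt(d / f"segment_{s:03d}_measured.csv", delimiter=",")
        pairs.append(
            SegmentImagePair(s, pred, meas, manifest["gantry_angles"][s - 1])
        )
    return pairs, manifest


def delivery_spec_variants(spec: DeliverySpec, errors: Sequence[ErrorSpec]) -> list[DeliverySpec]:
    """Copies of ``spec`` over a set of error cases (same patient and seed)."""
    return [replace(spec, error=e) for e in errors]
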