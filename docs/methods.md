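# Methods

`portalwatch` studies real-time error detection for volumetric modulated arc
therapy (VMAT) by forward-projection portal dosimetry: portal images are
predicted per arc segment at planning time, measured per segment during
delivery, and the stream of image-agreement measures is monitored so a
delivery error can be flagged while the fraction is still in progress.
Because deliberate-error measurements on a physical phantom cannot be
shipped, the package pairs a synthetic delivery simulator with the two
detectors under study — a per-metric threshold comparator and a small gated
recurrent network — and evaluates both by leave-two-out cross-validation on
a six-virtual-patient cohort.

## Delivery simulator

A delivery is 180 segments.  For each segment the *predicted* image is a
parametric fluence model: an MLC aperture (leaves of 4 mm width indexed
along y, leaf travel along x) rendered on a 256×256 panel with 1 mm
effective pitch, blurred with a Gaussian penumbra (σ = 3 mm) and given a 2%
out-of-field scatter floor.  The aperture follows a smooth plan template
shared by the cohort (all patients are prostate plans of similar
complexity), individualised by per-patient phases and per-leaf modulation:
the opening translates and contracts from a half-width of ~52 mm to ~29 mm
over the arc, so a geometric error of fixed physical size becomes
progressively more visible — broad fields early, small boost-like segments
late.  Per-segment monitor-unit weights vary ±20%.

Four deliberate error kinds can be injected into the measured side, each
present for the whole arc:

| kind | magnitudes | transform |
|---|---|---|
| MU increase | 2–10% in 2% steps | every pixel × (1 + pct/100) |
| MLC retraction | 2–10 mm | aperture dilated along leaf travel, per side |
| MLC shift | 2–10 mm | aperture translated along leaf travel |
| air gap | 10–50 mm | band at +30 mm boosted by exp(μ·w), μ = 0.005/mm |

The physical ranking M_e of an error is 1–5 (2% ↔ 1, … 10% ↔ 5; 10 mm air
gap ↔ 1, … 50 mm ↔ 5).

### Measurement noise

All components scale with `noise_sd` (default 1%), so `noise_sd = 0`
reproduces the predicted images exactly.  The components and their default
magnitudes:

* per-pixel multiplicative noise, 1% (panel quantum/readout);
* per-segment gain fluctuation, 1% (linac output);
* a gantry-angle-dependent gain response: one sinusoidal cycle per arc with
  random phase, amplitude 6% × a bounded mixture over deliveries (full
  amplitude w.p. 0.4, three-quarter w.p. 0.2, otherwise 0.2–0.55 of full);
* panel-sag: the measured aperture position drifts by the same kind of
  bounded angular modulation, amplitude 2.5 mm (area-preserving — the
  aperture *width* has no comparable systematic error source, only a
  0.5 mm per-segment scatter);
* 1 mm per-segment aperture-position scatter (MLC positioning and
  image-to-control-point allocation);
* penumbra-width mismatch: the measured edge blur differs from the model's
  by a bounded angular modulation of amplitude 1.6 mm plus small scatter —
  large edge-region RMS residuals with no mean-signal footprint, the
  dominant benign residual of forward-projection dosimetry.

The first 5% of segments are additionally unstable: measured output is
depressed by an exponentially settling start-up ramp (30% deep, time
constant 2.5 segments) and the stochastic gain/pixel components are
inflated ×5.  The analysis protocol discards the first 10% of segments,
comfortably covering this period.

Two structural choices matter most and were made deliberately:

1. **Hard-bounded, negatively skewed drift amplitudes.**  Thresholds are
   fitted as median + 2×range of only four reference cases, and the study's
   central observation is *zero* false positives.  Unbounded (Gaussian/AR)
   drift amplitudes make the maximum over an arc heavy-tailed across
   deliveries, which is irreconcilable with that observation; bounded
   angle-dependent responses with most mass at the full amplitude make it
   structurally attainable, while the low-amplitude minority keeps the
   fitted thresholds comfortably above the envelope (range inflation).
2. **Error-free variability lives mostly in directions the errors do not
   occupy** (area-preserving sag and blur mismatch), and the aperture
   contraction is calibrated so that the smallest (rank-1) errors stay
   inside the error-free envelope.  Both are required for a learnable
   margin: rank-1 error cases are relabeled as normal during training, so
   any feature that makes them prominent would force the network to
   tolerate error-like signals and forfeit either earliness or the zero
   false-positive property.

What the simulator does **not** emulate: real anatomy and dose deposition
(no dose engine; images are fluence-like), gantry-angle-dependent
attenuation of the phantom, panel calibration artefacts beyond the smooth
models above, and image-to-segment misallocation beyond its jitter proxy.
Passing the synthetic benchmark therefore shows that the pipeline and the
detectors behave as designed under a faithful statistical emulation — not
that the specific latencies would transfer to a particular clinic.

## Metric stream

At each retained segment the pixelwise sum of a running window of 10
segments is formed for predicted and measured images, and four agreement
measures are computed on the summed pair:

* `cax` — central-axis signal difference (% of prediction), averaged over a
  3×3 region around the beam axis (configurable to a single pixel);
* `mean_val` — mean image difference (%);
* `rms_global` — RMS difference as % of the global maximum of the predicted
  window;
* `rms_local` — RMS of pixelwise relative differences over pixels with at
  least 5% of the predicted maximum (threshold configurable).

The first 18 of 180 segments are excluded, leaving a stream of 162 windows
(internal index s = 1..162, original segments 19..180).  By default every
window is a full 10-segment sum (the first windows reach into the tail of
the excluded period, which is deliberately longer than the instability); a
`post_exclusion` mode restricts sums to retained segments instead.  All four
measures are invariant to a common rescaling of both images and vanish when
measured equals predicted; under a uniform 10% intensity error, `cax`,
`mean_val` and `rms_local` all equal 10 exactly.

## MSM threshold detector

For each metric, the maximum absolute value over the stream is taken per
reference case (the error-free deliveries of the four training patients);
the threshold is median + 2×(max − min) of those maxima.  Detection latches
at the first window where any metric's absolute value exceeds its
threshold, with a two-window persistence requirement (a single-window
statistical spike is not a believable delivery error; the latency cost is
one window).  An undetected delivery is reported at the sentinel segment
181.

## Recurrent detector

A four-layer stack of gated recurrent units with 4, 8, 4 and 1 units (594
parameters; per-layer 108/312/156/18) maps the metric 4-vector, divided by
10, to a scalar output y ∈ (−1, 1); y > 0 at any retained window flags an
error, latched.  Gates follow the standard formulation (update z, reset r,
tanh candidate, h′ = z·h + (1−z)·h̃) with biases on all three transforms.

Training minimises a weighted sum over cases and windows:

    f(w) = Σ_p Σ_e Σ_s f0(e)·fe(e)·fs(s)·fy(y) + (λ/2W)·Σ w_i²

with f0 = 10⁻² (normal) / 10⁻⁶ (error), fe = 10^(M_e−1) for errors, fs
emphasising early windows of normal cases ((163−s)/162) and late windows of
error cases (s/162), and fy the squared distance from the required output
state ((1+y)² / (1−y)²).  Cases with M_e = 1 are relabeled normal.  The L2
term (λ = 40) penalises only the 84 candidate input weights, with W the
count of penalised weights (both the weight set and the denominator are
configurable).

Optimisation is a derivative-free random search: start at uniform ±0.5
weights with the update-gate biases shifted +1 (a long-memory
initialisation, the GRU analogue of the customary positive LSTM forget-gate
bias — it lets the network integrate evidence over many segments), perturb
the whole vector with Gaussian noise (step 0.1, ×0.7 after 40 consecutive
rejections, floor 3×10⁻³), accept only improvements.  Up to four restarts
of 3000 iterations are run; restarting stops once a run converges below an
objective of 4.0 — converged runs reach similar values on every training
set, a plateau well above it marks a stuck search — *and* the trained
network stays below −0.02 on every training normal stream.  Among converged
restarts, those meeting that margin are preferred (best objective wins);
the margin is computed on training data only.  The whole nine-split
training uses at most ≈10⁵ objective evaluations, a deliberately small
budget standing in for the original multi-hour server training; the
batched forward pass is JIT-compiled with numba to keep it at minutes.

## Evaluation

Nine leave-two-out splits: one test patient from the full-error group
(all 20 error cases) and one from the partial-error group (4% MU, 4 mm
retraction, 4 mm shift, 20 mm air gap), the remaining four patients
training.  Pooling the nine training sets gives 432 error deliveries;
pooling the test sets gives 216.  Detection timeliness is the original
segment index of the first flag, sentinel 181 when undetected; false
positives are flags on error-free test deliveries, false negatives errors
never flagged.  Error cases are stratified small/medium/large by ranking
(1 / 2–3 / 4–5).  The *relative benefit* is the quotient of RNN and MSM
mean detection segments per split (overall row), pooled across splits by
the median; the headline earliness is also reported as the percentage
reduction of the pooled median detection segment.

## Numerical choices and degenerate inputs

Metric computation rejects windows whose predicted central-axis signal is
zero (degenerate aperture) and masks `rms_local` at 5% of the predicted
maximum to avoid division blow-up.  Threshold fitting requires at least two
reference cases; identical references yield the common maximum with a
warning.  Dilation or shift past the panel edge is clipped and logged.
Exact-zero network output counts as "no error" (the detection rule is
strictly y > 0).  Serialization of weights is bit-exact (IEEE doubles
round-trip through repr) and checksummed.

## Known limitations

* The simulator's noise structure, while calibrated to reproduce the
  qualitative phenomenology of a real phantom study (zero false positives,
  roughly one-third missed errors for the threshold method, latencies
  spread across the arc), is still a model; absolute latencies and
  false-negative ratios depend on its amplitudes.
* The random-search budget is orders of magnitude below the original
  study's; detection latency of the trained network varies by a few tens of
  segments between splits and seeds, and at adverse random seeds a trained
  network occasionally flags a single error-free test delivery late in the
  arc (the objective weights late windows of normal cases very weakly, so
  nothing enforces a wide margin there).
* Thresholds and training share the same cohort design (four training
  patients); with only six patients, split-to-split variability is large —
  as it is in the study being emulated.
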