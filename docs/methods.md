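# Methods

## Reporter kinetics model

The synthetic-data generator treats the mCherry-Cub-GFP (CCG) reporter as a
linear three-species system. U is the intact reporter, R_c the cleaved
mCherry-Cub fragment, G_c the cleaved GFP moiety:

    dU/dt   = s − (k_cl(t) + d_r)·U
    dR_c/dt = k_cl(t)·U − d_r·R_c
    dG_c/dt = k_cl(t)·U − d_g·G_c

k_cl(t) is piecewise constant: `cleavage_rate_on` while an interaction
window is active, `cleavage_rate_off` (default 0) otherwise. Red signal is
proportional to U + R_c, green to U + G_c. This is the minimal mechanism
consistent with interaction-gated cleavage followed by rapid degradation of
the released GFP; no spatial reaction–diffusion behavior, maturation
kinetics, or higher-order photophysics is modeled.

Assumptions and consequences worth knowing:

* **Pre-fusion steady state.** Before fusion U is constant at
  `initial_reporter` with R_c = G_c = 0. The steady state s/d_r is
  undefined at d_r = 0, so the pre-fusion level is an explicit parameter.
* **Synthesis.** The default is s = 0 (the reporter promoter is treated as
  shut off during the ~2 h measurement); continuing synthesis is supported
  by setting s > 0, which dilutes conversion and can make FD(t)
  non-monotone.
* **Monotone conversion.** With s = 0, noiseless FD(t) is non-decreasing
  for every schedule *provided* d_g ≥ d_r: the time derivative of the
  green/red ratio is proportional to G_c·(d_r − d_g). The defaults
  (d_g = 0.7/min, a ~1-min GFP half-life; d_r = 0, mCherry long-lived)
  satisfy this, and the property test asserts the qualified form.
* **Integration.** The system is integrated segment-by-segment over the
  piecewise-constant schedule with an adaptive solver (LSODA,
  rtol 1e-10, atol 1e-12), with every acquisition time and window boundary
  an exact grid point. A fixed-step explicit scheme was rejected: at the
  0.1-min step suggested by the sampling grid it neither meets the 1e-6
  agreement contract with the closed-form piecewise solution over a
  115-min trace nor remains stable for stiff settings such as
  d_g = 100/min. The independent check in the test suite propagates the
  closed-form solution of the constant-coefficient system with a matrix
  exponential.

## Sampling model (what the generator emulates)

Measured traces contain, per timepoint and channel, three mean-gray
readings: polarity-site ROI, cytosol, and extracellular background.

* ROI = roi_fraction·signal·bleach + background + noise;
  cytosol = (1 − roi_fraction)·signal·bleach + background + noise;
  background = background level + noise.
* **Bleaching** is first-order per exposure and per channel
  (cumulative factor (1 − b)^i at the i-th acquired frame; default
  b = 0.002 per channel). Equal red/green bleach cancels in FD; unequal
  bleach biases it, which is a real artifact the pipeline inherits.
* **Noise** is additive Gaussian on each reading (default SD 0.5 on a
  100-unit reporter). An ROI mean averages hundreds of pixels, so
  sub-percent noise on the *mean* is realistic; cell-to-cell biological
  variability is modeled separately as timing jitter (below), not as
  intensity noise. Poisson noise and segmentation/tracking errors are not
  modeled, so passing tests bound numerical and statistical behavior, not
  robustness to imaging artifacts.
* **Timing jitter.** In populations each cell's interaction windows are
  shifted by a Gaussian offset (default SD 1 min), representing
  cell-to-cell variability of event timing relative to the observed fusion
  frame; sampling times stay on the fixed 2/3/5-min grid.
* `roi_fraction` must exceed 0.5 for the localized intensity
  FI = ROI − cytosol to be positive; the default is 0.7. The geometric
  factor (2·roi_fraction − 1) cancels in RFI.

FRAP traces are generated directly from the one-phase association model
with an instantaneous bleach (default depth 0.9, a full-laser-power
bleach), 4 pre-bleach frames, 0.9-s frame interval, and 120 frames
(~12 half-times at the 8.82-s wild-type scale, i.e. recovery followed to
plateau). Acquisition bleaching decays ROI and reference jointly and is
removed by the ratio step. Noise is shot-like — Gaussian with
SD = noise_sd·sqrt(signal / pre-bleach level) — so nearly-dark post-bleach
frames carry proportionally less absolute noise, as photon statistics
dictate; the whole-cell reference averages a much larger area and is
quieter by `reference_noise_factor` (default 0.1, a ~100× area ratio).
This matters because the full-scale normalization anchors the curve on the
single first post-bleach frame: with flat additive noise that one frame
dominates the half-time error budget.

## Quantification

Two background conventions are exposed deliberately. The comparative-
localization ratio (I_f − I_b)/(I_c − I_b) is offset-invariant and used to
compare enrichment across strains. The SPLIFF path subtracts the
intracellular (cytosolic) background: FI = I_f − I_c, then
RFI(t) = FI(t)/FI(t_ref) with t_ref the last pre-fusion frame (a mean of
the last k pre-fusion frames is configurable), and
FD(t) = 100·(RFI_red − RFI_green)/RFI_red.

Numerical conventions: a near-zero ratio denominator (|I_c − I_b| below a
configurable floor, default 1e-9) flags the timepoint invalid rather than
raising; negative FD values (noise around zero conversion) are retained
for curve fitting and only the calling rules treat them through the slope
criteria; FD ≥ 80% sets the interpretability caveat flag (near exhaustion
of uncleaved reporter the statistic saturates); cells whose pre-fusion
reference is non-positive are excluded and listed in
`ConversionQuantifier.excluded_cells_`. Phase intervals are half-open
[start, end): a timepoint exactly on a boundary belongs to the later
phase. Missing timepoints propagate as gaps and are never interpolated.

## Population curve and interaction calling

* **Loess.** Degree-2 locally weighted regression with tricube weights on
  the span-nearest points (default span 0.25 of the pooled data), fitted to
  all replicate (time, FD) points pooled across cells. Fitted values come
  from a QR least-squares solve of the weighted local design; the 95% band
  is the pointwise normal band ±1.96·σ·‖l(x)‖ with the equivalent-kernel
  vector l(x) and σ² = RSS/(n − tr L) from the residuals at the data
  points. The band is pointwise, not simultaneous.
* **Windows.** Each window spans three consecutive grid points (two
  sampling intervals) and advances one grid point. The trend inside a
  window is fitted to the pooled replicate values, not to the smoothed
  line — testing the loess line alone would understate uncertainty — and
  at three support points a smooth additive-model term degenerates to a
  straight line, so the fit is ordinary least squares with a
  t-distributed slope test (two-sided). The loess curve supplies the
  window's mean conversion for the 70% rule. Window width is configurable.
* **Calling.** Below 70% mean conversion: slope ≥ 1 %/min (inclusive) and
  P < α (default 0.05). At or above 70%: slope > 0 and P < α. The negative
  control must not meet the same criterion in the same window (veto);
  without a control the veto is disabled and logged. Stars: P < 0.001
  (***), < 0.01 (**), < 0.05 (*). No multiple-testing correction is
  applied across windows by default, mirroring the per-window α rule;
  windows at ≥ 80% conversion keep their call but carry the caveat flag.
* **Pooling across sampling intervals** uses continuous time; the common
  grid runs at the finest interval present.

## Schedule-recovery benchmark

The standard benchmark simulates 20 cells on a 115-min cell cycle sampled
every 2 min, phases PCDI (0–20), PCDII (20–100) and PCDIII (100–115) min,
with one true interaction window per phase (2–14, 28–42, 100–108 min) at
cleavage rate 0.03/min (~3 %conversion/min initial rise, final conversion
~65%), timing jitter SD 1 min, and the noise model above. A window is
truly active when ≥ half of it overlaps a true window; windows straddling
a true boundary ± one sampling interval are excluded from scoring because
the truth there is genuinely ambiguous (jitter and the GFP lag blur the
transition by about a frame). Calls against a no-cleavage negative control
recover the truth with F1 ≥ 0.9 (1.0 at most seeds), and 200 null
replicates bound the per-window false-call rate at well under α — the
slope floor makes the test strongly conservative on null data. At
substantially higher noise (5% of the reporter scale per reading) recovery
degrades; a pilot-calibrated regression test pins that operating point.

## FRAP fitting

Double normalization divides ROI by reference per frame, then maps the
pre-bleach mean to 1 and the first post-bleach frame to 0. Traces with a
non-positive reference frame, or without a detectable bleach step
(relative drop < 0.05), are rejected; post-bleach values above the
pre-bleach mean are flagged. The post-bleach segment (t = 0 at the first
post-bleach frame; irregular frame times accepted) is fitted by nonlinear
least squares to P·(1 − e^(−kt)) with bounds P ∈ [0, 5], k > 0 and a
6-point multistart grid on k (geometric, spanning 0.1–50 recovery times
per trace duration) to avoid local minima. The plateau P estimates the
mobile fraction and is reported but is a free parameter, not fixed at 1;
t_1/2 = ln 2/k exactly by construction. Group summaries report mean ± SEM
across cells. Normality is tested per group with the D'Agostino–Pearson
omnibus test, which is undefined below n = 8; smaller groups (the
interface accepts n ≥ 3) are routed to the nonparametric branch.

## Problem sizes

Defaults were chosen so the full validation runs comfortably on a laptop:
the benchmark uses 20 cells (~1 s end to end), the null calibration 200
replicates of 10 cells (~30 s), and the FRAP ensembles 50 traces of 120
frames. All of these are parameters, not constants.

## Known limitations

* The kinetic model is well-mixed and linear; saturation of the cleavage
  machinery, reporter maturation, and diffusion between the polarity site
  and cytosol are not represented.
* The loess band and the window P-values treat pooled points as
  independent; repeated measures within a cell are correlated, so the
  stated coverage is approximate. The calling rules inherit this from the
  original two-stage design.
* Rendering of synthetic frames exists to validate the SUM-projection /
  mean-gray ROI conventions round trip; it draws flat discs, not realistic
  cells, and is not a segmentation testbed.
* The FRAP model is a single exponential; binding-diffusion mixtures and
  bleach-spot geometry corrections are out of scope.
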