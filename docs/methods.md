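# Methods

This note documents the models, estimators and numerical choices in
`runtumble`, the reasoning behind the open design decisions, and the
known limits of what the synthetic-data tests demonstrate.

## Track representation and units

Time is in minutes, positions in micrometres, angles in degrees in
(−180, 180] with 0° the local migration direction; column headers in
the CSV/TSV formats are case-insensitive and the decimal separator is
always a point.  Trajectories require strictly increasing times, at
least two points and finite coordinates; a missing z column is read as
0 so planar (simulated) and 3D (experimental) data share one schema.

## Alignment–speed segmentation

For displacement vectors **v**_i between consecutive frames,

- *A*_i = mean of cos∠(**v**_i, **v**_k) over k ∈ [i−w, i+w], k ≠ i,
  with window w = 2 frames at 1.5-min sampling (truncated at the track
  ends).  *A* ∈ [−1, 1] measures local directional persistence.
- *S*_i = |**v**_i| / Δt divided by the trajectory's mean
  instantaneous speed.

Frames with zero displacement get *A* = *S* = 0 and are flagged:
a stationary cell is treated as unaligned, tumble-like evidence.

The density *P(A, S)* pools all frames of an ensemble on a 41×41
histogram over *A* ∈ [−1, 1], *S* ∈ [0, 3], smoothed with a separable
Gaussian kernel and renormalised.  The default kernel SD is **2.0
bins**: at the ensemble sizes of interest (≈20–40 cells × 80 frames)
the histogram holds on the order of one point per bin, and a narrower
kernel leaves sampling ripples that capture the threshold search
(threshold SD across realisations ≈0.17 at 1.5 bins vs ≈0.07 at 2.0).

The **maximum line** *S\*(A)* is the least-squares line through the
per-*A* density maxima, using only columns whose peak reaches 5% of
the global peak.  The **threshold** is located on the 1D cross-section
of the density along that line: when the cross-section is convincingly
bimodal — a secondary mode with prominence ≥ 15% of the profile
maximum, with the profile zero-padded so a mode abutting *A* = 1
keeps its full prominence — the threshold is the local minimum
between the global maximum and the nearest other mode.  Otherwise a
flagged fallback places it at the knee of the shoulder on the
longer-tail side of the mode (maximum deviation below the
mode-to-tail chord), which proved far better conditioned than
curvature maxima on smooth profiles.

Classification projects each standardized (*A*, *S*) point (unit
variance in both coordinates, so "perpendicular" is defined on mixed
units) onto the maximum line; frames beyond the threshold point are
runs.  **No minimum segment length is imposed by default**: at 1.5-min
sampling many genuine tumbles span a single frame, and merging
one-frame segments away inflates segmented run durations roughly
two-fold.  `min_segment` remains available for noisier data.  The last
timepoint inherits the preceding label and carries no time interval,
so segment durations sum exactly to the track duration.

For short high-frame-rate tracks (~10–25 s frames) the density
approach is inapplicable and a direction-based rule is used: a run
continues while motion stays within 45° of the run's initial
direction or a larger deviation lasts < 5 frames; a deviation
persisting ≥ 5 frames opens a tumble (those five frames are its
evidence window), which ends when five consecutive frames agree with a
stable new direction.

## Phase statistics

Durations come from the segment tiling; instantaneous speeds are
pooled by the phase of each displacement frame; the speed ratio is
mean run speed over mean tumble speed; inter-run angles are measured
in 3D between net displacements of consecutive run segments;
persistence is net displacement over path length.  Phase durations are
fitted as exponentials (MLE mean, bootstrap 95% CI) with an SD/mean
diagnostic that is ≈1 for an exponential sample.

## Protrusion statistics

A protrusion is **actin-rich** if actin is present throughout its
expansion and its peak curvature reaches the threshold, a **bleb** if
it starts without actin and stays below the curvature threshold;
contradictory feature combinations are left unclassified with a
warning.  No universal curvature threshold ships with the package — it
depends on the imaging pipeline — so `calibrate_curvature_threshold`
selects it from labelled examples by accuracy maximisation.

The polar order parameter is computed per cell,
POP_c = |Σ w û(θ)| / Σ w (weights are Lifeact intensities for
actin-rich protrusions, 1 for blebs), and reported as mean ± SEM
across cells, with non-overlapping SEM intervals as the significance
convention.  For a von Mises sample with concentration κ the expected
POP is I₁(κ)/I₀(κ); the generator inverts this Bessel ratio by root
finding when a target POP is requested.  Formation-rate ratios divide
each cell's per-minute event rate in tumbles by that in runs.

## Pursuit model

Cells are 2D active Brownian particles.  Phase durations are i.i.d.
exponential with means τ_r (run) and τ_t (tumble).  At each run start
the heading mean is the true bearing to the current target position
plus N(0, σ_ε²); during the run the heading is an Ornstein–Uhlenbeck
process around that mean with relaxation time τ_rel = 1 min and
stationary SD √(D_θ·τ_rel).  Speeds are truncated Gaussians redrawn
every integration step (dt = 0.1 min).  Tumbles redraw an isotropic
heading each step — the plainest reading of "randomly moving without
preferred direction"; a rotational-diffusion tumble variant is
available behind a flag.  The target moves along +x at constant
v_target from (d₀, 0); defaults d₀ = 300 µm and v_target = 1 µm/min
are package choices (no measured values are available) and are
overridable.  Note that with per-dt isotropic tumbling the *observed*
tumble speed at 1.5-min sampling is ≈0.26× the generative tumble
speed parameter, which is why calibrated v_tumble exceeds v_run.

Output tracks are sampled every 1.5 min so simulated data are analysed
identically to experiments.  Per-cell RNG substreams spawn from the
master seed, making every ensemble, generator and sweep bit-for-bit
reproducible and independent of execution order.  Ensemble read-outs
are the mean Euclidean distance to the target and the positional
dispersion var(x) + var(y) (unbiased) at the evaluation time
t_e = 90 min.

## Calibration

The printed migration statistics are read-outs of the segmentation
applied to tracked nuclei, so the model is calibrated in a closed
loop: simulate an ensemble, segment it blind with the same pipeline,
compare pooled statistics to targets via a weighted sum of squared
relative errors.  The search is a Latin-hypercube screen (half the
budget) followed by coordinate-wise refinement, with common random
numbers across parameter points; the objective can average several
independently seeded ensembles to damp threshold-placement noise.
Because a noisy objective's apparent optimum is biased toward its own
random-number realisation, the top candidates are re-evaluated on
fresh seeds and scored as mean + SD across realisations, preferring
parameter regions whose segmented read-outs are *stable*, before the
final choice.  Calibration weights emphasise the statistics with the
tightest experimental spread (speed ratio for neighbour-free-host
controls, persistence for wild-type hosts).

## Scenario presets

The per-condition presets share one calibrated generative set
(τ_t = 1.2 min, v_run = 2.6 ± 0.3 µm/min, v_tumble = 3.5 ± 1.1 µm/min,
D_θ = 0.1 rad²/min, σ_ε = 1.1 rad) and differ **only in τ_r**
(control 1.75, *ezrin*-MO 1.48, CAEzrin 2.40 min), mirroring the
finding that Ezrin perturbations change run, not tumble, durations.
τ_r values were fixed once so that blind segmentation of preset tracks
recovers the per-condition mean run durations measured in vivo
(≈5 / 3.8 / 6.4 min).  The generative means are much shorter than the
segmented ones because tumbles shorter than about one frame are
invisible at 1.5-min sampling and silently merge adjacent runs.

Duration read-outs pool segments over several independently seeded
simulated experiments (by default 8 batches of 40 cells, 120 min
each), each batch segmented against its own density, as replicate
experiments would be; batching averages over the threshold-placement
noise that dominates the read-out SD.

## What the synthetic data do and do not show

The generators emulate exponential phase switching, detection-error
pursuit, von Mises protrusion orientations and lognormal actin
weights.  They do not emulate cell–cell contacts, spatially varying
guidance cues, measurement noise in nuclei positions, or protrusion
detection errors; passing tests therefore demonstrate the estimators'
correctness and the pipeline's internal consistency, not robustness to
those real-data effects.

## Known limitations

- **Segmented tumble durations are biased high.**  The ±2-frame
  alignment window pads every detected tumble by roughly one frame per
  boundary.  Empirically the pipeline's run-vs-tumble duration
  read-outs trade off along a front on which tumble means ≤3.6 min
  force run means ≥6.4 min; the in vivo pair (5.0, 3.1) lies outside
  it, so with the control preset the segmented tumble duration comes
  out near 4.4–4.7 min instead of 3.1 (the corresponding acceptance
  test fails by design, and run-duration fidelity was prioritised).
- **No dispersion minimum at the calibrated run time.**  In this model
  the dominant dispersion source is the per-run aiming error; matching
  the measured ~68° inter-run angles requires σ_ε ≈ 1 rad, which makes
  dispersion grow monotonically with τ_r for every pursuit geometry
  tried.  A minimum at the calibrated τ_r appears only for σ_ε ≲ 0.4
  together with arrival at the target by factor 1, which in turn bends
  the mean-distance curve upward at large τ_r.  The two predicted
  sweep properties are jointly unattainable in this variant; the
  distance monotonicity holds and is tested, the dispersion-minimum
  test fails by design.
- **The short-run regime is bistable.**  For generative τ_r ≲ 1.5 min
  the run mode in *P(A, S)* weakens and the threshold alternates
  between two states across realisations; the *ezrin*-MO read-out
  inherits an SD of ≈0.3–0.6 min from this.
- Problem sizes throughout (ensembles of 18–40 cells, 100-replicate
  sweeps, calibration budgets of ~160 evaluations) are the package's
  defaults chosen to keep every analysis reproducible on a laptop in
  minutes; all are parameters.
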