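# Methods

This note documents the models, estimators and numerical choices behind
`larvataxis`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Odor landscape

Concentration from a point source of flux γ (arbitrary units, default 1)
releasing at time t₀ into a medium with diffusion constant D
(default 0.025 cm²/min) is the free-space diffusion solution

    C(r, t) = γ / (4πD r) · erfc( r / √(4D (t − t₀)) ),

with r the 3-D Euclidean distance to the source; multiple sources
superpose. Internal units are cm and minutes; seconds are converted at the
API boundary. Sources sit by default 0.5 cm above the behavioral plane
(z = 0), and distances are 3-D — the animals never contact the source. The
spatial gradient is analytic:

    dC/dr = γ/(4πD) · [ −erfc(u)/r² − 2 e^(−u²) / (√π · r · √(4Dτ)) ],
    u = r/√(4Dτ),

pointing along the source direction. A quoted description of the geometry
mentions absorbing boundaries, but the implementable closed form is the
free-space solution; no boundary correction is applied and the field is
treated as unbounded.

`concentration_along_path` evaluates C along a trajectory (head, centroid
or tail) either at the true elapsed time or — the default for simulation
analysis — at a frozen "gradient age" (`static_time`), treating the field
as quasi-static over a few-minute assay. The temporal derivative is
estimated two ways:

* `central` (default): central differences of the moving-average-smoothed
  C series (window 1 s by default);
* `lagged`: backward difference over the window, after a light 0.25-s
  pre-smoothing. This matches a sensory integrator that compares "now"
  with "one second ago" and is the estimator used for hazard recovery
  (below).

Degenerate inputs: evaluating at a source is a singularity and raises;
grid cells that coincide with a source are flagged and set to NaN rather
than returned as infinities; t ≤ t₀ raises.

## Agent-based larva simulator

One larva is a 3-point skeleton (head, centroid, tail) advanced at 20 Hz.
States are RUN, STOP and CAST; every frame is labeled and every maneuver
recorded, so detectors can be scored exactly.

**Runs.** The tail advances along the heading at speed
v(φ) = v₀·(1 + cos 2πφ), peaking at the start of each peristaltic cycle
(the visceral-piston moment) with period P = 1 s and mean v₀ = 0.8 mm/s.
Body length is L₀ + A/2·(1 + cos 2π(φ − 340°/360°)), L₀ = 4 mm,
A = 0.6 mm, so the body-length peak falls just before the next tail-speed
peak — the structure the wave-cycle detector pairs. Heading performs a
wrapped-Gaussian random walk (5°/√s). Head and tail are placed half a body
length from the centroid, so the 3-point length |head−centroid| +
|centroid−tail| equals the instantaneous body length exactly.

**Sensing and run termination.** The sensed concentration change is the
difference between the current centroid concentration and that one
peristaltic period earlier (a ring buffer, cleared at each run start).
A per-frame difference would be useless: the centroid sways backward during
the half-cycle in which the body shortens, flipping the sign of a one-frame
ΔC within every cycle regardless of the direction of travel. Run
termination is a Bernoulli approximation of an inhomogeneous Poisson
process with per-frame probability 1 − exp(−λ·Δt), with λ = λ_up = 2/min
while the sensed ΔC > 0, λ_down = 8/min while ΔC < 0, and λ₀ = 4/min with
no odor. The `pdm_silenced` genotype sets λ_down := λ_up, abolishing the
asymmetry.

**Stops, casts, turns.** A spontaneous stop lasts a Gamma(2)-distributed
quiescent period (mean 2 s) followed by head-cast sweeps (1 + Poisson(1)
sweeps of ±60° at 120°/s). The turn direction is chosen toward the side on
which the head would sample a higher concentration with probability
`gradient_bias` (0.7), and the magnitude is a truncated normal
(mode 60°, sd 50°, truncated to [35°, 150°]): larval reorientations are
large-angle maneuvers, and small course corrections are already produced by
within-run heading noise. The ground truth records each turn's sign, angle
and whether the post-turn heading points up the local gradient.

**Optogenetic flash response (`chrimson`).** At each flash onset a stop
command is drawn with probability `p_stop` (0.95) and executed after a
latency of 0.4 s ± 0.05 s (clipped at ±2 sd, so commands always land within
0.5 s); a larva that is not running when the command arrives ignores it.
Casting begins after an exponential delay whose mean scales inversely with
cast vigor (3 s at 100°/s), and vigor is set by the pre-flash gradient sign
(100°/s up, 200°/s down) — more vigorous down-gradient responses also
engage earlier and therefore cast for a larger fraction of the flash.
Crawling resumes at min(flash end, stop onset + 3 s + noise) with a brief
speed ramp. Per-flash ground truth records both the drawn command
(commanded?, latency) and the realized response (did a non-RUN interval
begin inside the flash window, with what latency and duration), the latter
being the definition detectors are scored against.

**What the simulator does not emulate.** No biomechanical body, no
muscle or network dynamics, no larva–larva interactions, no arena walls
(assays are minutes long; animals stay within a plate-sized region), no
odor adsorption or airflow. Sensor noise is i.i.d. Gaussian position jitter
(10 µm), far simpler than real tracking artifacts (occlusions, head/tail
swaps, contour noise). Passing recovery tests therefore demonstrates the
correctness of the estimators under the model's assumptions, not their
robustness to real tracking pathologies.

## Behavioral segmentation

Kinematics are derived from positions smoothed with a 0.3-s moving average
(central differences for speeds; body length from the 3-point skeleton;
signed body-bend angle between tail→centroid and centroid→head, in
(−180°, 180°]). For peristalsis analysis a much lighter smoothing
(≤ 1 frame) is appropriate, since the 1-Hz tail-speed oscillation is the
signal.

The classifier thresholds (one config block, echoed in all outputs):
θ_stop = 0.3× the animal's median running tail speed (fallback
0.25 mm/s), θ_run = θ_stop, min_stop = 0.5 s, min_run = 1 s, cast
thresholds 20° / 20°/s, θ_turn = 30°. Sub-threshold intervals ≥ min_stop
are stops; within them, frames with large bend angle or bend-angle speed
are casts. Above-threshold fragments shorter than min_run keep RUN-state
frames but are not reported as runs: merging them into the stops would fuse
adjacent stop intervals and make a flash-evoked stop undetectable whenever
a short run preceded the flash. A turn event is anchored at the start of
each sustained run that follows a non-run gap, scored by the circular-mean
heading change between the last 0.5 s of the previous run and a 0.5-s
window shortly after resumption (offset by a quarter second to clear the
smoothing transient).

**Gradient conditioning and hazard recovery.** Runs are labeled UP/DOWN by
the sign of the mean ΔC/ΔT over the run (`classify_run_gradient`). For
recovering λ_up and λ_down, however, whole-run labels are biased by
survivorship: a long up-gradient run typically ends just after the heading
has rotated into the down-gradient regime, so its termination would be
charged to the UP class. `estimate_turn_hazards` therefore conditions on
the instantaneous class — time at risk is counted per frame by the sign of
the (lagged) ΔC/ΔT, and each termination is assigned the class of the final
run frame. On 100 simulated larvae this recovers λ_up and λ_down within
20% and their 4:1 ratio within 25%.

`distance_to_nearest_source` uses 2-D plate distance by default (3-D
optional — whether the original distance metric included the source height
is not determinable, so both are exposed); the snapshot statistic is the
per-larva mean within a 1-s window centered on 150 s.

## Flash-triggered analysis

Trials are aligned at flash onsets; partial trials are dropped and counted.
The pre-flash baseline is the 2-s window before onset. A trial counts as
stopped when a non-RUN interval of at least min_stop *begins* inside the
flash window; latency is measured to the interval start and the duration is
the full interval, which may outlast the flash. Stops already in progress
at onset never count. `running_at_onset` requires a clean half second of
running before the onset — with a single-frame check, boundary jitter in
the detected stop onset converts stops that began just before the flash
into spurious successes. The optional `max_latency` narrows the scoring
window (the acceptance analyses use 1 s, 2.5× the command latency) to
separate command-like evoked stops from spontaneous pauses later in the
flash; with the full 6-s window the measured probability sits a little
above the configured `p_stop` because non-commanded trials still pause
spontaneously.

Stop probability carries an exact Clopper–Pearson interval. The relation
between pre-flash speed and stop probability uses six equal-count bins and
ordinary least squares on the bin means (slope, R², two-sided slope test).
Per-trial extrema (e.g. minimum tail speed during the flash) should be
computed on a one-cycle (1-s) moving average of tail speed: the raw
waveform touches zero within every peristaltic cycle by construction.

## Peristaltic waves

A wave cycle runs from a tail-speed peak to the next body-length peak;
phase is linear in time over the cycle, with bins INITIAL [0°, 90°],
HINGE [135°, 225°], LATE [270°, 360°) and UNBINNED gaps; times outside any
cycle are OUTSIDE. The phase→segment mapping is nominal: the package labels
bins and never infers a segment from phase. Peak finding uses prominence
≥ 20% of the series IQR and a minimum separation of half the
autocorrelation-estimated period.

Segment traces (denticle displacement Δx or per-segment ΔF/F, posterior→
anterior, bilateral pairs merged by mean) are reduced to onsets: per-event
threshold crossings at 50% of the event-local peak. The peak-detection
prominence floor is max(0.35× the 99th percentile of |x − median|, 5× the
robust per-frame noise scaled by the smoothing width) — an IQR fraction
alone admits baseline noise at realistic SNR. Onsets chain into a wave when
consecutive-segment latencies lie within [0.02, 2] s (contraction) or
[0.1, 10] s (fictive); a chain reaching the most anterior segment is
complete. Single-segment chains are kept: they matter for pull-push
detection but are ignored ("non-propagating") when categories are decided,
because at SNR 5 an isolated noise onset at A4 would otherwise masquerade
as a new A4-initiated wave.

Flash outcomes are classified with precedence FAILURE_TO_STOP (a complete
posterior-initiated wave starts during the flash) > NEW_WAVE_FROM_A4 >
PULL_PUSH (≥ 2 posterior onsets during the flash, nothing anterior of A5)
> fate of the ongoing wave (no further onsets → IMMEDIATE_TERMINATION;
last onset at the hinge segment A4 (± a configurable segment tolerance,
default 0 — the fictive preparations truncate slightly earlier, which a
±1 tolerance covers) → TERMINATED_AT_HINGE; reached A1 with no new wave →
COMPLETED_THEN_BLOCKED). When two ongoing waves overlap a flash the most
recent is used and the outcome is flagged ambiguous. `count_waves` counts
complete waves by first onset in the 20-s windows before and through the
flash, each wave exactly once.

## Fluorescence

ΔF/F = (F_i − F₀)/F₀ with two baseline conventions: the whole-series mean
(motor imaging; the resulting ΔF/F averages to zero exactly) or the mean of
a 2-s pre-stimulus window per epoch (stimulus-triggered imaging; no
filtering by default). The pipeline order is ΔF/F first, then optional
Savitzky–Golay smoothing (order 3, frame length 15). The filter fits the
stated polynomial on truncated windows at the edges instead of padding —
no data are fabricated beyond the recording — and reproduces polynomials up
to the filter order to ~1e-12. ROI means accept boolean masks, rectangles
or polygons over (T, H, W) stacks or multi-page TIFF files. Peak response
is the per-epoch maximum of ΔF/F within a response window after each
stimulus; with noise the maximum is upward-biased by the expected maximum
of the noise over the window, which the test suite accounts for explicitly
with a Monte-Carlo oracle rather than pretending the estimator is unbiased.

## Statistics

Clopper–Pearson intervals use the beta-quantile formulation
(lower = Beta⁻¹(α/2; k, n−k+1), upper = Beta⁻¹(1−α/2; k+1, n−k), with the
k = 0 / k = n boundaries at 0 and 1); the test oracle inverts the binomial
CDF by bisection. The two-proportion Z-test is the pooled form with a
two-sided normal p-value; a pooled proportion of 0 or 1 is flagged rather
than returned as ±inf. Rank tests are delegated to scipy (rank-sum for
independent designs, signed-rank for paired), with the exact null used when
all groups are smaller than 25, and Bonferroni correction
p_adj = min(1, p·m) over the m pairwise comparisons of the family; the
family size is recorded in the output.

## Pipeline and determinism

All randomness flows from one master seed: cohorts derive per-larva seeds
via `numpy.random.SeedSequence.spawn`, and the pipeline offsets the master
seed per cohort. Reports serialize floats at 9 significant digits with
sorted keys and no timestamps, so identical config + seed produce
byte-identical JSON. The shipped demo (two 6-larva genotype cohorts and a
4-larva flash cohort, 2 minutes each, plus wave and ΔF/F stages) runs in a
few seconds on one CPU; the recovery analyses in the test suite use
cohorts of 100 × 5 min (hazards), 10 × 2 × 14 × 3 min (genotype contrast)
and 25 × 5.3 min (flash), sized to keep estimator noise well inside the
asserted tolerances.

## Known limitations

* The hazard-recovery estimator assumes the sensory lag of the simulated
  animal (one peristaltic period); on real data the integrator timescale
  is unknown and the smoothing window should be treated as a sensitivity
  parameter.
* Whole-run UP/DOWN labels are reported for turn-rate summaries because
  that is the field's convention, but they understate hazard contrasts for
  the survivorship reason above.
* Classifier thresholds are engineering defaults, not values inherited
  from any particular tracker; every output embeds the thresholds used.
* The odor model is free diffusion from points; no boundaries, advection
  or adsorption. Gradient geometry is meaningful, absolute concentration
  is not.
* Wave-outcome classification is exact on clean fixtures and ~90% at
  SNR 5; the residual errors are chain breaks in onset detection, not
  category logic.
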