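# larvataxis

Quantitative analysis of *Drosophila* larva chemotaxis and descending motor
control: an analytical odor-landscape model, behavioral segmentation of
larval trajectories into runs, stops, head casts and turns with
gradient-conditioned statistics, optogenetic flash-triggered analysis,
peristaltic wave-cycle and segmental-wave analysis, and ΔF/F fluorescence
quantification. Every analysis stage can be exercised on synthetic data
from an agent-based larva simulator that embodies the underlying
sensorimotor algorithm and returns complete ground truth.

## The science in brief

Larvae navigate odor gradients with a biased run-and-tumble strategy.
During runs the animal crawls forward by posterior-to-anterior peristaltic
waves; run termination is modeled as an inhomogeneous Poisson process whose
hazard depends on the sign of the concentration change the animal
experiences: turning is suppressed while ascending the gradient
(ΔC/ΔT > 0, hazard λ_up) and promoted while descending (λ_down > λ_up).
After stopping, the larva samples the gradient with lateral head casts and
resumes a run in a new direction, accepting directions that increase the
local concentration with a configurable bias.

The odor field of a point source with flux γ and diffusion constant D
(0.025 cm²/min) is

    C(r, t) = γ / (4 π D r) · erfc( r / √(4 D t) ),

summed over sources; its analytic spatial gradient supplies the
"toward-gradient" geometry of turn statistics.

Descending "stop neurons" are modeled optogenetically: in the
flash-responsive genotype each light flash evokes a stop command with
probability `p_stop` after a short latency, followed by head casting whose
vigor depends on the pre-flash gradient sign, and adaptation back to
crawling. At the motor level, a peristaltic cycle is the window from a
tail-speed peak to the next body-length peak (0–360° of phase; the hinge
phase, segments A4–A5, spans 135–225°). Stop commands interact with
ongoing segmental contraction waves: waves may complete and block further
initiation, terminate at the hinge segment A4, terminate immediately,
re-initiate from A4, enter a posterior "pull-push" loop, or fail to stop —
all six outcomes are generated by the fixture module and recovered by the
classifier.

Fluorescence analysis implements ΔF/F = (F_i − F₀)/F₀ with two baseline
conventions (whole-series mean, or the mean of a 2-s pre-stimulus window),
optional Savitzky–Golay smoothing (order 3, frame length 15), and per-epoch
peak responses. Shared statistics include exact Clopper–Pearson binomial
intervals, the pooled two-proportion Z-test and Wilcoxon rank tests with
Bonferroni correction.

## Worked example

```python
import larvataxis as lt

# odor landscape: one source 2.5 cm from the start, 0.5 cm above the plane
land = lt.OdorLandscape([lt.OdorSource((2.5, 0.0, 0.5), flux=1.0)])

# simulate 20 wildtype larvae for 5 minutes at 20 Hz
cfg = lt.SimulationConfig(seed=42, duration=300.0)
cohort = lt.simulate_cohort(cfg, 20, landscape=land)

# segment behavior and recover the gradient-conditioned turn hazards
from larvataxis.segmentation import estimate_turn_hazards
ku = kd = 0; tu = td = 0.0
for traj, truth in cohort:
    kin = lt.derive_kinematics(traj)
    ann = lt.segment_behavior(kin)
    _, dcdt = land.concentration_along_path(traj, "centroid",
                                            static_time=200.0,
                                            derivative="lagged")
    h = estimate_turn_hazards(ann, dcdt)
    ku += h["events_up"]; kd += h["events_down"]
    tu += h["time_up_min"]; td += h["time_down_min"]
print(f"lambda_up  = {ku/tu:.2f} /min")
print(f"lambda_down = {kd/td:.2f} /min")

dist = lt.distance_to_nearest_source([t for t, _ in cohort], land.sources)
print(f"mean distance to source at 150 s: {dist['snapshot'].mean():.2f} cm")
```

Output (seed 42):

```
lambda_up  = 1.67 /min
lambda_down = 7.28 /min
mean distance to source at 150 s: 1.39 cm
```

The recovered hazards reflect the configured suppression (λ_up = 2/min) and
facilitation (λ_down = 8/min) of turning — a 20-larva cohort is small, so
individual estimates scatter around the configured rates — and the cohort
has closed almost half of its initial 2.5 cm distance to the source by
150 s.

The same analyses are available from the command line:

```bash
larvataxis report --demo --out out/        # full pipeline demo
larvataxis simulate --out sim/             # trajectories + ground truth
larvataxis segment sim/larva-000.tsv --out seg/
```

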