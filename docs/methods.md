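# Methods

## Plant

One rotational degree of freedom (elbow flexion/extension in a parasagittal
plane) coupled to an exoskeleton:

    (I + σ·Is) θ̈ = τ_h + τ_r − B θ̇ − m_h l g cos θ

Angle convention: θ = 0 is the horizontal forearm, positive θ is flexion;
targets sit at ±22.5°, i.e. 45° movements centred on the horizontal.
Defaults (identified constants of the coupled system): I = 0.35 kg·m²,
B = 0.05 N·m·s/rad, m_h l = 0.2934 kg·m, g₀ = 9.81 m/s².

The robot torque compensates a fraction α of the gravity torque,
τ_r = α·m_h l·g₀·cos θ, which reduces the dynamics exactly to the same
equation with the effective gravity g̃ = g₀(1 − α). α ∈ [0, 2] covers 1g to
−1g; the experimental gradient uses eleven values in 0.2 steps.

`Is` models the exoskeleton's direction- and phase-dependent apparent-inertia
increment, gated by σ ∈ {0, 1} through a four-entry table
(direction × acceleration/deceleration). The published record does not print
the identified Is values or the σ table, so the default is the
ideal-exoskeleton setting (all σ = 0, Is = 0) and both are exposed in the
plant configuration (`plant_defaults.yaml`). The acceleration phase is the
span where the velocity magnitude grows (θ̈·θ̇ ≥ 0).

## The Smooth-Effort optimal control problem

State x = (θ, θ̇, τ_h), control u_h = τ̇_h (commanded torque change).
Rest-to-rest boundary conditions over a fixed duration T: θ pinned at both
ends, θ̇(0) = θ̇(T) = 0, and — forced by θ̈ = θ̇ = 0 under the dynamics —
τ_h at the boundaries equals the static holding torque m_h l g̃ cos θ.

Cost: J = Ce + β·Cs with Ce = ∫|τ_h θ̇|dt (absolute work) and
Cs = ∫(u_h − Bθ̈ + m_h l g̃ θ̇ sin θ)²dt. Along dynamics-consistent
trajectories the Cs integrand equals (I·θ⃛)², so Cs is I² times the
integrated squared jerk; this identity is used as an independent check in
the tests.

### Transcription and solver

Fixed-step Hermite–Simpson collocation (compressed form: midpoint states by
Hermite interpolation, Simpson defects per interval), N = 101 nodes by
default for T = 0.6 s. The NLP is solved with SLSQP on group-scaled
variables (θ, θ̇, τ, u scaled by 0.5, 2, 3, 50 — without this the
quasi-Newton model stalls in the kinky absolute-work valley), with analytic
objective gradients and constraint Jacobians, verified against finite
differences in the test suite. No randomness anywhere: identical problems
give identical trajectories.

The non-smooth |τ_h θ̇| integrand has two treatments:

* `smooth` (default): √(x² + ε²) with ε = 10⁻⁶. The bias is bounded by
  ε·T ≈ 6·10⁻⁷ J, far below solver tolerance, and the NLP stays
  smooth.
* `slack`: exact split into two non-negative slack profiles with
  s⁺ − s⁻ = τ_h θ̇ and ∫(s⁺+s⁻)dt in the objective. Exact, but the doubled
  variable count scales poorly in SLSQP's dense active-set QP, so it is the
  cross-check rather than the default; both modes agree on J to ~10⁻⁴
  relative at equal grids.

Small β (effort-dominant) problems are reached by a deterministic homotopy:
solve at β = 10⁻³ from a minimum-jerk initial guess, then step down a
half-decade ladder, warm-starting each stage. Convergence requires SLSQP
success *and* a maximum dynamics defect below `tol` (10⁻⁶ by default);
anything else raises with the solver diagnostic. Failed warm starts fall
back to the cold homotopy path automatically.

When Is ≠ 0 the inertia switches with the acceleration phase. This is
resolved by a fixed-point iteration: solve with a frozen per-node σ
pattern, re-derive the pattern from the solution's acceleration signs,
repeat until unchanged (typically 2–3 rounds). This replaces a two-phase
transcription with a free switching time; at grid resolution the two are
equivalent and the fixed-point version keeps the NLP unchanged.

An independent single-shooting re-optimization (piecewise-linear control,
dense RK4, separate quadrature; `_shooting.py`) confirms the collocation
optimum: re-optimizing from the collocation solution moves J by less than
0.1%.

## Movement metrics

Movements are segmented at 5% of peak velocity: onset is the last
up-crossing before the speed peak, offset the first down-crossing after,
both linearly interpolated below sample resolution. rtPV =
100·(t_PV − onset)/MD. The peak time is plateau-aware: optimal profiles
under a near-pure absolute-work cost can coast at almost constant velocity,
where a discrete argmax is numerically meaningless; the peak time is then
the midpoint of the contiguous run within 0.1% of the maximum (a sharp peak
falls back to parabolic refinement). Model trajectories are resampled on
their Hermite interpolants (6001 points) and passed through this very same
segmentation, so model and data are compared on identical footing.

A movement is invalid if its acceleration changes sign more than twice
within the movement; sign changes are counted between consecutive nonzero
samples (exact zeros skipped). A peak-speed floor of 10⁻⁴ rad/s rejects
"movements" made of numerical noise.

The net torque splits into Flex = ⌊τ_h⌋₊ and Ext = ⌊−τ_h⌋₊
(Flex − Ext = τ_h, Flex·Ext = 0). The phasic torque subtracts a tonic line
interpolating the static holding torques of the onset and offset postures —
the torque-domain analogue of the EMG baseline decomposition; positive and
negative areas are optionally normalized by the maximum |phasic| over a
compared condition set (per direction by default).

## Kinematic pipeline

Position at 179 Hz → zero-phase low-pass Butterworth (5 Hz cutoff, 5th
design order; the forward–backward pass doubles the effective order and
slightly lowers the −3 dB point) → central-difference velocity and
acceleration → segmentation, metrics, exclusion. Filters run as
second-order sections (the polynomial form is ill-conditioned at cutoff/fs
ratios this small) with odd-reflect padding of three filter time constants,
which keeps edge transients away from the movement. Clean loopback (model →
179 Hz samples → pipeline) reproduces the model rtPV to well under 1% of
MD.

## EMG pipeline

Per channel: band-pass 20–450 Hz (4th order, zero-phase), mean-centre,
rectify; normalize by the participant-and-muscle maximum over all trials;
envelope by 3 Hz low-pass (5th order, zero-phase; small ringing undershoots
are left in place). Normalization precedes enveloping — the laboratory
operation order; normalizing the envelope instead changes the areas.
Groups: flexors = mean of biceps long head and brachioradialis envelopes,
extensors = mean of the two triceps heads.

Tonic/phasic: the envelope average over [onset−1 s, onset−0.5 s] anchors
the tonic line at the onset, the average over [offset+0.5 s, offset+1 s]
anchors it at the offset ("averaged integrated EMG" is read as the envelope
average over the window; the anchor abscissae are a package choice — the
record gives the averages, not the anchors). phasic = envelope − tonic.
Activation area integrates phasic above +5% of its maximum, inactivation
area |phasic| below −5% of its minimum, both across the whole movement with
no assumption about burst boundaries.

## Synthetic experiments

The study's raw recordings are not deposited, so the generator produces
trial-by-trial datasets with the structure the analysis assumes. Designs
mirror the three experiments: exp1 (1g/0g/−1g, six 15-trial blocks per
condition, randomized order after the initial 1g blocks), exp2 (two
25-trial blocks), exp3 (eleven conditions, one 30-trial block each,
gradient traversed monotonically, half the participants in each direction);
trials alternate flexion/extension.

Kinematics: the per-condition SE trajectory (true β = 1.9×10⁻³ by default)
is time-scaled by a lognormal duration jitter (σ = 5%), amplitude-scaled
(σ = 2%), sampled at 179 Hz with ≥ 1.2 s rest padding, and perturbed by
band-limited (< 4 Hz) positional noise calibrated so its induced velocity
SD is 2% of peak velocity. EMG: each channel is an amplitude-modulated
white-noise carrier at 2000 Hz; the modulation is a small co-activation
floor plus a gain times the group's part of the net torque trace (positive
part for flexors, negative magnitude for extensors; static holding torque
during rest), with 10% multiplicative low-frequency noise. Because the
modulation carries the holding torque, tonic levels and inactivation drops
emerge from one mapping. Per-participant plant heterogeneity perturbs I and
m_h l lognormally (σ = 2%).

All randomness flows from one experiment seed through named streams
(participant/condition/block/trial via `SeedSequence` spawn keys), so any
single trial is regenerable in isolation and datasets are byte-identical
across regenerations.

What passing tests show — and don't: trial means follow the SE model *by
construction*, the noise levels are plausible choices (the study prints
only SEM bars, not variance components), and the EMG carrier is not a
motor-unit process. Closed-loop tests therefore validate the pipeline and
the estimator, not the biology of real recordings.

## Inverse optimal control

Given condition-mean rtPV over the gradient, the forward model is evaluated
on a log-spaced β grid over [10⁻⁵, 1] (25 points by default), traversed
from large to small β with each weight's eleven condition solves
warm-started from its neighbour's (warm and cold starts agree within solver
tolerance; spot-checked in tests). Criteria per weight: AAE (mean |pred −
obs|, % of MD, conditions equally weighted) and Pearson r across
conditions, computed only when the predicted curve's range exceeds 0.5% MD
(a flat curve carries no gradient information) and reported only when
p < 0.05. Optima: the AAE minimizer and the defined-and-significant r
maximizer. Both the guard (0.5% MD) and the significance level are
configurable.

## Problem sizes

Defaults aim at reference accuracy: N = 101 nodes for single solves (node
doubling moves rtPV by < 0.02% MD at 1g). Sweeps, the synthetic generator
and the test suite use N = 41, where the eleven-condition curve differs
from N = 101 by at most ~0.4% MD — far below the condition-to-condition
effects of interest — and a closed-loop test dataset uses two synthetic
participants on a 13-point β grid. These sizes are stated here as the
package's reference configuration for its own checks.

## Known limitations

* The σ/Is inertial-shift values of the real exoskeleton are not published;
  with the all-zero default the model omits the device's direction-dependent
  inertia, which shifts absolute rtPV levels (the study's own simulations
  include it and are centred differently).
* Movement duration is fixed, not optimized (no cost of time); single joint
  only; no muscle dynamics or metabolic cost.
* rtPV on near-flat velocity plateaus is intrinsically ill-conditioned; the
  plateau-midpoint rule makes it well-defined but is a convention.
* The Pearson criterion on 11 points has low power; the AAE optimum is the
  more stable of the two identified weights under noise.
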