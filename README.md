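# smootheffort

Optimal-control analysis of single-joint elbow movements under
exoskeleton-induced gravity-like torques, for researchers in computational
motor control and human-robot interaction.

When an active exoskeleton applies a torque that scales the effect of
gravity on the forearm — from normal gravity (1g) through microgravity (0g)
to reversed gravity (−1g) — people reshape the time course of their
movements. The signature quantity is the **relative time to peak velocity
(rtPV)**: the time from movement onset to peak velocity divided by movement
duration (MD). rtPV below 50% of MD means a short acceleration phase
(right-skewed velocity profile), above 50% a long one. If the nervous
system exploits gravity as a motive force, rtPV should track the effective
gravity; if it merely compensates gravity, rtPV should not change.

## The model

The coupled human-exoskeleton forearm is a single rotational degree of
freedom,

    (I + σ·Is) θ̈ = τ_h − B θ̇ − m_h l g̃ cos θ,       g̃ = g(1 − α),

with apparent inertia I = 0.35 kg·m², damping B = 0.05 N·m·s/rad, weight
moment m_h l = 0.2934 kg·m, and compensation fraction α ∈ [0, 2] (α = 0 →
1g, α = 1 → 0g, α = 2 → −1g). σ·Is is an optional direction- and
phase-dependent inertia increment of the exoskeleton (off by default).

The **Smooth-Effort (SE) model** plans a rest-to-rest movement of fixed
duration T by minimizing, in a commanded-torque-change framework
(u_h = τ̇_h),

    J(u_h) = Ce + β Cs
    Ce = ∫₀ᵀ |τ_h θ̇| dt                      (absolute work — effort)
    Cs = ∫₀ᵀ (u_h − B θ̈ + m_h l g̃ θ̇ sin θ)² dt    (smoothness; = I²∫ jerk² dt
                                              along dynamics-consistent paths)

The absolute-work effort term is what lets the model reproduce muscle
*inactivation*: dropping below the gravity-holding activity level and
letting gravity accelerate the limb. The weight β is the single free
parameter; it is identified from data by inverse optimal control
(`RtpvInverseOC.fit()` sweeps β over [10⁻⁵, 1] and scores each weight by
the average absolute rtPV error, AAE, and a variability-guarded Pearson r).

The problem is transcribed by fixed-step Hermite–Simpson collocation on the
state (θ, θ̇, τ_h) and solved deterministically with SLSQP using analytic
gradients and Jacobians.

The package also implements the experimental processing pipeline
(zero-phase Butterworth filtering, differentiation, 5%-of-peak-velocity
segmentation, trial exclusion; EMG band-pass/rectification/normalization/
envelope and tonic-phasic decomposition) and a synthetic-experiment
generator that emulates the study designs trial-by-trial, so the whole
analysis loop is testable without any recordings.

## Worked example

Solve the optimal 45° upward elbow movement (MD = 0.6 s, β = 1.9×10⁻³) in
normal and reversed gravity:

```sh
$ smootheffort simulate -o traj_1g.csv
rtPV = 46.11 % of MD   (PV = 2.408 rad/s, Ce = 2.4773 J)

$ smootheffort simulate --label-g -1 -o traj_m1g.csv
rtPV = 54.18 % of MD   (PV = 2.399 rad/s, Ce = 2.3686 J)
```

At 1g the optimal profile is right-skewed (rtPV < 50%: brake late, let
gravity decelerate); with gravity reversed it is left-skewed (rtPV > 50%:
the upward-pushing torque accelerates the limb for free, the effortful
braking is deferred). Sweeping the full eleven-condition gradient
(`sweep_conditions` or `smootheffort sweep`) gives the model's sigmoid
rtPV curve:

```
+1.0g  rtPV = 46.11 % MD    +0.2g  rtPV = 45.96 % MD    -0.6g  rtPV = 54.94 % MD
+0.8g  rtPV = 45.54 % MD     0.0g  rtPV = 48.95 % MD    -0.8g  rtPV = 54.69 % MD
+0.6g  rtPV = 45.21 % MD    -0.2g  rtPV = 53.63 % MD    -1.0g  rtPV = 54.17 % MD
+0.4g  rtPV = 45.26 % MD    -0.4g  rtPV = 54.73 % MD
```

(below 50% down to +0.2g, above 50% from −0.4g, maximum at −0.6g). The
full synthesize → process → fit loop runs with
`smootheffort run-all --seed 1 -o report/`; fitting β to a measured
mean-rtPV table is `smootheffort fit-beta means.csv`, or in Python:

```python
from smootheffort import RtpvInverseOC
model = RtpvInverseOC.from_dataframe(means, direction="upward")
print(model.fit().summary())
```

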