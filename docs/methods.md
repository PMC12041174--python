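# Methods

## Model

The celiac/hepatic arterial circulation is reduced to a zero-dimensional
(lumped-parameter) resistive network. Vessel segments are rigid cylinders
with Hagen–Poiseuille resistance R = 8μL/(πr⁴); a stenosis occupying part
of a segment is a series resistance evaluated at the effective radius
r·√(1 − a), where a is the cross-sectional area reduction. This is a
deliberate fidelity reduction relative to a 3-D Navier–Stokes solve: no
secondary flows, jet/recovery losses, curvature or non-Newtonian rheology.
It is consistent with using constant (non-pulsatile) flows, under which the
two-parameter Windkessel outlets degenerate to pure peripheral resistances
draining to a common reference pressure.

Topology (Michels type I template): aorta → celiac trunk → {splenic outlet,
common hepatic}; the common hepatic bifurcates into the proper hepatic
(liver outlet) and the gastroduodenal artery, which connects to the SMA
junction through a single equivalent pancreaticoduodenal-arcade segment —
the arcade's anastomotic loops are collapsed into one segment, with outlet
resistances absorbing the simplification. A replaced right hepatic artery
(Michels VIII) adds a segment and outlet off the SMA junction; the
celiac-stenosis variant applies an area reduction over the full trunk.

Steady flows solve nodal (Kirchhoff) conservation with a fixed-pressure
inlet; the linear system is assembled as a conductance matrix and solved by
a dense direct method (LAPACK via numpy) — networks have ~10 nodes, there
is no iterative tolerance to tune, and solutions are bit-reproducible.
Clamping removes the segment from the system exactly, rather than using a
large penalty resistance: clamped flows are exact zeros and conditioning is
unaffected. Components disconnected by clamping that retain an outlet stay
determinate; fully isolated dead-end nodes are pinned to 0 mmHg (their
flows are zero regardless); a clamp set that disconnects the inlet from
every outlet raises `no_open_path`.

Sign convention: flow is positive in each segment's declared
proximal→distal orientation. The GDA is oriented bifurcation→arcade, so
collateral perfusion of the liver (celiac stenosis, CHA clamping) appears
as a negative GDA flow; reversal detection compares signs against baseline
with a 1 ml/min dead-band to suppress flapping at numerically tiny flows.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| inlet pressure | 100 | mmHg | standard mean aortic reference; flow distribution is invariant to proportional rescaling after calibration |
| blood viscosity μ | 0.0035 | Pa·s | standard whole-blood value; only flow ratios matter after calibration |
| outlet reference pressure | 0 | mmHg | venous pressure; only pressure differences matter, calibration absorbs the offset |
| calibration tolerance | 0.01 | fraction | the <1 % calibration criterion, far below the probes' 10–15 % margin |
| interval variability | 0.15 | fraction | the probe's stated worst-case variability; reproduces the 67 → (56.95, 77.05) ml/min anchor |
| HABR gain | 0 | fraction | physics-only prediction; the conservative minimum used for safety |
| reversal dead-band | 1 | ml/min | numerical noise floor |

Template geometry (radii 1.5–4 mm, lengths 20–60 mm per segment) is
invented but physiological; per-patient geometry is supplied or generated,
and calibration of outlet resistances absorbs geometric error. Default
outlet resistances put the uncalibrated template near typical flows
(PHA ≈ 270, GDA ≈ 40, splenic ≈ 300, SMA ≈ 500 ml/min at 100 mmHg).

## Calibration

Outlet resistances are tuned by a damped multiplicative fixed point: each
measured branch maps to the controlling outlet found by walking distally
from the branch segment (preferring the proper-hepatic continuation at
bifurcations, so a CHA probe controls the liver outlet and a GDA probe the
pancreaticoduodenal one), and each iteration rescales that outlet's
resistance by (Q_sim/Q_target)^0.5. For reversed-flow targets the exponent
is negated — raising the pancreatic outlet resistance *increases* the
magnitude of a reversed GDA, because it diverts more arcade flow up to the
liver. The loop iterates to a tenth of the acceptance tolerance (the
tolerance is the convergence criterion, and derived quantities such as
PHA = CHA − GDA should not inherit its full slack; the extra iterations
cost microseconds), up to 200 iterations, damping 0.5. Infeasible targets
(requiring a negative or ~zero outlet resistance under the fixed inlet
pressure) raise `infeasible_targets`.

Redundant probes: noisy baseline CHA, GDA and PHA measurements are mutually
inconsistent under conservation (CHA = GDA + PHA), so when all three are
present the pipeline calibrates to CHA and GDA and infers baseline PHA —
the same reconciliation the clinical validation tables use. Compliance is
unidentifiable under steady flow and never tuned; outlets without a
measured branch (splenic, SMA) keep their defaults. Those unmeasured
resistances are structurally unidentifiable from hepatic probes, which is
why parameter-recovery checks perturb only the measured-branch outlets;
mis-specifying the unmeasured ones shifts post-clamp PHA predictions by
well under 1 % because conduit resistances are small (see Limitations).

## Synthetic patients

The generator emulates the study conditions, not any one patient: baseline
targets CHA ~ U(140, 340) and GDA ~ U(15, 70) ml/min (the cohort's printed
ranges) with PHA = CHA − GDA; splenic ~ U(200, 400) and SMA ~ U(300, 600)
ml/min (typical resting splanchnic values; these branches were not measured
clinically); replaced-RHA flow ~ U(45, 90) ml/min around the single
reported case. Geometry jitters ±10 % in radius and ±15 % in length around
the template. Ground-truth outlet resistances are obtained by calibrating
to these targets at 10⁻⁷ tolerance; the stenosis variant then applies an
area reduction ~ U(0.80, 0.95) over the full celiac trunk to that normal
vascular bed, so the baseline GDA reversal is an emergent solve.

Probe noise is multiplicative Gaussian, mean 1, sd v/1.96 truncated at 3 sd
(so ~95 % of draws fall within the stated margin v; default v = 0.12,
inside the device's 10–15 % band). A hepatic-arterial-buffer-response gain
~ U(0.05, 0.35) boosts the truth network's liver-outlet conductance in
post-clamp scenarios only, so synthetic "real" post-clamp PHA flows
systematically exceed the physics-only prediction — encoding the observed
regularity that measured flows sit above the predicted minimum, and making
that safety property a testable statement rather than an assumption. All
randomness flows through one seeded generator per patient; cohorts derive
per-patient seeds from a master seed.

What passing tests on synthetic patients do **not** show: that real
patients' geometry or peripheral beds match the templates, that probe error
is Gaussian, or that the buffer response has the assumed magnitude — the
generator encodes directions and printed ranges, nothing finer.

## Numerical choices and problem sizes

Dense direct linear solves (no tolerances); calibration is derivative-free
and deterministic; interval construction is exact arithmetic; percent
rounding for table comparison is decimal half-up (integer for the GDA-clamp
table, one decimal for the CHA-clamp table, matching printed precision).
The pulsatile Windkessel demonstrator integrates C·dP/dt = Q(t) − (P−P_ref)/R
analytically per piecewise half-sine/diastole interval (exact up to float
rounding; cross-checked against a numerical ODE integration in tests).
Property suites use 200-patient cohorts, 50-patient noise-free recovery
runs, 20-point stenosis sweeps over 20 seeds, and exhaustive random trees
up to 8 segments for the series–parallel oracle; the full test suite runs
in well under a minute on one core.

## Known limitations

* Conduit (segment) resistances at template geometry are ~1–2 % of
  peripheral resistances, so post-GDA-clamp PHA increases are directionally
  correct but smaller than the 5–20 % seen clinically; the clinical
  increases fold in 3-D losses and the buffer response, both outside the
  physics-only network. The conservative-minimum logic does not depend on
  this magnitude.
* The embedded validation tables are carried verbatim; some printed error
  entries do not reproduce under their stated formulas (flagged per row and
  excluded from exact-reproduction checks; range membership is unaffected).
* One inlet, steady flow: no pulsatile network solution, no portal-vein or
  cirrhotic-liver modelling, no prediction of buffer-response magnitude.
* The expected-range construction in the validation tables is not exactly
  ±15 % of the prediction row-by-row; the package's symmetric-interval
  contract is the implementable rule and reproduces the fully worked
  replaced-RHA anchor exactly.
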