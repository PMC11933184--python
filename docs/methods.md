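# Methods

## The closed-loop 0D model

The circulation is a single closed loop in clinical units (mmHg, mL, s).
Left and right ventricles are time-varying elastance chambers,
p = E(t)(V − V₀), with an asymmetric raised-cosine activation that peaks at
65 % of systole: the slow decay keeps the ventricle ejecting through most of
systole, which a symmetric activation does not (it produced a nonphysically
short ~0.11 s ejection).  Peak elastance equals E_max independently of the
cardiac period T; diastole duration follows an affine law T_dia = a·T + b.
The coefficients of that law (a = 0.8, b = −0.17 s, giving a diastolic time
fraction of 0.59 at T = 0.8 s that rises with T) are placeholders standing
in for the published regression of systolic duration on cycle length, which
is cited in the literature but whose coefficients are not reproduced here;
both are ordinary config keys.

Valves: the mitral, tricuspid and pulmonary valves are pressure-gated
resistances, exactly closed for reverse pressure and C¹-smoothed over a
0.1 mmHg opening width so the right-hand side stays Lipschitz.  The aortic
valve is different: a diode in series with the valve resistance, the
systemic characteristic resistance and an aortic-root inertance
(L_av = 0.008 mmHg·s²/mL).  This branch is what shapes a physiological
ejection (peak aortic flow a few hundred mL/s over ~0.2 s); with a purely
resistive valve the stroke volume leaves in a 1000 mL/s spike.  Only the
positive part of the branch flow carries volume, so valve backflow is
identically zero.

The graft branch is: aortic node → conduit resistance + inertance →
compliant conduit node (C_graft = 0.004 mL/mmHg) → stenosis element →
three-layer intramyocardial bed.  The conduit lumps the graft and the
recipient epicardial artery stump (default R = 10 mmHg·s/mL, a tapered-tube
Poiseuille estimate).  The conduit compliance matters qualitatively: it
carries the systolic capacitive inflow seen by a flow probe, and without it
the D/S-ratio *rises* with stenosis severity (damping of systolic backflow
dominates), the opposite of clinical behaviour.

Each myocardial layer j (subepicardial, mid-wall, subendocardial; mid-depth
fractions 1/6, 1/2, 5/6) has an arterial compliance C1_j, a venous
compliance C2_j, and three volume-dependent resistances
R = R₀(V₀/V)² (inflow, middle, outflow).  Compliances are fixed (their
volume dependence is a second-order effect for these analyses).  Both
compliant compartments feel p_im = depth · p_lv.  Reference volumes are
split across layers by weights (1, (1+r)/2, r)/norm where r is the
subendo/subepi volume ratio, with the total conserved as r changes, and the
per-layer R₀ scale inversely with the layer's volume share.  The venous
reference volume is twice the arterial one.

### Stenosis element

The element implements the three-term empirical relation (viscous,
turbulent, inertial) with K_t = 1.52, K_u = 1.2 and the geometric K_v; the
turbulent term is written Q|Q| so the drop is odd in the flow — graft flow
can transiently reverse.  Geometry is evaluated in CGS and the result
converted to mmHg.  Defaults: D₀ = 0.167 cm (the conduit's distal diameter,
where the constriction sits), effective length l_s = 0.3 cm, vena-contracta
diameter D_s = D₀(1 − pct/100); all config keys.

Inside the network the stenosis branch is solved quasi-statically: the
momentum balance a·q + b·q|q| = Δp (with a including the bed's instantaneous
inlet resistance) has a closed-form root evaluated each step.  The branch's
inertial time constant is ~0.3 ms — far below any stable explicit step — and
made the ODE system stiff at high severity; the omitted inertial pressure
contribution is ≲0.2 mmHg.  The full three-term element, including dQ/dt,
remains available in the stenosis module.  A disabled element contributes
zero pressure drop, which differs from a 0 % stenosis by the viscous term.

### Integration and diagnostics

Fixed-step classical Runge–Kutta, dt = T/2000 by default (configurable),
compiled with numba.  The 20-state initial condition is placed near the
default operating point, with pressures mapped to volumes through each
run's own compliances so moderate parameter changes still start near the
limit cycle; defaults converge within 10 beats.  A run records, per adjacent
beat pair, the relative L2 difference of aortic pressure and graft flow
(convergence flag: last residual < 1e−3), and the peak relative drift of
total blood volume, which is conserved to machine precision by
construction.  Non-finite states or a collapsed intramyocardial volume
(V ≤ 0, outside the model's validity) abort with a simulation error.

### Default constants

Defaults reproduce a resting adult: aortic pressure 124/85 mmHg, cardiac
output 4.8 L/min at T = 0.8 s, graft flow ≈ 60 mL/min (a typical LAD
territory at rest) with endo/epi flow ratio ≈ 1.06 and D/S ≈ 4.7.  The
graft-territory flow level was chosen so the autoregulation experiment has a
physiological dilation reserve: at ~60 mL/min a 60 % stenosis is the
steepest severity whose pressure loss can still be compensated by
microvascular dilation, consistent with the classical ~68 % compensation
limit.  All 39 registry constants are overridable via flat YAML/JSON config.

## Patency metrics

Phase integrals use the trapezoid rule on the record's native grid with
interpolated phase boundaries; sampling gaps are rejected.  Delivered
volumes and the DRI phase means use |Q|.  Two segmentations exist: simulated
runs use the aortic-valve-open interval as systole; clinical-like records
use ECG-style markers (beat onset = R peak, plus a systole-end time), which
include the isovolumic phase in systole and therefore give somewhat lower
D/S values — as in clinical practice.  Across beats the median is reported
(robust to a stray beat), matching the median/IQR summaries used for
intraoperative data; per-beat values are retained.  DF% = 100·DS/(1+DS) and
DRI = (p̄_dia/p̄_sys)(T_dia/T_sys)/DS hold beat-by-beat to ~1e−14 and are
asserted in the tests.

## Morris screening

All 39 registry constants are screened.  Marginals: truncated normals at
mean ± 2 sd with sd = 25 % of the mean (the fallback convention where no
literature value is adopted), uniform for stenosis percentage ([0, 75] %)
and the subendo/subepi volume ratio; an all-uniform mode spans the same
ranges as a robustness check against distribution-entropy artifacts.
Trajectories use p = 4 levels and Δ = p/(2(p−1)); physical values come from
renormalized inverse CDFs, never clipping (clipping creates boundary atoms
that bias the effects).  Spread maximization is a greedy max–min selection
from an oversampled candidate pool (default 200) — an approximation to the
published efficient selection schemes with the same goal, exactly
reproducible from a seed.  Failed runs at extreme corners yield NaN
responses whose elementary effects are dropped pairwise and counted.  The
trajectory count can be grown in steps of 10 until the top-3 ranking by
√(μ*² + σ²) stabilizes.

## Polynomial chaos and Sobol indices

Nine inputs: stenosis percentage (uniform [0, 75] %) and ±1.96 sd truncated
normals for peripheral resistance, systemic arterial compliance and
characteristic resistance, a graft cross-section scale, graft inertance,
intramyocardial arterial compliance and reference volume, and cardiac
period.  The cross-section scale s maps physically: conduit resistance
∝ s⁻² and stenosis reference diameter ∝ √s.  (Four of these inputs are 0D
surrogates for distributed-vessel properties — cross-section and wave speed
of the systemic artery and graft — that have no direct lumped counterpart.)

The basis is total-degree orthonormal Legendre after mapping every input to
[−1, 1] over its bounds.  For the uniform input this is exact; for the
truncated normals uniform-weight orthogonality is an approximation —
least-squares fitting does not require weight orthogonality, and the
spectral Sobol indices are cross-checked by Monte-Carlo pick-freeze
estimation on the fitted surrogate (they agree to ~0.02 on analytic test
functions).  Truncated-normal polynomial families have no standard closed
form, which is why this route was chosen.  Sampling is by rejection;
coefficients by numpy least squares with a rank check; order selection by
seeded k-fold cross-validation (10 folds) over orders whose basis is
identifiable from the training folds, ties resolved toward the lower order.
Runs whose aortic pressure peaks during diastole of the last beat are
removed as artifacts of independent sampling before fitting; the filter is
idempotent and its removals are reported.  The stage aborts if fewer than
half the runs survive failures plus filtering.

With the default budget (n = 110 = 2 × C(11,2)) the stenosis percentage
carries the largest total Sobol index for D/S-ratio (~0.34–0.42 across
seeds) and DRI (~0.43–0.55), ahead of systemic compliance and peripheral
resistance.  For Q_mean the stenosis share (~0.41–0.45) also edges out
peripheral resistance (~0.25–0.40) and the graft cross-section scale
(~0.15–0.31) in this model: the conduit-plus-stenosis path is a larger
share of mean-flow variance here than in distributed multiscale models,
where the graft cross-section tends to dominate Q_mean.  This is a known
structural property of the lumped analogue, not a sampling artifact.

## Autoregulation experiment

Two multiplicative knobs emulate microvascular tone: an overall scale on
the three reference resistances, and a subendo/subepi tilt applied through
the reference volume ratio.  A damped fixed-point iteration
(s ← s·(Q/Q_ref)^0.5) adjusts both until beat-median graft flow and the
endo–epi flow ratio are within 1 % of the un-stenosed reference (the
two-knob scheme is the minimal mechanism matching the two targets; tuning
three per-layer resistances independently would be underdetermined by
them).  At 20/40/50/60 % severity the overall knob falls monotonically
(0.99, 0.89, 0.71, 0.30) — the dilation demand — and tuned runs hold Q_mean
within 1 %.  Tuned-vs-untuned D/S and DRI agree to 0.4 % at 20 % severity
but diverge up to ~11 % at 50 %: restoring full reference flow through the
stenosis raises its quadratic loss by (Q_ref/Q_untuned)², which reshapes the
waveform.  The robust qualitative statement, asserted in tests, is that
tuning always moves D/S and DRI *less* than the stenosis itself does:
diastolic-dominance metrics keep tracking severity under autoregulation
while Q_mean is fully masked.

## Synthetic cohort generator

The generator emulates the *structure* of intraoperative TTFM datasets:
per patient, a six-parameter physiology draw (T, peripheral resistance,
arterial compliance, LV elastance, intramyocardial compliance and volume)
from the registry distributions; per graft, a patency class
(patent < 50 %, questionable 50–74 %, failed ≥ 75 % true diameter
reduction — a configurable convention) and a severity uniform in the class
range; then a simulation, a radial-like pressure waveform (second-order
resonant low-pass, 8 Hz / ζ = 0.3, rescaled to a +10 mmHg peripheral
systolic amplification), ECG-style markers from the simulation's beat
boundaries and valve closures, additive Gaussian flow noise (sd 2 mL/min)
and marker jitter (sd 10 ms), all seeded.  Central pressure is re-estimated
from the peripheral waveform by an N-point moving average (window default
0.25·T; the published method's N is not reproduced here, so the fraction is
exposed as a parameter).

What the generator does **not** emulate: graft-type and target-vessel
variety (sequential/venous grafts, competitive flow), hemodynamic shifts
from anesthesia and heart manipulation, probe-coupling artifacts, or
beat-to-beat physiological variability within a record.  Passing cohort
tests therefore demonstrates that the analysis stage recovers structure the
simulator put in — class trends, variability ranks, significance of planted
differences — not that it would behave identically on real recordings.

Comparison statistics: median/IQR per class, MAD/median variability of
SAP/DAP/MAP/PP/T/DTF, monotone-trend direction of class medians, and
two-sided rank tests (rank-sum unpaired, signed-rank paired) with an exact
enumeration path used automatically at n ≤ 10 and a continuity-corrected
normal approximation otherwise.

## Problem sizes

The test suite simulates 10-beat runs (~2000 steps/beat) and uses reduced
designs: screening oracles on analytic functions, UQ self-consistency at
n = 25–110, autoregulation at two severities, 16-record cohorts.  The
acceptance script uses the full per-stage sizes the analyses are defined
at: the r = 50 screening design (2000 points, counted, not simulated),
n = 110 UQ simulations, all four autoregulation severities, and a
123-record cohort (41 patients × 3 grafts).

## Known limitations

* One intramyocardial territory, no competitive flow through a partially
  occluded native vessel, no atrial contraction, no baroreflex, no
  pericardial constraint; wave propagation and probe-position effects are
  outside a lumped model by construction.
* The stenosis element's validity ends at full occlusion; severities above
  ~90 % can collapse the bed volumes and abort.
* The quasi-static stenosis branch omits a ≲0.2 mmHg inertial term.
* Mean-flow sensitivity: see the Sobol note above — Q_mean's variance is
  stenosis-dominated in this lumped analogue.
* The Legendre basis is not weight-orthogonal for the truncated-normal
  inputs; Sobol indices inherit a small approximation, bounded by the
  pick-freeze cross-check.
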