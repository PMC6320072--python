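# Methods

## The energy-balance model

The organismal energy content E (joules of physiologically accessible
stores — triglycerides, glycogen, protein) obeys the balance

    dE/dt = J − P,

where J is the net influx of food energy and P the metabolic rate
(heat loss). Because planarians change size predominantly by changing
total cell number N, the balance is read per cell: j = J/N (non-zero
only while the animal is digesting a meal), p = P/N, e = E/N. The model
makes no assumptions about cellular mechanism; it closes once a control
paradigm specifies how e behaves:

* **Paradigm 1 — dynamic reserve.** e is an independent state; the
  relative cell-number change responds linearly to the reserve
  deviation, (1/N)dN/dt = k(e − e_set). The linear response is the
  simplest increasing law consistent with cell number following the
  per-cell energy status; it is isolated behind the model interface so
  other monotone responses can be swapped in. Two animals of equal size
  may hold different reserves, so rates depend on feeding history.
* **Paradigm 2 — isometric.** E = ε·N. Growth converts surplus influx
  into cells at fixed cost ε; degrowth catabolises cells. Rates are
  size-independent: (1/N)dN/dt = (j·[fed] − p)/ε.
* **Paradigm 3 — allometric.** E/N = e_ref·(N/N_ref)^c, i.e. E scales
  as N^(1+c). The marginal energy content of a cell is
  e_ref(1+c)(N/N_ref)^c, so (1/N)dN/dt = (j·[fed] − p) / (e_ref(1+c)
  (N/N_ref)^c): rates fall as N^−c, and during starvation N^c decays
  linearly in time.

The paradigms are distinguished by the scaling of per-cell observables
with N: paradigm 2 predicts exponent 0 for E/N, P/N and J/N; paradigm 3
predicts exponent c for E/N and 0 for the others; paradigm 1 predicts
no pure power law for E/N (history-dependent).

### Parameters and units

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| p | metabolic rate per cell | pW/cell | 1.0 | measured magnitude of P/N |
| j | influx per cell while digesting | pW/cell | 2.5 | gives net weekly growth at j·(3.5/7) = 1.25 p |
| c | reserve allometry exponent | — | 0.38 | measured E/N~N exponent |
| e_ref | reserve per cell at N_ref | J/cell | 3e−6 | implies a ≈2 %/day degrowth rate at N_ref under p = 1 pW (e = p̃/((1+c)·rate)); with 0.3 mg dry mass at N_ref the gross energy density is ≈20 kJ/g dry, typical animal tissue |
| N_ref | reference cell number | cells | 1e6 | decouples the prefactor from unit choices; conversion to the absolute form is e_ref·N_ref^−c·N^c |
| ε | reserve per cell (paradigm 2) | J/cell | 3e−6 | continuity with paradigm 3 at c = 0 |
| k | reserve sensitivity (paradigm 1) | 1/(day·J/cell) | 0.04/e_set | percent-per-day rates with a reserve relaxation time of weeks, so feeding history stays observable |
| e_set | reserve set point (paradigm 1) | J/cell | 100·p̃ | one hundred days of heat loss held in reserve |

Internally rates are converted once at the API boundary:
1 pW = 86400e−12 J/day (p̃ denotes p in J/day). Feeding is a boxcar:
a continuous influx j·N over a digestion window (default 3.5 days per
weekly feeding). A 1-day window with j = 2.5 pW would average less
influx than heat loss and starve a weekly-fed animal; the 3.5-day
window makes weekly feeding a net-growth regime (average influx
1.25 p), which is the observed behaviour the schedule emulates.

### Numerics

Integration is adaptive explicit Runge–Kutta (scipy `RK45`,
rtol 1e−8, atol scaled to the state magnitudes), restarted at every
feeding-interval edge so the discontinuous forcing never crosses a
step. Paradigms 2/3 integrate N only and evaluate E from the
constraint; paradigm 1 integrates (N, E) jointly. Every simulation
carries the cumulative net influx Q(t) = ∫(J − P)dt as an extra state,
so energy conservation |E(t) − E(0) − Q(t)| is checked directly at
integrator tolerance instead of by post-hoc quadrature across pulse
edges. Starvation below a floor of 10³ cells truncates the trajectory
with a flag rather than chasing the N → 0 singularity.

## Power-law fitting and the scaling algebra

All fits are straight lines in ln y versus ln x. The default estimator
is IRLS with a Tukey bisquare weight (tuning constant 4.685, 95%
Gaussian efficiency, MAD scale, at most 50 iterations, coefficient
tolerance 1e−8); ordinary least squares is available for comparison.
Standard errors come from the method's weighted parameter covariance
(for the robust fit, the standard asymptotic IRLS covariance — an
approximation, as no finite-sample robust covariance is exact).
Intercepts are always free; fits are never forced through a point. On
numerically exact power-law data the IRLS scale is zero and the OLS
solution (which is then also the robust solution) is returned.

Derived laws propagate uncertainty to first order, treating distinct
fits as independent (no cross-fit covariance is available when laws
come from separate experiments): compose multiplies exponents, invert
reciprocates them (se′ = se/b²), per-unit subtracts one from the
exponent with unchanged covariance. Monte-Carlo checks in the test
suite confirm the propagated SEs to within 5% at 10⁴ draws. Prefactors
are reported as ln a at x = 1 in input units; exponents are invariant
under unit rescaling.

## Rate extraction

Growth/degrowth traces are split into equal-length overlapping time
windows (50% overlap; 2 windows for growth traces, 3 for degrowth, both
configurable — the window count convention, not the window length, is
the declared default). Per window the rate is 100 × the slope of ln N
versus time (an exponential fit), attached to the geometric mean of the
window's endpoint sizes — the log-space midpoint, matching the log-log
fits downstream. Plan-area traces are converted through the
cell-number/area law N = a·A^b, under which an area rate is b times the
cell-number rate. Rates are computed on cell numbers because the
per-cell energy balance is formulated in N.

Each window also reports the standard error of its slope. When rate
points carry these SEs, the paradigm fits use inverse-variance weights
in ln|rate| space with the per-point noise scale se_i/r̂_i evaluated at
*predicted* rates from a preliminary equal-weight fit: window noise is
additive in rate space, so a window whose rate is statistically
indistinguishable from zero is an unbounded-leverage outlier in log
space and must carry the negligible weight its precision implies, while
weighting by the observed rate would overweight upward noise and bias
the slope. All three paradigms share the same weights, so their RSS
values remain comparable; without SEs all points weigh equally (the
correct special case for constant multiplicative rate noise). AIC
(n·ln(RSS/n) + 2k) is reported alongside the RSS ranking as a
convenience.

Feeding-history dependence of degrowth rates is tested by removing the
fitted size law from ln|rate| and comparing residual means between
history groups with a seeded label-permutation null (≥1000 shuffles) —
chosen because the question is a qualitative group contrast with no
distributional commitments.

Paradigm-specific fitting notes: the allometric fit shares one c
between growth and degrowth with separate amplitudes (per-regime c is
available as an option); the growth amplitude identifies the
*time-averaged* influx under the feeding schedule (j·duty cycle − p),
not the instantaneous j. The dynamic-reserve fit integrates the scalar
per-cell reserve ODE de/dt = −p̃ − e·k(e − e_set) on a dense RK4 grid
and predicts degrowth rates as a function of starvation history alone
(the reserve ODE contains no N) — precisely the property that separates
it from size-dependent control; its parameters (k, e_set, e0) are found
by Levenberg–Marquardt from two starts, falling back to the
history-free constant predictor if both fail. On history-free data the
dynamic-reserve fit legitimately collapses onto the constant (isometric)
solution, so their RSS values coincide there.

## Physiological energy prediction

Under the allometric paradigm, starvation gives (1/N)dN/dt =
−p̃/(e(1+c)), so the reserve per cell follows from the degrowth-rate
law alone: e(N) = p̃/((1+c)·|rate(N)|), with p taken from the P/N fit
(or 1 pW by default). The ratio of the measured gross-energy law (bomb
calorimetry) to this prediction is summarised as a geometric mean with
its range over a log-spaced grid across the overlapping size range;
near-constancy of the range is the check that the two laws differ only
by a factor — the assimilation (gross/physiological) factor of about
two.

## Assays and composition budget

Cell counts: N = cells_loaded/volume_loaded × lysate_volume (histone-H3
standard curve) and N = cells/beads × total_beads (volume-tracer
imaging). Food intake: total red beads per animal over red beads per µl
liver, normalised by the yellow-green drop-volume ratio; energy at
6.15 J/µl liver (overridable). Q10 normalisation: P′ = P·Q10^(ΔT/10),
Q10 = 2.

The composition budget normalises per-animal component masses to
pg/cell through the length→area and N/A laws (the length–area law is a
config input, default A = 0.15·L^1.8, as its calibration lives outside
the main tables); the independently measured total dry mass minus the
component sum is the residual, flagged when below −10% of the total.
Fold changes are computed on replicate means; the per-component share
of the dry-mass-per-cell increase between the smallest and largest
class sums to one once the residual is included. ANOVA-style
significance testing is out of scope; bootstrap dispersion can be
obtained from the replicate SEMs the budget retains.

## The synthetic generator

The generator emulates the study conditions: ≥3 decades of cell number
(2e4–2e7), lognormal multiplicative noise on sizes/masses/energies
(CV 0.10 — positive and scale-free, the natural error model for
log-log fits), Poisson noise on counts, paradigm-3 dynamics with
c = 0.38, p = 1 pW, j = 2.5 pW as the default truth. Cohort vials hold
2–130 size-matched animals (inversely scaled with size, as in
size-matched calorimetry); bomb cohorts carry gross energy at twice the
physiological reserve; the composition truth anchors an 88-fold TG and
8.8-fold glycogen contrast between the 4 mm and 16 mm classes with an
8% unmeasured residual. One master seed feeds fixed per-table
substreams, so every table is independently reproducible and a seed
change alters noise realisations only.

Directly generated scaling datasets put noise on the response only
(x is the design variable); the measured *tables* (animals, cohorts,
bomb) carry noise on every measured column, which introduces a
negligible (≈0.4% over three decades) errors-in-variables attenuation
in chain-derived exponents. Trace rates are not given an explicit CV:
they inherit ≈25% effective noise from the 10% area measurement error
through the window regressions. What the generator does **not**
emulate: body-posture and segmentation artefacts in size extraction,
inter-animal physiological heterogeneity beyond size, within-vial
covariance of calorimetry noise, systematic (non-Poisson) bead
clumping, or any cell-type structure. Passing tests therefore
demonstrate correctness of the inference machinery under the stated
noise model, not robustness to every failure mode of the real assays.

## Problem sizes and defaults in the test suite

The suite runs the paradigm-discrimination experiment at 100 traces ×
20 seeds, cohort recovery at 80 vials, Monte-Carlo error-propagation
checks at 10⁴ draws, and the permutation test at 1000 shuffles — sizes
at which every recovery tolerance is met with comfortable statistical
margin while the whole suite stays fast. The coverage check of the
fitted standard errors uses 40 seeds against a 3-binomial-SD band
around the nominal 95%, because an exact small-count threshold on 20
seeds would fail a quarter of the time even for perfectly calibrated
intervals.

## Known limitations

* The robust bisquare fit of trace-derived |rate| laws is mildly biased
  toward flatter exponents (≈0.03–0.04) because additive rate noise is
  left-skewed in log space; the weighted shared-c paradigm fit does not
  share this bias and is the estimator used for c.
* First-order error propagation understates uncertainty for strongly
  nonlinear derivations (e.g. inverting exponents near zero).
* Paradigm-1 inference is only as identifiable as the history structure
  of the data; with a single feeding history its parameters are
  degenerate (the fit then reports its constant-rate limit).
* The dry-mass composition budget treats replicates as independent;
  pooled-cohort correlations are not modelled.
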