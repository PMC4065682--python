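# Methods

This note documents the models, defaults and numerical choices behind
`pkdiss`, and what the synthetic-data validation does and does not
demonstrate.

## Dissolution factors

The difference factor is implemented on the percent scale,
f1 = 100·Σ|R−T|/ΣR.  (The factor is sometimes written without the
×100; the percent convention is the regulatory one and matches the
magnitudes practitioners report, e.g. f1 ≈ 13 % for a visibly slower
brand.)  The similarity factor f2 uses the mean squared pointwise
difference; identical curves give exactly 100 and a uniform 10-point
gap gives 49.89, which is why f2 ≥ 50 operationalizes "average
difference below 10 %".

Truncation of profile points after both curves pass 85 % dissolved
(retaining at most one such point) is exposed as an option,
`truncate_after_85`, and is **off by default**: the plateau carries no
discriminating information, but whether to drop it is a protocol
choice, not a property of the statistic.  Mismatched time grids are an
error everywhere except `classify_release`, which explicitly
interpolates (linearly, with a (0, 0) anchor when the first sample is
after t = 0) to evaluate the 15- and 30-minute thresholds.

## Noncompartmental analysis

* **Trapezoid rule.**  Linear everywhere by default; the
  lin-up/log-down variant is available (`method="linlog"`) and is
  exact for exponential decay segments.  AUMC always uses the linear
  rule.  On sparse late sampling (4–8–12–24 hr) the linear rule
  overestimates a convex tail by a few percent; this is inherent to
  the estimator, not a bug, and is why compartmental Cl/F is preferred
  when the model is trusted.
* **Censoring.**  Below-LOQ samples are dropped, never zeroed; an
  explicit pre-dose (0, 0) sample is retained.  Adding such an anchor
  changes AUC only by the initial wedge and never changes λz.
* **λz window.**  Among suffixes (≥ 3 points) of the positive samples
  strictly after Cmax, the window with the highest adjusted R² wins;
  windows within 1e-4 of the best resolve to the longer one.  A
  nonpositive slope makes λz non-estimable: the result is flagged and
  all extrapolated quantities (AUC∞, Cl/F, Vz/F, Css) are NaN.
* **Two half-life conventions.**  The terminal-slope t½ = ln 2/λz and
  the moment-based pair Kel = 1/MRT, t½ = 0.693·MRT answer different
  questions and disagree for multi-compartment drugs; both are
  reported, clearly labelled, never mixed.  Css uses a fixed 24-hr
  dosing interval by default.
* **Ties.**  Cmax ties resolve to the earliest time.

## Compartmental model

Disposition eigenvalues are the roots of
s² − (k10+k12+k21)s + k10·k21 = 0 (α > β).  The oral curve is the
three-exponential form with first-order absorption ka; C(0) = 0 is
enforced exactly.  ka equal to α or β (relative tolerance 1e-8) is a
degenerate parameterization and raises an error.

Fitting is nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on log-transformed parameters, which enforces
positivity without constraints; the iv variant parameterizes
(A, B, β, α−β) so α > β by construction.  Convergence uses a relative
SSE tolerance of 1e-10 with an evaluation cap of 500 per parameter
(+1); non-convergence is flagged and the stripping initialization is
retained.  Weighting is uniform by default, with 1/C and 1/C² exposed;
for data with proportional residual error the 1/C² scheme is the
statistically matched choice and measurably sharpens parameter
recovery, but uniform is kept as the default to mirror common
practice when the error model is unknown.

**Curve stripping** supplies starting values: the terminal window
(chosen by strict-best adjusted R²; a longer-window tie rule is
deliberately *not* used here, because a window reaching into the fast
phase biases β and poisons the residuals) gives (B, β); positive
residuals of the earlier post-peak points give (A, α).  If fewer than
two positive residuals remain — monoexponential-looking data — a
flagged fallback (A = 0.1 B, α = 5β) is returned.  ka is initialized
from the observed Tmax and V1 from Dose/(A+B).

**Micro↔macro identities**: k21 = (Aβ + Bα)/(A+B), k10 = αβ/k21,
k12 = α+β−k21−k10.  For any A, B ≥ 0 the implied k12 is nonnegative;
values below −1e-8·(α+β) (possible only through numerical abuse of
the inputs) raise an inconsistency error.  The forward/backward round
trip is the identity to better than 1e-9 over the tested parameter
ranges (rates 0.02–5 /hr).

**Model selection** ranks variants by
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) with k = the number of
structural parameters (the PK-software convention; adding the error
variance to k would only shift every candidate by the same +1 pattern
at fixed n).  Equal-SSE ties therefore resolve to the simpler model.

### Identifiability caveat

On the 10-sample single-dose grid with ~5 % proportional noise, the
two-compartment oral model's extra phase is only weakly identifiable
when ka and α are of similar magnitude (here 3.5 and 2.2 /hr): the
one-compartment Bateman curve tracks the truth to within roughly the
noise floor, and AICc — whose complexity gap between k = 5 and k = 3
at n = 10 is 15 log-likelihood units — usually prefers it.  Selection
reliably recovers the two-compartment truth only at residual CVs
around 1–2 % or with richer sampling.  Parameter *recovery* (β, Cl/F)
is unaffected: fitting the correct model recovers β to a median few
percent at 5 % noise.  This is a statement about information in the
design, not about the optimizer; multi-start refits do not change it.

## Synthetic-data generator

The generator emulates a six-brand, six-subjects-per-brand single-dose
oral study in rabbits with sampling at 0, 0.25, 0.5, 1, 1.5, 2, 4, 8,
12 and 24 hr and LOQ 0.05 mg/L.  The preset truth is anchored to the
reference brand's reported disposition: k21 = 1.35 /hr, k12 = 0.77
/hr, k10 = 0.263 /hr (so α = 2.22 /hr, β = 0.160 /hr), V1/F = 30.41 L,
Cl/F = 8.0 L/hr, dose 500 mg.  The absorption rate is not recoverable
from published summaries; ka = 3.5 /hr was fixed so that the model
peak (Tmax 0.59 hr, Cmax 10.5 mg/L) lands inside the observed ranges
(Tmax 0.54–0.99 hr, Cmax 9.6–10.9 mg/L).  The dose is 500 mg per
tablet-strength accounting (printed clearance × AUC arithmetic is
consistent with 500 mg).

Between-subject variability is log-normal and median-preserving on ka,
V1/F and k10 only (k12, k21 fixed), default CV 3 % — matching the
few-percent spread of the published brand summaries; residual error is
proportional with default CV 5 % (assay-scale noise).  Censored values
are stored as explicit flags with an uninformative 0 value; the
pre-dose sample is an exact, uncensored zero.  Dissolution curves are
Weibull, f(t) = f_max(1 − exp(−(t/td)^b)), with brand parameters
chosen so B, C, E track the reference while A and D are slower and
fail the f2 ≥ 50 criterion, mirroring the published verdict pattern.
One simulated brand (D) sits just below the cutoff (f2 ≈ 48), so its
verdict is seed-sensitive by design.

What passing recovery tests shows: the estimators are implemented
correctly and are unbiased at the study's design points.  What it does
not show: robustness to model misspecification (real absorption is
rarely first-order), to assay error structures other than
proportional Gaussian, to dropout/missing samples, or to
between-subject variability in distribution rates — none of which the
generator produces.

## Statistics

ANOVA is the standard between/within decomposition
(`scipy.stats.f_oneway` underneath), with the degenerate
zero-within-variance case handled explicitly (F = ∞, p = 0 when means
differ; F = 0, p = 1 otherwise).  Tukey's A test computes
q = |Δmean|/SE with the Tukey–Kramer SE and refers it to the
studentized range with (k, N−k) parameters; significance is decided
against the cached critical quantile, and exact p-values can be
skipped in simulation loops (`compute_p=False`) because the
distribution's tail integral is expensive.  At equal n this is the
classical equal-n Tukey A formulation.

Relative bioavailability is reported under two conventions: ratio of
brand-mean AUCs (default) and the mean of index-paired individual
ratios.  The brands use different animals, so the pairing is by
subject index and the second convention is order-dependent; it is
provided because summary-table Fr values in the literature often match
neither convention exactly and showing both brackets the ambiguity.
The interchangeability flag uses the Fr ≥ 90 % working criterion, not
a formal 90 % confidence-interval average-bioequivalence test (out of
scope).

## Problem sizes

The validation suite uses 20 subjects for parameter recovery, 1000
random parameter sets for the round-trip identity, and 200 replicate
six-brand studies (7 200 NCA runs) for the null calibration of the
Tukey screen — sizes at which the binomial/simulation error bands in
the assertions are meaningful.
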