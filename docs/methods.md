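# Methods

## Signal model and units

All fitting assumes mono-exponential gradient-echo decay,
`S(TE) = S0·exp(−TE/T2*) (+ C)`, with TE and T2\* in milliseconds. R2\* is
reported in s⁻¹ with the fixed convention `R2* = 1000 / T2*[ms]`, asserted
on every fit result. Higher R2\* means more local iron (USPIO).

The default echo scheme is 8 echoes evenly spaced from 2.1 to 17.1 ms
(step 15/7 ms). The scheme's printed endpoints and count are fixed; the
even spacing is this package's choice, overridable per call or per config.
These cardiac echo times are deliberately kept even for the abdominal
organs, which reproduces the known failure modes at the extremes: long-T2\*
tissues (baseline blood) barely decay across the sampled window, and very
short-T2\* tissues (post-contrast spleen/bone at 3 T) decay to the noise
floor within two or three echoes.

## Phantom and cohort generator

`phantom` rasterizes a single mid-ventricular short-axis-like slice
(default 96×96): an LV blood-pool disk inside a myocardial annulus, with
elliptical liver, spleen, kidney, skeletal-muscle and bone-marrow regions
on a zero background. Masks are validated pairwise disjoint at
construction. Proton density S0 defaults to 1000 a.u. for every tissue;
relative proton-density differences are not modeled because only decay
rates are analyzed.

Noise is Rician by construction — the magnitude of the clean signal plus
two independent Gaussian channels of standard deviation `noise_sigma` —
so pure-noise pixels have the Rayleigh mean `σ·√(π/2)` and magnitude data
never go negative. The acquisition noise level of real scanners is not
modeled from physics; pipeline-level analyses parameterize it as
first-echo SNR in baseline myocardium (default 50, i.e.
`σ = S(TE₁)/50`), a mid-range value for breath-held cardiac T2\* imaging.

The blooming artifact is modeled phenomenologically as extra exponential
attenuation `exp(−TE·severity/1000)` applied inside a region from a
1-based onset echo (default 4) onward — the simplest mechanism that
reproduces the clinical signature of late echoes sagging below the decay
trajectory while early echoes stay intact. It is not a susceptibility
field simulation.

Cohorts are sampled from the per-tissue normal-value tables
(`tissues.NORMAL_VALUES`): baseline R2\* is truncated-normal (>0), the
myocardial change and BMI come from a bivariate normal with correlation
0.72 (the observed BMI–ΔR2\* association), other tissues draw independent
normal changes, and post = pre + change per subject. The printed
post-contrast SDs are *emergent* under this pairing, not enforced: the
published pre/change/post SD triplets are mutually inconsistent for some
tissues under any pairing correlation (e.g. 1.5 T myocardium:
√(5.4²+7.3²) ≈ 9.1 vs a printed post SD of 7.2), so the generator follows
the pre + change construction and lets the post spread fall where it
falls. Subjects whose sampled change would make post ≤ 0 have the change
redrawn; tissues where that event has probability > 1 % (3 T bone) warn.
BMI draws are floored at 12 kg/m² as a physiological guard. Default BMI
mean 24.5 / SD 3.5 kg/m² sits between the two study groups' medians.

What the generator does *not* emulate: partial-volume and motion effects,
spatial noise correlation, B0/B1 inhomogeneity, multi-exponential or
fat-water behavior, and through-plane geometry (one slice only). Passing
tests therefore demonstrate correctness of the estimation chain under the
stated model, not robustness to everything real data can do.

## Decay fitting

`fit_loglinear` is the workhorse: OLS of ln S on TE over the usable
echoes (non-positive signals auto-dropped), slope −1/T2\*. `fit_nls`
minimizes signal-space least squares (scipy `least_squares`, bounds
S0, R2\*, C ≥ 0), initialized from the log-linear fit; the offset model C
absorbs a constant noise floor and requires one more echo than the
minimum. `fit_truncation` drops echoes below
`floor_multiple·σ·√(π/2)` (default multiple 2.0) before the log-linear
fit — the standard remedy for short T2\*.

r² is always computed in signal space (1 − SSres/SStot of predicted vs
observed SI over used echoes), including for the log-linear route, so the
0.85 quality gate means the same thing for every method. Whether the
clinical tools this emulates gate in log or signal space is not
documented anywhere authoritative; signal space is the exposed default.

`min_echoes = 4` is the validity floor: 2–4-point fits are exactly the
regime flagged as unreliable in practice. Degenerate inputs (constant
signal, too few echoes, non-decaying slope, non-convergence) return
`valid=False` fits with a reason code rather than raising, so per-pixel
mapping never aborts.

`compute_map` uses a closed-form vectorized log-linear path (identical to
the scalar fit, asserted in tests) so whole-cohort simulations stay
desk-scale; the nls/offset/truncation methods map per pixel in a Python
loop and are intended for ROI-sized work. Background pixels are excluded
by a first-echo signal floor: 3σ when the noise level is known, else 1 %
of the image maximum.

## Artifact detection

`detect_artifact_echoes` fits the first `m_init = 3` echoes (the minimal
clean leading window when corruption starts at echo 4), predicts the
remaining echoes, and flags each later echo independently whose
log-signal residual exceeds `k_sigma = 3` times its noise scale. The
scale multiplies the leverage factor `√(1 + 1/m + (TE−T̄E)²/Sxx)` of the
initial-window regression and is floored by the propagated background
noise `σ/Ŝ(TE)` and a machine-epsilon guard: without the leverage term,
the growing extrapolation uncertainty of a 3-point fit would be
misread as artifact on clean noisy data (false-flag rates of tens of
percent at the last echo); with it, the false-flag rate stays below the
Gaussian 3σ tail (≈0.3 %/echo, ≤2 % required) while a blooming of
150 s⁻¹ from echo 4 shifts the log signal by 1.3–2.6 — far outside the
band — and is detected essentially always at SNR 20.

Refitting after exclusion keeps the `min_echoes = 4` floor by default;
the caller must opt in (`allow_relaxed=True`) to a 3-echo refit, because
fewer fitting points genuinely reduce sampling accuracy even when they
remove artifact. `weighted_fit` offers the softer alternative: geometric
late-echo down-weighting, or one reweighting pass
`w = 1/(1+(z/k)²)` from the detection residuals.

The detector needs at least one echo after the initial window
(length ≥ m_init + 1); a 4-echo series with m_init = 3 is the boundary
case and the report records how many echoes were testable. Detection is
strictly per decay curve; no spatial neighborhood information is used.

## ROI analysis

ROI R2\* is `1000 / mean(pixel T2*)` over quality-gated pixels — the
inverse-of-mean-T2\* reporting convention — with the pixelwise-mean R2\*
carried alongside because the two differ under noise (Jensen's
inequality). AHA segmentation assigns annulus pixels by polar angle
about the LV centre, counterclockwise from the anterior RV insertion
with anterior up, 6×60° sectors at basal (ids 1–6) and mid (7–12) levels
and 4×90° apically (13–16); segment 17 (apex) is not used. Sectors
exactly partition the input mask. Because the phantom is a single
mid-ventricular slice, the in-pipeline "panmyocardial" value averages
segments 7–12; `panmyocardial_average` itself accepts all 16 and
excludes invalid segments with a warning (unreliable beyond 4).
Pre/post ROIs are assumed co-registered (the phantom guarantees it);
registration of user-drawn ROIs is out of scope.

## Cohort statistics

The paired pre/post comparison is a two-level repeated-measures one-way
ANOVA computed directly from its sums of squares; with two timepoints
F(1, n−1) is identically the squared paired t statistic, which the tests
assert to 10⁻¹⁰. Zero within-subject variance returns a capped F with a
flag. Field-strength contrasts use Welch's unequal-variance t-test — a
robustness choice, not a claim about what the original analysis used.
The BMI association is a plain Pearson correlation of BMI with
myocardial ΔR2\*. p-values are reported raw per tissue (a Holm option
exists behind a flag, off by default). Summary cells report mean ± SD
(n−1); a subject whose ROI value is missing — every pixel gated out, the
short-T2\* regime — is skipped by the means and the paired test, with
`n_complete` reported beside `n`.

## Problem sizes and determinism

Every stochastic routine takes one explicit integer seed; identical
seeds give bit-identical phantoms, cohorts and CSV outputs (summary rows
are sorted by subject id before aggregation so record order cannot
perturb floating-point sums). The replicate analyses use 200 cohorts of
n = 9 (1.5 T) and n = 10 (3 T) subjects on 96×96 phantoms at first-echo
SNR 50 — enough that the standard error of the replicate-mean myocardial
ΔR2\* is ≈0.17 s⁻¹ — and complete in under a minute on one CPU thanks to
the vectorized mapping path. The full-matrix acquisition geometry
(256×115, 2.6×1.6 mm) is available as an optional preset but is not the
default.

## Known limitations

- The 0–60 ms colourmap and all defaults target cardiac work; organ-
  specific echo times are advised in practice and supported via config.
- High post-contrast rates (spleen/bone at 3 T) are systematically
  underestimated under noise because only 1–3 echoes carry signal — the
  documented short-T2\* regime; `fit_truncation` mitigates but cannot
  remove this. The cohort summary consequently reproduces myocardial and
  moderate-rate tissues faithfully while compressing the extreme ones.
- The artifact detector's window, threshold and weighting rules are
  reasonable defaults for the simulated artifact, not validated clinical
  settings.
- No multi-exponential models, phase data, k-space/Bloch simulation, LGE
  or functional (cine) analysis.
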