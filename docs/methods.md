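# Methods

## The eye model and the four formulae

All four formulae are implemented as the composition of (i) a
formula-specific *effective lens position* (ELP) model mapping the tunable
constant and the eye's biometry to a fictitious thin-IOL depth `d` (mm)
behind the corneal apex, and (ii) a shared thin-lens vergence chain through
a reduced eye with aqueous/vitreous index `n = 1.336`. For corneal power
`K` (D), optical axial length `L` (mm) and implanted power `P` (D), the
corneal-plane refraction `R` solves

```
n/(L − d) − P = n / ( n/(K + R) − d )        (lengths in m; 1336 in mm units)
```

and is converted to the spectacle plane over a fixed 12 mm vertex distance
(`Rx = R / (1 + 0.012·R)`). Inverting the same chain in closed form gives
the IOL power for a target refraction, so prediction and power calculation
are mutually inverse to machine precision — the test suite asserts 1e-6 D
over random eyes, and observes ~1e-12 D.

Per-formula pieces, transcribed from the original publications with their
published corrections and guards:

| formula | constant | ELP model | chain inputs |
|---|---|---|---|
| SRK/T | A-constant | corneal height (with the quadratic long-eye AL correction and the clamp of the corneal-height square root at zero) plus `0.62467·A − 68.747 − 3.336` | radius-based corneal power with index 1.333; `L = AL + (0.65696 − 0.02029·AL)` |
| Hoffer Q | pACD | tangent-based model with AL clamped to [18.5, 31] and the published short/long-eye branch (`M`, `G`) | `K` from the Javal index; IOL plane at `ELP + 0.05` mm; `L = AL` |
| Holladay 1 | SF | anatomical ACD from the corneal-width/radius geometry (`AG = 12.5·AL/23.45` capped at 13.5 mm, radius floored at 7 mm) plus the surgeon factor | radius-based corneal power with index 4/3; `L = AL + 0.2` |
| Haigis (simplified) | a0 | `a0 + 0.4·ACD + 0.1·AL` (a1/a2 preset, not fitted) | `K = 331.5/r` (index 1.3315); `L = AL` |

The implementation was verified against an independently coded second
transcription of each formula's expanded closed-form refraction equation
(kept in the test suite as an oracle); agreement is at the 1e-15 level, so
the vergence-chain formulation is exactly the published algebra.

Domain guards follow each publication (SRK/T corneal-height square root,
Holladay radius floor, Hoffer Q AL clamps); clamping events are logged,
never silent. Record-level plausibility ranges (AL ∈ (15, 40) mm etc.) are
package policy for screening gross data errors, applied at CSV ingest with
row-indexed diagnostics.

### Keratometry

Corneal radii enter as the harmonic mean `R12 = 2·r1·r2/(r1+r2)` of the
flat/steep meridians, which preserves the arithmetic mean of the meridional
powers. Keratometric power uses the Javal index 1.3375 (`K = 337.5/R12`)
for reporting and for the SRK/T, Hoffer Q and Holladay 1 formulae; Haigis
uses its own 1.3315. When a tuned index `nK` is supplied (strategy (e)), it
replaces the conversion index uniformly: formulae that consume a radius
receive the Javal-equivalent radius `337.5·R12·… /(…)` rescaled so that
corneal power scales by `(nK − 1)/0.3375`, reproducing native behaviour
exactly at the native index. This models nK tuning as a multiplicative
corneal-power correction, versus RO's additive refraction correction.

## Prediction-error metrics

`PE = achieved − predicted` SEQ (spectacle plane, D). Under this sign a
positive RO added to the prediction lowers every PE by RO, so the offset
zeroing the mean equals the mean error at RO = 0; this is also the
convention under which the minimal-SD strategy's residual mean error equals
the joint fit's offset — a cross-identity the suite asserts. MPE is the
mean, SDPE the sample SD (n−1; the optimizers are invariant to the
denominator choice since it is a monotone scaling), RMSPE the root mean
square, and the |PE| summaries (median, quartiles, 2.5 %/97.5 % quantiles)
are computed with linear interpolation between order statistics (the
"type 7" rule — the estimator behind the reported quantiles is a documented
package choice). SDPE of a single-eye vector is NaN, not zero. The
decomposition `RMSPE² = MPE² + SDPE²·(n−1)/n` is enforced to 1e-12 in
tests.

## Optimization

The objectives are smooth scalar functions of one or two parameters, so
general constrained solvers are unnecessary: zeroing MPE uses bracketed
Brent root finding (with a short secant polish to drive the residual below
the 1e-12 function tolerance), and the minimizations use bounded Brent with
step tolerance 1e-10. Search bounds are the per-formula plausibility
ranges (A ∈ [110, 125], pACD ∈ [2, 9], SF ∈ [−2, 5], a0 ∈ [−3, 5]); nK is
bounded to (1.30, 1.38) and flagged if it lands at a bound.

*Joint FC/RO (d).* Since RO is purely additive, the RMSPE at the
inner-optimal RO equals the population SD of the PE at RO = 0, a fixed
positive multiple of the sample SD. The joint problem therefore reduces to
the same 1-D SD minimization as strategy (b), followed by RO = mean error —
which is precisely the two-step procedure (f) in exact mode. The
implementation shares this search path deliberately, so (b)'s fitted
constant, (d)'s and (f)'s coincide and the equivalences hold to the float;
a naive 2-D Nelder–Mead search is retained behind `joint_mode="direct2d"`
and agrees to 1e-6 in tests.

*Joint FC/nK (e).* Nested bounded searches (outer over nK, inner over FC).
The RMSPE surface has a strongly coupled valley — the conditional FC
optimum moves by roughly 0.8 pACD units per 0.01 of nK for Hoffer Q — so
FC and nK are individually less well determined than their combination;
the grid-oracle test asserts parameter agreement at conditioning-appropriate
widths and objective agreement tightly.

*Two-step modes.* `exact` (default) solves step 1 to tolerance.
`single_update` emulates a one-iteration clinical update: one damped Newton
step on the central-difference derivative of SDPE (step 1e-4) from the
start value, clipped to a tenth of the search interval and rejected if it
would increase the SD. Start values default to typical nominal constants
(A 119.0, pACD 5.6, SF 1.8, a0 1.3); the exact-mode results do not depend
on them (bounded searches), which the equivalence tests confirm.

Numerical floor: bounded Brent localizes a minimum only to about
`sqrt(eps)·|x|` (≈ 2e-6 for an A-constant of magnitude 119), which bounds
the attainable constant precision in the SD/RMSPE strategies; this is far
below the ~1e-3 level at which constants are clinically meaningful and
below every tolerance asserted in the tests. Cohorts smaller than 10 eyes
are refused unless explicitly allowed; an SDPE flat to the function
tolerance across the constant bounds is reported as non-identifying rather
than returning an arbitrary constant.

## Synthetic cohorts

The generator emulates the *marginal* structure of four published clinical
datasets (886/613/821/467 eyes, four monofocal IOL models): per-dataset
means and SDs of AL, ACD, LT and R12 are packaged as presets. Sampling is
a correlated Gaussian truncated by rejection to the plausibility ranges.
The joint dependence of the real cohorts is not published, so the default
correlations (AL–ACD 0.45, AL–R12 0.35, ACD–LT −0.35, others 0) are package
policy from the general biometry literature and are recorded with each
generated cohort; truncation slightly shrinks the tails relative to the
real quantiles, so distributional checks are confined to means.

Outcomes are constructed forward through the package's own formula engine:
R12 is split into flat/steep radii by a half-normal corneal cylinder
(SD 0.75 D) that preserves the harmonic mean; a target refraction is drawn
from a two-point mixture (85 % at −0.25 D, 15 % at −2.0 D, reflecting the
predominance of near-emmetropic targets with a monovision/myopic minority);
the implanted power is the truth-formula power for that target rounded to
the 0.5 D labelling grid; the achieved SEQ is the truth-formula prediction
for the implanted power plus `Normal(0, noise_sd)` refraction noise
(Student-t noise available behind a flag). Defaults: SRK/T truth at each
dataset's nominal A-constant, RO truth 0, `noise_sd = 0.42` D — chosen
once so that the SD of the prediction error at the true constants matches
the 0.38–0.49 D range reported for real cohorts of this kind. Generation
is deterministic per seed, and the ground truth is persisted as a sidecar
JSON.

What passing tests on these cohorts do and do not show: they validate the
optimizers (parameter recovery, the (b)/(d)/(f) identities, grid-oracle
agreement) and the analytic structure of the strategy comparison; they do
not validate formula performance on real eyes, because a synthetic cohort
generated *by* one of the formulae has no model misspecification, and
cross-formula differences here reflect only inter-formula geometry, not
clinical reality.

## Problem sizes used in the shipped checks

Test and acceptance runs use cohorts of 100–886 eyes and 10–20 seeds per
stochastic claim; exhaustive grid oracles run at 1e-4 constant resolution
(staged coarse-to-fine where a full 2-D grid would be wasteful). The whole
suite completes in well under a minute on one CPU.

## Known limitations

- Only the four classical single-constant formulae; no toric prediction,
  no thick-lens/raytracing optics, no modern undisclosed formulae.
- Haigis a1/a2 are preset (0.4/0.1), never fitted; triple-constant Haigis
  optimization is out of scope.
- The 6 m refraction-lane distance is not modelled optically; RO absorbs
  it, as it absorbs any constant spectacle-plane offset.
- Median-PE zeroing and percentage-of-eyes-within-threshold benchmarks are
  not implemented.
- Cross-validation is a usage pattern (fit on one cohort, evaluate on
  another), not a packaged procedure.
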