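# Methods

## The model

The package simulates public-health problems during river floods from
questionnaire data with four latent constructs: flood **severity** (F),
**preparedness** (P), **help** (H) and **public-health problems** (PHP).
Severity and preparedness are exogenous with correlation φ; the structural
equations are

    H   = b_PH · P + e_H
    PHP = b_F · F + b_H · H + b_P · P + e_PHP

with standardized coefficients (all latents unit variance).  Each latent is
measured by a block of 0–10 rating items — 10 severity, 4 preparedness,
4 help, 10 PHP, 28 in all — through a congeneric measurement model.  The
model-implied covariance of the 28 items follows the usual latent-path
algebra

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ.

## Synthetic data generator

The published study deposited no raw data, so the generator *is* the data
source.  Its defaults are the published standardized solution:

| parameter | default | meaning |
|---|---|---|
| `structural_paths` | b_F = 0.287, b_H = −0.029, b_P = −0.008, b_PH = 0.452 | standardized paths |
| `exo_correlation_F_P` | 0.534 | severity↔preparedness correlation |
| `measurement_loading` | 0.70 | common standardized indicator loading |
| `n_respondents` | 560 | 20 × 28 observed variables |

Residual variances of the endogenous latents are solved (in topological
order) so every latent has exactly unit variance; a configuration whose
paths would force a negative residual variance is rejected with the name of
the offending equation.

Two defaults are calibrated rather than copied, because the source report
never prints them:

* **Measurement loadings** are unreported; 0.7 is a typical well-fitting
  survey loading and keeps the implied covariance positive definite.
* **φ = 0.534** is chosen so the population explained variance of the PHP
  equation equals the reported 7.7 %.  Covariance algebra gives
  Var(explained) = 0.0834837 − 0.0121160 φ (the cross-terms use
  Cov(F,H) = b_PH φ and Cov(H,P) = b_PH), so φ = 0.534 yields R² = 0.07701.
  `tests` verify this against an independent numeric covariance oracle.

Items are mapped from the latent scale to the 11-point rating scale by
`5 + (10/6)·z`, rounded half-up and clipped to [0, 10], so ±3 SD spans all
11 choices symmetrically.  Whether real respondents used the scale
symmetrically is unknown; the symmetric mapping is an explicit assumption.
Rounding adds ≈ h²/12 quantization variance (h = 0.6 SD), which slightly
attenuates item correlations and loadings but leaves the latent structure
intact — which is why the ML fit still recovers the structural paths from
discretized data (verified empirically by the recovery experiment).

Demographics are sampled independently per variable from the published
marginals (only marginals were reported, so no dependence structure is
imposed).  Age and household size come from normals with the published
mean/SD truncated to the sampled category's range; the open-ended category
bounds (adult minimum 18, maximum 80) are calibrated so the category mixture
reproduces the published mean age of 53.23.  Toy region geometries are grid
cells tiling a rectangular extent, grouped contiguously into districts in
one province — purely synthetic stand-ins carrying no real administrative
boundaries.

What passing tests therefore show: the pipeline is correct *for data that
match its own assumptions* (multivariate-normal latents, equal loadings,
symmetric item use, independent errors).  They cannot show robustness to
ordinal skew, item-specific loadings, or spatial correlation of flood
exposure in real surveys.

## Estimation

`fit_ml` minimizes the normal-theory discrepancy
F_ML = ln|Σ(θ)| + tr(S Σ⁻¹) − ln|S| − p with L-BFGS-B and an analytic
gradient (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ], specialized per parameter block).
Identification fixes exogenous latent variances to 1 (unit-variance
convention); standardized output is identical under the alternative
first-loading-fixed convention, which is exactly what the test-suite's
independently written oracle fitter uses for cross-checking.  Items are
treated as continuous (normal-theory ML).  Numerical choices:

* error variances bounded below at 10⁻⁶·median(S_ii), latent residual
  variances at 10⁻⁶, exogenous correlation inside (−0.999, 0.999) — this
  keeps Σ(θ) positive definite throughout the search;
* convergence at ftol 10⁻¹⁰ / gtol 10⁻⁸, up to 10 jittered restarts on
  failure; the `converged` flag reports the optimizer status honestly;
* χ² = (n−1)·F_ML; RMSEA uses the (n−1) denominator; CFI uses the
  independence baseline with free variances (ML solution diag(S)).

The published model's post-hoc adjustment (df = 160 after freeing
unreported parameters) cannot be reconstructed; the default specification
has df = 343 and optionally accepts correlated-error terms via
`SemModelSpec.correlated_errors`.

## Risk score and levels

The score uses the sign-adjusted normalized form

    S = [C1·F + |C2|(10−H) + |C3|(10−P) + |C2·C4|(10−H)(10−P)] / N,
    N = C1 + |C2| + |C3| + 10|C2·C4|

with C1..C4 the standardized effects severity→php, help→php,
preparedness→php and preparedness→help.  S is 10 at (F,H,P) = (10,0,0) and
0 at (0,10,10) by construction, and monotone (increasing in F, decreasing
in H and P) for sign-conforming loadings.  The published *expanded*
polynomial contains an internal inconsistency: its linear help coefficient
(−0.18908) double-counts |C2|, while the exact expansion gives −0.16008.
The package follows the exact general form by default — it alone satisfies
the best-case check S = 0 — and offers an `eq10_printed` compatibility flag
reproducing the printed polynomial, since which form the deployed
application used is unknowable.

Risk levels: all 11³ = 1331 integer scenarios are scored; cutoffs sit at the
k/11 empirical quantiles (linear interpolation, k = 1..10) and a score's
level is the number of cutoffs strictly below it (ties to the lower level).
The percentile convention is unstated in the source; equal-frequency
quantiles match the "ranks by percentiles" intent, and on the default grid
each level indeed holds exactly 121 scenarios.  Colour names follow the
published 11-colour legend with RGB frozen to the common named-colour
convention (Dark Red #8B0000 … Green #008000) so maps are bit-reproducible.

## Mapping

Scenarios attach per subdistrict; district/province values aggregate child
scores by `mean`, `max` or `area_weighted_mean` (default area-weighted
mean — the upward aggregation rule is unstated in the source, and
area-weighting is the natural choice for spatial intensity) and are
re-binned through the same level table.  Coordinates are taken as GeoJSON
lon/lat (WGS84) with no reprojection; the toy geometries are abstract.  The
legend always shows all 11 levels so maps are comparable across scenarios.

## Problem sizes used in checks

Analytic oracles (implied covariance, effect arithmetic, fit-index closed
forms) run at full precision.  Stochastic checks use: 100 000 respondents
for generator-covariance convergence (tolerance 0.02 max absolute
deviation), 200 000 for the diagnostic block-mean correlation, and the
recovery/calibration experiment fits 200 replicates of n = 560 — enough for
Monte-Carlo standard errors of ≈ 0.004 on the severity→php mean and
≈ 0.2 pp on mean R²(php).  Cross-fitter equivalence uses 20 random
two-latent, six-indicator models at n = 500 with a 10⁻³ agreement bound.

## Known limitations

* Items are treated as continuous; no ordinal (polychoric/WLSMV) estimation.
* No standard errors, missing-data FIML, multi-group models or bootstrap
  CIs for indirect effects.
* Estimated R² carries the usual finite-sample upward bias (≈ +0.8 pp for
  the PHP equation at n = 560), visible in the recovery experiment.
* The demographic generator reproduces marginals, not joint structure.
* Real flood exposure is spatially autocorrelated; the toy region scenarios
  are not.
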