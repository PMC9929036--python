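# Methods

## Model and estimation

### Stage 1: spatial correction

Raw plot yields are modelled as
y = Xb + Z₁l + Z₂g + Z₃f + Σᵢ₌₁⁹ Z₍ᵢ₊₃₎s + e, where the spatial term sums
an iid plot effect s ~ N(0, Iσ²_s) over the plot's 3×3 field neighborhood
(target plot plus its up-to-eight existing neighbors on the within-trial
grid; border plots simply have fewer neighbors).  Corrected phenotypes are
y_c = y − Zŝ with Z the summed neighborhood incidence.  The two-step
construction (correct first, model dispersion second) is deliberately
conservative: spatial trend absorbed into ŝ can include some genetic
signal, but it keeps the dispersion model's weight structure decoupled
from the field layout.

### Reference model (LMM-HET)

y_c = Xb + Z₁g + Z₂l + Z₃f + e_i with one residual variance per
year-location environment.  Fixed effects are trial-within-environment
dummies with drop-first (reference level) coding; g carries the VanRaden
method-1 GRM, l and f are iid.  Plot-level heritabilities per environment
use σ²_P = σ²_l + σ²_g + σ²_f + σ²_e(i), h² = σ²_g/σ²_P,
H² = (σ²_l + σ²_g)/σ²_P; a variant multiplying σ²_g by the mean GRM
diagonal d(G) is available (`fold_dg=True`).  The default matches the
internal arithmetic of the published wheat table this package reproduces;
the d(G)-folded variant matches the printed formula in its source.  The
discrepancy between the two is documented, not resolved: at d(G) = 1.84
they differ materially, and only the default reproduces the printed
heritabilities from the printed components.

### DHGLM

The iterative scheme:

1. homoscedastic mixed model on y_c (same effects as LMM-HET);
2. dispersion response y_d = ê²/(1−Λ), weight W_d = (1−Λ)/2, with Λ the
   hat-matrix diagonal of the mean model;
3. weighted gamma GLM, log link, response y_d, weight W_d, with the
   current dispersion BLUP ĝ_d as offset, re-estimating the dispersion
   fixed effects b_d each pass;
4. mean-model weights W = 1/fitted-dispersion;
5. bivariate AI-REML of [y_c; ζ], where ζ is the gamma GLM's IRLS working
   response on the log scale, with trait covariance
   [[σ²_g, σ_g,gd],[σ_g,gd, σ²_gd]] ⊗ G, l and f on the mean trait only,
   and residual covariances W⁻¹σ²_e, W_d⁻¹σ²_εv;
6. update ê, Λ, y_d, W, W_d from the bivariate fit (mean-trait rows);
7. repeat 3–6 until every variance component changes by < 1e-5 relative.

σ²_gd is therefore on the log (exponential-model) scale.  The leverage
used for y_d and W_d at every pass is the hat diagonal of the mean-trait
rows of the current bivariate system; at the first pass it comes from the
homoscedastic fit.

**Residual scale parameters.**  The scalings σ²_e and σ²_εv of the two
weight matrices are *fixed at one* (both are reported as exactly 1.0).
The weights already specify the residual variances completely: W⁻¹ is the
fitted plot variance and W_d is calibrated so that the line-level
information content of the squared residuals is correct.  Freeing σ²_εv
lets the *within*-line deficit of squared-residual variation — shrinkage
of the line and line-by-environment BLUPs makes residuals of paired
replicates anti-correlated, so their squared values are nearly duplicated
— drag the dispersion residual scale to ≈0.5, after which the unexplained
*between*-line variation is misattributed to σ²_gd (on null simulations
the bias was ≈ +0.08 on the log scale, versus a truth of 0).  With the
scales fixed the null case collapses cleanly to the boundary.  An
`estimate_scales=True` flag retains the free-scale variant.

### AI-REML engine

Variance components are estimated by average-information REML on
Henderson's mixed-model equations.  One random term whose incidence has a
single nonzero per row and identity covariance (in these models the
line-by-environment interaction, the largest block) is absorbed; the
remaining dense core (fixed effects + genomic block + line block) is
factored by Cholesky.  Hat-matrix diagonals, arbitrary entries of the
inverse coefficient matrix, and the REML log-likelihood all come from this
factorization.  Updates are Newton steps with the AI matrix, safeguarded
by step halving against the restricted likelihood and an EM fallback step
(guaranteed uphill) when the AI direction fails.  Details that matter:

* **Variance floors.**  Variances are bounded below by 1e-10, except
  GRM-correlated variances which use 1e-6: their contribution to the
  equations is G⁻¹/σ², and since an in-sample GRM is exactly singular
  (rows sum to zero) and is regularised by an escalating diagonal jitter
  (starting at 1e-8, only when the Cholesky pivot check fails), a 1e-10
  variance would create astronomically ill-conditioned blocks.  On the
  scale of these data (trait variance ≈ 0.3, log-variance parameters
  ≤ 0.3) a floor of 1e-6 is indistinguishable from zero.
* **Boundary handling.**  A variance pinned at its floor with a downhill
  gradient is frozen; the bivariate covariance is constrained to
  |ρ| ≤ 0.999 and, once it presses outward on that bound on two
  consecutive iterations, is slaved to the variances
  (cov = ±0.999·√(σ²_g σ²_gd)) for the rest of the fit — otherwise the
  optimizer zigzags along the constraint indefinitely.
* **Convergence.**  Primary criterion: relative parameter change < 1e-8.
  Two auxiliary stops handle degenerate geometry: two consecutive
  likelihood gains < 1e-9·(1+|ll|), and a windowed stationarity test
  (likelihood range < 1e-6·(1+|ll|) and parameter moves < 1e-3 over eight
  iterations), which only engage when the fit is already wobbling inside
  the numerical noise floor, far below the sampling precision of any
  estimate.
* **Outer-loop relaxation.**  The dispersion-BLUP/weights fixed-point
  iteration often alternates in sign with contraction ratio r ≈ −0.7.
  Each outer update of ĝ_d is relaxed by ω = 1/(1−r̂) (clipped to
  [0.3, 3]), with r̂ estimated online from successive update residuals.
  This damps the oscillation and leaves the fixed point untouched.  A
  12-iteration stationarity window accepts boundary fits whose components
  wobble within 0.3% without trending.

### Cross-validation

Leave-one-line-out: each fold masks every plot of one line (both the mean
and the dispersion rows in the DHGLM).  By default folds reuse the
converged full-data variance components and weights; fold BLUPs are then
computed by an exact Woodbury downdate of the mixed-model equations —
algebraically identical to re-solving with the line's rows deleted, and
verified against brute-force refits in the test suite.  Full per-fold
re-estimation is available (`refit=True`) but is quadratic-times-folds
expensive; the reuse default is standard practice and is a documented
deviation from strict per-fold re-estimation.  Predictive ability is the
Pearson correlation between fixed-effect-corrected line means and the
cross-validated predictions; for the dispersion level the "line mean" is
the average of the log-scale working response corrected by b̂_d.
Bootstrap SEs resample lines with replacement (default B = 10,000); model
contrasts recompute both statistics on identical resamples and apply a
two-tailed paired t-test (reported against the 0.01 threshold).  The
maximum potential predictive ability is √(k·h²/(1+(k−1)h²)) with k the
mean line replication, averaged over environments for g and computed at
h²_d for g_d.

### Genetic parameters

Per-environment residual variances of the DHGLM use the final residual
vector with denominator n_i − 1 − npar_i (npar_i = trials in environment
i).  The exponential→additive conversion is
σ²_e,add = mean(ŷ_d)·σ²_e, σ²_e,exp = σ²_e,add·exp(0.5σ²_gd),
σ²_gd,add = (σ²_e,exp)²·exp(σ²_gd) − (σ²_e,add)², reading the source's
garbled fourth-power symbols as squared variances so the chain is
dimensionally coherent and non-negative.  h²_d uses the
across-environment average of σ²_P.  Internal-consistency caveat: feeding
this chain the published wheat values (σ²_gd = 0.004, mean residual
variance ≈ 0.085, σ²_P ≈ 0.310) yields h²_d ≈ 3e-4, far from the
published 0.033; the package computes the chain as printed and reports
what it computes, without forcing agreement.

## Synthetic data generator

The generator emulates the target breeding programme: blocks of 46 plots
(two replicates of 21 lines and of 2 checks, randomized within block),
blocks laid out as grid columns within trial, trials nested in
year-location environments, yields around 9.15 kg/plot with trial effects
of SD 0.8, and the exponential dispersion model with correlated (g, g_d)
drawn from the GRM.  Genotypes are unlinked SNPs on nearly homozygous
lines arranged in full-sib families of 5 from biparental crosses of
homozygous founders, with residual heterozygosity 0.031 (the F6
expectation) and 3% missing calls.  The family structure matters: with
unrelated lines a masked line has no informative relatives and
leave-one-line-out prediction degenerates, which is not how a breeding
population behaves.  Variance defaults mirror the wheat population
(σ²_g = 0.054, σ²_l = 0.062, σ²_f = 0.108, residual ≈ 0.085 kg²,
σ²_gd = 0.004, ρ = 0.5).  Checks are ordinary genotyped lines flagged
`is_check` and analysed by default.

What the generator does **not** emulate: linkage disequilibrium and
chromosome structure, multi-cycle selection, autoregressive spatial
fields (the spatial effect is generated exactly as the analysis models
it, which makes stage-1 recovery a matched-model check, not a robustness
check), year-to-year genetic trend, and non-Gaussian residuals.  Passing
recovery tests therefore validate the estimation machinery under the
assumed model, not the model's adequacy for any real field dataset.

## Study sizes and expectations

The dispersion-recovery study runs 10 replicates of 500 lines × 8
replicates (4 environments), with σ²_g = 0.054, σ²_gd = 0.05, ρ = 0.5 and
the default nuisance variances — about 40 s per replicate.  The null
study and the cross-validation exercise use 300 lines.  Two properties of
the squared-residual DHGLM at this replication level are worth knowing
when reading results:

* estimates of σ²_gd carry substantial sampling spread at k = 8
  replicates (replicate SDs of order half the parameter), and the
  leverage-corrected response attenuates part of the line-dispersion
  signal when the mean model shrinks heavily (mean leverage here ≈ 0.35),
  so individual replicates can land well below truth;
* the implied correlation ρ̂ = σ̂_g,gd/√(σ̂²_g σ̂²_gd) inherits the noise
  of both variances and can reach the ±1 boundary on unlucky replicates.

The acceptance study reports replicate means; recovery is judged against
the replicate spread, not against per-replicate agreement.

## Known limitations

* The engine fits the model classes needed here (iid terms, one
  GRM-correlated univariate or bivariate term, diagonal residual classes),
  not arbitrary covariance structures.
* Leverages are computed exactly from the factorization; no stochastic
  estimator is provided, so paper-scale data (≈22k plots) is supported
  but slow (hours, as for the original analysis).
* Standard errors for h²_d and GCV_E are not produced (no delta method).
* The dispersion level carries only genomic effects; per-environment
  dispersion G×E covariance is out of scope.
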