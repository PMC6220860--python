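# Methods

## The analysis problem

In small-animal 2-deoxyglucose (2-DG) autoradiography, regional brain
activity is quantified once per animal as an *uptake ratio* (UR): the ¹⁴C
concentration in a region of interest divided by a whole-brain reference
concentration for the same animal.  Functional connectivity between regions
is then defined *across animals*: two regions are functionally connected in
a group when their uptake ratios co-vary over the group's animals.  This
package implements a seed-based version of that analysis — pick a seed
region, regress its UR on all other regions' URs within one group, and read
each target region's contribution off the regression — together with the
quantification stage that produces the UR table and the behavioural
statistics of the accompanying recognition-memory assay.

## Quantification

Section-level measurements (one value per animal × region × film section,
either tissue-equivalent activity in nCi/g or an optical density) are
collapsed to one UR per animal and region:

* **Calibration.** Optical densities are converted to activities through a
  monotone piecewise-cubic (PCHIP) interpolant of co-exposed calibrated
  standards (≥ 4 required, activities strictly positive, OD strictly
  monotone in activity in either direction).  PCHIP passes exactly through
  every standard and preserves monotonicity, hence invertibility.  Queries
  outside the calibrated OD range raise unless extrapolation is explicitly
  enabled.  A low-order polynomial fit is available as an alternative and is
  rejected if non-monotone over the standards' range.
* **Whole-brain denominator.** The default denominator for a region is the
  mean of *all* measurements in the sections in which that region was
  measured (one denominator per region).  The phrasing conventionally used
  for this quantity is ambiguous between that reading and one global mean
  per animal, so a `per_animal` switch implements the latter; neither is
  asserted as the "true" convention.  URs are invariant to rescaling an
  animal's entire section set (film-exposure invariance) under both.
* **Region-wise screening.** Each region is compared between groups with a
  two-sided pooled-variance Student's t-test at α = 0.05, each region
  treated as an independent variable (no multiplicity correction — the
  screening convention for overt metabolic change; Welch available).
  Missing cells are dropped pairwise, never imputed.

## PLS1 and the VIP statistic

With ~10 animals and 48 predictor regions, ordinary least squares is
undefined, so the seed regression uses univariate-response partial least
squares (PLS1).  Predictors and response are mean-centred and scaled to
unit sample SD (ddof = 1); VIP is not scale-invariant, so this convention is
fixed.  Components are extracted by NIPALS with predictor-matrix deflation;
for a univariate response each weight vector has the closed form
w_a ∝ X_aᵀy_a on the deflated data.  Fitted models satisfy, and the test
suite asserts: unit-norm weights, mutually orthogonal scores, equality with
the OLS fit when A = rank(X), and equality of fitted values with an
independently implemented PLS at matched A.

Edge strength is the variable importance in projection,

    VIP_j = sqrt( p · Σ_a SS_a w_{ja}² / Σ_a SS_a ),   SS_a = q_a² (t_aᵀ t_a),

normalised so mean(VIP²) = 1; VIP ≈ 1 is an average contribution and the
conventional threshold 0.8 marks a "considerable" one.

**Number of components.** The default is A = 2 (configurable, and echoed in
every output and log line, since the upstream protocol this emulates does
not fix A).  `choose_ncomp` offers a deterministic data-driven choice:
leave-one-out CV error for A = 1..max, then the smallest A within one
standard error of the minimum.  A relative floor of 1e-8·var(y) is added to
the one-SE threshold so the rule remains scale-free on (near-)noiseless
data.  Component extraction stops early if the residual response is
exhausted; constant predictor columns are dropped with a warning and the
dropped names propagate to reports.

## Jackknife uncertainty and connectivity calls

Per seed and group (n ≥ 3 animals), the VIP vector is refitted n times
leaving out one animal, and

    SD_jack = sqrt( (n−1)/n · Σ_i (θ_(i) − mean θ_(·))² ),
    CI = θ_full ± t_{0.975, n−1} · SD_jack.

The t multiplier (rather than 1.96) is deliberately conservative at n = 10.
The jackknife is implemented generically (any row-wise statistic) so its
closed form for the sample mean — SE = s/√n exactly — serves as a unit-level
oracle.

A target is *connected* to the seed when its CI clears the VIP threshold
0.8.  The default criterion is the CI **lower bound** exceeding 0.8 — the
conservative reading of "the 95% CI exceeds 0.8" — with a point-estimate
mode (`criterion="point"`) for sensitivity analysis.

## Between-group edge classification

For each edge the two groups' VIPs are compared with a Welch-type statistic
built from the jackknife SEs,

    t = (VIP_t − VIP_c) / sqrt(SD_t² + SD_c²),

with Welch–Satterthwaite degrees of freedom using n−1 per group, and a
Bonferroni correction over the seed's target family (48 targets for 49
regions; a global seeds × targets family is available by flag).  Labels:

| label     | requires                                                      |
|-----------|---------------------------------------------------------------|
| increased | corrected p < α, connected in both groups, VIP_t > VIP_c      |
| decreased | corrected p < α, connected in both groups, VIP_t < VIP_c      |
| gained    | corrected p < α, connected in treated only                    |
| lost      | corrected p < α, connected in control only                    |
| unchanged | otherwise                                                     |

A significant difference with **no** connection in either group is labelled
`unchanged`: the four directional categories all presuppose a connection in
at least one group.  Exchanging the group labels provably swaps
gained↔lost and increased↔decreased (asserted on every test replicate).
`compare_groups` on a single edge raises when both jackknife SDs are zero;
inside the vectorised report such (measure-zero) edges would fall back to
t = 0, p = 1.

## Synthetic studies

The generator is a latent factor model: for an animal in group g,
x = 1 + L_g z + ε with z ~ N(0, I_k) and ε ~ N(0, σ² I).  Functional
connectivity in the seed-regression sense *is* shared latent variance, so
expected correlations have the closed form
corr(x_i, x_j) = L_i·L_j / sqrt((|L_i|²+σ²)(|L_j|²+σ²)), which the tests use
as an oracle.  Defaults emulate the study design the pipeline targets: two
groups of 10 animals, 49 regions named after the design's regions of
interest, seeds DSub/MD/Hab/GP, k = 3 factors, dominant loading 0.08 and
cross-loading 0.03 per region (cyclic assignment), noise SD 0.05.  These
values put URs within a few percent of 1 and give r ≈ 0.72 between regions
sharing a dominant factor — a strong-covariance regime — while keeping
columns positive.  Columns are recentred to mean exactly 1 after generation
(a per-column constant, so no covariance is altered).  Draw order is fixed
(per animal: k latents, then p noise values, animals in row order), so one
integer seed reproduces a table bit for bit.

Ground-truth edge differences are injected by adding a loading delta on the
seed's dominant factor to a target region in one group; the companion truth
table marks exactly the perturbed (seed, target) pairs.

The behavioural generator inverts the novelty preference index
NPI = (B−A)/(B+A): it draws NPI ~ N(μ_g, 0.15) truncated to (−1, 1)
(respecting the index's range) and a positive total exploration time
T ~ N(40 s, 10 s) truncated at 0, then sets A = T(1−NPI)/2, B = T(1+NPI)/2.
Group means default to 0.201 (control) and 0.050 (treated) with n = 19/20.
Total-time moments are not pinned by the emulated design; 40 ± 10 s is a
realistic figure for a 5-minute test phase in mice and the NPI statistics do
not depend on it.

**What the generator does not emulate:** film physics and densitometry
noise, section geometry, anatomically structured covariance (factors are
assigned cyclically, not by circuit), heavy-tailed or animal-specific global
effects, and group differences in mean uptake.  Passing recovery tests
therefore show the estimator chain is correct under a factor-covariance
model, not that the pipeline's power matches what real, far more strongly
correlated uptake data would give.

## Behavioural statistics

* NPI with the full-immobility guard (zero total time → error).
* Paired/unpaired/one-sample two-tailed t-tests (scipy-backed; unpaired is
  pooled-variance by default).
* Grubbs single-outlier test, two-sided at α = 0.05, critical value
  G = ((n−1)/√n)·sqrt(t²/(n−2+t²)) with t the 1−α/(2n) Student quantile on
  n−2 df; applied at most once by convention.
* Two-sample power via the exact noncentral-t formulation:
  ncp = |μ₁−μ₂|/s_p · sqrt(n₁n₂/(n₁+n₂)), df = n₁+n₂−2,
  power = P(|T'| > t_crit).  For the default behavioural design (0.201 vs
  0.050, s_p = 0.15, n = 19/20, two-sided α = 0.05) this computes 86.4%.

## Monte-Carlo calibration (validation module)

* **Null calibration:** 1000 identical-group studies; the family-wise rate
  of any non-`unchanged` label per seed analysis is ~0.8–1.4%, within the
  Bonferroni guarantee of 5% — the procedure is conservative.
* **Edge recovery:** one injected edge at delta = 0.10 (asymptotic VIP
  difference ≈ 0.66, pre-computed from the factor model at n = 2000 per
  group).  Measured sensitivity at n = 10/group is ≈ 0: with 48 predictors
  and 10 animals the jackknife SE of a VIP value is ~0.3–0.5, so after
  Bonferroni correction only VIP differences around 2 are detectable, which
  the factor model cannot produce.  This is a real property of the
  estimator chain at this sample size and noise regime, not an
  implementation defect (the jackknife and PLS stages are verified against
  exact oracles); real uptake data with much higher inter-regional
  correlations yield far smaller jackknife SEs and hence usable power.  The
  corresponding acceptance test states the intended sensitivity and fails
  honestly under these conditions.

## Known limitations

* Power of the edge classifier at n = 10 with 48-fold correction is
  minimal under the generator's noise regime (see above).
* The CI-versus-threshold call and the Welch-from-jackknife comparison are
  each one of several defensible readings of the underlying convention;
  both alternatives (point-estimate criterion, global family) are exposed
  as options rather than silently chosen.
* Jackknife CIs assume approximate normality of the VIP estimator; at
  n = 3–5 they are indicative only.
* The power routine's printed 86.4% for the default behavioural design is
  the exact value for the stated inputs; figures quoted elsewhere for the
  same design can differ by ~1 point depending on rounding of the pooled
  SD before computation.
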