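# Methods

## Problem and model

`roidecode` asks how well trial-level behavior — reaction time (RT, in
seconds) and an ordinal confidence rating — can be predicted from the
trial-wise activation of a single cortical parcel, separately for each
subject. The data model is a per-subject matrix of single-trial beta
estimates (trials × parcels, e.g. 700 × 200 for a 200-parcel atlas with
seven large-scale networks), plus the two behavioral vectors and a
per-subject mean frame-displacement (FD) nuisance scalar.

For one subject, parcel and target, the decoder is a simple linear
regression of behavior on activation: trials are split at random into
disjoint training and testing bins (default 25 repeats), the model is fit
on the training bin, and performance is the Pearson correlation r between
empirical and predicted behavior on the testing bin. The 25 per-repeat
correlations are aggregated on the Fisher-z scale, z = atanh(r), averaged,
and mapped back with tanh. |r| is clipped to 1 − 1e-12 before atanh so
noiseless test cases stay finite.

For an affine prediction ŷ = a + b·x the identity
r(y, ŷ) = sign(b) · r(y, x) holds exactly; the implementation fits and
predicts explicitly (so non-affine regressors plug in through the same
contract), while the vectorized permutation path and several tests exploit
the identity.

## Subject-level inference

Significance of a cell is assessed against a permutation null: the target
vector is shuffled globally across trials, the repeated-split analysis is
re-run, and the observed aggregated r is ranked one-tailed (positive
decoding) against the null aggregates with the add-one estimator
p = (1 + #{null ≥ obs}) / (1 + n_perm); ties count against significance.
By default each of the (default 1000) permutations uses 5 fresh splits
rather than the full 25 — a 5× cost reduction that slightly widens the
null and makes the test mildly conservative; `null_repeats` is configurable
up to the full repeat count. A parametric alternative
(`parametric_pvalue`, the r→t conversion with df = n_test − 2) is exposed
because a permutation p is floored at 1/(n_perm + 1) and therefore cannot
pass very strict thresholds (e.g. 0.05/10000 with 1000 permutations);
the permutation route is the default criterion.

P-values are thresholded into a four-level Bonferroni ledger: uncorrected,
corrected for the number of subjects, for the number of parcels, and for
their product. The maps are nested by factor magnitude. Coverage is
summarized three ways per level: % of parcels significant in ≥1 subject,
% of subjects per parcel, % of parcels per subject.

Group-level inference averages subject performance per parcel on the
z scale and applies a one-tailed one-sample t-test against zero,
Bonferroni corrected across parcels. Testing on the z scale is the
variance-stabilized, statistically standard choice. Degenerate parcels
(identical z across subjects) and parcels with <3 subjects are flagged,
not dropped.

The direction of a cell is the sign of the mean fitted slope across the
observed repeats; a parcel is *divergent* at a level when at least one
subject is significant with positive direction and at least one with
negative. Divergence percentages are reported overall and per network
(network sizes as denominators).

The motion QC regresses per-subject mean performance (z scale, averaged
over parcels) on mean FD and reports R² and a two-tailed p.

## Trial-number sufficiency

A whole-brain multilinear model (all parcels jointly, with intercept) is
trained on 5%…95% of trials (5% grid) and tested on the held-out trials,
25 re-splits per fraction; a fixed-test-count variant scores a constant
number of held-out trials instead. Per subject the repeat-mean and the
across-repeat SD of r are computed, then averaged across subjects. Two
optima are located: the fraction minimizing SD and the fraction maximizing
mean − SD, ties broken toward the smaller fraction. When the training
count is below the predictor count the fit is rank deficient; the
minimum-norm least-squares solution is used (LAPACK gelsy, verified
against the pseudoinverse), a deterministic and canonical choice.

## Synthetic cohorts and what they show

The generator plants, per subject s and parcel r, a signed standardized
coupling c[s,r] between the parcel and a latent standardized behavioral
state z. Betas are built with unit variance,

    beta = c_rt·z_rt + c_conf·z_conf + lam·eta,   lam² = 1 − c_rt² − c_conf²,

where eta is unit-variance nuisance noise mixing a per-trial factor shared
across parcels with idiosyncratic noise. Hence corr(beta, latent) equals
the planted coupling exactly. Observables are monotone images of the
latents — RT is log-normal, exp(loc + scale·z), and confidence is an
equal-probability ordinal binning of its own latent — so the expected
behavior-scale correlation has a closed form exposed as
`expected_correlation`:

    corr(beta, rt)   = c · scale / sqrt(exp(scale²) − 1)
    corr(beta, conf) = c · Σ_k φ(Φ⁻¹(k/K)) / sqrt((K² − 1)/12).

Sign heterogeneity is sampled per subject × parcel (probability
`sign_mixture` of a positive slope), so opposite-sign prevalence is
directly controllable; `coupled_roi_fraction` leaves a chosen share of
parcels inert for specificity checks. Mean FD is drawn independently of
every coupling, making the motion QC null by construction. Presets mirror
the two study regimes (50 subjects × 700 trials with six shorter subjects;
36 × 804 with confidence rated on only the second half of trials, decoded
with a 301/101 split of the rated block).

Defaults: coupling magnitude 0.3 with sparsity 0.3 (a moderately coupled
cortex), sign mixture 0.5, shared noise SD 0.2 vs idiosyncratic 1.0, RT
median 0.8 s with log-scale 0.35, 4 confidence levels — conventional
values for perceptual decision tasks, exposed in config rather than
hard-coded.

What passing tests on these cohorts do *not* show: real beta series have
autocorrelated, heteroscedastic noise, run structure, non-linear and
non-stationary brain–behavior relationships, and parcel boundaries that
differ across subjects. The generator emulates none of these; results on
it validate the statistical machinery, not empirical claims about cortex.

## Numerical and design choices

- RT is decoded on the raw seconds scale; an optional log transform is
  deliberately not applied by default.
- Trials with a missing target are dropped before splitting; split sizes
  are absolute counts per target.
- Zero-variance predictors make a repeat (or a whole cell) missing;
  missing repeats are ignored by the Fisher mean, missing cells are NS at
  every ledger level and written as empty fields.
- Exactly-zero mean slope gives direction 0, counted in neither sign group.
- Per-cell RNG streams are derived by hashing (master seed, subject, ROI,
  target, stage), so results are independent of scheduling and reproducible
  bitwise; all file output uses %.17g with round-trip float parsing.
- Test-suite and acceptance-script problem sizes (e.g. a 10 × 20 null
  calibration cohort at 200 trials, sufficiency sweeps scaled to 4–10
  subjects, 500-permutation sign-recovery runs) are chosen as the smallest
  cohorts at which the statistical properties under test are
  well-resolved.

## Known limitations

- With 1000 permutations the subject-level permutation p cannot pass an
  alpha/10000-style threshold; use the parametric route for that regime.
- The 5-split null policy is slightly conservative; empirical type-I
  error runs just below nominal (observed ≈ 0.025–0.045 at alpha = 0.05 in
  the calibration runs).
- The false-divergence rate at the uncorrected level is inherently a few
  percent per inert parcel in small cohorts (two independent 5% tests with
  opposite random signs), so uncorrected divergence percentages on weakly
  coupled data should be read against that baseline.
- Group aggregation assumes approximately normal per-subject z values;
  very small cohorts rely on the t approximation.
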