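# Methods

`chemprofile` analyses GC–MS chemical profiles — here modelled on preen-oil
secretions of a small shorebird sampled during incubation — from per-sample
peak lists to a test of group differences in chemical composition. This note
records the models, the defaults and why, and the limits of what the test
suite demonstrates.

## From chromatograms to an abundance matrix

Each sample is a list of peaks `(retention time, integrated area)`; one peak
is treated as one substance identified by its retention time (RT). No mass
spectra are used and no substance identification is attempted.

**Alignment.** Retention times drift slightly between runs, so peaks are
pooled across samples, sorted globally by RT, and merged by a single-pass
greedy rule: a cluster keeps absorbing the next peak while it lies within
`2 × rt_tolerance` (default tolerance 0.05 min) of the cluster's first
retention time, bounding the within-cluster span by twice the tolerance.
Each cluster becomes a substance column labelled by its mean RT. A sample
can contribute at most one peak per column: the peak nearest the consensus
wins (ties go to the earlier RT) and displaced peaks are re-clustered so
each seeds its own column. This is deliberately simpler than dedicated
multi-step alignment tools (no drift-curve correction); a matrix aligned
elsewhere can be ingested directly, bypassing this stage. Retention times
are reported at 2 decimals of a minute; within-sample duplicates at that
precision are summed with a warning.

**Filtering.** Two categorical rules, applied in this order: (a) any
substance detected — at any level — in a solvent-only blank run is removed
as contamination; (b) any substance detected in exactly one biological
sample is removed as unreplicated. Blank rows are then dropped. The
operation is idempotent.

**Normalisation.** Because the amount of secretion collected is not
standardised, areas are divided by the sample's total chromatogram area.
The default scale is percent (0–100) rather than proportion: the subsequent
`log(X+1)` transform is meant to up-weight low-abundance substances, which
only works when typical values exceed 1 — on a 0–1 scale `log(X+1) ≈ X` and
the transform does nothing. Zeros (non-detections) remain zero, and carry
no signal downstream because Bray–Curtis ignores joint absences.

## Diversity

Alpha diversity per sample: richness (count of detected substances) and the
Shannon index `H = −Σ p_k ln p_k` (nats) over the positive entries. Beta
diversity between samples: Bray–Curtis dissimilarity
`d_ij = Σ|x_i − x_j| / Σ(x_i + x_j)`. Both are computed on the terminal
log-transformed relative abundances by default (a switch accepts raw
relative abundances); whether the original analysis used the transformed or
untransformed scale for the alpha indices is not derivable from the
pipeline itself, so the choice is exposed.

## PERMANOVA with sequential sums of squares

For a dissimilarity matrix `D` the Gower-centred matrix is
`G = −½ C D² C`, whose trace is the total sum of squares
`Σ_{i<j} d_ij²/n`. For the nested designs `X_0 = 1 ⊂ X_1 ⊂ … ⊂ X_p`
(term order: sex, days after laying, sex × days — type I SS depends on this
order), the sequential SS of term k is `tr(H_k G) − tr(H_{k−1} G)` with
`H_k` the hat matrix of `X_k`; the pseudo-F of each term uses the full-model
residual. Sex is treatment-coded, days after laying is a numeric covariate,
and the interaction is their product (1 df each). Significance comes from
free permutation of sample labels, `P = (1 + #{F* ≥ F}) / (1 + n_perm)`;
when `n! ≤ n_perm` all `n!` relabellings are enumerated and P is the exact
fraction. The decomposition `Σ SS_term + SS_resid = SS_total` holds to
1e-9 for every permutation, and the single-factor statistic is verified in
the tests against a brute-force oracle that recomputes SS from group-wise
within-distance sums over all relabellings.

## Pseudoreplication: balanced exclusion and the pooled P

Partners of a breeding pair are not independent samples, and blocked
permutation is not possible when most pairs contributed only one bird.
Instead, each iteration drops one partner from every complete pair, subject
to the dropped set being sex-balanced (with 4 mixed-sex pairs: 2 females
and 2 males dropped, giving C(4,2) = 6 admissible patterns; with the study
composition the retained set is 16 samples, 7 females + 9 males). The
PERMANOVA is re-run on each subset (Bray–Curtis on a subset of samples
equals the subset of the full distance matrix, since the index depends only
on the two samples compared). Across `N_iter` iterations the per-term
median and IQR of SS, R² and F are reported, and P-values are pooled as

    P = Σ_i (1 + Σ_j I(F_j ≥ F_obs,i)) / (N_iter × (1 + N_perm)),

i.e. the mean of the per-iteration permutation p-values. Ties count as
exceedances (`≥` exactly). Defaults: 1,000 iterations × 9,999 permutations.
One master seed spawns an independent substream per iteration, so results
are bit-reproducible and independent of execution order.

**Known limitation — the pooled P is conservative.** The single-iteration
permutation test is exactly calibrated (the test suite measures rejection
rates of 0.04–0.05 at α = 0.05 under the null generator). The pooled P,
however, is a mean of per-iteration p-values computed on subsets that share
most of their samples (only 6 distinct subsets exist under the default
design): averaging dependent p-values shrinks the distribution toward 0.5,
so tail mass below α is lost. The calibration experiment in the test suite
(500 null datasets, 50 iterations × 199 permutations) measures a sex-term
rejection rate of ≈ 0.02 at α = 0.05 — valid (never anti-conservative) but
below nominal, and the pooled-P distribution is measurably non-uniform.
Conclusions of "no difference" drawn from this statistic are therefore
slightly understated in significance, not overstated.

## Dispersion, PCoA and NMDS

The dispersion (homogeneity) test embeds `D` by principal coordinates.
Bray–Curtis is semi-metric, so some eigenvalues are negative; the negative
axes are kept as an imaginary block and each sample's squared distance to
its group centroid is `|real|² − |imaginary|²`, floored at zero. Group
means of these distances are compared by a one-way F, with P from
permuting the computed distances across samples (9,999 by default). The
centroid (not the spatial median) is the reference point: closed-form and
stable at n = 20. On purely Euclidean input these distances reduce exactly
to Euclidean distances to the group mean, which the tests verify.

NMDS minimises Kruskal stress-1
`√(Σ(d̂ − d̃)² / Σ d̃²)` (d̃ = configuration distances, d̂ = isotonic
disparities) by SMACOF from 20 random starts plus one PCoA start, keeping
the best configuration; defaults k = 2, tolerance 1e-7, max 300 iterations
per start. NMDS is used for visualisation only and no inference is attached
to the stress value.

## Alpha-diversity mixed models

Shannon and richness are each regressed on sex and days after laying
(interaction included by default, toggleable) with a random intercept per
breeding pair, fitted by REML; unpaired samples form singleton groups. When
every group is a singleton the model is exactly ordinary least squares and
is fitted as such. Significance is read from whether the 95% CI contains
zero. CIs are Wald-type, `β ± t_{n−k} · SE`: the t quantile (residual df)
replaces the normal quantile because at n = 20 normal-quantile Wald
intervals are visibly short. Even so, with a boundary-prone variance
component the coverage measured in the tests is ≈ 0.90 rather than 0.95 —
an inherent small-sample property of Wald intervals here, so borderline CI
exclusions of zero should be read cautiously. A pair variance estimated at
zero is reported with a boundary flag, not raised as an error.

## Detectability beta regression

The proportion of samples in which each substance occurs is modelled as a
beta regression: logit link on the mean, constant precision φ (log link),
predictor = orthogonal polynomial of consensus RT (degree 2 by default; a
raw centred-power basis is available behind a flag, but the linear
coefficient is only interpretable in the orthogonalised basis). Proportions
of exactly 0 or 1 (substances absent from or present in every sample) are
shrunk by `y' = (y(N−1) + 0.5)/N` before fitting. Wald P per coefficient.
A hump-shaped detectability–RT profile yields a negative quadratic
coefficient, matching the qualitative expectation that both the most and
least volatile substances are detected less often.

## Synthetic data generator

No generative model is given for real preen-oil data, so the generator is
declared, not inferred. Substances get fixed true RTs, uniform with a
minimum spacing of 0.15 min (≥ 4× the RT jitter SD of 0.01 min, so
alignment is well-posed); per-substance mean log abundances are normal
(between-substance SD 1.8), per-sample log areas add a breeding-pair effect
(SD 0.3, shared by partners, who also share a laying day), a multiplicative
sex effect δ on a flagged 30% of substances (δ = 0 by default — the null),
and within-substance noise (SD 1.0); areas below the detection threshold
(1e4 area units) are zeroed. Five blank-borne contaminants (each present in
at least one of 7 blanks, and sporadically in biological runs) and three
single-sample substances are planted for the filters to remove. With the
defaults (105 shared substances, ln-threshold offset 0.79) a typical
dataset retains ~90–95 substances after filtering, with ~60–68 detected per
sample (SD ≈ 7) and ~20–25% present in all 20 samples — the intended
right-skewed, presence/absence-structured shape.

What the generator does not emulate: chromatographic drift curves (jitter
is i.i.d., not monotone in RT), co-elution, abundance correlations between
substances, and any real relationship between RT and detectability. Tests
passing on synthetic data therefore validate the statistical machinery and
its calibration, not the chemistry of any real dataset.

## Problem sizes in the tests

The unit and acceptance tests scale the simulations to: 500 null datasets
at 50 iterations × 199 permutations for the pooled-P calibration, 200
replicates for parameter-recovery checks, 250 replicates for CI coverage,
and 200 replicates for the dispersion type-I check, with exhaustive
enumeration (n ≤ 7) wherever the oracle requires it. The acceptance script
runs the pipeline itself at the full 1,000 × 9,999 settings on one
study-shaped dataset and a 250-dataset calibration at the reduced settings.

## Degenerate inputs and numerical choices

Empty peak lists are accepted with a warning; a metadata/peak-file mismatch
is an error. All-zero abundance rows make Shannon and Bray–Curtis
undefined and raise. Aliased design terms (e.g. constant sex) raise naming
the term. Eigenvalues within 1e-8 (relative) of zero are treated as zero in
PCoA; exhaustive-permutation F comparisons use a 1e-12 tie tolerance;
alignment tie-breaks use a 1e-9 RT tolerance. Matrices round-trip through
CSV bit-identically (pandas shortest-repr floats).
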