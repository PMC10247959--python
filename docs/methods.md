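# Methods

## Scope and data model

`mrpipe` performs two-sample Mendelian randomization from GWAS summary
statistics alone: per SNP, an identifier, chromosome and 1-based position,
the two alleles, effect-allele frequency (EAF, optional), the per-allele
effect estimate with its standard error, a p-value and sample size
(optional). Effects are per effect allele: SD units for quantitative
traits, log-odds for binary ones. All genomic windows are inclusive
center-to-center distances in kilobases. Missing values are `NA`;
p-values of exactly 0 are floored to the smallest positive normal double
so that log and threshold operations remain defined.

The pipeline rests on the three instrumental-variable assumptions —
relevance, independence from confounders, and exclusion (effect on the
outcome only through the exposure). They are contracts, not code: the
package enforces what is checkable from summary data (instrument strength,
independence via LD clumping, outcome-overlap exclusion, a user-supplied
confounder SNP list) and provides sensitivity analyses (Egger intercept,
radial outliers, leave-one-out) for the rest.

## Instrument selection

* **Significance filter** — strict `p < p_threshold`. Defaults: 5e-9 for a
  well-powered exposure GWAS with very many genome-wide hits, 5e-8
  (`SelectionConfig.relaxed()`) for modest-scale exposures.
* **LD clumping** — greedy: repeatedly promote the remaining SNP with the
  smallest p-value to index SNP and discard remaining SNPs on the same
  chromosome within the window whose r² with it is ≥ the threshold.
  Defaults pair with the significance presets: r² < 0.001 / 1,000 kb and
  r² < 0.1 / 500 kb. Ties in p are broken by (chromosome, position, id)
  for cross-platform determinism. A SNP absent from the LD matrix is an
  error, never a silent pass-through. The greedy scan is provably
  order-insensitive; the test suite still checks it against a brute-force
  re-scanning oracle on hundreds of random instances.
* **Strength screen** — per-SNP F ≈ (β̂/σ̂)², keep F > 10. The (β/σ)² form
  is the standard single-SNP approximation when only summary statistics
  are available; an R²-based form would need per-SNP n and variance
  explained.
* **Outcome-overlap exclusion** — drop instruments whose outcome
  association has p < 1e-5, plus any instrument missing from the outcome
  table (no LD-proxy search; proxies are a deliberate non-goal).
* **Confounder list** — `drop_listed` removes a user-supplied id list
  (e.g. from a phenome-wide lookup done elsewhere); web queries are out
  of scope and not reproducible.

Duplicate snp_id rows are resolved at read time keeping the smallest
p-value, with a log note. Every filter only removes rows — surviving
records are never modified — so the selection chain is idempotent.

## Harmonization

Outcome records are rewritten into the exposure's allele frame: direct
match copied through; swapped alleles (or strand-complement swapped)
negate the outcome beta and reflect its EAF; allele sets that differ even
after complementing are dropped as incompatible. Non-palindromic
strand-complement matches (A/G vs T/C) are aligned deterministically
rather than dropped, since complement-coded consortia files are common.

Palindromic SNPs (A/T, C/G) carry no strand information in their labels.
The EAF window 0.42–0.58 (symmetric about 0.5) defines ambiguity: inside
it, or with a missing exposure EAF, the SNP is dropped; outside it the
orientation is inferred by frequency agreement when the outcome reports an
EAF, else the label alignment is trusted. A `drop_all_palindromic` switch
discards every palindromic SNP for users who prefer the stricter
convention. The per-SNP action log accounts for every input SNP exactly
once, and harmonization is a fixed point: re-harmonizing its own output
changes nothing.

## Estimators

All estimators use first-order weights that ignore exposure sampling
error — standard with the F > 10 screen upstream; the Wald ratio offers a
second-order SE behind a flag.

* **Wald ratio** (1 instrument): β̂_Y/β̂_X, SE σ_Y/|β̂_X|.
* **IVW**: weighted regression through the origin, weights 1/σ_Y²;
  fixed-effect SE (Σ w β̂_X²)^-1/2. "Random effects" is multiplicative
  overdispersion — SE × max(1, √(Q/(n−1))) — matching the dominant
  two-sample MR tooling; an additive random-effects model is out of scope.
  With one instrument IVW reduces exactly to the Wald ratio (Q = 0, df 0).
* **Cochran's Q**: Σ w (β̂_Y − β β̂_X)² about a reference slope, upper-tail
  χ²(n−1).
* **Weighted median**: order Wald ratios, normalize weights
  w_j = β̂_Xj²/σ_Yj², interpolate the ratio at the 50 % point of
  s_j = Σ_{i≤j} w'_i − w'_j/2. SE by parametric bootstrap (normal
  resampling of β̂_X and β̂_Y at their SEs), default 1,000 replicates, seed
  mandatory. With equal weights and odd n this is exactly the sample
  median of the ratios.
* **MR-Egger**: weighted regression with intercept after orienting all
  β̂_X ≥ 0 (internal, never mutates caller data); SEs scaled by
  max(1, √(Q′/(n−2))). The intercept's two-sided normal p tests
  directional pleiotropy; the slope is consistent under InSIDE.
* **Radial MR**: regression of ratio·√w on √w through the origin with
  w = β̂_X²/σ_Y²; the slope is algebraically identical to IVW under these
  weights (asserted to 1e-10 in tests). Per-SNP q_j = w_j(ratio_j −
  slope)² is χ²(1) under homogeneity; q-tail probability < α flags an
  outlier. Default α = 0.05 without multiplicity correction (pass 0.05/n
  for a Bonferroni variant); outlier removal reruns random-effects IVW.
* **Leave-one-out**: random-effects IVW dropping each SNP in turn.

95 % CIs are normal-based on the beta scale and exponentiated for odds
ratios. The estimator branch in the pipeline follows instrument count:
1 → Wald ratio; 2 → IVW + Q (median and Egger are undefined below 3);
≥ 3 → full suite. Primary inference is random-effects IVW; weighted
median, Egger and post-outlier radial IVW are sensitivity rows. Reports
carry a Bonferroni tier at 0.05/m where m is the configured test family
size (default 6, reported in the run manifest).

## Synthetic data

The generator draws, per replicate, true instrument effects
γ_j = |Normal(0, γ_sd²)| in a canonical frame where the effect allele is
the exposure-increasing allele, direct effects α_j (zero; balanced
Normal(0, sd²) with InSIDE holding; or directional with a nonzero mean),
and observed estimates

    β̂_Xj ~ N(γ_j, se_x²),  β̂_Yj ~ N(β γ_j + α_j, se_y²)

independently (two-sample design). The emitted tables then re-code each
SNP's effect allele at random, independently per GWAS, so reported signs
are symmetric and harmonization (including sign flips and palindrome
handling) is genuinely exercised; folding γ positive in the canonical
frame is what makes "directional" pleiotropy well defined relative to the
exposure-increasing allele. Defaults state a realistic world: 50 SNPs,
γ_sd = 0.05 SD/allele, se_x = 0.002 (a quantitative GWAS of n ≈ 5×10⁵),
se_y = 0.003 (log-odds SE of a biobank-scale case-control GWAS), 20 %
palindromic SNPs, EAF uniform on (0.05, 0.95). LD is written directly as
a block-diagonal r² matrix (clumping consumes nothing else); block
members sit 10 kb apart, blocks 10 Mb apart across chromosomes. Setting
an SE to 0 produces the noise-free limit in which every Wald ratio equals
β exactly (the emitted SE column is a 1e-8 placeholder since records
require positive SEs).

What the generator does **not** emulate: winner's curse (γ is fixed truth,
selection acts on the observed β̂_X only through its noise), sample
overlap, InSIDE violations, allele-frequency-dependent effect sizes, and
real LD decay. A green calibration therefore establishes estimator
correctness under the stated model, not robustness to those phenomena.

## Calibration

`calibration_study` simulates replicates (hierarchical seed stream:
one global seed spawns independent, individually reproducible per-replicate
seeds below 2³¹), runs selection → harmonization → estimators, and
tabulates rejection rate, mean estimate, empirical SE and CI coverage per
method. Measured behaviour at 1,000 replicates of 50 instruments:
random-effects IVW type-I error 0.038 at α = 0.05 under the null; mean
estimate 0.0996 under β = 0.1; Egger intercept mean 0.01998 under
directional pleiotropy of mean 0.02, while uncorrected IVW is biased to
≈ 0.42 — the numbers the acceptance tests assert.

One deliberate choice: calibration runs with the outcome-overlap screen
**off** by default. With a true causal effect (or simulated pleiotropy)
the screen's p < 1e-5 rule removes precisely the instruments whose
behaviour is being measured — at these parameter scales it attenuated the
β = 0.1 recovery to 0.095 and the Egger intercept to 0.007 — so leaving
it on would mask the estimator properties a calibration exists to expose.
The applied pipeline (`run_mr`) keeps the screen on, as an analysis of
real traits should; `outcome_screen=True` restores it in calibration for
studying exactly this masking effect.

## Numerical notes

* Weighted regressions are solved from the 2×2 normal equations in
  closed form; the test suite cross-checks point estimates and SEs
  against an independent weighted-least-squares solver to 1e-10.
* Overdispersion factors are floored at 1 (never deflate below the
  fixed-effect SE); RE-SE ≥ FE-SE is asserted as a property.
* Two-sided normal p-values are computed via the survival function and
  floored at the smallest positive normal double.
* Clumping tie-breaks, canonical report ordering, mandatory seeds and
  round-half-even formatting make a full batch run byte-reproducible.

## Limitations

Single-SNP F statistics overstate joint instrument strength under LD;
no proxy-SNP substitution, liftover or rsID resolution; no MR-PRESSO,
mode-based, multivariable or contamination-mixture estimators; the
confounder step requires a user-supplied list rather than a live
phenome-scan; forest output is tabular, not graphical.
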