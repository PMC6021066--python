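# Methods

## Data model

A dataset is a list of specimen records: id, locality of origin,
population pool, specimen type (live or skin), optional sex, and a
partial character → value map. Characters are defined once (name, class,
scale, valid range, ordinal level count) and every value is range-checked
on read. Sex is ignored throughout: phenotypic dimorphism has not been
recorded in this complex and few specimens are sexed. Tail fork depth is
a derived character, outer minus inner rectrix length (T6 − T1); it is
the only character allowed to be negative and is excluded from PCA input,
being a linear combination of two characters already present.

Summaries are reported as mean ± SE (min–max; n) per pool, with the
sample SD (n−1 denominator) everywhere — in SEs, in Cohen's d, and in the
SE·√n reconstruction of SDs from published tables. The SE of a single
observation is undefined and stored as missing.

## Specimen-type bias screening

Skins shrink and fade relative to live birds. The screen runs a
two-sided Welch two-sample t-test per character between live and skin
values inside one reference pool (default NZ — the only pool with a large
sample of both types), so that genuine between-pool differences cannot
load onto the specimen-type contrast. Decisions are per character at
α = 0.05 with no multiplicity correction, matching how such screens are
applied in practice (each character's exclusion is an independent
measurement-validity judgment); a Holm option exists for users who prefer
family-wise control. Ordinal plumage scores are screened with the same
Welch test on the raw scores.

A biased character has one class *excluded*, not corrected: regression
adjustment of skin measurements would import model assumptions the
downstream scoring does not need. The excluded class is the one absent
from at least one pool (live, in the motivating data — only two sites
contributed live birds), so the retained class keeps every pool
comparable. Exclusion only masks values; nothing is rescaled.

Degenerate cases: samples with fewer than two observations per class are
skipped with a warning; two zero-variance samples with equal means give
p = 1 by convention.

## Multivariate step

Pool-mean imputation precedes z-scoring, which precedes PCA. Imputation
uses the observed within-pool character mean (global mean as a logged
fallback when a pool has no observations for a character) and is
idempotent. The PCA is computed by SVD of the centered z-scored matrix,
i.e. an eigendecomposition of the sample correlation matrix; explained
variance is the eigenvalue share of total variance. Component signs are
arbitrary in any PCA, so each component is oriented with its
largest-magnitude loading positive to make outputs reproducible. Two
components are reported by default; all are retained internally.

Pool differences are tested with a one-factor ANOVA on each component's
scores (one factor — pool — is the whole design), excluding pools with
n < 7: below that, group variances are essentially unestimable and the
F-test untrustworthy.

## Univariate step

Continuous characters use one-factor ANOVA with Tukey HSD pairwise
comparisons (scipy's studentized-range implementation); ordinal
characters use the Kruskal–Wallis rank-sum omnibus with the standard tie
correction — essential here, since a 1–4 score over a hundred specimens
is almost all ties — followed by pairwise two-sided Welch t-tests on the
raw scores, uncorrected by default (a Holm option exists). Asymptotic χ²
p-values are used throughout; pool sizes in this design (≥ 7 after
exclusions) are large enough that exact small-sample p-values would
change nothing material. The n < 7 exclusion is applied per character per
pool, because per-character n varies once biased classes are masked.

The significance gate for delimitation is strict: a pairwise adjusted
p < α (not ≤). A note on a property one might expect: Tukey's adjusted p
is guaranteed to be at least the unadjusted p *of the same
pooled-variance contrast* (pooled MSE, N−k df); compared against a plain
two-sample t-test it can occasionally be smaller, because the pooled
error estimate carries more degrees of freedom.

## Delimitation scoring

Continuous characters are scored by binning |d|; the published bin
descriptions share their endpoints, so the bins are implemented half-open
[lo, hi): 0.2–2.0 → 1, 2.0–5.0 → 2, 5.0–10.0 → 3, ≥ 10 → 4, which keeps
"d > 10 → 4" exact and the step function monotone (d = 2.0 scores 2).
|d| < 0.2 scores 0, as does any character failing the significance gate.
Plumage scores are expert ordinal judgments (weak = 1 … exceptional = 4)
supplied as inputs, not auto-derived from the score statistics — the
magnitude of a plumage contrast is a visual judgment the rank tests do
not capture. The behavioural/ecological contrast (breeding habitat) is a
single 0/1 flag. The decision sums the two largest biometric scores, the
three largest plumage scores and the behavioural flag; species status is
supported at total ≥ 7. The threshold and its strictness are
configurable; the ≥ reading is the default because the originating
framework sets its cut *at* 7, and both worked species comparisons (8, 9)
are insensitive to the choice.

Cohen's d uses the pooled sample SD with no small-sample (Hedges)
correction, the default of the R `effsize` implementation this field
uses. The summary-statistic route (SD = SE·√n per pool) is algebraically
identical to the raw route for complete samples, and the test suite
asserts agreement to 1e−9.

## Synthetic data

The generator emulates the study conditions: four pools of 29/38/138/2
specimens; live fractions 0, 16/38, 127/138, 0 (only two sites
contributed live birds); biometric characters drawn from normals
truncated to each character's validity range, parametrised by the
packaged per-pool means and SDs; ordinal characters drawn from
categorical distributions over 1..K whose location/scale are
least-squares fitted (discretised-normal family) to the packaged means
and SDs — exact ordinal moment matching is impossible in general, so
ordinal pipeline tests are Monte-Carlo rather than exact. Skins receive
additive shrinkage offsets (t1_length −1.0 mm, bill_depth −0.4 mm) and
fading offsets (−1 score step on ear_covert_extent and flank_colour);
the magnitudes are not recorded anywhere in the source material and were
chosen once as realistic values on the order of those characters' pooled
SDs. Missingness is applied uniformly at random at rate 0.10, a round
figure reflecting the substantial but uneven per-character coverage of
the real tables. Seeding is hierarchical: one root seed, with a stable
per-(pool, character) stream derived by string hashing, so adding a
character to a spec never perturbs the draws of the others.

The moment-matched fixture generator rebuilds specimen-level data from a
summary table by drawing n values and affinely rescaling them so the
sample mean and SD equal the printed mean and SE·√n exactly; printed
min/max are not enforced, and which records carry values for a
low-coverage character is seed-randomised. The fixture reproduces
summary-level statistics (means, SEs, effect sizes) by construction, and
separations driven by mean/SD structure (PCA clustering, ANOVA gates)
reliably; it does **not** reproduce the real data's within-specimen
correlation structure, its live/skin composition, or its non-normal
features, so passing fixture tests validates the pipeline's arithmetic
and decision logic, not distributional claims about the birds.

## Problem sizes and numerics

The test suite's Monte-Carlo components use 10,000 replicates for the
Welch type-I calibration, 1,000 for shrinkage-recovery power and the
identity/brute-force cross-checks, and 20 seeds for fixture-level
pipeline checks — sizes at which the binomial error of each asserted rate
is comfortably inside its asserted band on a single CPU in seconds.
Numerical tolerances: exact identities (moment matching, summary-vs-raw
d, PCA reconstruction) are asserted at 1e−8–1e−9; statistical
reproductions of printed effect sizes at ±0.05 (the printed tables carry
two decimals and their n are small).

## Limitations

- Plumage Tobias scores are inputs, never derived; the package cannot
  delimit from plumage alone without expert judgment.
- The exact published F/χ²/PCA loadings are not reproducible by anyone:
  the underlying raw measurements were never deposited. The packaged
  summary tables are the recoverable record.
- Shrinkage is screened and excluded, not modelled; datasets where both
  classes are needed for coverage would require a correction model this
  package deliberately omits.
- The two-specimen Macquarie (novus) pool is carried through summaries
  but excluded from every significance test by the n < 7 rule.
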