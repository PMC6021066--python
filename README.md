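# phenodelim

Phenotypic species delimitation for allopatric population pools, built
around the dataset that split the Whenua Hou Diving Petrel
(*Pelecanoides whenuahouensis*) from the South Georgian Diving Petrel
(*P. georgicus*). The package is aimed at taxonomists and museum
scientists who need to test species limits from a mixture of live-bird
measurements and study skins when molecular data are thin: it screens for
specimen-type measurement bias, tests multivariate and univariate
differentiation between population pools, and runs the quantitative
Tobias scoring test for species status.

## The pipeline

Specimens are grouped into allopatric pools (here SAO = South Atlantic
Ocean, SIO = South Indian Ocean, NZ = New Zealand, novus = Macquarie
Island) and analysed in four stages:

1. **Specimen-type bias screening.** Study skins shrink and fade, so each
   character is compared between live birds and skins *within one
   reference pool* with a two-sided Welch *t*-test
   (Welch–Satterthwaite df). Characters that test biased at α = 0.05 have
   one specimen class excluded outright — the class missing from at least
   one pool — rather than corrected.
2. **Multivariate clustering.** Missing values are imputed with pool
   means, characters are z-scored, and a PCA (correlation structure) is
   extracted per character class; pool differences on each component are
   tested with a one-factor ANOVA, excluding pools with *n* < 7.
3. **Univariate tests.** Continuous characters: one-factor ANOVA +
   Tukey HSD per pool pair. Ordinal plumage scores: tie-corrected
   Kruskal–Wallis omnibus + pairwise Welch *t*-tests.
4. **Delimitation scoring.** For each pool pair, significant biometric
   contrasts are scored by binning the absolute pooled-SD Cohen's *d*

   | |d| | < 0.2 | 0.2–2.0 | 2.0–5.0 | 5.0–10.0 | ≥ 10.0 |
   |---|---|---|---|---|---|
   | score | 0 | 1 | 2 | 3 | 4 |

   with *d* = (x̄₁ − x̄₂)/s_p and
   s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2). Plumage characters carry
   expert magnitude scores (1–4); a behavioural/ecological contrast can
   score at most 1. The total = top-2 biometric + top-3 plumage +
   behavioural; species status is supported when the total reaches 7.

When only published summary tables are available (the raw measurements
for this complex were never deposited), per-pool SDs are reconstructed as
SE·√n — for complete samples this reproduces the raw-data *d* exactly —
and a moment-matched fixture generator rebuilds specimen-level datasets
whose per-pool mean, SE and *n* equal the printed values to machine
precision. A full synthetic-data generator (truncated-normal biometrics,
categorical ordinal scores, live/skin shrinkage and fading offsets,
missing-at-random masking) emulates the study conditions for end-to-end
testing.

## Worked example

The three pool comparisons, scored from the packaged summary tables:

```sh
$ phenodelim delimit --pool-a SIO --pool-b NZ
SIO vs NZ: biometric (top 2) = 2, plumage (top 3) = 6, behavioral = 1
total = 9 (threshold 7): species status supported
```

The NZ pool differs from SIO in six significant biometric characters,
each with 0.2 ≤ |d| < 2.0 (score 1 apiece, top two summed = 2), six
plumage characters scoring {3, 2, 1, 1, 1, 1} (top three summed = 6), and
the breeding-habitat contrast (sandy foredunes at sea level vs
high-altitude scree; score 1). NZ vs SAO gives total 8 (species), SAO vs
SIO gives 3 (no species status). The same machinery runs on raw
measurement CSVs:

```sh
phenodelim simulate --seed 1 --out sim.csv      # synthetic study-condition data
phenodelim screen   --data sim.csv              # live-vs-skin bias table
phenodelim compare  --data sim.csv --characters biometric
phenodelim pca      --data sim.csv
```

the last of which prints a loadings table with the explained variance and
per-component pool ANOVA, e.g. `variance_explained 26.85% 12.40%`,
`p (ANOVA) < 0.001 0.005` with the two-specimen novus pool excluded.

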