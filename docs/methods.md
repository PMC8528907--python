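# Methods

This note documents the statistical procedures implemented in `divshift`,
the modelling choices behind the synthetic-data generator, and the numerical
conventions, in enough detail that every reported number can be traced to a
formula and a parameter.

## Diversity estimation

### Abundance vectors and coverage

All estimators operate on a single sample's vector of positive counts
X₁,…,X_S with n = ΣXᵢ; zero-count features are dropped at extraction time
(every estimator here is defined on observed features only, so padding a
table with absent features never changes a result — a property the test
suite asserts). Sample coverage — the probability that one more read would
belong to an already-observed feature — is estimated two ways, each kept
with the estimator it originally belongs to:

* **Good–Turing**, Ĉ = 1 − f₁/n (f₁ = singleton count): used inside the
  Chao–Shen estimator.
* **Interpolated**, Ĉ(m) = 1 − Σᵢ (Xᵢ/n)·C(n−Xᵢ,m)/C(n−1,m) for
  1 ≤ m ≤ n−1: the expected coverage of a hypergeometric subsample of size
  m, used for rarefaction targets. At m = n−1 it reduces algebraically to
  the Good–Turing estimate, which the suite checks to 1e−12.

Degenerate case: a sample in which every read is a singleton (f₁ = n) has
Ĉ = 0 and would make the coverage-adjusted estimators 0/0. Where the
estimator itself needs Ĉ (Chao–Shen, Good–Turing coverage), the standard
practical adjustment f₁ ← n − 1 is applied and a `DegenerateCoverageWarning`
is emitted. Such a sample is still rejected, by name, as the *anchor* of
joint rarefaction, because a zero common coverage target is meaningless.

### Coverage-based rarefaction at q = 2

Samples are compared at the common coverage C\* = min over samples of
Ĉ(n−1). For each sample the smallest m with Ĉ(m) ≥ C\* is found by
bisection on the monotone coverage curve (ties resolved to the smallest m —
the least extrapolation of evenness); the sample attaining the minimum is
assigned m = n − 1 exactly, avoiding any floating-point round trip.
Diversity is then the analytic interpolation

    ²D(m) = 1 / [ 1/m + (1 − 1/m)·ΣXᵢ(Xᵢ−1)/(n(n−1)) ],

not a random subsample: the bracketed expression is the exact expectation
of the subsample's plugin Simpson concentration Σ(Yᵢ/m)², because
E[ΣYᵢ(Yᵢ−1)]/(m(m−1)) = ΣXᵢ(Xᵢ−1)/(n(n−1)) is an identity of the
multivariate hypergeometric distribution. At m = n the formula collapses
algebraically to the plugin inverse Simpson n²/ΣXᵢ², so interpolation is
seamless at full depth.

A seeded multivariate-hypergeometric subsampler is provided both as an
optional Monte-Carlo mode (`mode="montecarlo"`, reporting the mean plugin
²D over a chosen number of replicates) and as the validation oracle. One
subtlety matters for validation: the analytic value is 1/E[λ̂] (λ̂ the
subsampled concentration), whereas the Monte-Carlo mean of plugin ²D
estimates E[1/λ̂]. By Jensen's inequality these differ by a second-order
term that is *not* negligible against Monte-Carlo error at large replicate
counts (measured at ~10–15 SE for m/n ≤ 0.6 with 10⁴ replicates). The
oracle tests therefore compare on the concentration scale, where agreement
is exact in expectation at any m; this is a property of the oracle design,
not of the estimator.

### Hill numbers and entropy conventions

^q^D = (Σpᵢ^q)^(1/(1−q)); the q → 1 limit exp(−Σpᵢ ln pᵢ) is taken
analytically whenever |q−1| < 1e−9 rather than through the numerically
unstable 1/(1−q) exponent. All entropies are in nats and effective numbers
are exp of natural-log entropies; no base-2 or base-10 option is offered,
since "effective features" is base-invariant only if exponentiation matches
the logarithm base.

### Chao–Shen effective functions

For functional (GO-term) vectors the Shannon entropy is estimated with the
coverage-adjusted Horvitz–Thompson form

    H = − Σᵢ p̃ᵢ ln p̃ᵢ / (1 − (1 − p̃ᵢ)ⁿ),   p̃ᵢ = Ĉ·Xᵢ/n,

reported as ^1^D = exp(H) effective functions. The detection probability
1 − (1−p̃)ⁿ is computed as −expm1(n·log1p(−p̃)) for numerical stability at
small p̃ and large n. When f₁ = 0 the estimator is bounded below by the
plugin exp(Shannon) and converges to it as n grows (within 1% of the true
richness on an even 50-function community at n = 10⁴, asserted in the
suite). Functional tables are deliberately *not* rarefied before
estimation: the Chao–Shen form already corrects for incomplete coverage
through Ĉ, and rarefaction is applied only to the taxonomic (q = 2)
comparison.

### Binomial coefficients

All binomial-coefficient ratios are evaluated as log-gamma differences and
exponentiated last, so coverage interpolation is overflow-free up to
n ≈ 10⁸ reads.

## Group statistics

Per group: mean, sample SD (n−1 denominator, the reporting convention for
small-n summaries), n, and an Anderson–Darling normality p-value. The AD
test uses the estimated-mean-and-variance statistic

    A² = −n − (1/n)·Σ(2i−1)[ln Φ(z₍ᵢ₎) + ln(1 − Φ(z₍ₙ₊₁₋ᵢ₎))],

the small-sample adjustment A\*² = A²(1 + 0.75/n + 2.25/n²), and the
D'Agostino–Stephens piecewise-exponential p-value approximation. For
n < 8 the p-value is reported as "not computed" (the test is essentially
powerless there); zero-variance groups are flagged degenerate rather than
given a meaningless statistic. The implementation reproduces R's
`nortest::ad.test` to ~1e−6 on fixed references frozen into the tests, and
its A² matches `scipy.stats.anderson` to 1e−10.

Groups are compared with a two-tailed Welch's t-test built from (mean, SD,
n) summaries (Welch–Satterthwaite df; Student-t tail via scipy). Running
from summaries is a deliberate interface choice: it makes published summary
tables directly re-testable, which the acceptance layer exploits. The AD
result never gates the Welch test — both are reported. No multiplicity
correction is applied across index rows. Degenerate input (both groups
zero-variance with equal means) raises rather than fabricating p = 1. Both
tests are calibrated empirically in the suite: type-I error within
0.05 ± 0.01 over 10⁴ null replicates each (Welch at n = 10 per group, AD at
n = 50).

## The synthetic experiment

The generator produces the community structure whose diversity signature
the analysis is designed to detect; it is a statistical emulation of read
count tables, not a sequence simulator.

**Community.** Each taxon carries a function repertoire drawn without
replacement from two pools: a small *core* pool (functions shared across
the community) and a large *accessory* pool. Specialists draw small
repertoires mostly from the core pool; generalists draw large repertoires
mostly from the accessory pool. Baseline relative abundances are i.i.d.
lognormal(0, σ), normalized.

**Disturbance** is selection on repertoire size (niche breadth):
wᵢ ∝ aᵢ·exp(s·zᵢ) with zᵢ the standardized (sample SD) repertoire size.
s = 0 is the identity; increasing s strictly increases the generalist share
(both asserted as properties). The two-taxon closed form — post-disturbance
ratio exp(s√2) at equal baseline — anchors the implementation in the tests.

**Read sampling.** Taxonomic tables are multinomial draws over taxon
abundances. Functional reads pick a taxon by abundance, then one of its
functions uniformly; this two-stage scheme is sampled in one multinomial
draw from the induced marginal P(g) = Σᵢ aᵢ·[g ∈ Rᵢ]/|Rᵢ|, which a
chi-square goodness-of-fit test confirms at depth 10⁶. Uniform
within-taxon function usage is the simplest model consistent with treating
the *number* of distinct functions as the niche-breadth measure.

**Default configuration** (the reference scenario): 150 specialists
(repertoire 40–120, core fraction 0.8), 10 generalists (repertoire
400–800, core fraction 0.1), core pool 150, accessory pool 5000, σ = 1.0,
s = 2.5, 10⁵ reads per assay, 5 replicates per group, root seed 42. These
values make control communities taxon-rich but function-concentrated and
disturbed communities taxon-poor but function-rich; they are simulator
conventions chosen to place the scenario in a realistic regime, not
estimates of any real system. Each replicate is an independent community
(replicates model separate chambers), with child seed = root + sample
index, recorded in the sample metadata.

**What the simulator does not emulate:** sequence-level error, chimeras and
database assignment bias; temporal succession; dispersal; any correlation
between abundance and repertoire size beyond the imposed selection; GO
ontology structure (terms are opaque IDs). Passing tests on synthetic data
therefore demonstrate that the *pipeline* detects the designed-in
signature at realistic depths and replication — not that any particular
real community behaves this way.

## Pipeline conventions

* The rarefaction target is computed over the union of both groups — one
  global C\*, mirroring "rarefy to the dataset with the lowest coverage".
* End-to-end determinism: identical inputs produce byte-identical JSON
  reports (no timestamps inside the report; provenance carries a SHA-256
  of the input tables and metadata).
* TSV reports round to 6 significant digits (enough to re-parse to
  working precision); JSON keeps full double precision; the human-readable
  `summary()` displays 3 significant digits, the convention of the summary
  tables it mirrors.
* Problem sizes used by the validation layer: 10⁴ replicates for the
  calibration and oracle experiments, 20 random vectors with n ≤ 200 for
  subsampling checks, and the default synthetic configuration above for the
  end-to-end reproduction — sizes at which all Monte-Carlo tolerances
  (3 SE, ±0.01) are comfortably resolvable.

## Known limitations

* No extrapolation beyond observed sample size (m > n), and no asymptotic
  richness estimation (Chao1-type); interpolation only.
* The Welch test from summaries inherits the rounding of its inputs; at
  p-values of order 10⁻⁵ and below, 3-significant-digit summaries can move
  the recomputed p by tens of percent even though the significance
  conclusion is stable.
* The AD p-value approximation is accurate in the tail regions used for
  screening but is an approximation; it is not intended for p > 0.95
  precision work.
* Metadata supports exactly two groups (disturbed/control); multi-level
  designs are out of scope.
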