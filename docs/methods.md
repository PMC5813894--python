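# Methods

This note records the models implemented in `foxlink`, the defaults and
their rationale, the numerical choices, and what the synthetic registry
does and does not emulate.

## Transmission models on grandmother–granddaughter pairs

A granddaughter is *informative* when she has a determinable ovarian-cancer
status, both of her grandmothers are in the pedigree with determinable
statuses, and exactly one grandmother is affected. Status is determinable
for a woman who has (confirmed) ovarian cancer, or who is unaffected and
either reached 45 years at last contact or died without disease
(`EligibilityRule`; the age cutoff and the confirmation requirement are
configurable). Granddaughters with zero or two affected grandmothers are
carried through extraction but excluded from the transmission test.

With `(N_m, W_m, N_p, W_p)` the lineage-classified pair counts:

- Autosomal dominant: a single pooled rate `p̂ = (W_m+W_p)/(N_m+N_p)`;
  expected affected counts `p̂·N_m`, `p̂·N_p`.
- X-linked dominant: the paternal rate is constrained to twice the
  maternal rate. `transmission_expected` uses the moment estimator
  `m̂ = (W_m + W_p/2)/(N_m + N_p)`; `xlinked_mle` provides the exact
  maximizer of the binomial likelihood
  `W_m·log m + (N_m−W_m)·log(1−m) + W_p·log 2m + (N_p−W_p)·log(1−2m)`
  on (0, 1/2), located by bounded scalar minimization to within 1e−8.
  The two estimators differ in the fourth decimal on realistic tables;
  the moment form is the default because it is what the expected-count
  presentation of this design conventionally reports.

The goodness-of-fit statistic sums `(O−E)²/E` over the **two affected-count
cells only**, with df = 1 (two cells, one estimated rate). Including the
unaffected cells would change both the statistic and its reference
distribution; the two-cell form is the one this design reports.

Relative risks use the Katz log-transform Wald interval
`exp(log RR ± z·√(1/e₁ − 1/n₁ + 1/e₀ − 1/n₀))`; odds ratios use the Woolf
interval. `z = 1.959964` at the default 95% level. Zero event counts raise
rather than silently applying a continuity correction.

## Within-sibship segregation likelihood

For a sistership of `N` daughters with `W` affected, carriers and
non-carriers are affected independently with penetrances `p_c` and `p_n`
(defaults 0.65 and 0.15 — a high-risk dominant allele against the familial
background rate). Conditional on the carrier count `N_c`, `W` is the
convolution of `Binomial(N_c, p_c)` and `Binomial(N−N_c, p_n)`.

- Autosomal: `N_c ~ Binomial(N, 1/2)`. Marginally each daughter is
  affected with probability `(p_c+p_n)/2`, giving the closed form
  `W ~ Binomial(N, (p_c+p_n)/2)`.
- X-linked (paternal): the sistership segregates as a block, `N_c = N`
  (carrier father) or `N_c = 0`. Three combination modes are exposed:
  - `unweighted_sum` (default): `P(W|N_c=N) + P(W|N_c=0)`. This is not a
    probability (it sums to 2 over outcomes) but is the form this design
    conventionally reports, and ratios against it are well defined.
  - `half_half`: the proper equal-prior mixture (sums to 1).
  - `father_carrier`: conditions on a carrier father.

Both an enumeration over admissible `(W_c, W_n, N_c, N_n)` and the closed
forms are implemented; they agree to 1e−12 and serve as mutual oracles.

The family-level likelihood ratio multiplies per-sistership LRs over all
nuclear-family sisterships containing at least one eligible daughter
(sisterships segregate independently given the founders; no peeling over
loops is attempted). `N` counts eligible daughters and `W` the affected
among them, so a sister censored early (e.g. by prophylactic oophorectomy
before the age cutoff) drops out of the sistership rather than counting as
unaffected. Families are binned: LR ≤ 1 "equal", 1 < LR ≤ 1.5 "weak",
LR > 1.5 "strong" evidence for X-linkage, with a separate "excluded" class
from the compatibility test below.

### X-linkage compatibility

A family is compatible with a single segregating X-linked allele iff some
allele entry point (an individual with an absent parent of the sex able to
transmit to them) reaches every affected female along descent edges that
never pass father→son (a mother transmits to any child, a father only to
daughters). This is a polynomial reachability computation; an exhaustive
search over single-origin carrier assignments is implemented as a test
oracle for small families. Because the phenotype is female-limited, the
operational meaning of a "forced father→son step" is a connecting path
between affected females that has no valid alternative; on failure one
such father–son edge is returned as a witness. This is a principled
reconstruction — female-limited phenotypes leave the definition of
father–son exclusion underdetermined — and results flag it as such.

## Age-of-onset analysis

The endpoint is age at ovarian-cancer diagnosis. Each woman contributes
`time = min(diagnosis age, death age, oophorectomy age, last-contact age)`
with the event indicator true only when the minimum is the diagnosis age;
oophorectomy and death censor by default (a flag makes oophorectomy an
event). Women with no usable age are dropped and counted in a log message.

Kaplan–Meier, log-rank and Cox estimation delegate to `lifelines`
(Greenwood variance, log-log median intervals — the upper limit reported
as unbounded when the band never crosses one half; Cox ties handled by the
library's Efron approximation). Tests pin the numerics against
hand-computed product-limit and Mantel–Haenszel oracles, a brute-force
partial-likelihood grid, and the classical identity between the Cox score
test at β = 0 and the log-rank chi-square (asserted to 1e−6 on untied
data).

The variant scan filters to variants with a non-reference genotype rate of
at least 10% among scanned subjects, tests each retained variant with a
two-group log-rank under dominant coding (any alt vs none; additive coding
available), and reports `LOD = −log10(p)` against the Bonferroni threshold
`−log10(α/m)` with `m` the retained count (4.636 at m = 2161, α = 0.05).

## Association statistics

Hardy–Weinberg uses the three-genotype-class chi-square at the estimated
allele frequency. The default reference is df = 2 — matching how this
statistic is conventionally reported for this design — although the
asymptotically calibrated choice with an estimated frequency is df = 1,
exposed via the `df` argument and used for the type-I-error calibration
test. Exact binomial tests (genotype-frequency and sex-ratio) use the
minimum-likelihood two-sided rule, as does Fisher's exact test; the
sex-ratio null is 0.5 daughters by default (the demographic male excess
can be supplied). The frequency–incidence correlation is a plain Pearson
correlation with a least-squares line, with optional population
exclusions; a constant variable yields r = 0 by convention.

## Synthetic registry generator

Families mirror the pair design: two founder couples, a forced son on the
paternal side married to a forced daughter of the maternal side (forcing
one child of each sex keeps the three-generation chain present without
biasing the net sex ratio), random-sex siblings around them, and the
granddaughter generation (deeper generations extend through external
founder spouses). Sibship sizes are Poisson(2.5) truncated to ≥ 1.

A single heterozygous dominant allele enters through founders at frequency
0.05 (two draws for females, one for hemizygous males under X-linkage) and
transmits Mendelianly: autosomal carriers transmit with probability 1/2;
an X-linked carrier father transmits to every daughter and no son, a
carrier mother to each child with probability 1/2. An optional
sex-ratio-distortion parameter sets the daughter probability for carrier
fathers' children.

Female disease is a cure-rate model: a woman is *destined* with
probability `p_c`/`p_n` by carrier status; destined women draw a Weibull
onset age (shape 7.3, scale 52.6 — median ≈ 50 y for non-carriers) with
carriers' hazard multiplied by 2.85, advancing their median onset ≈ 6.7 y.
A diagnosis is recorded only if onset precedes last contact (and any
prophylactic oophorectomy). Carrier males are phenotype-silent for ovary;
an optional prostate penetrance reproduces the ovary–prostate–ovary
pattern qualitatively. Independent "other" cancers occur at a 5% lifetime
background. Last-contact ages are Normal with generation-specific means
(85/62/50 y, SD 10, truncated to [18, 105]) and generation-specific death
probabilities (0.6/0.2/0.05) — fixture choices, not estimates.

Registry ascertainment rejection-samples families against the enrollment
criteria (two or more ovarian cancers; one ovarian cancer plus two other
cancers; an early-onset (≤ 45 y) ovarian cancer plus another cancer) and
flags the earliest-onset case as the proband; an acceptance rate below
1e−4 aborts with a diagnostic. One seeded generator drives everything:
identical configs give byte-identical output.

**What the generator does not emulate:** correlated non-allelic familial
risk (the `p_n` background is i.i.d., where real registry backgrounds
cluster by BRCA status and shared environment), realistic marriage/
remarriage structure, half-sibships, variable family depth, linkage
disequilibrium among scan variants, genotyping error, and BRCA testing
patterns. Passing recovery tests therefore show estimator correctness
under the stated generative model, not robustness to these real-data
features.

## Recovery-test design

The prediction "paternal-lineage RR = 2" is a statement about
allele-driven disease: with the default background `p_n = 0.15`, pair-level
RR is analytically attenuated toward ≈ 1.1–1.45 because most affected
grandmothers are then background cases whose status carries little carrier
information. The recovery tests therefore simulate the allele-driven
condition (`p_n = 0`, founder frequency 0.05) — the regime the prediction
describes — while package defaults keep the registry-calibrated 0.65/0.15.

Raw pair counts under registry ascertainment are biased (an affected
granddaughter can be the family's second qualifying case, and the
disease-silent father cannot contribute one on the paternal side, so the
paternal rate is selectively inflated); excluding proband granddaughters —
the design's own sensitivity analysis — removes this and is consistent for
the predicted RR under both truths. The acceptance test averages the
proband-excluded log-RR over 5 replicate registries of 5,000 ascertained
families per truth mode (a single 5,000-family registry leaves the RR
standard error near the tolerance itself) and checks the geometric mean
within ±0.15 of 2.0 (X-linked truth) and 1.0 (autosomal truth).

Other simulation-based checks and their problem sizes: Mendelian
transmission and ascertainment criteria asserted exactly on every
generated family; paternal vs maternal granddaughter carrier-rate ratio
2.0 ± 10% on ≥ 10,000 single-carrier-grandmother triples (30,000
unascertained families); Cox recovery of the generative HR 2.85 (CI
coverage, n = 600); causal-variant top-LOD rank in ≥ 90% of 100 scan
replicates (159 cases, 25 null variants, carrier frequency 0.20 — high
enough that the causal variant reliably clears its own 10% retention
filter, so the test measures ranking power rather than filter
marginality); HWE (df = 1) and per-variant scan type-I error within
[0.03, 0.07] at α = 0.05 (1,000 HWE variants × 300 subjects; 1,500 null
scan variants × 250 subjects). All seeds are fixed in the tests.

## Numerical and convention notes

- Ages are real years; unknown ages propagate as missing, never as 0.
  Validation enforces ages in [0, 120], diagnosis ages no later than the
  last known age, parental sex consistency and acyclicity.
- The extended-PED dialect keeps the five LINKAGE columns (`family`,
  `id`, `father`, `mother`, `sex` 1/2/0) and appends proband, a
  semicolon-delimited `site:age:confirmed` diagnosis field, oophorectomy
  age, vital status, last-contact and death ages, and BRCA test status;
  missing ids are `0`, missing ages `NA`. Write→read round-trips to
  field-identical pedigrees and is byte-stable for fixed input.
- Family BRCA status: positive if any member tested positive, negative if
  at least one tested and none positive, unknown if no member tested.
  Disease pattern: breast-and-ovary requires ≥ 1 ovarian and ≥ 1 breast
  diagnosis (threshold configurable); ovarian without breast is
  site-specific ovary.
- "Equal" in the LR bins includes LR < 1 (evidence leaning autosomal);
  the scheme grades evidence *for* X-linkage only.
- The 2×2 tables reported by `pair_counts` restrict to granddaughters
  with exactly one affected grandmother, keeping the affected-grandmother
  pair; the optional age filter omits unaffected granddaughters under the
  cutoff while always keeping affected ones.
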