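# Methods

## The statistic

For one variant in one ancestry stratum, attributable risk is computed
with Levin's formula

PAR = p(OR − 1) / (p(OR − 1) + 1),

where *p* is the risk allele frequency (RAF) and OR the harmonized
(≥ 1) allelic odds ratio. Three modelling commitments are baked in:

* **The exposure unit is the allele.** *p* is the RAF itself, not the
  diploid carrier frequency 1 − (1 − RAF)²; the odds ratio is the
  per-allele (allelic) OR. This keeps the statistic a pure function of
  the two quantities summary statistics actually report.
* **OR stands in for relative risk.** Levin's formula is exact for a
  relative risk; a case-control OR equals the RR only in the
  rare-disease limit. No correction is applied. The error this induces
  is measured, not assumed: at 0.5% prevalence, a sampled 50,000
  allele/arm 2×2 table gives a PAR within 0.01 of the true RR-based
  attributable fraction for OR ≤ 3 and p ≤ 0.5 (see
  `scripts/acceptance.py`, key `rare_disease_par_max_abs_error`).
* **Point estimates only.** No delta-method or bootstrap intervals; the
  ranking consumes point values.

PAR is per-variant: no joint multi-variant attributable risk, and no
adjustment for LD between lead variants of different loci.

## Harmonization

Summary statistics orient effects to an arbitrary effect allele. Records
with β < 0 are flipped (risk allele := other allele, RAF := 1 − EAF,
β := |β|); records with β ≥ 0 pass through. β = 0 is treated as a
degenerate risk variant (OR = 1, PAR = 0) rather than an error. The
reported effect-allele frequency is taken at face value as that allele's
frequency — it is not re-folded to minor-allele convention, since the
flip rule is only coherent under that reading. Strand-ambiguous A/T and
C/G SNPs cannot be resolved without a reference panel, which is out of
scope; they pass through and are counted in a log warning. The operation
is idempotent and exact (the frequency complement is `1.0 - eaf` in
floating point, tested for exact equality).

## Selection

Nominal significance (p < α, default α = 0.05, strict inequality) is the
*inclusion* criterion: variants failing it are removed, which is what
"increasing confidence in effect directionality" requires. Each locus —
membership comes from the input's locus label, not positional windows —
is then represented by its minimum-p variant; ties break by larger |β|,
then lexicographically smallest variant id, so the selected set is
deterministic under any input permutation. Proxy substitution is purely
declarative: a user-supplied target→proxy map (injective, no
self-entries), applied after lead selection, with the replacement
annotated `proxy_for`. There is no LD-based proxy discovery.

## Fine-mapping

The posterior validation uses Wakefield's approximate Bayes factor under
a single-causal-variant assumption: with Gaussian likelihood
β̂ ~ N(β, se²) and Gaussian effect prior β ~ N(0, W),

ABF = √(se² / (se² + W)) · exp(z²W / 2(se² + W)),  z = β̂/se,

and PIP_i = ABF_i / Σ_j ABF_j with a uniform prior over the locus's
variants. Choices and consequences:

* **prior_sd = √W = 0.2** on the log-OR scale, a standard
  weakly-informative prior for complex-trait effect sizes; configurable.
* **No LD matrix is consumed** — the single-causal model needs only
  per-variant (β̂, se). A `LocusBlock` may carry an LD matrix for
  provenance and simulation, but the estimator ignores it. Multi-signal
  loci are fine-mapped once, not conditionally decomposed; their
  secondary signals dilute the primary PIP rather than receiving their
  own.
* **Numerics:** ABFs are computed in log space and normalized by
  max-subtraction, so z of any magnitude is safe. PIPs sum to 1 within
  1e-9 by construction.
* The **95% credible set** is the smallest prefix of variants in
  descending-PIP order (stable ties) whose PIPs reach 0.95. The
  high-confidence flag is PIP > 0.80 (strict); any threshold ≥ 0.5 can
  flag at most one variant per locus.

The closed form is cross-checked in the tests against numerical
quadrature of the Gaussian marginal likelihood.

## Ranking and classification

Ranks are dense (ties share a rank), 1 = highest PAR, assigned within
each ancestry; output order is (−PAR, variant id), so ranking is
permutation-invariant. The cross-ancestry matrix spans the union of
loci; absent cells mean the locus had no qualifying (significant) lead
variant in that ancestry; rows are ordered by descending mean of present
PARs. "Universal" is operationalized as top-k rank in ≥ m ancestries
(defaults k = 10, m = all, both exposed as flags) — a deliberately
explicit rule for a notion usually stated qualitatively. The three-way
universal/enriched/single scheme leaves one case undefined (a locus
present in several ancestries but top-k in none); it is labelled
`shared` rather than forced into `enriched` with an empty list.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions the pipeline is validated
under:

* **Single variants** are drawn from an allelic case-control model:
  control allele counts Binomial(2N_ctrl, p) at the population frequency
  (rare-disease approximation), case counts Binomial(2N_case, p_case)
  with p_case = OR·p / (1 + p(OR − 1)); β̂, se and the two-sided Wald p
  come from the sampled 2×2 table with Haldane–Anscombe 0.5 correction
  when a cell is zero. Reported EAF is the pooled sample frequency, as
  published summary statistics report it — this imports a small upward
  PAR bias (cases are over-represented relative to prevalence; ≈ +0.007
  at OR 1.3, RAF 0.3, 20k/20k), which is why recovery is validated to
  ±0.01 rather than to machine precision.
* **LD blocks** are simulated at the z-score level: z ~ MVN(Rλe_c, R)
  with R the AR(1) matrix ρ^|i−j| and λ the causal variant's expected z
  given its OR, RAF and sample sizes. Non-causal frequencies are drawn
  Uniform(0.05, 0.95). No individual genotypes exist.
* **Reporting orientation**: each record is emitted flipped
  (protective-looking) with probability 0.3 by default, so harmonization
  is always exercised.
* Default disease prevalence is 0.5%, in the range typical of the
  late-onset neurodegenerative diseases this kind of analysis targets.

Not emulated: genotype-level LD (so fine-mapping is validated under the
same RSS approximation it assumes), admixture and relatedness,
imputation error, cross-ancestry correlation of effect sizes, indels and
multi-allelic sites. Passing recovery tests therefore demonstrate the
pipeline's correctness under its own model assumptions, not robustness
to those real-data complications.

## Problem sizes used in validation

Chosen as the smallest sizes at which the statistical claims are
well-resolved: the Levin identity on a 99 × 10 (p, RR) grid at 1e-12;
rare-disease surrogate error on a 3 × 3 (p, OR) grid at 50,000
alleles/arm; PAR recovery over 200 studies of 20,000 cases / 20,000
controls at OR 1.3, RAF 0.3 (mean bias ≤ 0.01); fine-mapping recovery
over 100 loci of 20 variants, ρ = 0.7, causal expected z ≈ 8 (top PIP
for the causal variant in ≥ 95); harmonization contract over 10,000
random records; null calibration over 2,000 replicates at 2,000/2,000
(Kolmogorov–Smirnov uniformity, p > 0.01).

## I/O and determinism

Input tables are tab- or comma-delimited (auto-detected from the header
line); OR-bearing inputs are converted to β = ln OR on read, making β
the single internal effect scale. Rows violating invariants (EAF outside
(0,1), se ≤ 0, identical alleles, indels) are rejected individually; a
file where more than half the rows fail is rejected wholesale as
presumably mislabelled. All outputs are tab-delimited with floats at 6
significant digits and round-trip through the package's reader.
Coordinates are 1-based and build-agnostic; no liftover, no VCF parsing,
no multi-allelic support. The pipeline runner processes ancestries in
sorted label order and hashes inputs and configuration into its
manifest, so identical inputs give byte-identical artifacts. P-values
are floored at the smallest positive normal double so the (0, 1]
invariant survives arbitrarily large z. All simulation randomness
derives from a single integer seed through one `numpy` Generator.
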