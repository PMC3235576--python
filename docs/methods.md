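# Methods

## Scope and data model

The package operates on study-level counts, not individual genotypes:
the evidence unit is one study's case/control allele (and optionally
genotype) counts for one SNP, with study id, population label and
publication year. Population labels come from a closed vocabulary
(Caucasian, Asian, African, Hispanic, mixed, other); unknown labels are
coerced to "other" with a warning rather than rejected, because
stratified pooling must not silently drop evidence. When both allele
and genotype blocks are present they must agree (minor = 2·hom + het);
disagreement is a record-level error naming the row, never a silent
preference for one block.

## Random-effects meta-analysis

Per-study effects are allele-contrast log odds ratios with the usual
large-sample variance; a zero cell triggers the Haldane–Anscombe
correction (0.5 added to all four cells) and is flagged in the output.
Pooling is the classic DerSimonian–Laird method-of-moments estimator
with z-based (not t-based) confidence intervals, matching the original
formulation. τ² is floored at zero. I² is reported as a point estimate
only. The "all ethnic groups" result pools every study directly rather
than re-meta-analysing stratum summaries; strata with fewer than two
studies are reported as "n.a". Removing a study for sensitivity
analysis re-runs the same pooling code on the reduced set — there are
no incremental shortcuts that could drift from the full computation.

The minor allele is defined gene-wide from pooled control frequencies,
so the contrast direction is identical across studies of one SNP.
Genotype-based contrasts, haplotypes and meta-regression are out of
scope.

## Credibility grading

Grade boundaries follow the interim three-axis scheme: N minor must
*exceed* 1000 for amount grade A (exactly 1000 is B); I² of exactly 25
or 50 is B (A requires < 25). Grading is monotone by construction.

The protection-from-bias axis runs four checks:

- **Low OR**: `max(OR, 1/OR) < 1.15`. The screen is symmetric because
  protective alleles (OR ≈ 0.88) carry the same evidential weight as
  risk alleles. A lone low-OR flag caps the grade at B; it demonstrates
  fragility, not bias. A `strict_low_or` policy knob escalates it to C
  for users who want the literal reading.
- **First-study sensitivity**: the earliest-published study (ties by
  study id) is removed and the set re-pooled; losing significance
  (95% CI no longer excluding 1) flags the check. A single surviving
  study is judged by its own CI.
- **HWE sensitivity**: control groups whose exact conditional
  Hardy–Weinberg P < 0.05 are removed and the set re-pooled. The exact
  test (enumeration of the conditional heterozygote distribution given
  allele counts, summing all outcomes no more probable than the
  observed one) is used instead of the chi-square approximation because
  control groups can be small; it is valid at any counts and
  conservative by construction. Missing genotype blocks make this
  check unevaluable.
- **Small-study asymmetry**: Peters' test — weighted regression of the
  log OR on inverse total sample size, weights
  `1/(1/n_cases + 1/n_controls)` — at P < 0.10, requiring k ≥ 3. The
  Egger intercept test is available behind the same knob
  (`pub_bias_test="egger"`) but is not the default: for log odds
  ratios the estimated standard error is correlated with the effect,
  and in simulations under this package's own null conditions
  (well-powered equal-size studies, OR 2.0) the Egger test's measured
  size at nominal 0.10 was 0.29–0.57, rising as study sizes equalise.
  Peters' predictor is outcome-independent: measured size 0.05–0.07
  with varied study sizes, with power equal to Egger's (0.54 vs 0.54)
  against a significance-dependent retention filter (γ = 3). When all
  studies are the same size the Peters predictor is degenerate; the
  test then returns P = 1, because a small-study effect cannot
  manifest without a size axis. Note that funnel-asymmetry testing of
  any kind is uninformative in that design.

Demonstrated bias (either sensitivity failure, or asymmetry P below
threshold) grades C; an unevaluable check (missing genotypes, k < 3)
grades B ("important information missing"); otherwise A. Overall
credibility combines the three axes (A = "AAA"; any C ⇒ C; else B),
and genes are ranked by overall grade then ascending pooled P with a
lexical tie-break.

## Pathway stage

Annotations follow the true-path rule: every gene inherits all `is_a`
ancestors of its direct terms before testing. Only `is_a` edges are
honoured — the OBO dialect is deliberately minimal (id, name,
namespace, is_a, is_obsolete); `part_of` and cross-products are
non-goals. Over-representation is the upper-tail hypergeometric
probability; the Bonferroni multiplier counts only terms actually
tested (≥ 1 test gene, ≥ 2 background genes). Two distinct gene-count
knobs exist because the filters apply at different stages: terms need
≥ 2 test genes to be called significant, and slim groups need ≥ 3
distinct genes to be reported. The default significance threshold is
Bonferroni-adjusted P < 0.003 (strict), with raw P emitted alongside so
either reading is inspectable. Slim remapping returns the
*most-specific* slim ancestors (no other reachable slim term strictly
between); within a slim group a term whose test-gene set is nested in
another's collapses into the superset term, ties resolved by larger
background annotation count then lexical id. The three GO namespaces
are tested jointly.

## Synthetic data generator

The generator emulates the evidence structure behind a per-SNP
meta-analysis, not any particular cohort. Per study, a log OR is drawn
from Normal(ln OR_true, τ²); control genotypes are multinomial under an
inbreeding model (F > 0 bends controls away from HWE — cases are always
HWE at the case allele frequency implied by that study's OR, because
the bias axis inspects control groups only); allele counts are derived
as 2·hom + het, which makes control HWE testing meaningful. Publication
years are sequential from a configurable start year so "first study"
is well defined. An optional retention filter keeps study i with
probability `e^-γ + (1 − e^-γ)·sig_i`, where `sig_i` indicates the
study's own 95% CI excluding 1 — the only per-study significance
notion the pipeline defines.

Defaults describe a well-powered common-variant setting: 8 studies of
1000 cases/1000 controls, control MAF 0.30, true OR 1.2, τ² = 0.05, no
HWE violation, no filtering. One consequence worth knowing: with
studies this large the sampling variance (~0.004 on the log-OR scale)
is small, so τ² = 0.05 corresponds to I² ≈ 90% and a consistency grade
of C — I² is a *relative* measure and behaves exactly this way on
real mega-consortium data too.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, haplotypes, covariates, family-based designs, population
stratification within a label, or genotyping error beyond the
inbreeding-model HWE distortion. Tests passing on synthetic data
therefore validate the statistical machinery and its calibration, not
robustness to those real-data complications. There is no public
generative model for the underlying observational literature; the
simulation choices here are explicit stand-ins.

## Packaged fixtures

The package ships a transcription of a published 15-gene top list
(chromosome, N minor, quality string, per-stratum OR/CI) and nine
pathway term → gene lists, both checksum-verified at load. Two source
inconsistencies are stored as printed with a discrepancy flag rather
than resolved: the LDLR all-ethnic CI appears as 0.72–0.89 in the
table and 0.72–0.99 in the running text (both retained), and the TNF
all-ethnic entry prints a CI whose lower bound exceeds the OR (an
obvious typo, kept verbatim). For the pathway stage the printed gene
lists are embedded in a *synthetic* flat ontology (each term `is_a`
the biological-process root) over a synthetic 500-gene background
universe — large enough that every printed term clears the Bonferroni
threshold, since no historical annotation release is bundled. The
fixture pathway run validates the report path (propagation, testing,
correction, slimming, collapsing), not any historical GO release; a
literal reproduction of the original enrichment (which depended on a
2010 release and a proteome-scale background) is out of scope.

## Determinism and numerics

Every stochastic path takes an explicit integer seed
(`numpy.random.default_rng`); same config + seed gives byte-identical
output tables and an identical `report_hash` (stage timings are
recorded in the run report but excluded from the hash). Config hashes
exclude the output directory. The HWE exact test computes conditional
probabilities in log space and compares against the observed
probability with a `1 + 1e-12` relative tolerance to absorb float
rounding in the "as or more extreme" comparison. Two-sided pooled
P-values are clamped into (0, 1]. Degenerate inputs: monomorphic
control groups give HWE P = 1; a single study cannot be pooled or
bias-assessed (error); an empty case or control margin is an error;
strata with one study are skipped, mirroring "n.a" reporting.

## Problem sizes

The validation suites use 50 random pooling fixtures (1e-10 agreement
against direct-formula evaluation), 200 random HWE tables up to 500
individuals (exact-rational enumeration oracle), full hypergeometric
enumeration for all universes N ≤ 25, 500 replicates for parameter
recovery, 1000 for null CI coverage, 200 for bias-grade behaviour, and
2000 for HWE type-I error — sizes at which Monte-Carlo error is well
inside the asserted bands while the whole suite stays fast.
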