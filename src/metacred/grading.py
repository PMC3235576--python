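"""HuGENet interim credibility grading of cumulative association evidence.

Three axes are graded A/B/C per meta-analysis: amount of evidence (total
minor alleles in cases plus controls, "N minor"), consistency of
replication (the I^2 heterogeneity percentage), and protection from bias
(low summary OR, sensitivity to removing the first-published study or
HWE-violating control groups, and small-study/publication bias via
Egger's regression).  Overall credibility is A (strong) only with three
A grades, C (weak) with any C, else B (moderate).  Loci sharing a grade
are ordered by pooled P-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import lgamma

import numpy as np
import statsmodels.api as sm

from .io import StudyCounts
from .meta import MetaResult, StudyEffect, pool_dersimonian_laird, study_log_or

__all__ = [
    "BiasAssessment",
    "CredibilityGrade",
    "hwe_exact_test",
    "amount_grade",
    "consistency_grade",
    "egger_test",
    "peters_test",
    "assess_bias",
    "overall_credibility",
    "eligibility_filter",
    "select_best_snp",
    "rank_top_list",
]


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Exact conditional Hardy-Weinberg test on (hom_minor, het, hom_major).

    Conditions on the observed allele counts and sums the probability of
    every heterozygote count (same parity as the minor-allele total) whose
    conditional probability does not exceed that of the observed table.
    Returns 1.0 for monomorphic samples.  Valid at arbitrarily small
    counts, unlike the chi-square approximation.
    """
    hom_minor, het, hom_major = counts
    if min(hom_minor, het, hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom_minor + het + hom_major
    if n == 0:
        raise ValueError("empty sample")
    n_minor = 2 * hom_minor + het
    n_major = 2 * hom_major + het
    if n_minor == 0 or n_major == 0:
        return 1.0

    # log P(het = h | allele counts) up to the shared normalising constant
    def logp(h: int) -> float:
        a = (n_minor - h) // 2
        b = (n_major - h) // 2
        return h * math.log(2.0) - lgamma(a + 1) - lgamma(h + 1) - lgamma(b + 1)

    h_values = range(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logs = np.array([logp(h) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = np.exp(logp(het) - logs.max())
    obs /= np.sum(np.exp(logs - logs.max()))
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def amount_grade(n_minor: int) -> str:
    """Amount-of-evidence grade: A above 1000 minor alleles, C below 100."""
    if n_minor < 0:
        raise ValueError("n_minor must be non-negative")
    if n_minor > 1000:
        return "A"
    if n_minor >= 100:
        return "B"
    return "C"


def consistency_grade(i2: float) -> str:
    """Consistency grade from I^2: A below 25%, C above 50%, B between."""
    if not 0 <= i2 <= 100:
        raise ValueError("I^2 must lie in [0, 100]")
    if i2 < 25:
        return "A"
    if i2 <= 50:
        return "B"
    return "C"


def egger_test(effects: list[StudyEffect]) -> float:
    """Egger small-study-effect test: P for the intercept of the regression
    of standardised effect on precision.  Requires k >= 3.

    Beware: for log odds ratios the estimated SE is correlated with the
    effect, which inflates this test badly when study sizes are similar;
    :func:`peters_test` is the calibrated choice for allele-contrast data.
    """
    if len(effects) < 3:
        raise ValueError("Egger regression requires at least 3 studies")
    se = np.sqrt([e.var_log_or for e in effects])
    z = np.array([e.log_or for e in effects]) / se
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(z, x).fit()
    return float(fit.pvalues[0])


def peters_test(studies: list[StudyCounts]) -> float:
    """Peters small-study-effect test for log odds ratios.

    Weighted regression of the log OR on the inverse total (allele) sample
    size, weights ``1/(1/(a+b) + 1/(c+d))``; P is for the slope.  The
    predictor is outcome-independent, so the test keeps its nominal size
    for ORs where the Egger intercept test does not.  When all studies
    are the same size the predictor is degenerate and no small-study
    effect can manifest: returns 1.0.  Requires k >= 3.
    """
    if len(studies) < 3:
        raise ValueError("Peters regression requires at least 3 studies")
    y, x, w = [], [], []
    for s in studies:
        eff = study_log_or(s)
        n_case = s.case_minor + s.case_major
        n_ctrl = s.control_minor + s.control_major
        y.append(eff.log_or)
        x.append(1.0 / (n_case + n_ctrl))
        w.append(1.0 / (1.0 / n_case + 1.0 / n_ctrl))
    x = np.asarray(x)
    if np.ptp(x) <= 1e-12 * np.max(x):
        return 1.0
    fit = sm.WLS(np.asarray(y), sm.add_constant(x), weights=np.asarray(w)).fit()
    return float(fit.pvalues[1])


@dataclass(frozen=True)
class BiasAssessment:
    """The four bias checks and the resulting protection-from-bias grade.

    ``pub_bias_p`` is the small-study asymmetry P-value from the
    configured test (Peters by default), absent when k < 3.
    """

    low_or_flag: bool
    first_study_sensitivity: bool | None
    hwe_sensitivity: bool | None
    pub_bias_flag: bool | None
    pub_bias_p: float | None
    grade: str


@dataclass(frozen=True)
class CredibilityGrade:
    """Per-axis letters, overall credibility and the 3-letter quality string."""

    amount: str
    consistency: str
    bias: str
    overall: str
    quality_string: str


def _significant_after_drop(
    kept: list[StudyCounts], n_minor: int
) -> bool:
    """Significance of the re-pooled evidence after excluding studies.

    Re-pooling is the same DerSimonian-Laird computation on the reduced
    set; a single surviving study is judged by its own 95% CI, an empty
    set carries no significant evidence.
    """
    if not kept:
        return False
    if len(kept) == 1:
        return study_log_or(kept[0]).significant
    return pool_dersimonian_laird(
        [study_log_or(s) for s in kept], n_minor=n_minor
    ).significant


def assess_bias(
    meta: MetaResult,
    studies: list[StudyCounts],
    *,
    low_or_threshold: float = 1.15,
    hwe_alpha: float = 0.05,
    pub_bias_alpha: float = 0.10,
    pub_bias_test: str = "peters",
    strict_low_or: bool = False,
) -> BiasAssessment:
    """Run the four protection-from-bias checks for one meta-analysis.

    Demonstrated bias (loss of significance after excluding the
    first-published study or HWE-violating control groups, or a
    small-study asymmetry P below ``pub_bias_alpha``) grades C.  A check
    that cannot be run (no genotype data for the HWE screen, fewer than
    3 studies for the asymmetry test) leaves important information
    missing and caps the grade at B.  ``pub_bias_test`` selects the
    asymmetry test: "peters" (default, calibrated for ORs) or "egger".
    The low-OR screen is symmetric (``max(OR, 1/OR) < low_or_threshold``)
    so protective alleles are treated like risk alleles; on its own it
    caps the grade at B unless ``strict_low_or`` demands C.
    """
    if len(studies) < 2:
        raise ValueError("bias assessment requires >= 2 studies")
    low_or = max(meta.pooled_or, 1.0 / meta.pooled_or) < low_or_threshold

    ordered = sorted(studies, key=lambda s: (s.year, s.study_id))
    rest = ordered[1:]
    first_sens = meta.significant and not _significant_after_drop(
        rest, sum(s.case_minor + s.control_minor for s in rest)
    )

    hwe_sens: bool | None
    if all(s.has_genotypes for s in studies):
        kept = [
            s for s in studies if hwe_exact_test(s.control_genotypes) >= hwe_alpha
        ]
        if len(kept) == len(studies):
            hwe_sens = False
        else:
            hwe_sens = meta.significant and not _significant_after_drop(
                kept, sum(s.case_minor + s.control_minor for s in kept)
            )
    else:
        hwe_sens = None

    pub_p: float | None
    pub_flag: bool | None
    if len(studies) >= 3:
        if pub_bias_test == "peters":
            pub_p = peters_test(studies)
        elif pub_bias_test == "egger":
            pub_p = egger_test([study_log_or(s) for s in studies])
        else:
            raise ValueError(f"unknown pub_bias_test {pub_bias_test!r}")
        pub_flag = pub_p < pub_bias_alpha
    else:
        pub_p = None
        pub_flag = None

    if first_sens or hwe_sens or pub_flag or (strict_low_or and low_or):
        grade = "C"
    elif low_or or hwe_sens is None or pub_flag is None:
        grade = "B"
    else:
        grade = "A"
    return BiasAssessment(
        low_or_flag=low_or,
        first_study_sensitivity=first_sens,
        hwe_sensitivity=hwe_sens,
        pub_bias_flag=pub_flag,
        pub_bias_p=pub_p,
        grade=grade,
    )


def overall_credibility(amount: str, consistency: str, bias: str) -> CredibilityGrade:
    """Combine the three axis letters into overall epidemiologic credibility.

    A (strong) requires three A grades; any C grades C (weak); otherwise
    B (moderate).  The quality string concatenates the axes in
    amount/consistency/bias order.
    """
    axes = (amount, consistency, bias)
    for g in axes:
        if g not in {"A", "B", "C"}:
            raise ValueError(f"invalid axis grade {g!r}")
    if axes == ("A", "A", "A"):
        overall = "A"
    elif "C" in axes:
        overall = "C"
    else:
        overall = "B"
    return CredibilityGrade(amount, consistency, bias, overall, "".join(axes))


def eligibility_filter(
    studies_by_snp: dict[str, list[StudyCounts]],
    *,
    min_maf: float = 0.01,
    min_studies: int = 4,
) -> dict[str, list[StudyCounts]]:
    """Keep SNPs with pooled control MAF above ``min_maf`` and at least
    ``min_studies`` independent samples."""
    eligible = {}
    for snp, studies in studies_by_snp.items():
        if len(studies) < min_studies:
            continue
        minor = sum(s.control_minor for s in studies)
        total = minor + sum(s.control_major for s in studies)
        if total > 0 and minor / total > min_maf:
            eligible[snp] = studies
    return eligible


def select_best_snp(
    gene_results: dict[str, list[MetaResult]],
) -> tuple[str, MetaResult] | None:
    """Pick a gene's best SNP: among SNPs significant in any stratum, the
    one with the smallest all-stratum pooled P (ties broken by rsID).

    Returns None when no SNP is significant, in which case the gene does
    not enter the top list.
    """
    candidates = []
    for snp in sorted(gene_results):
        results = gene_results[snp]
        if not any(r.significant for r in results):
            continue
        overall = [r for r in results if r.stratum == "all"]
        primary = overall[0] if overall else min(results, key=lambda r: r.p_value)
        candidates.append((primary.p_value, snp, primary))
    if not candidates:
        return None
    _, snp, primary = min(candidates, key=lambda c: (c[0], c[1]))
    return snp, primary


def rank_top_list(
    graded: list[tuple[str, CredibilityGrade, MetaResult]],
) -> list[tuple[str, CredibilityGrade, MetaResult]]:
    """Order the top list: grade A before B before C, then ascending P."""
    order = {"A": 0, "B": 1, "C": 2}
    return sorted(graded, key=lambda g: (order[g[1].overall], g[2].p_value, g[0]))
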