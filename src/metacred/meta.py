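"""Allele-contrast effects and DerSimonian-Laird random-effects pooling.

Each study contributes a 2x2 table (minor vs major allele, cases vs
controls).  The per-study effect is the log odds ratio with the usual
large-sample variance ``1/a + 1/b + 1/c + 1/d``; zero cells receive the
Haldane-Anscombe 0.5 continuity correction.  Studies are pooled with the
DerSimonian-Laird method-of-moments estimator of the between-study
variance tau^2, z-based confidence intervals, Cochran's Q and the I^2
heterogeneity percentage.  Results are reported per population stratum
and for all studies combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import StudyCounts

__all__ = [
    "StudyEffect",
    "MetaResult",
    "study_log_or",
    "pool_dersimonian_laird",
    "heterogeneity_i2",
    "stratified_meta",
]

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class StudyEffect:
    """Log odds ratio and sampling variance for one study."""

    log_or: float
    var_log_or: float
    corrected: bool = False
    study_id: str = ""
    population: str = "other"
    year: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError(f"{self.study_id}: non-finite log OR")
        if not (self.var_log_or > 0 and math.isfinite(self.var_log_or)):
            raise ValueError(f"{self.study_id}: variance must be positive and finite")

    @property
    def significant(self) -> bool:
        """True when the study's own 95% CI excludes OR = 1."""
        half = Z975 * math.sqrt(self.var_log_or)
        return abs(self.log_or) > half


@dataclass(frozen=True)
class MetaResult:
    """Pooled random-effects summary for one SNP in one stratum."""

    pooled_or: float
    ci_low: float
    ci_high: float
    p_value: float
    q_stat: float
    tau2: float
    i2: float
    k: int
    n_minor: int
    stratum: str = "all"

    @property
    def significant(self) -> bool:
        """True when the pooled 95% CI excludes OR = 1."""
        return self.ci_low > 1.0 or self.ci_high < 1.0


def study_log_or(counts: StudyCounts) -> StudyEffect:
    """Per-study allele-contrast log OR and variance from the 2x2 table.

    Any zero cell triggers the Haldane-Anscombe correction (add 0.5 to all
    four cells) and sets the ``corrected`` flag.  A table with no cases or
    no controls carries no contrast and is an error.
    """
    a, b = counts.case_minor, counts.case_major
    c, d = counts.control_minor, counts.control_major
    if a + b == 0 or c + d == 0:
        raise ValueError(f"{counts.study_id}: empty case or control margin")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
    else:
        corrected = False
    log_or = math.log(a * d / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return StudyEffect(
        log_or=log_or,
        var_log_or=var,
        corrected=corrected,
        study_id=counts.study_id,
        population=counts.population,
        year=counts.year,
    )


def heterogeneity_i2(q_stat: float, k: int) -> float:
    """I^2 heterogeneity percentage: max(0, (Q - (k-1)) / Q) * 100."""
    if k < 2:
        raise ValueError("I^2 requires at least two studies")
    if q_stat < 0:
        raise ValueError("Q must be non-negative")
    if q_stat == 0:
        return 0.0
    return max(0.0, (q_stat - (k - 1)) / q_stat) * 100.0


def pool_dersimonian_laird(
    effects: list[StudyEffect], *, n_minor: int = 0, stratum: str = "all"
) -> MetaResult:
    """Pool study effects with the DerSimonian-Laird random-effects model.

    Fixed-effect weights ``w_i = 1/v_i`` give Cochran's
    ``Q = sum w_i (y_i - y_FE)^2``; the method-of-moments between-study
    variance is ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))``;
    random-effects weights ``1/(v_i + tau2)`` give the pooled estimate,
    its z-based 95% CI and two-sided normal P.  Results are exponentiated
    to the OR scale.
    """
    k = len(effects)
    if k < 2:
        raise ValueError(
            "DerSimonian-Laird pooling needs >= 2 studies; "
            "use the single study's own effect instead"
        )
    y = np.array([e.log_or for e in effects])
    v = np.array([e.var_log_or for e in effects])
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = math.sqrt(1.0 / float(np.sum(w_re)))
    z = mu / se
    # two-sided normal P, guarded into (0, 1]
    p = min(1.0, max(float(2.0 * norm.sf(abs(z))), 5e-324))
    return MetaResult(
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - Z975 * se),
        ci_high=math.exp(mu + Z975 * se),
        p_value=p,
        q_stat=q,
        tau2=tau2,
        i2=heterogeneity_i2(q, k),
        k=k,
        n_minor=n_minor,
        stratum=stratum,
    )


def _total_n_minor(studies: list[StudyCounts]) -> int:
    return sum(s.case_minor + s.control_minor for s in studies)


def stratified_meta(studies: list[StudyCounts]) -> list[MetaResult]:
    """Pool one SNP per population stratum plus the combined "all" stratum.

    Strata with fewer than two studies are omitted (reported as "n.a"
    downstream); the "all" stratum pools every study directly.  N minor is
    the total minor-allele count over cases and controls in the stratum.
    """
    snps = {s.snp for s in studies}
    if len(snps) != 1:
        raise ValueError(f"stratified_meta expects one SNP, got {sorted(snps)}")
    results = []
    strata = sorted({s.population for s in studies})
    for pop in strata:
        sub = [s for s in studies if s.population == pop]
        if len(sub) < 2:
            continue
        results.append(
            pool_dersimonian_laird(
                [study_log_or(s) for s in sub],
                n_minor=_total_n_minor(sub),
                stratum=pop,
            )
        )
    if len(studies) >= 2:
        results.append(
            pool_dersimonian_laird(
                [study_log_or(s) for s in studies],
                n_minor=_total_n_minor(studies),
                stratum="all",
            )
        )
    return results
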