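"""Synthetic multi-study case-control genotype data with known ground truth.

The generator emulates the evidence structure behind a per-SNP
meta-analysis: each study draws its own log odds ratio from
``Normal(ln(true_or), tau2)``, control genotypes from an inbreeding-model
multinomial (``F`` > 0 bends controls away from Hardy-Weinberg
equilibrium), and case genotypes under HWE at the case allele frequency
implied by the study's OR.  Genotypes are the primitive unit; allele
counts are derived as ``2*hom + het``, so downstream HWE checks on
controls are meaningful.  An optional significance-dependent retention
filter emulates publication bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import AnnotationSet, OntologyDAG, StudyCounts
from .meta import study_log_or

__all__ = [
    "SimulationConfig",
    "simulate_gene_studies",
    "apply_publication_filter",
    "simulate_annotation_universe",
]

ROOT_TERM = "GO:0008150"  # biological_process


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated gene/SNP.

    Defaults describe a well-powered common-variant meta-analysis: eight
    studies of 1000 cases and 1000 controls each, a modest pooled OR of
    1.2 with between-study variance tau2 = 0.05, control minor-allele
    frequency 0.30, controls in exact HWE, and no publication filtering.
    """

    true_or: float = 1.2
    tau2: float = 0.05
    k_studies: int = 8
    n_cases: int | list[int] = 1000
    n_controls: int | list[int] = 1000
    control_maf: float = 0.3
    hwe_inbreeding: float = 0.0
    pub_bias_gamma: float = 0.0
    seed: int = 0
    gene: str = "GENE1"
    snp: str = "rs0000001"
    population: str = "Caucasian"
    start_year: int = 1995

    def __post_init__(self) -> None:
        if not (math.isfinite(self.true_or) and self.true_or > 0):
            raise ValueError("true_or must be a positive real")
        if not (math.isfinite(self.tau2) and self.tau2 >= 0):
            raise ValueError("tau2 must be non-negative")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if not (0 < self.control_maf <= 0.5):
            raise ValueError("control_maf must lie in (0, 0.5]")
        if not (0 <= self.hwe_inbreeding < 1):
            raise ValueError("hwe_inbreeding must lie in [0, 1)")
        if self.pub_bias_gamma < 0:
            raise ValueError("pub_bias_gamma must be >= 0")
        for n in (*self.per_study("n_cases"), *self.per_study("n_controls")):
            if n < 1:
                raise ValueError("per-study sample sizes must be >= 1")

    def per_study(self, which: str) -> list[int]:
        v = getattr(self, which)
        if isinstance(v, int):
            return [v] * self.k_studies
        if len(v) != self.k_studies:
            raise ValueError(f"{which} list must have k_studies entries")
        return list(v)


def _genotype_freqs(p: float, f: float) -> np.ndarray:
    """(hom_minor, het, hom_major) frequencies under inbreeding coefficient f."""
    q = 1.0 - p
    return np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])


def simulate_gene_studies(config: SimulationConfig) -> list[StudyCounts]:
    """Draw per-study genotype tables for one SNP; deterministic given seed.

    Study i's log OR is theta_i ~ Normal(ln true_or, tau2); the case
    minor-allele frequency follows from the control frequency p via
    ``p_case = p*e^theta / (1 - p + p*e^theta)``.  Controls are multinomial
    at the inbreeding-model genotype frequencies; cases are HWE at p_case.
    Publication years are assigned sequentially from ``start_year`` so the
    "first study" is well defined downstream.
    """
    rng = np.random.default_rng(config.seed)
    n_cases = config.per_study("n_cases")
    n_controls = config.per_study("n_controls")
    p = config.control_maf
    studies = []
    for i in range(config.k_studies):
        theta = rng.normal(math.log(config.true_or), math.sqrt(config.tau2))
        p_case = p * math.exp(theta) / (1 - p + p * math.exp(theta))
        ctrl = rng.multinomial(
            n_controls[i], _genotype_freqs(p, config.hwe_inbreeding)
        )
        case = rng.multinomial(n_cases[i], _genotype_freqs(p_case, 0.0))
        studies.append(
            StudyCounts(
                gene=config.gene,
                snp=config.snp,
                study_id=f"{config.gene}_s{i + 1:02d}",
                population=config.population,
                year=config.start_year + i,
                case_minor=int(2 * case[0] + case[1]),
                case_major=int(2 * case[2] + case[1]),
                control_minor=int(2 * ctrl[0] + ctrl[1]),
                control_major=int(2 * ctrl[2] + ctrl[1]),
                case_hom_minor=int(case[0]),
                case_het=int(case[1]),
                case_hom_major=int(case[2]),
                control_hom_minor=int(ctrl[0]),
                control_het=int(ctrl[1]),
                control_hom_major=int(ctrl[2]),
            )
        )
    if config.pub_bias_gamma > 0:
        # spawn a fresh stream so retention noise is decoupled from counts
        studies = apply_publication_filter(
            studies, config.pub_bias_gamma, int(rng.integers(2**31))
        )
    return studies


def apply_publication_filter(
    studies: list[StudyCounts], gamma: float, seed: int
) -> list[StudyCounts]:
    """Retain each study with probability ``e^-gamma + (1-e^-gamma)*sig``.

    ``sig`` is 1 when the study's own 95% CI excludes OR = 1.  gamma = 0
    retains everything; large gamma keeps only individually significant
    studies.  Deterministic given seed.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return list(studies)
    rng = np.random.default_rng(seed)
    base = math.exp(-gamma)
    kept = []
    for s in studies:
        sig = 1.0 if study_log_or(s).significant else 0.0
        if rng.uniform() < min(1.0, base + (1 - base) * sig):
            kept.append(s)
    return kept


def simulate_annotation_universe(
    n_background: int,
    planted_terms: list[tuple[str, int]],
    test_genes: list[str],
    seed: int,
    *,
    n_decoy_terms: int = 5,
    background_rate: float = 0.05,
) -> tuple[AnnotationSet, OntologyDAG]:
    """Build a toy ontology + annotations where planted terms are enriched.

    The universe holds ``n_background`` genes including the test genes.
    Each planted ``(term_id, gene_count)`` is annotated to test genes
    first, then to random background genes until ``gene_count`` is
    reached, so the term is over-represented in the test set.  Decoy
    terms are annotated uniformly at ``background_rate``.  The DAG is the
    planted and decoy terms under a single biological_process root.
    """
    ids = [t for t, _ in planted_terms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate planted term ids")
    if len(test_genes) > n_background:
        raise ValueError("test set larger than background universe")
    for term, count in planted_terms:
        if count > n_background:
            raise ValueError(f"{term}: gene_count exceeds universe size")
    rng = np.random.default_rng(seed)
    filler = [f"BG{i:05d}" for i in range(n_background - len(test_genes))]
    universe = list(test_genes) + filler
    ann: dict[str, set[str]] = {}
    for term, count in planted_terms:
        targets = list(test_genes[:count])
        if count > len(test_genes):
            extra = rng.choice(filler, size=count - len(test_genes), replace=False)
            targets += [str(g) for g in extra]
        for g in targets:
            ann.setdefault(g, set()).add(term)
    terms: dict[str, tuple[str, str]] = {
        ROOT_TERM: ("biological_process", "biological_process")
    }
    edges = []
    for term, _ in planted_terms:
        terms[term] = (term, "biological_process")
        edges.append((term, ROOT_TERM))
    for j in range(n_decoy_terms):
        decoy = f"GO:99000{j:02d}"
        terms[decoy] = (decoy, "biological_process")
        edges.append((decoy, ROOT_TERM))
        for g in universe:
            if rng.uniform() < background_rate:
                ann.setdefault(g, set()).add(decoy)
    return AnnotationSet(ann, set(universe)), OntologyDAG(terms, edges)
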