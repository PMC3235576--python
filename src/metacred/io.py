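"""Readers, writers and validated domain types for all on-disk artifacts.

Study-level evidence travels as TSV tables of per-study allele (and
optionally genotype) counts; ontologies as a minimal OBO 1.2 dialect
(``id``, ``name``, ``namespace``, ``is_a``, ``is_obsolete`` only);
annotations as two-column TSV or a GAF 2.x subset (columns 3 and 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "POPULATIONS",
    "StudyCounts",
    "AnnotationSet",
    "OntologyDAG",
    "StudyTableError",
    "read_study_table",
    "write_study_table",
    "read_obo_subset",
    "read_annotations",
    "write_annotations",
]

#: Closed population vocabulary; unknown labels map to "other" with a warning.
POPULATIONS = ("Caucasian", "Asian", "African", "Hispanic", "mixed", "other")

ALLELE_COLUMNS = ["case_minor", "case_major", "control_minor", "control_major"]
GENOTYPE_COLUMNS = [
    "case_hom_minor",
    "case_het",
    "case_hom_major",
    "control_hom_minor",
    "control_het",
    "control_hom_major",
]
STUDY_COLUMNS = ["gene", "snp", "study_id", "population", "year"] + ALLELE_COLUMNS


class StudyTableError(ValueError):
    """Raised for malformed study tables; message names the offending row."""


@dataclass(frozen=True)
class StudyCounts:
    """One study's case/control counts for one SNP (allele contrast unit).

    Allele counts are the authoritative 2x2 table (minor vs major allele in
    cases vs controls).  The genotype block is optional but required for
    Hardy-Weinberg checks on controls; when present it must be consistent
    with the allele counts (minor = 2*hom_minor + het on each arm).
    """

    gene: str
    snp: str
    study_id: str
    population: str
    year: int
    case_minor: int
    case_major: int
    control_minor: int
    control_major: int
    case_hom_minor: int | None = None
    case_het: int | None = None
    case_hom_major: int | None = None
    control_hom_minor: int | None = None
    control_het: int | None = None
    control_hom_major: int | None = None

    def __post_init__(self) -> None:
        for col in ALLELE_COLUMNS:
            v = getattr(self, col)
            if v < 0:
                raise StudyTableError(f"{self.study_id}/{self.snp}: negative {col}={v}")
        if self.population not in POPULATIONS:
            warnings.warn(
                f"unknown population label {self.population!r}; coerced to 'other'",
                stacklevel=2,
            )
            object.__setattr__(self, "population", "other")
        geno = [getattr(self, c) for c in GENOTYPE_COLUMNS]
        present = [g is not None for g in geno]
        if any(present):
            if not all(present):
                raise StudyTableError(
                    f"{self.study_id}/{self.snp}: partial genotype block"
                )
            if any(g < 0 for g in geno):
                raise StudyTableError(
                    f"{self.study_id}/{self.snp}: negative genotype count"
                )
            self._check_consistency()

    def _check_consistency(self) -> None:
        pairs = [
            ("case", self.case_minor, self.case_major,
             self.case_hom_minor, self.case_het, self.case_hom_major),
            ("control", self.control_minor, self.control_major,
             self.control_hom_minor, self.control_het, self.control_hom_major),
        ]
        for arm, minor, major, hom_minor, het, hom_major in pairs:
            if minor != 2 * hom_minor + het or major != 2 * hom_major + het:
                raise StudyTableError(
                    f"{self.study_id}/{self.snp}: {arm} allele counts "
                    f"({minor}, {major}) inconsistent with genotypes "
                    f"({hom_minor}, {het}, {hom_major})"
                )

    @property
    def has_genotypes(self) -> bool:
        return self.control_het is not None

    @property
    def control_genotypes(self) -> tuple[int, int, int]:
        """Control (hom_minor, het, hom_major); requires the genotype block."""
        if not self.has_genotypes:
            raise ValueError(f"{self.study_id}: no genotype block")
        return (self.control_hom_minor, self.control_het, self.control_hom_major)


def read_study_table(path) -> list[StudyCounts]:
    """Read a study TSV, validating every record.

    Raises :class:`StudyTableError` naming the 1-based data row for any
    record violating the allele/genotype consistency invariant; missing
    mandatory columns are a hard error.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"gene": str, "snp": str, "study_id": str}
    )
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise StudyTableError(f"{path}: missing columns {missing}")
    has_geno = all(c in df.columns for c in GENOTYPE_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {c: getattr(row, c) for c in STUDY_COLUMNS}
        kwargs["year"] = int(kwargs["year"])
        for c in ALLELE_COLUMNS:
            kwargs[c] = int(kwargs[c])
        if has_geno:
            for c in GENOTYPE_COLUMNS:
                v = getattr(row, c)
                kwargs[c] = None if pd.isna(v) else int(v)
        try:
            records.append(StudyCounts(**kwargs))
        except StudyTableError as exc:
            raise StudyTableError(f"{path} row {i}: {exc}") from None
    return records


def write_study_table(studies: Iterable[StudyCounts], path) -> None:
    """Write studies as TSV; genotype columns included iff any study has them."""
    studies = list(studies)
    cols = list(STUDY_COLUMNS)
    if any(s.has_genotypes for s in studies):
        cols += GENOTYPE_COLUMNS
    df = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in studies], columns=cols)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationSet:
    """Gene -> GO-term assignments over a fixed background universe."""

    annotations: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        stray = set(self.annotations) - self.background
        if stray:
            raise ValueError(f"annotated genes outside background universe: {sorted(stray)[:5]}")

    def genes_for(self, term: str) -> set[str]:
        return {g for g, ts in self.annotations.items() if term in ts}

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out


class OntologyDAG:
    """GO-subset ontology: ``is_a`` edges child -> parent, acyclic.

    Obsolete terms are excluded from the graph and from traversal.
    """

    def __init__(self, terms: Mapping[str, tuple[str, str]],
                 edges: Iterable[tuple[str, str]]):
        self.terms = dict(terms)
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.terms)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise ValueError(f"is_a edge endpoint {endpoint!r} is not a known term")
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"cyclic is_a chain: {cycle}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def name(self, term: str) -> str:
        return self.terms[term][0]

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of *term* (term itself excluded)."""
        return nx.descendants(self.graph, term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))


def read_obo_subset(path) -> OntologyDAG:
    """Parse an OBO 1.2 file honoring only id/name/namespace/is_a/is_obsolete.

    Other stanza tags (``relationship:``, xrefs, defs) are ignored; obsolete
    terms never enter the graph; a cyclic is_a chain is a hard error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str]] = []
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            # obonet may emit edges to undeclared stubs; declare them
            terms.setdefault(parent, (parent, ""))
            edges.append((child, parent))
    return OntologyDAG(terms, edges)


def read_annotations(path, background: set[str] | None = None) -> AnnotationSet:
    """Read gene->term annotations from 2-column TSV or a GAF 2.x subset.

    GAF lines (detected by ``!`` headers or >=15 columns) contribute columns
    3 (symbol) and 5 (term id); everything else in the line is ignored.  The
    background universe defaults to the annotated genes themselves.
    """
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:  # GAF 2.x
                gene, term = parts[2], parts[4]
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
            else:
                raise ValueError(f"{path}: unparseable annotation line {line!r}")
            if gene == "gene" and term.startswith("term"):
                continue  # optional header
            ann.setdefault(gene, set()).add(term)
    universe = set(background) if background is not None else set(ann)
    return AnnotationSet(ann, universe | set(ann))


def write_annotations(annset: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annset.annotations):
            for term in sorted(annset.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
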