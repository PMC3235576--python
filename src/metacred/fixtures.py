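"""Packaged worked-example fixtures: the top-gene table and pathway lists.

The package ships a transcription of a published top-gene table (gene,
chromosome, N minor, HuGENet quality string, per-stratum OR/CI) and the
nine shared-pathway term -> gene lists selected from it.  File integrity
is enforced with stored SHA-256 checksums.  ``fixture_enrichment_inputs``
embeds the pathway lists in a synthetic flat ontology and background
universe so the whole enrichment/reporting path can be exercised on them.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from importlib import resources

from .io import AnnotationSet, OntologyDAG

__all__ = [
    "TopGeneRecord",
    "PathwayTerm",
    "load_reference_fixtures",
    "load_blacklist",
    "fixture_enrichment_inputs",
    "write_fixture_files",
]

ROOT_TERM = "GO:0008150"
FIXTURE_UNIVERSE_SIZE = 500  # synthetic stand-in for a proteome-scale background

_OR_RE = re.compile(r"([\d.]+)\s*\(([\d.]+)[-–]([\d.]+)\)")


@dataclass(frozen=True)
class TopGeneRecord:
    """One top-gene row: quality string plus per-stratum OR (95% CI).

    OR entries are ``(or, ci_low, ci_high)`` or None for "n.a" strata.
    ``or_all_alt`` holds a conflicting value printed elsewhere in the
    source for the same quantity; ``discrepant`` flags such rows.
    """

    gene: str
    chromosome: str
    n_minor: int
    quality: str
    or_caucasian: tuple[float, float, float] | None
    or_asian: tuple[float, float, float] | None
    or_all: tuple[float, float, float] | None
    or_all_alt: tuple[float, float, float] | None = None

    @property
    def discrepant(self) -> bool:
        return self.or_all_alt is not None


@dataclass(frozen=True)
class PathwayTerm:
    term_id: str
    term_name: str
    genes: tuple[str, ...]


def _data_text(name: str) -> str:
    ref = resources.files("metacred.data") / name
    raw = ref.read_bytes()
    checksums = json.loads(
        (resources.files("metacred.data") / "checksums.json").read_text()
    )
    digest = hashlib.sha256(raw).hexdigest()
    if digest != checksums[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupt: sha256 {digest} != {checksums[name]}"
        )
    return raw.decode()


def _parse_or(cell: str) -> tuple[float, float, float] | None:
    cell = cell.strip()
    if not cell or cell == "n.a":
        return None
    m = _OR_RE.fullmatch(cell)
    if not m:
        raise ValueError(f"unparseable OR cell {cell!r}")
    return tuple(float(g) for g in m.groups())


def load_reference_fixtures() -> tuple[list[TopGeneRecord], list[PathwayTerm]]:
    """Load the packaged top-gene table and pathway lists (checksum-verified)."""
    records = []
    lines = _data_text("top_genes.tsv").splitlines()
    for line in lines[1:]:
        parts = (line.split("\t") + [""] * 8)[:8]
        records.append(
            TopGeneRecord(
                gene=parts[0],
                chromosome=parts[1],
                n_minor=int(parts[2]),
                quality=parts[3],
                or_caucasian=_parse_or(parts[4]),
                or_asian=_parse_or(parts[5]),
                or_all=_parse_or(parts[6]),
                or_all_alt=_parse_or(parts[7]),
            )
        )
    pathways = []
    for line in _data_text("pathways.tsv").splitlines()[1:]:
        term_id, name, genes = line.split("\t")
        pathways.append(PathwayTerm(term_id, name, tuple(genes.split(","))))
    return records, pathways


def load_blacklist() -> set[str]:
    """Packaged names of nonspecific terms excluded from pathway reports."""
    return {
        line.strip()
        for line in _data_text("nonspecific.txt").splitlines()
        if line.strip()
    }


def fixture_enrichment_inputs() -> tuple[
    set[str], AnnotationSet, OntologyDAG, set[str]
]:
    """Enrichment inputs reconstructed from the packaged pathway lists.

    Returns ``(test_genes, annotations, dag, slim_terms)``: the top genes
    as test set, their printed term memberships as annotations inside a
    synthetic background universe of ``FIXTURE_UNIVERSE_SIZE`` genes, a
    flat ontology (each pathway term is_a the biological_process root)
    and the pathway terms themselves as the slim.
    """
    top_genes, pathways = load_reference_fixtures()
    test_genes = {r.gene for r in top_genes}
    ann: dict[str, set[str]] = {}
    terms = {ROOT_TERM: ("biological_process", "biological_process")}
    edges = []
    for p in pathways:
        terms[p.term_id] = (p.term_name, "biological_process")
        edges.append((p.term_id, ROOT_TERM))
        for g in p.genes:
            ann.setdefault(g, set()).add(p.term_id)
    filler = {f"BG{i:05d}" for i in range(FIXTURE_UNIVERSE_SIZE - len(test_genes))}
    universe = test_genes | filler
    dag = OntologyDAG(terms, edges)
    slim = {p.term_id for p in pathways}
    return test_genes, AnnotationSet(ann, universe), dag, slim


def write_fixture_files(outdir) -> list[str]:
    """Write the packaged fixtures and fixture-mode inputs to ``outdir``.

    Emits the top-gene table, pathway lists, nonspecific-term blacklist,
    plus OBO/annotation/slim/test-gene files for the synthetic fixture
    universe.  Returns the written file names.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ["top_genes.tsv", "pathways.tsv", "nonspecific.txt"]:
        (outdir / name).write_text(_data_text(name))
        written.append(name)
    test_genes, annset, dag, slim = fixture_enrichment_inputs()
    with open(outdir / "fixture.obo", "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            name, ns = dag.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {ns}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.name(parent)}\n")
    with open(outdir / "fixture_annotations.tsv", "w") as fh:
        for gene in sorted(annset.annotations):
            for term in sorted(annset.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
    (outdir / "fixture_universe.txt").write_text(
        "\n".join(sorted(annset.background)) + "\n"
    )
    (outdir / "fixture_test_genes.txt").write_text(
        "\n".join(sorted(test_genes)) + "\n"
    )
    (outdir / "fixture_slim.txt").write_text("\n".join(sorted(slim)) + "\n")
    written += [
        "fixture.obo",
        "fixture_annotations.tsv",
        "fixture_universe.txt",
        "fixture_test_genes.txt",
        "fixture_slim.txt",
    ]
    return written
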