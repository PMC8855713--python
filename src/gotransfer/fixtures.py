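"""Deterministic generators for toy input files in all five formats the
pipeline consumes: OBO ontology, GAF reference annotations, pfam2go
mapping, DIAMOND outfmt-6 hits and hmmscan tblout hits.

The generated corpus is a miniature of the real study setting — a
three-namespace GO DAG, a reference proteome with a tunable IEA /
curated evidence mix, and query proteins hitting known subjects with
log-uniform e-values (so -log10 weight contributions are uniform and
easy to check by hand).  Accessions live in reserved test ranges
(Q0TESTxx proteins, PF999xx families, GO:09xxxxx terms) so they can
never collide with real identifiers.  The same spec and seed always
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import random
from dataclasses import dataclass
from pathlib import Path

from .ontology import NAMESPACES

_NS_BASE = {
    "biological_process": 910000,
    "molecular_function": 920000,
    "cellular_component": 930000,
}
_NS_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}
_EVIDENCE_CURATED = ("EXP", "IDA", "TAS")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus.

    ``evidence_mix`` is the fraction of GAF records carrying the IEA
    code; the default leans heavily towards IEA because uncurated
    electronic annotations dominate real GOA releases (which is what
    makes the evidence ratio P exceed 1).  ``evalue_range`` bounds the log-uniform e-value draw for
    regular hits (two edge-case hits — one above the e<=1 filter, one
    exact 0.0 underflow — are always present among the protein hits).
    """

    n_terms: int = 8
    dag_shape: str = "random"  # chain | diamond | random
    edge_prob: float = 0.3
    n_reference_proteins: int = 6
    evidence_mix: float = 0.8
    n_queries: int = 3
    hits_per_query: int = 4
    domain_hits_per_query: int = 2
    evalue_range: tuple[float, float] = (1e-50, 1e-2)
    n_families: int = 3
    seed: int = 0
    namespaces: tuple[str, ...] = NAMESPACES

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2 per namespace")
        if self.dag_shape not in ("chain", "diamond", "random"):
            raise ValueError(f"unknown dag_shape {self.dag_shape!r}")
        if self.dag_shape == "diamond" and self.n_terms < 4:
            raise ValueError("diamond shape needs n_terms >= 4")
        if self.n_queries * self.hits_per_query < 2:
            raise ValueError("need at least 2 protein hits for the edge-case lines")


def _go_id(namespace: str, index: int) -> str:
    return f"GO:{_NS_BASE[namespace] + index:07d}"


def _namespace_edges(spec: FixtureSpec, rng: random.Random) -> list[tuple[int, int, str]]:
    """(child, parent, relation) triples for one namespace; node 0 is the root."""
    n = spec.n_terms
    edges: list[tuple[int, int, str]] = []
    if spec.dag_shape == "chain":
        for k in range(1, n):
            edges.append((k, k - 1, "is_a"))
    elif spec.dag_shape == "diamond":
        edges += [(1, 0, "is_a"), (2, 0, "is_a"), (3, 1, "is_a"), (3, 2, "is_a")]
        for k in range(4, n):
            edges.append((k, k - 1, "is_a"))
    else:  # random: parents always earlier in the order, hence acyclic
        for k in range(1, n):
            first = rng.randrange(k)
            edges.append((k, first, "is_a"))
            if k >= 2 and rng.random() < spec.edge_prob:
                second = rng.randrange(k)
                if second != first:
                    edges.append((k, second, "is_a"))
        if n >= 5 and max(
            sum(1 for c, _p, _r in edges if c == k) for k in range(1, n)
        ) < 2:
            # guarantee one multi-parent node
            existing = next(p for c, p, _ in edges if c == n - 1)
            other = 0 if existing != 0 else 1
            edges.append((n - 1, other, "is_a"))
    if n >= 3:
        # ensure at least one part_of edge
        idx = next(i for i, (c, _p, _r) in enumerate(edges) if c == 2)
        c, p, _ = edges[idx]
        edges[idx] = (c, p, "part_of")
    return sorted(set(edges))


def generate_ontology(spec: FixtureSpec) -> str:
    """Valid OBO text: one sub-DAG per namespace, plus an alt_id on one
    term and one obsolete term (with replaced_by) to exercise
    resolution."""
    rng = random.Random(spec.seed)
    lines = ["format-version: 1.2", "ontology: go-fixture", ""]
    for ns in spec.namespaces:
        edges = _namespace_edges(spec, rng)
        parents: dict[int, list[tuple[int, str]]] = {}
        for child, parent, relation in edges:
            parents.setdefault(child, []).append((parent, relation))
        for k in range(spec.n_terms):
            lines.append("[Term]")
            lines.append(f"id: {_go_id(ns, k)}")
            lines.append(f"name: {ns} term {k}")
            lines.append(f"namespace: {ns}")
            if k == 1:
                lines.append(f"alt_id: {_go_id(ns, 5000 + k)}")
            for parent, relation in sorted(parents.get(k, [])):
                if relation == "is_a":
                    lines.append(f"is_a: {_go_id(ns, parent)} ! {ns} term {parent}")
                else:
                    lines.append(
                        f"relationship: part_of {_go_id(ns, parent)} ! {ns} term {parent}"
                    )
            lines.append("")
    ns0 = spec.namespaces[0]
    lines += [
        "[Term]",
        f"id: {_go_id(ns0, 9999)}",
        f"name: retired {ns0} term",
        f"namespace: {ns0}",
        "is_obsolete: true",
        f"replaced_by: {_go_id(ns0, 0)}",
        "",
    ]
    return "\n".join(lines)


def _protein_id(i: int) -> str:
    return f"Q0TEST{i:02d}"


def _family_id(i: int) -> str:
    return f"PF999{i:02d}"


def generate_reference(spec: FixtureSpec) -> tuple[str, str]:
    """(GAF text, pfam2go text) over the generated ontology.

    Every reference protein is annotated in every namespace with 1-3
    non-root terms; evidence codes are IEA with probability
    ``evidence_mix``, otherwise drawn from EXP/IDA/TAS; annotation dates
    fall in 2018-2019.  Each Pfam family maps to 1-2 terms.
    """
    rng = random.Random(spec.seed + 1)
    gaf_lines = ["!gaf-version: 2.1", "!generated synthetic fixture"]
    for i in range(spec.n_reference_proteins):
        acc = _protein_id(i)
        for ns in spec.namespaces:
            k_terms = rng.randint(1, min(3, spec.n_terms - 1))
            terms = rng.sample(range(1, spec.n_terms), k_terms)
            for t in sorted(terms):
                evidence = (
                    "IEA" if rng.random() < spec.evidence_mix
                    else rng.choice(_EVIDENCE_CURATED)
                )
                date = f"{rng.randint(2018, 2019)}{rng.randint(1, 12):02d}{rng.randint(1, 28):02d}"
                fields = [
                    "UniProtKB", acc, acc, "", _go_id(ns, t), "GO_REF:0000001",
                    evidence, "", _NS_ASPECT[ns], f"{acc} fixture protein", "",
                    "protein", "taxon:9606", date, "FIXTURE", "", "",
                ]
                gaf_lines.append("\t".join(fields))

    p2g_lines = [
        "!version date: synthetic fixture",
        "!Mapping of Pfam entries to GO terms, fixture edition",
    ]
    for i in range(spec.n_families):
        fam = _family_id(i)
        k_terms = rng.randint(1, 2)
        for _ in range(k_terms):
            ns = rng.choice(spec.namespaces)
            t = rng.randrange(1, spec.n_terms)
            p2g_lines.append(
                f"Pfam:{fam} fixture_domain_{i} > GO:{ns} term {t} ; {_go_id(ns, t)}"
            )
    return "\n".join(gaf_lines) + "\n", "\n".join(p2g_lines) + "\n"


def generate_alignments(spec: FixtureSpec, reference: tuple[str, str]) -> tuple[str, str]:
    """(outfmt6 text, tblout text): queries hitting subjects drawn from
    the reference corpus, with log-uniform e-values.

    The first query's last two protein hits are replaced by the fixed
    edge cases: one e-value above 1 (exercising the e<=1 filter) and one
    reported as 0.0 (exercising the underflow cap).  Every other subject
    id carries UniProt FASTA decoration ("sp|ACC|NAME") to exercise
    stripping; tblout accessions are versioned ("PF99901.11") and
    descriptions contain spaces.
    """
    from .reference_data import parse_gaf, parse_pfam2go

    gaf_text, p2g_text = reference
    accessions = sorted(parse_gaf(gaf_text).by_protein)
    families = sorted(parse_pfam2go(p2g_text).by_family)
    rng = random.Random(spec.seed + 2)
    import math

    lo, hi = spec.evalue_range
    log_lo, log_hi = math.log10(lo), math.log10(hi)

    def draw_evalue() -> str:
        return f"{10 ** rng.uniform(log_lo, log_hi):.3e}"

    outfmt6: list[str] = []
    tblout: list[str] = [
        "#                                                               --- full sequence ---",
        "# target name        accession   query name           accession    E-value  score  bias",
        "#------------------- ----------  -------------------- ---------- --------- ------ -----",
    ]
    edge_slots = {(0, spec.hits_per_query - 1): "2.0", (0, spec.hits_per_query - 2): "0.0"}
    for q in range(spec.n_queries):
        query = f"QUERY{q:03d}"
        for h in range(spec.hits_per_query):
            subject = rng.choice(accessions)
            if (q + h) % 2 == 1:
                subject = f"sp|{subject}|{subject}_TEST"
            evalue = edge_slots.get((q, h), None) or draw_evalue()
            outfmt6.append(
                "\t".join([
                    query, subject, "85.0", "120", "18", "0", "1", "120", "1", "120",
                    evalue, "250.1",
                ])
            )
        for _ in range(spec.domain_hits_per_query):
            fam = rng.choice(families)
            tblout.append(
                f"{fam.lower():<20} {fam}.11  {query:<20} -          "
                f"{draw_evalue():>9} {rng.uniform(20, 80):5.1f}   0.1 "
                f"fixture domain model with a spaced description"
            )
    tblout += ["#", "# Program:         hmmscan", "# [ok]"]
    return "\n".join(outfmt6) + "\n", "\n".join(tblout) + "\n"


def generate_query_truth(spec: FixtureSpec, reference: tuple[str, str],
                         alignments: tuple[str, str]) -> str:
    """GAF of experimentally supported truth annotations for the query
    proteins, for exercising the evaluator.

    Each query inherits the direct GO terms of its closest protein-search
    subject (lowest e-value), the same way benchmark truth sets consist
    of proteins whose functions are experimentally known and which have
    homologs in the reference database.  Evidence is EXP and dates fall
    in the first half of 2020, inside the conventional test window.
    """
    from .alignment_io import HitSource, parse_diamond_tab
    from .reference_data import parse_gaf

    gaf_text, _ = reference
    diamond_text, _ = alignments
    by_protein = parse_gaf(gaf_text).by_protein
    best: dict[str, tuple[float, str]] = {}
    for hit in parse_diamond_tab(diamond_text):
        if hit.source is not HitSource.PROTEIN or hit.evalue > 1.0:
            continue
        if hit.query not in best or hit.evalue < best[hit.query][0]:
            best[hit.query] = (hit.evalue, hit.subject)
    rng = random.Random(spec.seed + 3)
    lines = ["!gaf-version: 2.1", "!synthetic query truth"]
    for query in sorted(best):
        subject = best[query][1]
        for term, _evidence in sorted(by_protein.get(subject, ())):
            ns = next(ns for ns, base in _NS_BASE.items()
                      if base <= int(term[3:]) < base + 10000)
            date = f"2020{rng.randint(1, 5):02d}{rng.randint(1, 28):02d}"
            fields = [
                "UniProtKB", query, query, "", term, "GO_REF:0000001",
                "EXP", "", _NS_ASPECT[ns], f"{query} fixture query", "",
                "protein", "taxon:9606", date, "FIXTURE", "", "",
            ]
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


FILE_NAMES = {
    "obo": "fixture.obo",
    "gaf": "fixture.gaf",
    "pfam2go": "fixture_pfam2go.txt",
    "diamond": "fixture_diamond.tsv",
    "hmmer": "fixture_hmmer.tblout",
    "truth": "fixture_truth.gaf",
}


def generate_all(spec: FixtureSpec) -> dict[str, str]:
    """All fixture files as {kind: text}: the five pipeline inputs plus
    a query-truth GAF for the evaluator."""
    obo = generate_ontology(spec)
    gaf, p2g = generate_reference(spec)
    diamond, hmmer = generate_alignments(spec, (gaf, p2g))
    truth = generate_query_truth(spec, (gaf, p2g), (diamond, hmmer))
    return {"obo": obo, "gaf": gaf, "pfam2go": p2g, "diamond": diamond,
            "hmmer": hmmer, "truth": truth}


def write_fixtures(spec: FixtureSpec, outdir) -> dict[str, tuple[Path, str]]:
    """Materialise the fixture set to ``outdir``; returns
    {kind: (path, sha256)} for a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, tuple[Path, str]] = {}
    for kind, text in generate_all(spec).items():
        path = outdir / FILE_NAMES[kind]
        path.write_text(text)
        manifest[kind] = (path, hashlib.sha256(text.encode()).hexdigest())
    return manifest
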