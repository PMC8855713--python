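"""Shared test fixtures.

The central one is ``cascade``: an 8-term single-namespace DAG with a
diamond, 3 reference proteins with mixed IEA/curated evidence, a
pfam2go mapping and 6 alignment hits covering the e-value filter, the
underflow cap and UniProt subject decoration.  It is defined once as
plain dicts (consumed directly by the brute-force oracles) and rendered
to the real file formats by trivial string formatting here, so the
package parsers and the oracle never share a code path.
"""

from __future__ import annotations

import math

import pytest

# ---- the 8-term / 3-protein cascade fixture, as plain data ----------------

A, B, C, D, E, F, G, H = (f"GO:080000{i}" for i in range(8))

CASCADE_PARENTS = {
    B: {A}, C: {A}, D: {B, C}, E: {B}, F: {D}, G: {C}, H: {E},
}
# relation per child edge; C part_of A, everything else is_a
CASCADE_RELATIONS = {(C, A): "part_of"}

CASCADE_ANNOTATIONS = {
    "Q0TEST01": {(D, "IEA"), (E, "IDA")},
    "Q0TEST02": {(F, "IEA"), (G, "EXP")},
    "Q0TEST03": {(H, "IEA"), (B, "IEA"), (G, "IEA")},
}
CASCADE_PFAM = {"PF99900": {C}, "PF99901": {E, G}}

# (query, subject, evalue, kind); one hit above the e<=1 filter, one 0.0
CASCADE_HITS = [
    ("QUERY001", "Q0TEST01", 1e-10, "protein"),
    ("QUERY001", "Q0TEST02", 1e-5, "protein"),
    ("QUERY001", "Q0TEST03", 2.0, "protein"),
    ("QUERY001", "PF99900", 1e-3, "domain"),
    ("QUERY002", "Q0TEST01", 0.0, "protein"),
    ("QUERY002", "PF99901", 1e-2, "domain"),
]

# IEA records: D, F, H, B, G(P3) = 5; non-IEA: E(IDA), G(EXP) = 2
CASCADE_MULTIPLIER = math.log2(5 / 2)

_NAMES = {A: "root", B: "b", C: "c", D: "d", E: "e", F: "f", G: "g", H: "h"}


def cascade_obo_text() -> str:
    lines = ["format-version: 1.2", "ontology: cascade-test", ""]
    for term in (A, B, C, D, E, F, G, H):
        lines += [f"[Term]", f"id: {term}", f"name: {_NAMES[term]}",
                  "namespace: biological_process"]
        for parent in sorted(CASCADE_PARENTS.get(term, ())):
            if CASCADE_RELATIONS.get((term, parent)) == "part_of":
                lines.append(f"relationship: part_of {parent} ! {_NAMES[parent]}")
            else:
                lines.append(f"is_a: {parent} ! {_NAMES[parent]}")
        lines.append("")
    return "\n".join(lines)


def cascade_gaf_text() -> str:
    lines = ["!gaf-version: 2.1"]
    for protein in sorted(CASCADE_ANNOTATIONS):
        for term, evidence in sorted(CASCADE_ANNOTATIONS[protein]):
            lines.append("\t".join([
                "UniProtKB", protein, protein, "", term, "GO_REF:0000001",
                evidence, "", "P", "", "", "protein", "taxon:9606",
                "20190101", "TEST", "", "",
            ]))
    return "\n".join(lines) + "\n"


def cascade_pfam2go_text() -> str:
    lines = ["!test mapping"]
    for family in sorted(CASCADE_PFAM):
        for term in sorted(CASCADE_PFAM[family]):
            lines.append(f"Pfam:{family} dom > GO:{_NAMES[term]} ; {term}")
    return "\n".join(lines) + "\n"


def cascade_diamond_text() -> str:
    lines = []
    for query, subject, evalue, kind in CASCADE_HITS:
        if kind != "protein":
            continue
        if subject == "Q0TEST02":  # exercise FASTA-header decoration stripping
            subject = f"sp|{subject}|{subject}_TEST"
        lines.append("\t".join([
            query, subject, "90.0", "100", "10", "0", "1", "100", "1", "100",
            str(evalue), "200.0",
        ]))
    return "\n".join(lines) + "\n"


def cascade_tblout_text() -> str:
    lines = [
        "# target name  accession  query name  accession  E-value  score  bias",
        "#------------- ---------- ----------- ---------- -------- ------ ----",
    ]
    for query, subject, evalue, kind in CASCADE_HITS:
        if kind != "domain":
            continue
        lines.append(
            f"{subject.lower():<14} {subject}.11 {query:<11} -          "
            f"{evalue:<8} 50.0   0.1 a description with spaces"
        )
    lines.append("# [ok]")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def cascade() -> dict:
    return {
        "parents": CASCADE_PARENTS,
        "root": A,
        "annotations": CASCADE_ANNOTATIONS,
        "pfam": CASCADE_PFAM,
        "hits": CASCADE_HITS,
        "multiplier": CASCADE_MULTIPLIER,
        "obo": cascade_obo_text(),
        "gaf": cascade_gaf_text(),
        "pfam2go": cascade_pfam2go_text(),
        "diamond": cascade_diamond_text(),
        "tblout": cascade_tblout_text(),
    }


@pytest.fixture(scope="session")
def cascade_dag(cascade):
    from gotransfer import parse_obo

    return parse_obo(cascade["obo"])


# ---- small helpers --------------------------------------------------------

def obo_text(terms: list[tuple[str, str, list[tuple[str, str]]]]) -> str:
    """Render [(id, namespace, [(parent, relation)])] as OBO."""
    lines = ["format-version: 1.2", ""]
    for term_id, namespace, parents in terms:
        lines += ["[Term]", f"id: {term_id}", f"name: {term_id}",
                  f"namespace: {namespace}"]
        for parent, relation in parents:
            if relation == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {relation} {parent}")
        lines.append("")
    return "\n".join(lines)


CHAIN_OBO = obo_text([
    ("GO:0000001", "biological_process", []),
    ("GO:0000002", "biological_process", [("GO:0000001", "is_a")]),
    ("GO:0000003", "biological_process", [("GO:0000002", "is_a")]),
])


@pytest.fixture()
def chain_dag():
    from gotransfer import parse_obo

    return parse_obo(CHAIN_OBO)
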