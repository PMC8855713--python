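"""Reference annotation sources: GOA (GAF) files and the pfam2go mapping.

The GAF reader keeps, for every UniProt accession, the set of directly
annotated (GO term, evidence code) pairs — ancestor closure is applied
later, by the DAG-aware stages.  It also tallies how many retained
records carry the uncurated IEA evidence code versus any other code;
that ratio P drives the evidence-based weight multiplier log2(P)
applied to non-IEA transfers.
"""

from __future__ import annotations

import io
import logging
import math
import os
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

logger = logging.getLogger(__name__)

#: Experimental / curated evidence codes used for test-set truth.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"})

GAF_COLUMNS = 17
_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
_PFAM2GO_RE = re.compile(r"^Pfam:(PF\d{5})\s+\S+\s*>\s*GO:.*?\s*;\s*(GO:\d{7})\s*$")


def _as_stream(source: Union[str, os.PathLike, IO[str]]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = str(source)
    if any(c in text for c in "\n\t ") and not os.path.exists(text):
        return io.StringIO(text)
    return open(text, "rt")


@dataclass
class ReferenceAnnotations:
    """GOA lookup: accession -> {(GO id, evidence code)} plus evidence tallies.

    ``iea_count`` / ``non_iea_count`` count retained annotation records
    (rows), not distinct GO ids.
    """

    by_protein: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    iea_count: int = 0
    non_iea_count: int = 0

    def add(self, protein: str, term: str, evidence: str) -> None:
        self.by_protein.setdefault(protein, set()).add((term, evidence))
        if evidence == "IEA":
            self.iea_count += 1
        else:
            self.non_iea_count += 1

    @property
    def n_proteins(self) -> int:
        return len(self.by_protein)


@dataclass
class Pfam2GoMap:
    """pfam2go lookup: un-versioned Pfam accession -> set of GO ids."""

    by_family: dict[str, set[str]] = field(default_factory=dict)
    skipped_lines: int = 0


def parse_gaf(
    source: Union[str, os.PathLike, IO[str]],
    evidence_whitelist: Iterable[str] | None = None,
    date_window: tuple[int, int] | None = None,
) -> ReferenceAnnotations:
    """Read a GAF 2.1/2.2 file into a :class:`ReferenceAnnotations`.

    Records are dropped when the qualifier (column 4) contains NOT, when
    the evidence code (column 7) is outside ``evidence_whitelist`` (if
    given), or when the annotation date (column 14, YYYYMMDD) falls
    outside the inclusive ``date_window`` (if given).  A row with a
    column count other than 17 is a hard error naming the line; a row
    whose date cannot be parsed is dropped with a warning.
    """
    whitelist = frozenset(evidence_whitelist) if evidence_whitelist is not None else None
    annotations = ReferenceAnnotations()
    stream = _as_stream(source)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) != GAF_COLUMNS:
            raise ValueError(
                f"GAF line {lineno}: expected {GAF_COLUMNS} columns, got {len(fields)}"
            )
        accession = fields[1]
        qualifier = fields[3]
        go_id = fields[4]
        evidence = fields[6]
        date_str = fields[13]
        if "NOT" in qualifier.split("|"):
            continue
        if whitelist is not None and evidence not in whitelist:
            continue
        if date_window is not None:
            try:
                date = int(date_str)
                if len(date_str) != 8:
                    raise ValueError
            except ValueError:
                logger.warning("GAF line %d: unparseable date %r; record dropped", lineno, date_str)
                continue
            lo, hi = date_window
            if not (lo <= date <= hi):
                continue
        annotations.add(accession, go_id, evidence)
    return annotations


def write_gaf(annotations: ReferenceAnnotations, dag=None, date: str = "20200101") -> str:
    """Serialise annotations back to minimal GAF 2.1 text.

    Aspect (column 9) is derived from the DAG when one is supplied,
    otherwise left blank; re-parsing the output recovers ``by_protein``
    exactly.
    """
    lines = ["!gaf-version: 2.1"]
    for protein in sorted(annotations.by_protein):
        for term, evidence in sorted(annotations.by_protein[protein]):
            aspect = ""
            if dag is not None and term in dag:
                aspect = _ASPECT[dag.namespace_of(term)]
            fields = [
                "UniProtKB", protein, protein, "", term, "GO_REF:0000001",
                evidence, "", aspect, "", "", "protein", "taxon:9606", date,
                "GOA", "", "",
            ]
            lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def parse_pfam2go(source: Union[str, os.PathLike, IO[str]]) -> Pfam2GoMap:
    """Read a pfam2go (external2go) mapping file.

    Each data line maps one Pfam family to one GO term; repeated
    families accumulate.  Comment lines start with "!"; lines that do
    not match the format are skipped and counted in ``skipped_lines``.
    """
    mapping = Pfam2GoMap()
    stream = _as_stream(source)
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        m = _PFAM2GO_RE.match(line)
        if m is None:
            mapping.skipped_lines += 1
            logger.warning("pfam2go line skipped (unrecognised format): %r", line[:80])
            continue
        family, go_id = m.groups()
        mapping.by_family.setdefault(family, set()).add(go_id)
    return mapping


def evidence_multiplier(annotations: ReferenceAnnotations) -> float:
    """Weight multiplier log2(P) for non-IEA-backed transfers, floored at 1.

    P is the ratio of IEA to non-IEA annotation records in the reference
    corpus.  In real GOA releases IEA records dominate, so P > 1 and the
    multiplier up-weights curated evidence; the floor guarantees that a
    small or atypical corpus (P <= 2) never *down*-weights it.
    Raises ``ValueError`` when the corpus has no non-IEA records.
    """
    if annotations.non_iea_count == 0:
        raise ValueError(
            "reference corpus has no non-IEA annotations; "
            "disable evidence weighting (multiplier=1) instead"
        )
    p = annotations.iea_count / annotations.non_iea_count
    if p <= 0.0:
        return 1.0
    return max(math.log2(p), 1.0)
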