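"""Readers for the two alignment report formats feeding the predictor:
BLAST/DIAMOND 12-column tabular output (``--outfmt 6``) against a
protein database, and HMMER3 hmmscan per-target table output
(``--tblout``) against Pfam-A.

Both are normalised to :class:`AlignmentHit` records; the ``source``
field decides which annotation lookup (GOA for protein hits, pfam2go
for domain hits) applies downstream.
"""

from __future__ import annotations

import io
import logging
import os
import re
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Union

logger = logging.getLogger(__name__)

_PFAM_VERSION_RE = re.compile(r"\.\d+$")


class HitSource(str, Enum):
    PROTEIN = "protein_search"
    DOMAIN = "domain_search"


@dataclass(frozen=True)
class AlignmentHit:
    """One query-subject alignment with its e-value."""

    query: str
    subject: str
    evalue: float
    source: HitSource


def _as_stream(source: Union[str, os.PathLike, IO[str]]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = str(source)
    if any(c in text for c in "\n\t ") and not os.path.exists(text):
        return io.StringIO(text)
    return open(text, "rt")


def _strip_uniprot_decoration(sseqid: str) -> str:
    # "sp|P12345|ABC_HUMAN" / "tr|Q9XYZ1|..." -> bare accession
    parts = sseqid.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return sseqid


def parse_diamond_tab(
    source: Union[str, os.PathLike, IO[str]],
    best_per_pair: bool = False,
) -> list[AlignmentHit]:
    """Parse BLAST/DIAMOND ``--outfmt 6`` tabular output.

    Columns are qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore; the e-value is read from column 11 and
    UniProt FASTA-header decoration is stripped from the subject id.
    Every line yields a hit (multiple HSPs per pair all contribute to
    the weight sums) unless ``best_per_pair`` keeps only the lowest
    e-value per (query, subject).
    """
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(_as_stream(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"outfmt6 line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            evalue = float(fields[10])
        except ValueError:
            raise ValueError(f"outfmt6 line {lineno}: non-numeric e-value {fields[10]!r}")
        if evalue < 0:
            raise ValueError(f"outfmt6 line {lineno}: negative e-value {evalue}")
        hits.append(
            AlignmentHit(
                query=fields[0],
                subject=_strip_uniprot_decoration(fields[1]),
                evalue=evalue,
                source=HitSource.PROTEIN,
            )
        )
    if best_per_pair:
        hits = _best_per_pair(hits)
    return hits


def parse_hmmer_tblout(
    source: Union[str, os.PathLike, IO[str]],
    best_per_pair: bool = False,
) -> list[AlignmentHit]:
    """Parse HMMER3 ``hmmscan --tblout`` output.

    Data lines are whitespace-delimited with 18 fixed leading columns
    followed by a free-text description, so spaces in descriptions do
    not affect parsing.  The subject is the target (Pfam) accession with
    its version suffix stripped; the full-sequence e-value (column 5) is
    used.  Lines whose accession field is "-" are dropped with a warning.
    """
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(_as_stream(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split(None, 18)
        if len(fields) < 5:
            raise ValueError(f"tblout line {lineno}: too few columns ({len(fields)})")
        accession = fields[1]
        if accession == "-":
            logger.warning("tblout line %d: missing target accession; hit dropped", lineno)
            continue
        try:
            evalue = float(fields[4])
        except ValueError:
            raise ValueError(f"tblout line {lineno}: non-numeric e-value {fields[4]!r}")
        hits.append(
            AlignmentHit(
                query=fields[2],
                subject=_PFAM_VERSION_RE.sub("", accession),
                evalue=evalue,
                source=HitSource.DOMAIN,
            )
        )
    if best_per_pair:
        hits = _best_per_pair(hits)
    return hits


def _best_per_pair(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        key = (hit.query, hit.subject)
        if key not in best or hit.evalue < best[key].evalue:
            best[key] = hit
    return list(best.values())
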