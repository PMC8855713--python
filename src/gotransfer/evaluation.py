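"""Protein-centric evaluation: test-set construction from a GOA file
and threshold-swept precision/recall, Fmax and Smin.

Truth sets follow the community benchmark conventions: experimental /
curated evidence only, optional annotation-date window, removal of
GO:0005515 (protein binding) when it is a protein's sole molecular
function term, ancestor closure over is_a/part_of, and exclusion of the
trivially predictable namespace roots from both truth and predictions.

Metrics sweep the normalised score threshold t over [0,1] in steps of
0.01.  Precision at t averages over the m(t) proteins with at least one
prediction at or above t; recall averages over all n truth proteins, so
a protein with no surviving predictions drags recall down but not
precision.  Smin combines the information content of false negatives
(remaining uncertainty, ru) and false positives (misinformation, mi) as
min_t sqrt(ru(t)^2 + mi(t)^2).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import pandas as pd

from .ontology import GoDag, IcTable
from .reference_data import EXPERIMENTAL_EVIDENCE, parse_gaf

logger = logging.getLogger(__name__)

PROTEIN_BINDING = "GO:0005515"

#: protein -> {term: score}, one namespace at a time
ScoreMap = Mapping[str, Mapping[str, float]]


@dataclass
class TestSet:
    """Ancestor-closed truth annotations, keyed namespace -> protein -> terms."""

    truth: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def namespaces(self) -> list[str]:
        return sorted(self.truth)

    def proteins(self, namespace: str) -> dict[str, frozenset[str]]:
        return self.truth.get(namespace, {})


@dataclass(frozen=True)
class CurvePoint:
    threshold: float
    avg_pr: float
    avg_rc: float
    m: int


@dataclass
class NamespaceReport:
    curve: list[CurvePoint]
    fmax: float
    smin: float
    n: int


@dataclass
class EvaluationReport:
    per_namespace: dict[str, NamespaceReport] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            ns: {"fmax": rep.fmax, "smin": rep.smin, "n": rep.n}
            for ns, rep in self.per_namespace.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def curve_frame(self) -> pd.DataFrame:
        rows = [
            (ns, pt.threshold, pt.avg_pr, pt.avg_rc, pt.m)
            for ns, rep in sorted(self.per_namespace.items())
            for pt in rep.curve
        ]
        return pd.DataFrame(rows, columns=["namespace", "threshold", "avg_pr", "avg_rc", "m"])


def build_test_set(
    gaf_source: Union[str, IO[str]],
    dag: GoDag,
    evidence_whitelist: Iterable[str] | None = EXPERIMENTAL_EVIDENCE,
    date_window: tuple[int, int] | None = None,
    include_roots: bool = False,
) -> TestSet:
    """Construct truth sets from a GAF file.

    After evidence/date filtering, GO:0005515 is removed from a protein
    iff it is that protein's only molecular_function term — the check
    runs on the direct annotations, before closure, since closure would
    always add binding ancestors and defeat the filter.  Every surviving
    set is expanded with all is_a/part_of ancestors; namespace roots are
    excluded unless ``include_roots``.  Proteins left with nothing are
    dropped; an entirely empty test set is an error.
    """
    annotations = parse_gaf(gaf_source, evidence_whitelist, date_window)
    roots = set(dag.roots.values())
    truth: dict[str, dict[str, frozenset[str]]] = {}
    for protein, pairs in annotations.by_protein.items():
        direct: dict[str, set[str]] = {}
        for term, _evidence in pairs:
            primary = dag.resolve(term)
            if primary is None:
                logger.warning("truth term %s (%s) unresolvable; dropped", term, protein)
                continue
            direct.setdefault(dag.namespace_of(primary), set()).add(primary)
        mf = direct.get("molecular_function")
        if mf == {PROTEIN_BINDING}:
            del direct["molecular_function"]
        for ns, terms in direct.items():
            closed: set[str] = set()
            for t in terms:
                closed |= dag.ancestors_and_self(t)
            if not include_roots:
                closed -= roots
            if closed:
                truth.setdefault(ns, {})[protein] = frozenset(closed)
    if not truth:
        raise ValueError("test set is empty after filtering")
    return TestSet(truth=truth)


def _thresholds(step: float) -> list[float]:
    n = round(1.0 / step)
    return [round(k * step, 10) for k in range(n + 1)]


def precision_recall_curve(
    predictions: ScoreMap, truth: Mapping[str, frozenset[str]], step: float = 0.01
) -> list[CurvePoint]:
    """Precision/recall over the threshold sweep, for one namespace.

    Predictions for proteins absent from the truth mapping are ignored;
    truth proteins without predictions contribute zero recall at every
    threshold.  avgPr is 0 by convention at thresholds where no protein
    has a surviving prediction (m(t)=0).
    """
    n = len(truth)
    pred_items = {
        v: sorted(scores.items()) for v, scores in predictions.items() if v in truth
    }
    curve: list[CurvePoint] = []
    for t in _thresholds(step):
        pr_sum = 0.0
        rc_sum = 0.0
        m = 0
        for v, true_terms in truth.items():
            pv = {term for term, s in pred_items.get(v, ()) if s >= t}
            if pv:
                m += 1
                overlap = len(pv & true_terms)
                pr_sum += overlap / len(pv)
                rc_sum += overlap / len(true_terms)
        curve.append(
            CurvePoint(
                threshold=t,
                avg_pr=pr_sum / m if m else 0.0,
                avg_rc=rc_sum / n if n else 0.0,
                m=m,
            )
        )
    return curve


def fmax(curve: Iterable[CurvePoint]) -> float:
    """Maximum harmonic mean of avgPr and avgRc over the sweep; a
    threshold where both are zero contributes F1 = 0."""
    best = 0.0
    for pt in curve:
        denom = pt.avg_pr + pt.avg_rc
        if denom > 0:
            best = max(best, 2.0 * pt.avg_pr * pt.avg_rc / denom)
    return best


def smin(
    predictions: ScoreMap,
    truth: Mapping[str, frozenset[str]],
    ic: IcTable,
    step: float = 0.01,
) -> float:
    """Minimum over thresholds of sqrt(ru^2 + mi^2) for one namespace.

    ru(t) averages, over all n truth proteins, the summed IC of truth
    terms missing from the prediction set at t; mi(t) the summed IC of
    predicted terms absent from truth.  Terms missing from the IC table
    fall back to the namespace maximum (logged).
    """
    n = len(truth)
    if n == 0:
        return 0.0
    pred_items = {
        v: sorted(scores.items()) for v, scores in predictions.items() if v in truth
    }
    best = math.inf
    for t in _thresholds(step):
        ru = 0.0
        mi = 0.0
        for v, true_terms in truth.items():
            pv = {term for term, s in pred_items.get(v, ()) if s >= t}
            # sorted: keep the float summation order hash-independent
            ru += sum(ic.get(term) for term in sorted(true_terms - pv))
            mi += sum(ic.get(term) for term in sorted(pv - true_terms))
        best = min(best, math.hypot(ru / n, mi / n))
    return best


def score_map(
    table: pd.DataFrame, namespace: str, dag: GoDag, include_roots: bool = False
) -> dict[str, dict[str, float]]:
    """Convert a prediction table to protein -> {term: ts_norm} for one
    namespace, dropping the namespace root unless asked to keep it."""
    sub = table[table["namespace"] == namespace]
    root = dag.roots.get(namespace)
    out: dict[str, dict[str, float]] = {}
    for protein, go_id, ts_norm in zip(sub["protein"], sub["go_id"], sub["ts_norm"]):
        if not include_roots and go_id == root:
            continue
        out.setdefault(protein, {})[go_id] = float(ts_norm)
    return out


def evaluate(
    table: pd.DataFrame,
    test_set: TestSet,
    ic: IcTable,
    dag: GoDag,
    step: float = 0.01,
    include_roots: bool = False,
) -> EvaluationReport:
    """Full per-namespace report (curve, Fmax, Smin) for a prediction
    table against a truth set.  Namespaces without truth are omitted
    with a warning."""
    report = EvaluationReport()
    for ns in dag.roots:
        truth = test_set.proteins(ns)
        if not truth:
            logger.warning("namespace %s has no truth proteins; omitted from report", ns)
            continue
        preds = score_map(table, ns, dag, include_roots)
        curve = precision_recall_curve(preds, truth, step)
        report.per_namespace[ns] = NamespaceReport(
            curve=curve,
            fmax=fmax(curve),
            smin=smin(preds, truth, ic, step),
            n=len(truth),
        )
    return report
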