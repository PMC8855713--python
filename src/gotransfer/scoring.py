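"""The weighted annotation-transfer cascade.

Every alignment hit transfers the GO terms of its subject (GOA terms
for protein hits, pfam2go terms for domain hits) to the query protein.
For protein v and term i the stages are:

1. raw weight      W(v,i)   = sum over hits j of -log10(E_j), with hits
                              of e-value > 1 discarded, an underflow cap
                              on E_j, and a log2(P) multiplier when the
                              subject's annotation of i is non-IEA;
2. DAG propagation W(v,i)  += direct weight of every descendant of i,
                              each descendant counted once;
3. internal conf.  InC(v,i) = W(v,i) / W(v, namespace root);
4. group score     GS(v,i)  = sum of InC(v,j) over the protein's terms j
                              with Lin similarity Sim(i,j) >= 0.7;
5. total score     TS(v,i)  = IC(i) * InC(v,i)/GS(v,i) * W(v,i),
                              min-max scaled to [0,1] per namespace.

Since Sim(i,i)=1, GS >= InC > 0 and step 5 never divides by zero.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping

import pandas as pd

from .alignment_io import AlignmentHit, HitSource
from .ontology import GoDag, IcTable, compute_ic, lin_similarity
from .reference_data import Pfam2GoMap, ReferenceAnnotations, evidence_multiplier

logger = logging.getLogger(__name__)

#: Columns of the prediction table, in output order.
SCORE_COLUMNS = ["protein", "go_id", "namespace", "weight", "inc", "gs", "ic", "ts", "ts_norm"]

DEFAULT_SIM_THRESHOLD = 0.7
DEFAULT_EVALUE_CAP = 1e-200


def accumulate_weights(
    hits: Iterable[AlignmentHit],
    goa: ReferenceAnnotations,
    pfam2go: Pfam2GoMap,
    dag: GoDag,
    multiplier: float = 1.0,
    evalue_cap: float = DEFAULT_EVALUE_CAP,
) -> dict[tuple[str, str], float]:
    """Direct (pre-propagation) weights per (query protein, GO term).

    Hits with e-value above 1 contribute nothing.  Each retained hit
    contributes -log10(max(E, evalue_cap)) to every GO term of its
    subject; for protein-search hits the contribution is multiplied by
    ``multiplier`` iff the subject's annotation of that term carries a
    non-IEA evidence code.  Domain-search hits transfer pfam2go terms
    un-multiplied.  Terms are remapped through alt_id resolution;
    subjects found in neither lookup are tallied and logged.
    """
    if multiplier < 1.0:
        raise ValueError(f"multiplier must be >= 1, got {multiplier}")
    if evalue_cap <= 0.0:
        raise ValueError(f"evalue_cap must be > 0, got {evalue_cap}")

    # subject protein -> {term: has non-IEA evidence}, alt-ids resolved
    protein_terms: dict[str, dict[str, bool]] = {}

    def _terms_of_protein(accession: str) -> dict[str, bool]:
        cached = protein_terms.get(accession)
        if cached is None:
            cached = {}
            # sorted: float accumulation order must not depend on set order
            for term, evidence in sorted(goa.by_protein.get(accession, ())):
                primary = dag.resolve(term)
                if primary is None:
                    logger.warning("GOA term %s (subject %s) unresolvable; dropped", term, accession)
                    continue
                cached[primary] = cached.get(primary, False) or evidence != "IEA"
            protein_terms[accession] = cached
        return cached

    family_terms: dict[str, set[str]] = {}

    def _terms_of_family(family: str) -> set[str]:
        cached = family_terms.get(family)
        if cached is None:
            cached = set()
            for term in sorted(pfam2go.by_family.get(family, ())):
                primary = dag.resolve(term)
                if primary is None:
                    logger.warning("pfam2go term %s (family %s) unresolvable; dropped", term, family)
                    continue
                cached.add(primary)
            family_terms[family] = cached
        return cached

    weights: dict[tuple[str, str], float] = defaultdict(float)
    n_filtered = 0
    unmapped: set[str] = set()
    for hit in hits:
        if hit.evalue > 1.0:
            n_filtered += 1
            continue
        contribution = -math.log10(max(hit.evalue, evalue_cap))
        if hit.source is HitSource.PROTEIN:
            terms = _terms_of_protein(hit.subject)
            if not terms:
                unmapped.add(hit.subject)
                continue
            for term, non_iea in terms.items():
                weights[(hit.query, term)] += contribution * (multiplier if non_iea else 1.0)
        else:
            terms = _terms_of_family(hit.subject)
            if not terms:
                unmapped.add(hit.subject)
                continue
            for term in sorted(terms):
                weights[(hit.query, term)] += contribution
    if n_filtered:
        logger.info("filtered %d hits with e-value > 1", n_filtered)
    if unmapped:
        logger.info("%d subjects had no GO annotation: %s", len(unmapped),
                    ", ".join(sorted(unmapped)[:10]))
    return dict(weights)


def propagate_weights(
    direct: Mapping[tuple[str, str], float], dag: GoDag
) -> dict[tuple[str, str], float]:
    """Cumulative weights: W(v,i) = sum of direct weight over i and all
    of i's descendants, each descendant counted exactly once regardless
    of how many paths connect it to i (the true-path rule applied to
    evidence).  Implemented by pushing each directly weighted term's
    mass up its ancestor closure."""
    propagated: dict[tuple[str, str], float] = defaultdict(float)
    # sorted: the result must not depend on dict/set iteration order,
    # so that repeated runs are bit-identical
    for (protein, term), w in sorted(direct.items()):
        for target in sorted(dag.ancestors_and_self(term)):
            propagated[(protein, target)] += w
    return dict(propagated)


def internal_confidence(
    weights: Mapping[tuple[str, str], float], dag: GoDag
) -> dict[tuple[str, str], float]:
    """InC(v,i) = W(v,i) / W(v, root of i's namespace); InC(v,root)=1.

    Propagation guarantees the root of every populated namespace holds
    the namespace's full weight, so the denominator is never zero.
    """
    inc: dict[tuple[str, str], float] = {}
    for (protein, term), w in weights.items():
        root = dag.root_of(term)
        root_weight = weights.get((protein, root), 0.0)
        assert root_weight > 0.0, f"no root weight for {protein}/{dag.namespace_of(term)}"
        inc[(protein, term)] = w / root_weight
    return inc


def group_score(
    inc: Mapping[tuple[str, str], float],
    ic: IcTable,
    dag: GoDag,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
) -> dict[tuple[str, str], float]:
    """GS(v,i): summed InC of the protein's same-namespace terms that are
    semantically similar to i (Lin >= ``sim_threshold``).

    Each term gets its own group score rather than one score per
    similarity cluster; self-similarity is 1, so GS(v,i) >= InC(v,i).
    """
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError(f"sim_threshold must be in (0,1], got {sim_threshold}")
    by_group: dict[tuple[str, str], list[str]] = defaultdict(list)
    for protein, term in sorted(inc):
        by_group[(protein, dag.namespace_of(term))].append(term)

    gs: dict[tuple[str, str], float] = {}
    sim_cache: dict[tuple[str, str], float] = {}
    for (protein, _ns), terms in by_group.items():
        for i in terms:
            total = 0.0
            for j in terms:
                key = (i, j) if i <= j else (j, i)
                sim = sim_cache.get(key)
                if sim is None:
                    sim = lin_similarity(ic, dag, *key)
                    sim_cache[key] = sim
                if sim >= sim_threshold:
                    total += inc[(protein, j)]
            gs[(protein, i)] = total
    return gs


def total_score(
    inc: Mapping[tuple[str, str], float],
    gs: Mapping[tuple[str, str], float],
    weights: Mapping[tuple[str, str], float],
    ic: IcTable,
    dag: GoDag,
    normalization: str = "batch",
) -> pd.DataFrame:
    """Assemble the final score table.

    TS(v,i) = IC(i) * InC(v,i)/GS(v,i) * W(v,i).  ``ts_norm`` rescales
    TS to [0,1] by min-max, per namespace — across the whole batch by
    default, or per protein with ``normalization="protein"``; a
    degenerate range (max == min) maps every score to 1.  Rows are
    sorted by (protein, namespace, TS descending, GO id).
    """
    if normalization not in ("batch", "protein"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    rows = []
    for (protein, term), w in weights.items():
        term_ic = ic.get(term)
        ts = term_ic * (inc[(protein, term)] / gs[(protein, term)]) * w
        rows.append(
            (protein, term, dag.namespace_of(term), w,
             inc[(protein, term)], gs[(protein, term)], term_ic, ts)
        )
    df = pd.DataFrame(rows, columns=SCORE_COLUMNS[:-1])
    if df.empty:
        df["ts_norm"] = pd.Series(dtype=float)
        return df

    group_cols = ["namespace"] if normalization == "batch" else ["protein", "namespace"]
    lo = df.groupby(group_cols)["ts"].transform("min")
    hi = df.groupby(group_cols)["ts"].transform("max")
    span = hi - lo
    df["ts_norm"] = ((df["ts"] - lo) / span.where(span > 0)).fillna(1.0)

    df = df.sort_values(
        ["protein", "namespace", "ts", "go_id"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    return df


def predict(
    hits: Iterable[AlignmentHit],
    goa: ReferenceAnnotations,
    pfam2go: Pfam2GoMap,
    dag: GoDag,
    ic: IcTable | None = None,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    evalue_cap: float = DEFAULT_EVALUE_CAP,
    evidence_weighting: bool = True,
    multiplier_floor: float = 1.0,
    normalization: str = "batch",
    namespaces: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Run the whole cascade from hits to a normalised score table.

    The IC table is computed from ``goa`` (the same corpus the terms are
    transferred from) unless one is supplied.  With
    ``evidence_weighting`` off, or a corpus without non-IEA records, the
    multiplier is 1 and evidence codes play no role.
    """
    if ic is None:
        ic = compute_ic(dag, goa)
    multiplier = 1.0
    if evidence_weighting:
        multiplier = max(evidence_multiplier(goa), multiplier_floor)
    direct = accumulate_weights(hits, goa, pfam2go, dag, multiplier, evalue_cap)
    weights = propagate_weights(direct, dag)
    inc = internal_confidence(weights, dag)
    gs = group_score(inc, ic, dag, sim_threshold)
    table = total_score(inc, gs, weights, ic, dag, normalization)
    if namespaces is not None:
        wanted = set(namespaces)
        table = table[table["namespace"].isin(wanted)].reset_index(drop=True)
    return table


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write the prediction table as TSV (the tool's exchange format)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_predictions(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"protein": str, "go_id": str})
    missing = set(SCORE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"prediction file {path} lacks columns: {sorted(missing)}")
    return table
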