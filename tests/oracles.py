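"""Independent brute-force oracles for the scoring cascade and metrics.

Everything here is written as straight-line set arithmetic over plain
dicts, deliberately sharing no code with the package: ancestor sets by
repeated edge expansion, IC by explicit protein counting, Lin similarity
by exhaustive common-ancestor search, the weight cascade by literal
per-hit loops, and precision/recall/Fmax/Smin by enumerating every
threshold.  Tests compare package output against these.
"""

from __future__ import annotations

import math


def closure_up(parents: dict[str, set[str]], term: str) -> set[str]:
    """Ancestors of ``term`` including itself, by repeated expansion."""
    out = {term}
    while True:
        grown = set(out)
        for t in out:
            grown |= parents.get(t, set())
        if grown == out:
            return out
        out = grown


def descendant_sets(parents: dict[str, set[str]]) -> dict[str, set[str]]:
    """term -> all descendants including itself (transitive closure)."""
    nodes = set(parents) | {p for ps in parents.values() for p in ps}
    desc = {t: {t} for t in nodes}
    for t in nodes:
        for u in nodes:
            if t in closure_up(parents, u):
                desc[t].add(u)
    return desc


def brute_ic(parents: dict[str, set[str]],
             annotations: dict[str, set[str]]) -> dict[str, float]:
    """IC per term from direct annotation sets, single namespace:
    close each protein's set, count, -log10(count / n_proteins)."""
    nodes = set(parents) | {p for ps in parents.values() for p in ps}
    counts = {t: 0 for t in nodes}
    for _protein, terms in annotations.items():
        closed: set[str] = set()
        for t in terms:
            closed |= closure_up(parents, t)
        for t in closed:
            counts[t] += 1
    n = len(annotations)
    ic = {}
    max_ic = 0.0
    for t, c in counts.items():
        if c > 0:
            ic[t] = abs(-math.log10(c / n))
            max_ic = max(max_ic, ic[t])
    for t, c in counts.items():
        if c == 0:
            ic[t] = max_ic
    return ic


def brute_joint_parent(parents, ic, i, j):
    common = closure_up(parents, i) & closure_up(parents, j)
    return max(common, key=lambda t: (ic[t], [-ord(c) for c in t]))


def brute_lin(parents, ic, i, j):
    if i == j:
        return 1.0
    denom = ic[i] + ic[j]
    if denom == 0.0:
        return 0.0
    return 2.0 * ic[brute_joint_parent(parents, ic, i, j)] / denom


def brute_cascade(
    parents: dict[str, set[str]],
    root: str,
    protein_annotations: dict[str, set[tuple[str, str]]],
    pfam_terms: dict[str, set[str]],
    hits: list[tuple[str, str, float, str]],
    multiplier: float,
    evalue_cap: float = 1e-200,
    sim_threshold: float = 0.7,
):
    """Full cascade on one namespace.

    ``hits`` rows are (query, subject, evalue, kind) with kind in
    {"protein", "domain"}.  Returns dict of stage outputs keyed
    (query, term): direct, weight, inc, gs, ts, and the ic table.
    """
    ic = brute_ic(parents, {p: {t for t, _e in pairs}
                            for p, pairs in protein_annotations.items()})

    direct: dict[tuple[str, str], float] = {}
    for query, subject, evalue, kind in hits:
        if evalue > 1.0:
            continue
        contribution = -math.log10(max(evalue, evalue_cap))
        if kind == "protein":
            terms: dict[str, bool] = {}
            for t, e in protein_annotations.get(subject, set()):
                terms[t] = terms.get(t, False) or (e != "IEA")
            for t, non_iea in terms.items():
                key = (query, t)
                direct[key] = direct.get(key, 0.0) + contribution * (
                    multiplier if non_iea else 1.0
                )
        else:
            for t in pfam_terms.get(subject, set()):
                key = (query, t)
                direct[key] = direct.get(key, 0.0) + contribution

    desc = descendant_sets(parents)
    queries = {q for q, _t in direct}
    weight: dict[tuple[str, str], float] = {}
    for q in queries:
        touched = {t for (qq, t) in direct if qq == q}
        reachable = set()
        for t in touched:
            reachable |= closure_up(parents, t)
        for target in reachable:
            weight[(q, target)] = sum(
                direct.get((q, d), 0.0) for d in desc[target]
            )

    inc = {(q, t): w / weight[(q, root)] for (q, t), w in weight.items()}

    gs: dict[tuple[str, str], float] = {}
    for q in queries:
        terms = [t for (qq, t) in inc if qq == q]
        for i in terms:
            gs[(q, i)] = sum(
                inc[(q, j)] for j in terms
                if brute_lin(parents, ic, i, j) >= sim_threshold
            )

    ts = {
        (q, t): ic[t] * (inc[(q, t)] / gs[(q, t)]) * weight[(q, t)]
        for (q, t) in weight
    }
    return {"ic": ic, "direct": direct, "weight": weight, "inc": inc,
            "gs": gs, "ts": ts}


def brute_pr_points(predictions: dict[str, dict[str, float]],
                    truth: dict[str, set[str]],
                    step: float = 0.01):
    """(threshold, avgPr, avgRc, m) at every threshold, by enumeration."""
    n = len(truth)
    points = []
    k = 0
    while True:
        t = round(k * step, 10)
        if t > 1.0:
            break
        prs, rc_sum, m = [], 0.0, 0
        for v, tv in truth.items():
            pv = {term for term, s in predictions.get(v, {}).items() if s >= t}
            if pv:
                m += 1
                prs.append(len(pv & tv) / len(pv))
                rc_sum += len(pv & tv) / len(tv)
        points.append((t, sum(prs) / m if m else 0.0, rc_sum / n if n else 0.0, m))
        k += 1
    return points


def brute_fmax(points) -> float:
    best = 0.0
    for _t, pr, rc, _m in points:
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def brute_smin(predictions: dict[str, dict[str, float]],
               truth: dict[str, set[str]],
               ic: dict[str, float],
               step: float = 0.01) -> float:
    n = len(truth)
    best = math.inf
    k = 0
    while True:
        t = round(k * step, 10)
        if t > 1.0:
            break
        ru = mi = 0.0
        for v, tv in truth.items():
            pv = {term for term, s in predictions.get(v, {}).items() if s >= t}
            ru += sum(ic[x] for x in tv - pv)
            mi += sum(ic[x] for x in pv - tv)
        best = min(best, math.sqrt((ru / n) ** 2 + (mi / n) ** 2))
        k += 1
    return best
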