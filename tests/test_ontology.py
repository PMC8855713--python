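"""Ontology parsing, ancestor closure, IC and Lin similarity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from gotransfer import (
    FixtureSpec,
    IcTable,
    ReferenceAnnotations,
    compute_ic,
    generate_all,
    joint_parent,
    lin_similarity,
    parse_gaf,
    parse_obo,
)
from gotransfer.ontology import ObsoleteTermError, UnknownTermError

from conftest import CHAIN_OBO, obo_text

BP = "biological_process"


class TestParseObo:
    def test_minimal_chain(self, chain_dag):
        assert len(chain_dag) == 3
        assert chain_dag.roots == {BP: "GO:0000001"}
        assert chain_dag.terms["GO:0000003"].parents == frozenset(
            {("GO:0000002", "is_a")}
        )

    def test_part_of_relationship_becomes_edge(self):
        dag = parse_obo(obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000001", "part_of")]),
        ]))
        assert dag.terms["GO:0000002"].parents == frozenset(
            {("GO:0000001", "part_of")}
        )

    def test_other_relationship_types_ignored(self):
        dag = parse_obo(obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000001", "is_a")]),
            ("GO:0000003", BP, [("GO:0000001", "is_a"),
                                ("GO:0000002", "regulates")]),
        ]))
        assert dag.terms["GO:0000003"].parents == frozenset(
            {("GO:0000001", "is_a")}
        )

    def test_obsolete_term_excluded_but_resolvable(self):
        text = obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000001", "is_a")]),
        ]) + "\n[Term]\nid: GO:0000009\nname: gone\nnamespace: biological_process\nis_obsolete: true\nreplaced_by: GO:0000002\n"
        dag = parse_obo(text)
        assert "GO:0000009" not in dag
        assert "GO:0000009" in dag.obsolete_ids
        assert dag.resolve("GO:0000009") == "GO:0000002"

    def test_alt_id_resolves_to_primary(self):
        text = obo_text([("GO:0000001", BP, [])]).replace(
            "name: GO:0000001", "name: GO:0000001\nalt_id: GO:0000077"
        )
        dag = parse_obo(text)
        assert dag.resolve("GO:0000077") == "GO:0000001"
        assert dag.resolve("GO:0999999") is None

    def test_cycle_is_hard_error(self):
        text = obo_text([
            ("GO:0000001", BP, [("GO:0000002", "is_a")]),
            ("GO:0000002", BP, [("GO:0000001", "is_a")]),
        ])
        with pytest.raises(ValueError, match="cycl"):
            parse_obo(text)

    def test_dangling_parent_is_hard_error(self):
        text = obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000404", "is_a")]),
        ])
        with pytest.raises(ValueError, match="dangling"):
            parse_obo(text)

    def test_multiple_roots_rejected(self):
        text = obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, []),
        ])
        with pytest.raises(ValueError, match="multiple roots"):
            parse_obo(text)


class TestAncestors:
    def test_root_has_no_ancestors(self, chain_dag):
        assert chain_dag.ancestors("GO:0000001") == frozenset()

    def test_chain(self, chain_dag):
        assert chain_dag.ancestors("GO:0000003") == {"GO:0000001", "GO:0000002"}

    def test_diamond_no_duplicates(self, cascade, cascade_dag):
        # d has parents b and c, both under the root
        from conftest import A, B, C, D

        assert cascade_dag.ancestors(D) == {A, B, C}
        assert cascade_dag.ancestors(D) == oracles.closure_up(
            cascade["parents"], D
        ) - {D}

    def test_matches_bruteforce_closure_everywhere(self, cascade, cascade_dag):
        for term in cascade_dag.terms:
            expected = oracles.closure_up(cascade["parents"], term) - {term}
            assert cascade_dag.ancestors(term) == expected

    def test_unknown_vs_obsolete_errors(self, chain_dag):
        with pytest.raises(UnknownTermError):
            chain_dag.ancestors("GO:0770000")
        chain_dag.obsolete_ids = frozenset({"GO:0770000"})
        with pytest.raises(ObsoleteTermError):
            chain_dag.ancestors("GO:0770000")


class TestComputeIc:
    def test_cascade_matches_bruteforce_counts(self, cascade, cascade_dag):
        goa = parse_gaf(cascade["gaf"])
        table = compute_ic(cascade_dag, goa)
        expected = oracles.brute_ic(
            cascade["parents"],
            {p: {t for t, _e in pairs}
             for p, pairs in cascade["annotations"].items()},
        )
        for term, value in expected.items():
            assert table[term] == pytest.approx(value, rel=1e-12)

    def test_root_ic_zero_and_fraction_one(self, cascade, cascade_dag):
        table = compute_ic(cascade_dag, parse_gaf(cascade["gaf"]))
        assert table[cascade["root"]] == 0.0
        assert table.annotated_fraction[cascade["root"]] == 1.0

    def test_one_in_ten_proteins_gives_ic_one(self, chain_dag):
        ann = ReferenceAnnotations()
        ann.add("P00", "GO:0000003", "IEA")
        for i in range(1, 10):
            ann.add(f"P{i:02d}", "GO:0000002", "IEA")
        table = compute_ic(chain_dag, ann)
        assert table["GO:0000003"] == pytest.approx(1.0)

    def test_unannotated_term_gets_namespace_max(self, chain_dag):
        ann = ReferenceAnnotations()
        ann.add("P1", "GO:0000002", "IEA")
        ann.add("P2", "GO:0000001", "IEA")
        table = compute_ic(chain_dag, ann)
        assert table["GO:0000003"] == table.max_ic[BP] == pytest.approx(
            math.log10(2)
        )

    def test_empty_namespace_is_error(self, chain_dag):
        with pytest.raises(ValueError, match=BP):
            compute_ic(chain_dag, ReferenceAnnotations())

    def test_monotone_from_root_to_leaves(self, cascade, cascade_dag):
        table = compute_ic(cascade_dag, parse_gaf(cascade["gaf"]))
        for term in cascade_dag.terms.values():
            for parent, _rel in term.parents:
                assert table[term.id] >= table[parent] - 1e-12


def _hand_ic(values, max_value=None):
    return IcTable(
        ic=dict(values),
        annotated_fraction={},
        max_ic={BP: max_value if max_value is not None else max(values.values())},
    )


class TestLinSimilarity:
    def test_identity_is_one(self, cascade, cascade_dag):
        table = compute_ic(cascade_dag, parse_gaf(cascade["gaf"]))
        for term in cascade_dag.terms:
            assert lin_similarity(table, cascade_dag, term, term) == 1.0

    def test_textbook_arithmetic(self):
        # k (IC 1) is the sole informative common ancestor of i and j (IC 2)
        dag = parse_obo(obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000001", "is_a")]),       # k
            ("GO:0000003", BP, [("GO:0000002", "is_a")]),       # i
            ("GO:0000004", BP, [("GO:0000002", "is_a")]),       # j
        ]))
        table = _hand_ic({"GO:0000001": 0.0, "GO:0000002": 1.0,
                          "GO:0000003": 2.0, "GO:0000004": 2.0})
        assert lin_similarity(table, dag, "GO:0000003", "GO:0000004") == \
            pytest.approx(0.5)

    def test_ancestor_pair_uses_the_ancestor(self, cascade, cascade_dag):
        from conftest import B, H

        table = compute_ic(cascade_dag, parse_gaf(cascade["gaf"]))
        expected = 2 * table[B] / (table[B] + table[H])
        assert lin_similarity(table, cascade_dag, B, H) == pytest.approx(expected)
        assert lin_similarity(table, cascade_dag, B, H) == pytest.approx(
            oracles.brute_lin(cascade["parents"],
                              {t: table[t] for t in cascade_dag.terms}, B, H)
        )

    def test_zero_information_pair_is_zero(self, chain_dag):
        table = _hand_ic({"GO:0000001": 0.0, "GO:0000002": 0.0,
                          "GO:0000003": 1.0}, max_value=1.0)
        assert lin_similarity(table, chain_dag, "GO:0000001", "GO:0000002") == 0.0

    def test_cross_namespace_rejected(self):
        dag = parse_obo(obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000005", "molecular_function", []),
        ]))
        table = _hand_ic({"GO:0000001": 0.0, "GO:0000005": 0.0})
        with pytest.raises(ValueError, match="namespace"):
            lin_similarity(table, dag, "GO:0000001", "GO:0000005")


class TestJointParent:
    def test_siblings_meet_at_parent(self, cascade, cascade_dag):
        from conftest import B, E, H

        table = compute_ic(cascade_dag, parse_gaf(cascade["gaf"]))
        # E and H share ancestors {E, B, A} ∩ {H, E, B, A} = {E, B, A}; E deepest
        assert joint_parent(table, cascade_dag, E, H) == E

    def test_ancestor_of_other_returns_ancestor(self, chain_dag):
        table = _hand_ic({"GO:0000001": 0.0, "GO:0000002": 0.5,
                          "GO:0000003": 1.0})
        assert joint_parent(table, chain_dag, "GO:0000002", "GO:0000003") == \
            "GO:0000002"

    def test_picks_most_informative_common_ancestor(self):
        # i has two common ancestors with j: GO:...2 (IC 1) and GO:...3 (IC 2)
        dag = parse_obo(obo_text([
            ("GO:0000001", BP, []),
            ("GO:0000002", BP, [("GO:0000001", "is_a")]),
            ("GO:0000003", BP, [("GO:0000002", "is_a")]),
            ("GO:0000004", BP, [("GO:0000003", "is_a")]),
            ("GO:0000005", BP, [("GO:0000003", "is_a")]),
        ]))
        table = _hand_ic({"GO:0000001": 0.0, "GO:0000002": 1.0,
                          "GO:0000003": 2.0, "GO:0000004": 3.0,
                          "GO:0000005": 3.0})
        assert joint_parent(table, dag, "GO:0000004", "GO:0000005") == "GO:0000003"
        assert joint_parent(table, dag, "GO:0000004", "GO:0000005") == \
            oracles.brute_joint_parent(
                {"GO:0000002": {"GO:0000001"}, "GO:0000003": {"GO:0000002"},
                 "GO:0000004": {"GO:0000003"}, "GO:0000005": {"GO:0000003"}},
                table.ic, "GO:0000004", "GO:0000005")


class TestDagProperties:
    """Structural invariants on randomly generated DAGs."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_random_fixture_dags_satisfy_invariants(self, seed):
        files = generate_all(FixtureSpec(seed=seed, n_terms=7))
        dag = parse_obo(files["obo"])
        goa = parse_gaf(files["gaf"])
        table = compute_ic(dag, goa)
        for ns, root in dag.roots.items():
            assert table[root] == 0.0
        terms = list(dag.terms)
        for term in terms:
            # closure is idempotent
            closed = dag.ancestors_and_self(term)
            reclosed = set(closed)
            for t in closed:
                reclosed |= dag.ancestors_and_self(t)
            assert reclosed == closed
            # IC monotone along edges
            for parent, _rel in dag.terms[term].parents:
                assert table[term] >= table[parent] - 1e-12
        rng_pairs = [(terms[i], terms[j])
                     for i in range(0, len(terms), 3)
                     for j in range(0, len(terms), 4)]
        for i, j in rng_pairs:
            if dag.namespace_of(i) != dag.namespace_of(j):
                continue
            sim_ij = lin_similarity(table, dag, i, j)
            sim_ji = lin_similarity(table, dag, j, i)
            assert sim_ij == pytest.approx(sim_ji)
            assert 0.0 <= sim_ij <= 1.0 + 1e-12
            k = joint_parent(table, dag, i, j)
            assert k in dag.ancestors_and_self(i)
            assert k in dag.ancestors_and_self(j)
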