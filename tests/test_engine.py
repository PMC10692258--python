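"""Decision-tree validation and stepwise traversal."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mcitriage as m
from mcitriage import TriageCategory as T
from mcitriage.engine import _definition_from_dict
from mcitriage.errors import (
    AlgorithmReferenceError,
    AlgorithmStructureError,
    TriageError,
    VocabularyError,
)
from mcitriage.vocabulary import CANONICAL_QUERIES, RESOURCE_QUERY

from conftest import full_answers


def tiny_def(nodes, root="n1", name="BER", role="secondary"):
    return _definition_from_dict({"name": name, "role": role, "root": root, "nodes": nodes})


ALWAYS_T3 = {"n1": {"kind": "leaf", "outcome": "T3"}}


class TestValidation:
    def test_single_leaf_definition_is_valid_with_zero_steps(self, vignette_factory):
        algo = tiny_def(ALWAYS_T3)
        result = m.triage(vignette_factory(), algo)
        assert (result.assigned, result.steps, result.path) == (T.T3, 0, ("n1",))

    def test_missing_branch_rejected(self):
        with pytest.raises(AlgorithmStructureError):
            tiny_def(
                {
                    "n1": {"kind": "binary_query", "query": "can_walk",
                           "branches": {"no": "n2"}},
                    "n2": {"kind": "leaf", "outcome": "T3"},
                }
            )

    def test_branch_to_undefined_node_rejected(self):
        with pytest.raises(AlgorithmReferenceError):
            tiny_def(
                {
                    "n1": {"kind": "binary_query", "query": "can_walk",
                           "branches": {"yes": "ghost", "no": "n2"}},
                    "n2": {"kind": "leaf", "outcome": "T3"},
                }
            )

    def test_cycle_rejected(self):
        with pytest.raises(AlgorithmStructureError, match="cycle"):
            tiny_def(
                {
                    "n1": {"kind": "binary_query", "query": "can_walk",
                           "branches": {"yes": "n2", "no": "n2"}},
                    "n2": {"kind": "binary_query", "query": "rr_gt_29",
                           "branches": {"yes": "n1", "no": "n3"}},
                    "n3": {"kind": "leaf", "outcome": "T3"},
                }
            )

    def test_unreachable_node_rejected(self):
        with pytest.raises(AlgorithmStructureError, match="unreachable"):
            tiny_def({**ALWAYS_T3, "orphan": {"kind": "leaf", "outcome": "T1"}})

    def test_resource_node_outside_esi_rejected(self):
        nodes = {
            "n1": {"kind": "resource_query", "query": RESOURCE_QUERY,
                   "branches": {"0": "n2", "1": "n2", "2": "n2"}},
            "n2": {"kind": "leaf", "outcome": "T3"},
        }
        with pytest.raises(AlgorithmStructureError, match="resource"):
            tiny_def(nodes, name="BER")
        assert tiny_def(nodes, name="ESI").name == "ESI"

    def test_secondary_algorithm_may_not_assign_special_outcomes(self):
        with pytest.raises(AlgorithmStructureError):
            tiny_def({"n1": {"kind": "leaf", "outcome": "DECEASED"}}, role="secondary")
        assert tiny_def(
            {"n1": {"kind": "leaf", "outcome": "DECEASED"}}, name="PETRA", role="primary"
        ).nodes["n1"].outcome is T.DECEASED

    def test_unknown_query_vocabulary_rejected(self):
        with pytest.raises(VocabularyError):
            tiny_def(
                {
                    "n1": {"kind": "binary_query", "query": "has_halo",
                           "branches": {"yes": "n2", "no": "n2"}},
                    "n2": {"kind": "leaf", "outcome": "T3"},
                }
            )


class TestResolveQuery:
    def test_codes_map_to_yes_no(self, vignette_factory):
        v = vignette_factory(can_walk="1", rr_gt_29="0")
        assert m.resolve_query(v, "can_walk") == "yes"
        assert m.resolve_query(v, "rr_gt_29") == "no"

    def test_alias_resolution(self, vignette_factory):
        v = vignette_factory(pelvic_fracture="1")
        assert m.resolve_query(v, "unstable_pelvis") == "yes"

    @pytest.mark.parametrize(
        "policy, binary, resource",
        [("no", "no", "0"), ("yes", "yes", "2")],
    )
    def test_n_policy_resolution(self, vignette_factory, policy, binary, resource):
        v = vignette_factory(fast_performed_positive="n", esi_resources="n")
        assert m.resolve_query(v, "fast_performed_positive", n_policy=policy) == binary
        assert m.resolve_query(v, RESOURCE_QUERY, n_policy=policy) == resource

    def test_n_policy_error_aborts(self, vignette_factory):
        with pytest.raises(TriageError):
            m.resolve_query(
                vignette_factory(fast_performed_positive="n"),
                "fast_performed_positive",
                n_policy="error",
            )

    def test_resource_codes_pass_through(self, vignette_factory):
        assert m.resolve_query(vignette_factory(esi_resources="2"), RESOURCE_QUERY) == "2"

    def test_unanswered_query_is_a_vocabulary_error(self):
        v = m.Vignette("v1", {"can_walk": "1"})
        with pytest.raises(VocabularyError):
            m.resolve_query(v, "rr_gt_29")


class TestEsiLevelMapping:
    @pytest.mark.parametrize(
        "level, category",
        [(1, T.T1), (2, T.T2), (3, T.T3), (4, T.T3), (5, T.T3)],
    )
    def test_grouping(self, level, category):
        assert m.esi_level_to_category(level) is category

    @pytest.mark.parametrize("level", [0, 6, -1])
    def test_out_of_range(self, level):
        with pytest.raises(ValueError):
            m.esi_level_to_category(level)


class TestTraversal:
    def test_walking_casualty_exits_mstart_green_in_one_step(
        self, algorithms, vignette_factory
    ):
        r = m.triage(vignette_factory(can_walk="1"), algorithms["mSTaRT"])
        assert (r.assigned, r.steps) == (T.T3, 1)

    def test_immediate_lifesaving_exits_esi_red_in_one_step(
        self, algorithms, vignette_factory
    ):
        r = m.triage(
            vignette_factory(requires_immediate_lifesaving="1"), algorithms["ESI"]
        )
        assert (r.assigned, r.steps, r.esi_level) == (T.T1, 1, 1)

    def test_fully_negative_casualty_traverses_all_of_ber(
        self, algorithms, vignette_factory
    ):
        r = m.triage(vignette_factory(), algorithms["BER"])
        assert (r.assigned, r.steps) == (T.T3, 17)

    def test_n_policy_hits_are_counted(self, algorithms, vignette_factory):
        v = vignette_factory(fast_performed_positive="n", blunt_abdominal_trauma="n")
        r = m.triage(v, algorithms["BER"])
        assert r.n_policy_hits == 2
        assert r.assigned is T.T3  # both n-answers resolved to "no"

    def test_apnoeic_unresponsive_casualty_is_deceased_under_mstart(
        self, algorithms, vignette_factory
    ):
        v = vignette_factory(
            spontaneous_breathing="0", breathing_after_airway_opening="0"
        )
        r = m.triage(v, algorithms["mSTaRT"])
        assert (r.assigned, r.steps) == (T.DECEASED, 4)


class TestRunAll:
    def test_cross_product_row_count(self, algorithms):
        vset = m.generate_vignettes(210, seed=1)
        table = m.run_all(vset, algorithms.values())
        assert len(table) == 210 * 7

    def test_vignette_major_order_and_determinism(self, algorithms):
        vset = m.generate_vignettes(25, seed=2)
        t1 = m.run_all(vset, algorithms.values())
        t2 = m.run_all(vset, algorithms.values())
        assert t1.equals(t2)
        assert list(t1["vignette_id"][:7]) == [vset[0].id] * 7

    def test_empty_set_gives_empty_table(self, algorithms):
        table = m.run_all(m.VignetteSet(), algorithms.values())
        assert len(table) == 0
        assert list(table.columns) == [
            "vignette_id", "algorithm", "assigned", "steps", "n_policy_hits", "path",
        ]


class TestPathLengthProfile:
    def test_degenerate_tree(self):
        assert m.path_length_profile(tiny_def(ALWAYS_T3)) == {T.T3: (0, 0)}

    def test_esi_places_a_red_leaf_at_step_one(self, algorithms):
        assert m.path_length_profile(algorithms["ESI"])[T.T1] == (1, 1)

    def test_jord_longest_path_is_eleven_queries(self, algorithms):
        profile = m.path_length_profile(algorithms["JorD"])
        assert max(hi for _, hi in profile.values()) == 11


answer_vectors = st.fixed_dictionaries(
    {
        q: (
            st.sampled_from(["0", "1", "2", "n"])
            if q == RESOURCE_QUERY
            else st.sampled_from(["0", "1", "n"])
        )
        for q in sorted(CANONICAL_QUERIES)
    }
)


class TestTraversalProperties:
    @settings(derandomize=True, max_examples=150)
    @given(answers=answer_vectors, policy=st.sampled_from(["no", "yes"]))
    def test_every_total_assignment_reaches_a_leaf_deterministically(
        self, algorithms, answers, policy
    ):
        v = m.Vignette("fuzz", answers)
        for algo in algorithms.values():
            r1 = m.triage(v, algo, n_policy=policy)
            r2 = m.triage(v, algo, n_policy=policy)
            assert r1 == r2
            assert algo.nodes[r1.path[-1]].is_leaf
            assert r1.steps == len(r1.path) - 1
            lo, hi = m.path_length_profile(algo)[r1.assigned]
            assert lo <= r1.steps <= hi
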