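import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import matrix_from_rows
from yhap.fixtures import CHILD_ORDER, PRIMARY_MARKERS, table1_cohort
from yhap.haplotree import CladeNode, Haplotree
from yhap.placement import (
    DerivedSet,
    IncompatibleMarkersError,
    build_refined_tree,
    classify_pair,
    derived_set,
    detect_incompatibilities,
)
from yhap.simulate import expected_counts_cohort


def dset(marker, carriers, observed):
    return DerivedSet(marker, frozenset(carriers), frozenset(observed))


class TestDerivedSet:
    def test_all_derived_column(self):
        m = matrix_from_rows({"S1": {"M1": "D"}, "S2": {"M1": "D"}})
        ds = derived_set(m, "M1")
        assert ds.carriers == ds.observed == {"S1", "S2"}

    def test_all_no_call_column(self):
        m = matrix_from_rows({"S1": {"M1": "N"}, "S2": {"M1": "N"}})
        ds = derived_set(m, "M1")
        assert ds.observed == frozenset()

    def test_unknown_marker(self):
        m = matrix_from_rows({"S1": {"M1": "A"}})
        with pytest.raises(KeyError):
            derived_set(m, "M9")

    def test_carriers_must_be_observed(self):
        with pytest.raises(ValueError):
            dset("M1", {"S1"}, set())


class TestClassifyPair:
    def test_equivalent(self):
        rel = classify_pair(dset("A", {1, 2}, {1, 2, 3}),
                            dset("B", {1, 2}, {1, 2, 3}))
        assert rel.relation == "equivalent" and not rel.ambiguous

    def test_downstream_marker_is_descendant(self):
        # derived in a subset of the root's carriers
        root = dset("root", {1, 2, 3, 4}, {1, 2, 3, 4})
        sub = dset("sub", {1, 2}, {1, 2, 3, 4})
        assert classify_pair(root, sub).relation == "ancestor"
        assert classify_pair(sub, root).relation == "descendant"

    def test_overlap_without_nesting_is_incompatible(self):
        rel = classify_pair(dset("A", {1, 2}, {1, 2, 3}),
                            dset("B", {2, 3}, {1, 2, 3}))
        assert rel.relation == "incompatible"
        assert (rel.n_both, rel.n_a_only, rel.n_b_only) == (1, 1, 1)

    def test_disjoint(self):
        rel = classify_pair(dset("A", {1}, {1, 2, 3}),
                            dset("B", {2}, {1, 2, 3}))
        assert rel.relation == "disjoint" and not rel.ambiguous

    def test_vacuous_pairs_are_ambiguous(self):
        no_overlap = classify_pair(dset("A", {1}, {1}), dset("B", {2}, {2}))
        assert no_overlap.ambiguous
        both_empty = classify_pair(dset("A", set(), {1, 2}),
                                   dset("B", set(), {1, 2}))
        assert both_empty.relation == "equivalent" and both_empty.ambiguous

    @given(
        st.sets(st.integers(0, 7)), st.sets(st.integers(0, 7)),
        st.sets(st.integers(0, 7)), st.sets(st.integers(0, 7)),
    )
    @settings(derandomize=True, max_examples=120)
    def test_ancestor_descendant_duality(self, ca, oa, cb, ob):
        a = dset("A", ca & (oa | ca), oa | ca)
        b = dset("B", cb & (ob | cb), ob | cb)
        ab, ba = classify_pair(a, b), classify_pair(b, a)
        dual = {"ancestor": "descendant", "descendant": "ancestor"}
        assert ba.relation == dual.get(ab.relation, ab.relation)
        assert (ab.n_a_only, ab.n_b_only) == (ba.n_b_only, ba.n_a_only)


def _chain_matrix():
    """6 samples x 4 markers: root + one equivalent, one child, one grandchild."""
    return matrix_from_rows({
        "S1": {"R": "D", "Req": "D", "C": "D", "G": "D"},
        "S2": {"R": "D", "Req": "D", "C": "D", "G": "D"},
        "S3": {"R": "D", "Req": "D", "C": "D", "G": "A"},
        "S4": {"R": "D", "Req": "D", "C": "A", "G": "A"},
        "S5": {"R": "D", "Req": "D", "C": "A", "G": "A"},
        "S6": {"R": "A", "Req": "A", "C": "A", "G": "A"},
    })


def brute_force_chain_oracle(matrix):
    """Enumerate every rooted tree on the three carrier-distinct classes;
    keep those where every strict carrier containment is an ancestor
    relation (the perfect-phylogeny condition)."""
    classes = {
        "root": frozenset({"S1", "S2", "S3", "S4", "S5"}),
        "child": frozenset({"S1", "S2", "S3"}),
        "grand": frozenset({"S1", "S2"}),
    }

    def ancestors(assignment, node):
        out = set()
        while assignment.get(node) is not None:
            node = assignment[node]
            if node in out:  # cycle
                return None
            out.add(node)
        return out

    valid = []
    non_root = ["child", "grand"]
    for parents in itertools.product(["root", "child", "grand"], repeat=2):
        assignment = {"root": None, **dict(zip(non_root, parents))}
        if any(k == v for k, v in assignment.items()):
            continue
        anc = {k: ancestors(assignment, k) for k in classes}
        if any(a is None for a in anc.values()):
            continue
        if all(
            (y in anc[x]) == (classes[x] < classes[y])
            for x in classes for y in classes if x != y
        ):
            valid.append({k: v for k, v in assignment.items() if v is not None})
    return valid


class TestBuildRefinedTree:
    def test_chain_recovered_and_unique_by_enumeration(self):
        matrix = _chain_matrix()
        oracle = brute_force_chain_oracle(matrix)
        assert oracle == [{"child": "root", "grand": "child"}]

        tree, report = build_refined_tree(matrix, "R", root_name="Q1")
        names = [(n.ycc_name, set(n.defining_markers)) for n in tree.root.preorder()]
        assert names == [("Q1", {"R", "Req"}), ("Q1a", {"C"}), ("Q1a1", {"G"})]
        assert report.placed["Req"] == "R"
        assert report.excluded_samples == ["S6"]

    def test_single_root_marker(self):
        m = matrix_from_rows({"S1": {"R": "D"}, "S2": {"R": "A"}})
        tree, _ = build_refined_tree(m, "R", root_name="Q1")
        assert tree.node_names() == ["Q1"]

    def test_marker_without_carriers_unplaced(self):
        m = matrix_from_rows({"S1": {"R": "D", "M": "A"},
                              "S2": {"R": "D", "M": "N"}})
        tree, report = build_refined_tree(m, "R", root_name="Q1")
        assert report.unplaced_no_carriers == ["M"]
        assert tree.node_names() == ["Q1"]

    def test_root_conflict_reported_and_excluded(self):
        # S3 derived at M but ancestral at the root marker
        m = matrix_from_rows({"S1": {"R": "D", "M": "D"},
                              "S2": {"R": "D", "M": "A"},
                              "S3": {"R": "A", "M": "D"}})
        tree, report = build_refined_tree(m, "R", root_name="Q1")
        assert report.root_conflicts == {"M": ["S3"]}
        assert [n.ycc_name for n in tree.root.preorder()] == ["Q1", "Q1a"]

    def test_strict_homoplasy_is_a_hard_error(self):
        m = matrix_from_rows({
            "S1": {"R": "D", "A1": "D", "B1": "A"},
            "S2": {"R": "D", "A1": "D", "B1": "D"},
            "S3": {"R": "D", "A1": "A", "B1": "D"},
        })
        with pytest.raises(IncompatibleMarkersError) as err:
            build_refined_tree(m, "R", root_name="Q1")
        assert ("A1", "B1") in [(a, b) for a, b, _ in err.value.pairs]

    def test_drop_lower_callrate_policy(self):
        m = matrix_from_rows({
            "S1": {"R": "D", "A1": "D", "B1": "A"},
            "S2": {"R": "D", "A1": "D", "B1": "D"},
            "S3": {"R": "D", "A1": "A", "B1": "D"},
            "S4": {"R": "D", "A1": "A", "B1": "N"},
        })
        tree, report = build_refined_tree(m, "R", root_name="Q1",
                                          homoplasy_policy="drop-lower-callrate")
        assert report.dropped_incompatible == ["B1"]
        assert "B1" not in tree.markers()


class TestDetectIncompatibilities:
    def test_clean_cohort_has_none(self):
        matrix, _, _ = table1_cohort(include_outside=False)
        assert detect_incompatibilities(matrix, "002611") == []

    def test_injected_homoplasy_found_once(self):
        matrix, _, _ = table1_cohort(include_outside=False)
        calls = matrix.calls.copy()
        # a column overlapping two disjoint subclades violates nesting
        calls["HOMO"] = "A"
        carriers = list(calls.index[calls["F632"] == "D"])[:2] + \
            list(calls.index[calls["F449"] == "D"])[:2]
        calls.loc[carriers, "HOMO"] = "D"
        from yhap.genotype_io import GenotypeMatrix

        found = detect_incompatibilities(GenotypeMatrix(calls), "002611")
        assert found, "homoplasious column must be flagged"
        pairs = [(a, b) for a, b, _ in found]
        assert len(pairs) == len(set(pairs))  # each unordered pair once
        assert all("HOMO" in p for p in pairs)


def random_perfect_tree(seed, max_nodes=12):
    """Random rooted tree, 1-3 markers per node, every node >= 1 exclusive
    carrier; returns (Haplotree, exclusive counts)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    parents = [int(rng.integers(0, i)) for i in range(1, n)]
    nodes = [CladeNode(ycc_name=f"node{i}",
                       defining_markers=tuple(
                           f"M{i}_{k}" for k in range(int(rng.integers(1, 4)))))
             for i in range(n)]
    for i, p in enumerate(parents, start=1):
        nodes[p].children.append(nodes[i])
    tree = Haplotree(nodes[0], root_letter="Q")
    tree.assign_names("Q1")
    counts = {node.ycc_name: int(rng.integers(1, 20))
              for node in tree.root.preorder()}
    return tree, counts


@pytest.mark.parametrize("seed", range(10))
def test_perfect_phylogeny_recovery(seed):
    """Error-free, fully called cohorts give back the generating tree:
    identical marker classes with identical parent classes."""
    truth_tree, counts = random_perfect_tree(seed)
    matrix, _, _ = expected_counts_cohort(truth_tree, counts)
    root_marker = truth_tree.root.defining_markers[0]
    recovered, report = build_refined_tree(matrix, root_marker, root_name="Q1")

    def class_edges(tree):
        edges = set()
        for node in tree.root.preorder():
            parent = tree.parent_name(node.ycc_name)
            parent_markers = (frozenset(tree.node(parent).defining_markers)
                              if parent else None)
            edges.add((frozenset(node.defining_markers), parent_markers))
        return edges

    assert class_edges(recovered) == class_edges(truth_tree)
    assert not report.ambiguous_merges
    assert not report.unplaced_no_carriers


@pytest.mark.parametrize("seed", range(5))
def test_no_calls_never_create_incompatibility(seed):
    """Monotone degradation: masking calls to N on a perfect cohort may
    lose resolution but never produces an 'incompatible' relation."""
    truth_tree, counts = random_perfect_tree(seed, max_nodes=8)
    matrix, _, _ = expected_counts_cohort(truth_tree, counts)
    rng = np.random.default_rng(seed + 1000)
    calls = matrix.calls.copy()
    values = calls.to_numpy(dtype=object)
    values[rng.random(values.shape) < 0.3] = "N"
    from yhap.genotype_io import GenotypeMatrix

    masked = GenotypeMatrix(
        calls.__class__(values, index=calls.index, columns=calls.columns))
    root_marker = truth_tree.root.defining_markers[0]
    if (masked.column(root_marker) == "D").sum() == 0:
        return
    assert detect_incompatibilities(masked, root_marker) == []
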