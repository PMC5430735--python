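import numpy as np
import pandas as pd
import pytest

from yhap.calling import call_cohort
from yhap.simulate import (
    OUTSIDE,
    SimulationConfig,
    concordance,
    expected_counts_cohort,
    simulate_cohort,
)


@pytest.fixture()
def small_freqs():
    return {"O2a1c1a": 0.08, "O2a1c1a1": 0.04, "O2a1c1b1": 0.02, "O2a1c2": 0.01}


def make_config(fig1_tree, freqs, **kwargs):
    defaults = dict(n_samples=300, seed=11)
    defaults.update(kwargs)
    return SimulationConfig(tree=fig1_tree, exclusive_freqs=dict(freqs), **defaults)


class TestSimulationConfig:
    def test_outside_probability_completed(self, fig1_tree, small_freqs):
        config = make_config(fig1_tree, small_freqs)
        assert config.exclusive_freqs[OUTSIDE] == pytest.approx(0.85)

    def test_invalid_probability_rejected(self, fig1_tree):
        with pytest.raises(ValueError):
            make_config(fig1_tree, {"O2a1c1a": 1.5})
        with pytest.raises(ValueError):
            make_config(fig1_tree, {"O2a1c1a": 0.5, OUTSIDE: 0.6})

    def test_unknown_node_rejected(self, fig1_tree):
        with pytest.raises(ValueError):
            make_config(fig1_tree, {"O9": 0.5})

    def test_file_round_trip(self, fig1_tree, small_freqs, tmp_path):
        config = make_config(fig1_tree, small_freqs)
        path = tmp_path / "sim.json"
        config.to_file(path)
        loaded = SimulationConfig.from_file(path)
        assert loaded.exclusive_freqs == config.exclusive_freqs
        assert loaded.tree.to_dict() == fig1_tree.to_dict()


class TestSimulateCohort:
    def test_same_seed_bit_identical(self, fig1_tree, small_freqs):
        a = simulate_cohort(make_config(fig1_tree, small_freqs, seed=5))
        b = simulate_cohort(make_config(fig1_tree, small_freqs, seed=5))
        assert a[0].calls.equals(b[0].calls)
        assert a[1].equals(b[1])

    def test_different_seeds_differ(self, fig1_tree, small_freqs):
        a = simulate_cohort(make_config(fig1_tree, small_freqs, seed=5))
        b = simulate_cohort(make_config(fig1_tree, small_freqs, seed=6))
        assert not a[0].calls.equals(b[0].calls)

    def test_all_outside_is_all_ancestral(self, fig1_tree):
        config = SimulationConfig(tree=fig1_tree, exclusive_freqs={OUTSIDE: 1.0},
                                  n_samples=1, seed=0)
        matrix, truth, _ = simulate_cohort(config)
        assert (matrix.calls == "A").all().all()
        assert truth["true_node"].tolist() == [OUTSIDE]

    def test_column_is_union_of_subtree_truth(self, fig1_tree, small_freqs):
        """Error-free: each marker's carriers are exactly the samples whose
        true node lies in that marker's subtree."""
        matrix, truth, _ = simulate_cohort(make_config(fig1_tree, small_freqs))
        truth_node = truth.set_index("sample_id")["true_node"]
        for marker in ("002611", "F18", "F11", "F632", "F449", "L133.2"):
            node = fig1_tree.node_of_marker(marker)
            subtree = {n.ycc_name for n in fig1_tree.subtree_nodes(node)}
            expected = set(truth_node.index[truth_node.isin(subtree)])
            col = matrix.column(marker)
            assert set(col.index[col == "D"]) == expected

    def test_count_means_approach_expectation(self, fig1_tree, small_freqs):
        """Multinomial sanity: seed-averaged node counts within 3 SE."""
        n, runs = 300, 20
        totals = {name: 0 for name in small_freqs}
        for seed in range(runs):
            _, truth, _ = simulate_cohort(
                make_config(fig1_tree, small_freqs, seed=seed))
            counts = truth["true_node"].value_counts()
            for name in totals:
                totals[name] += int(counts.get(name, 0))
        for name, p in small_freqs.items():
            mean = totals[name] / runs
            se = np.sqrt(n * p * (1 - p) / runs)
            assert abs(mean - n * p) <= 3 * se + 1e-9, name

    def test_error_rate_lowers_concordance(self, fig1_tree, small_freqs):
        config = make_config(fig1_tree, small_freqs, error_rate=0.05,
                             n_samples=500, seed=3)
        matrix, truth, _ = simulate_cohort(config)
        assignments = call_cohort(fig1_tree, matrix)
        called = pd.DataFrame({
            "sample_id": [a.sample_id for a in assignments],
            "called_node": [a.node if a.in_clade else OUTSIDE
                            for a in assignments],
        })
        frac, confusion = concordance(truth, called)
        assert frac < 1.0
        assert confusion
        assert any(a.path_conflicts for a in assignments)


class TestExpectedCounts:
    def test_fixture_regenerates_305_in_clade(self, fixture_cohort):
        matrix, truth, _ = fixture_cohort
        assert matrix.shape[0] == 2139
        assert int((truth["true_node"] != OUTSIDE).sum()) == 305

    def test_zero_table_is_empty(self, fig1_tree):
        matrix, truth, meta = expected_counts_cohort(fig1_tree, {})
        assert matrix.shape[0] == 0 and truth.empty and meta == []

    def test_negative_count_rejected(self, fig1_tree):
        with pytest.raises(ValueError):
            expected_counts_cohort(fig1_tree, {"O2a1c": -1})

    def test_region_split_must_sum(self, fig1_tree):
        with pytest.raises(ValueError, match="sum to"):
            expected_counts_cohort(fig1_tree, {"O2a1c": 3},
                                   {"O2a1c": {"East": 1, "North": 1}})

    def test_per_node_recall_is_exact(self, fig1_tree):
        counts = {"O2a1c1a5": 4, "O2a1c1b": 2, OUTSIDE: 3}
        matrix, truth, _ = expected_counts_cohort(fig1_tree, counts)
        assignments = call_cohort(fig1_tree, matrix)
        got = {}
        for a in assignments:
            key = a.node if a.in_clade else OUTSIDE
            got[key] = got.get(key, 0) + 1
        assert got == counts

    def test_latent_exclusive_carriers_fall_to_parent_star(self, fig1_tree):
        """Samples of an untyped lineage are indistinguishable from the
        parent's paragroup — the documented consequence of a latent node."""
        matrix, _, _ = expected_counts_cohort(fig1_tree, {"O2a1c1a6": 5})
        assignments = call_cohort(fig1_tree, matrix)
        assert {a.display_name() for a in assignments} == {"O2a1c1a*"}


class TestConcordance:
    def test_identical_inputs(self):
        truth = pd.DataFrame({"sample_id": ["S1", "S2"],
                              "true_node": ["X1", "X2"]})
        called = pd.DataFrame({"sample_id": ["S2", "S1"],
                               "called_node": ["X2", "X1"]})
        frac, confusion = concordance(truth, called)
        assert frac == 1.0 and confusion == []

    def test_id_mismatch_rejected(self):
        truth = pd.DataFrame({"sample_id": ["S1"], "true_node": ["X1"]})
        called = pd.DataFrame({"sample_id": ["S9"], "called_node": ["X1"]})
        with pytest.raises(ValueError):
            concordance(truth, called)
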