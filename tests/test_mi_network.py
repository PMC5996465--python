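import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdrenet import (
    ConfigurationError,
    DomainError,
    MIResult,
    PreconditionError,
    StructuralError,
    all_pairs_mi,
    auto_bins,
    binned_entropy,
    build_bipartite_network,
    discretize,
    mutual_information,
    percentile_filter,
    read_gml,
    write_gml,
)
from conftest import make_matrix


def grid_result(mi_values, n_mirs, n_genes, n_bins=10, n_samples=200):
    """Wrap a flat MI vector over an (n_mirs x n_genes) pair grid."""
    mi_values = np.asarray(mi_values, dtype=float)
    assert mi_values.size == n_mirs * n_genes
    mir_index, gene_index = np.divmod(np.arange(mi_values.size), n_genes)
    return MIResult(
        [f"m{i}" for i in range(n_mirs)],
        [f"g{j}" for j in range(n_genes)],
        mir_index, gene_index, mi_values, n_bins, n_samples,
    )


class TestDiscretize:
    def test_median_split(self):
        np.testing.assert_array_equal(
            discretize(np.array([1.0, 2.0, 3.0, 4.0]), 2), [0, 0, 1, 1]
        )

    def test_constant_vector_all_zero(self):
        assert (discretize(np.full(11, 3.3), 5) == 0).all()

    def test_equal_frequency_counts(self):
        labels = discretize(np.random.default_rng(0).normal(size=400), 4)
        counts = np.bincount(labels, minlength=4)
        assert (np.abs(counts - 100) <= 1).all()

    def test_ties_take_lower_bin_deterministically(self):
        v = np.array([2.0, 1.0, 2.0, 3.0])  # the two 2s share rank 1
        labels = discretize(v, 4)
        assert labels[0] == labels[2] == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ConfigurationError):
            discretize(np.arange(5.0), 1)

    def test_auto_bins_policy(self):
        assert auto_bins(200) == 15
        assert auto_bins(100_000) == 20  # capped


class TestMutualInformation:
    def test_identical_binary_uniform_is_one_bit(self):
        x = np.tile([0, 1], 10)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_degenerate_marginal_is_zero(self):
        x = np.tile([0, 1], 10)
        assert mutual_information(x, np.zeros(20, dtype=int)) == 0.0

    def test_hand_evaluated_2x2_table(self):
        # joint counts [[2,1],[1,2]], n=6: direct plug-in evaluation
        x = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([0, 0, 1, 0, 1, 1])
        expected = sum(
            (c / 6) * math.log2((c / 6) / (0.5 * 0.5)) for c in (2, 1, 1, 2)
        )
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            mutual_information(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(5, 60))
    def test_symmetry_exact_and_nonnegative(self, seed, n_bins, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, n_bins, n)
        y = rng.integers(0, n_bins, n)
        mi = mutual_information(x, y)
        assert mi == mutual_information(y, x)  # bitwise equal
        assert mi >= 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 8))
    def test_self_mi_equals_binned_entropy(self, seed, n_bins):
        x = np.random.default_rng(seed).integers(0, n_bins, 40)
        assert mutual_information(x, x) == binned_entropy(x)

    def test_noise_never_increases_mean_mi(self):
        # data-processing flavor: y plus noise carries no extra information
        n_bins, n = 8, 150
        deltas = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=n)
            y = x + 0.3 * rng.normal(size=n)
            y_noisier = y + 1.0 * rng.normal(size=n)
            xb = discretize(x, n_bins)
            deltas.append(
                mutual_information(xb, discretize(y_noisier, n_bins))
                - mutual_information(xb, discretize(y, n_bins))
            )
        assert np.mean(deltas) < 0


class TestAllPairs:
    def test_cardinality(self):
        rng = np.random.default_rng(1)
        mir = make_matrix(rng.uniform(size=(2, 30)), "mir")
        gene = make_matrix(rng.uniform(size=(3, 30)), "gene")
        res = all_pairs_mi(mir, gene, n_bins=4)
        assert len(res) == 6
        assert (res.mi >= 0).all()

    def test_duplicated_profile_attains_max(self):
        rng = np.random.default_rng(2)
        mir_vals = rng.uniform(size=(3, 60))
        gene_vals = rng.uniform(size=(10, 60))
        gene_vals[4] = mir_vals[1]  # gene4 duplicates mir1
        res = all_pairs_mi(
            make_matrix(mir_vals, "mir"), make_matrix(gene_vals, "gene"), 5
        )
        df = res.to_frame()
        best = df.loc[df["mi"].idxmax()]
        assert (best["mir_id"], best["gene_id"]) == ("mir1", "gene4")

    def test_agrees_with_scalar_estimator(self):
        rng = np.random.default_rng(3)
        mir = make_matrix(rng.normal(size=(4, 50)), "mir")
        gene = make_matrix(np.abs(rng.normal(size=(5, 50))), "gene")
        res = all_pairs_mi(mir, gene, n_bins=6)
        for _, row in res.to_frame().iterrows():
            xb = discretize(mir.values.loc[row["mir_id"]].to_numpy(), 6)
            yb = discretize(gene.values.loc[row["gene_id"]].to_numpy(), 6)
            assert row["mi"] == pytest.approx(mutual_information(xb, yb), abs=1e-10)

    def test_permutation_destroys_dependence(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        coupled = 0.9 * x + 0.2 * rng.normal(size=200)
        shuffled = rng.permutation(coupled)
        mir = make_matrix(x[None, :], "mir")
        res_paired = all_pairs_mi(mir, make_matrix(coupled[None, :], "gene"), 10)
        res_broken = all_pairs_mi(mir, make_matrix(shuffled[None, :], "gene"), 10)
        assert res_broken.mi[0] < res_paired.mi[0] / 2

    def test_zero_variance_feature_scores_zero(self):
        rng = np.random.default_rng(5)
        mir = make_matrix(rng.uniform(size=(1, 40)), "mir")
        gene = make_matrix(np.full((1, 40), 7.0), "gene")
        assert all_pairs_mi(mir, gene, 4).mi[0] == 0.0

    def test_unaligned_samples_rejected(self):
        mir = make_matrix(np.random.default_rng(6).uniform(size=(2, 12)), "mir")
        gene = make_matrix(np.random.default_rng(7).uniform(size=(2, 12)), "gene")
        gene.values.columns = [f"t{j}" for j in range(12)]
        with pytest.raises(PreconditionError):
            all_pairs_mi(mir, gene, 3)


class TestPercentileFilter:
    def test_distinct_values_exact_count(self):
        mi = np.random.default_rng(8).permutation(1000) / 1000.0
        edges = percentile_filter(grid_result(mi, 10, 100), 0.99)
        assert len(edges) == 10
        kept = {e[2] for e in edges}
        assert kept == set(np.sort(mi)[-10:])

    def test_all_ties_retained(self):
        edges = percentile_filter(grid_result(np.full(100, 0.5), 10, 10), 0.9)
        assert len(edges) == 100  # cutoff value is tied everywhere: keep all

    def test_quantile_out_of_domain(self):
        res = grid_result(np.arange(10.0), 2, 5)
        for q in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ConfigurationError):
                percentile_filter(res, q)

    def test_null_calibration_fraction(self):
        # independent profiles: the fraction of fresh pairs above the
        # 0.99741 quantile of a same-law reference null is ~0.259%
        rng = np.random.default_rng(9)

        def null_mi(n_pairs, rng):
            n_mirs = 40
            n_genes = n_pairs // n_mirs
            mir = make_matrix(rng.normal(size=(n_mirs, 200)), "mir")
            gene = make_matrix(np.abs(rng.normal(size=(n_genes, 200))), "gene")
            return all_pairs_mi(mir, gene, n_bins=10).mi

        reference = null_mi(20_000, rng)
        fresh = null_mi(20_000, rng)
        cutoff = np.quantile(reference, 0.99741)
        frac = (fresh > cutoff).mean()
        p = 1 - 0.99741
        se = math.sqrt(p * (1 - p) / fresh.size)
        assert abs(frac - p) < 4 * se + 1e-9


class TestNetworkConstruction:
    def test_node_sets_from_edges_only(self):
        edges = [("m1", "g1", 0.5), ("m1", "g2", 0.4), ("m2", "g3", 0.3)]
        G = build_bipartite_network(edges)
        assert G.number_of_edges() == 3
        classes = {d["feature_class"] for _, d in G.nodes(data=True)}
        assert classes == {"mir", "gene"}
        assert set(G.nodes) == {"m1", "m2", "g1", "g2", "g3"}

    def test_empty_edge_list(self):
        G = build_bipartite_network([])
        assert G.number_of_nodes() == 0 and G.number_of_edges() == 0

    def test_same_node_in_both_roles_rejected(self):
        with pytest.raises(StructuralError):
            build_bipartite_network([("x", "g1", 0.1), ("m1", "x", 0.2)])


class TestGmlRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path, toy_graph):
        import pandas as pd

        lfc = pd.Series({"A": 1.25, "3": -0.75})
        oriented = [
            (u, v, d["weight"])
            if toy_graph.nodes[u]["feature_class"] == "mir"
            else (v, u, d["weight"])
            for u, v, d in toy_graph.edges(data=True)
        ]
        G = build_bipartite_network(oriented, lfc)
        path = tmp_path / "net.gml"
        write_gml(G, path)
        back = read_gml(path)
        assert set(back.nodes) == set(G.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, G.edges))
        for u, v, d in G.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"], abs=1e-6)
        assert back.nodes["A"]["lfc"] == pytest.approx(1.25)
        assert back.nodes["A"]["feature_class"] == "mir"
        assert back.nodes["3"]["lfc"] == pytest.approx(-0.75)

    def test_empty_network_round_trips(self, tmp_path):
        path = tmp_path / "empty.gml"
        write_gml(build_bipartite_network([]), path)
        assert read_gml(path).number_of_nodes() == 0

    def test_same_class_edge_rejected_on_read(self, tmp_path):
        path = tmp_path / "bad.gml"
        path.write_text(
            'graph [\n'
            '  node [ id 0 label "g1" feature_class "gene" ]\n'
            '  node [ id 1 label "g2" feature_class "gene" ]\n'
            '  edge [ source 0 target 1 value 0.5 ]\n'
            ']\n'
        )
        with pytest.raises(StructuralError):
            read_gml(path)

    def test_malformed_gml_raises_parse_error(self, tmp_path):
        from cdrenet import ParseError

        path = tmp_path / "broken.gml"
        path.write_text("graph [ node [ id 0\n")
        with pytest.raises(ParseError):
            read_gml(path)
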