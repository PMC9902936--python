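"""Density roles, membership propagation and the full clustering pipeline."""

import numpy as np
import pandas as pd
import pytest

from clam.containers import CLAMError
from clam.cluster import (
    assign,
    compute_density,
    find_centers_outliers,
    init_membership,
    iterate,
    run_clam,
    solve_membership,
)
from clam.graph import Similarity, fuse, knn_weights
from clam.simulate import SimulationConfig, generate, truth_comparison
from tests.test_graph import graph_from_dict, sim_from_matrix


def clustered_points_graph(seed, n, k=4, n_clumps=3, spread=0.7):
    """KNN graph over 2D clustered points with similarity 1/(1+d)."""
    gen = np.random.default_rng(seed)
    centers = gen.uniform(-6, 6, size=(n_clumps, 2))
    pts = np.vstack(
        [c + gen.normal(0, spread, size=(n // n_clumps + 1, 2)) for c in centers]
    )[:n]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    sim = 1 / (1 + d)
    np.fill_diagonal(sim, 0)
    genes = [f"g{i:02d}" for i in range(n)]
    return knn_weights(sim_from_matrix(sim, genes), k=k)


class TestDensity:
    def test_mean_of_neighbor_similarities(self):
        graph = graph_from_dict(
            {"x": [("a", 0.45, 0.9), ("b", 0.3, 0.6), ("c", 0.25, 0.5)],
             "a": [("x", 1.0, 0.9)], "b": [("x", 1.0, 0.6)], "c": [("x", 1.0, 0.5)]}
        )
        density = compute_density(graph)
        assert density["x"] == pytest.approx(2.0 / 3.0)

    def test_constant_similarities(self):
        graph = graph_from_dict(
            {"x": [("a", 0.5, 0.42), ("b", 0.5, 0.42)], "a": [("x", 1.0, 0.42)], "b": [("x", 1.0, 0.42)]}
        )
        assert compute_density(graph)["x"] == pytest.approx(0.42)

    def test_matches_independent_recomputation(self, rng):
        graph = clustered_points_graph(3, 10, k=3)
        density = compute_density(graph)
        for gene in graph.objects:
            sims = [s for _, _, s in graph.neighbors[gene]]
            assert density[gene] == pytest.approx(sum(sims) / len(sims))


class TestRoles:
    def test_two_clumps_two_centers(self):
        graph = clustered_points_graph(11, 14, k=4, n_clumps=2, spread=0.5)
        density = compute_density(graph)
        table = find_centers_outliers(graph, density, outlier_threshold=None)
        # brute-force oracle over the strict rule
        expected_centers = sorted(
            g
            for g in graph.objects
            if all(density[g] > density[n] for n in graph.neighbor_ids(g))
        )
        assert table.centers == expected_centers
        assert len(table.centers) == 2

    def test_density_tie_is_ordinary(self):
        graph = graph_from_dict(
            {"a": [("b", 1.0, 0.5)], "b": [("a", 0.5, 0.5), ("c", 0.5, 0.9)],
             "c": [("b", 1.0, 0.9)]}
        )
        density = pd.Series({"a": 0.5, "b": 0.5, "c": 0.9})
        table = find_centers_outliers(graph, density, outlier_threshold=None)
        assert table.roles["a"] == "ordinary"

    def test_uniform_densities_is_error(self):
        graph = graph_from_dict(
            {"a": [("b", 1.0, 0.5)], "b": [("a", 1.0, 0.5)]}
        )
        density = pd.Series({"a": 0.5, "b": 0.5})
        with pytest.raises(CLAMError):
            find_centers_outliers(graph, density)

    def test_threshold_mode_protects_dense_minima(self):
        # chain of densities 1.0 > 0.8 > 0.6, all far above the mean of a
        # low-density tail: the 0.6 gene is a strict local minimum but must
        # stay ordinary; the tail genes become outlier prototypes
        neighbors = {
            "hub": [("mid", 1.0, 0.9)],
            "mid": [("hub", 0.5, 0.9), ("low", 0.5, 0.8)],
            "low": [("mid", 1.0, 0.8)],
            "noise1": [("noise2", 1.0, 0.05)],
            "noise2": [("noise1", 1.0, 0.05)],
        }
        graph = graph_from_dict(neighbors)
        density = pd.Series(
            {"hub": 1.0, "mid": 0.8, "low": 0.6, "noise1": 0.05, "noise2": 0.06}
        )
        table = find_centers_outliers(graph, density, outlier_threshold="mean")
        assert table.roles["low"] == "ordinary"
        assert table.roles["noise1"] == "outlier"
        assert table.roles["noise2"] == "outlier"
        strict = find_centers_outliers(graph, density, outlier_threshold=None)
        assert strict.roles["low"] == "outlier"


class TestInitMembership:
    def test_vectors(self):
        graph = clustered_points_graph(5, 18, k=4, n_clumps=3, spread=0.5)
        density = compute_density(graph)
        table = find_centers_outliers(graph, density, outlier_threshold=None)
        state = init_membership(table)
        M = len(state.centers)
        for gene in state.membership.index:
            vec = state.membership.loc[gene].to_numpy()
            if gene in state.centers:
                slot = state.centers.index(gene)
                assert vec[slot] == 1.0 and vec.sum() == 1.0
            elif gene in state.outliers:
                assert vec[M] == 1.0 and vec.sum() == 1.0
            else:
                assert np.allclose(vec, 1.0 / (M + 1))


class TestIterate:
    def test_absorbing_one_hot_neighborhood(self):
        # ordinary object fed only by centers of cluster 1 converges there
        graph = graph_from_dict(
            {"c1": [("x", 1.0, 0.9)], "c2": [("x", 1.0, 0.1)],
             "x": [("c1", 0.6, 0.9), ("c1b", 0.4, 0.8)],
             "c1b": [("c1", 1.0, 0.9)]}
        )
        density = pd.Series({"c1": 0.9, "c1b": 0.85, "c2": 0.95, "x": 0.2})
        import pandas as pd2

        roles = pd2.Series({"c1": "center", "c1b": "center", "c2": "center", "x": "ordinary"})
        from clam.cluster import DensityTable

        table = DensityTable(density=density, roles=roles)
        state = iterate(init_membership(table), graph, tol=1e-12)
        vec = state.membership.loc["x"]
        # c1 and c1b are distinct centers; x's mass splits between their
        # clusters only, never the third slot or the outlier slot
        assert vec[state.membership.columns[-1]] == pytest.approx(0.0)
        assert vec.sum() == pytest.approx(1.0)
        assert vec.loc["cluster_1"] == pytest.approx(0.6)

    def test_symmetric_split_converges_symmetric(self):
        graph = graph_from_dict(
            {"a": [("x", 1.0, 0.9)], "b": [("x", 1.0, 0.9)],
             "x": [("a", 0.5, 0.9), ("b", 0.5, 0.9)]}
        )
        from clam.cluster import DensityTable

        table = DensityTable(
            density=pd.Series({"a": 0.9, "b": 0.9, "x": 0.5}),
            roles=pd.Series({"a": "center", "b": "center", "x": "ordinary"}),
        )
        state = iterate(init_membership(table), graph, tol=1e-12)
        vec = state.membership.loc["x"]
        assert vec["cluster_1"] == pytest.approx(vec["cluster_2"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_fixed_point_equals_linear_solve(self, seed):
        graph = clustered_points_graph(seed, 12 + 3 * seed, k=4)
        density = compute_density(graph)
        table = find_centers_outliers(graph, density)
        init = init_membership(table)
        state = iterate(init, graph, tol=1e-13, max_iter=20000)
        exact = solve_membership(init, graph)
        diff = np.abs(state.membership.to_numpy() - exact.to_numpy()).max()
        assert diff < 1e-6

    def test_free_residual_monotone_and_simplex_kept(self):
        graph = clustered_points_graph(9, 21, k=4)
        density = compute_density(graph)
        table = find_centers_outliers(graph, density)
        state = iterate(init_membership(table), graph, tol=1e-10, max_iter=5000)
        path = np.array(state.free_residual_path)
        assert np.all(np.diff(path[1:]) <= 1e-12)
        sums = state.membership.to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (state.membership.to_numpy() >= -1e-12).all()


class TestAssign:
    def _state(self, vectors, centers=("c1", "c2"), outliers=()):
        from clam.cluster import MembershipState

        frame = pd.DataFrame(
            vectors, columns=["cluster_1", "cluster_2", "outlier"]
        ).T
        return MembershipState(
            membership=frame.T, centers=list(centers), outliers=list(outliers)
        )

    def test_argmax_and_outlier_slot(self):
        frame = pd.DataFrame(
            {
                "a": [0.7, 0.2, 0.1],
                "b": [0.2, 0.2, 0.6],
                "c": [0.5, 0.5, 0.0],
            }
        ).T
        frame.columns = ["cluster_1", "cluster_2", "outlier"]
        from clam.cluster import MembershipState

        state = MembershipState(membership=frame, centers=["c1", "c2"], outliers=[])
        modules = assign(state)
        assert "a" in modules.modules["module_1"]
        assert "b" in modules.outliers
        assert "c" in modules.modules["module_1"]  # tie -> lowest index

    def test_min_size_folding(self):
        frame = pd.DataFrame(
            {
                "a": [1.0, 0.0, 0.0],
                "b": [0.9, 0.1, 0.0],
                "c": [0.8, 0.1, 0.1],
                "d": [0.0, 1.0, 0.0],
            }
        ).T
        frame.columns = ["cluster_1", "cluster_2", "outlier"]
        from clam.cluster import MembershipState

        state = MembershipState(membership=frame, centers=["a", "d"], outliers=[])
        modules = assign(state, min_module_size=2)
        assert "d" in modules.outliers
        assert len(modules.modules) == 1


class TestPipeline:
    def test_deterministic(self):
        study = generate(SimulationConfig(seed=2, n_background=60, n_modules=3))
        a = run_clam(study.datasets, study.interactions)
        b = run_clam(study.datasets, study.interactions)
        assert a.modules == b.modules
        assert a.outliers == b.outliers

    def test_single_dataset_matches_individual_clustering(self):
        study = generate(SimulationConfig(seed=5, n_datasets=1, n_background=60, n_modules=3))
        merged = run_clam(study.datasets, None, use_prior=False)
        assert len(merged.modules) >= 1

    def test_namespaced_mode_keeps_layers_distinct(self):
        study = generate(SimulationConfig(seed=2, n_background=40, n_modules=2))
        modules = run_clam(study.datasets, None, use_prior=False, merge_identifiers=False)
        genes = set().union(*modules.modules.values()) | modules.outliers
        assert all("@omics_" in g for g in genes)

    def test_unrenormalized_prior_path_stays_on_simplex(self):
        study = generate(SimulationConfig(seed=2, n_background=40, n_modules=2))
        _, state, _, _ = run_clam(
            study.datasets,
            study.interactions,
            renormalize_prior=False,
            return_state=True,
        )
        sums = state.membership.to_numpy().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_planted_modules_recovered(self):
        study = generate(SimulationConfig(seed=3))
        modules = run_clam(study.datasets, study.interactions)
        scores = truth_comparison(modules, study.truth)
        assert scores["ari"] >= 0.9

    def test_centers_non_increasing_in_k(self):
        """Wider neighborhoods resolve fewer local density maxima.

        Checked on a fixed geometric fixture with well-separated clumps,
        where k genuinely controls the resolution of the density landscape.
        """
        gen = np.random.default_rng(4)
        centers = gen.uniform(-8, 8, size=(5, 2))
        pts = np.vstack([c + gen.normal(0, 0.8, size=(25, 2)) for c in centers])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        sim = 1 / (1 + d)
        np.fill_diagonal(sim, 0)
        table_sim = sim_from_matrix(sim, [f"g{i:03d}" for i in range(len(pts))])
        counts = []
        for k in range(5, 16):
            graph = knn_weights(table_sim, k)
            table = find_centers_outliers(graph, compute_density(graph))
            counts.append(len(table.centers))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]
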