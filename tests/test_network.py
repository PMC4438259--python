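import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coexstack import network as nw
from coexstack.io_formats import ConsistencyError, ExpressionMatrix
from coexstack.synthetic_data import SyntheticConfig, generate, \
    evaluate_module_recovery

from conftest import brute_force_tom, random_adjacency


def matrix_from_values(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])], values)


class TestSignedAdjacency:
    def test_correlation_endpoints(self):
        s = np.arange(5.0)
        mat = matrix_from_values([s, 2 * s + 1, -s])
        for beta in (1, 5, 12):
            a = nw.signed_adjacency(mat, beta)
            assert a[0, 1] == pytest.approx(1.0)       # r = +1
            assert a[0, 2] == pytest.approx(0.0)       # r = -1
            assert np.all(np.diag(a) == 0.0)

    def test_known_correlation_value(self):
        # two features engineered to have Pearson r = 0.6 exactly
        x = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        y = 0.6 * x + np.sqrt(1 - 0.36) * np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        x = x - x.mean()
        y = y - y.mean()
        r = float(np.corrcoef(x, y)[0, 1])
        mat = matrix_from_values([x, y])
        a = nw.signed_adjacency(mat, 5)
        assert a[0, 1] == pytest.approx(((1 + r) / 2) ** 5, rel=1e-12)

    def test_r06_beta5_closed_form(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=200)
        e = rng.normal(size=200)
        # empirical check of the transform itself on arbitrary data
        mat = matrix_from_values([z, 0.5 * z + e])
        r = np.corrcoef(mat.values)[0, 1]
        a = nw.signed_adjacency(mat, 5)
        assert a[0, 1] == pytest.approx(((1 + r) / 2) ** 5, rel=1e-12)
        assert ((1 + 0.6) / 2) ** 5 == pytest.approx(0.32768)

    def test_zero_variance_rejected(self):
        mat = matrix_from_values([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.raises(ConsistencyError, match="intersect_features"):
            nw.signed_adjacency(mat, 5)


class TestScaleFreeFit:
    @staticmethod
    def clique_fixture():
        """Exact power-law degree fixture: counts 64/32/16 at k = 1/2/4.

        Each bin is one clique whose uniform edge weight realizes the
        target connectivity exactly, so log10(count) is exactly linear in
        log10(k) with slope -1.
        """
        blocks = []
        for count, k in [(64, 1.0), (32, 2.0), (16, 4.0)]:
            w = k / (count - 1)
            b = np.full((count, count), w)
            np.fill_diagonal(b, 0.0)
            blocks.append(b)
        n = sum(b.shape[0] for b in blocks)
        a = np.zeros((n, n))
        o = 0
        for b in blocks:
            m = b.shape[0]
            a[o:o + m, o:o + m] = b
            o += m
        return a

    def test_exact_power_law_returns_one(self):
        assert nw.scale_free_fit(self.clique_fixture()) == pytest.approx(
            1.0, abs=1e-9)

    def test_gaussian_noise_fits_poorly_at_beta_one(self):
        rng = np.random.default_rng(11)
        mat = matrix_from_values(rng.normal(size=(300, 20)))
        a = nw.signed_adjacency(mat, 1)
        assert nw.scale_free_fit(a) < 0.85

    def test_increasing_degree_trend_gives_negative_value(self):
        # mirror the power-law fixture: counts grow with k
        blocks = []
        for count, k in [(16, 1.0), (32, 2.0), (64, 4.0)]:
            w = k / (count - 1)
            b = np.full((count, count), w)
            np.fill_diagonal(b, 0.0)
            blocks.append(b)
        n = sum(b.shape[0] for b in blocks)
        a = np.zeros((n, n))
        o = 0
        for b in blocks:
            m = b.shape[0]
            a[o:o + m, o:o + m] = b
            o += m
        assert nw.scale_free_fit(a) < 0.0

    def test_identical_connectivities_error(self):
        a = np.ones((20, 20)) - np.eye(20)
        with pytest.raises(ConsistencyError):
            nw.scale_free_fit(a)


class TestPickSoftThreshold:
    @pytest.fixture(scope="class")
    @staticmethod
    def modular_matrix():
        ds = generate(SyntheticConfig(
            n_modules_a=4, n_modules_b=0, module_sizes=80, n_background=80,
            loading_range=(0.7, 0.9), coupled_pairs=[], effect_modules=[],
            seed=21))
        return ds.layer_a

    def test_matches_independent_per_beta_scan(self, modular_matrix):
        # oracle: evaluate the fit per beta directly and find the first
        # candidate crossing the target
        target = 0.4
        crossings = []
        for beta in range(1, 21):
            a = nw.signed_adjacency(modular_matrix, beta)
            if nw.scale_free_fit(a) >= target:
                crossings.append(beta)
        assert crossings, "fixture must cross the target"
        pick = nw.pick_soft_threshold(modular_matrix, target_r2=target)
        assert pick.beta == crossings[0]
        assert pick.reached_target

    def test_target_zero_returns_smallest_positive_fit(self, modular_matrix):
        pick = nw.pick_soft_threshold(modular_matrix, target_r2=0.0)
        scan = pick.table
        first_positive = int(scan.loc[scan["r2"] >= 0, "beta"].iloc[0])
        assert pick.beta == first_positive

    def test_noise_data_falls_back_to_max_r2_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        mat = matrix_from_values(rng.normal(size=(120, 15)))
        with caplog.at_level("WARNING", logger="coexstack"):
            pick = nw.pick_soft_threshold(mat, candidate_betas=range(1, 7),
                                          target_r2=0.99)
        assert not pick.reached_target
        assert pick.beta == int(pick.table.loc[pick.table["r2"].idxmax(),
                                               "beta"])
        assert any("no candidate" in r.message for r in caplog.records)

    def test_empty_candidates_error(self, modular_matrix):
        with pytest.raises(ValueError):
            nw.pick_soft_threshold(modular_matrix, candidate_betas=[])


class TestTopologicalOverlap:
    def test_three_node_clique_hand_value(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = nw.topological_overlap(a)
        # l_12 = 1, k = 2 -> (1+1)/(2+1-1) = 1
        assert np.allclose(tom, 1.0)

    def test_star_graph_leaf_pair(self):
        a = np.zeros((4, 4))
        a[0, 1:] = a[1:, 0] = 1.0
        tom = nw.topological_overlap(a)
        # leaves share the hub: (1+0)/(1+1-0) = 0.5
        assert tom[1, 2] == pytest.approx(0.5)

    def test_zero_adjacency(self):
        tom = nw.topological_overlap(np.zeros((5, 5)))
        assert np.allclose(tom, np.eye(5))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = random_adjacency(rng, 20)
            assert np.max(np.abs(nw.topological_overlap(a)
                                 - brute_force_tom(a))) < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_symmetry_property(self, seed):
        a = random_adjacency(np.random.default_rng(seed), 12)
        tom = nw.topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert np.all((tom >= 0.0) & (tom <= 1.0))
        assert np.allclose(np.diag(tom), 1.0)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ConsistencyError):
            nw.topological_overlap(np.ones((3, 3)))  # nonzero diagonal
        bad = np.zeros((3, 3))
        bad[0, 1] = 0.5
        with pytest.raises(ConsistencyError):
            nw.topological_overlap(bad)  # asymmetric


class TestClusterAndCut:
    @staticmethod
    def two_block_tom(sizes=(6, 5)):
        rng = np.random.default_rng(8)
        profiles = [rng.normal(size=12), rng.normal(size=12)]
        rows = [profiles[b] for b, size in enumerate(sizes) for _ in range(size)]
        mat = matrix_from_values(np.array(rows) +
                                 rng.normal(scale=1e-6, size=(sum(sizes), 12)))
        a = nw.signed_adjacency(mat, 6)
        return nw.topological_overlap(a), mat.feature_ids

    def test_planted_blocks_recovered(self):
        tom, ids = self.two_block_tom()
        part = nw.cluster_and_cut(tom, ids, min_module_size=4, cut_height=0.99)
        assert sorted(part.module_sizes.values()) == [5, 6]
        labels = [part.assignment[f] for f in ids]
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_min_size_above_blocks_leaves_all_unassigned(self):
        tom, ids = self.two_block_tom()
        part = nw.cluster_and_cut(tom, ids, min_module_size=7, cut_height=0.99)
        assert part.module_sizes == {}
        assert set(part.assignment.values()) == {0}

    def test_permutation_invariance_up_to_relabeling(self):
        cfg = SyntheticConfig(n_modules_a=3, n_modules_b=0, module_sizes=40,
                              n_background=20, loading_range=(0.8, 0.9),
                              coupled_pairs=[], effect_modules=[], seed=9)
        mat = generate(cfg).layer_a
        a = nw.signed_adjacency(mat, 8)
        tom = nw.topological_overlap(a)
        part = nw.cluster_and_cut(tom, mat.feature_ids, 30, 0.995)
        perm = np.random.default_rng(0).permutation(len(mat.feature_ids))
        ids_p = [mat.feature_ids[i] for i in perm]
        tom_p = tom[np.ix_(perm, perm)]
        part_p = nw.cluster_and_cut(tom_p, ids_p, 30, 0.995)
        assert part_p.assignment == part.assignment

    def test_three_block_recovery_ari(self):
        cfg = SyntheticConfig(
            n_samples_per_group={"control": 12, "case": 12},
            n_modules_a=3, n_modules_b=0, module_sizes=50, n_background=30,
            loading_range=(0.85, 0.95), coupled_pairs=[], effect_modules=[],
            seed=31)
        ds = generate(cfg)
        a = nw.signed_adjacency(ds.layer_a, 18)
        part = nw.cluster_and_cut(nw.topological_overlap(a),
                                  ds.layer_a.feature_ids, 40, 0.99)
        rec = evaluate_module_recovery(ds.truth_partition_a, part)
        assert rec.ari >= 0.9


class TestModuleEigengene:
    def test_identical_rows_give_member_correlation_one(self):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=10)
        mat = matrix_from_values([profile * 2 + 1, profile, profile - 3])
        part = nw.ModulePartition({f: 1 for f in mat.feature_ids})
        eig = nw.module_eigengene(mat, part).loc[1].to_numpy()
        for row in mat.values:
            assert np.corrcoef(eig, row)[0, 1] == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_sign_orientation_stable_under_global_flip(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 15))
        vals[1:] = vals[0] + rng.normal(scale=0.3, size=(5, 15))
        mat = matrix_from_values(vals)
        part = nw.ModulePartition({f: 1 for f in mat.feature_ids})
        eig = nw.module_eigengene(mat, part).loc[1].to_numpy()
        flipped = matrix_from_values(-vals)
        eig_f = nw.module_eigengene(flipped, part).loc[1].to_numpy()
        corr = [np.corrcoef(eig, row)[0, 1] for row in vals]
        corr_f = [np.corrcoef(eig_f, row)[0, 1] for row in -vals]
        assert np.mean(corr) > 0 and np.mean(corr_f) > 0

    def test_planted_eigengene_recovered(self):
        cfg = SyntheticConfig(
            n_samples_per_group={"control": 12, "case": 12},
            n_modules_a=1, n_modules_b=0, module_sizes=50, n_background=0,
            loading_range=(0.8, 0.8), coupled_pairs=[], effect_modules=[],
            seed=13)
        ds = generate(cfg)
        part = nw.ModulePartition(ds.truth_partition_a)
        eig = nw.module_eigengene(ds.layer_a, part).loc[1].to_numpy()
        # reconstruct the planted factor as the mean member profile
        planted = ds.layer_a.values.mean(axis=0)
        assert abs(np.corrcoef(eig, planted)[0, 1]) >= 0.95

    def test_singleton_module_rejected(self, small_matrix):
        part = nw.ModulePartition({"gA": 1, "gB": 0, "gC": 0})
        with pytest.raises(ConsistencyError):
            nw.module_eigengene(small_matrix, part)


class TestHubGenes:
    def test_high_connectivity_feature_ranks_first(self):
        rng = np.random.default_rng(6)
        hub = rng.normal(size=20)
        rows = [hub] + [0.9 * hub + 0.44 * rng.normal(size=20)
                        for _ in range(6)]
        mat = matrix_from_values(rows)
        a = nw.signed_adjacency(mat, 4)
        part = nw.ModulePartition({f: 1 for f in mat.feature_ids})
        ranked = nw.hub_genes(part, a, mat.feature_ids, top_n=3)[1]
        assert ranked[0] == "g0"

    def test_top_n_and_order_invariance(self):
        rng = np.random.default_rng(14)
        mat = matrix_from_values(rng.normal(size=(8, 10)))
        a = nw.signed_adjacency(mat, 2)
        part = nw.ModulePartition({f: 1 for f in mat.feature_ids})
        full = nw.hub_genes(part, a, mat.feature_ids, top_n=100)[1]
        assert sorted(full) == sorted(mat.feature_ids)
        perm = np.random.default_rng(1).permutation(8)
        ids_p = [mat.feature_ids[i] for i in perm]
        a_p = a[np.ix_(perm, perm)]
        assert nw.hub_genes(part, a_p, ids_p, top_n=100)[1] == full
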