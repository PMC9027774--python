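"""Network construction: adjacency, TOM, modules, eigengenes, GS/MM, hubs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from comethyl.conetwork import (
    GREY,
    CoMethylationNetwork,
    ModuleAssignment,
    compute_adjacency,
    compute_eigengenes,
    compute_tom,
    detect_modules,
    export_edges,
    gene_significance,
    intramodular_connectivity,
    merge_close_modules,
    module_gs_summary,
    module_membership,
    pick_soft_threshold,
    select_hubs,
)


def _profiles(rows, prefix="F"):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return pd.DataFrame(
        rows,
        index=pd.Index([f"{prefix}{i}" for i in range(rows.shape[0])], name="feature_id"),
        columns=[f"s{j}" for j in range(rows.shape[1])],
    )


def _exact_correlation_pair(rho):
    """Two profiles whose sample Pearson correlation is exactly rho."""
    x = np.array([1.0, -1.0, 1.0, -1.0])
    z = np.array([1.0, 1.0, -1.0, -1.0])  # zero-mean, orthogonal to x
    return _profiles([x, rho * x + np.sqrt(1 - rho**2) * z])


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Literal triple-loop topological overlap (independent oracle)."""
    n = a.shape[0]
    out = np.eye(n)
    k = [sum(a[i, j] for j in range(n) if j != i) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j)) + a[i, j]
            out[i, j] = num / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def _random_adjacency(rng, n=20):
    a = rng.uniform(size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        adj = compute_adjacency(_exact_correlation_pair(1.0 - 1e-15), power=14)
        assert adj.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.9, -0.9])
    def test_power_fourteen_worked_case(self, rho):
        adj = compute_adjacency(_exact_correlation_pair(rho), power=14)
        assert adj.iloc[0, 1] == pytest.approx(0.9**14, rel=1e-9)
        assert adj.iloc[0, 1] == pytest.approx(0.2288, abs=1e-4)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(7)
        adj = compute_adjacency(_profiles(rng.normal(size=(15, 10))), power=6)
        a = adj.to_numpy()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1

    def test_zero_variance_feature_named_in_error(self):
        rows = np.vstack([np.random.default_rng(0).normal(size=(3, 6)), np.zeros(6)])
        with pytest.raises(ValueError, match="F3"):
            compute_adjacency(_profiles(rows), power=6)


class TestTom:
    def test_three_node_hand_cases(self):
        half = np.full((3, 3), 0.5)
        np.fill_diagonal(half, 1.0)
        tom = compute_tom(pd.DataFrame(half)).tom.to_numpy()
        assert tom[0, 1] == pytest.approx(0.5, abs=1e-12)

        ones = np.ones((3, 3))
        tom = compute_tom(pd.DataFrame(ones)).tom.to_numpy()
        assert tom[0, 1] == pytest.approx(1.0, abs=1e-12)

        zero = np.eye(3)
        tom = compute_tom(pd.DataFrame(zero)).tom.to_numpy()
        assert tom[0, 1] == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        worst = 0.0
        for seed in range(50):
            a = _random_adjacency(np.random.default_rng(seed))
            fast = compute_tom(pd.DataFrame(a)).tom.to_numpy()
            worst = max(worst, np.abs(fast - tom_brute_force(a)).max())
        assert worst < 1e-10

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            result = compute_tom(pd.DataFrame(_random_adjacency(rng, n=12)))
            tom = result.tom.to_numpy()
            assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(result.dist_tom.to_numpy()), 0.0)

    def test_connectivity_excludes_diagonal(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        assert compute_tom(pd.DataFrame(a)).connectivity.tolist() == [1.0, 1.0, 1.0]


class TestDetectModules:
    @staticmethod
    def _block_dist(sizes, within=0.1, between=0.9):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(
            d, index=[f"F{i}" for i in range(n)], columns=[f"F{i}" for i in range(n)]
        )

    def test_two_blocks_sized_sixty_forty(self):
        assignment = detect_modules(self._block_dist([60, 40]), cut_height=0.5,
                                    min_module_size=10)
        sizes = assignment.sizes()
        assert sizes["turquoise"] == 60
        assert sizes["blue"] == 40

    def test_single_block_single_module(self):
        assignment = detect_modules(self._block_dist([30]), cut_height=0.5,
                                    min_module_size=10)
        assert assignment.sizes().to_dict() == {"turquoise": 30}

    def test_small_cluster_goes_grey(self):
        assignment = detect_modules(self._block_dist([40, 5]), cut_height=0.5,
                                    min_module_size=10)
        sizes = assignment.sizes()
        assert sizes["turquoise"] == 40 and sizes[GREY] == 5

    def test_cut_height_validated(self):
        with pytest.raises(ValueError, match="cut_height"):
            detect_modules(self._block_dist([10]), cut_height=1.5)


class TestEigengenes:
    def test_identical_profiles_with_sign_flips(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=12)
        profiles = _profiles([v, v + 0.0, -v])  # majority positive orientation
        assignment = ModuleAssignment(pd.Series(["turquoise"] * 3, index=profiles.index))
        me = compute_eigengenes(profiles, assignment)["ME_turquoise"]
        assert abs(np.corrcoef(me, v)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert me.std(ddof=1) == pytest.approx(1.0)

    def test_orientation_mean_member_correlation_nonnegative(self, planted_study):
        net = planted_study.net
        profiles = planted_study.regions.values
        for module in net.assignment_.module_names:
            members = net.assignment_.members(module)
            me = net.eigengenes_[f"ME_{module}"]
            cors = [np.corrcoef(profiles.loc[f], me)[0, 1] for f in members]
            assert np.mean(cors) >= 0

    def test_recovers_planted_factors(self, planted_study):
        truth, net = planted_study.truth, planted_study.net
        for k in truth.module_ids:
            best = max(
                abs(np.corrcoef(truth.factors[f"factor_{k}"], net.eigengenes_[c])[0, 1])
                for c in net.eigengenes_.columns
            )
            assert best >= 0.9


class TestMerge:
    def test_modules_from_same_factor_are_merged(self):
        rng = np.random.default_rng(7)
        factor = rng.normal(size=20)
        profiles = _profiles(
            factor[None, :] * rng.uniform(0.7, 0.9, size=(40, 1))
            + rng.normal(0, 0.2, size=(40, 20))
        )
        labels = pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=profiles.index)
        merged = merge_close_modules(profiles, ModuleAssignment(labels), merge_cut=0.15)
        assert merged.module_names == ["turquoise"]

    def test_distinct_factors_not_merged(self):
        rng = np.random.default_rng(7)
        f1, f2 = rng.normal(size=(2, 25))
        block = lambda f: f[None, :] * 0.8 + rng.normal(0, 0.2, size=(15, 25))
        profiles = _profiles(np.vstack([block(f1), block(f2)]))
        labels = pd.Series(["turquoise"] * 15 + ["blue"] * 15, index=profiles.index)
        merged = merge_close_modules(profiles, ModuleAssignment(labels), merge_cut=0.15)
        assert len(merged.module_names) == 2

    def test_merge_is_idempotent(self, planted_study):
        net = planted_study.net
        again = merge_close_modules(
            planted_study.regions.values, net.assignment_, merge_cut=0.15
        )
        pd.testing.assert_series_equal(again.labels, net.assignment_.labels)


class TestGsMmHubs:
    @pytest.mark.parametrize("p,expected", [(0.5, 1.0), (1.0, 0.0), (0.05, np.log2(20))])
    def test_gene_significance_values(self, p, expected):
        assert gene_significance([p])[0] == pytest.approx(expected, rel=1e-12)

    def test_p_zero_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            gs = gene_significance([0.0])
        assert np.isfinite(gs[0])

    def test_mm_of_feature_equal_and_orthogonal_to_eigengene(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        profiles = _profiles([x, z])
        me = pd.DataFrame({"ME_turquoise": x}, index=profiles.columns)
        mm = module_membership(profiles, me)
        assert mm.loc["F0", "ME_turquoise"] == pytest.approx(1.0, abs=1e-12)
        assert mm.loc["F1", "ME_turquoise"] == pytest.approx(0.0, abs=1e-12)

    def test_mm_bounded_on_random_data(self):
        rng = np.random.default_rng(7)
        profiles = _profiles(rng.normal(size=(30, 15)))
        me = pd.DataFrame(
            {"ME_x": rng.normal(size=15), "ME_y": rng.normal(size=15)},
            index=profiles.columns,
        )
        mm = module_membership(profiles, me).to_numpy()
        assert (np.abs(mm) <= 1).all()

    def test_module_gs_summary_ordering_and_grey_flag(self):
        labels = ModuleAssignment(
            pd.Series(["turquoise"] * 3 + ["blue"] * 2 + [GREY], index=list("abcdef"))
        )
        gs = pd.Series([1.0, 2.0, 3.0, 5.0, 7.0, 0.5], index=list("abcdef"))
        table = module_gs_summary(labels, gs)
        assert table.loc["turquoise", "mean_gs"] == pytest.approx(2.0)
        assert table.loc["turquoise", "n_features"] == 3
        assert table["mean_gs"].is_monotonic_decreasing
        assert bool(table.loc[GREY, "is_unassigned"])

    def test_hub_selection_sizes_and_order(self, planted_study):
        net, gs = planted_study.net, planted_study.gs
        module = net.assignment_.module_names[0]
        hubs = select_hubs(net.module_membership_, gs, net.assignment_, module, top_n=20)
        assert len(hubs) == 20
        assert hubs["MM"].is_monotonic_decreasing
        assert hubs["hub_rank"].tolist() == list(range(1, 21))
        # a module smaller than top_n returns every member
        small = ModuleAssignment(
            pd.Series(["yellow"] * 12, index=net.assignment_.labels.index[:12])
        )
        mm_small = net.module_membership_.iloc[:12].rename(
            columns={net.module_membership_.columns[0]: "ME_yellow"}
        )
        assert len(select_hubs(mm_small, gs, small, "yellow", top_n=20)) == 12

    def test_unknown_module_rejected(self, planted_study):
        with pytest.raises(KeyError):
            select_hubs(
                planted_study.net.module_membership_,
                planted_study.gs,
                planted_study.net.assignment_,
                "chartreuse",
            )

    def test_higher_loading_gives_larger_membership(self):
        """Spearman(loading, MM) across a planted module with a wide loading range."""
        from comethyl import differential, methylation_values, synthetic_data

        config = synthetic_data.SimulationConfig(
            seed=7, n_promoters=80, n_modules=1, module_sizes=(80,),
            loading_range=(0.3, 0.9), noise_sd=0.2,
        )
        _, intensities, annotation, truth = synthetic_data.simulate_dataset(config)
        m = methylation_values.beta_to_m(methylation_values.compute_beta(intensities))
        regions = differential.summarize_regions(m, annotation, "promoter")
        assignment = ModuleAssignment(
            pd.Series("turquoise", index=regions.values.index)
        )
        me = compute_eigengenes(regions.values, assignment)
        mm = module_membership(regions.values, me)["ME_turquoise"]
        rho = sps.spearmanr(truth.loadings[mm.index], mm).statistic
        assert rho >= 0.7


class TestEdgesAndConnectivity:
    def test_hand_enumerated_edge_count(self):
        w = pd.DataFrame(
            [
                [1.0, 0.30, 0.10, 0.25],
                [0.30, 1.0, 0.22, 0.05],
                [0.10, 0.22, 1.0, 0.21],
                [0.25, 0.05, 0.21, 1.0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        assignment = ModuleAssignment(pd.Series("turquoise", index=list("abcd")))
        edges = export_edges(w, assignment, "turquoise", threshold=0.22)
        # pairs ≥ 0.22: (a,b)=0.30, (a,d)=0.25, (b,c)=0.22 → 3 edges
        assert len(edges) == 3
        assert (edges["feature_a"] < edges["feature_b"]).all()
        assert len(edges[["feature_a", "feature_b"]].drop_duplicates()) == 3

    def test_threshold_one_yields_no_edges(self, planted_study):
        net = planted_study.net
        module = net.assignment_.module_names[0]
        edges = export_edges(net.tom_, net.assignment_, module, threshold=1.0)
        assert len(edges) == 0

    def test_intramodular_connectivity_zero_for_grey(self, planted_study):
        net = planted_study.net
        k_within = intramodular_connectivity(net.adjacency_, net.assignment_)
        grey = net.assignment_.members(GREY)
        assert (k_within[grey] == 0).all()
        module = net.assignment_.module_names[0]
        assert (k_within[net.assignment_.members(module)] > 0).all()


class TestSoftThreshold:
    def test_mean_connectivity_non_increasing(self, planted_study):
        table, _ = pick_soft_threshold(planted_study.regions.values)
        assert (np.diff(table["mean_k"]) <= 1e-9).all()

    def test_explicit_power_overrides_scan(self, planted_study):
        _, chosen = pick_soft_threshold(planted_study.regions.values, power=14)
        assert chosen == 14

    def test_planted_power_law_reaches_fit_target(self):
        from comethyl.synthetic_data import simulate_power_law_profiles

        profiles = simulate_power_law_profiles(seed=7)
        table, chosen = pick_soft_threshold(profiles)
        assert table["sft_fit_signed_r2"].max() >= 0.8
        assert table.loc[chosen, "sft_fit_signed_r2"] >= 0.8

    def test_too_few_features_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="20 features"):
            pick_soft_threshold(_profiles(rng.normal(size=(10, 8))))


class TestEstimator:
    def test_fit_exposes_sklearn_surface(self, planted_study):
        net = planted_study.net
        assert net.power_ == 14
        assert len(net.labels_) == 300
        assert set(net.get_params()) >= {"power", "cut_height", "merge_cut"}
        assert net.eigengenes_.shape == (35, len(net.assignment_.module_names))

    def test_turquoise_is_largest_module(self, planted_study):
        sizes = planted_study.net.assignment_.sizes().drop(GREY, errors="ignore")
        assert sizes.idxmax() == "turquoise"

    def test_fit_predict_returns_labels(self):
        rng = np.random.default_rng(7)
        factor = rng.normal(size=15)
        profiles = (
            factor[None, :] * 0.9 + rng.normal(0, 0.2, size=(40, 15))
        )
        labels = CoMethylationNetwork(power=6, min_module_size=5).fit_predict(profiles.T)
        assert len(labels) == 40
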