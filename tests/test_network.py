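"""Ensemble network engine: metrics, nulls, merging, assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aggregatomics._metrics import batch_score, pairwise_scores
from aggregatomics.feature_table import SVTable, relative_abundance
from aggregatomics.network import (
    NetworkConfig,
    bh_adjust,
    bootstrap_scores,
    brown_merge,
    build_network,
    compute_scores,
    edge_pvalue,
    preselect_edges,
    reboot_null,
    stability_filter,
)
from aggregatomics.simulate import simulate_null_table

CFG = NetworkConfig(n_perm=200, n_boot=200, k_preselect=50, seed=0)


def _rel(rows, samples=None):
    rows = np.asarray(rows, float)
    df = pd.DataFrame(
        rows,
        index=[f"SV{i}" for i in range(rows.shape[0])],
        columns=samples or [f"S{j}" for j in range(rows.shape[1])],
    )
    return df / df.sum(axis=0)


class TestScores:
    def test_identical_rows_extreme_scores(self):
        rel = _rel([[1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], [9, 1, 4, 2, 7, 3]])
        assert compute_scores(rel, "pearson", CFG).iloc[0, 1] == pytest.approx(1.0)
        assert compute_scores(rel, "bray_curtis", CFG).iloc[0, 1] == pytest.approx(0.0)
        assert compute_scores(rel, "kullback_leibler", CFG).iloc[0, 1] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_disjoint_support_bray_curtis_one(self):
        X = np.array([[1.0, 0.0]])
        Y = np.array([[0.0, 1.0]])
        assert batch_score("bray_curtis", X, Y)[0] == pytest.approx(1.0)

    def test_monotone_pair_mi_equals_log_bins(self):
        """Strictly monotone pair with n divisible by b: MI = ln(b)."""
        n, b = 36, 6
        x = np.arange(n, dtype=float)[None, :]
        y = (x + 3.0) ** 2
        mi = batch_score("mutual_information", x, y, n_bins=b)[0]
        assert mi == pytest.approx(np.log(b), abs=1e-9)

    def test_pairwise_matches_batch_kernels(self, rng):
        R = rng.random((6, 20))
        iu, ju = np.triu_indices(6, k=1)
        for metric in ("pearson", "spearman", "bray_curtis", "kullback_leibler", "mutual_information"):
            S = pairwise_scores(R, metric, n_bins=4, pseudocount=1e-8)
            batch = batch_score(metric, R[iu], R[ju], n_bins=4, pseudocount=1e-8)
            np.testing.assert_allclose(S[iu, ju], batch, atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            compute_scores(_rel([[1, 2], [3, 4]]), "pearson", CFG)


class TestPreselect:
    def _scores(self, values):
        ids = [f"SV{i}" for i in range(values.shape[0])]
        return pd.DataFrame(values, index=ids, columns=ids)

    def test_large_k_selects_every_pair_per_metric(self, rng):
        R = rng.random((5, 12))
        cfg = NetworkConfig(k_preselect=1000, seed=0)
        scores = {m: compute_scores(_rel(R), m, cfg) for m in cfg.metrics}
        cands = preselect_edges(scores, cfg)
        assert len(cands) == 10
        assert all(set(v) == set(cfg.metrics) for v in cands.values())

    def test_k1_three_svs_picks_extremes(self):
        vals = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]])
        cfg = NetworkConfig(k_preselect=1, metrics=("pearson",), min_support=1, seed=0)
        cands = preselect_edges({"pearson": self._scores(vals)}, cfg)
        assert set(cands) == {(0, 1), (0, 2)}
        assert cands[(0, 1)]["pearson"] == ("high",)
        assert cands[(0, 2)]["pearson"] == ("low",)

    def test_union_bound(self, rng):
        R = rng.random((12, 15))
        cfg = NetworkConfig(k_preselect=3, seed=0)
        scores = {m: compute_scores(_rel(R), m, cfg) for m in cfg.metrics}
        cands = preselect_edges(scores, cfg)
        assert len(cands) <= 2 * 3 * len(cfg.metrics)


class TestResampling:
    def test_reboot_null_deterministic_under_seed(self, random_table):
        rel = relative_abundance(random_table)
        edge = (rel.index[0], rel.index[1])
        a = reboot_null(rel, edge, "pearson", CFG, np.random.default_rng(5))
        b = reboot_null(rel, edge, "pearson", CFG, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_reboot_null_centered_for_independent_pair(self, rng):
        table = simulate_null_table(10, 40, 10000, seed=8)
        rel = relative_abundance(table)
        null = reboot_null(rel, ("SV1", "SV2"), "pearson", CFG, rng)
        assert abs(null.mean()) < 0.1

    def test_bootstrap_deterministic_and_centered_on_strong_edge(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.01, 0.2, 30) + rng.normal(0, 0.002, 30)
        y = x * 2 + rng.normal(0, 0.002, 30)
        rest = np.full(30, 0.5)
        rel = pd.DataFrame(
            [x, y, rest], index=["SV0", "SV1", "SV2"], columns=[f"S{i}" for i in range(30)]
        )
        boot1 = bootstrap_scores(rel, ("SV0", "SV1"), "pearson", CFG, np.random.default_rng(3))
        boot2 = bootstrap_scores(rel, ("SV0", "SV1"), "pearson", CFG, np.random.default_rng(3))
        np.testing.assert_array_equal(boot1, boot2)
        null = reboot_null(rel, ("SV0", "SV1"), "pearson", CFG, np.random.default_rng(4))
        lo, hi = np.percentile(boot1, (2.5, 97.5))
        assert not (lo <= null.mean() <= hi)  # CI excludes the null mean


class TestStability:
    def test_degenerate_bootstrap_is_stable(self):
        assert stability_filter(0.7, np.full(100, 0.7), CFG)

    def test_observed_beyond_all_bootstrap_is_unstable(self):
        assert not stability_filter(0.99, np.linspace(0, 0.5, 100), CFG)

    def test_observed_exactly_at_upper_percentile_is_stable(self):
        boot = np.linspace(0.0, 1.0, 1001)  # P97.5 = 0.975 exactly
        assert stability_filter(0.975, boot, CFG)
        assert not stability_filter(0.9761, boot, CFG)


class TestEdgePvalue:
    def test_observed_at_null_mean_gives_p_one(self, rng):
        null = rng.normal(0.3, 0.05, 500)
        p, _ = edge_pvalue(null.mean(), null)
        assert p == pytest.approx(1.0)

    def test_add_one_bound(self, rng):
        null = rng.normal(0, 0.1, 1000)
        p, sign = edge_pvalue(5.0, null, "similarity")
        assert p == pytest.approx(1 / 1001)
        assert sign == 1

    def test_dissimilarity_sign_flips(self, rng):
        null = rng.normal(0.6, 0.05, 500)
        _, sign = edge_pvalue(0.1, null, "dissimilarity")
        assert sign == 1  # far below the null mean: co-presence
        _, sign = edge_pvalue(0.95, null, "dissimilarity")
        assert sign == -1

    def test_normal_tail_calibration(self):
        rng = np.random.default_rng(0)
        null = rng.standard_normal(200_000)
        p, _ = edge_pvalue(1.96, null)
        assert p == pytest.approx(0.05, abs=0.005)

    def test_per_metric_p_uniform_under_global_null(self):
        """Fixed (unselected) pair over 200 null tables: KS vs uniform.

        The fold-about-the-mean two-sided p on a skewed permutation null
        is only approximately uniform; the KS test at alpha = 0.01 checks
        the approximation is not grossly off.
        """
        cfg = NetworkConfig(n_perm=200, seed=0)
        pvals = []
        for seed in range(200):
            table = simulate_null_table(20, 30, 5000, seed=1000 + seed)
            rel = relative_abundance(table)
            scores = compute_scores(rel, "pearson", cfg)
            rng = np.random.default_rng(seed)
            null = reboot_null(rel, ("SV1", "SV2"), "pearson", cfg, rng)
            p, _ = edge_pvalue(float(scores.loc["SV1", "SV2"]), null)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestBrownMerge:
    def test_single_p_identity(self):
        assert brown_merge([0.0317]) == pytest.approx(0.0317)

    def test_independent_reduces_to_fisher(self, rng):
        null = rng.random((20_000, 4))  # independent uniform p columns
        for p in ([0.01, 0.2, 0.5, 0.9], [0.001, 0.001, 0.5, 0.8]):
            ours = brown_merge(p, null)
            fisher = stats.combine_pvalues(p, method="fisher")[1]
            assert ours == pytest.approx(fisher, rel=0.15)

    def test_perfect_dependence_returns_single_p(self, rng):
        u = rng.random(50_000)
        null = np.column_stack([u] * 3)
        for p0 in (0.02, 0.2, 0.6):
            merged = brown_merge([p0] * 3, null)
            assert merged == pytest.approx(p0, rel=0.1)

    def test_no_covariance_estimate_equals_fisher_exactly(self):
        p = [0.03, 0.4]
        assert brown_merge(p) == pytest.approx(
            stats.combine_pvalues(p, method="fisher")[1], rel=1e-9
        )

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            brown_merge([0.0, 0.5])
        with pytest.raises(ValueError):
            brown_merge([])


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_q_at_least_p(self, rng):
        p = rng.random(50)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestBuildNetwork:
    def test_too_few_samples_yields_empty_network(self):
        counts = pd.DataFrame({"A": [5, 5], "B": [3, 7]}, index=["SV1", "SV2"])
        result = build_network(SVTable(counts), config=CFG)
        assert result.n_edges == 0 and len(result.nodes) == 0

    def test_deterministic_given_seed(self):
        table = simulate_null_table(12, 20, 8000, seed=3)
        cfg = NetworkConfig(n_perm=50, n_boot=50, k_preselect=10, seed=7)
        r1 = build_network(table, config=cfg)
        r2 = build_network(table, config=cfg)
        pd.testing.assert_frame_equal(r1.edge_table(), r2.edge_table())
        t1 = pd.DataFrame([(e.sv_a, e.sv_b, e.merged_p) for e in r1.tested])
        t2 = pd.DataFrame([(e.sv_a, e.sv_b, e.merged_p) for e in r2.tested])
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_edge_recovered_with_positive_sign(self):
        from conftest import aggregate_benchmark
        from aggregatomics.feature_table import flag_contaminants, remove_svs

        table, meta, _ = aggregate_benchmark(seed=1)
        filtered, _ = remove_svs(table, flag_contaminants(table, meta))
        cfg = NetworkConfig(n_perm=200, n_boot=200, k_preselect=35, seed=1)
        result = build_network(filtered, meta, cfg, group="aggregate_5.3mg")
        found = {frozenset((e.sv_a, e.sv_b)): e.sign for e in result.edges}
        assert found.get(frozenset(("SV1", "SV2"))) == 1

    def test_lenient_mode_is_superset_of_strict(self):
        from conftest import aggregate_benchmark
        from aggregatomics.feature_table import flag_contaminants, remove_svs

        table, meta, _ = aggregate_benchmark(seed=2)
        filtered, _ = remove_svs(table, flag_contaminants(table, meta))
        base = dict(n_perm=150, n_boot=150, k_preselect=25, seed=4)
        strict = build_network(
            filtered, meta, NetworkConfig(strict_mode=True, **base), group="aggregate_5.3mg"
        )
        lenient = build_network(
            filtered, meta, NetworkConfig(strict_mode=False, **base), group="aggregate_5.3mg"
        )
        strict_pairs = {frozenset((e.sv_a, e.sv_b)) for e in strict.edges}
        lenient_pairs = {frozenset((e.sv_a, e.sv_b)) for e in lenient.edges}
        assert strict_pairs <= lenient_pairs

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(metrics=("pearson", "cosine"))
        with pytest.raises(ValueError):
            NetworkConfig(min_support=6)
        with pytest.raises(ValueError):
            NetworkConfig(p_method="bayes")
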