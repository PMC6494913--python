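"""Q-factor computation and stepwise population-weight optimization."""

import json

import numpy as np
import pytest
from scipy.optimize import nnls

from premix.ensemble import (
    FitConfig,
    PREEnsembleModel,
    WeightedEnsemble,
    align_observed,
    best_single_structure,
    hierarchical_fit,
    optimize_group,
    q_ens,
)
from premix.peaks import Gamma2Entry, Gamma2Set


class TestQFactor:
    def test_generating_weights_give_zero(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0, 10, size=(6, 20))
        w = rng.uniform(0, 1, size=6)
        obs = w @ C
        assert q_ens(obs, C, w) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_give_unity(self):
        C = np.ones((3, 4))
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        assert q_ens(obs, C, np.zeros(3)) == pytest.approx(1.0)

    def test_hand_example(self):
        # obs = (3, 4), calc = (3, 0), p = 1  ->  sqrt(16/25) = 0.8
        assert q_ens(np.array([3.0, 4.0]), np.array([[3.0, 0.0]]),
                     np.array([1.0])) == pytest.approx(0.8)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            q_ens(np.zeros(4), np.ones((2, 4)), np.ones(2))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            q_ens(np.ones(4), np.ones((2, 4)), np.array([1.0, -0.1]))

    def test_prediction_linear_in_weights(self):
        rng = np.random.default_rng(3)
        C = rng.uniform(0, 5, size=(8, 15))
        w1, w2 = rng.uniform(0, 1, size=(2, 8))
        pred = (w1 + w2) @ C
        brute = np.zeros(15)
        for k in range(8):  # brute-force accumulation
            brute += (w1[k] + w2[k]) * C[k]
        assert np.allclose(pred, brute, rtol=1e-12)


class TestBestSingle:
    def test_truth_in_pool_noiseless(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 10, size=(10, 25))
        obs = 0.7 * C[4]
        k, q, p = best_single_structure(obs, C)
        assert k == 4
        assert q == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(0.7, rel=1e-10)

    def test_all_zero_calc_gives_unit_q(self):
        obs = np.array([1.0, 2.0])
        k, q, p = best_single_structure(obs, np.zeros((3, 2)))
        assert q == pytest.approx(1.0) and p == 0.0

    def test_disjoint_mixture_beats_single_structure(self):
        # 50/50 mixture of two members with disjoint footprints: one free
        # scale cannot fit both blocks, an ensemble of two fits exactly
        a = np.concatenate([np.full(10, 8.0), np.zeros(10)])
        b = np.concatenate([np.zeros(10), np.full(10, 8.0)])
        C = np.stack([a, b])
        obs = 0.5 * a + 0.5 * b
        _, q_single, _ = best_single_structure(obs, C)
        w, q_two = optimize_group(obs, C, None, FitConfig(seed=0))
        assert q_two < 1e-8
        assert q_single - q_two > 0.2
        assert q_single == pytest.approx(np.sqrt(0.5), rel=1e-6)


class TestOptimizeGroup:
    def test_single_generating_member(self):
        rng = np.random.default_rng(2)
        C = rng.uniform(1, 10, size=(1, 30))
        obs = 0.42 * C[0]
        w, q = optimize_group(obs, C, None, FitConfig(seed=0))
        assert q <= 1e-6
        assert w[0] == pytest.approx(0.42, rel=1e-4)

    def test_never_worse_than_init(self):
        rng = np.random.default_rng(5)
        C = rng.uniform(0, 10, size=(20, 40))
        truth = np.zeros(20)
        truth[[3, 11]] = (0.5, 0.25)
        obs = truth @ C
        q_init = q_ens(obs, C, truth)
        _, q = optimize_group(obs, C, truth, FitConfig(seed=1))
        assert q <= q_init + 1e-12

    def test_matches_nnls_oracle(self):
        # the inner problem is nonnegative least squares; scipy's solver is
        # the independent oracle for the reachable optimum
        rng = np.random.default_rng(7)
        for trial in range(5):
            C = rng.uniform(0, 10, size=(30, 20))
            obs = rng.uniform(0, 1, 30) @ C + rng.normal(0, 0.5, 20)
            obs = np.clip(obs, 0.01, None)
            _, q = optimize_group(obs, C, None, FitConfig(seed=trial))
            w_ref, _ = nnls(C.T, obs)
            assert q == pytest.approx(q_ens(obs, C, w_ref), abs=1e-6)

    def test_two_planted_members_among_decoys(self, small_pool, toy):
        pool, _, matrix = small_pool
        C = matrix.to_numpy()[:100]
        truth = np.zeros(100)
        truth[0], truth[1] = 0.3, 0.2
        obs = truth @ C
        w, q = optimize_group(obs, C, None, FitConfig(seed=3))
        assert q < 1e-6
        assert abs(w[0] - 0.3) < 0.02 and abs(w[1] - 0.2) < 0.02

    def test_nonfinite_calc_rejected_by_alignment(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        bad = matrix.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            align_observed(noiseless_gsets, bad)


class TestHierarchicalFit:
    def test_single_group_degenerates_to_joint_optimization(self):
        rng = np.random.default_rng(11)
        C = rng.uniform(0, 10, size=(40, 30))
        truth = np.zeros(40)
        truth[[2, 17]] = (0.4, 0.1)
        obs = truth @ C
        ens = hierarchical_fit(obs, C, FitConfig(group_size=40, seed=2))
        _, q_joint = optimize_group(obs, C, None, FitConfig(seed=2))
        assert ens.q_ens == pytest.approx(q_joint, abs=1e-6)

    def test_pool_smaller_than_group_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_fit(np.ones(4), np.ones((5, 4)), FitConfig(group_size=10))

    def test_deterministic_given_seed(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        obs, C, _, err = align_observed(noiseless_gsets, matrix)
        cfg = FitConfig(group_size=60, final_size=120, seed=9)
        a = hierarchical_fit(obs, C, cfg, err)
        b = hierarchical_fit(obs, C, cfg, err)
        assert np.array_equal(a.member_ids, b.member_ids)
        assert np.array_equal(a.weights, b.weights)

    def test_duplicated_decoy_leaves_prediction_unchanged(self):
        rng = np.random.default_rng(13)
        C = rng.uniform(0, 10, size=(60, 30))
        truth = np.zeros(60)
        truth[[1, 5, 9]] = (0.4, 0.2, 0.1)
        obs = truth @ C
        cfg = FitConfig(group_size=30, seed=4)
        base = hierarchical_fit(obs, C, cfg)
        dup = hierarchical_fit(obs, np.vstack([C, C[30:31]]), cfg)
        pred_a = base.weights @ C[np.asarray(base.member_ids, int)]
        Cd = np.vstack([C, C[30:31]])
        pred_b = dup.weights @ Cd[np.asarray(dup.member_ids, int)]
        assert abs(q_ens(obs, C[np.asarray(base.member_ids, int)], base.weights)
                   - q_ens(obs, Cd[np.asarray(dup.member_ids, int)], dup.weights)) < 1e-6
        assert np.allclose(pred_a, pred_b, atol=1e-4)

    def test_q_never_increases_across_funnel_stages(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        obs, C, _, _ = align_observed(noiseless_gsets, matrix)
        ens = hierarchical_fit(obs, C, FitConfig(group_size=60, seed=6))
        stages = {s["stage"]: s for s in ens.provenance["stages"]}
        assert min(stages["merge"]["q"]) <= min(stages["groups"]["q"]) + 1e-9
        assert stages["final"]["q"] <= min(stages["merge"]["q"]) + 1e-9

    def test_recovers_planted_weights_noiseless(self, toy, noiseless_gsets, small_pool):
        _, truth_idx, matrix = small_pool
        obs, C, _, err = align_observed(noiseless_gsets, matrix)
        ens = hierarchical_fit(obs, C, FitConfig(group_size=60, final_size=150, seed=8), err)
        ids = np.asarray(ens.member_ids)
        fitted = {int(m): w for m, w in zip(ids, ens.weights)}
        for k in truth_idx:
            assert abs(fitted.get(int(k), 0.0) - toy.truth_weights[k]) < 0.01
        assert ens.q_ens < 1e-6


class TestModelResults:
    def test_fit_and_summary(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        model = PREEnsembleModel(noiseless_gsets, matrix)
        res = model.fit("hierarchical", FitConfig(group_size=60, final_size=120, seed=1))
        assert res.q_ens < 1e-5
        text = res.summary()
        assert "Q_ens" in text and "hierarchical" in text
        assert set(res.per_site_q().index) == {"L366C", "Q344C", "V351C"}
        assert len(res.predict()) == model.n_obs

    def test_single_and_group_methods(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        model = PREEnsembleModel(noiseless_gsets, matrix)
        single = model.fit("single")
        assert len(single.member_ids) == 1
        assert single.q_ens >= 0
        with pytest.raises(ValueError):
            model.fit("nope")

    def test_save_and_from_tables(self, tmp_path, noiseless_gsets, small_pool):
        from premix.forward import write_gamma2_matrix
        from premix.peaks import write_gamma2_table

        _, _, matrix = small_pool
        model = PREEnsembleModel(noiseless_gsets, matrix)
        res = model.fit("hierarchical", FitConfig(group_size=60, final_size=120, seed=1))
        res.save(tmp_path / "w.tsv", tmp_path / "rep.json")
        report = json.loads((tmp_path / "rep.json").read_text())
        assert report["q_ens"] == pytest.approx(res.q_ens)

        write_gamma2_matrix(matrix, tmp_path / "m.tsv")
        paths = {}
        for g in noiseless_gsets:
            p = tmp_path / f"g_{g.label_site}.tsv"
            write_gamma2_table(g, p)
            paths[g.label_site] = str(p)
        model2 = PREEnsembleModel.from_tables(paths, str(tmp_path / "m.tsv"))
        assert model2.n_obs == model.n_obs
        assert np.allclose(model2.endog, model.endog)

    def test_plot_fit_returns_axis(self, noiseless_gsets, small_pool):
        _, _, matrix = small_pool
        res = PREEnsembleModel(noiseless_gsets, matrix).fit(
            "hierarchical", FitConfig(group_size=60, final_size=120, seed=1)
        )
        ax = res.plot_fit()
        assert ax.get_ylabel().startswith("$\\Gamma_2$")


def test_weighted_ensemble_validation():
    with pytest.raises(ValueError):
        WeightedEnsemble(np.array([0, 1]), np.array([0.1]), 0.2)
    with pytest.raises(ValueError):
        WeightedEnsemble(np.array([0]), np.array([-0.1]), 0.2)
    ens = WeightedEnsemble(np.array([0, 1]), np.array([1.0, 3.0]), 0.2)
    assert np.allclose(ens.normalized_weights, [0.25, 0.75])
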