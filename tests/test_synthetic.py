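"""Toy-complex generator: geometry, forward simulation, pool construction."""

import math

import numpy as np
import pytest

import premix as px
from premix.forward import backcalc_pool, backcalc_structure
from premix.peaks import PeakFlag, gamma2_from_table, invert_eq1
from premix.pool import clash_filter
from premix.synthetic import _R90, true_gamma2


class TestToySystem:
    def test_deterministic_given_seed(self):
        a = px.make_toy_system(seed=3)
        b = px.make_toy_system(seed=3)
        assert np.array_equal(a.assembly.probe_xyz, b.assembly.probe_xyz)
        for x, y in zip(a.truth_members, b.truth_members):
            assert np.array_equal(x.probe_xyz, y.probe_xyz)

    def test_config_echo(self, toy):
        assert len(toy.probe_ids) == 60
        assert toy.site_ids == ["L366C", "Q344C", "V351C"]
        sites = toy.assembly.all_sites()
        for sid in toy.site_ids:
            assert sites[sid].shape[0] == 4   # four symmetric copies
            assert sites[sid].shape[1] == 5   # five label conformers

    def test_fourfold_symmetry_exact(self, toy):
        for sid in ("Q344C", "V351C"):
            conf = toy.assembly.fixed_sites[sid]
            for c in range(3):
                assert np.allclose(conf[c + 1], conf[c] @ _R90.T, atol=1e-8)

    def test_truth_members_clash_free(self, toy):
        for m in toy.truth_members:
            assert clash_filter(toy.assembly.fixed_atoms, m.atoms,
                                toy.config.clash_cutoff)

    def test_truth_contribution_window(self, toy):
        lo, hi = toy.config.truth_contrib_range
        for w, member in zip(toy.truth_weights, toy.truth_members):
            gmax = float(backcalc_structure(member, toy.params).max())
            assert lo <= w * gmax <= hi

    def test_truth_members_mutually_distinct(self, toy):
        F = backcalc_pool(toy.truth_members, toy.params).to_numpy()
        FN = F / np.linalg.norm(F, axis=1, keepdims=True)
        cos = FN @ FN.T
        off = cos[~np.eye(len(F), dtype=bool)]
        assert np.all(off <= toy.config.truth_cos_max + 1e-12)
        cents = np.array([m.probe_xyz.mean(axis=0) for m in toy.truth_members])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        assert np.all(d[~np.eye(len(F), dtype=bool)] >= toy.config.min_truth_separation)

    def test_default_weights_span(self, toy):
        assert toy.truth_weights[0] == pytest.approx(0.30)
        assert toy.truth_weights[-1] == pytest.approx(0.05)


class TestSimulateObserved:
    def test_noiseless_round_trip(self, toy, noiseless_gsets):
        gt = true_gamma2(toy)
        for gset in noiseless_gsets:
            for e in gset.entries:
                if e.flag is PeakFlag.OK:
                    assert abs(e.gamma2 - gt[(gset.label_site, e.methyl_id)]) < 1e-6

    def test_zero_weight_truth_gives_unit_ratios(self):
        cfg = px.ToyConfig(n_true=1, true_weights=(0.0,),
                           truth_contrib_range=(0.0, math.inf))
        system = px.make_toy_system(cfg, seed=2)
        noise = px.NoiseModel(snr_para=float("inf"), snr_dia=float("inf"))
        tables = px.simulate_observed(system, noise=noise, seed=0)
        for records in tables.values():
            for r in records:
                assert r.I_para / r.I_dia == pytest.approx(1.0)

    def test_same_seed_reproduces_tables(self, toy):
        a = px.simulate_observed(toy, seed=5)
        b = px.simulate_observed(toy, seed=5)
        for site in a:
            for x, y in zip(a[site], b[site]):
                assert x == y

    def test_rates_shared_across_sites(self, toy):
        tables = px.simulate_observed(toy, seed=1)
        sites = list(tables)
        for i, m in enumerate(toy.probe_ids[:5]):
            rates = {(tables[s][i].R2_diaH, tables[s][i].R2_diaHC) for s in sites}
            assert len(rates) == 1

    def test_noise_matches_delta_method_prediction(self, toy):
        # empirical spread of recovered Γ₂ across replicates should track the
        # first-order propagated uncertainty
        noise = px.NoiseModel(snr_para=50, snr_dia=50)
        gt = true_gamma2(toy)
        watch = [m for (s, m), g in gt.items() if s == "L366C" and 5.0 < g < 25.0][:3]
        recovered = {m: [] for m in watch}
        errs = {m: [] for m in watch}
        for rep in range(120):
            tables = px.simulate_observed(toy, noise=noise, seed=1000 + rep)
            for r in tables["L366C"]:
                if r.methyl_id in recovered:
                    e = invert_eq1(r)
                    if e.flag is PeakFlag.OK:
                        recovered[r.methyl_id].append(e.gamma2)
                        errs[r.methyl_id].append(e.gamma2_err)
        for m in watch:
            empirical = np.std(recovered[m])
            predicted = np.mean(errs[m])
            assert empirical == pytest.approx(predicted, rel=0.25)


class TestPoolWithTruth:
    def test_zero_decoys_returns_truth_only(self, toy):
        pool, truth_idx, matrix = px.make_pool_with_truth(toy, 0)
        assert len(pool) == len(toy.truth_members)
        assert list(truth_idx) == list(range(len(pool)))
        assert matrix.shape[0] == len(pool)

    def test_pool_reproducible_and_clash_free(self, toy, small_pool):
        pool, truth_idx, matrix = small_pool
        pool2, _, matrix2 = px.make_pool_with_truth(toy, 300, seed=7)
        assert np.array_equal(matrix.to_numpy(), matrix2.to_numpy())
        for m in pool[5:40]:
            assert clash_filter(toy.assembly.fixed_atoms, m.atoms, 2.5)

    def test_decoy_fingerprints_respect_floors(self, toy, small_pool):
        pool, truth_idx, matrix = small_pool
        F = matrix.to_numpy()
        truth_F = F[: len(truth_idx)]
        tn = np.linalg.norm(truth_F, axis=1)
        decoys = F[len(truth_idx):]
        d = np.linalg.norm(decoys[:, None, :] - truth_F[None, :, :], axis=2) / tn
        assert d.min() > 0.15
        dN = decoys / np.linalg.norm(decoys, axis=1, keepdims=True)
        tN = truth_F / tn[:, None]
        assert (dN @ tN.T).max() < 0.8

    def test_matrix_matches_backcalc(self, toy, small_pool):
        pool, _, matrix = small_pool
        recomputed = backcalc_pool(pool[:10], toy.params)
        assert np.allclose(matrix.iloc[:10].to_numpy(), recomputed.to_numpy(),
                           rtol=1e-10)


class TestDockToy:
    def test_geometry_and_restraints(self, dock_toy):
        assert set(dock_toy.observed) == {"L366C", "Q344C", "V351C"}
        assert all(v.shape == (60,) for v in dock_toy.observed.values())
        assert clash_filter(dock_toy.receptor.atoms, dock_toy.ligand.atoms, 2.5)
        # restraints are the forward model evaluated at the stored true pose
        truth = px.LabeledStructure(
            probe_ids=list(dock_toy.ligand.probe_ids),
            probe_xyz=dock_toy.ligand.probe_xyz,
            sites=dock_toy.receptor.sites,
        )
        g = backcalc_structure(truth, dock_toy.params)
        for site, vec in dock_toy.observed.items():
            assert np.allclose(vec, g.xs(site, level="site").to_numpy(), rtol=1e-12)

    def test_deterministic(self):
        a = px.make_dock_toy(seed=4)
        b = px.make_dock_toy(seed=4)
        assert np.array_equal(a.ligand.probe_xyz, b.ligand.probe_xyz)


def test_full_chain_recovery_small_scale(toy, noiseless_gsets, small_pool):
    """simulate → invert → back-calculate → fit recovers the planted weights."""
    _, truth_idx, matrix = small_pool
    model = px.PREEnsembleModel(noiseless_gsets, matrix)
    res = model.fit("hierarchical", px.FitConfig(group_size=60, final_size=150, seed=2))
    ids = np.asarray(res.member_ids)
    tw = np.array([toy.truth_weights[m] if m < 5 else 0.0 for m in ids])
    r = np.corrcoef(res.weights.to_numpy(), tw)[0, 1]
    assert r > 0.99
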