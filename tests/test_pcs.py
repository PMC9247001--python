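"""PCS evaluation, tensor fitting, UTR, bootstrap, Q factors, expansion."""

import numpy as np
import pandas as pd
import pytest

from methylwalk import structures, synthetic
from methylwalk.pcs import (
    DchiTensor,
    PCSDataset,
    bootstrap_tensor,
    calc_pcs,
    fit_tensor,
    opposite_orientation,
    pcs_from_shifts,
    q_factor,
    to_utr,
)

RNG = np.random.default_rng(100)


def random_tensor(metal=None):
    return DchiTensor(RNG.normal(0, 5, 5), metal if metal is not None else RNG.normal(0, 5, 3))


def contraction_pcs(tensor, pos):
    """Independent evaluation via the full 3x3 traceless matrix contraction."""
    rel = np.atleast_2d(np.asarray(pos, float) - tensor.metal_position)
    mat = tensor.matrix()
    out = []
    for v in rel:
        r = np.linalg.norm(v)
        out.append(1e4 / (4 * np.pi) * (v @ mat @ v) / r**5)
    return np.array(out)


class TestCalcPCS:
    def test_on_axis_closed_form(self):
        # dchi_xx = dchi_yy = -1 (1e-32 m^3) => dchi_zz = +2; nucleus 10 A up
        t = DchiTensor(np.array([-1.0, -1.0, 0, 0, 0]), np.zeros(3))
        val = calc_pcs(t, np.array([0.0, 0.0, 10.0]))
        # -(xx + yy) / (4 pi r^3) = 2e-32 / (4 pi 1e-27) m^3/m^3 = 1.5915 ppm
        assert val == pytest.approx(1.5915494, rel=1e-6)

    def test_zero_tensor_is_zero_everywhere(self):
        t = DchiTensor(np.zeros(5), np.zeros(3))
        pts = RNG.normal(0, 20, (10, 3))
        assert np.all(calc_pcs(t, pts) == 0)

    def test_zero_distance_rejected(self):
        t = random_tensor(metal=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="coincides"):
            calc_pcs(t, np.array([1.0, 2.0, 3.0]))

    def test_equivalent_to_matrix_contraction_form(self):
        for _ in range(25):
            t = random_tensor()
            pts = t.metal_position + RNG.normal(0, 15, (8, 3))
            a = calc_pcs(t, pts)
            b = contraction_pcs(t, pts)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-15)

    def test_invariant_under_joint_rigid_rotation(self):
        t = random_tensor(metal=np.array([2.0, -1.0, 3.0]))
        pts = t.metal_position + RNG.normal(0, 12, (6, 3))
        q = np.linalg.qr(RNG.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot_mat = q @ t.matrix() @ q.T
        rot = DchiTensor(
            np.array([rot_mat[0, 0], rot_mat[1, 1], rot_mat[0, 1], rot_mat[0, 2],
                      rot_mat[1, 2]]),
            q @ t.metal_position,
        )
        np.testing.assert_allclose(
            calc_pcs(rot, pts @ q.T), calc_pcs(t, pts), rtol=1e-10
        )

    def test_field_is_traceless_over_principal_axis_points(self):
        t = random_tensor(metal=np.zeros(3))
        utr = to_utr(t)
        vals, vecs = np.linalg.eigh(t.matrix())
        pts = np.concatenate([10.0 * vecs.T, -10.0 * vecs.T])
        assert abs(calc_pcs(t, pts).sum()) < 1e-10
        assert utr.eigenvalues.sum() == pytest.approx(0.0, abs=1e-12)


class TestPcsFromShifts:
    def test_identical_spectra_give_zero(self):
        pl = pd.DataFrame({"peak_id": ["p1"], "delta_H": [1.0], "delta_C": [20.0]})
        ds, unmatched = pcs_from_shifts(pl, pl, {"p1": "p1"}, spectrometer_mhz=500.0)
        assert ds.observations["pcs_ppm"].iloc[0] == 0.0
        assert unmatched == []

    def test_ppm_to_hz_at_500_mhz(self):
        dia = pd.DataFrame({"peak_id": ["p"], "delta_H": [1.00], "delta_C": [20.0]})
        para = pd.DataFrame({"peak_id": ["q"], "delta_H": [1.10], "delta_C": [20.0]})
        ds, _ = pcs_from_shifts(dia, para, {"p": "q"}, spectrometer_mhz=500.0)
        assert ds.observations["pcs_ppm"].iloc[0] == pytest.approx(0.10)
        assert ds.pcs_hz.iloc[0] == pytest.approx(50.0)

    def test_unmatched_peaks_listed_not_fabricated(self):
        dia = pd.DataFrame({"peak_id": ["p", "r"], "delta_H": [1.0, 2.0], "delta_C": [20, 21]})
        para = pd.DataFrame({"peak_id": ["q"], "delta_H": [1.1], "delta_C": [20.0]})
        ds, unmatched = pcs_from_shifts(dia, para, {"p": "q"})
        assert len(ds.observations) == 1
        assert unmatched == ["r"]


class TestFitTensor:
    def test_recovery_from_noiseless_synthetic_field(self, toy50, toy50_ensemble):
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        metal = centre + np.array([4.0, 2.0, -1.0])
        truth = DchiTensor(np.array([8.0, -3.0, 2.0, 1.0, -1.5]), metal)
        ds = synthetic.simulate_pcs(truth, toy50.methyls_a, noise_hz=0.0)
        fit, report = fit_tensor(ds, toy50_ensemble, metal + np.array([2.0, -1.0, 2.0]))
        scale = np.abs(truth.components).max()
        assert np.abs(fit.components - truth.components).max() < 0.01 * scale
        assert np.linalg.norm(fit.metal_position - metal) < 0.1
        assert report.q < 1e-6

    def test_fixed_metal_at_truth_gives_q_zero(self, toy50, toy50_ensemble):
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        truth = DchiTensor(np.array([5.0, 1.0, -2.0, 0.5, 0.0]), centre + 3.0)
        ds = synthetic.simulate_pcs(truth, toy50.methyls_a, noise_hz=0.0)
        fit, report = fit_tensor(ds, toy50_ensemble, truth.metal_position, move_metal=False)
        assert report.q == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.metal_position, truth.metal_position)

    def test_duplicated_model_ensemble_equals_single_model(self, toy50):
        ens1 = structures.build_ensemble([toy50.model_a])
        ens2 = structures.build_ensemble([toy50.model_a, toy50.model_a])
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        truth = DchiTensor(np.array([5.0, 1.0, -2.0, 0.5, 0.0]), centre + 3.0)
        ds = synthetic.simulate_pcs(truth, toy50.methyls_a, noise_hz=0.0)
        f1, _ = fit_tensor(ds, ens1, centre, move_metal=False)
        f2, _ = fit_tensor(ds, ens2, centre, move_metal=False)
        np.testing.assert_allclose(f1.components, f2.components, rtol=1e-9)

    def test_underdetermined_fit_rejected(self, toy50_ensemble, toy50):
        keys = [g.key for g in toy50.methyls_a[:4]]
        ds = PCSDataset(pd.DataFrame({"key": keys, "pcs_ppm": 0.1, "error_ppm": 0.01}))
        with pytest.raises(ValueError, match="underdetermined"):
            fit_tensor(ds, toy50_ensemble, np.zeros(3))


class TestUTR:
    def test_diagonal_tensor_preserved(self):
        t = DchiTensor(np.array([1.0, 2.0, 0, 0, 0]), np.zeros(3))  # zz = -3
        utr = to_utr(t)
        np.testing.assert_allclose(sorted(utr.eigenvalues), [-3.0, 1.0, 2.0])
        assert utr.dchi_ax == pytest.approx(-3.0 - 0.5 * (1.0 + 2.0))
        assert not utr.degenerate

    def test_rotation_leaves_principal_values(self):
        t = random_tensor(metal=np.zeros(3))
        q = np.linalg.qr(RNG.normal(size=(3, 3)))[0]
        m = q @ t.matrix() @ q.T
        rot = DchiTensor(np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]]),
                         np.zeros(3))
        u1, u2 = to_utr(t), to_utr(rot)
        assert u1.dchi_ax == pytest.approx(u2.dchi_ax, rel=1e-9)
        assert u1.dchi_rh == pytest.approx(u2.dchi_rh, rel=1e-9)

    def test_matches_eigh_oracle_and_axial_dominance(self):
        for _ in range(20):
            t = random_tensor(metal=np.zeros(3))
            utr = to_utr(t)
            vals = np.sort(np.linalg.eigvalsh(t.matrix()))
            np.testing.assert_allclose(np.sort(utr.eigenvalues), vals, rtol=1e-10)
            assert abs(utr.dchi_ax) >= 1.5 * abs(utr.dchi_rh) - 1e-9

    def test_degenerate_tensor_flags_angles(self):
        # axially symmetric: xx = yy
        t = DchiTensor(np.array([1.0, 1.0, 0, 0, 0]), np.zeros(3))
        utr = to_utr(t)
        assert utr.degenerate
        assert np.isnan(utr.alpha)


class TestBootstrap:
    def test_noiseless_data_gives_near_zero_sds(self, toy50, toy50_ensemble):
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        truth = DchiTensor(np.array([8.0, -3.0, 2.0, 1.0, -1.5]), centre + 3.0)
        ds = synthetic.simulate_pcs(truth, toy50.methyls_a, noise_hz=0.0)
        out = bootstrap_tensor(ds, toy50_ensemble, truth.metal_position, iterations=20,
                               seed=4)
        assert out["component_sd"].max() < 1e-6
        assert out["metal_sd"] < 1e-3
        assert out["n_used"] == 20

    def test_sds_grow_with_noise(self, toy50, toy50_ensemble):
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        truth = DchiTensor(np.array([8.0, -3.0, 2.0, 1.0, -1.5]), centre + 3.0)
        sds = []
        for sigma in (1.0, 2.0, 4.0):
            ds = synthetic.simulate_pcs(truth, toy50.methyls_a, noise_hz=sigma, seed=6)
            out = bootstrap_tensor(ds, toy50_ensemble, truth.metal_position,
                                   iterations=30, seed=5)
            sds.append(out["component_sd"].mean())
        assert sds[0] < sds[1] < sds[2]

    def test_single_iteration_rejected(self, toy50, toy50_ensemble):
        centre = np.stack([g.carbon_position for g in toy50.methyls_a]).mean(axis=0)
        truth = DchiTensor(np.ones(5), centre + 3.0)
        ds = synthetic.simulate_pcs(truth, toy50.methyls_a)
        with pytest.raises(ValueError, match="at least 2 iterations"):
            bootstrap_tensor(ds, toy50_ensemble, truth.metal_position, iterations=1)


class TestQFactor:
    def test_hand_evaluated_example(self):
        # obs = [3, 4], calc = [3, 0]: sqrt((0 + 16) / (9 + 16)) = 0.8
        assert q_factor([3.0, 4.0], [3.0, 0.0]) == pytest.approx(0.8)

    def test_perfect_fit_and_null_model(self):
        obs = np.array([1.0, -2.0, 3.0])
        assert q_factor(obs, obs) == 0.0
        assert q_factor(obs, np.zeros(3)) == pytest.approx(1.0)

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            q_factor(np.zeros(3), np.ones(3))

    def test_joint_scaling_invariance_only(self):
        obs = np.array([1.0, 2.0, -1.0])
        calc = np.array([0.9, 2.2, -0.8])
        q = q_factor(obs, calc)
        assert q_factor(3 * obs, 3 * calc) == pytest.approx(q)
        assert q_factor(obs, 3 * calc) != pytest.approx(q)

    def test_multi_model_reduces_to_mean_based_form(self):
        obs = np.array([2.0, 5.0])
        calc = np.array([[1.0, 4.0], [3.0, 8.0]])
        # numerator per atom: (2*obs - sum_m calc)^2
        num = (2 * obs - calc.sum(0)) ** 2
        den = (2 * obs) ** 2
        assert q_factor(obs, calc) == pytest.approx(np.sqrt(num.sum() / den.sum()))


class TestOppositeOrientation:
    def test_self_is_not_opposite_negation_is(self):
        t = random_tensor(metal=np.zeros(3))
        neg = DchiTensor(-t.components, t.metal_position)
        pts = RNG.normal(0, 15, (30, 3))
        assert opposite_orientation(t, t, pts) is False
        assert opposite_orientation(t, neg, pts) is True

    def test_matches_brute_force_correlation(self):
        pts = RNG.normal(0, 15, (40, 3))
        for _ in range(10):
            ta, tb = random_tensor(np.zeros(3)), random_tensor(np.zeros(3))
            fa = contraction_pcs(ta, pts)
            fb = contraction_pcs(tb, pts)
            expected = bool(np.corrcoef(fa, fb)[0, 1] < 0)
            assert opposite_orientation(ta, tb, pts) == expected

    def test_constant_field_rejected(self):
        t = DchiTensor(np.zeros(5), np.zeros(3))
        with pytest.raises(ValueError, match="degenerate"):
            opposite_orientation(t, t, RNG.normal(0, 10, (5, 3)))
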