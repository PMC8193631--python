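"""synthetic: generator ground truth, reproducibility, OU statistics."""

import math

import numpy as np
import pytest

from dnanchor import synthetic as syn
from dnanchor.dna_structure import BasePairing, average_rise, bp_centers, broken_bp_count
from dnanchor.io_model import select
from conftest import single_frame


class TestGenBdna:
    def test_consecutive_bp_centers_spaced_by_rise(self, ideal_duplex, pairing30):
        top, coords = ideal_duplex
        centers = bp_centers(top, coords, pairing30)
        steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.32, atol=1e-9)

    def test_two_bp_single_step(self):
        top, coords = syn.gen_bdna(syn.BDnaParams(n_bp=2, rise=5.0))
        centers = bp_centers(top, coords, BasePairing.from_duplex(2))
        assert np.linalg.norm(centers[1] - centers[0]) == pytest.approx(5.0)

    def test_full_turn_returns_to_same_azimuth(self):
        # 10 steps x 36 degrees: terminal bp at the same azimuth as the first
        top, coords = syn.gen_bdna(syn.BDnaParams(n_bp=11))
        c1 = select(top, "chain A and name C1'")
        first, last = coords[c1.indices[0]], coords[c1.indices[-1]]
        assert math.atan2(first[1], first[0]) == pytest.approx(
            math.atan2(last[1], last[0]), abs=1e-9
        )

    def test_analyzer_recovers_rise_selfconsistently(self):
        # generator/analyzer oracle: rise measured on own output == params.rise
        for n_bp, rise in [(2, 3.32), (7, 2.9), (30, 3.32), (41, 3.5)]:
            top, coords = syn.gen_bdna(syn.BDnaParams(n_bp=n_bp, rise=rise))
            traj = single_frame(top, coords)
            rs = average_rise(traj, BasePairing.from_duplex(n_bp))
            assert abs(rs.mean_rise[0] - rise) <= 1e-6


class TestFrayTerminalBps:
    def test_six_frayed_pairs_break_under_default_criterion(self, ideal_duplex, pairing30):
        top, coords = ideal_duplex
        frayed = syn.fray_terminal_bps(top, coords, k=6, displacement=10.0)
        _, counts = broken_bp_count(single_frame(top, frayed), pairing30)
        assert counts[0] == 6

    def test_all_pairs_frayed(self, ideal_duplex, pairing30):
        top, coords = ideal_duplex
        frayed = syn.fray_terminal_bps(top, coords, k=30, displacement=10.0)
        _, counts = broken_bp_count(single_frame(top, frayed), pairing30)
        assert counts[0] == 30

    def test_zero_displacement_is_identity(self, ideal_duplex, pairing30):
        top, coords = ideal_duplex
        frayed = syn.fray_terminal_bps(top, coords, k=6, displacement=0.0)
        np.testing.assert_allclose(frayed, coords)
        _, counts = broken_bp_count(single_frame(top, frayed), pairing30)
        assert counts[0] == 0

    def test_k_out_of_range_rejected(self, ideal_duplex):
        top, coords = ideal_duplex
        for k in (0, 31):
            with pytest.raises(ValueError):
                syn.fray_terminal_bps(top, coords, k=k, displacement=10.0)

    def test_unaffected_pairs_untouched(self, ideal_duplex, pairing30):
        top, coords = ideal_duplex
        frayed = syn.fray_terminal_bps(top, coords, k=6, displacement=10.0)
        keep = np.ones(top.n_atoms, bool)
        for _, res2 in pairing30.pairs[-6:]:
            keep &= ~((top.chains == res2[0]) & (top.resids == res2[1]))
        np.testing.assert_allclose(frayed[keep], coords[keep])


class TestGenBilayer:
    def test_noise_free_leaflets_at_planes(self):
        top, coords = syn.gen_bilayer(syn.BilayerParams(n_per_leaflet=50, z_noise_sd=0.0))
        assert set(np.round(coords[:, 2], 9)) == {-19.0, 19.0}
        assert len(top.atoms) == 100

    def test_thinned_disk_moves_planes_inward(self):
        thin = syn.ThinningSpec(center_xy=(40.0, 40.0), radius=15.0, delta_z=5.0)
        params = syn.BilayerParams(n_per_leaflet=500, z_noise_sd=0.0, thinning=thin)
        top, coords = syn.gen_bilayer(params, seed=1)
        dx = coords[:, :2] - 40.0
        dx -= 80.0 * np.round(dx / 80.0)
        inside = np.hypot(dx[:, 0], dx[:, 1]) <= 15.0
        assert inside.any() and (~inside).any()
        assert set(np.round(np.abs(coords[inside, 2]), 9)) == {14.0}
        assert set(np.round(np.abs(coords[~inside, 2]), 9)) == {19.0}

    def test_noise_sd_matches_request(self):
        params = syn.BilayerParams(n_per_leaflet=2000, z_noise_sd=1.0)
        _, coords = syn.gen_bilayer(params, seed=7)
        for sign in (1, -1):
            z = coords[:, 2][np.sign(coords[:, 2]) == sign]
            assert abs(z.std(ddof=1) - 1.0) < 0.05


class TestGenWaterSlab:
    def test_exact_inside_outside_partition(self):
        _, coords = syn.gen_water_slab(37, 500, half_width=10.0, box=(80, 80, 120), seed=2)
        inside = np.abs(coords[:, 2]) < 10.0
        assert inside.sum() == 37
        assert (~inside).sum() == 500

    def test_zero_inside(self):
        _, coords = syn.gen_water_slab(0, 50, half_width=10.0, box=(80, 80, 120), seed=2)
        assert (np.abs(coords[:, 2]) < 10.0).sum() == 0

    def test_boundary_margin_honoured(self):
        _, coords = syn.gen_water_slab(200, 200, half_width=10.0, box=(80, 80, 120), seed=3)
        assert np.all(np.abs(np.abs(coords[:, 2]) - 10.0) >= 0.5)


class TestOUProcess:
    def test_zero_sd_limit_is_constant(self):
        ou = syn.OUParams(stationary_sd=1e-12, mean_z=2.0, n_frames=500, seed=4)
        z = syn.ou_series(ou)
        np.testing.assert_allclose(z, 2.0, atol=1e-9)

    def test_same_seed_bit_identical(self, ideal_duplex):
        top, coords = ideal_duplex
        ou = syn.OUParams(stationary_sd=1.0, n_frames=200, seed=42)
        bil = syn.BilayerParams(n_per_leaflet=16)
        t1 = syn.gen_anchored_trajectory((top, coords), bil, ou)
        t2 = syn.gen_anchored_trajectory((top, coords), bil, ou)
        assert np.array_equal(t1.coords, t2.coords)
        t3 = syn.gen_anchored_trajectory(
            (top, coords), bil, syn.OUParams(stationary_sd=1.0, n_frames=200, seed=43)
        )
        assert not np.array_equal(t1.coords, t3.coords)

    def test_lag1_autocorrelation_matches_theory(self):
        ou = syn.OUParams(stationary_sd=1.0, relaxation_time=1.0, dt=0.02, n_frames=200_000, seed=9)
        z = syn.ou_series(ou)
        zc = z - z.mean()
        rho1 = float(zc[:-1] @ zc[1:] / (zc @ zc))
        expected = math.exp(-ou.dt / ou.relaxation_time)
        # Monte-Carlo error ~ 1/sqrt(n_eff); generous 3-sigma band
        assert abs(rho1 - expected) < 0.01

    def test_stationary_sd_after_burn_in(self):
        ou = syn.OUParams(stationary_sd=1.05, relaxation_time=5.0, n_frames=50_000, seed=123)
        z = syn.ou_series(ou)
        sd = z[10_000:].std(ddof=1)  # after 200 ns
        assert abs(sd - 1.05) < 3 * 1.05 / math.sqrt(2 * 800 / 10)


class TestSmdGenerator:
    def test_constant_force_rectangle_work(self):
        rec = syn.gen_smd_record(syn.ConstantForce(10.0), 0.0, 10.0)
        from dnanchor.smd import work_curve

        assert work_curve(rec).total_pN_A == pytest.approx(100.0, rel=1e-9)

    def test_zero_force_zero_work(self):
        rec = syn.gen_smd_record(syn.ConstantForce(0.0), 0.0, 40.0)
        from dnanchor.smd import work_curve

        np.testing.assert_allclose(work_curve(rec).work_pN_A, 0.0)

    def test_linear_ramp_triangle_work(self):
        rec = syn.gen_smd_record(syn.LinearForce(1.0), 0.0, 10.0)
        from dnanchor.smd import work_curve

        assert work_curve(rec).total_pN_A == pytest.approx(50.0, rel=1e-6)

    def test_record_kinematics(self):
        rec = syn.gen_smd_record(syn.ConstantForce(1.0), 5.0, 25.0, velocity=0.5, dt=0.02)
        assert rec.z[0] == 5.0 and rec.z[-1] == pytest.approx(25.0)
        np.testing.assert_allclose(rec.z, 5.0 + 0.5 * rec.times, atol=1e-12)
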