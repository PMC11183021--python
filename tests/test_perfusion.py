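"""T1 mapping, signal conversion, forward kinetics and voxel fitting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hepadce import perfusion as pf


def make_vfa(t1_ms, m0, angles=(3.0, 6.0, 9.0, 12.0), tr_ms=4.0, shape=(2, 2, 2)):
    vols = np.stack(
        [np.full(shape, pf.spgr_signal(t1_ms, m0, a, tr_ms)) for a in angles]
    )
    return pf.VfaSet(volumes=vols, flip_angles_deg=np.array(angles), tr_ms=tr_ms)


class TestT1Mapping:
    def test_recovers_t1_m0_from_noise_free_signals(self):
        vfa = make_vfa(1000.0, 1000.0)
        # sanity on the forward SPGR values the fit inverts
        assert pf.spgr_signal(1000, 1000, 3, 4) == pytest.approx(39.0005, abs=1e-3)
        assert pf.spgr_signal(1000, 1000, 12, 4) == pytest.approx(32.2235, abs=1e-3)
        res = pf.fit_t1_vfa(vfa)
        assert np.allclose(res.t1_ms, 1000.0, rtol=1e-6)
        assert np.allclose(res.m0, 1000.0, rtol=1e-6)
        assert res.valid.all()

    def test_pure_sine_signals_flagged_non_physical(self):
        # S proportional to sin(alpha) is the E1 -> 0 (T1 -> 0+) limit
        angles = np.array([3.0, 6.0, 9.0, 12.0])
        vols = 100.0 * np.sin(np.deg2rad(angles))[:, None, None, None] * np.ones(
            (1, 1, 1)
        )
        res = pf.fit_t1_vfa(pf.VfaSet(vols, angles, 4.0))
        assert not res.valid.any()

    def test_single_flip_angle_rejected(self):
        with pytest.raises(pf.InsufficientDataError):
            pf.VfaSet(np.ones((1, 2, 2, 2)), np.array([9.0]), 4.0)

    def test_linearized_fit_matches_grid_search(self):
        rng = np.random.default_rng(42)
        angles = (3.0, 5.0, 8.0, 12.0)
        for _ in range(5):
            t1 = rng.uniform(300, 1800)
            m0 = rng.uniform(500, 2000)
            vfa = make_vfa(t1, m0, angles=angles, shape=(1, 1, 1))
            fit = pf.fit_t1_vfa(vfa)
            # brute-force 2-parameter grid search oracle
            sig = vfa.volumes[:, 0, 0, 0]
            t1_grid = np.linspace(0.8 * t1, 1.2 * t1, 401)
            m0_grid = np.linspace(0.8 * m0, 1.2 * m0, 401)
            sse = np.array(
                [
                    [
                        np.sum((pf.spgr_signal(tt, mm, np.array(angles), 4.0) - sig) ** 2)
                        for mm in m0_grid
                    ]
                    for tt in t1_grid
                ]
            )
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            assert fit.t1_ms[0, 0, 0] == pytest.approx(t1_grid[i], rel=1e-3)
            assert fit.m0[0, 0, 0] == pytest.approx(m0_grid[j], rel=1e-3)


class TestSignalConversion:
    def _uniform_voxel(self, t1=810.0, m0=1000.0):
        t1map = pf.T1M0Map(
            np.full((1, 1, 1), t1), np.full((1, 1, 1), m0), np.ones((1, 1, 1), bool)
        )
        return t1map

    def test_baseline_signal_gives_zero_concentration(self, time_grid):
        t1map = self._uniform_voxel()
        sig = np.full((42, 1, 1, 1), pf.spgr_signal(810.0, 1000.0, 12.0, 4.0))
        dyn = pf.DynamicSeries(sig, time_grid, 12.0, 4.0)
        conc = pf.signal_to_concentration(dyn, t1map)
        assert np.allclose(conc, 0.0, atol=1e-10)

    def test_delta_r1_definition(self, time_grid):
        # delta-R1 of 0.45 1/s at r1 = 4.5 1/s/mM must read 0.1 mM
        t1 = 810.0
        r1_t = 1000.0 / t1 + 0.45
        t1map = self._uniform_voxel(t1=t1)
        sig = np.full((42, 1, 1, 1), pf.spgr_signal(1000.0 / r1_t, 1000.0, 12.0, 4.0))
        sig[:3] = pf.spgr_signal(t1, 1000.0, 12.0, 4.0)  # pre-bolus baseline
        dyn = pf.DynamicSeries(sig, time_grid, 12.0, 4.0)
        conc = pf.signal_to_concentration(dyn, t1map)
        assert conc[-1, 0, 0, 0] == pytest.approx(0.1, rel=1e-9)

    def test_concentration_signal_round_trip(self, time_grid, inputs, canonical_params):
        ct = pf.simulate_tissue_curve(canonical_params, inputs)
        t1 = 810.0
        r1_t = 1000.0 / t1 + 4.5 * ct
        sig = pf.spgr_signal(1000.0 / r1_t, 1000.0, 12.0, 4.0)[:, None, None, None]
        dyn = pf.DynamicSeries(sig, time_grid, 12.0, 4.0)
        conc = pf.signal_to_concentration(dyn, self._uniform_voxel(t1=t1))
        assert np.allclose(conc[:, 0, 0, 0], ct, atol=1e-6)

    def test_invalid_voxel_yields_missing_not_zero(self, time_grid):
        t1map = pf.T1M0Map(
            np.full((1, 1, 1), np.nan),
            np.full((1, 1, 1), np.nan),
            np.zeros((1, 1, 1), bool),
        )
        sig = np.full((42, 1, 1, 1), 30.0)
        conc = pf.signal_to_concentration(pf.DynamicSeries(sig, time_grid, 12.0, 4.0), t1map)
        assert np.isnan(conc).all()


class TestForwardModel:
    def test_zero_flow_gives_zero_curve(self, inputs):
        params = pf.PerfusionParams(art=np.nan, fa=0.0, fp=0.0, ft=0.0, dv=25.0, mtt=np.nan)
        ct = pf.simulate_tissue_curve(params, inputs)
        assert np.allclose(ct, 0.0)

    def test_steady_state_approaches_dv(self, canonical_params):
        t = np.linspace(0.0, 900.0, 901)
        const = pf.InputFunctions(t, np.ones_like(t), np.ones_like(t))
        ct = pf.simulate_tissue_curve(canonical_params, const)
        assert ct[-1] == pytest.approx(0.25, abs=1e-4)

    def test_matches_fine_ode_oracle(self, time_grid, inputs):
        rng = np.random.default_rng(1)
        for _ in range(3):
            params = pf.PerfusionParams.from_flows(
                rng.uniform(10, 150), rng.uniform(10, 150), rng.uniform(10, 40)
            )
            ct = pf.simulate_tissue_curve(params, inputs)
            fa_s, fp_s, k2 = params.rates()

            def rhs(t, y):
                ca = np.interp(t, time_grid, inputs.ca_mM)
                cp = np.interp(t, time_grid, inputs.cp_mM)
                return fa_s * ca + fp_s * cp - k2 * y

            sol = solve_ivp(
                rhs, (0, time_grid[-1]), [0.0], t_eval=time_grid,
                rtol=1e-10, atol=1e-13, max_step=0.05,
            )
            assert np.max(np.abs(sol.y[0] - ct)) < 1e-4

    def test_negative_delay_rejected(self, inputs, canonical_params):
        with pytest.raises(pf.InvalidInputError):
            pf.simulate_tissue_curve(canonical_params, inputs, delay_a_s=-1.0)


class TestVoxelFit:
    def test_noise_free_round_trip(self, inputs, canonical_params):
        ct = pf.simulate_tissue_curve(canonical_params, inputs)
        res = pf.fit_dual_input_voxel(ct, inputs)
        assert res.converged
        for name, truth in canonical_params.as_dict().items():
            assert res.params.as_dict()[name] == pytest.approx(truth, rel=1e-3)

    def test_single_input_degenerate_recovers_zero_portal(self, inputs):
        truth = pf.PerfusionParams.from_flows(80.0, 0.0, 25.0)
        ct = pf.simulate_tissue_curve(truth, inputs)
        res = pf.fit_dual_input_voxel(ct, inputs)
        assert res.params.fp == pytest.approx(0.0, abs=1e-3)
        assert res.params.fa == pytest.approx(80.0, rel=1e-3)

    def test_all_zero_curve_skipped(self, inputs):
        res = pf.fit_dual_input_voxel(np.zeros(42), inputs)
        assert res.skipped and res.params is None

    def test_tracer_linearity_leaves_flows_invariant(self, inputs, canonical_params):
        ct = pf.simulate_tissue_curve(canonical_params, inputs)
        for c in (0.5, 2.0):
            scaled = pf.InputFunctions(
                inputs.time_s, c * inputs.ca_mM, c * inputs.cp_mM
            )
            res = pf.fit_dual_input_voxel(c * ct, scaled)
            assert res.params.ft == pytest.approx(canonical_params.ft, rel=1e-3)
            assert res.params.fa == pytest.approx(canonical_params.fa, rel=1e-3)


class TestDerivedParameters:
    def test_definitional_examples(self):
        ft, art, dv, mtt = pf.derive_secondary_params(30.0, 70.0, pf.k2_from_flows(30, 70, 25))
        assert (ft, art) == (100.0, 30.0)
        assert dv == pytest.approx(25.0)
        assert mtt == pytest.approx(15.0)

    def test_zero_total_flow_undefined(self):
        ft, art, dv, mtt = pf.derive_secondary_params(0.0, 0.0, 0.1)
        assert ft == 0.0 and np.isnan(art) and np.isnan(mtt)

    def test_identities_hold_to_machine_precision(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            fa, fp_ = rng.uniform(0.1, 300, 2)
            k2 = rng.uniform(1e-3, 2.0)
            ft, art, dv, mtt = pf.derive_secondary_params(fa, fp_, k2)
            assert ft == pytest.approx(fa + fp_, rel=1e-14)
            assert art * ft == pytest.approx(100 * fa, rel=1e-12)
            assert mtt == pytest.approx(60 * dv / ft, rel=1e-12)
            assert mtt == pytest.approx(1.0 / k2, rel=1e-12)


class TestParameterMaps:
    def test_empty_mask_rejected(self, time_grid):
        dyn = pf.DynamicSeries(np.ones((42, 2, 2, 2)), time_grid, 12.0, 4.0)
        t1m0 = pf.T1M0Map(
            np.full((2, 2, 2), 800.0), np.full((2, 2, 2), 1000.0), np.ones((2, 2, 2), bool)
        )
        with pytest.raises(pf.InvalidInputError):
            pf.fit_parameter_maps(dyn, t1m0, None, np.zeros((2, 2, 2), bool))
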