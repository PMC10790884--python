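import numpy as np
import pytest
from scipy.integrate import solve_ivp

import occupet as op
from occupet.frames import SECONDS_PER_MINUTE
from occupet.srtm import frame_average


class TestSrtmForward:
    def test_bp_zero_r1_one_reproduces_reference(self, fine_grid, reference_curve):
        """With BP_ND = 0 and R1 = 1, k2 = k2a and the convolution term
        vanishes: the target is the reference for any k2REF."""
        p = op.SRTMParams(r1=1.0, k2ref=0.23, bp_nd=0.0)
        ct = op.srtm_forward(p, reference_curve, fine_grid)
        np.testing.assert_allclose(ct, reference_curve, atol=1e-12)

    def test_step_reference_reaches_dvr_equilibrium(self, fine_grid):
        """For a constant reference input the target/reference ratio
        tends to DVR = 1 + BP_ND."""
        step = np.full_like(fine_grid, 7.0)
        p = op.SRTMParams(r1=1.0, k2ref=0.2, bp_nd=1.5)
        ct = op.srtm_forward(p, step, fine_grid)
        assert ct[-1] / 7.0 == pytest.approx(1.0 + 1.5, rel=0.01)

    def test_at_time_zero_target_is_r1_times_reference(self, fine_grid):
        ref = np.full_like(fine_grid, 3.0)  # nonzero at t=0
        p = op.SRTMParams(r1=0.8, k2ref=0.15, bp_nd=1.0)
        ct = op.srtm_forward(p, ref, fine_grid)
        assert ct[0] == pytest.approx(0.8 * 3.0)

    def test_matches_ode_integrator_oracle(self, protocol, fine_grid):
        """The discretized convolution agrees with an independent ODE
        integration of dC_T/dt = R1 dC_R/dt + k2 C_R - k2a C_T within
        0.1% at every frame midpoint, over random parameter sets."""
        l1, l2 = 1 / 2400.0, 1 / 120.0
        raw = np.exp(-l1 * fine_grid) - np.exp(-l2 * fine_grid)
        scale = 10.0 / raw.max()
        ref = op.simulate_reference_curve(fine_grid, model="biexponential",
                                          amplitude=10.0, lambdas=(l1, l2))
        cr = lambda t: scale * (np.exp(-l1 * t) - np.exp(-l2 * t))
        dcr = lambda t: scale * (-l1 * np.exp(-l1 * t) + l2 * np.exp(-l2 * t))
        mids = protocol.midpoints()
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = op.SRTMParams(
                r1=rng.uniform(0.7, 1.3),
                k2ref=rng.uniform(0.08, 0.25),
                bp_nd=rng.uniform(0.2, 4.0),
            )
            k2 = p.k2 / SECONDS_PER_MINUTE
            k2a = p.k2a / SECONDS_PER_MINUTE
            sol = solve_ivp(
                lambda t, y: [p.r1 * dcr(t) + k2 * cr(t) - k2a * y[0]],
                (0.0, protocol.total_duration), [0.0], t_eval=mids,
                rtol=1e-10, atol=1e-12, method="LSODA",
            )
            mine = np.interp(mids, fine_grid, op.srtm_forward(p, ref, fine_grid))
            rel = np.abs(mine - sol.y[0]) / np.abs(sol.y[0])
            assert rel.max() < 1e-3

    def test_nonuniform_grid_rejected(self):
        grid = np.array([0.0, 1.0, 3.0])
        p = op.SRTMParams(r1=1.0, k2ref=0.15, bp_nd=1.0)
        with pytest.raises(ValueError, match="uniform"):
            op.srtm_forward(p, np.zeros(3), grid)

    @pytest.mark.parametrize("bad", [dict(r1=0.0, k2ref=0.1, bp_nd=1.0),
                                     dict(r1=1.0, k2ref=-0.1, bp_nd=1.0),
                                     dict(r1=1.0, k2ref=0.1, bp_nd=-1.5)])
    def test_out_of_domain_params_rejected(self, bad):
        with pytest.raises(ValueError):
            op.SRTMParams(**bad)


class TestFrameAverage:
    def test_constant_curve(self, protocol, fine_grid):
        vals = frame_average(np.full_like(fine_grid, 2.5), fine_grid, protocol)
        np.testing.assert_allclose(vals, 2.5)

    def test_linear_curve_gives_midpoints(self, protocol, fine_grid):
        """Trapezoid interval-averaging is exact for linear curves: the
        frame value equals the curve at the frame midpoint."""
        vals = frame_average(fine_grid.copy(), fine_grid, protocol)
        np.testing.assert_allclose(vals, protocol.midpoints(), rtol=1e-12)

    def test_grid_refinement_agreement(self, protocol):
        """Gamma-variate frame averages computed on a 10x finer grid
        agree within 0.01%."""
        coarse = np.arange(0.0, 5401.0, 1.0)
        fine = np.arange(0.0, 5400.01, 0.1)
        gv = lambda t: t * np.exp(-t / 300.0)
        v1 = frame_average(gv(coarse), coarse, protocol)
        v2 = frame_average(gv(fine), fine, protocol)
        np.testing.assert_allclose(v1, v2, rtol=1e-4)

    def test_grid_not_covering_schedule_rejected(self, protocol):
        short = np.arange(0.0, 1000.0)
        with pytest.raises(ValueError, match="cover"):
            frame_average(np.zeros_like(short), short, protocol)


class TestBpndToDvr:
    @pytest.mark.parametrize("bp, dvr", [(0.0, 1.0), (0.2, 1.2), (2.25, 3.25)])
    def test_values(self, bp, dvr):
        assert op.bpnd_to_dvr(bp) == pytest.approx(dvr)

    def test_domain(self):
        with pytest.raises(ValueError):
            op.bpnd_to_dvr(-1.0)


class TestFitSrtmCoupled:
    def test_noiseless_parameter_recovery(self, noiseless_study):
        """fit(forward(theta)) == theta within 0.5% relative, with the
        shared k2REF recovered too."""
        baseline, _, ledger = noiseless_study
        fit = op.fit_srtm_coupled(baseline)
        assert abs(fit.k2ref - ledger.k2ref_baseline) / ledger.k2ref_baseline < 5e-3
        for i in range(len(ledger.roi_ids)):
            p = fit.params[i]
            assert abs(p.r1 - ledger.r1[i]) / ledger.r1[i] < 5e-3
            assert abs(p.bp_nd - ledger.bp_baseline[i]) / ledger.bp_baseline[i] < 5e-3

    def test_shared_k2ref_identical_across_rois(self, noiseless_study):
        baseline, _, _ = noiseless_study
        fit = op.fit_srtm_coupled(baseline)
        assert len({p.k2ref for p in fit.params.values()}) == 1
        assert all(w >= 0 for w in fit.wrss.values())

    def test_null_bp_recovered(self):
        baseline, _, _ = op.simulate_study(
            n_rois=1, bp_values=np.array([0.0]), r1_values=np.array([1.1]),
            occupancy_field=np.array([0.0]), seed=5,
        )
        fit = op.fit_srtm_coupled(baseline)
        assert abs(fit.params[0].bp_nd) < 0.01

    def test_scale_equivariance(self, noiseless_study):
        """Multiplying all TACs by s > 0 leaves (R1, k2REF, BP) unchanged."""
        baseline, _, _ = noiseless_study
        s = 37.0
        scaled = op.TACSet(
            tacs={
                rid: op.TimeActivityCurve(rid, t.values * s, t.schedule, t.weights)
                for rid, t in baseline.tacs.items()
            },
            reference=op.TimeActivityCurve(
                "reference", baseline.reference.values * s, baseline.schedule,
                baseline.reference.weights,
            ),
            schedule=baseline.schedule,
        )
        f1 = op.fit_srtm_coupled(baseline)
        f2 = op.fit_srtm_coupled(scaled)
        assert f2.k2ref == pytest.approx(f1.k2ref, rel=1e-6)
        for rid in f1.params:
            assert f2.params[rid].bp_nd == pytest.approx(f1.params[rid].bp_nd, rel=1e-5)
            assert f2.params[rid].r1 == pytest.approx(f1.params[rid].r1, rel=1e-5)

    def test_objective_trace_best_so_far_monotone(self, noiseless_study):
        """The running best of the outer objective never increases, and
        the reported total WRSS attains it."""
        baseline, _, _ = noiseless_study
        fit = op.fit_srtm_coupled(baseline)
        best = np.minimum.accumulate(fit.objective_trace)
        assert np.all(np.diff(best) <= 0)
        assert fit.total_wrss <= best[-1] + 1e-9

    def test_deterministic(self, noiseless_study):
        baseline, _, _ = noiseless_study
        f1 = op.fit_srtm_coupled(baseline)
        f2 = op.fit_srtm_coupled(baseline)
        assert f1.k2ref == f2.k2ref
        assert all(f1.params[r].bp_nd == f2.params[r].bp_nd for r in f1.params)

    def test_all_zero_reference_rejected(self, protocol):
        ref = op.TimeActivityCurve("ref", np.zeros(30), protocol)
        tac = op.TimeActivityCurve(0, np.ones(30), protocol)
        ts = op.TACSet(tacs={0: tac}, reference=ref, schedule=protocol)
        with pytest.raises(ValueError, match="reference"):
            op.fit_srtm_coupled(ts)
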