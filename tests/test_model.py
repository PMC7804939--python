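"""Unit tests for the spatial firing-rate model: kernels, fixed points, dynamics."""

import numpy as np
import pytest
from dataclasses import replace

from sweepnet.config import default_params
from sweepnet.model import (
    ConnectivityParams,
    DynamicsParams,
    InvalidParameterError,
    ModelParams,
    PerturbationSpec,
    StimulusSpec,
    TonotopicGrid,
    apply_perturbation,
    build_kernels,
    calibrate_mu,
    decompose_inputs,
    isn_certificate,
    simulate,
    steady_state,
    stimulus_drive,
    transfer,
)


def _uniform_conn(w=1.0, lam=0.5):
    W = np.full((3, 3), w)
    W[:, 1] = -abs(w) if w else 0.0
    W[:, 2] = -abs(w) if w else 0.0
    return ConnectivityParams(W=W, lam=np.full((3, 3), lam))


class TestKernels:
    def test_rows_sum_to_weight(self, params_small):
        K = build_kernels(params_small.grid, params_small.conn)
        W = params_small.conn.W
        for a in range(3):
            for b in range(3):
                assert np.allclose(K[a, b].sum(axis=1), W[a, b], atol=1e-10)

    def test_zero_weight_gives_zero_operator(self):
        grid = TonotopicGrid(n_points=21)
        conn = _uniform_conn(0.0)
        K = build_kernels(grid, conn)
        assert np.all(K == 0)

    def test_constant_field_maps_to_weighted_constant(self, params_small):
        K = build_kernels(params_small.grid, params_small.conn)
        ones = np.ones(params_small.grid.n_points)
        out = K[0, 0] @ ones
        assert np.allclose(out, params_small.conn.W[0, 0], atol=1e-10)

    def test_matches_direct_quadrature_on_coarse_grid(self):
        # brute-force oracle: evaluate the Gaussian kernel and its grid
        # normalization explicitly, point by point
        grid = TonotopicGrid(n_points=21)
        W, lam = 0.7, 0.8
        conn = ConnectivityParams(
            W=np.array([[W, -0.1, -0.1]] * 3).T * 0 + np.array([[W, -0.1, -0.1]] * 3),
            lam=np.full((3, 3), lam),
        )
        x = grid.x
        expected = np.empty((21, 21))
        for i in range(21):
            g = np.exp(-((x[i] - x) ** 2) / lam**2)
            G = np.sum(g * grid.dx)
            expected[i] = W * np.exp(-((x[i] - x) ** 2) / lam**2) * grid.dx / G
        K = build_kernels(grid, conn)
        assert np.allclose(K[0, 0], expected, atol=1e-12)

    def test_huge_scale_approaches_uniform_rows(self):
        grid = TonotopicGrid(n_points=21)
        conn = _uniform_conn(1.0, lam=1e4)
        K = build_kernels(grid, conn)
        assert np.allclose(K[0, 0], 1.0 / 21, rtol=1e-5)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(InvalidParameterError):
            ConnectivityParams(W=np.zeros((3, 3)), lam=np.zeros((3, 3)))

    def test_positive_inhibitory_weight_rejected(self):
        W = np.zeros((3, 3))
        W[0, 2] = 0.5  # SOM output must be non-positive
        with pytest.raises(InvalidParameterError):
            ConnectivityParams(W=W, lam=np.ones((3, 3)))


class TestTransfer:
    @pytest.mark.parametrize("v,expected", [(-1.0, 0.0), (0.0, 0.0), (2.5, 2.5)])
    def test_threshold_linear(self, v, expected):
        assert transfer(v) == expected

    def test_elementwise(self):
        out = transfer(np.array([-2.0, 0.0, 3.0]))
        assert np.array_equal(out, [0.0, 0.0, 3.0])


class TestStimulus:
    def test_bump_center_and_peak(self):
        grid = TonotopicGrid(n_points=401)
        spec = StimulusSpec(s=20.0, f0=4.0, amp=[7.0, 7.0, 0.0], sigma=[0.3] * 3)
        b = stimulus_drive(spec, grid, 0.1)
        # center x = 20 * 0.1 + log2(4) = 4, i.e. 16 kHz
        i = np.argmax(b[0])
        assert np.isclose(grid.x[i], 4.0, atol=grid.dx)
        assert np.isclose(b[0].max(), 7.0, rtol=1e-6)

    def test_zero_outside_gate(self):
        grid = TonotopicGrid(n_points=51)
        spec = StimulusSpec(s=20.0, f0=4.0, amp=[1.0] * 3, sigma=[0.3] * 3)
        assert np.all(stimulus_drive(spec, grid, spec.t_stop + 1e-9) == 0)
        assert np.all(stimulus_drive(spec, grid, spec.t_start - 1e-9) == 0)

    def test_ramp_reaches_amp_min_frac_at_stop(self):
        grid = TonotopicGrid(n_points=401)
        spec = StimulusSpec(
            s=20.0, f0=4.0, amp=[10.0] * 3, sigma=[0.3] * 3, ramp=True, amp_min_frac=0.8
        )
        b = stimulus_drive(spec, grid, spec.t_stop)
        assert np.isclose(b[0].max(), 8.0, rtol=1e-6)


class TestSteadyState:
    def test_decoupled_equals_mu(self):
        grid = TonotopicGrid(n_points=11)
        conn = _uniform_conn(0.0)
        dyn = DynamicsParams(tau_m=[0.01] * 3, tau_r=[0, 0, 0.1], mu=[5, 10, 3], r0=[5, 10, 3])
        p = ModelParams(grid=grid, conn=conn, dyn=dyn, amp=[0] * 3, sigma=[0.3] * 3)
        st = steady_state(p)
        assert np.allclose(st.r[:, 0], [5, 10, 3], atol=1e-12)

    def test_default_residual_below_tolerance(self, params_small):
        st = steady_state(params_small)
        r0 = st.r[:, 0]
        resid = r0 - (params_small.conn.W @ transfer(r0) + params_small.dyn.mu)
        assert np.max(np.abs(resid)) < 1e-10

    def test_calibrate_mu_roundtrip(self, params_small):
        target = np.array([2.0, 6.0, 3.5])
        mu = calibrate_mu(target, params_small.conn)
        dyn = replace(params_small.dyn, mu=mu, r0=target)
        p = replace(params_small, dyn=dyn)
        assert np.allclose(steady_state(p).r[:, 0], target, atol=1e-10)

    def test_calibrate_mu_decoupled(self):
        conn = _uniform_conn(0.0)
        assert np.allclose(calibrate_mu([5, 10, 3], conn), [5, 10, 3])

    def test_calibrate_mu_rejects_nonpositive_target(self, params_small):
        with pytest.raises(InvalidParameterError):
            calibrate_mu([1.0, -1.0, 1.0], params_small.conn)


class TestIsnCertificate:
    def test_default_parameters_are_isn(self, params_medium):
        cert = isn_certificate(params_medium)
        assert cert["lambda_e_only"] > 0
        assert cert["lambda_full"] < 0
        assert cert["is_isn"]

    def test_non_isn_after_beta_scaling(self, params_medium):
        p = apply_perturbation(params_medium, PerturbationSpec(kind="non_isn", beta=0.2))
        cert = isn_certificate(p)
        assert not cert["is_isn"]  # E-only subsystem is stable once W_EE < 1


class TestPerturbations:
    def test_none_is_identity(self, params_small):
        assert apply_perturbation(params_small, PerturbationSpec(kind="none")) is params_small

    def test_som_inactivation_scales_outgoing_by_20_percent(self, params_small):
        p = apply_perturbation(params_small, PerturbationSpec(kind="som_inactivation"))
        assert np.allclose(p.conn.W[:, 2], 0.8 * params_small.conn.W[:, 2])
        assert np.allclose(p.conn.W[:, :2], params_small.conn.W[:, :2])
        assert p.extra_drive[2] == -1.5

    def test_non_isn_halves_weights_and_amp(self, params_small):
        p = apply_perturbation(params_small, PerturbationSpec(kind="non_isn", beta=0.5))
        assert np.allclose(p.conn.W, 0.5 * params_small.conn.W)
        assert np.allclose(p.amp, 0.5 * params_small.amp)
        assert np.isclose(steady_state(p).r[0, 0], 0.1, atol=1e-10)

    def test_narrow_som_sets_som_scales(self, params_small):
        p = apply_perturbation(
            params_small, PerturbationSpec(kind="narrow_som", narrow_lambda=0.3)
        )
        assert np.all(p.conn.lam[2, :] == 0.3)
        assert np.all(p.conn.lam[:, 2] == 0.3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(kind="bogus")


class TestSimulate:
    def test_zero_stimulus_stays_at_equilibrium(self, params_small):
        spec = StimulusSpec(s=20.0, f0=4.0, amp=[0.0] * 3, sigma=[0.3] * 3)
        res = simulate(params_small, spec, t_span=(0.0, 1.0))
        drift = np.abs(res.r - res.r0[None, :, None]).max()
        assert drift < 10 * 1e-5 * np.abs(res.r0).max() + 10 * 1e-6

    def test_mirror_symmetry_up_down(self, params_small):
        from sweepnet.protocols import run_sweep_pair

        pair = run_sweep_pair(params_small, 20.0, rtol=1e-8, atol=1e-10)
        up = pair.up.rates()[:, 0, :]
        down = pair.down.rates()[:, 0, :]
        assert np.abs(up - down[:, ::-1]).max() < 1e-4 * max(1.0, up.max())

    def test_grid_refinement_converges(self):
        from sweepnet.protocols import model_dsi, run_sweep_pair

        d = {}
        for n in (201, 401):
            pair = run_sweep_pair(default_params(n), 20.0)
            d[n] = model_dsi(pair)
        coarse_on_fine = d[401].dsi[::2]
        assert np.nanmax(np.abs(d[201].dsi - coarse_on_fine)) < 0.02

    def test_small_tau_r_fallback_matches_algebraic(self, params_small):
        # a 0.1-ms rate filter on E and P lags the algebraic solution by at
        # most tau * dr/dt pointwise; the integrated DSI profile must agree
        from sweepnet.protocols import SweepPairResult, model_dsi

        def profile(p):
            up = simulate(p, StimulusSpec.full_sweep(20.0, amp=p.amp, sigma=p.sigma))
            down = simulate(p, StimulusSpec.full_sweep(-20.0, amp=p.amp, sigma=p.sigma))
            return model_dsi(SweepPairResult(up, down, 20.0)).dsi

        d0 = profile(params_small)
        dyn = replace(params_small.dyn, tau_r=np.array([1e-4, 1e-4, 0.15]))
        d1 = profile(replace(params_small, dyn=dyn))
        assert np.nanmax(np.abs(d0 - d1)) < 1e-3


class TestDecomposeInputs:
    def test_sum_of_parts_identity(self, pair20_medium):
        res = pair20_medium.down
        comp = decompose_inputs(res, np.log2(5.0))
        t = comp["t"]
        total = (
            comp["feedforward"] + comp["recurrent_e"] + comp["pv_input"]
            + comp["som_input"] + comp["mu_E"] - comp["A_E"]
        )
        # integral form avoids differentiating across threshold kinks:
        # tau_E (A(t1) - A(t0)) = int total dt over any subinterval
        tau = res.params.dyn.tau_m[0]
        i0, i1 = 50, len(t) - 50
        lhs = tau * (comp["A_E"][i1] - comp["A_E"][i0])
        rhs = np.trapezoid(total[i0:i1 + 1], t[i0:i1 + 1])
        assert abs(lhs - rhs) < 1e-3 * max(1.0, np.abs(comp["A_E"]).max())

    def test_zero_som_weight_zeroes_som_component(self, params_small):
        W = params_small.conn.W.copy()
        W[0, 2] = 0.0
        conn = ConnectivityParams(W=W, lam=params_small.conn.lam)
        dyn = replace(
            params_small.dyn, mu=calibrate_mu(params_small.dyn.r0, conn)
        )
        p = replace(params_small, conn=conn, dyn=dyn)
        spec = StimulusSpec.full_sweep(20.0, amp=p.amp, sigma=p.sigma)
        res = simulate(p, spec)
        comp = decompose_inputs(res, 4.0)
        assert np.all(comp["som_input"] == 0)

    def test_leading_suppression_before_feedforward_peak(self, pair20_medium):
        # at a 5-kHz probe the downward sweep recruits SOM inhibition from the
        # high-frequency side before the stimulus bump arrives
        comp = decompose_inputs(pair20_medium.down, np.log2(5.0))
        som_dev = comp["som_input"] - comp["som_input"][0]
        thr = 0.1 * np.abs(som_dev).max()
        t_onset = comp["t"][np.argmax(som_dev < -thr)]
        t_ff_peak = comp["t"][np.argmax(comp["feedforward"])]
        assert t_onset < t_ff_peak

    def test_probe_outside_grid_rejected(self, pair20_medium):
        with pytest.raises(InvalidParameterError):
            decompose_inputs(pair20_medium.up, 7.5)
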