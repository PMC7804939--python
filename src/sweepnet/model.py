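"""Three-population spatial firing-rate model of A1 on a tonotopic continuum.

The model places excitatory (E), parvalbumin (P) and somatostatin (S)
populations on a one-dimensional tonotopic axis, where position ``x`` in
log2-kHz corresponds to a best frequency of ``2**x`` kHz.  Each population
carries an input activity ``A_alpha(x, t)`` driven by recurrent interactions,
a feedforward stimulus drive and a constant background drive::

    tau_m_alpha dA_alpha/dt = -A_alpha
                              + sum_beta int K_ab(x, y) F(r_beta(y)) dy
                              + b_alpha(x, t) + mu_alpha

and a rate variable obtained through a first-order temporal filter
``tau_r_alpha dr_alpha/dt = A_alpha - r_alpha`` (instantaneous, ``r = A``,
when ``tau_r_alpha == 0``).  The firing output is the threshold-linear
``F(r) = max(r, 0)``.  Connectivity kernels are Gaussians in octave distance,
normalized so the total effective interaction from population beta onto
population alpha is exactly ``W_ab`` at every tonotopic position; the
normalization is computed with the same discrete quadrature used to apply the
kernels, so conservation is exact on the grid.

An FM sweep is a Gaussian bump of feedforward drive travelling along the axis
at a signed rate ``s`` (oct/s, positive upward).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "POPULATIONS",
    "TonotopicGrid",
    "ConnectivityParams",
    "DynamicsParams",
    "StimulusSpec",
    "PerturbationSpec",
    "ModelParams",
    "NetworkState",
    "SimulationResult",
    "transfer",
    "build_kernels",
    "steady_state",
    "calibrate_mu",
    "stimulus_drive",
    "apply_perturbation",
    "linear_stability",
    "isn_certificate",
    "simulate",
    "decompose_inputs",
]

POPULATIONS = ("E", "P", "S")

_E, _P, _S = 0, 1, 2


class InvalidParameterError(ValueError):
    """Raised for parameter values outside the model's domain."""


class UnstableFixedPointError(RuntimeError):
    """Raised when the requested baseline state is linearly unstable."""


@dataclass(frozen=True)
class TonotopicGrid:
    """Uniform discretization of the tonotopic axis in log2-kHz units."""

    x_min: float = 2.0
    x_max: float = 6.0
    n_points: int = 401

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidParameterError("grid needs at least 3 points")
        if not self.x_max > self.x_min:
            raise InvalidParameterError("x_max must exceed x_min")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_points)

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / (self.n_points - 1)

    @property
    def bf_khz(self) -> np.ndarray:
        """Best frequency (kHz) at each grid point."""
        return 2.0 ** self.x

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.x_min + self.x_max)

    def index_of(self, x: float) -> int:
        if not (self.x_min <= x <= self.x_max):
            raise InvalidParameterError(f"position {x} outside grid [{self.x_min}, {self.x_max}]")
        return int(round((x - self.x_min) / self.dx))


@dataclass(frozen=True)
class ConnectivityParams:
    """Signed effective weights W[post, pre] and Gaussian spatial scales (octaves)."""

    W: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, float)
        lam = np.asarray(self.lam, float)
        if W.shape != (3, 3) or lam.shape != (3, 3):
            raise InvalidParameterError("W and lam must be 3x3 (post, pre) over (E, P, S)")
        if np.any(lam <= 0):
            raise InvalidParameterError("all spatial scales must be positive")
        if np.any(W[:, _P] > 0) or np.any(W[:, _S] > 0):
            raise InvalidParameterError("PV and SOM output weights must be non-positive")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "lam", lam)


@dataclass(frozen=True)
class DynamicsParams:
    """Time constants (seconds), background drives and baseline rates per population."""

    tau_m: np.ndarray
    tau_r: np.ndarray
    mu: np.ndarray
    r0: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_r", "mu", "r0"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.tau_m <= 0):
            raise InvalidParameterError("membrane/input time constants must be positive")
        if np.any(self.tau_r < 0):
            raise InvalidParameterError("rate-filter time constants must be non-negative")


@dataclass(frozen=True)
class StimulusSpec:
    """Travelling Gaussian drive for a logarithmic FM sweep.

    ``s`` is the sweep rate in oct/s (positive upward), ``f0`` the starting
    frequency in kHz.  ``amp`` and ``sigma`` are per-population amplitudes and
    bump widths (octaves).  When ``ramp`` is set the amplitude decreases
    linearly from ``amp`` at ``t_start`` to ``amp_min_frac * amp`` at
    ``t_stop``, which imprints a direction preference on the feedforward
    input itself.
    """

    s: float
    f0: float
    amp: np.ndarray
    sigma: np.ndarray
    t_start: float = 0.0
    t_stop: float | None = None
    span_oct: float = 4.0
    ramp: bool = False
    amp_min_frac: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "amp", np.asarray(self.amp, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if np.any(self.sigma <= 0):
            raise InvalidParameterError("stimulus widths must be positive")
        if self.t_stop is None:
            if self.s == 0:
                raise InvalidParameterError("t_stop required for a stationary stimulus")
            object.__setattr__(self, "t_stop", self.t_start + self.span_oct / abs(self.s))
        if not self.t_stop > self.t_start:
            raise InvalidParameterError("t_stop must exceed t_start")

    @classmethod
    def full_sweep(
        cls,
        rate: float,
        amp: Sequence[float],
        sigma: Sequence[float],
        x_min: float = 2.0,
        x_max: float = 6.0,
        **kw,
    ) -> "StimulusSpec":
        """A sweep covering the whole axis: 4->64 kHz upward, 64->4 kHz downward."""
        if rate == 0:
            raise InvalidParameterError("sweep rate must be nonzero")
        f0 = 2.0 ** (x_min if rate > 0 else x_max)
        return cls(s=rate, f0=f0, amp=amp, sigma=sigma, span_oct=x_max - x_min, **kw)

    @classmethod
    def restricted_sweep(
        cls,
        rate: float,
        f_cent: float,
        amp: Sequence[float],
        sigma: Sequence[float],
        span_oct: float = 1.0,
        **kw,
    ) -> "StimulusSpec":
        """A sweep spanning ``span_oct`` octaves logarithmically centred at ``f_cent`` kHz."""
        if rate == 0:
            raise InvalidParameterError("sweep rate must be nonzero")
        half = span_oct / 2.0
        f0 = f_cent * 2.0 ** (-half if rate > 0 else half)
        return cls(s=rate, f0=f0, amp=amp, sigma=sigma, span_oct=span_oct, **kw)


@dataclass(frozen=True)
class PerturbationSpec:
    """In-silico circuit manipulation applied before the sweep protocol.

    kinds
    -----
    none              unperturbed control.
    som_inactivation  scale SOM output weights by ``weight_scale`` and inject
                      ``inact_current`` into the SOM dA/dt equation.
    pv_inactivation   same for PV.
    narrow_som        set every spatial scale involving SOM to ``narrow_lambda``.
    non_isn           scale all weights and feedforward amplitudes by ``beta``
                      and recalibrate drives so the pyramidal baseline is
                      ``r0_E_override`` Hz.
    ff_dsi            enable the linear feedforward amplitude ramp.
    """

    kind: str = "none"
    weight_scale: float = 0.8
    inact_current: float = -1.5
    beta: float = 0.5
    r0_E_override: float = 0.1
    narrow_lambda: float | None = None
    scale_incoming: bool = False

    KINDS = ("none", "som_inactivation", "pv_inactivation", "narrow_som", "non_isn", "ff_dsi")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InvalidParameterError(f"unknown perturbation kind {self.kind!r}")
        if not (0 < self.weight_scale <= 1):
            raise InvalidParameterError("weight_scale must lie in (0, 1]")
        if not (0 < self.beta <= 1):
            raise InvalidParameterError("beta must lie in (0, 1]")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter bundle: grid, connectivity, dynamics, stimulus shape."""

    grid: TonotopicGrid
    conn: ConnectivityParams
    dyn: DynamicsParams
    amp: np.ndarray
    sigma: np.ndarray
    extra_drive: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "amp", np.asarray(self.amp, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        object.__setattr__(self, "extra_drive", np.asarray(self.extra_drive, float))

    @property
    def total_drive(self) -> np.ndarray:
        """Background drive plus any perturbation-injected constant current."""
        return self.dyn.mu + self.extra_drive


@dataclass
class NetworkState:
    """Input activities and rate variables over the grid, shape (3, n)."""

    A: np.ndarray
    r: np.ndarray

    def rates(self) -> np.ndarray:
        return transfer(self.r)


@dataclass
class SimulationResult:
    """Trajectory of the network: ``A`` and ``r`` have shape (T, 3, n)."""

    t: np.ndarray
    A: np.ndarray
    r: np.ndarray
    params: ModelParams
    spec: StimulusSpec
    perturbation: PerturbationSpec
    r0: np.ndarray

    def rates(self) -> np.ndarray:
        """Firing output F(r), shape (T, 3, n)."""
        return transfer(self.r)

    def delta_r_E(self) -> np.ndarray:
        """Change of pyramidal firing from baseline, F(r_E) - r_E^0, shape (T, n)."""
        return transfer(self.r[:, _E, :]) - transfer(self.r0[_E])


def transfer(v):
    """Threshold-linear transfer function F(v) = max(v, 0)."""
    return np.maximum(v, 0.0)


def build_kernels(grid: TonotopicGrid, conn: ConnectivityParams) -> np.ndarray:
    """Discrete connectivity operators, shape (3, 3, n, n).

    ``K[a, b] @ F(r_b)`` approximates ``int K_ab(x, y) F(r_b(y)) dy``; the
    quadrature weight dx and the normalization G(x) are folded in so every row
    of ``K[a, b]`` sums to exactly ``W[a, b]``.
    """
    x = grid.x
    d2 = (x[:, None] - x[None, :]) ** 2
    K = np.empty((3, 3, grid.n_points, grid.n_points))
    for a in range(3):
        for b in range(3):
            g = np.exp(-d2 / conn.lam[a, b] ** 2)
            K[a, b] = conn.W[a, b] * g / g.sum(axis=1, keepdims=True)
    return K


def calibrate_mu(target_r0: Sequence[float], conn: ConnectivityParams) -> np.ndarray:
    """Background drives giving spatially uniform baseline rates ``target_r0``.

    At a positive fixed point the threshold is inactive, so
    ``mu = (I - W) r0`` exactly.
    """
    r0 = np.asarray(target_r0, float)
    if np.any(r0 <= 0):
        raise InvalidParameterError("target baseline rates must be positive")
    return r0 - conn.W @ r0


def steady_state(params: ModelParams, check_stability: bool = False) -> NetworkState:
    """Spatially uniform fixed point of the network with zero stimulus.

    Solves ``r = W F(r) + mu`` over the 8 threshold sign patterns and returns
    the consistent solution broadcast across the grid.  Because the kernels
    conserve total interaction, a uniform fixed point of the 3-dimensional
    reduced system is a fixed point of the full spatial system.
    """
    W = params.conn.W
    mu = params.total_drive
    solution = None
    for mask in range(8):
        active = np.array([(mask >> i) & 1 for i in range(3)], bool)
        D = np.diag(active.astype(float))
        try:
            r = np.linalg.solve(np.eye(3) - W @ D, mu)
        except np.linalg.LinAlgError:
            continue
        ok = np.all(r[active] > 0) and np.all(r[~active] <= 0)
        if ok:
            solution = r
            break
    if solution is None:
        raise UnstableFixedPointError("no consistent threshold-linear fixed point found")
    resid = solution - (W @ transfer(solution) + mu)
    if np.max(np.abs(resid)) > 1e-10:
        raise UnstableFixedPointError(f"fixed-point residual {np.max(np.abs(resid)):.2e}")
    if check_stability:
        lam_max = linear_stability(params, solution)
        if lam_max >= 0:
            raise UnstableFixedPointError(
                f"baseline state unstable: largest eigenvalue real part {lam_max:.4g} 1/s"
            )
    n = params.grid.n_points
    field_r = np.tile(solution[:, None], (1, n))
    return NetworkState(A=field_r.copy(), r=field_r.copy())


def _jacobian(params: ModelParams, r0: np.ndarray, pops: Sequence[int]) -> np.ndarray:
    """Jacobian of the discrete dynamics at a uniform fixed point ``r0``.

    ``pops`` selects the sub-circuit (other populations frozen at baseline).
    Threshold gain F'(r0) is 1 for positive baseline and 0 for silenced
    populations.  State ordering: A blocks for each selected population, then
    r blocks for those with a nonzero rate filter.
    """
    grid = params.grid
    n = grid.n_points
    K = build_kernels(grid, params.conn)
    gain = (r0 > 0).astype(float)
    filtered = [p for p in pops if params.dyn.tau_r[p] > 0]
    nA = len(pops) * n
    size = nA + len(filtered) * n
    J = np.zeros((size, size))
    eye = np.eye(n)
    r_index = {p: nA + k * n for k, p in enumerate(filtered)}
    for i, a in enumerate(pops):
        sl_a = slice(i * n, (i + 1) * n)
        J[sl_a, sl_a] += -eye / params.dyn.tau_m[a]
        for j, b in enumerate(pops):
            block = K[a, b] * gain[b] / params.dyn.tau_m[a]
            if params.dyn.tau_r[b] > 0:
                J[sl_a, r_index[b]:r_index[b] + n] += block
            else:
                J[sl_a, j * n:(j + 1) * n] += block
    for p in filtered:
        i = pops.index(p)
        sl_r = slice(r_index[p], r_index[p] + n)
        J[sl_r, i * n:(i + 1) * n] += eye / params.dyn.tau_r[p]
        J[sl_r, sl_r] += -eye / params.dyn.tau_r[p]
    return J


def linear_stability(params: ModelParams, r0: np.ndarray | None = None) -> float:
    """Largest real part (1/s) over eigenvalues of the full linearized system."""
    if r0 is None:
        r0 = steady_state(params).r[:, 0]
    J = _jacobian(params, np.asarray(r0, float), [0, 1, 2])
    return float(np.max(np.linalg.eigvals(J).real))


def isn_certificate(params: ModelParams) -> dict:
    """Inhibition-stabilized-network check at the baseline state.

    Returns the largest eigenvalue real parts of (a) the E-only subsystem with
    inhibition frozen and (b) the full system.  The network is an ISN when the
    former is positive (runaway excitation) while the latter is negative
    (stabilized by feedback inhibition).
    """
    r0 = steady_state(params).r[:, 0]
    lam_e = float(np.max(np.linalg.eigvals(_jacobian(params, r0, [_E])).real))
    lam_full = linear_stability(params, r0)
    return {"lambda_e_only": lam_e, "lambda_full": lam_full, "is_isn": lam_e > 0 and lam_full < 0}


def stimulus_drive(
    spec: StimulusSpec, grid: TonotopicGrid, t: float, amp: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> np.ndarray:
    """Per-population feedforward drive field at time ``t``, shape (3, n).

    Gaussian bump centred at ``x_c(t) = s (t - t_start) + log2 f0``; exactly
    zero outside the stimulus gate.  With ``spec.ramp`` the amplitude decays
    linearly to ``amp_min_frac`` of its initial value at ``t_stop``.
    """
    amp = spec.amp if amp is None else np.asarray(amp, float)
    sigma = spec.sigma if sigma is None else np.asarray(sigma, float)
    if t < spec.t_start or t > spec.t_stop:
        return np.zeros((3, grid.n_points))
    a = amp.astype(float).copy()
    if spec.ramp:
        frac = (t - spec.t_start) / (spec.t_stop - spec.t_start)
        a = a * (1.0 + (spec.amp_min_frac - 1.0) * frac)
    xc = spec.s * (t - spec.t_start) + np.log2(spec.f0)
    bump = np.exp(-((grid.x - xc) ** 2)[None, :] / (sigma ** 2)[:, None])
    return a[:, None] * bump


def apply_perturbation(params: ModelParams, pert: PerturbationSpec) -> ModelParams:
    """Return parameters modified by an in-silico manipulation.

    Photoinactivation scales the target population's outgoing weights (its
    effect on the network) and injects a constant hyperpolarizing current into
    its dA/dt equation; ``scale_incoming`` additionally scales its inputs for
    sensitivity analyses.  The caller obtains the new pre-stimulus steady
    state via :func:`steady_state` on the returned parameters.
    """
    if pert.kind == "none":
        return params
    W = params.conn.W.copy()
    lam = params.conn.lam.copy()
    dyn = params.dyn
    amp = params.amp.copy()
    extra = params.extra_drive.copy()
    if pert.kind in ("som_inactivation", "pv_inactivation"):
        tgt = _S if pert.kind == "som_inactivation" else _P
        W[:, tgt] *= pert.weight_scale
        if pert.scale_incoming:
            W[tgt, :] *= pert.weight_scale
        extra[tgt] += pert.inact_current
        conn = ConnectivityParams(W=W, lam=lam)
        return replace(params, conn=conn, extra_drive=extra)
    if pert.kind == "narrow_som":
        if pert.narrow_lambda is None:
            narrow = float(np.min(lam))
        else:
            narrow = pert.narrow_lambda
        lam[_S, :] = narrow
        lam[:, _S] = narrow
        conn = ConnectivityParams(W=W, lam=lam)
        return replace(params, conn=conn)
    if pert.kind == "non_isn":
        W *= pert.beta
        amp *= pert.beta
        conn = ConnectivityParams(W=W, lam=lam)
        r0 = dyn.r0.copy()
        r0[_E] = pert.r0_E_override
        mu = calibrate_mu(r0, conn)
        new_dyn = DynamicsParams(tau_m=dyn.tau_m, tau_r=dyn.tau_r, mu=mu, r0=r0)
        return replace(params, conn=conn, dyn=new_dyn, amp=amp)
    if pert.kind == "ff_dsi":
        return params  # the ramp lives in the stimulus spec
    raise InvalidParameterError(f"unknown perturbation kind {pert.kind!r}")


class _CompiledModel:
    """Precomputed kernels and state packing for the integrator."""

    def __init__(self, params: ModelParams):
        self.params = params
        self.n = params.grid.n_points
        self.K = build_kernels(params.grid, params.conn)
        self.tau_m = params.dyn.tau_m
        self.tau_r = params.dyn.tau_r
        self.mu = params.total_drive
        self.filtered = [p for p in range(3) if self.tau_r[p] > 0]

    def pack(self, state: NetworkState) -> np.ndarray:
        parts = [state.A.ravel()]
        for p in self.filtered:
            parts.append(state.r[p])
        return np.concatenate(parts)

    def unpack(self, y: np.ndarray):
        n = self.n
        A = y[: 3 * n].reshape(3, n)
        r = A.copy()
        for k, p in enumerate(self.filtered):
            r[p] = y[3 * n + k * n: 3 * n + (k + 1) * n]
        return A, r

    def rhs(self, t: float, y: np.ndarray, spec: StimulusSpec, amp: np.ndarray) -> np.ndarray:
        n = self.n
        A, r = self.unpack(y)
        rates = transfer(r)
        b = stimulus_drive(spec, self.params.grid, t, amp=amp)
        dy = np.empty_like(y)
        for a in range(3):
            inp = self.K[a, 0] @ rates[0] + self.K[a, 1] @ rates[1] + self.K[a, 2] @ rates[2]
            dy[a * n:(a + 1) * n] = (-A[a] + inp + b[a] + self.mu[a]) / self.tau_m[a]
        for k, p in enumerate(self.filtered):
            dy[3 * n + k * n: 3 * n + (k + 1) * n] = (A[p] - r[p]) / self.tau_r[p]
        return dy


def simulate(
    params: ModelParams,
    spec: StimulusSpec,
    pert: PerturbationSpec | None = None,
    t_span: tuple[float, float] | None = None,
    rtol: float = 1e-5,
    atol: float = 1e-6,
    dt_record: float = 1e-3,
    settle_s: float = 1.0,
) -> SimulationResult:
    """Integrate the network response to a sweep from the (perturbed) steady state.

    The trajectory starts at the fixed point of the possibly perturbed system
    ("the system was allowed to reach its new steady state before the
    stimulus").  Integration is split at the stimulus gate times so the
    adaptive solver never steps across the drive discontinuity.  Defaults
    record at 1-ms resolution and extend ``settle_s`` seconds past stimulus
    offset so rates return to baseline before the DSI integrals are truncated.
    """
    pert = pert or PerturbationSpec()
    p = apply_perturbation(params, pert)
    if pert.kind == "ff_dsi" and not spec.ramp:
        spec = replace(spec, ramp=True)
    model = _CompiledModel(p)
    base = steady_state(p)
    y0 = model.pack(base)
    if t_span is None:
        t_span = (min(0.0, spec.t_start), spec.t_stop + settle_s)
    t0, t1 = t_span
    breaks = sorted({t0, t1} | {t for t in (spec.t_start, spec.t_stop) if t0 < t < t1})
    t_eval_all, ys = [], []
    y = y0
    # the non-ISN manipulation also weakens the feedforward drive
    amp = spec.amp * (pert.beta if pert.kind == "non_isn" else 1.0)
    for seg0, seg1 in zip(breaks[:-1], breaks[1:]):
        n_rec = max(2, int(round((seg1 - seg0) / dt_record)) + 1)
        t_eval = np.linspace(seg0, seg1, n_rec)
        sol = solve_ivp(
            model.rhs, (seg0, seg1), y, method="RK45", t_eval=t_eval,
            rtol=rtol, atol=atol, args=(spec, amp),
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{seg0}, {seg1}]: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise RuntimeError("non-finite state encountered during integration")
        y = sol.y[:, -1]
        skip = 1 if ys else 0  # drop duplicated segment endpoint
        t_eval_all.append(sol.t[skip:])
        ys.append(sol.y[:, skip:])
    t = np.concatenate(t_eval_all)
    Y = np.concatenate(ys, axis=1)
    T = t.size
    A = np.empty((T, 3, model.n))
    r = np.empty((T, 3, model.n))
    for i in range(T):
        A[i], r[i] = model.unpack(Y[:, i])
    return SimulationResult(
        t=t, A=A, r=r, params=p, spec=spec, perturbation=pert, r0=base.r[:, 0].copy()
    )


def decompose_inputs(result: SimulationResult, probe_x: float) -> dict[str, np.ndarray]:
    """Input decomposition onto a pyramidal cell at tonotopic position ``probe_x``.

    Returns time series of the feedforward drive, recurrent excitatory input,
    PV input, SOM input, the constant background drive, and the firing output
    F(r_E) at the probe.  The components satisfy the bookkeeping identity
    ``tau_E dA_E/dt = -A_E + ff + rec_E + pv + som + mu_E`` at every stored
    time.
    """
    p = result.params
    grid = p.grid
    idx = grid.index_of(probe_x)
    K = build_kernels(grid, p.conn)
    rates = result.rates()  # (T, 3, n)
    rec_e = rates[:, _E, :] @ K[_E, _E][idx]
    pv = rates[:, _P, :] @ K[_E, _P][idx]
    som = rates[:, _S, :] @ K[_E, _S][idx]
    ff = np.array([
        stimulus_drive(result.spec, grid, t, amp=p.amp)[_E, idx] for t in result.t
    ])
    return {
        "t": result.t,
        "feedforward": ff,
        "recurrent_e": rec_e,
        "pv_input": pv,
        "som_input": som,
        "mu_E": np.full_like(ff, p.total_drive[_E]),
        "A_E": result.A[:, _E, idx],
        "rate_E": rates[:, _E, idx],
    }
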