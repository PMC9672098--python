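"""Single-junction mechanochemical model of an actomyosin "concentration oscillator".

A cell edge is treated as an overdamped elastic element pulled by an external
tension ``T(t)`` and compressed by its own myosin contractility.  Myosin line
density on the edge is advected (concentrated/diluted) by length changes, turns
over toward a target density, and fluctuates with additive white noise.  Two
slow processes sit on top of the fast oscillator: viscoelastic remodeling of the
rest length, and mechanical feedback that raises the target density in
proportion to the relative strain rate of the edge.

State variables (units in parentheses):

* ``L``      edge length (µm)
* ``L0r``    rest length of the elastic element (µm)
* ``m``      myosin line density (a.u./µm)
* ``m0t``    target density the turnover relaxes toward (a.u./µm)

Governing equations::

    gamma * dL/dt   = T(t) - Tel(L) - Ta(m)                 (fast, friction-limited)
    Tel(L)          = k * L0r * ln(L / L0r)                 (large-deformation elasticity)
    Ta(m)           = beta * m**2 / (m_sat**2 + m**2)       (cooperative contractility)
    dm/dt           = -(m - m0t)/tau - (m/L)*dL/dt + sigma*xi(t)
    dL0r/dt         = (L - L0r)/tau_r                       (if remodeling)
    dm0t/dt         = c * m0t * (1/L)*dL/dt                 (if feedback)

Near the rest length ``Tel`` reduces to the linear spring ``k*(L - L0r)``;
under strong compression it diverges, so the edge cannot be contracted to
zero length.  The sigmoidal (Hill-2, cooperative myosin assembly) active
tension reduces the oscillator drive on both the high- and low-density
excursion sides.  Together these two standard nonlinearities make the
oscillatory (Hopf) instability of the concentration oscillator saturate into
a stable limit cycle; with purely linear elasticity and contractility the
dilution nonlinearity (``m ~ 1/L`` under contraction) makes the contracted
branch run away and the edge collapses.

The feedback law integrates exactly to the power law
``m0t(t) = m0t(0) * (L(t)/L(0))**c``: a junction that undergoes a net
fold-extension Lambda ends with its target density multiplied by Lambda**c.

Discretization is an explicit split step at fixed ``dt`` (Euler for the length,
rest-length and turnover updates, Euler–Maruyama for the noise), with the
advection and feedback sub-steps applied as exact log-increments so that
``m*L`` is conserved to machine precision when turnover, feedback and noise are
off, and the feedback power law holds exactly for any ``dt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ModelParams",
    "JunctionState",
    "TensionProtocol",
    "JunctionTrace",
    "StabilityResult",
    "step",
    "simulate",
    "ensemble_simulate",
    "linear_stability",
    "hopf_contractility",
    "default_state",
    "active_tension",
    "elastic_tension",
    "fixed_point_tension",
    "DEFAULT_REST_LENGTH",
]

#: Default junction rest length (µm); a typical germband edge is ~5–10 µm.
DEFAULT_REST_LENGTH = 10.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the junction model.

    Defaults put the noise-free fast subsystem slightly past its oscillatory
    (Hopf) instability, giving a stable limit cycle with a linear period of
    ~73 s — the observed timescale regime of junctional myosin/length
    oscillations.  They are conventions of this package, not measured values.

    Attributes
    ----------
    elastic_k : float
        Elastic stiffness, tension per unit extension near the rest length
        (a.u./µm).
    friction_gamma : float
        Friction coefficient of length relaxation (a.u.·s/µm).
    contractility_beta : float
        Maximal contractile tension at saturating myosin density (a.u.).
    contractile_saturation : float
        Half-saturation density ``m_sat`` of the Hill-2 active tension
        (a.u./µm).
    turnover_tau : float
        Myosin turnover time (s); ``inf`` disables turnover.
    rest_remodel_tau : float
        Rest-length remodeling time (s).
    baseline_density : float
        Initial/target myosin density (a.u./µm).
    feedback_c : float
        Dimensionless feedback coefficient (target-density e-foldings per unit
        log-strain).
    noise_sigma : float
        Amplitude of white noise on the density rate (a.u./µm/sqrt(s)).
    dt : float
        Integration time step (s).
    feedback_enabled, remodeling_enabled : bool
        Toggles for the two slow processes.
    feedback_rectified : bool
        If True, feedback acts only while the edge extends (recruitment only);
        by default it is sign-symmetric.
    """

    elastic_k: float = 1.5
    friction_gamma: float = 10.0
    contractility_beta: float = 41.0
    contractile_saturation: float = 1.0
    turnover_tau: float = 20.0
    rest_remodel_tau: float = 300.0
    baseline_density: float = 1.0
    feedback_c: float = 1.0
    noise_sigma: float = 0.05
    dt: float = 0.05
    feedback_enabled: bool = True
    remodeling_enabled: bool = True
    feedback_rectified: bool = False

    def __post_init__(self) -> None:
        if not self.friction_gamma > 0:
            raise ValueError("friction_gamma must be > 0")
        if not self.turnover_tau > 0:
            raise ValueError("turnover_tau must be > 0 (inf disables turnover)")
        if not self.rest_remodel_tau > 0:
            raise ValueError("rest_remodel_tau must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.feedback_c < 0:
            raise ValueError("feedback_c must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.elastic_k < 0:
            raise ValueError("elastic_k must be >= 0")
        if not (self.contractile_saturation > 0
                and math.isfinite(self.contractile_saturation)):
            raise ValueError("contractile_saturation must be finite and > 0")
        if self.baseline_density < 0:
            raise ValueError("baseline_density must be >= 0")


@dataclass(frozen=True)
class JunctionState:
    """Instantaneous state of one junction."""

    time: float
    length: float
    rest_length: float
    myosin_density: float
    target_density: float

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be > 0")
        if not self.rest_length > 0:
            raise ValueError("rest_length must be > 0")
        if self.myosin_density < 0:
            raise ValueError("myosin_density must be >= 0")
        if self.target_density < 0:
            raise ValueError("target_density must be >= 0")


class TensionProtocol:
    """Piecewise external tension T(t) in tension units (a.u.).

    Construct with :meth:`constant`, :meth:`step` or :meth:`ramp`; instances
    are callables ``T(t)`` accepting scalars or arrays.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], description: dict):
        self._fn = fn
        self.description = dict(description)

    def __call__(self, t):
        out = self._fn(np.asarray(t, dtype=float))
        if not np.all(np.isfinite(out)):
            raise ValueError("tension protocol returned a non-finite value")
        return out if np.ndim(t) else float(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TensionProtocol({self.description})"

    @classmethod
    def constant(cls, value: float) -> "TensionProtocol":
        return cls(lambda t: np.full_like(t, float(value)),
                   {"kind": "constant", "value": float(value)})

    @classmethod
    def step(cls, t_step: float, before: float, after: float) -> "TensionProtocol":
        return cls(lambda t: np.where(t < t_step, float(before), float(after)),
                   {"kind": "step", "t_step": float(t_step),
                    "before": float(before), "after": float(after)})

    @classmethod
    def ramp(cls, t0: float, t1: float, before: float, after: float) -> "TensionProtocol":
        """Linear ramp from ``before`` to ``after`` over [t0, t1]."""
        if not t1 > t0:
            raise ValueError("ramp requires t1 > t0")

        def fn(t):
            frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            return float(before) + (float(after) - float(before)) * frac

        return cls(fn, {"kind": "ramp", "t0": float(t0), "t1": float(t1),
                        "before": float(before), "after": float(after)})


@dataclass(frozen=True)
class JunctionTrace:
    """Uniformly sampled simulation output of one junction.

    All arrays share the same length; ``times`` is strictly increasing with
    constant spacing ``params.dt``.
    """

    times: np.ndarray
    length: np.ndarray
    rest_length: np.ndarray
    myosin_density: np.ndarray
    target_density: np.ndarray
    params: ModelParams
    protocol: dict
    seed: int

    def __post_init__(self) -> None:
        n = len(self.times)
        for arr in (self.length, self.rest_length, self.myosin_density,
                    self.target_density):
            if len(arr) != n:
                raise ValueError("trace arrays must have equal length")
        dts = np.diff(self.times)
        if n > 1 and (np.any(dts <= 0)
                      or np.max(np.abs(dts - dts[0])) > 1e-9 * max(dts[0], 1.0)):
            raise ValueError("trace times must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def default_state(params: ModelParams,
                  rest_length: float = DEFAULT_REST_LENGTH) -> JunctionState:
    """State with the edge at its rest length and density at baseline."""
    return JunctionState(time=0.0, length=rest_length, rest_length=rest_length,
                         myosin_density=params.baseline_density,
                         target_density=params.baseline_density)


def active_tension(params: ModelParams, m: float) -> float:
    """Sigmoidal contractile tension ``beta*m**2/(m_sat**2 + m**2)``."""
    ms2 = params.contractile_saturation ** 2
    return params.contractility_beta * m * m / (ms2 + m * m)


def elastic_tension(params: ModelParams, length: float, rest_length: float) -> float:
    """Large-deformation elastic tension ``k * L0r * ln(L/L0r)``.

    Reduces to the linear spring ``k*(L - L0r)`` for small strain and diverges
    under strong compression.
    """
    return params.elastic_k * rest_length * math.log(length / rest_length)


def fixed_point_tension(params: ModelParams, state: JunctionState) -> float:
    """External tension that balances the given state (dL/dt = 0)."""
    return (elastic_tension(params, state.length, state.rest_length)
            + active_tension(params, state.myosin_density))


def _advance(t, L, L0r, m, m0t, p: ModelParams, t_ext, z):
    """One split step of the governing equations on raw floats.

    Order: length (Euler) -> exact dilution -> turnover (Euler) -> noise
    (Euler–Maruyama, clipped at 0) -> rest-length remodeling (Euler) ->
    exact feedback log-increment.
    """
    dt = p.dt
    ms2 = p.contractile_saturation ** 2
    t_active = p.contractility_beta * m * m / (ms2 + m * m)
    t_elastic = p.elastic_k * L0r * math.log(L / L0r)
    dLdt = (t_ext - t_elastic - t_active) / p.friction_gamma
    L1 = L + dt * dLdt
    if not L1 > 0:
        raise FloatingPointError(
            f"edge length became non-positive at t={t + dt:.6g} s "
            f"(L={L1:.3g}); reduce dt")
    # exact advection: integrates dm/dt = -(m/L) dL/dt along this sub-step,
    # conserving m*L
    m1 = m * (L / L1)
    if math.isfinite(p.turnover_tau):
        m1 += dt * (m0t - m1) / p.turnover_tau
    if p.noise_sigma > 0.0:
        m1 += p.noise_sigma * math.sqrt(dt) * z
        if m1 < 0.0:
            m1 = 0.0
    L0r1 = L0r + dt * (L1 - L0r) / p.rest_remodel_tau if p.remodeling_enabled else L0r
    if p.feedback_enabled and (not p.feedback_rectified or L1 > L):
        # exact integral of dm0t/m0t = c dL/L over the sub-step
        m0t1 = m0t * (L1 / L) ** p.feedback_c
    else:
        m0t1 = m0t
    return t + dt, L1, L0r1, m1, m0t1


def step(state: JunctionState, params: ModelParams, t_ext: float,
         noise_draw: float = 0.0) -> JunctionState:
    """Advance a single junction state by one time step ``params.dt``.

    ``noise_draw`` is a standard-normal variate scaled internally by
    ``noise_sigma * sqrt(dt)``.
    """
    vals = (state.time, state.length, state.rest_length,
            state.myosin_density, state.target_density, float(t_ext))
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite state or tension: {vals}")
    t, L, L0r, m, m0t = _advance(state.time, state.length, state.rest_length,
                                 state.myosin_density, state.target_density,
                                 params, float(t_ext), float(noise_draw))
    return JunctionState(time=t, length=L, rest_length=L0r,
                         myosin_density=m, target_density=m0t)


def simulate(params: ModelParams, protocol: TensionProtocol, duration: float,
             initial: JunctionState | None = None, seed: int = 0) -> JunctionTrace:
    """Integrate the junction model for ``duration`` seconds.

    Returns a trace of ``floor(duration/dt)+1`` states (initial state
    included).  Identical inputs and seed give a bit-identical trace.
    """
    p = params
    dt = p.dt
    if duration < dt:
        raise ValueError("duration must be >= dt")
    if initial is None:
        initial = default_state(p)
    n = int(math.floor(duration / dt + 1e-9))
    times = initial.time + dt * np.arange(n + 1)
    tension = np.asarray(protocol(times[:-1]), dtype=float)
    if tension.ndim == 0:
        tension = np.full(n, float(tension))
    noise = (np.random.default_rng(seed).standard_normal(n)
             if p.noise_sigma > 0.0 else np.zeros(n))

    L_arr = np.empty(n + 1)
    L0r_arr = np.empty(n + 1)
    m_arr = np.empty(n + 1)
    m0t_arr = np.empty(n + 1)
    t = initial.time
    L, L0r = initial.length, initial.rest_length
    m, m0t = initial.myosin_density, initial.target_density
    L_arr[0], L0r_arr[0], m_arr[0], m0t_arr[0] = L, L0r, m, m0t

    # inlined _advance loop (kept in sync; consistency is unit-tested)
    k, gamma, beta = p.elastic_k, p.friction_gamma, p.contractility_beta
    ms2 = p.contractile_saturation ** 2
    tau, tau_r = p.turnover_tau, p.rest_remodel_tau
    sigma, c = p.noise_sigma, p.feedback_c
    has_turnover = math.isfinite(tau)
    remodel, feedback = p.remodeling_enabled, p.feedback_enabled
    rectified = p.feedback_rectified
    sqdt = math.sqrt(dt)
    log = math.log
    for i in range(n):
        dLdt = (tension[i] - k * L0r * log(L / L0r)
                - beta * m * m / (ms2 + m * m)) / gamma
        L1 = L + dt * dLdt
        if not L1 > 0:
            raise FloatingPointError(
                f"edge length became non-positive at step {i + 1} "
                f"(t={t + dt:.6g} s); reduce dt")
        m = m * (L / L1)
        if has_turnover:
            m += dt * (m0t - m) / tau
        if sigma > 0.0:
            m += sigma * sqdt * noise[i]
            if m < 0.0:
                m = 0.0
        if remodel:
            L0r += dt * (L1 - L0r) / tau_r
        if feedback and (not rectified or L1 > L):
            m0t *= (L1 / L) ** c
        L = L1
        t += dt
        L_arr[i + 1], L0r_arr[i + 1] = L, L0r
        m_arr[i + 1], m0t_arr[i + 1] = m, m0t

    for name, arr in (("length", L_arr), ("myosin_density", m_arr),
                      ("rest_length", L0r_arr), ("target_density", m0t_arr)):
        if not np.all(np.isfinite(arr)):
            idx = int(np.argmax(~np.isfinite(arr)))
            raise FloatingPointError(
                f"non-finite {name} at step {idx} (t={times[idx]:.6g} s)")
    return JunctionTrace(times=times, length=L_arr, rest_length=L0r_arr,
                         myosin_density=m_arr, target_density=m0t_arr,
                         params=p, protocol=dict(protocol.description),
                         seed=int(seed))


def ensemble_simulate(params: ModelParams, protocol: TensionProtocol,
                      n_runs: int, duration: float,
                      initial: JunctionState | None = None,
                      seed: int = 0) -> list[JunctionTrace]:
    """Run ``n_runs`` independent seeded simulations.

    Child seeds are derived deterministically from the master seed, so the
    ensemble is reproducible and run ``i`` does not depend on ``n_runs``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    return [simulate(params, protocol, duration, initial=initial, seed=int(s))
            for s in child_seeds]


@dataclass(frozen=True)
class StabilityResult:
    """Linearization of the fast (L, m) subsystem about its fixed point."""

    fixed_point_length: float
    fixed_point_density: float
    eigenvalues: tuple
    oscillatory: bool
    unstable: bool
    period: float  # 2*pi/|Im lambda| for a complex pair, else nan


def linear_stability(params: ModelParams, t_ext: float,
                     rest_length: float = DEFAULT_REST_LENGTH) -> StabilityResult:
    """Analytic stability of the fast subsystem at fixed rest length/target.

    The fixed point is ``m* = baseline_density`` and
    ``L* = L0r * exp((t_ext - Ta(m*)) / (k*L0r))``; the Jacobian of (L, m)
    about it is evaluated in closed form.  Raises if no admissible fixed
    point exists in the numerically representable range.
    """
    p = params
    if p.elastic_k <= 0:
        raise ValueError("linear_stability requires elastic_k > 0")
    m_star = p.baseline_density
    exponent = (t_ext - active_tension(p, m_star)) / (p.elastic_k * rest_length)
    if abs(exponent) > 50.0:
        raise ValueError(
            f"no admissible fixed point: log fold-extension {exponent:.3g} "
            f"is out of range for t_ext = {t_ext:.4g}")
    L_star = rest_length * math.exp(exponent)
    k, gamma, tau = p.elastic_k, p.friction_gamma, p.turnover_tau
    # local slopes of the two tension laws at the fixed point
    ms2 = p.contractile_saturation ** 2
    slope_a = (2.0 * p.contractility_beta * ms2 * m_star
               / (ms2 + m_star ** 2) ** 2)
    slope_el = k * rest_length / L_star
    inv_tau = 1.0 / tau if math.isfinite(tau) else 0.0
    jac = np.array([
        [-slope_el / gamma, -slope_a / gamma],
        [slope_el * m_star / (gamma * L_star),
         -inv_tau + slope_a * m_star / (gamma * L_star)],
    ])
    eig = np.linalg.eigvals(jac)
    oscillatory = bool(np.max(np.abs(eig.imag)) > 1e-12)
    unstable = bool(np.max(eig.real) > 0)
    period = 2.0 * math.pi / float(np.max(np.abs(eig.imag))) if oscillatory else math.nan
    return StabilityResult(fixed_point_length=float(L_star),
                           fixed_point_density=float(m_star),
                           eigenvalues=tuple(eig),
                           oscillatory=oscillatory, unstable=unstable,
                           period=period)


def hopf_contractility(params: ModelParams,
                       rest_length: float = DEFAULT_REST_LENGTH) -> float:
    """Contractility ``beta`` at the oscillatory instability threshold.

    Assumes the external tension is co-adjusted so the fixed-point length
    stays at ``rest_length``.  The threshold is where the local slope of the
    active tension reaches ``(k/gamma + 1/tau) * gamma * L* / m*``:
    ``beta_c = slope_c * (m_sat**2 + m***2)**2 / (2 * m_sat**2 * m*)``.
    """
    p = params
    inv_tau = 1.0 / p.turnover_tau if math.isfinite(p.turnover_tau) else 0.0
    slope_c = ((p.elastic_k / p.friction_gamma + inv_tau)
               * p.friction_gamma * rest_length / p.baseline_density)
    ms2 = p.contractile_saturation ** 2
    m0 = p.baseline_density
    return slope_c * (ms2 + m0 ** 2) ** 2 / (2.0 * ms2 * m0)
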