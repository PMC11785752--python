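"""Semi-quantitative dynamics of signed regulatory networks.

Each node carries a normalised activation level x_n ∈ [0, 1] obeying

    dx_n/dt = A(ω_n) − γ x_n

where ω_n ∈ [0, 1] is a fuzzy-logic aggregate of the node's regulators and
A is a sigmoid with gain h normalised so that A(0)=0, A(0.5)=0.5, A(1)=1.
With activator levels s_a = Σ α x (total activator weight W_a = Σ α) and
inhibitor levels s_i = Σ β x (weight W_i):

    only activators:  ω = ((1+W_a)/W_a) · s_a/(1+s_a)
    only inhibitors:  ω = 1 − ((1+W_i)/W_i) · s_i/(1+s_i)
    both:             product of the two factors

This is the classic fuzzy-logic interpolation of Boolean network rules
(Mendoza & Xenarios 2006): at h → ∞ the ODE recovers the Boolean update, at
finite h it yields smooth, bounded semi-quantitative trajectories.

Nodes without regulators ("input" nodes) have no defined ω; they hold their
initial value, acting as implicit clamps.  Explicit clamping fixes a node at
a value throughout integration by zeroing its derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import RegulatoryNetwork, UnknownNodeError

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "CompiledModel",
    "InputNodeError",
    "IntegrationError",
    "omega_input",
    "activation_response",
    "derivative_field",
    "integrate_to_steady_state",
    "find_fixed_points",
    "validate_clamps",
]


class InputNodeError(ValueError):
    """ω requested for a node without regulators."""


class IntegrationError(RuntimeError):
    """Numerical failure (non-finite state) during integration."""


@dataclass
class SimulationConfig:
    """All dynamical parameters.

    h       sigmoid gain (dimensionless; 10 gives smooth semi-quantitative
            behaviour, large h approaches the Boolean limit)
    gamma   first-order decay rate per node
    alpha   weight of every activating edge
    beta    weight of every inhibiting edge
    t_end   integration horizon in model time units (the system typically
            reaches steady state well within 30 units at gamma=1)
    t_max   cap when extending unconverged runs in t_end-sized chunks
    ss_tol  steady-state threshold on max |dx/dt|
    rel_tol / abs_tol  adaptive-integrator tolerances
    """

    h: float = 10.0
    gamma: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    t_end: float = 30.0
    t_max: float = 300.0
    ss_tol: float = 1e-6
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    cluster_tol: float = 0.01  # attractor-identity tolerance (Chebyshev)
    phenotype_margin: float = 0.1

    def __post_init__(self):
        for attr in ("h", "gamma", "alpha", "beta"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.t_end > self.t_max:
            raise ValueError("t_end must not exceed t_max")
        for attr in ("ss_tol", "rel_tol", "abs_tol", "t_end"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (len(times), n_nodes)
    converged: bool
    t_converged: float | None = None
    node_names: list[str] = field(default_factory=list)


def validate_clamps(
    clamps: dict[str, float] | None, net: RegulatoryNetwork
) -> dict[str, float]:
    clamps = dict(clamps or {})
    for name, value in clamps.items():
        if not net.has_node(name):
            raise UnknownNodeError(name)
        if not 0.0 <= float(value) <= 1.0:
            raise ValueError(f"clamp value for {name!r} outside [0, 1]: {value}")
    return clamps


def activation_response(omega, h: float):
    """Sigmoid activation A(ω) with gain h, normalised on [0, 1].

    Product-form denominator: A = (e^{−h(ω−0.5)} − e^{0.5h}) /
    ((1−e^{0.5h})(1+e^{−h(ω−0.5)})), which pins A(0)=0, A(0.5)=0.5, A(1)=1
    for every h>0.  Evaluated in a rescaled form that stays finite for
    large h.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    omega = np.asarray(omega, dtype=float)
    if 0.5 * h > 700.0:  # exact Boolean limit; exp would overflow
        return np.where(omega < 0.5, 0.0, np.where(omega > 0.5, 1.0, 0.5))
    # divide numerator and denominator by e^{0.5h}:
    #   A = (e^{−hω} − 1) / ((e^{−0.5h} − 1)(1 + e^{−h(ω−0.5)}))
    with np.errstate(over="ignore", invalid="ignore"):
        z = np.clip(-h * (omega - 0.5), None, 700.0)
        num = np.expm1(-h * omega)
        den = np.expm1(-0.5 * h) * (1.0 + np.exp(z))
        out = num / den
    return np.clip(out, 0.0, 1.0) if out.ndim else float(np.clip(out, 0.0, 1.0))


class CompiledModel:
    """Vectorised right-hand side for one (network, config, clamps) triple.

    Precomputes activator/inhibitor incidence matrices so that ω for all
    nodes is two mat-vecs; used by every integration entry point.
    """

    def __init__(
        self,
        net: RegulatoryNetwork,
        cfg: SimulationConfig,
        clamps: dict[str, float] | None = None,
    ):
        self.net = net
        self.cfg = cfg
        self.names = net.node_names
        self.index = {n: i for i, n in enumerate(self.names)}
        n = len(self.names)
        self.act = np.zeros((n, n))
        self.inh = np.zeros((n, n))
        for i in net.interactions:
            row, col = self.index[i.target], self.index[i.source]
            if i.effect == 1:
                self.act[row, col] = cfg.alpha
            else:
                self.inh[row, col] = cfg.beta
        self.w_act = self.act.sum(axis=1)
        self.w_inh = self.inh.sum(axis=1)
        self.has_act = self.w_act > 0
        self.has_inh = self.w_inh > 0
        self.is_input = ~(self.has_act | self.has_inh)
        clamps = validate_clamps(clamps, net)
        self.clamp_idx = np.array(
            [self.index[k] for k in clamps], dtype=int
        )
        self.clamp_values = np.array([float(v) for v in clamps.values()])
        self.free = np.ones(n, dtype=bool)
        self.free[self.clamp_idx] = False
        self.free &= ~self.is_input

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def apply_clamps(self, x: np.ndarray) -> np.ndarray:
        x = np.array(x, dtype=float)
        if self.clamp_idx.size:
            x[self.clamp_idx] = self.clamp_values
        return x

    def omega(self, x: np.ndarray) -> np.ndarray:
        """ω for every node; NaN marks input nodes (undefined)."""
        x = np.asarray(x, dtype=float)
        s_act = self.act @ x
        s_inh = self.inh @ x
        fa = np.ones_like(s_act)
        fi = np.ones_like(s_inh)
        wa = np.where(self.has_act, self.w_act, 1.0)
        wi = np.where(self.has_inh, self.w_inh, 1.0)
        np.divide(
            (1.0 + wa) * s_act, wa * (1.0 + s_act), out=fa, where=self.has_act
        )
        fi = np.where(
            self.has_inh,
            1.0 - ((1.0 + wi) / wi) * (s_inh / (1.0 + s_inh)),
            1.0,
        )
        om = np.clip(fa * fi, 0.0, 1.0)
        return np.where(self.is_input, np.nan, om)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        om = self.omega(x)
        with np.errstate(invalid="ignore"):
            dx = activation_response(om, self.cfg.h) - self.cfg.gamma * x
        dx = np.where(self.is_input, 0.0, dx)
        if self.clamp_idx.size:
            dx[self.clamp_idx] = 0.0
        return dx

    def residual(self, x: np.ndarray) -> float:
        """max |dx/dt| over all nodes (clamped/input contribute 0)."""
        return float(np.max(np.abs(self.rhs(0.0, x)))) if self.n_nodes else 0.0


# ---------------------------------------------------------------------------
# functional API


def omega_input(
    node: str,
    state,
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
) -> float:
    """Fuzzy-logic total input ω of one node given a system state.

    ``state`` is a mapping name → level or an array in node order.  Raises
    :class:`InputNodeError` for nodes without regulators (ω undefined; such
    nodes hold their initial value).
    """
    cfg = cfg or SimulationConfig()
    model = CompiledModel(net, cfg)
    if node not in model.index:
        raise UnknownNodeError(node)
    x = _state_vector(state, model)
    om = model.omega(x)[model.index[node]]
    if np.isnan(om):
        raise InputNodeError(f"{node!r} has no regulators; ω is undefined")
    return float(om)


def _state_vector(state, model: CompiledModel) -> np.ndarray:
    if isinstance(state, dict):
        missing = [n for n in model.names if n not in state]
        if missing:
            raise UnknownNodeError(f"state missing nodes: {missing}")
        x = np.array([float(state[n]) for n in model.names])
    else:
        x = np.asarray(state, dtype=float)
        if x.shape != (model.n_nodes,):
            raise ValueError(
                f"state has shape {x.shape}, expected ({model.n_nodes},)"
            )
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("state levels must lie in [0, 1]")
    return np.clip(x, 0.0, 1.0)


def derivative_field(
    state,
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
    clamps: dict[str, float] | None = None,
) -> np.ndarray:
    """dx/dt at ``state``: A(ω) − γx for regulated nodes, 0 for clamped and
    input nodes."""
    cfg = cfg or SimulationConfig()
    model = CompiledModel(net, cfg, clamps)
    return model.rhs(0.0, _state_vector(state, model))


def _check_finite(x: np.ndarray, t: float):
    if not np.all(np.isfinite(x)):
        bad = np.where(~np.isfinite(x))[0]
        raise IntegrationError(
            f"non-finite state at t={t:.3f} in coordinates {bad.tolist()}"
        )


def _rk4_chunk(model, x, t0, t1, dt):
    steps = max(1, int(round((t1 - t0) / dt)))
    hstep = (t1 - t0) / steps
    times = [t0]
    states = [x]
    for k in range(steps):
        t = t0 + k * hstep
        k1 = model.rhs(t, x)
        k2 = model.rhs(t + hstep / 2, x + hstep / 2 * k1)
        k3 = model.rhs(t + hstep / 2, x + hstep / 2 * k2)
        k4 = model.rhs(t + hstep, x + hstep * k3)
        x = x + hstep / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        times.append(t0 + (k + 1) * hstep)
        states.append(x)
    return np.array(times), np.array(states)


def integrate_to_steady_state(
    x0,
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
    clamps: dict[str, float] | None = None,
    method: str = "adaptive",
    rk4_dt: float = 0.01,
    n_report: int = 31,
) -> tuple[Trajectory, np.ndarray]:
    """Integrate from ``x0`` until steady state or the time cap.

    Integrates to ``cfg.t_end``; if max |dx/dt| still exceeds ``cfg.ss_tol``,
    extends in t_end-sized chunks up to ``cfg.t_max``.  Clamped coordinates
    of ``x0`` are overwritten by their clamp values and stay exactly fixed;
    input nodes hold their initial value (a warning is emitted once).

    ``method`` is ``"adaptive"`` (Runge–Kutta 4(5), the ode45 analogue) or
    ``"rk4"`` (fixed step ``rk4_dt``, cross-check mode).  Returns the
    recorded :class:`Trajectory` and the final state.
    """
    cfg = cfg or SimulationConfig()
    model = CompiledModel(net, cfg, clamps)
    unclamped_input = model.is_input.copy()
    unclamped_input[model.clamp_idx] = False
    if np.any(unclamped_input):
        inputs = [model.names[i] for i in np.where(unclamped_input)[0]]
        warnings.warn(
            f"input nodes (no regulators) hold their initial value: {inputs}",
            stacklevel=2,
        )
    x = model.apply_clamps(_state_vector(x0, model))

    all_times = [np.array([0.0])]
    all_states = [x[None, :]]
    t = 0.0
    converged = model.residual(x) <= cfg.ss_tol
    t_converged = 0.0 if converged else None
    while not converged and t < cfg.t_max - 1e-12:
        t1 = min(t + cfg.t_end, cfg.t_max)
        if method == "adaptive":
            t_eval = np.linspace(t, t1, n_report)[1:]
            sol = solve_ivp(
                model.rhs,
                (t, t1),
                x,
                method="RK45",
                t_eval=t_eval,
                rtol=cfg.rel_tol,
                atol=cfg.abs_tol,
            )
            if not sol.success:
                raise IntegrationError(f"solver failed: {sol.message}")
            chunk_t, chunk_x = sol.t, sol.y.T
        elif method == "rk4":
            chunk_t, chunk_x = _rk4_chunk(model, x, t, t1, rk4_dt)
            chunk_t, chunk_x = chunk_t[1:], chunk_x[1:]
        else:
            raise ValueError(f"unknown method {method!r}")
        x = chunk_x[-1]
        _check_finite(x, t1)
        # numerical excursions beyond the invariant box are solver noise
        chunk_x = np.clip(chunk_x, 0.0, 1.0)
        x = np.clip(x, 0.0, 1.0)
        if model.clamp_idx.size:
            chunk_x[:, model.clamp_idx] = model.clamp_values
            x[model.clamp_idx] = model.clamp_values
        all_times.append(chunk_t)
        all_states.append(chunk_x)
        t = t1
        if model.residual(x) <= cfg.ss_tol:
            converged = True
            t_converged = t
    traj = Trajectory(
        times=np.concatenate(all_times),
        states=np.vstack(all_states),
        converged=converged,
        t_converged=t_converged,
        node_names=list(model.names),
    )
    return traj, x


def find_fixed_points(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
    clamps: dict[str, float] | None = None,
    grid: int = 3,
    tol: float = 1e-9,
    dedupe_tol: float = 1e-5,
) -> list[dict]:
    """Locate fixed points x* = A(ω*)/γ by Newton iteration from a grid of
    starting points over the free coordinates; input nodes must be clamped.

    Returns a list of ``{"state": array, "stable": bool}`` sorted
    lexicographically by state.  Stability is judged from the numerical
    Jacobian restricted to free coordinates.
    """
    from itertools import product as iproduct

    from scipy.optimize import fsolve

    cfg = cfg or SimulationConfig()
    model = CompiledModel(net, cfg, clamps)
    free_input = model.is_input.copy()
    free_input[model.clamp_idx] = False
    if np.any(free_input):
        raise InputNodeError(
            "clamp input nodes before fixed-point search: "
            f"{[model.names[i] for i in np.where(free_input)[0]]}"
        )
    free_idx = np.where(model.free)[0]
    base = model.apply_clamps(np.zeros(model.n_nodes))

    def g(xf):
        x = base.copy()
        x[free_idx] = np.clip(xf, 0.0, 1.0)
        return model.rhs(0.0, x)[free_idx]

    found: list[np.ndarray] = []
    levels = np.linspace(0.0, 1.0, grid)
    for start in iproduct(levels, repeat=len(free_idx)):
        sol, info, ier, _ = fsolve(g, np.array(start), full_output=True)
        if ier != 1 or np.max(np.abs(info["fvec"])) > tol:
            continue
        sol = np.clip(sol, 0.0, 1.0)
        if np.max(np.abs(g(sol))) > 1e-7:  # clipped away from a true root
            continue
        if all(np.max(np.abs(sol - f)) > dedupe_tol for f in found):
            found.append(sol)
    results = []
    for xf in sorted(found, key=lambda a: tuple(np.round(a, 8))):
        eps = 1e-6
        jac = np.zeros((len(free_idx), len(free_idx)))
        for j in range(len(free_idx)):
            step = np.zeros(len(free_idx))
            step[j] = eps
            jac[:, j] = (g(xf + step) - g(xf - step)) / (2 * eps)
        stable = bool(np.all(np.real(np.linalg.eigvals(jac)) < 0))
        state = base.copy()
        state[free_idx] = xf
        results.append({"state": state, "stable": stable})
    return results
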