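"""Dimensionless ODE model of the yeast MAL regulon.

The regulon couples positive and negative transcriptional feedback around
intracellular palatinose ``p``: the Mal11 transporter ``T`` imports
palatinose (positive feedback, Hill activation of *MAL11* with EC50
``K_T``), while the isomaltases ``I`` (Ima1 + Ima5 pooled) cleave it
(negative feedback, Michaelis–Menten in ``p``, Hill activation of *IMA*
with EC50 ``K_I``).  Time is measured in units of the isomaltase turnover
rate and concentrations in units of ``K_I``, so ``K_I == 1`` throughout and
the repression constraint reads ``K_T > 1``: isomaltases are induced at
lower palatinose than the transporter.

State equations (dimensionless)::

    dp/dt = v_T * T - I * p / (K_M + p)
    dI/dt = u_I_max * p^n / (1 + p^n) - I
    dT/dt = b_T + u_T_max * p^n / (K_T^n + p^n) - d_T * T

The regulon is ON when steady-state ``p / K_T > 1`` — enough inducer to
drive *MAL11* expression and sustain the positive feedback.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "RegulonParams",
    "RegulonState",
    "SteadyState",
    "SteadyStateSet",
    "Classification",
    "Trajectory",
    "DEFAULT_PARAMS",
    "regulon_rhs",
    "regulon_jacobian",
    "steady_I",
    "steady_T",
    "reduced_steady_residual",
    "minimal_ratio",
    "find_steady_states",
    "classify_regulon",
    "simulate_regulon",
]

# Labels for the steady-state structure of the regulon.
OFF = "OFF"
ON = "ON"
BISTABLE = "BISTABLE"
UNBOUNDED = "UNBOUNDED"

_NONHYPERBOLIC_TOL = 1e-8
_ROOT_MERGE_REL = 1e-6


@dataclass(frozen=True)
class RegulonParams:
    """Dimensionless parameters of the MAL regulon model.

    Parameters
    ----------
    v_T : float
        Palatinose import rate per unit transporter; increases with the
        extracellular palatinose concentration.
    u_I_max : float
        Maximal isomaltase (*IMA1* + *IMA5*) expression rate.
    u_T_max : float
        Maximal regulated *MAL11* expression rate.
    b_T : float
        Basal *MAL11* expression rate (may be zero).
    d_T : float
        Mal11 degradation rate.
    K_T : float
        EC50 of *MAL11* expression, in units of ``K_I``; must exceed 1 so
        that isomaltases are induced before the transporter.
    K_M : float
        Michaelis constant of isomaltase cleavage, in units of ``K_I``.
    n : int
        Hill number shared by both expression functions (1–8).
    K_I : float
        EC50 of *IMA* expression; fixed to 1 by the nondimensionalisation.
    """

    v_T: float = 1.0
    u_I_max: float = 4.0
    u_T_max: float = 3.0
    b_T: float = 0.05
    d_T: float = 1.0
    K_T: float = 1.2
    K_M: float = 1.0
    n: int = 3
    K_I: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.K_I != 1.0:
            raise ValueError("K_I is fixed to 1 by the nondimensionalisation")
        for name in ("u_I_max", "u_T_max", "d_T", "K_T", "K_M"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")
        if not np.isfinite(self.v_T) or self.v_T < 0:
            raise ValueError("v_T must be non-negative and finite")
        if not np.isfinite(self.b_T) or self.b_T < 0:
            raise ValueError("b_T must be non-negative and finite")
        if self.K_T <= self.K_I:
            raise ValueError("repression constraint violated: require K_T > K_I (= 1)")
        if int(self.n) != self.n or not (1 <= self.n <= 8):
            raise ValueError("Hill number n must be an integer in 1..8")

    def replace(self, **changes) -> "RegulonParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def ratio(self) -> float:
        """The bifurcation ratio u_I_max / v_T (inf when v_T == 0)."""
        return np.inf if self.v_T == 0 else self.u_I_max / self.v_T


#: Frozen default parameter set used throughout (regression-tested topology).
DEFAULT_PARAMS = RegulonParams()


@dataclass(frozen=True)
class RegulonState:
    """State of the regulon: intracellular palatinose ``p``, pooled
    isomaltase ``I`` and Mal11 transporter ``T`` (all non-negative,
    dimensionless)."""

    p: float
    I: float
    T: float

    def __post_init__(self) -> None:
        for name in ("p", "I", "T"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be non-negative and finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.I, self.T], dtype=float)


@dataclass(frozen=True)
class SteadyState:
    state: RegulonState
    stable: bool
    #: leading eigenvalue real part of the Jacobian (None if assessed via
    #: the 1-D reduction because the full Jacobian was non-hyperbolic)
    leading_eigenvalue: float | None = None


@dataclass(frozen=True)
class SteadyStateSet:
    """Steady states of one parameter set, sorted by ``p`` ascending, with
    an overall label OFF / ON / BISTABLE / UNBOUNDED."""

    states: tuple[SteadyState, ...]
    label: str

    @property
    def stable_states(self) -> tuple[SteadyState, ...]:
        return tuple(s for s in self.states if s.stable)

    @property
    def low(self) -> SteadyState | None:
        st = self.stable_states
        return st[0] if st else None

    @property
    def high(self) -> SteadyState | None:
        st = self.stable_states
        return st[-1] if st else None


@dataclass(frozen=True)
class Classification:
    """Outcome of classifying one parameter set.

    ``label`` is the structural label (OFF / ON / BISTABLE / UNBOUNDED);
    ``attained`` is the branch actually reached given the history
    convention (low branch when approaching from low palatinose), and
    ``p_over_KT`` the steady-state ``p/K_T`` on that branch.
    """

    label: str
    attained: str | None
    p_over_KT: float


def _hill(p, n):
    pn = np.power(p, n)
    return pn / (1.0 + pn)


def _hill_K(p, K, n):
    pn = np.power(p, n)
    return pn / (np.power(K, n) + pn)


def regulon_rhs(state: RegulonState | Sequence[float], params: RegulonParams) -> tuple[float, float, float]:
    """Right-hand side (dp/dt, dI/dt, dT/dt) of the regulon ODEs."""
    if isinstance(state, RegulonState):
        p, I, T = state.p, state.I, state.T
    else:
        p, I, T = (float(x) for x in state)
        if min(p, I, T) < 0:
            raise ValueError("state components must be non-negative")
    dp = params.v_T * T - I * p / (params.K_M + p)
    dI = params.u_I_max * _hill(p, params.n) - I
    dT = params.b_T + params.u_T_max * _hill_K(p, params.K_T, params.n) - params.d_T * T
    return (dp, dI, dT)


def regulon_jacobian(state: RegulonState | Sequence[float], params: RegulonParams) -> np.ndarray:
    """Analytic Jacobian of :func:`regulon_rhs` at ``state``."""
    if isinstance(state, RegulonState):
        p, I, T = state.p, state.I, state.T
    else:
        p, I, T = (float(x) for x in state)
    n, KM, KT = params.n, params.K_M, params.K_T
    pn = p**n
    # d/dp of p^n/(1+p^n) and of p^n/(KT^n+p^n)
    dh = n * p ** (n - 1) / (1.0 + pn) ** 2
    dg = n * KT**n * p ** (n - 1) / (KT**n + pn) ** 2
    return np.array(
        [
            [-I * KM / (KM + p) ** 2, -p / (KM + p), params.v_T],
            [params.u_I_max * dh, -1.0, 0.0],
            [params.u_T_max * dg, 0.0, -params.d_T],
        ]
    )


def steady_I(p, params: RegulonParams):
    """Quasi-steady isomaltase level I*(p)."""
    return params.u_I_max * _hill(p, params.n)


def steady_T(p, params: RegulonParams):
    """Quasi-steady transporter level T*(p)."""
    return (params.b_T + params.u_T_max * _hill_K(p, params.K_T, params.n)) / params.d_T


def reduced_steady_residual(p, params: RegulonParams):
    """1-D steady-state residual f(p) = v_T T*(p) − I*(p) p/(K_M+p).

    Because ``I`` and ``T`` relax linearly to their quasi-steady values,
    the full system is at steady state exactly where ``f(p) = 0``.
    Vectorised over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("p must be non-negative")
    out = params.v_T * steady_T(p, params) - steady_I(p, params) * p / (params.K_M + p)
    return float(out) if out.ndim == 0 else out


def minimal_ratio(params: RegulonParams) -> float:
    """Minimal u_I_max/v_T preventing steady states at infinite ``p``.

    As ``p`` grows, both Hill functions and the Michaelis–Menten term
    saturate, so f(p) → v_T (b_T + u_T_max)/d_T − u_I_max.  Import outruns
    cleavage for all large ``p`` — palatinose accumulates without bound —
    exactly when u_I_max/v_T < (b_T + u_T_max)/d_T.
    """
    return (params.b_T + params.u_T_max) / params.d_T


def _root_grid(params: RegulonParams, n_grid: int) -> np.ndarray:
    # largest possible root is where saturated import balances cleavage:
    # v_T (b_T+u_T_max)/d_T = u_I_max * p/(K_M+p)  =>  p = K_M q/(1-q)
    q = minimal_ratio(params) / params.ratio if np.isfinite(params.ratio) else 0.0
    p_balance = params.K_M * q / (1.0 - q) if 0 < q < 1 else params.K_M
    p_max = 10.0 * max(params.K_T, p_balance, 1.0)
    return np.concatenate([[0.0], np.geomspace(1e-9 * p_max, p_max, n_grid - 1)])


def _is_stable(p_root: float, params: RegulonParams) -> tuple[bool, float | None]:
    st = (float(p_root), float(steady_I(p_root, params)), float(steady_T(p_root, params)))
    lead = float(np.max(np.linalg.eigvals(regulon_jacobian(st, params)).real))
    if abs(lead) >= _NONHYPERBOLIC_TOL:
        return lead < 0, lead
    # non-hyperbolic Jacobian: fall back to the direction of the 1-D
    # residual through the root (I and T relax with strictly negative rates)
    eps = max(1e-9, 1e-6 * max(p_root, 1.0))
    lo = reduced_steady_residual(max(p_root - eps, 0.0), params)
    hi = reduced_steady_residual(p_root + eps, params)
    return bool(lo >= 0 >= hi), None


def find_steady_states(params: RegulonParams, n_grid: int = 10_000) -> SteadyStateSet:
    """All steady states via dense log-grid bracketing of the 1-D residual.

    Sign changes of :func:`reduced_steady_residual` on a log-spaced grid
    (plus the origin) are refined by Brent's method; stability comes from
    the full Jacobian's leading eigenvalue.  When u_I_max/v_T is at or
    below the boundedness threshold the set is labelled UNBOUNDED with an
    empty state list.
    """
    if params.ratio <= minimal_ratio(params) * (1.0 + 1e-12):
        return SteadyStateSet(states=(), label=UNBOUNDED)
    grid = _root_grid(params, n_grid)
    f = reduced_steady_residual(grid, params)
    roots: list[float] = []
    if abs(f[0]) < 1e-13:  # p = 0 is a steady state iff v_T b_T = 0
        roots.append(0.0)
    sgn = np.sign(f)
    (idx,) = np.nonzero((sgn[:-1] * sgn[1:] < 0))
    for i in idx:
        try:
            r = brentq(
                lambda p: reduced_steady_residual(p, params),
                grid[i],
                grid[i + 1],
                xtol=1e-14,
                rtol=1e-14,
                maxiter=200,
            )
        except RuntimeError as exc:  # pragma: no cover - brentq converges on sign changes
            raise RuntimeError(
                f"root refinement failed in bracket [{grid[i]:g}, {grid[i + 1]:g}]"
            ) from exc
        roots.append(float(r))
    # merge near-degenerate roots
    merged: list[float] = []
    tol = _ROOT_MERGE_REL * grid[-1]
    for r in sorted(roots):
        if merged and r - merged[-1] < tol:
            continue
        merged.append(r)
    states = []
    for r in merged:
        stable, lead = _is_stable(r, params)
        states.append(
            SteadyState(
                state=RegulonState(p=r, I=float(steady_I(r, params)), T=float(steady_T(r, params))),
                stable=stable,
                leading_eigenvalue=lead,
            )
        )
    stable_states = [s for s in states if s.stable]
    if len(stable_states) >= 2:
        label = BISTABLE
    elif stable_states and stable_states[0].state.p / params.K_T > 1.0:
        label = ON
    else:
        label = OFF
    return SteadyStateSet(states=tuple(states), label=label)


def classify_regulon(
    params: RegulonParams, from_low: bool = True, n_grid: int = 10_000
) -> Classification:
    """Classify one parameter set as OFF / ON / BISTABLE / UNBOUNDED.

    ``from_low`` selects the branch reached by cells approaching from low
    intracellular palatinose (the biological convention: without prior
    induction, p starts low).  For a bistable set this is the low branch,
    so such cells report OFF even though an ON state coexists.
    """
    sset = find_steady_states(params, n_grid=n_grid)
    if sset.label == UNBOUNDED:
        return Classification(label=UNBOUNDED, attained=None, p_over_KT=np.inf)
    chosen = sset.low if from_low else sset.high
    if chosen is None:  # no stable state found (non-generic)
        return Classification(label=sset.label, attained=None, p_over_KT=np.nan)
    ratio = chosen.state.p / params.K_T
    attained = ON if ratio > 1.0 else OFF
    return Classification(label=sset.label, attained=attained, p_over_KT=ratio)


@dataclass(frozen=True)
class Trajectory:
    """Time course of the regulon state; ``diverged`` flags runaway
    palatinose accumulation (p exceeded the divergence bound)."""

    t: np.ndarray
    p: np.ndarray
    I: np.ndarray
    T: np.ndarray
    diverged: bool

    @property
    def end(self) -> RegulonState:
        return RegulonState(p=float(self.p[-1]), I=float(self.I[-1]), T=float(self.T[-1]))


def simulate_regulon(
    params: RegulonParams,
    init: RegulonState,
    horizon: float,
    n_points: int = 500,
    divergence_factor: float = 1e3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the regulon ODEs from ``init`` over ``[0, horizon]``.

    Integration stops early, with ``diverged=True``, once ``p`` exceeds
    ``divergence_factor * K_T`` — the signature of the unbounded regime.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    bound = divergence_factor * params.K_T

    def rhs(t, y):
        return regulon_rhs(np.maximum(y, 0.0), params)

    def jac(t, y):
        return regulon_jacobian(np.maximum(y, 0.0), params)

    def escape(t, y):
        return y[0] - bound

    escape.terminal = True
    escape.direction = 1.0

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        init.as_array(),
        method="LSODA",
        jac=jac,
        t_eval=np.linspace(0.0, float(horizon), n_points),
        events=escape,
        rtol=rtol,
        atol=atol,
    )
    if sol.status == -1:  # pragma: no cover - LSODA is robust on this system
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    diverged = sol.status == 1
    y = np.maximum(sol.y, 0.0)
    return Trajectory(t=sol.t, p=y[0], I=y[1], T=y[2], diverged=diverged)
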