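"""Two-parameter bifurcation analysis of the MAL regulon.

The plane scanned is (``K_T``, ``u_I_max / v_T``): repression strength of
*MAL11* expression against the ratio of maximal isomaltase expression to
palatinose import.  Three regions arise — ON (steady-state ``p/K_T > 1``),
OFF, and a bistable band where a low (OFF) and a high (ON) state coexist.
Cells entering the bistable band from low palatinose stay on the low
branch: hysteresis keeps them OFF until the band's lower edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regulon import (
    BISTABLE,
    OFF,
    ON,
    Classification,
    RegulonParams,
    RegulonState,
    classify_regulon,
    minimal_ratio,
    simulate_regulon,
    steady_I,
    steady_T,
)

__all__ = [
    "BifurcationGrid",
    "bifurcation_scan",
    "HysteresisResult",
    "hysteresis_sweep",
    "critical_KT_for_escape",
]


@dataclass(frozen=True)
class BifurcationGrid:
    """Region labels and branch values over the (K_T, u_I_max/v_T) plane.

    Matrices are indexed ``[i_K_T, j_ratio]``.  ``p_over_KT_high`` is NaN
    wherever no ON-branch state exists (pure OFF cells); ``p_over_KT_low``
    is the low-branch value everywhere.
    """

    K_T_values: np.ndarray
    ratio_values: np.ndarray
    labels: np.ndarray
    p_over_KT_low: np.ndarray
    p_over_KT_high: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(
            np.arange(len(self.K_T_values)), np.arange(len(self.ratio_values)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "K_T": self.K_T_values[ii.ravel()],
                "ratio": self.ratio_values[jj.ravel()],
                "label": self.labels.ravel(),
                "p_over_KT_low": self.p_over_KT_low.ravel(),
                "p_over_KT_high": self.p_over_KT_high.ravel(),
            }
        )

    @property
    def region_labels(self) -> set[str]:
        return set(np.unique(self.labels))


def _column_roots(p_grid, A, B, u_I_values, params, K_T):
    """Roots of f(p) = A(p) - u_I B(p) for every u_I in one K_T column.

    Sign-change brackets for all cells are refined together by vectorised
    bisection on the exact residual; returns (cell_index, root) arrays
    sorted by cell then by p."""
    F = A[:, None] - B[:, None] * u_I_values[None, :]
    sgn = np.sign(F)
    rows, cols = np.nonzero(sgn[:-1, :] * sgn[1:, :] < 0)
    lo = p_grid[rows]
    hi = p_grid[rows + 1]
    uI = u_I_values[cols]
    flo = _residual_vec(lo, uI, params, K_T)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = _residual_vec(mid, uI, params, K_T)
        same = np.sign(fm) == np.sign(flo)
        lo = np.where(same, mid, lo)
        flo = np.where(same, fm, flo)
        hi = np.where(same, hi, mid)
    roots = 0.5 * (lo + hi)
    if abs(A[0]) < 1e-13:  # p = 0 is a root in every cell (v_T b_T = 0)
        cols = np.concatenate([np.arange(len(u_I_values)), cols])
        roots = np.concatenate([np.zeros(len(u_I_values)), roots])
        rows = np.concatenate([np.full(len(u_I_values), -1), rows])
    order = np.lexsort((rows, cols))
    return cols[order], roots[order]


def _residual_vec(p, u_I, params: RegulonParams, K_T):
    n, KM = params.n, params.K_M
    pn = np.power(p, n)
    T = (params.b_T + params.u_T_max * pn / (K_T**n + pn)) / params.d_T
    I = u_I * pn / (1.0 + pn)
    return params.v_T * T - I * p / (KM + p)


def _stability_rh(p, u_I, params: RegulonParams, K_T):
    """Routh–Hurwitz stability of steady states at palatinose levels ``p``
    (vectorised).  Equivalent to the sign of the Jacobian's leading
    eigenvalue for this 3x3 system."""
    p = np.asarray(p, dtype=float)
    n, KM, dT = params.n, params.K_M, params.d_T
    pn = np.power(p, n)
    I = u_I * pn / (1.0 + pn)
    a = -I * KM / (KM + p) ** 2
    b = -p / (KM + p)
    c = u_I * n * np.power(p, n - 1) / (1.0 + pn) ** 2
    d = params.u_T_max * n * K_T**n * np.power(p, n - 1) / (K_T**n + pn) ** 2
    v = params.v_T
    c2 = 1.0 + dT - a
    c1 = -a - b * c - a * dT - v * d + dT
    c0 = -(a * dT + b * c * dT + v * d)
    return (c2 > 0) & (c0 > 0) & (c2 * c1 > c0)


def bifurcation_scan(
    base: RegulonParams,
    K_T_values: np.ndarray,
    ratio_values: np.ndarray,
    n_grid: int = 4000,
) -> BifurcationGrid:
    """Classify every cell of the (K_T, u_I_max/v_T) grid.

    The residual is affine in ``u_I_max`` at fixed ``K_T``, so each K_T
    column shares one evaluation of the import and cleavage profiles; cell
    roots are then refined by bisection and labelled exactly as
    :func:`~maldiauxie.regulon.classify_regulon` would label them.
    """
    K_T_values = np.asarray(K_T_values, dtype=float)
    ratio_values = np.asarray(ratio_values, dtype=float)
    for name, ax in (("K_T_values", K_T_values), ("ratio_values", ratio_values)):
        if ax.ndim != 1 or len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} must be 1-D and strictly increasing")
    if np.any(K_T_values <= base.K_I):
        raise ValueError("K_T axis must satisfy K_T > K_I (= 1)")
    rmin = minimal_ratio(base)
    if ratio_values[0] <= rmin:
        raise ValueError(
            f"ratio axis must lie above the boundedness threshold {rmin:g}"
        )
    if base.v_T <= 0:
        raise ValueError("scan requires v_T > 0")

    nK, nR = len(K_T_values), len(ratio_values)
    labels = np.empty((nK, nR), dtype=object)
    low = np.full((nK, nR), np.nan)
    high = np.full((nK, nR), np.nan)

    # p-grid spanning up to the largest possible balance point on the axes
    q = rmin / ratio_values[0]
    p_balance = base.K_M * q / (1.0 - q) if 0 < q < 1 else base.K_M
    p_max = 10.0 * max(K_T_values[-1], p_balance, 1.0)
    p_grid = np.concatenate([[0.0], np.geomspace(1e-9 * p_max, p_max, n_grid - 1)])

    u_I_values = ratio_values * base.v_T
    for i, K_T in enumerate(K_T_values):
        pn = np.power(p_grid, base.n)
        A = base.v_T * (base.b_T + base.u_T_max * pn / (K_T**base.n + pn)) / base.d_T
        B = (pn / (1.0 + pn)) * p_grid / (base.K_M + p_grid)
        cols, roots = _column_roots(p_grid, A, B, u_I_values, base, K_T)
        stable = _stability_rh(roots, u_I_values[cols], base, K_T)
        starts = np.searchsorted(cols, np.arange(nR))
        ends = np.searchsorted(cols, np.arange(nR) + 1)
        for j in range(len(ratio_values)):
            sl = slice(starts[j], ends[j])
            srts = roots[sl][stable[sl]]
            if srts.size >= 2:
                labels[i, j] = BISTABLE
            elif srts.size == 1 and srts[0] / K_T > 1.0:
                labels[i, j] = ON
            else:
                labels[i, j] = OFF
            if srts.size:
                low[i, j] = srts[0] / K_T
                if srts[-1] / K_T > 1.0:
                    high[i, j] = srts[-1] / K_T
    return BifurcationGrid(
        K_T_values=K_T_values,
        ratio_values=ratio_values,
        labels=labels,
        p_over_KT_low=low,
        p_over_KT_high=high,
    )


@dataclass(frozen=True)
class HysteresisResult:
    """Forward/backward transition points of a carried-state K_T sweep.

    ``forward_off_KT`` is the K_T at which the state first drops OFF while
    K_T increases; ``backward_on_KT`` the K_T at which it first jumps ON
    while K_T decreases.  Both are None when the path never crosses the
    corresponding boundary ("no transition").
    """

    K_T_path: np.ndarray
    forward_on: np.ndarray
    backward_on: np.ndarray
    forward_off_KT: float | None
    backward_on_KT: float | None

    @property
    def gap(self) -> float | None:
        if self.forward_off_KT is None or self.backward_on_KT is None:
            return None
        return self.forward_off_KT - self.backward_on_KT


def _relax(params: RegulonParams, state: RegulonState, horizon: float) -> RegulonState:
    return simulate_regulon(params, state, horizon=horizon, n_points=2).end


def hysteresis_sweep(
    base: RegulonParams,
    K_T_path: np.ndarray,
    horizon_per_step: float = 400.0,
) -> HysteresisResult:
    """Sweep K_T forward then backward, carrying the state between steps.

    The forward sweep starts from the uninduced state (p=0, I=0,
    T=b_T/d_T) relaxed at the first K_T; each subsequent step relaxes the
    previous endpoint under the new K_T.  The backward sweep retraces the
    path from its far end, seeded by the forward sweep's final state.
    Through a bistable band the forward OFF-transition occurs at strictly
    larger K_T than the backward ON-transition.
    """
    K_T_path = np.asarray(K_T_path, dtype=float)
    if K_T_path.ndim != 1 or len(K_T_path) < 2 or np.any(np.diff(K_T_path) <= 0):
        raise ValueError("K_T_path must be 1-D and strictly increasing")
    if np.any(K_T_path <= base.K_I):
        raise ValueError("K_T path must satisfy K_T > K_I (= 1)")

    def sweep(path, init_state):
        on = np.zeros(len(path), dtype=bool)
        state = init_state
        for k, K_T in enumerate(path):
            params = base.replace(K_T=float(K_T))
            state = _relax(params, state, horizon_per_step)
            on[k] = state.p / K_T > 1.0
        return on, state

    init = RegulonState(p=0.0, I=0.0, T=base.b_T / base.d_T)
    init = _relax(base.replace(K_T=float(K_T_path[0])), init, horizon_per_step)
    forward_on, end_state = sweep(K_T_path, init)
    backward_on_rev, _ = sweep(K_T_path[::-1], end_state)
    backward_on = backward_on_rev[::-1]

    forward_off_KT = None
    for k in range(1, len(K_T_path)):
        if forward_on[k - 1] and not forward_on[k]:
            forward_off_KT = float(K_T_path[k])
            break
    # scan the backward sweep in its traversal order (decreasing K_T)
    backward_on_KT = None
    for k in range(1, len(K_T_path)):
        prev_on = backward_on_rev[k - 1]
        now_on = backward_on_rev[k]
        if not prev_on and now_on:
            backward_on_KT = float(K_T_path[::-1][k])
            break
    return HysteresisResult(
        K_T_path=K_T_path,
        forward_on=forward_on,
        backward_on=backward_on,
        forward_off_KT=forward_off_KT,
        backward_on_KT=backward_on_KT,
    )


def _on_from_low_exists(
    base: RegulonParams, K_T: float, ratio_values: np.ndarray, p_grid_size: int = 3000
) -> bool:
    """True iff some ratio in the sweep is ON from the low branch at K_T.

    The low branch is ON exactly when the residual stays positive on
    [0, K_T] (the first root then lies beyond K_T), i.e. when
    u_I_max < min_{0<p<=K_T} A(p)/B(p)."""
    p = np.geomspace(1e-9 * K_T, K_T, p_grid_size)
    pn = np.power(p, base.n)
    A = base.v_T * (base.b_T + base.u_T_max * pn / (K_T**base.n + pn)) / base.d_T
    B = (pn / (1.0 + pn)) * p / (base.K_M + p)
    u_I_crit = float(np.min(A / B))
    u_I_sweep = ratio_values * base.v_T
    return bool(np.any(u_I_sweep < u_I_crit))


def critical_KT_for_escape(
    base: RegulonParams,
    ratio_bounds: tuple[float, float],
    K_T_bounds: tuple[float, float] = (1.05, 5.0),
    n_ratio: int = 400,
    tol: float = 1e-3,
) -> float | None:
    """Largest K_T at which lowering u_I_max/v_T can still switch cells ON.

    A mutant with reduced isomaltase expression moves vertically down the
    bifurcation plane; this returns the supremum of K_T for which that
    vertical move, restricted to ``ratio_bounds``, reaches the ON region
    from the low branch.  Returns None when no ratio in bounds is ON even
    at the smallest admissible K_T.  Computed by bisection on K_T with an
    inner sweep over a log-spaced ratio grid.
    """
    rmin = minimal_ratio(base)
    if ratio_bounds[0] <= rmin:
        raise ValueError(f"ratio bounds must lie above the boundedness threshold {rmin:g}")
    if base.v_T <= 0:
        raise ValueError("escape analysis requires v_T > 0")
    ratios = np.geomspace(ratio_bounds[0], ratio_bounds[1], n_ratio)
    lo, hi = float(K_T_bounds[0]), float(K_T_bounds[1])
    if lo <= base.K_I:
        raise ValueError("K_T bounds must satisfy K_T > K_I (= 1)")
    if not _on_from_low_exists(base, lo, ratios):
        return None
    if _on_from_low_exists(base, hi, ratios):
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _on_from_low_exists(base, mid, ratios):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
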