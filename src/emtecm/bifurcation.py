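"""Steady-state branches, folds, and bifurcation families of the circuit.

The primary tracer is pseudo-arclength continuation of the steady-state
equations f(x, I) = 0 in the extended (state, signal) space: a predictor
step along the branch tangent followed by a Newton corrector constrained
to the hyperplane orthogonal to the tangent, with adaptive step size.
Saddle-node (fold) points are detected by sign changes of the tangent's
I-component and refined by Newton on the standard extended fold system

    f(x, I) = 0,   J(x, I) v = 0,   ||v||^2 = 1 .

A brute-force dense-I multistart sweep (`sweep_steady_states`) is kept
as an independent oracle for branch topology.

All continuation is done in scaled variables (each component divided by
its characteristic concentration) so the corrector is well conditioned
despite the 1e3..1e6 spread of molecule numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import root

from .circuit import (
    STATE_NAMES,
    CircuitParams,
    CircuitState,
    _characteristic_scale,
    classify_state,
    find_steady_states,
    rhs,
)

__all__ = [
    "BifurcationBranch",
    "trace_branch",
    "trace_diagram",
    "fold_points",
    "refine_fold",
    "sweep_steady_states",
    "bifurcation_family",
    "family_to_frame",
]

_I_SCALE = 1e4


@dataclass
class BifurcationBranch:
    """One continuation branch: states along the curve plus fold points."""

    I: np.ndarray                  # (n,)
    states: np.ndarray             # (n, 7), molecule units
    stable: np.ndarray             # (n,) bool
    folds: list[tuple[float, np.ndarray]] = field(default_factory=list)
    truncated: bool = False
    K_LE: Optional[float] = None

    def z_range(self) -> tuple[float, float]:
        return float(self.states[:, 2].min()), float(self.states[:, 2].max())


def _scaled_system(p: CircuitParams):
    scale = _characteristic_scale(p)

    def f(y, iy):
        return rhs(np.maximum(y, 0.0) * scale, p, iy * _I_SCALE) / scale

    def jac(y, iy, eps=1e-7):
        n = y.size
        J = np.zeros((n, n + 1))
        for m in range(n):
            h = eps * max(abs(y[m]), 1e-3)
            yp = y.copy(); yp[m] += h
            ym = y.copy(); ym[m] -= h
            J[:, m] = (f(yp, iy) - f(ym, iy)) / (2 * h)
        h = eps * max(abs(iy), 1e-3)
        J[:, n] = (f(y, iy + h) - f(y, iy - h)) / (2 * h)
        return J

    return f, jac, scale


def _tangent(J_ext: np.ndarray, prev: Optional[np.ndarray]) -> np.ndarray:
    """Unit null vector of the (n x n+1) extended Jacobian."""
    _u, _s, vt = np.linalg.svd(J_ext)
    t = vt[-1]
    t /= np.linalg.norm(t)
    if prev is not None and t @ prev < 0:
        t = -t
    return t


def _is_stable(x: np.ndarray, p: CircuitParams, I: float, eps: float = -1e-9) -> bool:
    from .circuit import jacobian

    eig = np.linalg.eigvals(jacobian(x, p, I))
    return bool(np.max(eig.real) < eps)


def trace_branch(
    p: CircuitParams,
    x0: np.ndarray,
    I0: float,
    I_range: tuple[float, float],
    direction: float = 1.0,
    h0: float = 0.05,
    h_min: float = 1e-6,
    h_max: float = 0.1,
    max_steps: int = 3000,
    tol: float = 1e-10,
) -> BifurcationBranch:
    """Pseudo-arclength continuation of one branch from (x0, I0).

    Follows the branch in the given initial I direction, around folds,
    until I leaves ``I_range`` or the step limit is hit.
    """
    f, jac, scale = _scaled_system(p)
    lo, hi = I_range[0] / _I_SCALE, I_range[1] / _I_SCALE

    y = x0 / scale
    iy = I0 / _I_SCALE
    # polish the starting point
    sol = root(lambda v: f(v, iy), y, method="hybr", options={"xtol": 1e-13})
    if sol.success:
        y = sol.x

    prev_t = np.zeros(y.size + 1)
    prev_t[-1] = np.sign(direction)
    t = _tangent(jac(y, iy), prev_t)

    ys = [y.copy()]
    iys = [iy]
    tangents = [t.copy()]
    h = h0
    truncated = False
    for _ in range(max_steps):
        pred = np.concatenate([y, [iy]]) + h * t

        def corrector(v):
            return np.concatenate([
                f(v[:-1], v[-1]),
                [t @ (v - pred)],
            ])

        sol = root(corrector, pred, method="hybr", options={"xtol": 1e-12})
        ok = sol.success and np.linalg.norm(f(sol.x[:-1], sol.x[-1])) < 1e-8
        if not ok:
            h *= 0.5
            if h < h_min:
                truncated = True
                break
            continue
        y_new, iy_new = sol.x[:-1], sol.x[-1]
        t_new = _tangent(jac(y_new, iy_new), t)
        y, iy, t = y_new, iy_new, t_new
        ys.append(y.copy())
        iys.append(iy)
        tangents.append(t.copy())
        h = min(h * 1.3, h_max)
        if iy > hi + 0.05 * (hi - lo) or iy < lo - 0.05 * (hi - lo):
            break

    states = np.array(ys) * scale
    I_vals = np.array(iys) * _I_SCALE
    stable = np.array([_is_stable(s, p, Iv) for s, Iv in zip(states, I_vals)])

    folds = []
    tg = np.array(tangents)
    # a fold flips the tangent's I-component; also catch local extrema of
    # I along the polyline in case a step straddles a close fold pair
    cand = set(np.flatnonzero(np.sign(tg[:-1, -1]) * np.sign(tg[1:, -1]) < 0))
    dI = np.diff(I_vals)
    cand.update(np.flatnonzero(np.sign(dI[:-1]) * np.sign(dI[1:]) < 0) + 1)
    # a saddle-node also flips stability along the branch
    flips = np.flatnonzero(stable[:-1] != stable[1:])
    cand.update(flips)
    cand.update(flips + 1)
    # large state jumps flag corrector hops between close branches;
    # their endpoints often sit next to a fold
    rel = np.abs(np.diff(states, axis=0)) / scale
    jumps = np.flatnonzero(np.sqrt((rel**2).sum(axis=1)) > 0.15)
    cand.update(jumps)
    cand.update(jumps + 1)
    expanded = set()
    for idx in cand:
        expanded.update((idx - 1, idx, idx + 1))
    for idx in sorted(expanded):
        if idx < 0 or idx >= len(I_vals):
            continue
        fp = refine_fold(p, states[idx], I_vals[idx])
        if fp is not None and not any(abs(fp[0] - f[0]) < 1e-3 for f in folds):
            folds.append(fp)

    return BifurcationBranch(I=I_vals, states=states, stable=stable,
                             folds=folds, truncated=truncated)


def refine_fold(
    p: CircuitParams,
    x_guess: np.ndarray,
    I_guess: float,
) -> Optional[tuple[float, np.ndarray]]:
    """Newton refinement of a saddle-node on the extended fold system."""
    f, jac, scale = _scaled_system(p)
    n = x_guess.size
    y0 = x_guess / scale
    iy0 = I_guess / _I_SCALE
    J = jac(y0, iy0)[:, :n]
    _u, _s, vt = np.linalg.svd(J)
    v0 = vt[-1]

    def F(w):
        y, iy, v = w[:n], w[n], w[n + 1:]
        Jy = jac(y, iy)[:, :n]
        return np.concatenate([f(y, iy), Jy @ v, [v @ v - 1.0]])

    sol = root(F, np.concatenate([y0, [iy0], v0]), method="hybr",
               options={"xtol": 1e-12, "maxfev": 8000})
    if not sol.success:
        return None
    y, iy = sol.x[:n], sol.x[n]
    if np.linalg.norm(f(y, iy)) > 1e-7:
        return None
    return float(iy * _I_SCALE), y * scale


def trace_diagram(
    p: CircuitParams,
    I_range: tuple[float, float],
    n_seed: int = 7,
) -> list[BifurcationBranch]:
    """All branches over an I window.

    Branches are seeded from multistart steady states at several I
    values and traced in both directions; duplicates (branches passing
    within tolerance of an already-covered point) are merged away.
    """
    lo, hi = I_range
    scale = _characteristic_scale(p)
    branches: list[BifurcationBranch] = []

    def covered(x, I):
        for br in branches:
            sel = np.abs(br.I - I) < 0.02 * (hi - lo) + 1e-9
            if np.any(sel):
                d = np.abs(br.states[sel] - x) / (scale + np.abs(x))
                if np.any(np.all(d < 1e-3, axis=1)):
                    return True
        return False

    for I_seed in np.linspace(lo, hi, n_seed):
        for st, _stab in find_steady_states(p, I_seed):
            x = st.to_array()
            if covered(x, I_seed):
                continue
            br_up = trace_branch(p, x, I_seed, I_range, direction=+1.0)
            br_dn = trace_branch(p, x, I_seed, I_range, direction=-1.0)
            merged = BifurcationBranch(
                I=np.concatenate([br_dn.I[::-1], br_up.I[1:]]),
                states=np.vstack([br_dn.states[::-1], br_up.states[1:]]),
                stable=np.concatenate([br_dn.stable[::-1], br_up.stable[1:]]),
                folds=br_dn.folds + br_up.folds,
                truncated=br_dn.truncated or br_up.truncated,
            )
            branches.append(merged)
    return branches


def fold_points(branches: Sequence[BifurcationBranch], dedup: float = 1.0) -> np.ndarray:
    """Sorted unique fold-point I coordinates across branches."""
    vals = sorted(I for br in branches for (I, _x) in br.folds)
    out: list[float] = []
    for v in vals:
        if not out or abs(v - out[-1]) > dedup:
            out.append(v)
    return np.array(out)


def sweep_steady_states(
    p: CircuitParams,
    I_values: Sequence[float],
) -> pd.DataFrame:
    """Dense multistart sweep: independent oracle for branch topology."""
    rows = []
    for I in I_values:
        for st, stab in find_steady_states(p, I):
            row = {"I": I, "stable": stab, "phenotype": classify_state(st, p)}
            row.update(dict(zip(STATE_NAMES, st.to_array())))
            rows.append(row)
    return pd.DataFrame(rows)


def bifurcation_family(
    p: CircuitParams,
    I_range: tuple[float, float],
    K_LE_values: Sequence[float],
) -> dict[float, list[BifurcationBranch]]:
    """Branch families over a list of mechanosensing thresholds KLE.

    Decreasing KLE strengthens the LOXL2 feedback and shifts the
    diagram toward lower external signal.
    """
    fam = {}
    for K in K_LE_values:
        pk = replace(p, K_LE=float(K))
        brs = trace_diagram(pk, I_range)
        for br in brs:
            br.K_LE = float(K)
        fam[float(K)] = brs
    return fam


def family_to_frame(fam: dict[float, list[BifurcationBranch]]) -> pd.DataFrame:
    """Long-format table (KLE, branch id, I, state..., stable, fold)."""
    rows = []
    for K, brs in fam.items():
        for b, br in enumerate(brs):
            for m in range(br.I.size):
                row = {"K_LE": K, "branch": b, "I": br.I[m],
                       "stable": bool(br.stable[m]), "fold": False}
                row.update(dict(zip(STATE_NAMES, br.states[m])))
                rows.append(row)
            for (If, xf) in br.folds:
                row = {"K_LE": K, "branch": b, "I": If,
                       "stable": False, "fold": True}
                row.update(dict(zip(STATE_NAMES, xf)))
                rows.append(row)
    return pd.DataFrame(rows)
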