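"""EMT regulatory circuit with LOXL2/stiffness mechanosensing feedback.

The core network is the established microRNA-based EMT switch: two
interlinked double-negative loops, miR-200 against ZEB (with ZEB
self-activation) and miR-34 against SNAIL, with an external EMT-inducing
signal I driving SNAIL transcription.  MicroRNA action combines
translational silencing and active mRNA degradation through binomially
distributed occupancy of the microRNA binding sites on the target mRNA.
Across I the circuit exhibits epithelial (low ZEB), hybrid E/M, and
mesenchymal (high ZEB) states, with tristable windows.

The extension adds a non-cell-autonomous positive feedback through the
extracellular matrix: ZEB drives secretion of the collagen cross-linker
LOXL2 (Michaelis–Menten, Hill order 1),

    dc/dt = gLOXL / (1 + (KZL/Z)) - kLOXL * c ,

and the resulting matrix stiffening feeds a mechanosensing signal into
SNAIL as a high-order Hill function of the LOXL2 level,

    IECM = gECM / (1 + (KLE/c)^nLE) ,

which adds to the external signal: Itot = I + IECM.  The threshold KLE
measures how much LOXL2 is needed to push the local network past its
isostatic point; only the ratio KLE/c matters.

Default core-circuit constants are the published values of the cited
switch model (concentrations in molecules, time in hours); every
constant is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

__all__ = [
    "MirnaSilencing",
    "CircuitParams",
    "CircuitState",
    "STATE_NAMES",
    "shifted_hill",
    "mirna_modulation",
    "iecm",
    "rhs",
    "jacobian",
    "find_steady_states",
    "classify_state",
]

STATE_NAMES = ("u200", "mZ", "Z", "u34", "mS", "S", "cLOXL")


def shifted_hill(X, X0: float, n: float, fold: float):
    """Shifted Hill function H = (1 + fold*(X/X0)^n) / (1 + (X/X0)^n).

    H(0) = 1 and H(inf) = fold; fold < 1 is repression, fold > 1
    activation.
    """
    if X0 <= 0:
        raise ValueError("Hill threshold X0 must be positive")
    x = np.minimum(np.asarray(X, dtype=float) / X0, 1e12)  # overflow guard
    xn = x**n
    out = (1.0 + fold * xn) / (1.0 + xn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MirnaSilencing:
    """Per-occupancy microRNA silencing weights for one mRNA target.

    ``l[i]``: translation fraction with i sites occupied (l[0] = 1,
    decreasing); ``gm[i]``: active mRNA degradation rate; ``gu[i]``:
    per-site microRNA loss rate.  Occupancies are binomial in u/u0.
    """

    u0: float
    l: tuple[float, ...]
    gm: tuple[float, ...]
    gu: tuple[float, ...]

    @property
    def n_sites(self) -> int:
        return len(self.l) - 1


def mirna_modulation(u, sil: MirnaSilencing):
    """Silencing factors (L, Ym, Yu) at microRNA level u.

    With binomial occupancy weights
    ``M_i(u) = C(n, i) (u/u0)^i / (1 + u/u0)^n``:
    L = sum l_i M_i (translation), Ym = sum gm_i M_i (mRNA degradation),
    Yu = sum i*gu_i M_i (microRNA consumed with degraded mRNA).
    """
    n = sil.n_sites
    x = np.minimum(np.asarray(u, dtype=float) / sil.u0, 1e12)  # overflow guard
    denom = (1.0 + x) ** n
    L = np.zeros_like(x)
    Ym = np.zeros_like(x)
    Yu = np.zeros_like(x)
    for i in range(n + 1):
        Mi = comb(n, i) * x**i / denom
        L += sil.l[i] * Mi
        Ym += sil.gm[i] * Mi
        Yu += i * sil.gu[i] * Mi
    if L.ndim == 0:
        return float(L), float(Ym), float(Yu)
    return L, Ym, Yu


# published silencing tables: 6 miR-200 sites on ZEB mRNA, 2 miR-34 sites
# on SNAIL mRNA
_SIL_200 = MirnaSilencing(
    u0=10_000.0,
    l=(1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05),
    gm=(0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0),
    gu=(0.0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5),
)
_SIL_34 = MirnaSilencing(
    u0=10_000.0,
    l=(1.0, 0.6, 0.3),
    gm=(0.0, 0.04, 0.2),
    gu=(0.0, 0.005, 0.05),
)


@dataclass(frozen=True)
class CircuitParams:
    """All rate constants (molecules, per hour).

    The core block is the published parameter set of the cited EMT
    switch; the LOXL2/mechanosensing block is this package's extension.
    ``gECM = 0`` (or ``KLE = inf``) recovers the baseline circuit.
    """

    # miR-200 (repressed by ZEB and SNAIL)
    g_u200: float = 2100.0
    Z0_u200: float = 220_000.0
    n_Z_u200: float = 3.0
    fold_Z_u200: float = 0.1
    S0_u200: float = 180_000.0
    n_S_u200: float = 2.0
    fold_S_u200: float = 0.1
    k_u200: float = 0.05
    # ZEB mRNA (self-activated by ZEB, activated by SNAIL)
    g_mZ: float = 11.0
    Z0_mZ: float = 25_000.0
    n_Z_mZ: float = 2.0
    fold_Z_mZ: float = 7.5
    S0_mZ: float = 180_000.0
    n_S_mZ: float = 2.0
    fold_S_mZ: float = 10.0
    k_mZ: float = 0.5
    # ZEB protein
    g_Z: float = 100.0
    k_Z: float = 0.1
    # miR-34 (repressed by SNAIL and ZEB)
    g_u34: float = 1350.0
    S0_u34: float = 300_000.0
    n_S_u34: float = 2.0
    fold_S_u34: float = 0.1
    Z0_u34: float = 600_000.0
    n_Z_u34: float = 2.0
    fold_Z_u34: float = 0.2
    k_u34: float = 0.05
    # SNAIL mRNA (activated by the total signal, self-inhibited)
    g_mS: float = 90.0
    I0: float = 50_000.0
    n_I: float = 2.0
    fold_I: float = 10.0
    S0_mS: float = 200_000.0
    n_S_mS: float = 1.0
    fold_S_mS: float = 0.1
    k_mS: float = 0.5
    # SNAIL protein
    g_S: float = 100.0
    k_S: float = 0.125
    # microRNA silencing tables
    sil_200: MirnaSilencing = _SIL_200
    sil_34: MirnaSilencing = _SIL_34
    # LOXL2 production/decay (ZEB -> LOXL2, Hill order nZL = 1)
    g_LOXL: float = 10_000.0
    K_ZL: float = 220_000.0
    n_ZL: float = 1.0
    k_LOXL: float = 0.1
    # mechanosensing input to SNAIL (LOXL2 -> stiffness -> SNAIL)
    g_ECM: float = 100_000.0
    K_LE: float = 50_000.0
    n_LE: float = 4.0

    def baseline(self) -> "CircuitParams":
        """Same circuit with the mechanosensing feedback severed."""
        return replace(self, g_ECM=0.0)


@dataclass
class CircuitState:
    u200: float
    mZ: float
    Z: float
    u34: float
    mS: float
    S: float
    cLOXL: float

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CircuitState":
        return cls(*map(float, x))

    def to_array(self) -> np.ndarray:
        return np.array([self.u200, self.mZ, self.Z, self.u34, self.mS, self.S, self.cLOXL])


def iecm(cLOXL, p: CircuitParams):
    """Mechanosensing signal gECM / (1 + (KLE/c)^nLE).

    0 at c = 0, gECM/2 at c = KLE, saturates at gECM; for KLE = 0 the
    signal is at maximum for any positive LOXL2 level.
    """
    c = np.asarray(cLOXL, dtype=float)
    if np.any(c < 0):
        raise ValueError("LOXL2 concentration must be non-negative")
    if p.K_LE == 0:
        out = np.where(c > 0, p.g_ECM, 0.0)
    else:
        cn = c**p.n_LE
        out = p.g_ECM * cn / (cn + p.K_LE**p.n_LE)
    return float(out) if out.ndim == 0 else out


def rhs(x: np.ndarray, p: CircuitParams, I: float, t: float = 0.0) -> np.ndarray:
    """Time derivative of (u200, mZ, Z, u34, mS, S, cLOXL).

    The SNAIL-driving signal is Itot = I + IECM(cLOXL); LOXL2 follows
    ZEB with Michaelis–Menten production.  Raises on negative state
    components (the dynamics preserve non-negativity from non-negative
    initial conditions).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-9):
        raise ValueError("negative state component")
    u200, mZ, Z, u34, mS, S, c = np.maximum(x, 0.0)

    L2, Ym2, Yu2 = mirna_modulation(u200, p.sil_200)
    L3, Ym3, Yu3 = mirna_modulation(u34, p.sil_34)
    Itot = I + iecm(c, p)

    du200 = (
        p.g_u200
        * shifted_hill(Z, p.Z0_u200, p.n_Z_u200, p.fold_Z_u200)
        * shifted_hill(S, p.S0_u200, p.n_S_u200, p.fold_S_u200)
        - mZ * Yu2
        - p.k_u200 * u200
    )
    dmZ = (
        p.g_mZ
        * shifted_hill(Z, p.Z0_mZ, p.n_Z_mZ, p.fold_Z_mZ)
        * shifted_hill(S, p.S0_mZ, p.n_S_mZ, p.fold_S_mZ)
        - mZ * Ym2
        - p.k_mZ * mZ
    )
    dZ = p.g_Z * mZ * L2 - p.k_Z * Z
    du34 = (
        p.g_u34
        * shifted_hill(S, p.S0_u34, p.n_S_u34, p.fold_S_u34)
        * shifted_hill(Z, p.Z0_u34, p.n_Z_u34, p.fold_Z_u34)
        - mS * Yu3
        - p.k_u34 * u34
    )
    dmS = (
        p.g_mS
        * shifted_hill(max(Itot, 0.0), p.I0, p.n_I, p.fold_I)
        * shifted_hill(S, p.S0_mS, p.n_S_mS, p.fold_S_mS)
        - mS * Ym3
        - p.k_mS * mS
    )
    dS = p.g_S * mS * L3 - p.k_S * S
    if p.n_ZL == 1.0:
        prod = p.g_LOXL / (1.0 + p.K_ZL / Z) if Z > 0 else 0.0
    else:
        prod = p.g_LOXL / (1.0 + (p.K_ZL / Z) ** p.n_ZL) if Z > 0 else 0.0
    dc = prod - p.k_LOXL * c
    return np.array([du200, dmZ, dZ, du34, dmS, dS, dc])


def jacobian(x: np.ndarray, p: CircuitParams, I: float, rel_eps: float = 1e-6) -> np.ndarray:
    """Finite-difference Jacobian of the vector field at x."""
    x = np.asarray(x, dtype=float)
    n = x.size
    J = np.zeros((n, n))
    f0 = rhs(x, p, I)
    for m in range(n):
        h = rel_eps * max(abs(x[m]), 1.0)
        xp = x.copy()
        xp[m] += h
        xm = x.copy()
        xm[m] = max(xm[m] - h, 0.0)
        J[:, m] = (rhs(xp, p, I) - rhs(xm, p, I)) / (xp[m] - xm[m])
    del f0
    return J


def _characteristic_scale(p: CircuitParams) -> np.ndarray:
    """Upper-range concentration per component, Hill folds included."""
    mz = p.g_mZ * max(1.0, p.fold_Z_mZ) * max(1.0, p.fold_S_mZ) / p.k_mZ
    ms = p.g_mS * max(1.0, p.fold_I) / p.k_mS
    return np.array([
        p.g_u200 / p.k_u200,
        mz,
        p.g_Z * mz / p.k_Z,
        p.g_u34 / p.k_u34,
        ms,
        p.g_S * ms / p.k_S,
        max(p.g_LOXL / p.k_LOXL, 1.0),
    ])


def _default_grid(p: CircuitParams) -> np.ndarray:
    """Multistart initial conditions spanning E-like to M-like corners."""
    scale = _characteristic_scale(p)
    fracs = [0.001, 0.01, 0.1, 0.4, 0.9]
    starts = []
    for fu in fracs:          # microRNA level (E-like when high)
        for fz in fracs:      # ZEB arm
            s = scale * np.array([fu, fz, fz, fu, fz, fz, fz])
            starts.append(s)
    return np.array(starts)


def find_steady_states(
    p: CircuitParams,
    I: float,
    starts: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    dedup_rtol: float = 1e-5,
    stability_eps: float = -1e-9,
) -> list[tuple[CircuitState, bool]]:
    """All distinct steady states at external signal I, with stability.

    Damped-Newton (hybrid Powell) root finding from a grid of initial
    conditions, deduplicated by relative distance; stability from the
    real parts of the Jacobian eigenvalues.
    """
    if starts is None:
        starts = _default_grid(p)
    scale = _characteristic_scale(p)

    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(lambda x: rhs(np.maximum(x, 0.0), p, I), x0, method="hybr",
                   options={"xtol": 1e-12, "maxfev": 4000})
        if not sol.success:
            continue
        x = np.maximum(sol.x, 0.0)
        if np.linalg.norm(rhs(x, p, I) / scale) > tol:
            continue
        if any(np.all(np.abs(x - r) <= dedup_rtol * (scale + np.abs(r))) for r in roots):
            continue
        roots.append(x)

    out = []
    for x in roots:
        eig = np.linalg.eigvals(jacobian(x, p, I))
        stable = bool(np.max(eig.real) < stability_eps)
        out.append((CircuitState.from_array(x), stable))
    out.sort(key=lambda sr: sr[0].Z)
    return out


def classify_state(state: CircuitState, p: CircuitParams) -> str:
    """Epithelial / hybrid / mesenchymal label from the ZEB protein level."""
    zmax = _characteristic_scale(p)[2]
    frac = state.Z / zmax
    if frac < 0.05:
        return "epithelial"
    if frac < 0.35:
        return "hybrid"
    return "mesenchymal"
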