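"""EMT/MET dynamics of a cell migrating away from the tumor.

A mesenchymal cell leaves the tumor edge at radius r0 = R and moves
radially outward at constant speed v through the *static* LOXL2 field.
The handful of migrating cells do not remodel the matrix, so the
LOXL2–ECM feedback is severed: the LOXL2 level entering the
mechanosensing signal is the local field value c(r(t)), not the cell's
own secretion, and the cell-intrinsic LOXL2 equation is not integrated.
The core EMT circuit is driven by the time-dependent total signal

    Itot(t) = I + IECM(c(r0 + v t)) ,

which decays as the cell recedes.  When Itot falls below the fold point
of the mesenchymal branch the cell undergoes MET: ZEB drops sharply at a
critical distance from the tumor.  Larger tumor secretion (alpha*rho /
lambda) pushes that critical distance outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import (
    STATE_NAMES,
    CircuitParams,
    CircuitState,
    find_steady_states,
    iecm,
    rhs,
)
from .field import FieldParams, steady_concentration

__all__ = [
    "MigrationSetup",
    "MigrationTrajectory",
    "simulate_migration",
    "met_location",
]

_CORE = slice(0, 6)  # core circuit variables; cLOXL is slaved to the field


@dataclass(frozen=True)
class MigrationSetup:
    """Parameters of one outward migration run.

    ``v`` is the radial speed in lattice lengths per circuit-time unit
    (hours).  The initial state must be a stable (mesenchymal) steady
    state of the circuit at the tumor-edge signal.
    """

    field: FieldParams
    circuit: CircuitParams
    v: float
    I_background: float = 0.0
    r0: Optional[float] = None        # default: tumor edge R
    t_max: float = 2000.0
    initial: Optional[CircuitState] = None

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("migration speed v must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    @property
    def start_radius(self) -> float:
        return self.field.R if self.r0 is None else self.r0


@dataclass
class MigrationTrajectory:
    times: np.ndarray
    radii: np.ndarray
    concentrations: np.ndarray
    I_total: np.ndarray
    states: np.ndarray            # (n, 7); cLOXL column holds the field value
    setup: MigrationSetup = field(repr=False, default=None)

    @property
    def zeb_mrna(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def zeb(self) -> np.ndarray:
        return self.states[:, 2]


def _itot(setup: MigrationSetup, t: float) -> tuple[float, float, float]:
    r = setup.start_radius + setup.v * t
    c = steady_concentration(r, setup.field)
    return r, c, setup.I_background + iecm(c, setup.circuit)


def initial_mesenchymal_state(setup: MigrationSetup) -> CircuitState:
    """Stable steady state with the highest ZEB at the tumor-edge signal."""
    _r, _c, I0 = _itot(setup, 0.0)
    # the feedback is severed during migration: solve the baseline circuit
    states = find_steady_states(setup.circuit.baseline(), I0)
    stable = [s for s, st in states if st]
    if not stable:
        raise ValueError("no stable state at the tumor edge")
    return max(stable, key=lambda s: s.Z)


def simulate_migration(
    setup: MigrationSetup,
    n_out: int = 600,
    rtol: float = 1e-8,
    atol: float = 1e-3,
) -> MigrationTrajectory:
    """Integrate the core circuit along the outward path.

    Uses a stiff-capable adaptive solver (LSODA).  Raises if the supplied
    initial state is not a steady state of the circuit at the start
    position's total signal (within solver tolerance).
    """
    x0_full = (setup.initial or initial_mesenchymal_state(setup)).to_array()
    _r, c0, I0 = _itot(setup, 0.0)
    resid = rhs(np.maximum(x0_full, 0.0), setup.circuit.baseline(), I0)[_CORE]
    scale = np.maximum(np.abs(x0_full[_CORE]), 1.0)
    if np.max(np.abs(resid) / scale) > 1e-4:
        raise ValueError("initial state is not a steady state at r0")

    # IECM(c(r(t))) is folded into the signal driving the baseline
    # (g_ECM = 0) circuit, so the cell's own LOXL2 equation never runs
    pbase = setup.circuit.baseline()

    def f(t, x):
        _r, c, Itot = _itot(setup, t)
        full = np.concatenate([np.maximum(x, 0.0), [c]])
        return rhs(full, pbase, Itot)[_CORE]

    t_eval = np.linspace(0.0, setup.t_max, n_out)
    sol = solve_ivp(
        f, (0.0, setup.t_max), x0_full[_CORE],
        method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")

    radii = setup.start_radius + setup.v * sol.t
    cs = steady_concentration(radii, setup.field)
    itot = setup.I_background + iecm(cs, setup.circuit)
    states = np.column_stack([np.maximum(sol.y.T, 0.0), cs])
    return MigrationTrajectory(
        times=sol.t, radii=radii, concentrations=cs,
        I_total=itot, states=states, setup=setup,
    )


def met_location(
    trajectory: MigrationTrajectory,
    drop_fraction: float = 0.1,
) -> Optional[float]:
    """First radius where ZEB mRNA falls below a fraction of its start value.

    Returns None if no such drop occurs before the end of the run.
    """
    mz = trajectory.zeb_mrna
    below = np.flatnonzero(mz < drop_fraction * mz[0])
    if below.size == 0:
        return None
    return float(trajectory.radii[below[0]])
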