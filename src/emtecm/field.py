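"""Steady-state LOXL2 field around a secreting tumor and its ECM imprint.

A spherical tumor of radius ``R`` and cell density ``rho`` secretes LOXL2
at per-cell rate ``alpha``; the enzyme diffuses (``D``) and decays
(``lam``).  The spherically symmetric steady state is

    c(r) = alpha*rho/lam                          for r < R
    c(r) = (alpha*rho/lam) * (R/r) * exp(-(r-R)/d)  for r >= R

with decay length ``d = sqrt(D/lam)``.  LOXL2 cross-links collagen, which
the lattice model represents as a *decrease* of the phantomization
probability:

    pphan(c) = pphan0 / (1 + (c/cLP0)^2)

so high local LOXL2 drives the network above the isostatic point and
stiffens it.  The field is three-dimensional (hence the R/r prefactor)
but is evaluated on the 2D lattice plane through the tumor center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .lattice import FiberNetwork, LatticeSpec, build_lattice
from .mechanics import (
    DegenerateProbeError,
    ElasticParams,
    TrapSetup,
    probe_compliance,
)

__all__ = [
    "FieldParams",
    "PhantomMap",
    "steady_concentration",
    "pphan_from_concentration",
    "build_spatial_network",
    "compliance_map",
]


@dataclass(frozen=True)
class FieldParams:
    """Secretion–diffusion–decay parameters (lattice length units)."""

    alpha: float = 1.0
    rho: float = 1.0
    lam: float = 0.1
    D: float = 40.0
    R: float = 10.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        for name in ("alpha", "rho", "lam", "D", "R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def decay_length(self) -> float:
        return float(np.sqrt(self.D / self.lam))

    @property
    def plateau(self) -> float:
        """Interior concentration c0 = alpha*rho/lam."""
        return self.alpha * self.rho / self.lam


@dataclass(frozen=True)
class PhantomMap:
    """Mapping from local LOXL2 concentration to phantomization."""

    pphan0: float = 0.8
    cLP0: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.pphan0 <= 1.0):
            raise ValueError("pphan0 must be in [0, 1]")
        if self.cLP0 <= 0:
            raise ValueError("cLP0 must be positive")


def steady_concentration(r, p: FieldParams):
    """Steady-state LOXL2 concentration at radial distance r (>= 0).

    Continuous at r = R and monotone non-increasing in r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be non-negative")
    c0 = p.plateau
    d = p.decay_length
    with np.errstate(divide="ignore"):
        outer = c0 * (p.R / np.where(r > 0, r, np.inf)) * np.exp(-(r - p.R) / d)
    out = np.where(r < p.R, c0, outer)
    return float(out) if out.ndim == 0 else out


def pphan_from_concentration(c, pmap: PhantomMap):
    """Local phantomization pphan0 / (1 + (c/cLP0)^2); decreasing in c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = pmap.pphan0 / (1.0 + (c / pmap.cLP0) ** 2)
    return float(out) if out.ndim == 0 else out


def build_spatial_network(
    spec: LatticeSpec,
    field: FieldParams,
    pmap: PhantomMap,
) -> FiberNetwork:
    """Lattice whose per-site pphan follows the local LOXL2 level.

    The scalar ``spec.pphan`` is ignored; each site's phantomization is
    ``pphan(c(|x - center|))``.  Randomness is common-random-number
    coupled through ``spec.seed``: a site cross-linked at low
    concentration stays cross-linked at any higher concentration.
    """
    import warnings

    pos = _site_positions_of(spec)
    center = np.asarray(field.center, dtype=float)
    lo = np.zeros(2)
    hi = np.array([spec.nx + 0.5 * spec.ny, np.sqrt(3.0) / 2.0 * spec.ny])
    if not (lo[0] <= center[0] <= hi[0] and lo[1] <= center[1] <= hi[1]):
        warnings.warn("tumor center lies outside the lattice extent")
    r = np.sqrt(((pos - center) ** 2).sum(axis=1))
    pphan_sites = pphan_from_concentration(steady_concentration(r, field), pmap)
    spatial_spec = LatticeSpec(
        nx=spec.nx,
        ny=spec.ny,
        pbond=spec.pbond,
        pphan=pphan_sites,
        seed=spec.seed,
        boundary=spec.boundary,
    )
    return build_lattice(spatial_spec)


def _site_positions_of(spec: LatticeSpec) -> np.ndarray:
    s = np.arange(spec.nx * spec.ny)
    a = (s % spec.nx).astype(float)
    b = (s // spec.nx).astype(float)
    return np.column_stack([a + 0.5 * b, np.sqrt(3.0) / 2.0 * b])


def compliance_map(
    spec: LatticeSpec,
    field: FieldParams,
    pmap: PhantomMap,
    probe_points: Iterable[tuple[float, float]],
    trap_template: TrapSetup,
    params: Optional[ElasticParams] = None,
    inner_margin: float = 0.25,
) -> pd.DataFrame:
    """Map of local compliance with and without the LOXL2 field.

    One bead probe per grid point, fixed boundary, on two networks built
    with the same seed: the spatially phantomized one and the zero-
    concentration baseline.  ``ratio = J_baseline / J_field`` is >= ~1
    where the field stiffens the matrix.  Probe points outside the inner
    measurement region (a fractional margin from the pinned rim) are
    skipped and reported with NaN compliances.
    """
    if spec.boundary != "fixed":
        raise ValueError("compliance mapping requires a fixed-boundary lattice")
    params = params or ElasticParams()

    net_field = build_spatial_network(spec, field, pmap)
    baseline_spec = LatticeSpec(
        nx=spec.nx, ny=spec.ny, pbond=spec.pbond,
        pphan=np.full(spec.nx * spec.ny, pmap.pphan0),
        seed=spec.seed, boundary="fixed",
    )
    net_base = build_lattice(baseline_spec)

    a1, a2 = net_base.box_vectors
    center = np.asarray(field.center, dtype=float)
    rows = []
    for (x, y) in probe_points:
        pt = np.array([x, y], dtype=float)
        # fractional coordinates in the parallelogram frame
        M = np.column_stack([a1, a2])
        frac = np.linalg.solve(M, pt)
        inside = np.all(frac >= inner_margin) and np.all(frac <= 1 - inner_margin)
        r = float(np.linalg.norm(pt - center))
        c = float(steady_concentration(r, field))
        row = {
            "x": x, "y": y, "r": r, "c": c,
            "pphan": float(pphan_from_concentration(c, pmap)),
            "J_field": np.nan, "J_baseline": np.nan, "ratio": np.nan,
            "converged": False, "skipped": not inside,
        }
        if inside:
            trap = TrapSetup(
                center=(x, y),
                bead_radius=trap_template.bead_radius,
                ktrap=trap_template.ktrap,
                dtrap=trap_template.dtrap,
                directions=trap_template.directions,
            )
            try:
                rf = probe_compliance(net_field, params, trap)
                rb = probe_compliance(net_base, params, trap)
            except DegenerateProbeError:
                rows.append(row)
                continue
            row.update(
                J_field=rf.compliance,
                J_baseline=rb.compliance,
                ratio=rb.compliance / rf.compliance,
                converged=rf.converged and rb.converged,
            )
        rows.append(row)
    return pd.DataFrame(rows)
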