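"""Quasistatic mechanics of fiber networks.

Energy model: harmonic stretching of each unit-rest-length bond,
``E_stretch = 1/2 k (l_ij - 1)^2``, plus harmonic bending of each fiber
segment (two consecutive, initially colinear bonds of the same fiber),
``E_bend = 1/2 kappa theta_ijk^2`` with ``theta_ijk`` the angular
deviation from colinearity.  Bending is typically much softer than
stretching (``kappa << k``), as for thin fibers.

Simple shear is imposed through Lees–Edwards boundary conditions: the
strain gamma enters only through the horizontal shift of periodic images
in minimum-image displacements, node coordinates stay in the unsheared
frame.  The shear modulus is the second strain derivative of the relaxed
energy density, evaluated by a central finite-difference stencil with
each stencil point independently relaxed.

Local stiffness is probed with an in-silico optical-trap bead: nodes
within the bead radius co-move rigidly with the bead (two extra degrees
of freedom), a harmonic trap drags the bead along four orthogonal
directions, and the compliance J averages bead displacement per unit trap
force over the four pulls.  Bead probing uses fixed (pinned-rim)
boundaries, since a periodic network would translate freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

from .lattice import FiberNetwork

__all__ = [
    "ElasticParams",
    "TrapSetup",
    "MechanicsResult",
    "total_energy",
    "relax",
    "shear_modulus",
    "probe_compliance",
]


@dataclass(frozen=True)
class ElasticParams:
    """Elastic constants and solver tolerances (lattice units)."""

    k: float = 1.0
    kappa: float = 1e-4
    force_tol: float = 1e-8
    gamma0: float = 1e-3
    max_iter: int = 200_000

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("stretching modulus k must be positive")
        if self.kappa < 0:
            raise ValueError("bending modulus kappa must be non-negative")
        if self.force_tol <= 0:
            raise ValueError("force_tol must be positive")


@dataclass(frozen=True)
class TrapSetup:
    """Harmonic optical-trap probe around an embedded rigid bead."""

    center: tuple[float, float]
    bead_radius: float = 1.0
    ktrap: float = 1.0
    dtrap: float = 0.02
    directions: tuple[tuple[float, float], ...] = (
        (1.0, 0.0),
        (-1.0, 0.0),
        (0.0, 1.0),
        (0.0, -1.0),
    )

    def __post_init__(self):
        if self.ktrap <= 0:
            raise ValueError("ktrap must be positive")
        if self.dtrap <= 0:
            raise ValueError("dtrap must be positive")


@dataclass
class MechanicsResult:
    positions: np.ndarray
    e_stretch: float
    e_bend: float
    e_trap: float
    converged: bool
    iterations: int
    max_force: float
    modulus: Optional[float] = None
    compliance: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def e_total(self) -> float:
        return self.e_stretch + self.e_bend + self.e_trap


class DegenerateProbeError(RuntimeError):
    """Raised when a trap bead is attached to no network node."""


def _box_rows(network: FiberNetwork, gamma: float) -> np.ndarray:
    """Box vectors with the Lees–Edwards image shift applied to the second."""
    box = network.box_vectors
    box[1, 0] += gamma * box[1, 1]
    return box


def energy_and_gradient(
    network: FiberNetwork,
    positions: np.ndarray,
    params: ElasticParams,
    gamma: float = 0.0,
) -> tuple[float, float, np.ndarray]:
    """Stretch and bend energies with the exact analytic gradient.

    Returns ``(e_stretch, e_bend, grad)`` where grad has shape
    (n_nodes, 2).  Shear enters only through the image shift applied to
    bonds that cross the periodic boundary.
    """
    box = _box_rows(network, gamma)
    pos = positions
    grad = np.zeros_like(pos)

    i, j = network.bonds[:, 0], network.bonds[:, 1]
    shift = network.bond_offset @ box
    d = pos[j] - pos[i] + shift
    l = np.sqrt(np.einsum("ij,ij->i", d, d))
    if np.any(l < 1e-12):
        raise FloatingPointError("zero-length bond encountered")
    dl = l - 1.0
    e_stretch = 0.5 * params.k * float(dl @ dl)
    f = (params.k * dl / l)[:, None] * d
    n = pos.shape[0]
    for c in (0, 1):
        grad[:, c] += np.bincount(j, f[:, c], minlength=n)
        grad[:, c] -= np.bincount(i, f[:, c], minlength=n)

    e_bend = 0.0
    if params.kappa > 0.0 and network.triples.shape[0] > 0:
        ti, tj, tk = network.triples.T
        u = pos[tj] - pos[ti] + network.triple_offset_ij @ box
        v = pos[tk] - pos[tj] + network.triple_offset_jk @ box
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dot = np.einsum("ij,ij->i", u, v)
        theta = np.arctan2(cross, dot)
        e_bend = 0.5 * params.kappa * float(theta @ theta)
        u2 = np.einsum("ij,ij->i", u, u)
        v2 = np.einsum("ij,ij->i", v, v)
        # d(theta)/du = (u_y, -u_x)/|u|^2 ; d(theta)/dv = (-v_y, v_x)/|v|^2
        gth = params.kappa * theta
        gu = np.column_stack([u[:, 1], -u[:, 0]]) * (gth / u2)[:, None]
        gv = np.column_stack([-v[:, 1], v[:, 0]]) * (gth / v2)[:, None]
        gj = gu - gv
        for c in (0, 1):
            grad[:, c] -= np.bincount(ti, gu[:, c], minlength=pos.shape[0])
            grad[:, c] += np.bincount(tj, gj[:, c], minlength=pos.shape[0])
            grad[:, c] += np.bincount(tk, gv[:, c], minlength=pos.shape[0])

    return e_stretch, e_bend, grad


def total_energy(
    network: FiberNetwork,
    positions: np.ndarray,
    params: ElasticParams,
    gamma: float = 0.0,
    trap: Optional[TrapSetup] = None,
    bead_disp: Optional[np.ndarray] = None,
    trap_direction: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Total energy and gradient w.r.t. node positions.

    If a trap is given, ``bead_disp`` is the bead displacement and
    ``trap_direction`` the unit pull axis; the trap term is
    ``1/2 ktrap (d_bead_par - d_trap_par)^2`` and its gradient (w.r.t.
    the bead) is returned in ``diag['bead_grad']`` via the probe routine
    rather than here — this entry point reports the network part plus the
    scalar trap energy for inspection.
    """
    es, eb, grad = energy_and_gradient(network, positions, params, gamma)
    e = es + eb
    if trap is not None and bead_disp is not None and trap_direction is not None:
        dpar = float(bead_disp @ trap_direction)
        e += 0.5 * trap.ktrap * (dpar - trap.dtrap) ** 2
    return e, grad


def assemble_hessian(
    network: FiberNetwork,
    positions: np.ndarray,
    params: ElasticParams,
    gamma: float = 0.0,
) -> sp.csc_matrix:
    """Exact analytic Hessian of the elastic energy (2N x 2N, sparse).

    Stretch block per bond: k [n n^T + (l-1)/l (I - n n^T)]; bend blocks
    follow from the exact second derivative of the signed bend angle.
    """
    box = _box_rows(network, gamma)
    pos = positions
    n = pos.shape[0]
    rows, cols, vals = [], [], []

    def add_blocks(m_nodes, n_nodes, blocks):
        # blocks: (nb, 2, 2) contribution H[m, n] += blocks
        nb = blocks.shape[0]
        r = (2 * m_nodes[:, None, None] + np.array([[0], [1]])[None, :, :]).repeat(2, axis=2)
        c = (2 * n_nodes[:, None, None] + np.array([[0, 1]])[None, :, :]).repeat(2, axis=1)
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(blocks.ravel())

    i, j = network.bonds[:, 0], network.bonds[:, 1]
    d = pos[j] - pos[i] + network.bond_offset @ box
    l = np.sqrt(np.einsum("ij,ij->i", d, d))
    nh = d / l[:, None]
    eye = np.eye(2)[None, :, :]
    P = nh[:, :, None] * nh[:, None, :]
    Hb = params.k * (P + ((l - 1.0) / l)[:, None, None] * (eye - P))
    add_blocks(i, i, Hb)
    add_blocks(j, j, Hb)
    add_blocks(i, j, -Hb)
    add_blocks(j, i, -Hb)

    if params.kappa > 0.0 and network.triples.shape[0] > 0:
        ti, tj, tk = network.triples.T
        u = pos[tj] - pos[ti] + network.triple_offset_ij @ box
        v = pos[tk] - pos[tj] + network.triple_offset_jk @ box
        u2 = np.einsum("ij,ij->i", u, u)
        v2 = np.einsum("ij,ij->i", v, v)
        cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
        dot = np.einsum("ij,ij->i", u, v)
        theta = np.arctan2(cross, dot)
        a = np.column_stack([u[:, 1], -u[:, 0]]) / u2[:, None]
        b = np.column_stack([-v[:, 1], v[:, 0]]) / v2[:, None]
        Ru = np.column_stack([u[:, 1], -u[:, 0]])
        Rv = np.column_stack([-v[:, 1], v[:, 0]])
        Rmat = np.array([[0.0, 1.0], [-1.0, 0.0]])
        A = (Rmat[None, :, :] * u2[:, None, None]
             - 2.0 * Ru[:, :, None] * u[:, None, :]) / (u2**2)[:, None, None]
        B = (-Rmat[None, :, :] * v2[:, None, None]
             - 2.0 * Rv[:, :, None] * v[:, None, :]) / (v2**2)[:, None, None]
        g1, g2, g3 = -a, a - b, b
        th = theta[:, None, None]
        kap = params.kappa

        def outer(x, y):
            return x[:, :, None] * y[:, None, :]

        add_blocks(ti, ti, kap * (th * A + outer(g1, g1)))
        add_blocks(tj, tj, kap * (th * (A + B) + outer(g2, g2)))
        add_blocks(tk, tk, kap * (th * B + outer(g3, g3)))
        Hij = kap * (-th * A + outer(g1, g2))
        Hjk = kap * (-th * B + outer(g2, g3))
        Hik = kap * outer(g1, g3)
        add_blocks(ti, tj, Hij)
        add_blocks(tj, ti, Hij.transpose(0, 2, 1))
        add_blocks(tj, tk, Hjk)
        add_blocks(tk, tj, Hjk.transpose(0, 2, 1))
        add_blocks(ti, tk, Hik)
        add_blocks(tk, ti, Hik.transpose(0, 2, 1))

    H = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * n, 2 * n),
    )
    return H.tocsc()


def _pair_fmax(g: np.ndarray) -> float:
    """Largest per-node (per-2-DOF-pair) residual force magnitude."""
    if g.size == 0:
        return 0.0
    gm = g.reshape(-1, 2)
    return float(np.sqrt((gm**2).sum(axis=1)).max())


def _newton_minimize(eg, hess, x0, force_tol, k_scale, max_newton=300, warm_lbfgs=400):
    """Damped (Levenberg-regularized) Newton minimization.

    ``eg(x) -> (energy, grad)``; ``hess(x) -> sparse Hessian``.  A short
    L-BFGS warm-up takes the large early steps; Newton with the exact
    sparse Hessian then converges the residual force to tolerance even at
    kappa/k ~ 1e-6, where quasi-Newton methods stall on the
    ill-conditioned soft-mode spectrum.  Only descent directions are
    accepted (Armijo backtracking), so the iteration cannot terminate on
    an energy saddle it did not start on.
    """
    nit = 0
    x = np.asarray(x0, dtype=float)
    if x.size == 0:
        e, g = eg(x)
        return x, e, 0.0, True, 0

    raw_eg = eg

    def eg(xv):  # transient collapses during line search: infinite energy
        try:
            return raw_eg(xv)
        except FloatingPointError:
            return np.inf, np.zeros_like(xv)

    if warm_lbfgs:
        res = minimize(
            eg, x, jac=True, method="L-BFGS-B",
            options={"maxiter": warm_lbfgs, "ftol": 1e-18, "gtol": force_tol / 10},
        )
        x = res.x
        nit += res.nit
    e, g = eg(x)
    lam = 0.0
    ident = sp.identity(x.size, format="csc")
    for _ in range(max_newton):
        fmax = _pair_fmax(g)
        if fmax <= force_tol:
            return x, e, fmax, True, nit
        H = hess(x)
        step = None
        for _try in range(15):
            try:
                lu = splu(
                    (H + lam * ident).tocsc() if lam else H.tocsc(),
                    diag_pivot_thresh=0.0,
                    options={"SymmetricMode": True},
                )
                d = lu.solve(-g)
            except RuntimeError:
                lam = max(10.0 * lam, 1e-10 * k_scale)
                continue
            if not np.all(np.isfinite(d)) or d @ g >= 0:
                lam = max(10.0 * lam, 1e-10 * k_scale)
                continue
            step = d
            break
        if step is None:
            return x, e, fmax, False, nit
        t, gd = 1.0, step @ g
        accepted = False
        for _ls in range(40):
            xt = x + t * step
            et, gt = eg(xt)
            if et <= e + 1e-4 * t * gd:
                x, e, g = xt, et, gt
                accepted = True
                break
            t *= 0.5
        nit += 1
        if not accepted:
            lam = max(10.0 * lam, 1e-8 * k_scale)
        else:
            lam *= 0.1
            if lam < 1e-12 * k_scale:
                lam = 0.0
    return x, e, _pair_fmax(g), _pair_fmax(g) <= force_tol, nit


def _minimize_with_escapes(eg, hess, x0, force_tol, k_scale, rng,
                           kick_amps=(5e-3, 1e-3), max_newton=300):
    """Newton minimization with random-kick escapes from shallow saddles.

    Networks of initially straight fibers have an affine stationary point
    at any strain (stretch relief by transverse buckling is second
    order), so after convergence the state is kicked by a small random
    displacement and re-relaxed; the lower-energy state is kept.
    """
    x, e, fmax, conv, nit = _newton_minimize(eg, hess, x0, force_tol, k_scale,
                                             max_newton=max_newton)
    for amp in kick_amps:
        xt = x + amp * rng.standard_normal(x.size)
        x2, e2, f2, c2, n2 = _newton_minimize(eg, hess, xt, force_tol, k_scale,
                                              max_newton=max_newton, warm_lbfgs=100)
        nit += n2
        if c2 and e2 < e - max(1e-14, 1e-10 * abs(e)):
            x, e, fmax, conv = x2, e2, f2, c2
    return x, e, fmax, conv, nit


def _rim_mask(network: FiberNetwork, width: float = 1.0) -> np.ndarray:
    """Nodes within `width` lattice rows of the parallelogram boundary."""
    coords = network.fractional_site_coords()[network.node_site]
    a, b = coords[:, 0], coords[:, 1]
    return (
        (a < width)
        | (a >= network.nx - width)
        | (b < width)
        | (b >= network.ny - width)
    )


def relax(
    network: FiberNetwork,
    params: ElasticParams,
    gamma: float = 0.0,
    boundary: Optional[str] = None,
    initial: Optional[np.ndarray] = None,
    pinned: Optional[np.ndarray] = None,
    perturb: Optional[float] = None,
) -> MechanicsResult:
    """Minimize the elastic energy at fixed strain.

    Starts from the affinely sheared rest configuration unless ``initial``
    is given; a small deterministic random perturbation breaks the
    straight-fiber symmetry (the affine state is a stationary point of
    networks of initially colinear bonds, so an unperturbed start would
    sit on a saddle and report the affine energy).  For fixed boundaries
    the outer rim (one lattice spacing) is pinned at its affine position.
    Convergence is judged on the maximum per-node residual force, not on
    energy decrease, because floppy modes make energy-based criteria
    unreliable.
    """
    boundary = boundary or network.boundary
    pos0 = network.node_positions()
    if initial is None:
        initial = pos0 + np.column_stack([gamma * pos0[:, 1], np.zeros(len(pos0))])
    pos = initial.copy()

    if pinned is None:
        pinned = (
            _rim_mask(network) if boundary == "fixed"
            else np.zeros(network.n_nodes, dtype=bool)
        )
    free = ~pinned
    nfree = int(free.sum())

    rng = np.random.default_rng(0)  # fixed stream: deterministic given inputs
    if perturb is None:
        perturb = 0.0 if gamma == 0.0 else min(0.03, 0.3 * np.sqrt(abs(gamma)))
    if perturb and nfree:
        pos[free] += perturb * rng.standard_normal((nfree, 2))

    def eg(x):
        p = pos.copy()
        p[free] = x.reshape(nfree, 2)
        es, eb, g = energy_and_gradient(network, p, params, gamma)
        return es + eb, g[free].ravel()

    free_dof = np.repeat(free, 2)

    def hess(x):
        p = pos.copy()
        p[free] = x.reshape(nfree, 2)
        return assemble_hessian(network, p, params, gamma)[free_dof][:, free_dof]

    kicks = (5e-3, 1e-3) if gamma != 0.0 else ()
    x, _e, fmax, converged, nit = _minimize_with_escapes(
        eg, hess, pos[free].ravel(), params.force_tol, params.k, rng,
        kick_amps=kicks,
    )
    p = pos.copy()
    p[free] = x.reshape(nfree, 2)
    es, eb, _ = energy_and_gradient(network, p, params, gamma)
    return MechanicsResult(
        positions=p,
        e_stretch=es,
        e_bend=eb,
        e_trap=0.0,
        converged=converged,
        iterations=nit,
        max_force=fmax,
    )


def shear_modulus(
    network: FiberNetwork,
    params: ElasticParams,
    gamma: float = 0.0,
    dgamma: Optional[float] = None,
    stencil: int = 3,
) -> MechanicsResult:
    """Shear modulus G(gamma) = (1/A) d2E/dgamma2 under Lees–Edwards BC.

    Central finite difference of the relaxed energy; each stencil point
    is relaxed independently, starting from the affinely sheared minimum
    at the central strain.  ``A = nx * ny * sqrt(3)/2`` is the area per
    period.  A 5-point stencil is available for moduli near the numerical
    floor.
    """
    if network.boundary != "periodic":
        raise ValueError("shear_modulus requires a periodic network")
    if stencil not in (3, 5):
        raise ValueError("stencil must be 3 or 5")
    dg = params.gamma0 if dgamma is None else dgamma
    area = network.nx * network.ny * np.sqrt(3.0) / 2.0

    base = relax(network, params, gamma=gamma)
    converged = base.converged
    iterations = base.iterations

    def energy_at(g):
        nonlocal converged, iterations
        dgam = g - gamma
        init = base.positions + np.column_stack(
            [dgam * base.positions[:, 1], np.zeros(network.n_nodes)]
        )
        r = relax(network, params, gamma=g, initial=init)
        converged &= r.converged
        iterations += r.iterations
        return r.e_stretch + r.e_bend

    e0 = base.e_stretch + base.e_bend
    if stencil == 3:
        ep, em = energy_at(gamma + dg), energy_at(gamma - dg)
        d2 = (ep - 2.0 * e0 + em) / dg**2
    else:
        e1p, e1m = energy_at(gamma + dg), energy_at(gamma - dg)
        e2p, e2m = energy_at(gamma + 2 * dg), energy_at(gamma - 2 * dg)
        d2 = (-e2p + 16 * e1p - 30 * e0 + 16 * e1m - e2m) / (12 * dg**2)

    g_mod = d2 / area
    return MechanicsResult(
        positions=base.positions,
        e_stretch=base.e_stretch,
        e_bend=base.e_bend,
        e_trap=0.0,
        converged=converged,
        iterations=iterations,
        max_force=base.max_force,
        modulus=float(g_mod),
        diagnostics={"dgamma": dg, "stencil": stencil, "area": area},
    )


def probe_compliance(
    network: FiberNetwork,
    params: ElasticParams,
    trap: TrapSetup,
    rim_width: float = 1.0,
) -> MechanicsResult:
    """Local compliance J from a four-direction optical-trap bead pull.

    Nodes whose rest position lies within the bead radius translate
    rigidly with the bead.  For each pull direction the trap bottom is
    displaced by ``dtrap`` and the network plus bead is relaxed; the
    compliance is the average of ``d_bead / (ktrap * (dtrap - d_bead))``
    over the pulls, with displacements measured along the pull axis.
    """
    pos0 = network.node_positions()
    pinned = _rim_mask(network, rim_width)
    center = np.asarray(trap.center, dtype=float)
    attached = (
        np.sqrt(((pos0 - center) ** 2).sum(axis=1)) <= trap.bead_radius
    ) & ~pinned
    if not attached.any():
        raise DegenerateProbeError("bead overlaps no free network node")
    free = ~pinned & ~attached
    nfree = int(free.sum())

    # reduction matrix: full node DOFs <- (free node DOFs, bead DOFs)
    n = network.n_nodes
    nred = 2 * nfree + 2
    rows_i = np.repeat(2 * np.flatnonzero(free), 2) + np.tile([0, 1], nfree)
    cols_i = np.arange(2 * nfree)
    natt = int(attached.sum())
    rows_b = np.repeat(2 * np.flatnonzero(attached), 2) + np.tile([0, 1], natt)
    cols_b = np.tile([2 * nfree, 2 * nfree + 1], natt)
    C = sp.coo_matrix(
        (np.ones(rows_i.size + rows_b.size),
         (np.concatenate([rows_i, rows_b]), np.concatenate([cols_i, cols_b]))),
        shape=(2 * n, nred),
    ).tocsc()

    def unpack(x):
        p = pos0.copy()
        if nfree:
            p[free] = x[: 2 * nfree].reshape(nfree, 2)
        bead = x[-2:]
        p[attached] = pos0[attached] + bead
        return p, bead

    js, dbeads, iters = [], [], 0
    converged = True
    last_x = None
    for direction in trap.directions:
        axis = np.asarray(direction, dtype=float)
        axis /= np.linalg.norm(axis)

        def eg(x):
            p, bead = unpack(x)
            es, eb, g = energy_and_gradient(network, p, params, gamma=0.0)
            dpar = float(bead @ axis)
            et = 0.5 * trap.ktrap * (dpar - trap.dtrap) ** 2
            gred = C.T @ g.ravel()
            gred[-2:] += trap.ktrap * (dpar - trap.dtrap) * axis
            return es + eb + et, gred

        def hess(x):
            p, bead = unpack(x)
            H = assemble_hessian(network, p, params, gamma=0.0)
            Hred = (C.T @ H @ C).tolil()
            Hred[-2:, -2:] += trap.ktrap * np.outer(axis, axis)
            return Hred.tocsc()

        x0 = np.concatenate([pos0[free].ravel(), np.zeros(2)])
        x, _e, fmax, conv, nit = _newton_minimize(
            eg, hess, x0, params.force_tol, max(params.k, trap.ktrap),
            warm_lbfgs=50,
        )
        iters += nit
        converged &= conv
        _p, bead = unpack(x)
        dpar = float(bead @ axis)
        dbeads.append(dpar)
        if dpar >= trap.dtrap:
            converged = False  # trap too soft / floppy network
            js.append(np.inf)
        else:
            js.append(dpar / (trap.ktrap * (trap.dtrap - dpar)))
        last_x = x

    p, _bead = unpack(last_x)
    es, eb, _ = energy_and_gradient(network, p, params, gamma=0.0)
    return MechanicsResult(
        positions=p,
        e_stretch=es,
        e_bend=eb,
        e_trap=0.0,
        converged=converged,
        iterations=iters,
        max_force=np.nan,
        compliance=float(np.mean(js)),
        diagnostics={"per_direction": js, "dbead": dbeads, "n_attached": natt},
    )
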