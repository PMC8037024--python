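"""Diluted, partially phantom triangular fiber lattices.

The extracellular matrix is represented as a 2D triangular lattice of
unit-length fiber segments.  Three straight fibers cross at every lattice
site; a fully bonded, fully cross-linked site therefore has connectivity
z = 6.  Two kinds of quenched disorder reduce the connectivity:

* **dilution** — each candidate bond is present independently with
  probability ``pbond`` (collagen density);
* **phantomization** — with probability ``pphan`` one of the three fibers
  crossing a site detaches from the cross-link and slides freely through
  it (a missing cross-link).  The two bond-ends of the detached fiber are
  moved onto a new *phantom node* co-located with the site, so the fiber
  keeps its own bending continuity but no longer couples mechanically to
  the other two fibers.

The resulting mean connectivity, counted at the primary (cross-linked)
node of each site, is

    z = pbond * (6 * (1 - pphan) + 4 * pphan)

Randomness uses common random numbers: a single uniform draw per site
decides the split, one draw per site picks the detached fiber, and one
draw per candidate bond decides dilution, all in a fixed order that does
not depend on the probabilities.  Lowering ``pphan`` (e.g. by raising the
local LOXL2 level) with the same seed therefore monotonically un-splits
sites and never rewires unrelated parts of the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "LatticeSpec",
    "FiberNetwork",
    "build_lattice",
    "average_connectivity",
    "enumerate_bend_triples",
]

ROOT3_2 = np.sqrt(3.0) / 2.0

# unit-cell displacement (da, db) of the +direction neighbor for the three
# fiber directions: (1,0), (1/2,r3/2), (-1/2,r3/2)
_DIR_STEPS = np.array([[1, 0], [0, 1], [-1, 1]], dtype=np.int64)


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a random fiber lattice realization.

    ``pphan`` may be a scalar or a per-site array (length ``nx * ny``,
    site index ``a + nx * b``) for spatially varying cross-linking.
    """

    nx: int
    ny: int
    pbond: float = 1.0
    pphan: Union[float, np.ndarray] = 0.0
    seed: int = 0
    boundary: str = "periodic"

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"lattice must be at least 2x2, got {self.nx}x{self.ny}")
        if not (0.0 <= self.pbond <= 1.0):
            raise ValueError(f"pbond must be in [0, 1], got {self.pbond}")
        pphan = np.asarray(self.pphan, dtype=float)
        if pphan.ndim not in (0, 1):
            raise ValueError("pphan must be a scalar or a 1D per-site array")
        if pphan.ndim == 1 and pphan.size != self.nx * self.ny:
            raise ValueError(
                f"per-site pphan must have length nx*ny={self.nx * self.ny}, "
                f"got {pphan.size}"
            )
        if np.any(pphan < 0.0) or np.any(pphan > 1.0):
            raise ValueError("pphan values must lie in [0, 1]")
        if self.boundary not in ("periodic", "fixed"):
            raise ValueError(f"boundary must be 'periodic' or 'fixed', got {self.boundary!r}")

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny

    def pphan_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.pphan, dtype=float), (self.n_sites,)).copy()


@dataclass
class FiberNetwork:
    """A realized fiber network.

    Nodes are mechanical degrees of freedom: every site owns a primary
    (cross-linked) node with the same index as the site; split sites own
    one extra phantom node.  Bonds store the node ids of their two ends
    plus the periodic image offset (in units of the two box vectors) that
    takes end *i* to end *j*.  Bend triples (i, j, k) are consecutive,
    initially colinear bonds of the same fiber joined at node j.
    """

    nx: int
    ny: int
    boundary: str
    site_pos: np.ndarray        # (n_sites, 2) rest coordinates
    node_site: np.ndarray       # (n_nodes,) owning site of each node
    is_phantom: np.ndarray      # (n_nodes,) bool
    phantom_of: np.ndarray      # (n_sites,) phantom node id or -1
    split_dir: np.ndarray       # (n_sites,) detached fiber direction or -1
    bonds: np.ndarray           # (n_bonds, 2) node ids
    bond_dir: np.ndarray        # (n_bonds,) fiber direction 0/1/2
    bond_offset: np.ndarray     # (n_bonds, 2) integer image offsets (i -> j)
    triples: np.ndarray         # (n_triples, 3) node ids (i, j, k)
    triple_offset_ij: np.ndarray  # (n_triples, 2)
    triple_offset_jk: np.ndarray  # (n_triples, 2)
    spec: LatticeSpec | None = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return self.nx * self.ny

    @property
    def n_nodes(self) -> int:
        return self.node_site.size

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    @property
    def box_vectors(self) -> np.ndarray:
        """Rows are the two periodic box vectors."""
        return np.array(
            [[float(self.nx), 0.0], [0.5 * self.ny, ROOT3_2 * self.ny]]
        )

    def node_positions(self) -> np.ndarray:
        """Rest positions of all nodes (phantom nodes sit on their site)."""
        return self.site_pos[self.node_site].copy()

    def fractional_site_coords(self) -> np.ndarray:
        """Lattice coordinates (a, b) of every site."""
        s = np.arange(self.n_sites)
        return np.column_stack([s % self.nx, s // self.nx]).astype(float)


def _site_positions(nx: int, ny: int) -> np.ndarray:
    s = np.arange(nx * ny)
    a = (s % nx).astype(float)
    b = (s // nx).astype(float)
    return np.column_stack([a + 0.5 * b, ROOT3_2 * b])


def build_lattice(spec: LatticeSpec) -> FiberNetwork:
    """Build a random diluted, partially phantom triangular lattice.

    Phantomization is applied first on the full lattice, then bonds are
    diluted; bond-ends follow their node assignment.  Deterministic given
    ``spec.seed`` (common random numbers across probability values).
    """
    nx, ny, ns = spec.nx, spec.ny, spec.n_sites
    pphan = spec.pphan_array()

    rng = np.random.default_rng(spec.seed)
    u_split = rng.random(ns)
    fiber_choice = rng.integers(0, 3, size=ns)
    u_bond = rng.random(3 * ns)

    split = u_split < pphan
    split_dir = np.where(split, fiber_choice, -1).astype(np.int64)

    # phantom node ids appended after the ns primary nodes
    phantom_of = np.full(ns, -1, dtype=np.int64)
    split_sites = np.flatnonzero(split)
    phantom_of[split_sites] = ns + np.arange(split_sites.size)
    n_nodes = ns + split_sites.size

    node_site = np.concatenate([np.arange(ns), split_sites])
    is_phantom = np.zeros(n_nodes, dtype=bool)
    is_phantom[ns:] = True

    # candidate bonds: (site, direction), index 3*s + d
    s = np.arange(ns)
    a, b = s % nx, s // nx
    cand_site = np.repeat(s, 3)
    cand_dir = np.tile(np.arange(3), ns)
    da = _DIR_STEPS[cand_dir, 0]
    db = _DIR_STEPS[cand_dir, 1]
    a2, b2 = a[cand_site] + da, b[cand_site] + db
    wrap_a = a2 // nx
    wrap_b = b2 // ny
    nbr_site = (a2 % nx) + nx * (b2 % ny)

    keep = u_bond < spec.pbond
    if spec.boundary == "fixed":
        keep &= (wrap_a == 0) & (wrap_b == 0)

    def node_at(sites: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Node carrying fiber direction d at each site (phantom if detached)."""
        out = sites.copy()
        detached = split_dir[sites] == dirs
        out[detached] = phantom_of[sites[detached]]
        return out

    end_i = node_at(cand_site, cand_dir)
    end_j = node_at(nbr_site, cand_dir)

    bonds = np.column_stack([end_i[keep], end_j[keep]])
    bond_dir = cand_dir[keep]
    bond_offset = np.column_stack([wrap_a[keep], wrap_b[keep]])

    # bend triples: for each (site, dir), the incoming bond (prev -> s) and
    # outgoing bond (s -> next) of the same fiber, both present
    prev_a, prev_b = a[cand_site] - da, b[cand_site] - db
    prev_site = (prev_a % nx) + nx * (prev_b % ny)
    incoming_idx = 3 * prev_site + cand_dir     # candidate index of bond prev -> s
    both = keep & keep[incoming_idx]
    ti = np.flatnonzero(both)
    node_i = end_i[incoming_idx[ti]]
    node_j = end_i[ti]                           # == end_j[incoming_idx[ti]]
    node_k = end_j[ti]
    off_ij = np.column_stack([wrap_a[incoming_idx[ti]], wrap_b[incoming_idx[ti]]])
    off_jk = np.column_stack([wrap_a[ti], wrap_b[ti]])

    return FiberNetwork(
        nx=nx,
        ny=ny,
        boundary=spec.boundary,
        site_pos=_site_positions(nx, ny),
        node_site=node_site,
        is_phantom=is_phantom,
        phantom_of=phantom_of,
        split_dir=split_dir,
        bonds=bonds,
        bond_dir=bond_dir,
        bond_offset=bond_offset,
        triples=np.column_stack([node_i, node_j, node_k]),
        triple_offset_ij=off_ij,
        triple_offset_jk=off_jk,
        spec=spec,
    )


def average_connectivity(network: FiberNetwork) -> float:
    """Mean number of bonds at the primary (cross-linked) node per site.

    Phantom crossings contribute no cross-link, so only primary-node bond
    ends are counted; the expectation over realizations equals
    ``pbond * (6*(1-pphan) + 4*pphan)``.
    """
    ns = network.n_sites
    ends = network.bonds.ravel()
    deg = np.bincount(ends[ends < ns], minlength=ns)
    return float(deg.mean())


def enumerate_bend_triples(network: FiberNetwork) -> np.ndarray:
    """Bend triples (i, j, k): surviving colinear bond pairs of one fiber.

    Both bonds share the same fiber direction and attach to the same node
    at the central site, so a detached fiber bends about its phantom node
    and never couples to the crossing fibers.
    """
    return network.triples.copy()
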