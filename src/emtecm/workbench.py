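"""Experiment drivers, reproducibility plumbing, and test fixtures.

Each experiment reproduces one of the framework's headline computations
as a tidy long-format table: the isostatic stiffening sweep
(``isostatic_sweep``), the spatial compliance map around a secreting
tumor (``compliance_map``), the bifurcation family over the
mechanosensing threshold (``bifurcation_family``), and the migrating-
cell MET panel (``migration_panel``).  Outputs carry a manifest (config
hash, seed, package version) sufficient for exact replay; rerunning a
deterministic experiment with the same config reproduces the tables
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import bifurcation_family, family_to_frame
from .circuit import CircuitParams
from .field import FieldParams, PhantomMap, compliance_map as _compliance_map
from .lattice import (
    FiberNetwork,
    LatticeSpec,
    average_connectivity,
    build_lattice,
)
from .mechanics import ElasticParams, TrapSetup, shear_modulus
from .migration import MigrationSetup, met_location, simulate_migration

__all__ = ["ExperimentConfig", "run_experiment", "make_fixture",
           "isostatic_sweep", "EXPERIMENTS"]


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Optional[str] = None

    def digest(self) -> str:
        payload = json.dumps(
            {"name": self.name, "params": self.params, "seed": self.seed},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def isostatic_sweep(
    nx: int = 30,
    ny: int = 30,
    pbond: float = 0.8,
    pphan_values=None,
    seeds=(0, 1, 2, 3, 4),
    kappa_over_k: float = 1e-6,
    dgamma: float = 1e-2,
    force_tol: float = 1e-8,
) -> pd.DataFrame:
    """Small-strain G/k versus connectivity across the isostatic point.

    Sweeps pphan at fixed pbond on periodic lattices; z spans the
    isostatic value 4 when pbond(6 - 2*pphan) does.  pbond = 0.8 keeps
    periodically spanning straight fibers (which are topologically taut
    under Lees-Edwards shear and would mask the floppy regime on small
    boxes) exponentially rare.
    """
    if pphan_values is None:
        pphan_values = np.linspace(0.75, 0.25, 8)
    params = ElasticParams(k=1.0, kappa=kappa_over_k, force_tol=force_tol,
                           gamma0=dgamma)
    rows = []
    for pphan in pphan_values:
        for seed in seeds:
            net = build_lattice(LatticeSpec(nx, ny, pbond, float(pphan), seed=int(seed)))
            z = average_connectivity(net)
            res = shear_modulus(net, params)
            rows.append({
                "pbond": pbond, "pphan": float(pphan), "seed": int(seed),
                "z": z, "z_expected": pbond * (6 - 2 * float(pphan)),
                "G_over_k": res.modulus, "converged": res.converged,
            })
    return pd.DataFrame(rows)


def _exp_isostatic(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = dict(cfg.params)
    seeds = p.pop("seeds", None) or [cfg.seed + i for i in range(5)]
    return {"sweep": isostatic_sweep(seeds=seeds, **p)}


def _exp_compliance_map(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = dict(cfg.params)
    nx = p.get("nx", 24)
    ny = p.get("ny", 24)
    spec = LatticeSpec(nx, ny, p.get("pbond", 0.8), 0.0,
                       seed=cfg.seed, boundary="fixed")
    fld = FieldParams(**p.get("field", {"alpha": 1.0, "rho": 1.0, "lam": 0.1,
                                        "D": 10.0, "R": 4.0,
                                        "center": (nx * 0.75, ny * 0.43)}))
    pmap = PhantomMap(**p.get("map", {"pphan0": 0.8, "cLP0": 2.0}))
    n_side = p.get("grid", 5)
    a1 = np.array([nx, 0.0])
    a2 = np.array([ny / 2.0, ny * np.sqrt(3) / 2.0])
    fr = np.linspace(0.3, 0.7, n_side)
    pts = [tuple(f1 * a1 + f2 * a2) for f1 in fr for f2 in fr]
    trap = TrapSetup(center=pts[0], bead_radius=p.get("bead_radius", 1.2),
                     ktrap=p.get("ktrap", 1.0), dtrap=p.get("dtrap", 0.02))
    mech = ElasticParams(k=1.0, kappa=p.get("kappa", 1e-4))
    return {"map": _compliance_map(spec, fld, pmap, pts, trap, mech)}


def _exp_bifurcation(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = dict(cfg.params)
    circuit = CircuitParams(**p.get("circuit", {}))
    KLEs = p.get("K_LE_values", [1e30, 2e5, 1e5, 5e4, 2e4])
    I_range = tuple(p.get("I_range", (-50_000, 150_000)))
    fam = bifurcation_family(circuit, I_range, KLEs)
    return {"family": family_to_frame(fam)}


def _exp_migration(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    p = dict(cfg.params)
    circuit = CircuitParams(**p.get("circuit", {}))
    c0_values = p.get("c0_values", [1e5, 2e5, 4e5, 8e5])
    v = p.get("v", 0.05)
    I_bg = p.get("I_background", 20_000.0)
    lam = p.get("lam", 0.1)
    rows = []
    for c0 in c0_values:
        fld = FieldParams(alpha=c0 * lam, rho=1.0, lam=lam,
                          D=p.get("D", 40.0), R=p.get("R", 10.0))
        setup = MigrationSetup(field=fld, circuit=circuit, v=v,
                               I_background=I_bg, t_max=p.get("t_max", 6000.0))
        tr = simulate_migration(setup)
        r_met = met_location(tr)
        for m in range(tr.times.size):
            rows.append({
                "c0": c0, "v": v, "t": tr.times[m], "r": tr.radii[m],
                "c": tr.concentrations[m], "I_total": tr.I_total[m],
                "mZ": tr.states[m, 1], "Z": tr.states[m, 2],
                "met_radius": r_met if r_met is not None else np.nan,
            })
    return {"panel": pd.DataFrame(rows)}


EXPERIMENTS = {
    "isostatic_sweep": _exp_isostatic,
    "compliance_map": _exp_compliance_map,
    "bifurcation_family": _exp_bifurcation,
    "migration_panel": _exp_migration,
}


def run_experiment(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Run a named experiment; write tables and a manifest if outdir set."""
    if cfg.name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {cfg.name!r}; known: {sorted(EXPERIMENTS)}"
        )
    tables = EXPERIMENTS[cfg.name](cfg)
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in tables.items():
            df.to_csv(out / f"{cfg.name}_{key}.csv", index=False)
        manifest = {
            "experiment": cfg.name,
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
            "version": __version__,
            "params": cfg.params,
        }
        with open(out / f"{cfg.name}_manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    return tables


# ---------------------------------------------------------------------------
# hand-constructed fixtures with closed-form expected values

def _custom_network(nx, ny, node_sites, bonds, bond_dir, triples=None) -> FiberNetwork:
    ns = nx * ny
    s = np.arange(ns)
    a = (s % nx).astype(float)
    b = (s // nx).astype(float)
    site_pos = np.column_stack([a + 0.5 * b, np.sqrt(3) / 2 * b])
    node_sites = np.asarray(node_sites)
    nb = len(bonds)
    triples = np.asarray(triples if triples else [], dtype=np.int64).reshape(-1, 3)
    return FiberNetwork(
        nx=nx, ny=ny, boundary="fixed",
        site_pos=site_pos,
        node_site=node_sites,
        is_phantom=np.zeros(node_sites.size, dtype=bool),
        phantom_of=np.full(ns, -1, dtype=np.int64),
        split_dir=np.full(ns, -1, dtype=np.int64),
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_dir=np.asarray(bond_dir, dtype=np.int64),
        bond_offset=np.zeros((nb, 2), dtype=np.int64),
        triples=triples,
        triple_offset_ij=np.zeros((triples.shape[0], 2), dtype=np.int64),
        triple_offset_jk=np.zeros((triples.shape[0], 2), dtype=np.int64),
    )


def make_fixture(name: str):
    """Tiny deterministic objects with closed-form expected behavior."""
    if name == "single-bond":
        # two horizontally adjacent interior-ish sites of a 4x4 sheet
        return _custom_network(4, 4, [5, 6], [[0, 1]], [0])
    if name == "bend-triple":
        net = _custom_network(4, 4, [4, 5, 6], [[0, 1], [1, 2]], [0, 0],
                              triples=[[0, 1, 2]])
        return net
    if name == "full-3x3":
        return build_lattice(LatticeSpec(3, 3, 1.0, 0.0, seed=0))
    if name == "phantom-site":
        pphan = np.zeros(9)
        pphan[4] = 1.0
        return build_lattice(LatticeSpec(3, 3, 1.0, pphan, seed=0))
    if name == "one-spring-probe":
        # bead node at site (2,2), wall node at rim site (3,2); one spring
        net = _custom_network(4, 4, [10, 11], [[0, 1]], [0])
        trap = TrapSetup(center=tuple(net.site_pos[10]), bead_radius=0.5,
                         ktrap=1.0, dtrap=1e-3,
                         directions=((1.0, 0.0), (-1.0, 0.0)))
        return net, trap
    if name == "decoupled-circuit":
        return CircuitParams().baseline()
    raise KeyError(f"unknown fixture {name!r}")
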