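"""Serialization of networks and configurations.

Networks go to a self-describing HDF5 container (node, bond, and triple
tables plus lattice metadata); configurations are YAML mappings that
round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .lattice import FiberNetwork, LatticeSpec

__all__ = ["save_network", "load_network", "network_tables",
           "load_config", "save_config"]


def network_tables(network: FiberNetwork) -> dict:
    """Node / bond / triple tables as plain arrays (diff-friendly)."""
    pos = network.node_positions()
    return {
        "nodes": np.column_stack([
            np.arange(network.n_nodes), network.node_site,
            pos[:, 0], pos[:, 1], network.is_phantom.astype(int),
        ]),
        "bonds": np.column_stack([network.bonds, network.bond_dir,
                                  network.bond_offset]),
        "triples": np.column_stack([network.triples,
                                    network.triple_offset_ij,
                                    network.triple_offset_jk]),
    }


def save_network(network: FiberNetwork, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["nx"] = network.nx
        f.attrs["ny"] = network.ny
        f.attrs["boundary"] = network.boundary
        f.create_dataset("site_pos", data=network.site_pos)
        f.create_dataset("node_site", data=network.node_site)
        f.create_dataset("is_phantom", data=network.is_phantom)
        f.create_dataset("phantom_of", data=network.phantom_of)
        f.create_dataset("split_dir", data=network.split_dir)
        f.create_dataset("bonds", data=network.bonds)
        f.create_dataset("bond_dir", data=network.bond_dir)
        f.create_dataset("bond_offset", data=network.bond_offset)
        f.create_dataset("triples", data=network.triples)
        f.create_dataset("triple_offset_ij", data=network.triple_offset_ij)
        f.create_dataset("triple_offset_jk", data=network.triple_offset_jk)
        if network.spec is not None:
            s = network.spec
            f.attrs["pbond"] = s.pbond
            f.attrs["seed"] = s.seed
            f.create_dataset("pphan", data=s.pphan_array())


def load_network(path) -> FiberNetwork:
    with h5py.File(path, "r") as f:
        spec = None
        if "pphan" in f:
            spec = LatticeSpec(
                nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
                pbond=float(f.attrs["pbond"]), pphan=f["pphan"][...],
                seed=int(f.attrs["seed"]), boundary=str(f.attrs["boundary"]),
            )
        return FiberNetwork(
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
            boundary=str(f.attrs["boundary"]),
            site_pos=f["site_pos"][...],
            node_site=f["node_site"][...],
            is_phantom=f["is_phantom"][...].astype(bool),
            phantom_of=f["phantom_of"][...],
            split_dir=f["split_dir"][...],
            bonds=f["bonds"][...],
            bond_dir=f["bond_dir"][...],
            bond_offset=f["bond_offset"][...],
            triples=f["triples"][...],
            triple_offset_ij=f["triple_offset_ij"][...],
            triple_offset_jk=f["triple_offset_jk"][...],
            spec=spec,
        )


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
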