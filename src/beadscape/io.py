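"""HDF5 caches and tabular output for grids, maps, fits and trajectories."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .fitting import FittedPotential
from .grids import MagnetizationGrid
from .potential import PotentialGridSpec, PotentialMap

__all__ = [
    "save_grid",
    "load_grid",
    "save_potential_map",
    "load_potential_map",
    "save_fit",
    "load_fit",
    "save_trajectory",
    "save_metrics",
]


def _spec_attrs(g, spec):
    g.attrs["x_range"] = spec.x_range
    g.attrs["y_range"] = spec.y_range
    g.attrs["n_nodes"] = spec.n_nodes
    g.attrs["periodic"] = [int(p) for p in spec.periodic]
    g.attrs["n_images"] = spec.n_images
    g.create_dataset("z_layers", data=spec.z_layers)


def _spec_from(g):
    return PotentialGridSpec(
        x_range=tuple(g.attrs["x_range"]),
        y_range=tuple(g.attrs["y_range"]),
        n_nodes=tuple(int(v) for v in g.attrs["n_nodes"]),
        z_layers=g["z_layers"][...],
        periodic=tuple(bool(v) for v in g.attrs["periodic"]),
        n_images=tuple(int(v) for v in g.attrs["n_images"]),
    )


def save_grid(path, grid):
    with h5py.File(path, "w") as f:
        f.create_dataset("M", data=grid.M)
        f.attrs["cell_size"] = grid.cell_size
        f.attrs["origin"] = grid.origin
        f.attrs["Ms"] = grid.Ms
        f.attrs["periodic"] = [int(p) for p in grid.periodic]
        f.attrs["n_images"] = grid.n_images


def load_grid(path):
    with h5py.File(path, "r") as f:
        return MagnetizationGrid(
            M=f["M"][...],
            cell_size=tuple(f.attrs["cell_size"]),
            origin=tuple(f.attrs["origin"]),
            Ms=float(f.attrs["Ms"]),
            periodic=tuple(bool(v) for v in f.attrs["periodic"]),
            n_images=tuple(int(v) for v in f.attrs["n_images"]),
        )


def save_potential_map(path, pmap):
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=pmap.U)
        if pmap.times is not None:
            f.create_dataset("times", data=pmap.times)
        if pmap.angles is not None:
            f.create_dataset("angles", data=pmap.angles)
        if pmap.frequency is not None:
            f.attrs["frequency"] = pmap.frequency
        _spec_attrs(f.create_group("spec"), pmap.spec)


def load_potential_map(path):
    with h5py.File(path, "r") as f:
        return PotentialMap(
            U=f["U"][...],
            spec=_spec_from(f["spec"]),
            times=f["times"][...] if "times" in f else None,
            angles=f["angles"][...] if "angles" in f else None,
            frequency=float(f.attrs["frequency"]) if "frequency" in f.attrs else None,
        )


def save_fit(path, fit):
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=fit.A)
        f.create_dataset("B", data=fit.B)
        f.attrs["omega"] = fit.omega
        f.attrs["submatrix"] = fit.submatrix
        _spec_attrs(f.create_group("spec"), fit.spec)


def load_fit(path):
    with h5py.File(path, "r") as f:
        return FittedPotential(
            A=f["A"][...],
            B=f["B"][...],
            omega=float(f.attrs["omega"]),
            spec=_spec_from(f["spec"]),
            submatrix=int(f.attrs["submatrix"]),
        )


def save_trajectory(csv_path, traj, events_path=None):
    traj.to_dataframe().to_csv(csv_path, index=False)
    if events_path is not None:
        with open(events_path, "w") as fh:
            json.dump(_jsonable(traj.events), fh, indent=1)


def save_metrics(path, metrics):
    with open(path, "w") as fh:
        json.dump(_jsonable(metrics.to_dict()), fh, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
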