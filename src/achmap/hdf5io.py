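"""HDF5 persistence for tissues, Vm movies, EGM grids and cell states."""

from __future__ import annotations

import json

import h5py
import numpy as np

from achmap.egm import EgmGrid, ElectrodeGrid
from achmap.ionic import CellState
from achmap.solver import VmField
from achmap.tissue import Patch, TissueModel

__all__ = ["save_tissue", "load_tissue", "save_vmfield", "load_vmfield",
           "save_egm", "load_egm", "save_cell_state", "load_cell_state"]


def save_tissue(path, tissue: TissueModel, attrs: dict | None = None):
    with h5py.File(path, "w") as f:
        g = f.create_group("tissue")
        g.create_dataset("cell_label", data=tissue.cell_label, compression="gzip")
        g.create_dataset("ach_map", data=tissue.ach_map, compression="gzip")
        reg = [(p.cx, p.cy, p.r, p.kind) for p in tissue.patch_registry]
        g.attrs["patch_registry"] = json.dumps(reg)
        for k in ("nx", "ny", "dx", "d_long", "anisotropy_ratio",
                  "fibro_coupling_factor", "fiber_axis"):
            g.attrs[k] = getattr(tissue, k)
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def load_tissue(path) -> TissueModel:
    with h5py.File(path, "r") as f:
        g = f["tissue"]
        reg = [Patch(cx, cy, r, kind)
               for cx, cy, r, kind in json.loads(g.attrs["patch_registry"])]
        return TissueModel(
            nx=int(g.attrs["nx"]), ny=int(g.attrs["ny"]),
            dx=float(g.attrs["dx"]), cell_label=g["cell_label"][()],
            ach_map=g["ach_map"][()], d_long=float(g.attrs["d_long"]),
            anisotropy_ratio=float(g.attrs["anisotropy_ratio"]),
            fibro_coupling_factor=float(g.attrs["fibro_coupling_factor"]),
            fiber_axis=str(g.attrs["fiber_axis"]), patch_registry=reg)


def save_vmfield(path, field: VmField, attrs: dict | None = None):
    with h5py.File(path, "w") as f:
        g = f.create_group("vm_field")
        g.create_dataset("vm", data=field.vm.astype(np.float32),
                         chunks=(1,) + field.vm.shape[1:], compression="gzip")
        g.attrs["sample_dt"] = field.sample_dt
        g.attrs["dx"] = field.dx
        g.attrs["t0"] = field.t0
        g.attrs["meta"] = json.dumps({k: str(v) for k, v in field.meta.items()})
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def load_vmfield(path) -> VmField:
    with h5py.File(path, "r") as f:
        g = f["vm_field"]
        return VmField(vm=g["vm"][()].astype(float),
                       sample_dt=float(g.attrs["sample_dt"]),
                       dx=float(g.attrs["dx"]), t0=float(g.attrs["t0"]),
                       meta=json.loads(g.attrs["meta"]))


def save_egm(path, egm: EgmGrid):
    with h5py.File(path, "w") as f:
        g = f.create_group("egm")
        g.create_dataset("phi", data=egm.phi, compression="gzip")
        g.create_dataset("positions_mm", data=egm.positions_mm)
        g.attrs["sample_dt"] = egm.sample_dt
        g.attrs["t0"] = egm.t0
        g.attrs["filter_spec"] = egm.filter_spec or ""
        g.attrs["normalization"] = egm.normalization or 0.0
        g.attrs["noise_spec"] = json.dumps(egm.noise_spec or {})
        for k in ("n_rows", "n_cols", "pitch_mm", "z_mm", "footprint", "size_mm"):
            g.attrs[k] = getattr(egm.grid, k)


def load_egm(path) -> EgmGrid:
    with h5py.File(path, "r") as f:
        g = f["egm"]
        grid = ElectrodeGrid(
            n_rows=int(g.attrs["n_rows"]), n_cols=int(g.attrs["n_cols"]),
            pitch_mm=float(g.attrs["pitch_mm"]), z_mm=float(g.attrs["z_mm"]),
            footprint=str(g.attrs["footprint"]), size_mm=float(g.attrs["size_mm"]))
        noise = json.loads(g.attrs["noise_spec"]) or None
        return EgmGrid(phi=g["phi"][()], sample_dt=float(g.attrs["sample_dt"]),
                       grid=grid, positions_mm=g["positions_mm"][()],
                       t0=float(g.attrs["t0"]),
                       filter_spec=str(g.attrs["filter_spec"]) or None,
                       noise_spec=noise,
                       normalization=float(g.attrs["normalization"]) or None)


def save_cell_state(path, state: CellState):
    """Flat named-vector record so tissue runs can be checkpointed."""
    with h5py.File(path, "w") as f:
        g = f.create_group("cell_state")
        g.attrs["variant"] = state.variant
        for n, v in state.to_dict().items():
            g.attrs[n] = v


def load_cell_state(path) -> CellState:
    with h5py.File(path, "r") as f:
        g = f["cell_state"]
        variant = str(g.attrs["variant"])
        d = {k: float(g.attrs[k]) for k in g.attrs if k != "variant"}
        return CellState.from_dict(d, variant=variant)
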