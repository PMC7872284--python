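"""File I/O: TSV profiles with commented headers, HDF5 trajectory containers,
PLY / legacy-VTK surface exports, and run manifests."""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import AxisymShape
from .stochastic import SpeciesState, SurfaceMesh

__all__ = ["write_tsv", "read_tsv", "shape_to_tsv", "shape_from_tsv",
           "save_trajectory", "load_trajectory", "write_vtk_surface",
           "write_ply_surface", "write_manifest"]

SHAPE_COLUMNS = ("s", "r", "z", "theta", "kappa_s", "kappa_phi", "h")


def write_tsv(path, columns: dict, header: dict | None = None):
    """Tab-separated table with a '# key: value' commented header block."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        df = pd.DataFrame(columns)
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_tsv(path):
    """Read a commented-header TSV; returns (DataFrame, header dict)."""
    path = Path(path)
    header = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return df, header


def shape_to_tsv(shape: AxisymShape, path, header: dict | None = None):
    write_tsv(path, {c: getattr(shape, c) for c in SHAPE_COLUMNS}, header)


def shape_from_tsv(path) -> AxisymShape:
    df, _ = read_tsv(path)
    return AxisymShape(**{c: df[c].to_numpy() for c in SHAPE_COLUMNS})


def _write_shape(grp, shape: AxisymShape):
    for c in SHAPE_COLUMNS:
        grp.create_dataset(c, data=getattr(shape, c))


def _read_shape(grp) -> AxisymShape:
    return AxisymShape(**{c: grp[c][...] for c in SHAPE_COLUMNS})


def save_trajectory(traj, path, attrs: dict | None = None):
    """Continuum Trajectory -> HDF5 (one group per snapshot)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "shmoo-continuum-trajectory-1"
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        f.create_dataset("times", data=np.asarray(traj.times))
        for i, t in enumerate(traj.times):
            g = f.create_group(f"snap{i:05d}")
            if traj.shapes[i] is not None:
                _write_shape(g.create_group("shape"), traj.shapes[i])
            if traj.polarity[i] is not None:
                g.create_dataset("rho_C", data=traj.polarity[i].rho_C)
                g.create_dataset("rho_Ba", data=traj.polarity[i].rho_Ba)
            if traj.wall[i] is not None:
                w = traj.wall[i]
                for name in ("sigma_ss", "sigma_phiphi", "eps_s_dot",
                             "eps_phi_dot", "u", "v_n", "mu", "G"):
                    g.create_dataset(name, data=getattr(w, name))
            for k, v in traj.metrics[i].items():
                g.attrs[k] = v


def load_trajectory(path):
    """HDF5 -> lightweight dict mirror of the trajectory contents."""
    out = {"times": None, "snapshots": []}
    with h5py.File(path, "r") as f:
        out["times"] = f["times"][...]
        for i in range(out["times"].size):
            g = f[f"snap{i:05d}"]
            snap = {"metrics": dict(g.attrs)}
            if "shape" in g:
                snap["shape"] = _read_shape(g["shape"])
            for name in ("rho_C", "rho_Ba", "sigma_ss", "sigma_phiphi",
                         "eps_s_dot", "eps_phi_dot", "u", "v_n", "mu", "G"):
                if name in g:
                    snap[name] = g[name][...]
            out["snapshots"].append(snap)
    return out


def _revolve(shape: AxisymShape, n_phi: int = 48):
    """Vertices and quad faces of the surface of revolution."""
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    verts = []
    for ri, zi in zip(shape.r, shape.z):
        for p in phi:
            verts.append((ri * np.cos(p), ri * np.sin(p), zi))
    verts = np.asarray(verts)
    faces = []
    n = shape.n_nodes
    for i in range(n - 1):
        for j in range(n_phi):
            a = i * n_phi + j
            b = i * n_phi + (j + 1) % n_phi
            c = (i + 1) * n_phi + (j + 1) % n_phi
            d = (i + 1) * n_phi + j
            faces.append((a, b, c, d))
    return verts, np.asarray(faces, dtype=int)


def write_vtk_surface(shape: AxisymShape, path, n_phi: int = 48,
                      cell_scalars: dict | None = None):
    """Legacy-VTK ASCII POLYDATA export of the revolved surface.

    ``cell_scalars`` maps names to per-face arrays (lengths must match the
    (n_nodes-1)*n_phi quad count).
    """
    verts, faces = _revolve(shape, n_phi)
    with Path(path).open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\naxisymmetric cell surface\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} float\n")
        for v in verts:
            fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        fh.write(f"POLYGONS {len(faces)} {5 * len(faces)}\n")
        for f4 in faces:
            fh.write("4 " + " ".join(str(i) for i in f4) + "\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {len(faces)}\n")
            for name, arr in cell_scalars.items():
                arr = np.asarray(arr, float)
                if arr.size != len(faces):
                    raise ValueError(f"scalar {name!r} length mismatch")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write(f"{x:.6g}\n")


def write_ply_surface(shape: AxisymShape, path, n_phi: int = 48):
    """ASCII PLY export of the revolved surface (via trimesh)."""
    import trimesh

    verts, quads = _revolve(shape, n_phi)
    tris = np.vstack([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]])
    mesh = trimesh.Trimesh(vertices=verts, faces=tris, process=False)
    Path(path).write_bytes(mesh.export(file_type="ply", encoding="ascii"))


def patch_counts_to_tsv(mesh: SurfaceMesh, state: SpeciesState, path,
                        header: dict | None = None):
    write_tsv(path, {
        "patch": np.arange(mesh.n_patches),
        "band": mesh.band_of,
        "s_mid": mesh.s_mid,
        "phi_mid": mesh.phi_mid,
        "area": mesh.area,
        "n_GDP": state.n_GDP,
        "n_GTP": state.n_GTP,
        "n_cable": state.n_cable,
    }, {**(header or {}), "N_cyt": state.N_cyt, "N_mono": state.N_mono})


def write_manifest(path, parameters: dict, seed=None):
    """Machine-readable run manifest (parameters, seed, versions)."""
    from . import __version__

    doc = {
        "package": "shmoo",
        "version": __version__,
        "python": sys.version.split()[0],
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "parameters": parameters,
        "formats": {"tsv": 1, "trajectory_hdf5": 1, "vtk": "legacy-3.0", "ply": 1},
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return doc
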