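"""Mesh and solution serialisation: Gmsh MSH v2.2 ASCII and VTK legacy.

Both formats are written and parsed directly (line-oriented ASCII).  MSH
physical volumes carry the tissue labels and physical surfaces the named
boundary patches; VTK unstructured grids carry tissue labels as cell data
and optionally a nodal potential (point data) and per-element field
(cell vectors).
"""
from __future__ import annotations

import json
from typing import Dict, Optional

import numpy as np

from .meshing import VolumeMesh

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtk",
    "read_vtk",
    "write_solution_vtk",
]

_PATCH_TAG_OFFSET = 1000


def write_msh(mesh: VolumeMesh, path: str) -> None:
    """Gmsh MSH 2.2 ASCII: tets as physical volumes, patches as surfaces."""
    labels = sorted({int(c) for c in np.unique(mesh.tet_labels)})
    patch_names = sorted(mesh.boundary_patches)
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n")
        f.write(f"{len(labels) + len(patch_names)}\n")
        for c in labels:
            f.write(f'3 {c + 1} "{mesh.label_names[int(c)]}"\n')
        for i, name in enumerate(patch_names):
            f.write(f'2 {_PATCH_TAG_OFFSET + i} "{name}"\n')
        f.write("$EndPhysicalNames\n")
        f.write("$Nodes\n")
        f.write(f"{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.16g} {y:.16g} {z:.16g}\n")
        f.write("$EndNodes\n")
        n_tri = sum(len(v) for v in mesh.boundary_patches.values())
        f.write("$Elements\n")
        f.write(f"{mesh.n_tets + n_tri}\n")
        eid = 1
        for i, name in enumerate(patch_names):
            tag = _PATCH_TAG_OFFSET + i
            for tri in np.asarray(mesh.boundary_patches[name]):
                a, b, c = (int(v) + 1 for v in tri)
                f.write(f"{eid} 2 2 {tag} {tag} {a} {b} {c}\n")
                eid += 1
        for tet, lab in zip(mesh.tets, mesh.tet_labels):
            a, b, c, d = (int(v) + 1 for v in tet)
            f.write(f"{eid} 4 2 {int(lab) + 1} {int(lab) + 1} {a} {b} {c} {d}\n")
            eid += 1
        f.write("$EndElements\n")


def read_msh(path: str) -> VolumeMesh:
    """Parse a Gmsh MSH 2.2 ASCII file written by :func:`write_msh`.

    Also accepts generic MSH 2.2 files with tetrahedral physical volumes;
    physical surfaces become boundary patches.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0

    def find(tag):
        nonlocal i
        while i < len(lines) and lines[i].strip() != tag:
            i += 1
        if i == len(lines):
            raise ValueError(f"section {tag} not found in {path}")
        i += 1

    phys_vol: Dict[int, str] = {}
    phys_surf: Dict[int, str] = {}
    if any(l.strip() == "$PhysicalNames" for l in lines):
        find("$PhysicalNames")
        n = int(lines[i]); i += 1
        for k in range(n):
            parts = lines[i + k].split(maxsplit=2)
            dim, tag = int(parts[0]), int(parts[1])
            name = parts[2].strip().strip('"')
            (phys_vol if dim == 3 else phys_surf)[tag] = name
        i += n
    i = 0
    find("$Nodes")
    n_nodes = int(lines[i]); i += 1
    nodes = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        parts = lines[i + k].split()
        nodes[int(parts[0]) - 1] = [float(parts[1]), float(parts[2]),
                                    float(parts[3])]
    i += n_nodes
    find("$Elements")
    n_el = int(lines[i]); i += 1
    tets, labs = [], []
    patches: Dict[str, list] = {}
    for k in range(n_el):
        parts = [int(p) for p in lines[i + k].split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3:3 + ntags]
        conn = [v - 1 for v in parts[3 + ntags:]]
        phys = tags[0] if tags else 0
        if etype == 4:
            tets.append(conn)
            labs.append(phys - 1 if phys - 1 >= 0 else 0)
        elif etype == 2:
            name = phys_surf.get(phys, f"patch_{phys}")
            patches.setdefault(name, []).append(conn)
    label_names = {tag - 1: name for tag, name in phys_vol.items()}
    if not label_names:
        label_names = {int(c): f"tissue_{c}" for c in set(labs)}
    return VolumeMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int32),
        tet_labels=np.asarray(labs, dtype=np.int16),
        label_names=label_names,
        boundary_patches={k: np.asarray(v, dtype=np.int64)
                          for k, v in patches.items()},
        provenance={"kind": "user_mesh", "source": path, "format": "msh2"},
    )


def write_vtk(mesh: VolumeMesh, path: str,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """VTK legacy ASCII unstructured grid with tissue labels as cell data."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("ocufield unstructured mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            f.write(f"{x:.16g} {y:.16g} {z:.16g}\n")
        f.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        for tet in mesh.tets:
            f.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        f.write("\n".join(["10"] * mesh.n_tets) + "\n")

        f.write(f"CELL_DATA {mesh.n_tets}\n")
        f.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(c)) for c in mesh.tet_labels) + "\n")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                f.write(f"VECTORS {name} double\n")
                for v in arr:
                    f.write(f"{v[0]:.16g} {v[1]:.16g} {v[2]:.16g}\n")
            else:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.16g}" for v in arr) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.16g}" for v in np.asarray(arr)) + "\n")
        # label names as a trailing comment for round-tripping
        f.write("# label_names " + json.dumps(
            {str(k): v for k, v in mesh.label_names.items()}) + "\n")


def read_vtk(path: str) -> VolumeMesh:
    """Parse a VTK legacy ASCII unstructured grid (tets only)."""
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0
    nodes = None
    tets = None
    labels = None
    label_names = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            nodes = np.asarray(vals).reshape(n, 3)
            continue
        if line.startswith("CELLS"):
            n = int(line.split()[1])
            rows = []
            i += 1
            for k in range(n):
                parts = [int(v) for v in lines[i + k].split()]
                if parts[0] != 4:
                    raise ValueError("only tetrahedral cells supported")
                rows.append(parts[1:])
            tets = np.asarray(rows, dtype=np.int32)
            i += n
            continue
        if line.startswith("SCALARS tissue"):
            i += 2                      # skip LOOKUP_TABLE
            vals = []
            while len(vals) < len(tets):
                vals.extend(int(v) for v in lines[i].split())
                i += 1
            labels = np.asarray(vals, dtype=np.int16)
            continue
        if line.startswith("# label_names"):
            label_names = {int(k): v for k, v in
                           json.loads(line.split("label_names", 1)[1]).items()}
        i += 1
    if nodes is None or tets is None:
        raise ValueError(f"{path} is not a VTK unstructured grid")
    if labels is None:
        labels = np.zeros(len(tets), dtype=np.int16)
    if label_names is None:
        label_names = {int(c): f"tissue_{c}" for c in np.unique(labels)}
    return VolumeMesh(nodes=nodes, tets=tets, tet_labels=labels,
                      label_names=label_names,
                      provenance={"kind": "user_mesh", "source": path,
                                  "format": "vtk"})


def write_solution_vtk(mesh: VolumeMesh, path: str, phi: np.ndarray,
                       field: np.ndarray,
                       sidecar: Optional[Dict] = None) -> None:
    """Solution dump: potential as point data, field as cell vectors.

    When ``sidecar`` is given, a JSON file with delivered current and
    solver diagnostics is written next to the VTK file.
    """
    norm = np.linalg.norm(field, axis=1)
    write_vtk(mesh, path, point_data={"phi_V": phi},
              cell_data={"E_V_per_m": field, "E_norm_V_per_m": norm})
    if sidecar is not None:
        with open(path + ".json", "w") as f:
            json.dump(sidecar, f, indent=2, default=_js)


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")
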