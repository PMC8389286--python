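"""Synthetic labeled tetrahedral head and validation geometries.

The head model is a five-layer concentric sphere (white matter, gray matter,
CSF, bone, skin, listed by outer radius) with two embedded eyeball spheres
near the anterior surface.  A cylindrical plug of tissue in front of each
eye is carved out so the anterior eye cap (the cornea region) borders air,
like the real eye opening: the facial skin ends at the lid margins and
periocular currents are funnelled into the exposed conductive eye surface
rather than bypassing it.  ``exposure_fraction`` sets the radius of the
carved channel as a fraction of the eye radius.

Coordinate convention: origin at the head centre, +y anterior (out of the
face), +z superior, +x toward the right-eye side.  Coordinates are in mm.

Meshing strategy: deterministic point sampling (a jittered body-centred
lattice plus ring-sampled points on every tissue interface sphere) followed
by a Delaunay tetrahedralisation; elements are labeled by centroid
membership in the implicit geometry and elements outside the domain are
discarded.  Identical parameters and seed reproduce the mesh byte for byte.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .tissues import TISSUES, ConductivityTable, default_conductivities

__all__ = [
    "HeadGeometryParams",
    "VolumeMesh",
    "MeshValidationReport",
    "generate_layered_head",
    "generate_homogeneous_box",
    "validate_mesh",
    "sample_sphere_points",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric parameters."""


@dataclass(frozen=True)
class HeadGeometryParams:
    """Parameters of the synthetic layered head.

    ``layer_radii`` are the outer radii (mm) of white matter, gray matter,
    CSF, bone and skin, strictly increasing.  ``eye_center_offsets`` places
    the two eyeball centres relative to the head centre; the defaults put
    the eye surfaces at anatomically plausible anterior positions (the
    whole geometry is a synthetic stand-in, not an MRI-derived head).
    """

    layer_radii: Tuple[float, ...] = (74.0, 78.0, 80.0, 82.0, 85.0)
    eye_radius: float = 12.0
    eye_center_offsets: Tuple[Tuple[float, float, float], ...] = (
        (31.0, 65.0, 5.0), (-31.0, 65.0, 5.0))
    target_edge_length: float = 6.0
    seed: int = 0
    #: radius of the carved exposure channel in front of each eye (the
    #: cornea opening), as a fraction of the eye radius.
    exposure_fraction: float = 0.75

    def validate(self) -> None:
        r = np.asarray(self.layer_radii, dtype=float)
        if len(r) != 5 or np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise GeometryError(
                f"layer_radii must be 5 strictly increasing positive values, got {self.layer_radii}")
        if not self.eye_radius > 0:
            raise GeometryError(f"eye_radius must be > 0, got {self.eye_radius}")
        if not self.target_edge_length > 0:
            raise GeometryError("target_edge_length must be > 0")
        centers = np.asarray(self.eye_center_offsets, dtype=float)
        if centers.shape != (2, 3):
            raise GeometryError("eye_center_offsets must be two 3-vectors")
        gap = np.linalg.norm(centers[0] - centers[1])
        if gap <= 2 * self.eye_radius:
            raise GeometryError(
                f"eye spheres overlap: centre distance {gap:.1f} <= 2*r={2*self.eye_radius:.1f}")
        bone_r, skin_r = r[3], r[4]
        for c in centers:
            reach = np.linalg.norm(c) + self.eye_radius
            if reach <= bone_r:
                raise GeometryError(
                    f"eye at {tuple(c)} does not reach the skin layer (reach {reach:.1f} <= {bone_r})")
            if reach > skin_r + 1e-9:
                raise GeometryError(
                    f"eye at {tuple(c)} pokes out of the head (reach {reach:.1f} > {skin_r})")

    @property
    def skin_radius(self) -> float:
        return float(self.layer_radii[-1])


@dataclass
class VolumeMesh:
    """Discretised domain: nodes, tetrahedra, tissue labels, tagged boundary.

    ``tet_labels`` holds integer codes resolved through ``label_names``;
    ``boundary_patches`` maps a patch name to an (F, 3) array of node
    triples that are a subset of the exterior surface.
    """

    nodes: np.ndarray           # (N, 3) float64, mm
    tets: np.ndarray            # (M, 4) int32
    tet_labels: np.ndarray      # (M,) int16
    label_names: Dict[int, str]
    boundary_patches: Dict[str, np.ndarray] = field(default_factory=dict)
    provenance: Dict = field(default_factory=dict)

    _exterior_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tissue_names(self) -> set:
        return {self.label_names[c] for c in np.unique(self.tet_labels)}

    def tet_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes in mm^3."""
        p = self.nodes
        t = self.tets
        a = p[t[:, 1]] - p[t[:, 0]]
        b = p[t[:, 2]] - p[t[:, 0]]
        c = p[t[:, 3]] - p[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def exterior_faces(self) -> Tuple[np.ndarray, np.ndarray]:
        """(faces, adjacent_tet): triangles on the exterior surface.

        Faces are returned with their node triples sorted ascending; the
        second array gives the index of the single adjacent tetrahedron.
        """
        if self._exterior_cache is None:
            faces = self.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
            faces = faces.reshape(-1, 3)
            owner = np.repeat(np.arange(self.n_tets), 4)
            key = np.sort(faces, axis=1)
            _, first, counts = np.unique(
                key, axis=0, return_index=True, return_counts=True)
            ext = first[counts == 1]
            self._exterior_cache = (key[ext], owner[ext])
        return self._exterior_cache

    def exterior_nodes(self) -> np.ndarray:
        faces, _ = self.exterior_faces()
        return np.unique(faces)

    def patch_nodes(self, name: str) -> np.ndarray:
        return np.unique(self.boundary_patches[name])

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.tets).tobytes())
        h.update(np.ascontiguousarray(self.tet_labels).tobytes())
        for name in sorted(self.boundary_patches):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.boundary_patches[name]).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# point sampling helpers

def sample_sphere_points(radius: float, spacing: float) -> np.ndarray:
    """Deterministic quasi-uniform sphere sampling, mirror-symmetric in x.

    Latitude bands at polar spacing ~``spacing``; each ring carries an even
    number of points starting at azimuth 0 (the +y meridian), which makes
    the set exactly symmetric under x -> -x.
    """
    n_theta = max(3, int(round(np.pi * radius / spacing)))
    pts = [(0.0, 0.0, radius), (0.0, 0.0, -radius)]
    for i in range(1, n_theta):
        theta = np.pi * i / n_theta
        rho = radius * np.sin(theta)
        z = radius * np.cos(theta)
        n_phi = max(1, int(round(2 * np.pi * rho / spacing)))
        if n_phi > 1 and n_phi % 2:
            n_phi += 1
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        x = rho * np.sin(phi)
        y = rho * np.cos(phi)
        pts.extend(zip(x, y, np.full(n_phi, z)))
    return np.asarray(pts, dtype=float)


def _lattice(bounds_lo, bounds_hi, h) -> np.ndarray:
    """Axis-aligned lattice with a node at the origin (symmetric in x)."""
    axes = []
    for lo, hi in zip(bounds_lo, bounds_hi):
        n_lo = int(np.floor(lo / h))
        n_hi = int(np.ceil(hi / h))
        axes.append(h * np.arange(n_lo, n_hi + 1))
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


# ---------------------------------------------------------------------------
# head generator

def generate_layered_head(params: HeadGeometryParams | None = None) -> VolumeMesh:
    """Generate the labeled synthetic head mesh.

    Deterministic for fixed parameters and seed.  The resulting mesh carries
    exactly the six tissue labels of the default conductivity table and a
    ``scalp`` boundary patch covering the whole exterior surface.
    """
    params = params or HeadGeometryParams()
    params.validate()
    h = params.target_edge_length
    radii = np.asarray(params.layer_radii, dtype=float)
    R = radii[-1]
    eye_r = params.eye_radius
    centers = np.asarray(params.eye_center_offsets, dtype=float)
    eye_h = min(h / 2.0, 1.5)

    # --- interior lattice, refined near the eyes -------------------------
    base = _lattice([-R] * 3, [R] * 3, h)
    rad = np.linalg.norm(base, axis=1)
    keep = rad <= R - 0.45 * h
    # avoid slivers against the sampled interface spheres
    for rk in radii:
        keep &= np.abs(rad - rk) > 0.35 * h
    # defer the eye neighbourhood to the fine lattice
    margin = eye_r + 1.5 * h
    near_eye = np.zeros(len(base), dtype=bool)
    for c in centers:
        near_eye |= np.all(np.abs(base - c) <= margin, axis=1)
    pts = [base[keep & ~near_eye]]

    fine_h = min(h / 2.0, 2.5)
    for c in centers:
        fine = _lattice(c - margin, c + margin, fine_h)
        inbox = np.all(np.abs(fine - c) <= margin, axis=1)
        fine = fine[inbox]
        frad = np.linalg.norm(fine, axis=1)
        fkeep = frad <= R - 0.45 * h
        d_eye = np.linalg.norm(fine - c, axis=1)
        fkeep &= np.abs(d_eye - eye_r) > 0.35 * eye_h
        for rk in radii:
            fkeep &= np.abs(frad - rk) > 0.3 * fine_h
        pts.append(fine[fkeep])

    # --- interface samples ----------------------------------------------
    for rk in radii:
        s = sample_sphere_points(rk, h)
        ok = np.ones(len(s), dtype=bool)
        for c in centers:
            d = np.linalg.norm(s - c, axis=1)
            ok &= d > eye_r + 0.35 * eye_h   # keep clear of the eye surface
        s = s[ok]
        pts.append(s)
    for c in centers:
        pts.append(c + sample_sphere_points(eye_r, eye_h))

    points = np.vstack(pts)

    # deterministic jitter breaks lattice/cospherical degeneracies
    rng = np.random.default_rng(params.seed)
    points = points + rng.uniform(-0.03 * h, 0.03 * h, size=points.shape)

    tri = Delaunay(points)
    tets = tri.simplices.astype(np.int64)
    cent = points[tets].mean(axis=1)
    crad = np.linalg.norm(cent, axis=1)

    labels = np.full(len(tets), -1, dtype=np.int16)
    eye_code = TISSUES.index("eyeball")
    in_eye = np.zeros(len(tets), dtype=bool)
    for c in centers:
        in_eye |= np.linalg.norm(cent - c, axis=1) <= eye_r
    labels[in_eye] = eye_code

    # Carve the exposure channel in front of each eye: the tissue plug
    # between the anterior eye cap and the outer surface is removed so the
    # cap (cornea region) borders air.  This reproduces the anatomy of the
    # eye opening, where the facial skin ends at the lid margins and
    # periocular surface currents are funnelled into the conductive eye
    # surface instead of bypassing it through a (non-existent) skin film.
    drop = crad > R + 0.2
    plug_r = params.exposure_fraction * eye_r
    for c in centers:
        axis = c / np.linalg.norm(c)
        rel = cent - c
        ax = rel @ axis
        perp = np.linalg.norm(rel - ax[:, None] * axis, axis=1)
        drop |= (~in_eye) & (ax > 0) & (perp < plug_r)

    shell = ~in_eye & ~drop
    bin_idx = np.searchsorted(radii, crad[shell])
    bin_idx = np.minimum(bin_idx, 4)
    labels[shell] = bin_idx.astype(np.int16)

    keep_t = _repair_pinches(points, tets, ~drop)
    # label any tets restored by the repair pass (former plug elements)
    unlabeled = keep_t & (labels < 0)
    if np.any(unlabeled):
        bi = np.minimum(np.searchsorted(radii, crad[unlabeled]), 4)
        labels[unlabeled] = bi.astype(np.int16)
    tets, labels = tets[keep_t], labels[keep_t]

    # fix orientation, compact node numbering
    mesh = _finalise(points, tets, labels,
                     {i: name for i, name in enumerate(TISSUES)})
    faces, _ = mesh.exterior_faces()
    mesh.boundary_patches["scalp"] = faces
    mesh.provenance = {
        "kind": "synthetic_layered_head",
        "synthetic": True,
        "params": {
            "layer_radii": tuple(float(r) for r in params.layer_radii),
            "eye_radius": float(params.eye_radius),
            "eye_center_offsets": tuple(tuple(float(v) for v in c)
                                        for c in params.eye_center_offsets),
            "target_edge_length": float(params.target_edge_length),
            "seed": int(params.seed),
            "exposure_fraction": float(params.exposure_fraction),
        },
    }
    return mesh


def _repair_pinches(points, tets, keep, max_rounds: int = 25) -> np.ndarray:
    """Make the boundary of the kept-tet set edge-manifold.

    Centroid-based carving can leave 'pinches': exterior edges shared by
    four boundary faces where two surface sheets touch.  Each round re-adds
    the largest dropped tetrahedron incident to a pinched edge (slightly
    narrowing the carve there); if none exists the smallest kept incident
    tet is dropped instead.  Returns the updated keep mask.
    """
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    keep = keep.copy()

    for _ in range(max_rounds):
        kt = tets[keep]
        faces = kt[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, first, counts = np.unique(key, axis=0, return_index=True,
                                     return_counts=True)
        ext = key[first[counts == 1]]
        edges = np.sort(ext[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1)
        ue, ec = np.unique(edges, axis=0, return_counts=True)
        bad = ue[ec != 2]
        if len(bad) == 0:
            return keep
        for n0, n1 in bad:
            has_both = ((tets == n0).any(axis=1) & (tets == n1).any(axis=1))
            cand = np.flatnonzero(has_both & ~keep)
            if cand.size:
                keep[cand[np.argmax(vols[cand])]] = True
            else:
                inc = np.flatnonzero(has_both & keep)
                if inc.size:
                    keep[inc[np.argmin(vols[inc])]] = False
    return keep


def _finalise(points, tets, labels, label_names) -> VolumeMesh:
    """Orient tets positively, drop unused nodes, renumber deterministically."""
    p = points
    a = p[tets[:, 1]] - p[tets[:, 0]]
    b = p[tets[:, 2]] - p[tets[:, 0]]
    c = p[tets[:, 3]] - p[tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c))
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]

    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return VolumeMesh(
        nodes=np.ascontiguousarray(points[used]),
        tets=np.ascontiguousarray(remap[tets].astype(np.int32)),
        tet_labels=np.ascontiguousarray(labels),
        label_names=dict(label_names),
    )


# ---------------------------------------------------------------------------
# box generator (oracle geometry)

_KUHN = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
         (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]


def generate_homogeneous_box(edge_mm: float, sigma: float,
                             target_edge_length: float,
                             label: str = "medium",
                             mirror_x: bool = False) -> VolumeMesh:
    """Single-tissue box mesh, exact Kuhn tessellation, all faces tagged.

    The box is centred at the origin.  With ``mirror_x`` the tessellation is
    built on the half-domain x >= 0 and reflected, so the mesh (nodes and
    connectivity) is exactly symmetric under x -> -x; this supports discrete
    symmetry tests at solver tolerance.
    """
    if not edge_mm > 0:
        raise GeometryError(f"edge_mm must be > 0, got {edge_mm}")
    if not sigma > 0:
        raise GeometryError(f"sigma must be > 0, got {sigma}")
    n = max(1, int(round(edge_mm / target_edge_length)))
    if mirror_x and n % 2:
        n += 1
    h = edge_mm / n
    ax = -edge_mm / 2 + h * np.arange(n + 1)

    if not mirror_x:
        nodes, tets = _kuhn_grid(ax, ax, ax)
    else:
        half = ax[n // 2:]          # x in [0, L/2]
        nodes_h, tets_h = _kuhn_grid(half, ax, ax)
        nodes, tets = _mirror_x(nodes_h, tets_h)

    labels = np.zeros(len(tets), dtype=np.int16)
    mesh = _finalise(nodes, tets, labels, {0: label})
    faces, _ = mesh.exterior_faces()
    mesh.boundary_patches["all"] = faces
    fc = mesh.nodes[faces].mean(axis=1)
    tol = 1e-9 * edge_mm
    for axis_i, name in ((0, "x"), (1, "y"), (2, "z")):
        mesh.boundary_patches[f"{name}_min"] = faces[
            np.abs(fc[:, axis_i] + edge_mm / 2) < tol]
        mesh.boundary_patches[f"{name}_max"] = faces[
            np.abs(fc[:, axis_i] - edge_mm / 2) < tol]
    mesh.provenance = {
        "kind": "homogeneous_box", "synthetic": True,
        "edge_mm": float(edge_mm), "sigma": float(sigma),
        "target_edge_length": float(h), "label": label,
        "mirror_x": bool(mirror_x),
    }
    return mesh


def _kuhn_grid(ax_x, ax_y, ax_z):
    nx, ny, nz = len(ax_x), len(ax_y), len(ax_z)
    g = np.meshgrid(ax_x, ax_y, ax_z, indexing="ij")
    nodes = np.stack([a.ravel() for a in g], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack([nid(i + di, j + dj, k + dk)
                        for di in (0, 1) for dj in (0, 1) for dk in (0, 1)],
                       axis=1)  # bit order (di,dj,dk) -> index di*4+dj*2+dk
    tets = np.concatenate([corners[:, list(t)] for t in _KUHN], axis=0)
    return nodes, tets.astype(np.int64)


def _mirror_x(nodes, tets):
    """Reflect a half-domain mesh (x >= 0) through the x = 0 plane."""
    on_plane = np.abs(nodes[:, 0]) < 1e-12
    n = len(nodes)
    new_idx = -np.ones(n, dtype=np.int64)
    off = ~on_plane
    new_idx[on_plane] = np.flatnonzero(on_plane)
    new_idx[off] = n + np.arange(off.sum())
    mirrored_nodes = nodes[off] * np.array([-1.0, 1.0, 1.0])
    all_nodes = np.vstack([nodes, mirrored_nodes])
    mirrored_tets = new_idx[tets][:, [0, 2, 1, 3]]  # parity fix
    return all_nodes, np.vstack([tets, mirrored_tets])


# ---------------------------------------------------------------------------
# validation

@dataclass
class MeshValidationReport:
    checks: Dict[str, bool]
    details: Dict[str, str]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def __repr__(self) -> str:  # pragma: no cover
        lines = [f"  {'PASS' if ok else 'FAIL'} {k}: {self.details.get(k, '')}"
                 for k, ok in self.checks.items()]
        return "MeshValidationReport(\n" + "\n".join(lines) + "\n)"


def validate_mesh(mesh: VolumeMesh,
                  sigma: ConductivityTable | None = None) -> MeshValidationReport:
    """Report-only checks of the mesh invariants.

    Checks: positive signed volumes, label coverage in the conductivity
    table, watertight exterior surface, boundary patches on the exterior,
    and pairwise disjointness of electrode patches.
    """
    sigma = sigma or default_conductivities()
    checks: Dict[str, bool] = {}
    details: Dict[str, str] = {}

    vols = mesh.tet_volumes()
    n_bad = int(np.sum(vols <= 0))
    checks["positive_volume"] = n_bad == 0
    details["positive_volume"] = f"{n_bad} non-positive of {len(vols)}"

    names = mesh.tissue_names()
    missing = sorted(n for n in names if n not in sigma)
    checks["label_coverage"] = not missing
    details["label_coverage"] = (f"labels missing from table: {missing}"
                                 if missing else f"labels {sorted(names)} all covered")

    faces, _ = mesh.exterior_faces()
    edges = np.sort(faces[:, [[0, 1], [1, 2], [0, 2]]].reshape(-1, 2), axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    watertight = bool(np.all(counts == 2))
    checks["watertight_exterior"] = watertight
    details["watertight_exterior"] = (
        "every exterior edge shared by exactly 2 exterior faces" if watertight
        else f"edge face-counts range {counts.min()}..{counts.max()}")

    ext = {tuple(f) for f in faces}
    on_ext = True
    for name, patch in mesh.boundary_patches.items():
        if not all(tuple(sorted(f)) in ext for f in np.asarray(patch)):
            on_ext = False
            details.setdefault("patches_on_exterior",
                               f"patch {name!r} has non-exterior faces")
    checks["patches_on_exterior"] = on_ext
    details.setdefault("patches_on_exterior", "all patches on exterior surface")

    elec = {k: np.unique(v) for k, v in mesh.boundary_patches.items()
            if k.startswith("electrode")}
    overlap = []
    keys = sorted(elec)
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            if np.intersect1d(elec[keys[a]], elec[keys[b]]).size:
                overlap.append((keys[a], keys[b]))
    checks["electrode_patch_disjointness"] = not overlap
    details["electrode_patch_disjointness"] = (
        f"overlapping pairs: {overlap}" if overlap
        else f"{len(keys)} electrode patches pairwise disjoint")

    return MeshValidationReport(checks=checks, details=details)
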