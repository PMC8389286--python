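"""Electrode montages and multichannel superposition.

A stimulation channel is one forehead/cheek electrode pair with a current
(mA) and a phase (degrees); a montage is one or two channels.  On the
synthetic head, electrode stations are parametric: azimuth (degrees from
the +y anterior axis toward +x, i.e. toward the right) and elevation above
the horizontal plane, scaled to the scalp radius.  The station angles
follow the facial layout of the reference placements (three forehead
stations per side from temporal to nasal plus a far-temporal station, and
two cheek stations per side), spread just enough that the 42 mm square
patches never overlap on the 85 mm scalp.

Phases are handled generally via in-phase/quadrature components; the
surveyed conditions use 0 (same phase: forehead anode, cheek cathode) and
180 degrees (anti-phase: the channel polarity is reversed).  The reported
scalar is the peak-over-cycle field norm, which for 0/180 phases reduces
to the norm of the signed sum of the channel fields.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .fem import ChannelUnitSolution, MontageError
from .meshing import VolumeMesh

__all__ = [
    "ElectrodePatch",
    "StimulationChannel",
    "Montage",
    "CombinedField",
    "SurfacePatch",
    "STATIONS",
    "project_patch_to_scalp",
    "build_study_montages",
    "apply_phase_condition",
    "superpose",
    "validate_montage",
]

DEFAULT_EDGE_MM = 42.0

#: Parametric scalp stations: name -> (azimuth_deg, elevation_deg).
#: Right-side stations have positive azimuth; "F" = forehead, "C" = cheek.
STATIONS: Dict[str, Tuple[float, float]] = {
    "F_temporal_far_R": (48.0, 17.0), "F_temporal_far_L": (-48.0, 17.0),
    "F_oe_temporal_R": (56.0, 20.0),  "F_oe_temporal_L": (-56.0, 20.0),
    "F_temporal_R": (39.0, 20.0),     "F_temporal_L": (-39.0, 20.0),
    "F_mid_R": (28.0, 20.0),          "F_mid_L": (-28.0, 20.0),
    "F_nasal_R": (18.0, 20.0),        "F_nasal_L": (-18.0, 20.0),
    "C_R": (30.0, -22.0),             "C_L": (-30.0, -22.0),
    "C_low_R": (48.0, -56.0),         "C_low_L": (-48.0, -56.0),
}


def station_direction(name: str) -> np.ndarray:
    az, el = STATIONS[name]
    az, el = math.radians(az), math.radians(el)
    return np.array([math.cos(el) * math.sin(az),
                     math.cos(el) * math.cos(az),
                     math.sin(el)])


@dataclass(frozen=True)
class ElectrodePatch:
    """Square scalp electrode: centre (mm), edge length (default 42 mm)."""

    center: Tuple[float, float, float]
    edge_length: float = DEFAULT_EDGE_MM
    station: str | None = None

    def __post_init__(self):
        if not self.edge_length > 0:
            raise MontageError("edge_length must be > 0")

    @classmethod
    def at_station(cls, name: str, scalp_radius: float,
                   edge_length: float = DEFAULT_EDGE_MM) -> "ElectrodePatch":
        c = scalp_radius * station_direction(name)
        return cls(center=tuple(float(v) for v in c),
                   edge_length=edge_length, station=name)


@dataclass(frozen=True)
class StimulationChannel:
    forehead: ElectrodePatch
    cheek: ElectrodePatch
    current_mA: float = 1.0
    phase_deg: float = 0.0
    channel_id: str = ""

    def __post_init__(self):
        if not self.current_mA > 0:
            raise MontageError("current must be > 0 mA")

    @property
    def on_right_side(self) -> bool:
        return self.forehead.center[0] > 0


@dataclass(frozen=True)
class Montage:
    id: str
    channels: Tuple[StimulationChannel, ...]
    annotation: str = ""
    constituents: Tuple[str, ...] = ()

    def __post_init__(self):
        if not 1 <= len(self.channels):
            raise MontageError("montage needs at least one channel")


@dataclass
class SurfacePatch:
    """Projection of an electrode patch onto the meshed exterior surface."""

    name: str
    triangles: np.ndarray       # (F, 3) node triples
    nodes: np.ndarray           # unique node indices
    center: np.ndarray          # projected centre, mm
    area_mm2: float


@dataclass
class CombinedField:
    """Superposed stimulation field in quadrature form.

    ``inphase`` and ``quadrature`` are the cos/sin phasor components of the
    per-element field; ``peak_norm`` is the peak-over-cycle magnitude
    (square root of the largest eigenvalue of the 2x2 Gram matrix of the
    two components).  With all phases in {0, 180} the quadrature component
    is identically zero and the peak norm is the plain Euclidean norm of
    the signed current-weighted sum.
    """

    inphase: np.ndarray         # (M, 3) V/m
    quadrature: np.ndarray      # (M, 3) V/m
    montage_id: str = ""
    condition: str = ""

    @property
    def peak_norm(self) -> np.ndarray:
        g11 = np.einsum("ij,ij->i", self.inphase, self.inphase)
        g22 = np.einsum("ij,ij->i", self.quadrature, self.quadrature)
        if not g22.any():
            return np.sqrt(g11)
        g12 = np.einsum("ij,ij->i", self.inphase, self.quadrature)
        half_tr = 0.5 * (g11 + g22)
        disc = np.sqrt((0.5 * (g11 - g22)) ** 2 + g12 ** 2)
        return np.sqrt(half_tr + disc)


# ---------------------------------------------------------------------------
# patch projection

def project_patch_to_scalp(mesh: VolumeMesh, patch: ElectrodePatch,
                           name: str = "electrode",
                           register: bool = False) -> SurfacePatch:
    """Select the exterior surface region approximating the square patch.

    The patch centre is projected onto the nearest exterior point; exterior
    triangles whose centroids fall inside the square (measured in geodesic
    tangent coordinates around the projected centre) are selected.  On the
    head mesh, selection is restricted to outer-scalp skin so the contact
    region never creeps onto the exposed eye surface or into the carved
    exposure channel.
    """
    faces, owner = mesh.exterior_faces()
    fc = mesh.nodes[faces].mean(axis=1)

    candidate = np.ones(len(faces), dtype=bool)
    prov = mesh.provenance or {}
    if prov.get("kind") == "synthetic_layered_head":
        skin_code = {v: k for k, v in mesh.label_names.items()}["skin"]
        R = prov["params"]["layer_radii"][-1]
        candidate &= (mesh.tet_labels[owner] == skin_code)
        candidate &= np.linalg.norm(fc, axis=1) >= 0.97 * R

    center = np.asarray(patch.center, dtype=float)
    cand_idx = np.flatnonzero(candidate)
    if cand_idx.size == 0:
        raise MontageError("mesh exposes no electrode-capable surface")
    d = np.linalg.norm(fc[cand_idx] - center, axis=1)
    nearest = cand_idx[np.argmin(d)]
    if d.min() > 30.0:
        raise MontageError(
            f"patch centre {tuple(center)} is {d.min():.1f} mm from the "
            "surface (limit 30 mm)")
    proj_center = fc[nearest]

    n = proj_center / np.linalg.norm(proj_center)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(n, ref)) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    R_loc = np.linalg.norm(proj_center)

    def geodesic_uv(points):
        qn = points / np.linalg.norm(points, axis=1, keepdims=True)
        cosang = np.clip(qn @ n, -1.0, 1.0)
        ang = np.arccos(cosang)
        tang = qn - cosang[:, None] * n
        tnorm = np.linalg.norm(tang, axis=1)
        tnorm[tnorm == 0] = 1.0
        tdir = tang / tnorm[:, None]
        return R_loc * ang * (tdir @ u), R_loc * ang * (tdir @ v)

    # Select triangles with all three vertices inside the square.  The
    # square is expanded by a third of the local surface edge length, which
    # compensates the boundary ring the all-vertex rule would otherwise
    # shave off while keeping neighbouring patches node-disjoint.
    cand_tris = faces[cand_idx]
    p_all = mesh.nodes
    e01 = np.linalg.norm(p_all[cand_tris[:, 1]] - p_all[cand_tris[:, 0]], axis=1)
    half = patch.edge_length / 2.0 + float(np.mean(e01)) / 3.0
    vert_uv = geodesic_uv(p_all[cand_tris.reshape(-1)])
    in_u = np.abs(vert_uv[0]).reshape(-1, 3)
    in_v = np.abs(vert_uv[1]).reshape(-1, 3)
    inside = np.all((in_u <= half) & (in_v <= half), axis=1)
    sel = cand_idx[inside]
    if sel.size == 0:
        raise MontageError(
            f"patch at {tuple(center)} selects no surface triangles "
            "(mesh resolution too coarse?)")
    tris = faces[sel]
    p = mesh.nodes
    areas = 0.5 * np.linalg.norm(
        np.cross(p[tris[:, 1]] - p[tris[:, 0]],
                 p[tris[:, 2]] - p[tris[:, 0]]), axis=1)
    sp = SurfacePatch(name=name, triangles=tris, nodes=np.unique(tris),
                      center=proj_center, area_mm2=float(areas.sum()))
    if register:
        mesh.boundary_patches[name] = tris
    return sp


# ---------------------------------------------------------------------------
# montage families

#: two-pair combinations of the separation sweep: pair id -> (right, left)
SWEEP_PAIRS = {7: (6, 3), 8: (5, 3), 9: (4, 3), 10: (4, 2), 11: (5, 2),
               12: (6, 2), 13: (6, 1), 14: (5, 1), 15: (4, 1)}

_SWEEP_SINGLES = {
    1: ("F_temporal_L", "C_L"), 2: ("F_mid_L", "C_L"), 3: ("F_nasal_L", "C_L"),
    4: ("F_temporal_R", "C_R"), 5: ("F_mid_R", "C_R"), 6: ("F_nasal_R", "C_R"),
}

_INTENDED_SINGLES = {
    "i": ("F_temporal_far_R", "C_R", "Right hand of the visual field"),
    "ii": ("F_nasal_R", "C_low_R", "Central visual field"),
    "iii": ("F_nasal_L", "C_low_L", "Central visual field"),
    "iv": ("F_temporal_far_L", "C_L", "Left hand of the visual field"),
}

_INTENDED_PAIRS = {
    "I": (("i", "iv"), "Right and left hand of the visual field"),
    "II": (("i", "iii"), "Right and center of the visual field"),
    "III": (("ii", "iv"), "Center and left of the visual field"),
}

#: montages whose second measure raises the centre-targeting channel
_CENTER_CHANNEL = {"II": "iii", "III": "ii"}

FAMILIES = ("separation_sweep", "intended_region", "one_eye", "center_boost")


def _channel(station_fh: str, station_ck: str, scalp_radius: float,
             current: float = 1.0, cid: str = "") -> StimulationChannel:
    return StimulationChannel(
        forehead=ElectrodePatch.at_station(station_fh, scalp_radius),
        cheek=ElectrodePatch.at_station(station_ck, scalp_radius),
        current_mA=current, phase_deg=0.0, channel_id=cid)


def build_study_montages(family: str,
                         scalp_radius: float = 85.0) -> List[Montage]:
    """The four montage families of the interference study.

    ``separation_sweep``: 6 single-pair placements (1-3 left, 4-6 right,
    temporal to nasal) and the 9 two-pair combinations 7-15 composed from
    them, with progressively varied forehead separation.
    ``intended_region``: single placements i-iv targeting one visual-field
    direction each and pairs I-III targeting two directions.
    ``one_eye``: both channels on one face side so only that eyeball is
    stimulated.  ``center_boost``: pairs II and III with the
    centre-targeting channel raised to 1.5 mA.
    """
    R = scalp_radius
    if family == "separation_sweep":
        singles = {k: _channel(fh, ck, R, cid=f"ch{k}")
                   for k, (fh, ck) in _SWEEP_SINGLES.items()}
        out = [Montage(id=f"electrode_{k}", channels=(singles[k],),
                       annotation="single pair")
               for k in sorted(singles)]
        for k, (r_id, l_id) in sorted(SWEEP_PAIRS.items()):
            out.append(Montage(
                id=f"electrode_{k}",
                channels=(singles[r_id], singles[l_id]),
                annotation=f"two pairs: composed of electrodes {r_id} and {l_id}",
                constituents=(f"electrode_{r_id}", f"electrode_{l_id}")))
        return out

    if family == "intended_region":
        singles = {k: _channel(fh, ck, R, cid=f"ch_{k}")
                   for k, (fh, ck, _) in _INTENDED_SINGLES.items()}
        out = [Montage(id=k, channels=(singles[k],), annotation=note)
               for k, (_, _, note) in _INTENDED_SINGLES.items()]
        for k, ((a, b), note) in _INTENDED_PAIRS.items():
            out.append(Montage(id=k, channels=(singles[a], singles[b]),
                               annotation=note, constituents=(a, b)))
        return out

    if family == "one_eye":
        # Both channels sit on one face side, so the far-temporal electrode
        # is pushed outward (az 56) to keep the simultaneous 42 mm patches
        # disjoint; the centre-targeting channel reuses the nasal/low-cheek
        # pair of the intended-region family.
        return [
            Montage(id="right_only",
                    channels=(_channel("F_oe_temporal_R", "C_R", R, cid="ch_oe_t_R"),
                              _channel("F_nasal_R", "C_low_R", R, cid="ch_oe_c_R")),
                    annotation="stimulates only the right eyeball "
                               "(right/center direction)"),
            Montage(id="left_only",
                    channels=(_channel("F_nasal_L", "C_low_L", R, cid="ch_oe_c_L"),
                              _channel("F_oe_temporal_L", "C_L", R, cid="ch_oe_t_L")),
                    annotation="stimulates only the left eyeball "
                               "(center/left direction)"),
        ]

    if family == "center_boost":
        out = []
        for pair_id, (ids, note) in _INTENDED_PAIRS.items():
            if pair_id not in _CENTER_CHANNEL:
                continue
            boosted = _CENTER_CHANNEL[pair_id]
            chans = []
            for k in ids:
                fh, ck, _ = _INTENDED_SINGLES[k]
                cur = 1.5 if k == boosted else 1.0
                chans.append(_channel(fh, ck, R, current=cur, cid=f"ch_{k}"))
            out.append(Montage(
                id=f"{pair_id}_boost", channels=tuple(chans),
                annotation=f"{note}; centre channel {boosted} at 1.5 mA",
                constituents=ids))
        return out

    raise ValueError(f"unknown montage family {family!r}; "
                     f"expected one of {FAMILIES}")


def apply_phase_condition(montage: Montage, condition: str) -> Montage:
    """Assign channel phases for the 'same' or 'anti' phase condition.

    Same phase: every forehead electrode is the anode (phase 0).  Anti
    phase: the polarity of the right-side channel is reversed (phase 180);
    for a single-channel montage the one channel is reversed, which leaves
    its norm field unchanged.
    """
    if condition not in ("same", "anti"):
        raise ValueError("phase condition must be 'same' or 'anti'")
    chans = []
    for ch in montage.channels:
        if condition == "anti" and (len(montage.channels) == 1 or ch.on_right_side):
            chans.append(replace(ch, phase_deg=180.0))
        else:
            chans.append(replace(ch, phase_deg=0.0))
    return replace(montage, channels=tuple(chans))


# ---------------------------------------------------------------------------
# superposition

def _phase_factors(phase_deg: float) -> Tuple[float, float]:
    """cos/sin of the phase, exact at multiples of 90 degrees."""
    quarter = phase_deg % 360.0
    table = {0.0: (1.0, 0.0), 90.0: (0.0, 1.0),
             180.0: (-1.0, 0.0), 270.0: (0.0, -1.0)}
    if quarter in table:
        return table[quarter]
    rad = math.radians(phase_deg)
    return math.cos(rad), math.sin(rad)


def superpose(units: Sequence[ChannelUnitSolution],
              channels: Sequence[StimulationChannel],
              montage_id: str = "", condition: str = "") -> CombinedField:
    """Scale and sum per-channel unit fields into one stimulation field.

    in-phase = sum_i I_i cos(theta_i) E_i, quadrature = sum_i I_i
    sin(theta_i) E_i, with I_i in mA against 1 mA unit solutions.
    """
    if len(units) != len(channels):
        raise ValueError(
            f"{len(units)} unit solutions vs {len(channels)} channels")
    if not units:
        raise ValueError("empty superposition")
    shape = units[0].field.shape
    inph = np.zeros(shape)
    quad = np.zeros(shape)
    for u, ch in zip(units, channels):
        if u.field.shape != shape:
            raise ValueError("unit solutions from different meshes")
        c, s = _phase_factors(ch.phase_deg)
        if c != 0.0:
            inph += (ch.current_mA * c) * u.field
        if s != 0.0:
            quad += (ch.current_mA * s) * u.field
    return CombinedField(inphase=inph, quadrature=quad,
                         montage_id=montage_id, condition=condition)


def validate_montage(mesh: VolumeMesh, montage: Montage) -> Dict[str, bool]:
    """Project every patch and check pairwise node-set disjointness."""
    patches = []
    for ch in montage.channels:
        for role, ep in (("fh", ch.forehead), ("ck", ch.cheek)):
            patches.append(project_patch_to_scalp(
                mesh, ep, name=f"{montage.id}_{ch.channel_id}_{role}"))
    ok = True
    for a in range(len(patches)):
        for b in range(a + 1, len(patches)):
            if np.intersect1d(patches[a].nodes, patches[b].nodes).size:
                ok = False
    return {"patches_nonempty": all(p.nodes.size for p in patches),
            "patches_disjoint": ok}
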