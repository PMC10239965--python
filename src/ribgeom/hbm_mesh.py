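"""Extract cortical border contours from shell-element HBM rib meshes.

Finite-element human body models (GHBMC, THUMS, VIVA+) represent rib
cortical bone as shell elements whose nodes form successive circumferential
rings along each rib, with an assigned shell thickness.  This module reads
such rib geometry from a neutral JSON format, reconstructs periosteal and
endosteal borders by offsetting each node ring by the shell thickness, and
measures section properties exactly as for CT-derived contours so the model
can be audited against population corridors.

Neutral ring-mesh JSON::

    {"model": "THUMS M50", "sex": "M", "rib": 6,
     "rings": [{"nodes": [[x, y, z], ...], "thickness": 0.7}, ...]}

``thickness`` is either a scalar (broadcast to all nodes, the THUMS/VIVA+
uniform-0.7 mm convention) or a per-node list (GHBMC-style variable
thickness).  Parsing native LS-DYNA/ABAQUS decks is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .geometry import Contour, ContourError, validate_contour, vertex_normals, \
    batch_composite_properties, SectionProperties
from .rib_model import RibRecord, StationGrid

__all__ = [
    "RingMesh",
    "RING_MESH_SCHEMA",
    "read_ring_mesh",
    "write_ring_mesh",
    "ring_to_borders",
    "hbm_rib_to_record",
    "element_to_node_thickness",
]

NodeSurface = Literal["mid", "outer", "inner"]


class _RingModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nodes: List[Tuple[float, float, float]] = Field(min_length=3)
    thickness: Union[float, List[float]]


class _RingMeshModel(BaseModel):
    """Pydantic schema for the neutral ring-mesh JSON file."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())
    model: str
    sex: Literal["M", "F"]
    rib: int = Field(ge=2, le=11)
    rings: List[_RingModel] = Field(min_length=2)

    @field_validator("rings")
    @classmethod
    def _consistent(cls, rings):
        sizes = {len(r.nodes) for r in rings}
        if len(sizes) != 1:
            raise ValueError("inconsistent ring sizes")
        for i, r in enumerate(rings):
            t = np.atleast_1d(np.asarray(r.thickness, dtype=float))
            if t.size not in (1, len(r.nodes)):
                raise ValueError(f"ring {i}: thickness length mismatch")
            if np.any(t <= 0):
                raise ValueError(f"ring {i}: nonpositive thickness")
        return rings


RING_MESH_SCHEMA = _RingMeshModel.model_json_schema()


@dataclass(frozen=True)
class RingMesh:
    """Validated rib cortical shell mesh as node rings with thickness.

    ``nodes`` has shape (n_rings, nodes_per_ring, 3) in mm, ordered along
    the rib; ``thickness`` has shape (n_rings, nodes_per_ring) in mm.
    """

    model_name: str
    sex: str
    rib_number: int
    nodes: np.ndarray
    thickness: np.ndarray

    @property
    def n_rings(self) -> int:
        return self.nodes.shape[0]

    @property
    def nodes_per_ring(self) -> int:
        return self.nodes.shape[1]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "sex": self.sex,
            "rib": self.rib_number,
            "rings": [
                {"nodes": self.nodes[i].tolist(),
                 "thickness": self.thickness[i].tolist()}
                for i in range(self.n_rings)
            ],
        }


def _from_model(m: _RingMeshModel) -> RingMesh:
    k = len(m.rings[0].nodes)
    nodes = np.array([r.nodes for r in m.rings], dtype=float)
    thickness = np.vstack([
        np.broadcast_to(np.atleast_1d(np.asarray(r.thickness, float)), (k,))
        for r in m.rings
    ])
    return RingMesh(model_name=m.model, sex=m.sex, rib_number=m.rib,
                    nodes=nodes, thickness=thickness.copy())


def read_ring_mesh(path) -> RingMesh:
    """Read and validate a neutral ring-mesh JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return _from_model(_RingMeshModel.model_validate(payload))


def write_ring_mesh(mesh: RingMesh, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(mesh.to_dict(), fh)


def element_to_node_thickness(element_thickness: np.ndarray) -> np.ndarray:
    """Convert per-element shell thickness around a ring to per-node values.

    Element j spans nodes j and j+1 (circularly); each node receives the
    mean of its two adjacent elements' thickness.
    """
    t = np.asarray(element_thickness, dtype=float)
    return 0.5 * (t + np.roll(t, 1, axis=-1))


def _project_ring(nodes: np.ndarray) -> np.ndarray:
    """Project a 3D node ring onto its least-squares plane (2D, CCW)."""
    centered = nodes - nodes.mean(axis=0)
    # right singular vectors: first two span the LSQ plane
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pts = centered @ vt[:2].T
    # normalize winding so offsetting conventions apply
    area = 0.5 * float(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                              - np.roll(pts[:, 0], -1) * pts[:, 1]))
    if area < 0:
        pts = pts[::-1].copy()
    return pts


def ring_to_borders(nodes: np.ndarray, thickness,
                    frame: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                    node_surface: NodeSurface = "mid",
                    ring_index: Optional[int] = None
                    ) -> Tuple[Contour, Contour]:
    """Periosteal and endosteal contours from one node ring.

    Nodes are projected into the section plane (``frame`` basis vectors, or
    the ring's least-squares plane when omitted) and offset along outward
    vertex normals by the shell thickness.  ``node_surface`` states which
    surface the nodes represent: ``mid`` (default shell-element convention,
    offsets of +-t/2), ``outer`` (nodes are periosteal; erode by t) or
    ``inner`` (nodes are endosteal; dilate by t).
    """
    nodes = np.asarray(nodes, dtype=float)
    t = np.broadcast_to(np.atleast_1d(np.asarray(thickness, float)),
                        (nodes.shape[0],))
    if np.any(t <= 0):
        raise ValueError("nonpositive thickness")
    if frame is not None:
        e1, e2 = frame
        centered = nodes - nodes.mean(axis=0)
        pts = np.stack([centered @ np.asarray(e1, float),
                        centered @ np.asarray(e2, float)], axis=1)
        area = 0.5 * float(np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                                  - np.roll(pts[:, 0], -1) * pts[:, 1]))
        if area < 0:
            pts = pts[::-1].copy()
            t = t[::-1].copy()
    else:
        pts = _project_ring(nodes)
    mid = validate_contour(pts)
    # validate_contour may drop duplicate vertices; keep thickness aligned
    if mid.n_vertices != pts.shape[0]:
        raise ContourError(
            f"ring {ring_index}: duplicate nodes prevent thickness alignment"
            if ring_index is not None else
            "duplicate nodes prevent thickness alignment")
    normals = vertex_normals(mid.points)
    if node_surface == "mid":
        d_out, d_in = 0.5 * t, -0.5 * t
    elif node_surface == "outer":
        d_out, d_in = np.zeros_like(t), -t
    elif node_surface == "inner":
        d_out, d_in = t, np.zeros_like(t)
    else:
        raise ValueError("node_surface must be 'mid', 'outer' or 'inner'")
    peri_pts = mid.points + d_out[:, None] * normals
    endo_pts = mid.points + d_in[:, None] * normals
    label = f"ring {ring_index}" if ring_index is not None else "ring"
    # an erosion past the medial axis reverses edge directions (possibly
    # leaving a spuriously valid inverted polygon): treat as collapse
    mid_edges = np.roll(mid.points, -1, axis=0) - mid.points
    endo_edges = np.roll(endo_pts, -1, axis=0) - endo_pts
    if np.any(np.sum(mid_edges * endo_edges, axis=1) <= 0.0):
        raise ContourError(f"{label}: endosteal collapse "
                           f"(thickness too large locally)")
    try:
        peri = validate_contour(peri_pts)
        endo = validate_contour(endo_pts)
    except ContourError as exc:
        raise ContourError(f"{label}: endosteal collapse "
                           f"(thickness too large locally)") from exc
    if endo.area <= 0 or endo.area >= peri.area:
        raise ContourError(f"{label}: endosteal collapse "
                           f"(thickness too large locally)")
    return peri, endo


def hbm_rib_to_record(mesh: RingMesh, grid: StationGrid,
                      node_surface: NodeSurface = "mid") -> RibRecord:
    """Measure an HBM rib and interpolate its traces onto a station grid.

    Ring centroids define the rib midline; each ring is assigned the
    arc-length station of its centroid (0% first ring, 100% last ring).
    Per-ring properties are interpolated linearly in station onto ``grid``
    with no extrapolation beyond the terminal rings (clamped).  ``Ct.Ar``
    and ``Irat`` are re-derived from the interpolated primary quantities so
    the identities Tt.Ar = Ct.Ar + Es.Ar and Irat = ln(Imax/Imin) hold at
    every station.
    """
    if mesh.n_rings < 2:
        raise ValueError("mesh must have at least 2 rings")
    centroids = mesh.nodes.mean(axis=1)
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("coincident consecutive ring centroids")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    ring_stations = 100.0 * cum / cum[-1]

    peri_stack, endo_stack, theta_list = [], [], []
    for i in range(mesh.n_rings):
        peri, endo = ring_to_borders(mesh.nodes[i], mesh.thickness[i],
                                     node_surface=node_surface, ring_index=i)
        peri_stack.append(peri.points)
        endo_stack.append(endo.points)
    # rings keep a common vertex count, so batch evaluation applies
    k = {p.shape[0] for p in peri_stack} | {e.shape[0] for e in endo_stack}
    if len(k) == 1:
        props = batch_composite_properties(np.stack(peri_stack),
                                           np.stack(endo_stack))
        tt, es = props["tt_ar"], props["es_ar"]
        imax, imin, theta = props["i_max"], props["i_min"], props["theta_max"]
    else:  # heterogeneous vertex counts after deduplication
        from .geometry import composite_section_properties, Contour as _C
        sp = [composite_section_properties(_C(p), _C(e))
              for p, e in zip(peri_stack, endo_stack)]
        tt = np.array([s.tt_ar for s in sp])
        es = np.array([s.es_ar for s in sp])
        imax = np.array([s.i_max for s in sp])
        imin = np.array([s.i_min for s in sp])
        theta = np.array([s.theta_max for s in sp])

    s = np.asarray(grid.stations)
    tt_g = np.interp(s, ring_stations, tt)
    es_g = np.interp(s, ring_stations, es)
    imax_g = np.interp(s, ring_stations, imax)
    imin_g = np.interp(s, ring_stations, imin)
    theta_g = np.interp(s, ring_stations, theta)
    records: Dict[float, SectionProperties] = {}
    for j, st in enumerate(s):
        records[float(st)] = SectionProperties(
            tt_ar=float(tt_g[j]), ct_ar=float(tt_g[j] - es_g[j]),
            es_ar=float(es_g[j]), i_max=float(imax_g[j]),
            i_min=float(imin_g[j]),
            i_rat=float(np.log(imax_g[j] / imin_g[j])),
            theta_max=float(theta_g[j]), centroid=(float("nan"), float("nan")))
    return RibRecord(subject_id=mesh.model_name, sex=mesh.sex,
                     rib_number=mesh.rib_number, properties=records)
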