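"""Rib-level data model: station grids, section frames, per-rib records.

Positions along a rib are expressed as *stations*: percent of total
arc length from the vertebral (costovertebral) end (0%) to the sternal end
(100%).  The default measurement grid places stations every 2.5% from 2.5%
to 97.5% inclusive -- 39 stations, endpoints excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .geometry import Contour, ContourError, SectionProperties, \
    composite_section_properties, validate_contour

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("Tt.Ar", "Ct.Ar", "Es.Ar", "Imax", "Imin", "Irat")
RIB_NUMBERS = tuple(range(2, 12))

__all__ = [
    "PROPERTY_NAMES",
    "RIB_NUMBERS",
    "StationGrid",
    "RibCurve",
    "RibRecord",
    "SubjectDemographics",
    "default_station_grid",
    "arc_length_stations",
    "section_frame",
    "assemble_rib_record",
]


@dataclass(frozen=True)
class StationGrid:
    """Ordered station positions in percent of rib length, all in (0, 100)."""

    stations: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.stations, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("station grid must be a non-empty 1-D sequence")
        if np.any(np.diff(s) <= 0):
            raise ValueError("stations must be strictly increasing")
        if s[0] <= 0 or s[-1] >= 100:
            raise ValueError("stations must lie strictly inside (0, 100)")
        object.__setattr__(self, "stations", s)

    def __len__(self) -> int:
        return self.stations.size

    def __iter__(self):
        return iter(self.stations)


def default_station_grid() -> StationGrid:
    """Stations at 2.5%, 5.0%, ..., 97.5% of rib length (39 stations)."""
    return StationGrid(np.arange(1, 40) * 2.5)


@dataclass(frozen=True)
class RibCurve:
    """Ordered 3D polyline (mm) along the rib midline, vertebral to sternal."""

    points: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("rib curve needs at least 2 points of shape (m, 3)")
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("rib curve has repeated consecutive points")
        object.__setattr__(self, "points", p)

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class SubjectDemographics:
    """Subject metadata (never used in geometric computation)."""

    sex: str
    age: float
    weight_kg: float
    height_cm: float
    bmi: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if not 18 <= self.age <= 90:
            raise ValueError("age must be within [18, 90] years")
        implied = self.weight_kg / (self.height_cm / 100.0) ** 2
        if np.isnan(self.bmi):
            object.__setattr__(self, "bmi", implied)
        elif abs(self.bmi - implied) > 0.01 * implied:
            raise ValueError("bmi inconsistent with weight and height")


@dataclass
class RibRecord:
    """Measured section-property traces for one rib of one subject/model."""

    subject_id: str
    sex: str
    rib_number: int
    properties: Dict[float, SectionProperties]
    age: Optional[float] = None
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.rib_number not in RIB_NUMBERS:
            raise ValueError("rib_number must be in 2..11")

    def trace(self, prop: str) -> Dict[float, float]:
        """Station -> value mapping for one named property."""
        attr = {"Tt.Ar": "tt_ar", "Ct.Ar": "ct_ar", "Es.Ar": "es_ar",
                "Imax": "i_max", "Imin": "i_min", "Irat": "i_rat"}[prop]
        return {s: getattr(p, attr) for s, p in self.properties.items()}


def arc_length_stations(curve: RibCurve, grid: StationGrid
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Station points and unit tangents along a rib midline.

    Each station s is placed at fraction s/100 of the total arc length,
    linearly interpolated along the polyline; the tangent is the direction
    of the containing segment.
    """
    pts = curve.points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    targets = np.asarray(grid.stations) / 100.0 * total
    out_pts = np.stack([np.interp(targets, cum, pts[:, k]) for k in range(3)],
                       axis=1)
    idx = np.clip(np.searchsorted(cum, targets, side="right") - 1,
                  0, len(seg_len) - 1)
    tangents = seg[idx] / seg_len[idx, None]
    return out_pts, tangents


def section_frame(tangent: np.ndarray, up_hint: np.ndarray
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis (e_north, e_east) for a section plane.

    ``e_north`` is the superior hint projected off the tangent (compass
    north = rib superior aspect); ``e_east`` (cutaneous side) completes a
    right-handed triad (e_east, e_north, tangent).
    """
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    h = np.asarray(up_hint, dtype=float)
    n = h - np.dot(h, t) * t
    norm = np.linalg.norm(n)
    if norm < 1e-9 * np.linalg.norm(h):
        raise ValueError("up hint is parallel to the tangent")
    e_north = n / norm
    e_east = np.cross(e_north, t)
    return e_north, e_east


def assemble_rib_record(sections: Mapping[float, Tuple], subject_id: str,
                        sex: str, rib_number: int,
                        age: Optional[float] = None) -> RibRecord:
    """Measure section properties at every provided station of one rib.

    ``sections`` maps station (percent) to a (periosteal, endosteal) pair of
    :class:`Contour` objects or raw point sequences.  Stations whose
    contours fail validation become *missing* (counted, logged) rather than
    aborting the rib.
    """
    props: Dict[float, SectionProperties] = {}
    n_missing = 0
    for station in sorted(sections):
        peri, endo = sections[station]
        try:
            if not isinstance(peri, Contour):
                peri = validate_contour(peri)
            if not isinstance(endo, Contour):
                endo = validate_contour(endo)
            props[float(station)] = composite_section_properties(peri, endo)
        except ContourError as exc:
            n_missing += 1
            logger.warning("subject %s rib %d station %.1f%% skipped: %s",
                           subject_id, rib_number, station, exc)
    return RibRecord(subject_id=subject_id, sex=sex, rib_number=rib_number,
                     properties=props, age=age, n_missing=n_missing)
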