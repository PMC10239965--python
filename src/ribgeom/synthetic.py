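"""Synthetic rib populations and synthetic HBM ring meshes.

The study design this package serves pools CT-derived rib cross-sections
from 240 adults (118 male, 122 female), ribs 2-11, measured at 2.5%
arc-length stations, into sex-specific population corridors, and audits
shell-element human body model (HBM) ribs against them.  Real inputs of
that kind are not redistributable, so this module generates populations of
elliptical-annulus sections carrying the same statistical structure:

* total area (Tt.Ar) declining from the vertebral toward the sternal end,
  mid-level ribs largest;
* cross-sections elongating toward the sternal end, with the Imax/Imin
  aspect profile peaking at the 90% station at ratios of ~15 (males) and
  ~18 (females) on ribs 2-5 and lower peaks on ribs 6-11;
* males larger than females in Tt.Ar by a prescribed number of population
  SDs (default 1.5), with a shared cortical-thickness profile so the
  male-female Ct.Ar gap is smaller than the Tt.Ar gap;
* between-subject size variation (lognormal similarity scaling),
  independent per-station noise, and lognormal aspect-ratio perturbation.

It also builds ring meshes that trace a fitted corridor at chosen SD
offsets (to exercise mesh extraction and the audit end to end) and the
segmentation-bias demonstration: dilating periosteal borders by a fixed
offset (default 0.42 mm, the reported bias of threshold-based segmentation)
and measuring the resulting Tt.Ar inflation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .corridors import Corridor, CorridorResults
from .geometry import Contour, batch_composite_properties, offset_contour, \
    vertex_normals, SectionProperties
from .hbm_mesh import RingMesh
from .rib_model import RIB_NUMBERS, RibRecord, StationGrid, \
    SubjectDemographics, default_station_grid

__all__ = [
    "PopulationSpec",
    "SimulatedPopulation",
    "default_population_spec",
    "simulate_population",
    "simulate_hbm_mesh",
    "apply_segmentation_bias",
]


@dataclass
class PopulationSpec:
    """Generative parameters for a synthetic rib population.

    All areas in mm^2, lengths in mm, stations in percent of rib length.
    The aspect profile is expressed as the target Imax/Imin ratio of the
    underlying solid ellipse; the generated hollow sections approach it.
    """

    n_male: int = 118
    n_female: int = 122
    age_range: Tuple[float, float] = (18.0, 90.0)
    seed: int = 0
    n_vertices: int = 64

    # Tt.Ar mean structure (female baseline, male = offset multiple of SD)
    tt_ar_base: float = 40.0          # female rib-2 vertebral-end area
    tt_ar_rib_amplitude: float = 25.0  # mid-rib enlargement (peak ~rib 6-7)
    tt_ar_decay: float = 0.011         # exponential decline per % station
    sex_offset_sds: float = 1.5        # male mean above female, in female SDs

    # aspect (Imax/Imin) profile: base at vertebral end, Gaussian bump at
    # the peak station
    aspect_base: float = 2.0
    aspect_peak_station: float = 90.0
    aspect_peak_width: float = 25.0
    aspect_peak_male_upper: float = 15.0    # ribs 2-5
    aspect_peak_female_upper: float = 18.0
    aspect_peak_male_lower: float = 10.0    # ribs 6-11
    aspect_peak_female_lower: float = 12.0

    # cortical thickness profile, shared between sexes
    thickness_start: float = 0.85      # mm at the vertebral end
    thickness_slope: float = -0.003    # mm per % station

    # noise (lognormal sigmas; 0 = deterministic)
    subject_sigma_log: float = 0.18    # between-subject area scale
    station_sigma_log: float = 0.05    # independent within-rib area noise
    aspect_sigma_log: float = 0.06     # aspect-ratio perturbation

    def __post_init__(self) -> None:
        if self.n_male <= 0 or self.n_female <= 0:
            raise ValueError("subject counts must be positive")
        if self.tt_ar_base <= 0 or self.tt_ar_rib_amplitude < 0:
            raise ValueError("area profile parameters must be positive")
        if min(self.aspect_base, self.aspect_peak_male_upper,
               self.aspect_peak_female_upper, self.aspect_peak_male_lower,
               self.aspect_peak_female_lower) < 1:
            raise ValueError("aspect ratios must be >= 1")
        if self.thickness_start <= 0:
            raise ValueError("thickness must be positive")
        if self.n_vertices < 8:
            raise ValueError("need at least 8 contour vertices")

    # -- mean profiles ----------------------------------------------------

    def total_cv(self) -> float:
        """Coefficient of variation of the combined area noise."""
        s2 = self.subject_sigma_log ** 2 + self.station_sigma_log ** 2
        return math.sqrt(math.exp(s2) - 1.0)

    def tt_ar_profile(self, sex: str, rib: int, stations) -> np.ndarray:
        """Mean Tt.Ar (mm^2) along the rib."""
        s = np.asarray(stations, dtype=float)
        base = (self.tt_ar_base
                + self.tt_ar_rib_amplitude * math.sin(math.pi * (rib - 2) / 9))
        prof = base * np.exp(-self.tt_ar_decay * (s - 2.5))
        if sex == "M":
            prof = prof * (1.0 + self.sex_offset_sds * self.total_cv())
        return prof

    def aspect_ratio_profile(self, sex: str, rib: int, stations) -> np.ndarray:
        """Target Imax/Imin ratio of the *measured* section along the rib
        (peak at the 90% station).  The generator calibrates the ellipse
        aspect so the hollow ring's moments actually realize this ratio."""
        s = np.asarray(stations, dtype=float)
        if rib <= 5:
            peak = (self.aspect_peak_male_upper if sex == "M"
                    else self.aspect_peak_female_upper)
        else:
            peak = (self.aspect_peak_male_lower if sex == "M"
                    else self.aspect_peak_female_lower)
        bump = np.exp(-0.5 * ((s - self.aspect_peak_station)
                              / self.aspect_peak_width) ** 2)
        return np.exp(math.log(self.aspect_base)
                      + (math.log(peak) - math.log(self.aspect_base)) * bump)

    def target_irat(self, sex: str, rib: int, stations) -> np.ndarray:
        """ln(Imax/Imin) implied by the aspect profile."""
        return np.log(self.aspect_ratio_profile(sex, rib, stations))

    def thickness_profile(self, stations) -> np.ndarray:
        """Mean cortical thickness (mm) along the rib, shared by sexes."""
        s = np.asarray(stations, dtype=float)
        return self.thickness_start + self.thickness_slope * s

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "PopulationSpec":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:  # path-like
            with open(source, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        return cls(**data)


def default_population_spec(sex_differences: bool = True) -> PopulationSpec:
    """The default study conditions (240 subjects: 118 M, 122 F).

    With ``sex_differences`` off the male profiles are set equal to the
    female ones (no size offset, same aspect peaks).
    """
    spec = PopulationSpec()
    if not sex_differences:
        spec.sex_offset_sds = 0.0
        spec.aspect_peak_male_upper = spec.aspect_peak_female_upper
        spec.aspect_peak_male_lower = spec.aspect_peak_female_lower
    return spec


@dataclass
class SimulatedPopulation:
    """Generated records plus subject metadata (and optional contours)."""

    records: List[RibRecord]
    demographics: Dict[str, SubjectDemographics]
    spec: PopulationSpec
    # (subject_id, rib) -> {station: (periosteal Contour, endosteal Contour)}
    contours: Optional[Dict[Tuple[str, int], Dict[float, Tuple[Contour, Contour]]]] = None


def _ellipse_polygon_factor(n_vertices: int) -> float:
    """Area of the inscribed n-gon of a unit-axes ellipse param polygon."""
    return 0.5 * n_vertices * math.sin(2.0 * math.pi / n_vertices)


def _check_convex(pts: np.ndarray) -> None:
    """Construction-time validity check for generated CCW polygons.

    Convexity (all consecutive edge cross-products positive) is sufficient
    for simplicity and positive area; the generated ellipse-family polygons
    are convex by design, so a violation indicates a nonphysical parameter
    combination.
    """
    e = np.roll(pts, -1, axis=-2) - pts
    cross = e[..., 0] * np.roll(e, -1, axis=-2)[..., 1] \
        - e[..., 1] * np.roll(e, -1, axis=-2)[..., 0]
    if not np.all(cross > 0):
        raise ValueError("generated contour is not simple/convex")


def _elliptical_annulus(tt_ar, aspect, thickness, n_vertices: int):
    """Vectorized outer/inner polygon stacks for elliptical annuli.

    ``tt_ar``, ``aspect`` broadcast to a common shape (...,); thickness
    broadcasts likewise.  The outer polygon's shoelace area equals
    ``tt_ar`` exactly; the inner polygon is the ellipse eroded by
    ``thickness`` on both semi-axes.  The major axis lies along +y (the
    superior, compass-north direction).  Returns (outer, inner) of shape
    (..., n_vertices, 2) plus the clamped semi-minor axis array.
    """
    tt_ar, aspect, thickness = np.broadcast_arrays(
        np.asarray(tt_ar, float), np.asarray(aspect, float),
        np.asarray(thickness, float))
    kappa = _ellipse_polygon_factor(n_vertices)
    c = math.sqrt(math.pi / kappa)  # pre-scale so polygon area == tt_ar
    b = np.sqrt(tt_ar / (math.pi * aspect)) * c
    # truncate noise to physical validity: keep a margin over the thickness
    b = np.maximum(b, 1.25 * thickness)
    a = aspect * b
    phi = np.arange(n_vertices) * (2.0 * math.pi / n_vertices)
    cos, sin = np.cos(phi), np.sin(phi)
    outer = np.stack([b[..., None] * cos, a[..., None] * sin], axis=-1)
    inner = np.stack([(b - thickness)[..., None] * cos,
                      (a - thickness)[..., None] * sin], axis=-1)
    return outer, inner, b


def _calibrate_aspect(tt_ar: np.ndarray, ratio_target: np.ndarray,
                      thickness: np.ndarray, n_vertices: int) -> np.ndarray:
    """Ellipse aspect q(s) whose hollow ring measures the target Irat.

    The eroded (non-similar) inner border lowers the ring's Imax/Imin
    below the solid-ellipse value q^2, so q is found by monotone bisection
    on the measured log-ratio of the constructed annulus (vectorized over
    stations).
    """
    target = np.log(np.asarray(ratio_target, dtype=float))
    lo = np.ones_like(target)
    hi = np.full_like(target, 10.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        outer, inner, _ = _elliptical_annulus(tt_ar, mid, thickness,
                                              n_vertices)
        irat = batch_composite_properties(outer, inner)["i_rat"]
        go_up = irat < target
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    return 0.5 * (lo + hi)


def simulate_population(spec: PopulationSpec,
                        grid: Optional[StationGrid] = None,
                        seed: Optional[int] = None,
                        keep_contours: bool = False) -> SimulatedPopulation:
    """Draw a full synthetic population of rib records.

    Each subject carries a lognormal similarity size factor; each station
    adds independent lognormal area noise and an aspect perturbation.
    Sections are elliptical annuli oriented with the long axis superiorly
    (compass north).  Reproducible: the same (spec, seed) yields an
    identical population.

    Raises ``ValueError`` naming the profile if the mean profiles are
    nonphysical (cortical thickness >= semi-minor axis).
    """
    grid = grid or default_station_grid()
    stations = np.asarray(grid.stations)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    thick = spec.thickness_profile(stations)
    if np.any(thick <= 0):
        raise ValueError("thickness profile is nonpositive at some station")

    # calibrate the ellipse aspect to the target measured moment ratio and
    # check physical validity of the mean profiles themselves
    kappa_c = math.sqrt(math.pi / _ellipse_polygon_factor(spec.n_vertices))
    aspect_mean: Dict[Tuple[str, int], np.ndarray] = {}
    for sex in ("M", "F"):
        for rib in RIB_NUMBERS:
            tt = spec.tt_ar_profile(sex, rib, stations)
            ratio = spec.aspect_ratio_profile(sex, rib, stations)
            q = _calibrate_aspect(tt, ratio, thick, spec.n_vertices)
            aspect_mean[(sex, rib)] = q
            b = np.sqrt(tt / (math.pi * q)) * kappa_c
            if np.any(b <= thick):
                raise ValueError(
                    f"nonphysical profile: thickness >= semi-minor axis for "
                    f"sex {sex}, rib {rib}")

    records: List[RibRecord] = []
    demographics: Dict[str, SubjectDemographics] = {}
    contours = {} if keep_contours else None
    n_stations = stations.size

    for sex, n_subj in (("M", spec.n_male), ("F", spec.n_female)):
        ages = _sample_ages(rng, n_subj, spec.age_range)
        heights = rng.normal(177.0 if sex == "M" else 163.0, 8.0, n_subj)
        weights = np.clip(rng.normal(89.0 if sex == "M" else 80.0,
                                     19.0 if sex == "M" else 22.0, n_subj),
                          40.0, None)
        subj_ids = [f"{sex}{i:03d}" for i in range(n_subj)]
        for sid, age, h, w in zip(subj_ids, ages, heights, weights):
            demographics[sid] = SubjectDemographics(
                sex=sex, age=float(age), weight_kg=float(w),
                height_cm=float(h))
        ss = spec.subject_sigma_log
        subject_scale = np.exp(ss * rng.standard_normal(n_subj) - 0.5 * ss * ss)
        for rib in RIB_NUMBERS:
            sv = spec.station_sigma_log
            sq = spec.aspect_sigma_log
            station_scale = np.exp(
                sv * rng.standard_normal((n_subj, n_stations)) - 0.5 * sv * sv)
            aspect_noise = np.exp(sq * rng.standard_normal((n_subj, n_stations)))
            tt = (spec.tt_ar_profile(sex, rib, stations)[None, :]
                  * subject_scale[:, None] * station_scale)
            aspect = np.maximum(aspect_mean[(sex, rib)][None, :]
                                * aspect_noise, 1.0)
            outer, inner, _ = _elliptical_annulus(tt, aspect,
                                                  thick[None, :],
                                                  spec.n_vertices)
            _check_convex(outer)
            _check_convex(inner)
            props = batch_composite_properties(outer, inner)
            for i, sid in enumerate(subj_ids):
                per_station: Dict[float, SectionProperties] = {}
                for j, st in enumerate(stations):
                    per_station[float(st)] = SectionProperties(
                        tt_ar=float(props["tt_ar"][i, j]),
                        ct_ar=float(props["ct_ar"][i, j]),
                        es_ar=float(props["es_ar"][i, j]),
                        i_max=float(props["i_max"][i, j]),
                        i_min=float(props["i_min"][i, j]),
                        i_rat=float(props["i_rat"][i, j]),
                        theta_max=float(props["theta_max"][i, j]),
                        centroid=(float(props["centroid"][i, j, 0]),
                                  float(props["centroid"][i, j, 1])))
                records.append(RibRecord(
                    subject_id=sid, sex=sex, rib_number=rib,
                    properties=per_station,
                    age=float(demographics[sid].age)))
                if keep_contours:
                    contours[(sid, rib)] = {
                        float(st): (Contour(outer[i, j].copy()),
                                    Contour(inner[i, j].copy()))
                        for j, st in enumerate(stations)}
    return SimulatedPopulation(records=records, demographics=demographics,
                               spec=spec, contours=contours)


def _sample_ages(rng: np.random.Generator, n: int,
                 age_range: Tuple[float, float]) -> np.ndarray:
    """Approximately uniform counts within each decade of age."""
    lo, hi = age_range
    dec_lo = np.arange(math.floor(lo / 10) * 10, hi, 10.0)
    ages = np.empty(n)
    for i in range(n):
        d = dec_lo[i % len(dec_lo)]
        ages[i] = rng.uniform(max(d, lo), min(d + 10.0, hi))
    return rng.permutation(ages)


# ---------------------------------------------------------------------------
# Synthetic HBM ring meshes tracing a corridor


def _corridor_lookup(corridors, sex: str, rib: int, prop: str) -> Corridor:
    if isinstance(corridors, CorridorResults):
        return corridors.corridors[(sex, rib, prop)]
    return corridors[(sex, rib, prop)]


def _solve_ring(tt_target: float, irat_target: float, n_vertices: int,
                thickness: Optional[float], es_target: Optional[float]):
    """Midsurface scale/aspect (and thickness) hitting the ring targets.

    The midsurface polygon is lam * v(q) with v the unit elliptical n-gon
    of aspect q; its unit vertex normals m(q) are scale-invariant, so the
    periosteal/endosteal polygons lam*v +- (t/2)*m have shoelace areas
    that are exact quadratic forms in (lam, t):

        A_p = Av lam^2 + B lam (t/2) + Am (t/2)^2
        A_e = Av lam^2 - B lam (t/2) + Am (t/2)^2

    with Av = area(v), Am = area(m) and B the bilinear mixed term.  Given
    the two area targets the sum/difference decouple into a quadratic in
    lam^2 and a closed form for t; with a fixed thickness only the A_p
    quadratic is solved.  The aspect q is then found by bisection on the
    resulting Irat.  Returns (midsurface points (n, 2), thickness).
    """

    def base(q):
        phi = np.arange(n_vertices) * (2.0 * math.pi / n_vertices)
        v = np.stack([np.cos(phi), q * np.sin(phi)], axis=1)
        return v, vertex_normals(v)

    def area(pts):
        nxt = np.roll(pts, -1, axis=0)
        return 0.5 * float(np.sum(pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]))

    def solve_geometry(q):
        v, m = base(q)
        a_v, a_m = area(v), area(m)
        b = area(v + m) - a_v - a_m  # bilinear mixed area term
        if es_target is not None:
            s = tt_target + es_target
            d = tt_target - es_target
            if d <= 0:
                raise ValueError("ring solve: Es.Ar target >= Tt.Ar target")
            c = 0.5 * a_m * d * d / (b * b)
            disc = s * s - 8.0 * a_v * c
            if disc < 0:
                raise ValueError("ring solve: no physical thickness")
            x = (s + math.sqrt(disc)) / (4.0 * a_v)  # x = lam^2
            lam = math.sqrt(x)
            t = d / (lam * b)
        else:
            t = thickness
            # A_p quadratic in lam
            a2, a1 = a_v, 0.5 * t * b
            a0 = 0.25 * t * t * a_m
            lam = (-a1 + math.sqrt(a1 * a1 - 4.0 * a2 * (a0 - tt_target))) \
                / (2.0 * a2)
        return v, m, lam, t

    def ring_irat(q):
        v, m, lam, t = solve_geometry(q)
        peri = lam * v + 0.5 * t * m
        endo = lam * v - 0.5 * t * m
        props = batch_composite_properties(peri[None], endo[None])
        return float(props["i_rat"][0]), lam, t, v

    def resid(q):
        return ring_irat(q)[0] - irat_target

    q_lo, q_hi = 1.0 + 1e-9, 12.0
    if resid(q_lo) >= 0:
        q = q_lo
    elif resid(q_hi) <= 0:
        q = q_hi
    else:
        q = brentq(resid, q_lo, q_hi, xtol=1e-12, rtol=1e-14)
    _, lam, t, v = ring_irat(q)
    return lam * v, t


def simulate_hbm_mesh(corridors, sex: str, rib: int,
                      model_name: str = "SYNTH",
                      nodes_per_ring: int = 16,
                      thickness: Optional[float] = None,
                      offsets: Optional[Mapping[str, float]] = None,
                      rib_length: Optional[float] = None,
                      ring_step_pct: float = 2.5) -> RingMesh:
    """Build a ring mesh tracing a corridor at chosen SD offsets.

    Rings are placed on a straight centerline spanning 0-100% of the rib
    length at ``ring_step_pct`` increments, each solved so the *extracted*
    periosteal area equals corridor mean + offset*SD for Tt.Ar, likewise
    Es.Ar (via per-ring thickness, unless a uniform ``thickness`` in mm is
    given, in which case Es.Ar follows from it), and the extracted Irat
    matches its target.  Imax and Imin are consequences of the elliptical
    ring family and are not independently offset.  Offsets default to 0
    (corridor mean).  ``nodes_per_ring``: 16 (GHBMC/VIVA+ style) or 12
    (THUMS style); uniform thickness of 0.7 mm mimics THUMS/VIVA+.
    """
    offsets = dict(offsets or {})
    unknown = set(offsets) - {"Tt.Ar", "Es.Ar", "Irat"}
    if unknown:
        raise ValueError(f"cannot offset propert{'ies' if len(unknown)>1 else 'y'} "
                         f"{sorted(unknown)}; controllable: Tt.Ar, Es.Ar, Irat")
    c_tt = _corridor_lookup(corridors, sex, rib, "Tt.Ar")
    c_es = _corridor_lookup(corridors, sex, rib, "Es.Ar")
    c_ir = _corridor_lookup(corridors, sex, rib, "Irat")
    ring_stations = np.arange(0.0, 100.0 + ring_step_pct / 2, ring_step_pct)
    tt_m, tt_s = c_tt.interp(ring_stations)
    es_m, es_s = c_es.interp(ring_stations)
    ir_m, ir_s = c_ir.interp(ring_stations)
    tt_t = tt_m + offsets.get("Tt.Ar", 0.0) * np.nan_to_num(tt_s)
    es_t = es_m + offsets.get("Es.Ar", 0.0) * np.nan_to_num(es_s)
    ir_t = ir_m + offsets.get("Irat", 0.0) * np.nan_to_num(ir_s)
    length = rib_length if rib_length is not None else 150.0 + 15.0 * (rib - 2)

    nodes = np.empty((ring_stations.size, nodes_per_ring, 3))
    thick = np.empty((ring_stations.size, nodes_per_ring))
    for i, s in enumerate(ring_stations):
        mid2d, t = _solve_ring(float(tt_t[i]), float(ir_t[i]), nodes_per_ring,
                               thickness,
                               None if thickness is not None else float(es_t[i]))
        nodes[i, :, 0] = length * s / 100.0
        nodes[i, :, 1] = mid2d[:, 0]
        nodes[i, :, 2] = mid2d[:, 1]
        thick[i] = t
    return RingMesh(model_name=model_name, sex=sex, rib_number=rib,
                    nodes=nodes, thickness=thick)


# ---------------------------------------------------------------------------
# Segmentation-bias demonstration


def apply_segmentation_bias(sections: Mapping[float, Tuple[Contour, Contour]],
                            delta: float = 0.42):
    """Dilate periosteal borders by ``delta`` mm; report Tt.Ar inflation.

    Emulates the periosteal over-estimation of threshold-based CT
    segmentation (reported average 0.42 mm).  Endosteal contours are left
    unchanged.  Returns (biased sections, report frame) where the report
    has one row per station with tt_ar_before, tt_ar_after and
    pct_increase.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    biased: Dict[float, Tuple[Contour, Contour]] = {}
    rows = []
    for station in sorted(sections):
        peri, endo = sections[station]
        new_peri = offset_contour(peri, delta)
        biased[float(station)] = (new_peri, endo)
        before, after = peri.area, new_peri.area
        rows.append((float(station), before, after,
                     100.0 * (after - before) / before))
    report = pd.DataFrame(rows, columns=["station_pct", "tt_ar_before",
                                         "tt_ar_after", "pct_increase"])
    return biased, report
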