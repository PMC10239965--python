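"""Population corridors: per-station mean +- SD of section properties.

Records are pooled by sex, rib number and station (percent of rib length);
for each (sex, rib, property, station) cell the corridor stores the sample
mean, the sample standard deviation (n-1 denominator) and the number of
contributing subjects.  Corridors are the population reference against
which human-body-model ribs are audited.

The pooling step is exposed both as the functional :func:`build_corridors`
and as a statsmodels-style :class:`CorridorModel` whose ``fit()`` returns a
:class:`CorridorResults` carrying the estimates, a ``summary()`` table, the
+-k SD ``band`` and ``compare`` / ``plot`` helpers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rib_model import PROPERTY_NAMES, RibRecord, StationGrid

__all__ = [
    "Corridor",
    "CorridorKey",
    "records_to_frame",
    "build_corridors",
    "corridor_band",
    "write_corridor_csv",
    "read_corridor_csv",
    "CorridorModel",
    "CorridorResults",
]

CorridorKey = Tuple[str, int, str]  # (sex, rib_number, property)

CSV_COLUMNS = ["sex", "rib", "station_pct", "property", "mean", "sd", "n"]


@dataclass(frozen=True)
class Corridor:
    """Mean/SD/n trace of one property for one (sex, rib) population."""

    sex: str
    rib_number: int
    property_name: str
    stations: np.ndarray     # percent of rib length
    mean: np.ndarray
    sd: np.ndarray           # NaN where undefined (n < 2)
    n: np.ndarray

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTY_NAMES:
            raise ValueError(f"unknown property {self.property_name!r}")
        for name in ("stations", "mean", "sd", "n"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name)))
        if not (self.stations.shape == self.mean.shape == self.sd.shape
                == self.n.shape):
            raise ValueError("corridor arrays must share one shape")
        with np.errstate(invalid="ignore"):
            if np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative")

    def interp(self, stations) -> Tuple[np.ndarray, np.ndarray]:
        """Mean and sd linearly interpolated at requested stations."""
        s = np.asarray(stations, dtype=float)
        return (np.interp(s, self.stations, self.mean),
                np.interp(s, self.stations, self.sd))


def records_to_frame(records: Iterable[RibRecord]) -> pd.DataFrame:
    """Flatten rib records into a tidy long frame.

    Columns: subject, sex, rib, station_pct, and one column per property.
    """
    rows = []
    for rec in records:
        for station, sp in rec.properties.items():
            rows.append((rec.subject_id, rec.sex, rec.rib_number, station,
                         sp.tt_ar, sp.ct_ar, sp.es_ar, sp.i_max, sp.i_min,
                         sp.i_rat))
    if not rows:
        raise ValueError("no measured stations in the supplied records")
    return pd.DataFrame(rows, columns=["subject", "sex", "rib", "station_pct",
                                       *PROPERTY_NAMES])


def build_corridors(records: Iterable[RibRecord],
                    grid: Optional[StationGrid] = None
                    ) -> Dict[CorridorKey, Corridor]:
    """Pool records into corridors keyed by (sex, rib_number, property).

    Stations outside ``grid`` (when given) are dropped.  Single-subject
    stations get sd = NaN (undefined); an empty pool is an error.
    """
    frame = records_to_frame(records)
    if grid is not None:
        allowed = np.asarray(grid.stations)
        frame = frame[np.isclose(frame["station_pct"].to_numpy()[:, None],
                                 allowed[None, :]).any(axis=1)]
        if frame.empty:
            raise ValueError("no record stations fall on the requested grid")
    out: Dict[CorridorKey, Corridor] = {}
    grouped = frame.groupby(["sex", "rib"], sort=True)
    for (sex, rib), sub in grouped:
        agg = sub.groupby("station_pct", sort=True)[list(PROPERTY_NAMES)]
        mean = agg.mean()
        sd = agg.std(ddof=1)
        n = agg.count()
        stations = mean.index.to_numpy(dtype=float)
        for prop in PROPERTY_NAMES:
            out[(sex, int(rib), prop)] = Corridor(
                sex=sex, rib_number=int(rib), property_name=prop,
                stations=stations, mean=mean[prop].to_numpy(),
                sd=sd[prop].to_numpy(), n=n[prop].to_numpy())
    return out


def corridor_band(c: Corridor, k: float = 1.0
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stations, lower, upper) of the mean +- k*sd band.

    Stations with undefined sd are omitted.
    """
    ok = ~np.isnan(c.sd)
    return (c.stations[ok], c.mean[ok] - k * c.sd[ok],
            c.mean[ok] + k * c.sd[ok])


def corridors_to_frame(corridors: Mapping[CorridorKey, Corridor]) -> pd.DataFrame:
    rows = []
    for (sex, rib, prop), c in sorted(corridors.items()):
        for s, m, sd, n in zip(c.stations, c.mean, c.sd, c.n):
            rows.append((sex, rib, f"{s:.1f}", prop, m, sd, int(n)))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_corridor_csv(corridors: Mapping[CorridorKey, Corridor], path) -> None:
    """Write corridors to CSV (columns sex, rib, station_pct, property,
    mean, sd, n; station_pct with one decimal; sd empty where undefined)."""
    corridors_to_frame(corridors).to_csv(path, index=False)


def read_corridor_csv(path) -> Dict[CorridorKey, Corridor]:
    """Read a corridor CSV written by :func:`write_corridor_csv`.

    Raises ``ValueError`` naming the offending line for malformed rows and
    for missing columns.
    """
    frame = pd.read_csv(path, dtype={"sex": str, "property": str},
                        float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"corridor CSV missing column(s): {', '.join(missing)}")
    for col in ("rib", "station_pct", "mean", "sd", "n"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if col in ("rib", "station_pct", "mean", "n"):
            bad |= frame[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"corridor CSV: malformed value in column "
                             f"{col!r} at line {line}")
        frame[col] = coerced
    out: Dict[CorridorKey, Corridor] = {}
    for (sex, rib, prop), sub in frame.groupby(["sex", "rib", "property"]):
        sub = sub.sort_values("station_pct")
        out[(str(sex), int(rib), str(prop))] = Corridor(
            sex=str(sex), rib_number=int(rib), property_name=str(prop),
            stations=sub["station_pct"].to_numpy(dtype=float),
            mean=sub["mean"].to_numpy(dtype=float),
            sd=sub["sd"].to_numpy(dtype=float),
            n=sub["n"].to_numpy(dtype=int))
    return out


class CorridorModel:
    """Population-corridor estimator over a collection of rib records.

    Parameters
    ----------
    records : iterable of RibRecord
        Measured ribs, at least two subjects per (sex, rib) pool for the
        SD to be defined.
    grid : StationGrid, optional
        Station grid to restrict pooling to (default: the records' own
        stations).
    """

    def __init__(self, records: Sequence[RibRecord],
                 grid: Optional[StationGrid] = None):
        self.records = list(records)
        self.grid = grid
        if not self.records:
            raise ValueError("no records supplied")

    def fit(self) -> "CorridorResults":
        corridors = build_corridors(self.records, self.grid)
        return CorridorResults(self, corridors)


class CorridorResults:
    """Fitted population corridors with summary, band and audit helpers."""

    def __init__(self, model: CorridorModel,
                 corridors: Dict[CorridorKey, Corridor]):
        self.model = model
        self.corridors = corridors

    def __getitem__(self, key: CorridorKey) -> Corridor:
        return self.corridors[key]

    def band(self, sex: str, rib: int, prop: str, k: float = 1.0):
        return corridor_band(self.corridors[(sex, rib, prop)], k)

    def to_frame(self) -> pd.DataFrame:
        frame = corridors_to_frame(self.corridors)
        frame["station_pct"] = frame["station_pct"].astype(float)
        return frame

    def to_csv(self, path) -> None:
        write_corridor_csv(self.corridors, path)

    def compare(self, models: Sequence[RibRecord]) -> pd.DataFrame:
        """Audit HBM rib records against these corridors (full-precision
        comparison table; see :mod:`ribgeom.comparison`)."""
        from .comparison import comparison_table
        return comparison_table(models, self.corridors)

    def plot(self, sex: str, rib: int, prop: str, ax=None, k: float = 1.0,
             model_records: Sequence[RibRecord] = ()):
        from .plotting import plot_corridor
        return plot_corridor(self, sex, rib, prop, ax=ax, k=k,
                             model_records=model_records)

    def summary(self) -> str:
        """Compact text summary of the fitted corridors."""
        frame = self.to_frame()
        buf = io.StringIO()
        n_sub = frame.groupby("sex")["n"].max()
        buf.write("Population corridor summary\n")
        buf.write("===========================\n")
        buf.write(f"pools (sex x rib x property): {len(self.corridors)}; "
                  f"rows: {len(frame)}\n")
        for sex in sorted(frame["sex"].unique()):
            buf.write(f"sex {sex}: max n = {int(n_sub[sex])}\n")
        mid = frame[np.isclose(frame["station_pct"], 50.0)]
        if not mid.empty:
            piv = (mid.groupby(["sex", "property"])["mean"].mean()
                   .unstack("property").round(2))
            buf.write("\nMean at mid-shaft (50% station), averaged over ribs:\n")
            buf.write(piv.to_string())
            buf.write("\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path) -> "CorridorResults":
        corridors = read_corridor_csv(path)
        dummy = CorridorModel.__new__(CorridorModel)
        dummy.records, dummy.grid = [], None
        return cls(dummy, corridors)
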