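"""Model-vs-population audit: z-scores, average SD offsets, high/in/low %.

For each property trace of an HBM rib the per-station z-score against the
matching population corridor is

    z(s) = (model(s) - mean(s)) / sd(s)

summarized per rib as the signed average z (``avg_sds``) and the percentage
of the rib's length lying above (+1 SD), within, or below (-1 SD) the
corridor.  The boundary |z| = 1 counts as "within" (inclusive rule, with a
1e-9 relative guard so a model constructed exactly on the boundary is not
pushed out by floating-point round-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .corridors import Corridor, CorridorKey
from .rib_model import PROPERTY_NAMES, RibRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonRow",
    "zscore_series",
    "summarize_comparison",
    "comparison_table",
    "format_table",
    "write_comparison_csv",
]

#: inclusive "within 1 SD" boundary with a floating-point tie guard
_IN_BOUND = 1.0 + 1e-9


@dataclass(frozen=True)
class ComparisonRow:
    """One rib x property audit line (Table-style row, full precision)."""

    model_name: str
    sex: str
    rib_number: int
    property_name: str
    avg_sds: float
    pct_high: float
    pct_in: float
    pct_low: float
    n_stations: int

    def __post_init__(self) -> None:
        total = self.pct_high + self.pct_in + self.pct_low
        if not np.isclose(total, 100.0):
            raise ValueError("percentages must sum to 100 before rounding")


def zscore_series(trace: Mapping[float, float], corridor: Corridor
                  ) -> Dict[float, float]:
    """Per-station z-scores of a model trace against a corridor.

    Only stations present in both the trace and the corridor contribute;
    stations with undefined or zero corridor sd are excluded with a
    warning.  An empty overlap is an error.
    """
    stations = np.array(sorted(trace), dtype=float)
    idx = {round(float(s), 6): i for i, s in enumerate(corridor.stations)}
    out: Dict[float, float] = {}
    skipped = 0
    for s in stations:
        i = idx.get(round(float(s), 6))
        if i is None:
            continue
        sd = corridor.sd[i]
        if not np.isfinite(sd) or sd <= 0:
            skipped += 1
            continue
        out[float(s)] = (trace[s] - corridor.mean[i]) / sd
    if skipped:
        logger.warning("%s rib %d %s: %d station(s) with undefined/zero sd "
                       "excluded", corridor.sex, corridor.rib_number,
                       corridor.property_name, skipped)
    if not out:
        raise ValueError("no overlapping stations with defined sd")
    return out


def summarize_comparison(z: Mapping[float, float], model_name: str, sex: str,
                         rib_number: int, property_name: str) -> ComparisonRow:
    """Collapse a z-score series into one audit row."""
    zs = np.array([z[s] for s in sorted(z)], dtype=float)
    if zs.size == 0:
        raise ValueError("empty z-score series")
    high = int(np.sum(zs > _IN_BOUND))
    low = int(np.sum(zs < -_IN_BOUND))
    n = zs.size
    return ComparisonRow(
        model_name=model_name, sex=sex, rib_number=rib_number,
        property_name=property_name, avg_sds=float(zs.mean()),
        pct_high=100.0 * high / n, pct_in=100.0 * (n - high - low) / n,
        pct_low=100.0 * low / n, n_stations=n)


def comparison_table(models: Sequence[RibRecord],
                     corridors: Mapping[CorridorKey, Corridor]
                     ) -> pd.DataFrame:
    """Full-precision audit table: one row per (model rib, property).

    Model records are matched to corridors of the same sex and rib number;
    ribs without a matching corridor are skipped with a warning.
    """
    rows = []
    for rec in models:
        for prop in PROPERTY_NAMES:
            key = (rec.sex, rec.rib_number, prop)
            corridor = corridors.get(key)
            if corridor is None:
                logger.warning("no corridor for %s rib %d %s: row skipped",
                               rec.sex, rec.rib_number, prop)
                continue
            z = zscore_series(rec.trace(prop), corridor)
            row = summarize_comparison(z, rec.subject_id, rec.sex,
                                       rec.rib_number, prop)
            rows.append(row)
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if frame.empty:
        raise ValueError("no model/corridor overlap: empty comparison table")
    return frame.rename(columns={
        "model_name": "model", "rib_number": "rib",
        "property_name": "property"})


def write_comparison_csv(table: pd.DataFrame, path) -> None:
    """Machine-readable audit CSV, full precision."""
    cols = ["model", "sex", "rib", "property", "avg_sds",
            "pct_high", "pct_in", "pct_low", "n_stations"]
    table[cols].to_csv(path, index=False)


def format_table(table: pd.DataFrame) -> str:
    """Human-readable audit report (signed avg SDs to one decimal, integer
    high/in/low percentages, grouped by rib with models side by side)."""
    models = list(dict.fromkeys(table["model"]))
    lines = []
    header = f"{'':>8s} {'':>6s}"
    sub = f"{'':>8s} {'':>6s}"
    for m in models:
        header += f" | {m:^22s}"
        sub += f" | {'Avg':>5s} {'high':>4s} {'in':>4s} {'low':>4s}"
    unit = f"{'':>8s} {'':>6s}" + "".join(
        f" | {'SDs':>5s} {'%':>4s} {'%':>4s} {'%':>4s}" for _ in models)
    lines += [header, sub, unit]
    for rib in sorted(table["rib"].unique()):
        first = True
        for prop in PROPERTY_NAMES:
            line = f"{('Rib ' + str(rib)) if first else '':>8s} {prop:>6s}"
            first = False
            for m in models:
                sel = table[(table["rib"] == rib) & (table["model"] == m)
                            & (table["property"] == prop)]
                if sel.empty:
                    line += f" | {'--':>5s} {'':>4s} {'':>4s} {'':>4s}"
                    continue
                r = sel.iloc[0]
                v = r["avg_sds"]
                v = 0.0 if abs(v) < 0.05 else v  # avoid "-0.0"
                avg = f"{v:+.1f}".replace("-", "−")
                line += (f" | {avg:>5s} {round(r['pct_high']):>4d} "
                         f"{round(r['pct_in']):>4d} {round(r['pct_low']):>4d}")
            lines.append(line)
    return "\n".join(lines) + "\n"
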