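"""Corridor and audit figures (matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .corridors import CorridorResults, corridor_band
from .rib_model import RibRecord

__all__ = ["plot_corridor"]

_UNITS = {"Tt.Ar": "mm$^2$", "Ct.Ar": "mm$^2$", "Es.Ar": "mm$^2$",
          "Imax": "mm$^4$", "Imin": "mm$^4$", "Irat": "-"}


def plot_corridor(results: CorridorResults, sex: str, rib: int, prop: str,
                  ax=None, k: float = 1.0,
                  model_records: Sequence[RibRecord] = ()):
    """Mean +- k SD corridor band with optional HBM traces overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    corridor = results.corridors[(sex, rib, prop)]
    s, lo, hi = corridor_band(corridor, k)
    ax.fill_between(s, lo, hi, color="0.8",
                    label=f"population mean ± {k:g} SD")
    ax.plot(corridor.stations, corridor.mean, color="0.3", lw=1.2)
    for rec in model_records:
        if rec.rib_number != rib:
            continue
        trace = rec.trace(prop)
        st = np.array(sorted(trace))
        ax.plot(st, [trace[x] for x in st], lw=1.5, label=rec.subject_id)
    ax.set_xlabel("station (% of rib length, vertebral → sternal)")
    ax.set_ylabel(f"{prop} ({_UNITS[prop]})")
    ax.set_title(f"{sex} rib {rib}")
    ax.legend(fontsize=7, frameon=False)
    return ax
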