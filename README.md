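# ribgeom

Rib cross-sectional geometry for human body model (HBM) audits: exact
section properties of cortical-bone rib cross-sections, sex-specific
population corridors along rib lengths, and quantified comparisons of
finite-element HBM ribs against those corridors.

## The problem

Thorax finite-element models used in vehicle-safety research (GHBMC,
THUMS, VIVA+) model ribs as cortical shell elements whose geometry comes
from a single individual. Whether those rib cross-sections actually
represent the model's target demographic matters: local cross-sectional
size and aspect ratio are among the strongest predictors of rib stiffness
and fracture location. Auditing an HBM rib therefore requires (a)
population reference data — mean ± SD corridors of cross-sectional
properties as functions of rib number and position along the rib — and
(b) a way to extract equivalent cross-sections from the model's shell
mesh and score them against the corridors.

`ribgeom` implements that pipeline end to end. Because clinical CT
contours and commercial HBM meshes are not redistributable, the package
ships a first-class synthetic generator that emulates both inputs with
the statistical structure the analysis assumes, so every stage runs,
is testable, and is reproducible from a seed.

## The measurements

Each cross-section is the region between a periosteal (outer) and an
endosteal (inner) closed planar contour. For the cortical ring the
package computes, via exact Green's-theorem polygon sums:

- **Tt.Ar** — total sub-periosteal area (mm²),
- **Es.Ar** — endosteal area (mm²),
- **Ct.Ar** — cortical area, `Tt.Ar − Es.Ar` (mm²),
- **Imax, Imin** — principal/secondary second moments of area about the
  ring's own centroid (mm⁴), from the eigen-decomposition of the 2×2
  moment tensor,
- **Irat** — `ln(Imax/Imin)`, 0 for round sections, ~2.9 at an 18:1
  moment ratio.

Sections are measured at *stations*: 2.5 %, 5.0 %, …, 97.5 % of rib arc
length (39 stations, vertebral → sternal). Corridors pool subjects per
(sex, rib 2–11, property, station) into mean, sample SD (n−1) and n. An
HBM rib is scored per property by the per-station z-score
`z(s) = (model(s) − mean(s)) / sd(s)`, summarized as the signed average
(`Avg SDs`) and the percentage of rib length above (+1 SD), within, or
below (−1 SD) the corridor (boundary counts as "in").

HBM ribs enter as rings of shell-element nodes with thickness (neutral
JSON; 16-node GHBMC/VIVA+ style or 12-node THUMS style). Periosteal and
endosteal borders are recovered by offsetting each node ring by ± half
the shell thickness along outward vertex normals (midsurface convention;
configurable).

## Worked example

```python
import numpy as np
from ribgeom import *
from ribgeom.corridors import CorridorModel
from ribgeom.comparison import comparison_table, format_table

# exact section properties of an elliptical annulus (mm)
phi = np.arange(4096) * 2 * np.pi / 4096
outer = validate_contour(np.stack([3 * np.cos(phi), 2 * np.sin(phi)], 1))
inner = validate_contour(np.stack([2 * np.cos(phi), 1 * np.sin(phi)], 1))
sp = composite_section_properties(outer, inner)
print(f"Tt.Ar={sp.tt_ar:.3f} Ct.Ar={sp.ct_ar:.3f} Es.Ar={sp.es_ar:.3f}")
print(f"Imax={sp.i_max:.3f} Imin={sp.i_min:.3f} Irat={sp.i_rat:.4f}")

# population corridors from the default synthetic cohort (118 M / 122 F)
pop = simulate_population(default_population_spec(), seed=1)
corridors = CorridorModel(pop.records).fit()

# audit a synthetic HBM rib built 2 SD oversized in cross-sectional area
mesh = simulate_hbm_mesh(corridors, "M", 6, model_name="SYNTH M50",
                         offsets={"Tt.Ar": 2.0, "Es.Ar": 2.0})
record = hbm_rib_to_record(mesh, default_station_grid())
print(format_table(comparison_table([record], corridors.corridors)))
```

prints

```
Tt.Ar=18.850 Ct.Ar=12.566 Es.Ar=6.283
Imax=36.128 Imin=17.279 Irat=0.7376
                |       SYNTH M50
                |   Avg high   in  low
                |   SDs    %    %    %
   Rib 6  Tt.Ar |  +2.0  100    0    0
          Ct.Ar |  +2.0  100    0    0
          Es.Ar |  +2.0  100    0    0
           Imax |  +2.1  100    0    0
           Imin |  +2.1  100    0    0
           Irat |  +0.0    0  100    0
```

The annulus values match the closed forms (Ct.Ar = 4π;
Irat = ln(46/22)). The audit shows the oversized model rib sitting +2.0
SD above the population in every area measure along 100 % of its length
— the Table-style layout used for real HBM audits — while its aspect
ratio (Irat) tracks the population mean.

The same pipeline is available from the shell:

```sh
ribgeom simulate --out-corridors corridors.csv --seed 1
ribgeom compare --corridors corridors.csv --mesh my_rib.json --out-csv audit.csv
```

## Layout

- `src/ribgeom/geometry.py` — contours, exact polygon section
  properties, vertex-normal offsetting, rasterization test oracle
- `src/ribgeom/rib_model.py` — station grids, section-plane frames, rib
  records
- `src/ribgeom/hbm_mesh.py` — ring-mesh JSON, border extraction,
  mesh → record
- `src/ribgeom/corridors.py` — `CorridorModel` / `CorridorResults`,
  corridor CSV
- `src/ribgeom/comparison.py` — z-scores, audit tables and reports
- `src/ribgeom/synthetic.py` — population spec/generator, synthetic HBM
  meshes, segmentation-bias demo
- `src/ribgeom/cli.py` — `ribgeom` command (simulate / measure /
  corridors / compare / report)

See `docs/methods.md` for the generative model, conventions and
numerical choices.
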