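"""Shared fixtures: parametric contours and a small simulated population."""

import math

import numpy as np
import pytest

from ribgeom import default_population_spec, simulate_population
from ribgeom.corridors import CorridorModel
from ribgeom.geometry import validate_contour


def ellipse_polygon(a, b, n=4096, center=(0.0, 0.0), phase=0.0):
    """Polygonized ellipse with semi-axis a along x, b along y (CCW)."""
    phi = np.arange(n) * 2 * math.pi / n + phase
    return np.stack([center[0] + a * np.cos(phi),
                     center[1] + b * np.sin(phi)], axis=1)


def circle_polygon(r, n=4096, center=(0.0, 0.0)):
    return ellipse_polygon(r, r, n=n, center=center)


def regular_polygon_area(n, vertex_radius):
    """Exact area of a regular n-gon with given vertex radius."""
    return 0.5 * n * vertex_radius ** 2 * math.sin(2 * math.pi / n)


def random_hollow_section(rng, n=256, min_aspect=1.0):
    """Random star-convex hollow section (outer, inner) Contour pair.

    Outer boundary: smooth star-shaped radius function (low harmonics) of a
    base ellipse; inner boundary: the outer radius scaled by a smooth
    factor in [0.55, 0.8], guaranteeing strict nesting and simplicity.
    """
    theta = np.arange(n) * 2 * math.pi / n
    r0 = rng.uniform(4.0, 8.0)
    aspect = rng.uniform(min_aspect, max(min_aspect, 2.5))
    wobble = np.zeros(n)
    for k in (2, 3, 5):
        wobble += rng.uniform(0.0, 0.06) * np.cos(k * theta + rng.uniform(0, 2 * math.pi))
    r_out = r0 * (1.0 + wobble)
    outer = np.stack([r_out * np.cos(theta), aspect * r_out * np.sin(theta)],
                     axis=1)
    factor = 0.675 + 0.1 * np.cos(2 * theta + rng.uniform(0, 2 * math.pi)) \
        + 0.025 * np.cos(3 * theta)
    inner = factor[:, None] * outer
    return validate_contour(outer), validate_contour(inner)


@pytest.fixture(scope="session")
def small_population():
    spec = default_population_spec()
    spec.n_male = 15
    spec.n_female = 15
    return simulate_population(spec, seed=123)


@pytest.fixture(scope="session")
def small_corridors(small_population):
    return CorridorModel(small_population.records).fit()
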