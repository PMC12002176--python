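import numpy as np
import pytest

from ectopicgc.shm import GermlineReference
from ectopicgc.spatial import CellPoint, GCRegion, SpatialSample

KEY = 33


def make_plain_reference(n_codons: int = 40) -> GermlineReference:
    """Hand-framed reference: GCT (Ala) everywhere except TGG at codon 33."""
    codons = ["GCT"] * n_codons
    codons[KEY - 1] = "TGG"
    return GermlineReference(name="plain", seq="".join(codons))


@pytest.fixture
def plain_ref() -> GermlineReference:
    return make_plain_reference()


@pytest.fixture
def square_region() -> GCRegion:
    return GCRegion(((-10.0, -10.0), (10.0, -10.0), (10.0, 10.0), (-10.0, 10.0)))


def sample_from_points(points, region=None, cell_type="Tfh") -> SpatialSample:
    region = region or GCRegion(
        ((-10.0, -10.0), (10.0, -10.0), (10.0, 10.0), (-10.0, 10.0)))
    cells = [CellPoint(float(x), float(y), cell_type) for x, y in points]
    return SpatialSample("gc", region, cells)


def star_polygon(rng: np.random.Generator, n_vertices: int = 12,
                 r_min: float = 2.0, r_max: float = 10.0) -> GCRegion:
    """Random star-shaped (hence simple) polygon around the origin.

    Angles are jittered regular spacings so they always wrap the full
    circle; purely random angles can cluster in a half-plane, leaving
    the origin outside and letting the closing edge self-intersect.
    """
    angles = (np.arange(n_vertices)
              + rng.uniform(0.1, 0.9, n_vertices)) * 2 * np.pi / n_vertices
    radii = rng.uniform(r_min, r_max, n_vertices)
    xs, ys = radii * np.cos(angles), radii * np.sin(angles)
    return GCRegion(tuple(zip(xs, ys)))
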