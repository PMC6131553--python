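import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def square_lattice(nx: int, spacing: float = 1.0) -> np.ndarray:
    """nx x nx square lattice of cell centres, unit cells of area spacing^2."""
    g = (np.arange(nx) + 0.5) * spacing
    xx, yy = np.meshgrid(g, g)
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def hexagonal_lattice(nx: int, ny: int):
    """Periodic triangular lattice whose Voronoi cells are unit-area
    regular hexagons; returns (positions, (Lx, Ly)).  ny must be even for
    periodicity."""
    a = np.sqrt(2.0 / np.sqrt(3.0))  # lattice constant for unit cell area
    dy = a * np.sqrt(3.0) / 2.0
    pts = []
    for j in range(ny):
        for i in range(nx):
            pts.append(((i + 0.5 * (j % 2)) * a, j * dy))
    return np.array(pts), (nx * a, ny * dy)
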