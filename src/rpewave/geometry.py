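"""Hexagonal-monolayer geometry.

The epithelium is idealized as a plane tiling of regular hexagonal cells.
One mechanically stimulated (MS) cell sits at the origin and its neighbours
are grouped into concentric rings: NB1 is the ring of cells touching the MS
cell, NB2 the ring touching NB1, and so on.  Each ring is treated as a single
well-mixed compartment, so the only geometric quantities the dynamics need
are the ring's radial distance from the MS cell centre, the membrane area
through which one ring touches the next, and the cytoplasmic volume of a
single cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellGeometry",
    "layer_distance",
    "layer_distances",
    "interface_area",
    "interface_areas",
    "cytoplasmic_volume",
]


@dataclass(frozen=True)
class CellGeometry:
    """Geometry of a single hexagonal cell and the ring layout.

    Parameters
    ----------
    side_length : float
        Hexagon side ``s`` in μm.  Equals the circumradius, so the
        corner-to-corner cell width is ``2 s`` (14 μm by default).
    cell_height : float
        Monolayer height ``h`` in μm.
    cytoplasm_fraction : float
        Fraction of the total cell volume occupied by cytoplasm.
    n_layers : int
        Number of concentric neighbour rings simulated.
    """

    side_length: float = 7.0
    cell_height: float = 12.0
    cytoplasm_fraction: float = 0.7
    n_layers: int = 10

    def __post_init__(self) -> None:
        if self.side_length < 0:
            raise ValueError("side_length must be non-negative")
        if self.cell_height <= 0:
            raise ValueError("cell_height must be positive")
        if not 0 < self.cytoplasm_fraction <= 1:
            raise ValueError("cytoplasm_fraction must be in (0, 1]")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def apothem(self) -> float:
        """Hexagon apothem ``a = s / (2 tan(pi/6))`` in μm."""
        return self.side_length / (2.0 * math.tan(math.pi / 6.0))


def layer_distance(n: int, geom: CellGeometry = CellGeometry()) -> float:
    """Distance ``x`` (μm) of ring *n* from the MS cell centre.

    Crossing from one ring to the next advances the radial position by one
    cell width measured flat-to-flat, i.e. two apothems: ``x = 2 n a``.
    """
    if n < 1:
        raise ValueError(f"layer index must be >= 1, got {n}")
    return 2.0 * n * geom.apothem


def layer_distances(geom: CellGeometry = CellGeometry()) -> np.ndarray:
    """Distances of rings 1..n_layers as an array (μm)."""
    return 2.0 * geom.apothem * np.arange(1, geom.n_layers + 1, dtype=float)


def interface_area(n: int, geom: CellGeometry = CellGeometry()) -> float:
    """Membrane area ``A`` (μm²) between ring *n* and ring *n + 1*.

    Ring *n* contains six corner cells that present three edges to the next
    ring and ``6 (n - 1)`` side cells that present two, so the shared wall
    counts ``(3 + 2 (n - 1)) · 6`` hexagon edges of area ``s · h`` each.
    """
    if n < 1:
        raise ValueError(f"layer index must be >= 1, got {n}")
    n_edges = (3 + 2 * (n - 1)) * 6
    return n_edges * geom.side_length * geom.cell_height


def interface_areas(geom: CellGeometry = CellGeometry()) -> np.ndarray:
    """Areas A(n -> n+1) for n = 1..n_layers as an array (μm²)."""
    n = np.arange(1, geom.n_layers + 1, dtype=float)
    return (3.0 + 2.0 * (n - 1.0)) * 6.0 * geom.side_length * geom.cell_height


def cytoplasmic_volume(geom: CellGeometry = CellGeometry()) -> float:
    """Cytoplasmic volume of one cell in m³.

    Regular-hexagon footprint ``(3 √3 / 2) s²`` times the cell height, scaled
    by the cytoplasm fraction and converted from μm³ to m³.
    """
    footprint_um2 = 1.5 * math.sqrt(3.0) * geom.side_length**2
    volume_um3 = footprint_um2 * geom.cell_height * geom.cytoplasm_fraction
    return volume_um3 * 1e-18
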