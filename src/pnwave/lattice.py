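"""Cell lattices: 1D chains and 2D hexagonal patches/discs.

The model tissue is a static lattice of cells.  A lattice stores cell-centre
coordinates (unit spacing between adjacent cells), the symmetric neighbour
relation, and, where meaningful, a per-cell column index along the wave axis
and the polar angle about the lattice centre (used by angular-sector initial
conditions on discs).

Boundaries are no-flux: boundary cells simply have fewer neighbours, so the
discrete diffusion operator conserves total mass automatically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "LatticeKind",
    "CellLattice",
    "build_chain",
    "build_hex_rect",
    "build_hex_disc",
    "laplacian",
    "neighbor_mean",
]

_NEIGHBOR_TOL = 1e-6  # adjacency = centre distance within this of unit spacing


class LatticeKind(str, enum.Enum):
    CHAIN_1D = "CHAIN_1D"
    HEX_RECT = "HEX_RECT"
    HEX_DISC = "HEX_DISC"


@dataclass
class CellLattice:
    """A static cell arrangement with symmetric, irreflexive adjacency.

    Attributes
    ----------
    coordinates : (n, 2) array of cell-centre positions, unit spacing.
    neighbors : list of index arrays, one per cell.
    column : per-cell integer column index along the wave (x) axis
        (chains and rectangular patches; -1 on discs).
    angle : polar angle of each cell about the lattice centroid, in
        [0, 2π) measured counter-clockwise from +x (discs; 0 elsewhere).
    """

    kind: LatticeKind
    coordinates: np.ndarray
    neighbors: list[np.ndarray]
    column: np.ndarray = field(default=None)  # type: ignore[assignment]
    angle: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.n_cells
        if self.column is None:
            self.column = np.full(n, -1, dtype=int)
        if self.angle is None:
            self.angle = np.zeros(n)
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("neighbor relation must be irreflexive")

    @property
    def n_cells(self) -> int:
        return len(self.coordinates)

    @property
    def coupling_constant(self) -> float:
        """Stencil prefactor making the neighbour-difference sum consistent
        with the continuum Laplacian at unit spacing: 1 on chains, 2/3 on
        hexagonal lattices (exact for quadratic fields)."""
        return 1.0 if self.kind is LatticeKind.CHAIN_1D else 2.0 / 3.0

    @property
    def adjacency(self) -> sparse.csr_matrix:
        rows = np.concatenate([np.full(len(nb), i) for i, nb in enumerate(self.neighbors)])
        cols = np.concatenate(self.neighbors) if self.n_cells else np.array([], dtype=int)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n_cells,) * 2)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def boundary_cells(self) -> np.ndarray:
        """Cells with fewer neighbours than an interior cell (2 on chains,
        6 on hexagonal lattices)."""
        interior = 2 if self.kind is LatticeKind.CHAIN_1D else 6
        return np.flatnonzero(self.degrees < interior)

    def laplacian_matrix(self) -> sparse.csr_matrix:
        A = self.adjacency
        L = A - sparse.diags(self.degrees.astype(float))
        return (self.coupling_constant * L).tocsr()

    # -- plain-text serialization ------------------------------------------
    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(cells, edges) tables: cells has cell_id/x/y/column/angle, edges
        one row per undirected edge (cell_a < cell_b)."""
        cells = pd.DataFrame({
            "cell_id": np.arange(self.n_cells),
            "x": self.coordinates[:, 0],
            "y": self.coordinates[:, 1],
            "column": self.column,
            "angle": self.angle,
        })
        pairs = sorted({(min(i, j), max(i, j))
                        for i, nb in enumerate(self.neighbors) for j in nb})
        edges = pd.DataFrame(pairs, columns=["cell_a", "cell_b"])
        return cells, edges

    def save(self, path) -> None:
        cells, edges = self.to_tables()
        with open(path, "w") as fh:
            fh.write(f"# pnwave lattice kind={self.kind.value}\n")
            fh.write(f"# n_cells={self.n_cells} n_edges={len(edges)}\n")
            cells.to_csv(fh, sep="\t", index=False)
            fh.write("# edges\n")
            edges.to_csv(fh, sep="\t", index=False)


def _lattice_from_points(points: np.ndarray, kind: LatticeKind, **kw) -> CellLattice:
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=1.0 + _NEIGHBOR_TOL, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(len(points))]
    for a, b in pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)
    nb = [np.array(sorted(x), dtype=int) for x in neighbors]
    return CellLattice(kind=kind, coordinates=points, neighbors=nb, **kw)


def build_chain(n: int) -> CellLattice:
    """A 1D array of ``n`` cells with unit spacing and no-flux ends."""
    if n < 2:
        raise ValueError(f"chain needs at least 2 cells, got {n}")
    pts = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    lat = _lattice_from_points(pts, LatticeKind.CHAIN_1D)
    lat.column = np.arange(n)
    return lat


def build_hex_rect(n_cols: int, n_rows: int) -> CellLattice:
    """A rectangular hexagonal patch of n_cols x n_rows cells.

    Columns run along the wave (x) axis with horizontal spacing sqrt(3)/2;
    odd columns are shifted up by 1/2 ("odd-q" offset), giving each interior
    cell six neighbours at unit distance.
    """
    if n_cols < 2 or n_rows < 2:
        raise ValueError("hexagonal patch needs n_cols, n_rows >= 2")
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows), indexing="ij")
    cols, rows = cols.ravel(), rows.ravel()
    x = cols * (np.sqrt(3.0) / 2.0)
    y = rows + 0.5 * (cols % 2)
    lat = _lattice_from_points(np.column_stack([x, y]), LatticeKind.HEX_RECT)
    lat.column = cols.astype(int)
    return lat


def build_hex_disc(radius: float) -> CellLattice:
    """All triangular-lattice cells within ``radius`` of a centre cell.

    The disc is generated from the axial basis u=(1,0), v=(1/2, sqrt(3)/2)
    and is invariant under 60° rotation about its centre.  Per-cell polar
    angles (counter-clockwise from +x) support angular-sector initial
    conditions.
    """
    if radius < 1:
        raise ValueError(f"disc radius must be >= 1, got {radius}")
    m = int(np.ceil(radius)) + 1
    u = np.array([1.0, 0.0])
    v = np.array([0.5, np.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-2 * m, 2 * m + 1):
        for j in range(-2 * m, 2 * m + 1):
            p = i * u + j * v
            if np.hypot(*p) <= radius + 1e-9:
                pts.append(p)
    pts = np.array(sorted(pts, key=lambda p: (round(p[1], 9), round(p[0], 9))))
    lat = _lattice_from_points(pts, LatticeKind.HEX_DISC)
    lat.angle = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    return lat


def _check_field(field_values, lattice: CellLattice) -> np.ndarray:
    f = np.asarray(field_values, dtype=float)
    if f.shape != (lattice.n_cells,):
        raise ValueError(
            f"field shape {f.shape} does not match lattice with {lattice.n_cells} cells")
    return f


def laplacian(field_values, lattice: CellLattice) -> np.ndarray:
    """Discrete no-flux Laplacian: c * sum_j (f_j - f_i) over neighbours j,
    with c = 1 (chain) or 2/3 (hexagonal)."""
    f = _check_field(field_values, lattice)
    return lattice.laplacian_matrix() @ f


def neighbor_mean(field_values, lattice: CellLattice) -> np.ndarray:
    """Arithmetic mean of a field over each cell's neighbours (the trans
    Delta signal a cell receives)."""
    f = _check_field(field_values, lattice)
    deg = lattice.degrees
    if np.any(deg == 0):
        raise ValueError("lattice has isolated cells; neighbor_mean undefined")
    return (lattice.adjacency @ f) / deg
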