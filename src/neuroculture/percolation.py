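"""Continuum-percolation geometry of developing neuronal cultures.

Neurons are modelled as randomly placed cells in the unit square.  Each
cell has a circular dendrite (reception) region of radius ``R`` centred on
its soma ("tail") and a straight axon of length ``H`` whose end point
("head") transmits the cell's output.  Connectivity arises geometrically
in three ways:

``circle``
    No axons (``H = 0``): two cells are coupled when their dendrite
    circles overlap — the classical scalar disk-percolation problem.
``dipole``
    Axons transmit both ways: each cell is an undirected pair of head-
    and tail-circles and any head/tail overlap couples the pair.
``vector``
    Axons transmit one way: a directed link i → j exists when the head
    of i falls within reach of the dendrite circle of j.

The control parameter is the mean occupancy ``B = pi * R**2 * n`` (``n``
cells per unit area): the expected number of cell centres inside one
dendrite circle.  A spanning cluster — one touching both the left and the
right boundary of the square — appears with probability 1/2 at a critical
occupancy ``B_c``, estimated here by Monte-Carlo sweeps over ``B``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

CASES = ("circle", "dipole", "vector")

__all__ = [
    "CellField",
    "ConnectivityGraph",
    "PercolationEstimate",
    "sample_field",
    "build_connectivity",
    "spanning_cluster_exists",
    "estimate_Bc",
]


@dataclass(frozen=True)
class CellField:
    """A random planar arrangement of model neurons in the unit square."""

    positions: np.ndarray  # (N, 2) tail (soma) centres in [0, 1]^2
    axon_angles: np.ndarray  # (N,) angles in [0, 2*pi)
    R: float  # dendrite-circle radius
    H: float  # axon length

    @property
    def N(self) -> int:
        return len(self.positions)

    @property
    def head_positions(self) -> np.ndarray:
        """Axon end points: tail + H * (cos(theta), sin(theta))."""
        offsets = self.H * np.column_stack(
            [np.cos(self.axon_angles), np.sin(self.axon_angles)]
        )
        return self.positions + offsets


@dataclass(frozen=True)
class ConnectivityGraph:
    """Pairwise geometric couplings of a :class:`CellField`.

    ``edges`` is an (M, 2) integer array.  For the undirected cases each
    unordered pair appears once; for ``vector`` rows are ordered (i, j)
    meaning i → j.
    """

    node_count: int
    edges: np.ndarray
    directed: bool = False


@dataclass(frozen=True)
class PercolationEstimate:
    """Monte-Carlo estimate of the spanning threshold for one geometry."""

    case_label: str
    H_over_R: float
    B_c_hat: float
    spanning_curve: list  # [(B, spanning_probability), ...]
    n_realizations: int
    seed: int


def sample_field(N: int, R: float, H: float, seed: int) -> CellField:
    """Draw a field of ``N`` cells with i.i.d. uniform positions and
    isotropic axon directions.

    Parameters
    ----------
    N : cell count (>= 1)
    R : dendrite radius in unit-square units (> 0)
    H : axon length (>= 0); heads coincide with tails when 0
    seed : RNG seed; identical seeds give identical fields
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if R <= 0:
        raise ValueError(f"R must be > 0, got {R}")
    if H < 0:
        raise ValueError(f"H must be >= 0, got {H}")
    rng = np.random.default_rng(seed)
    positions = rng.random((N, 2))
    angles = rng.uniform(0.0, 2.0 * np.pi, N)
    return CellField(positions=positions, axon_angles=angles, R=float(R), H=float(H))


def _undirected_unique(pairs: np.ndarray) -> np.ndarray:
    """Canonicalize an (M, 2) pair array: sorted rows, deduplicated,
    self-loops removed."""
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(np.asarray(pairs, dtype=np.int64), axis=1)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    return np.unique(pairs, axis=0)


def build_connectivity(field: CellField, case_label: str) -> ConnectivityGraph:
    """Build the geometric coupling graph for one of the three cases.

    circle : undirected edge iff dist(tail_i, tail_j) <= 2R (heads ignored)
    dipole : undirected edge iff any of the four head/tail pairings of the
             two cells are within 2R
    vector : directed edge i -> j iff dist(head_i, tail_j) <= 2R
    """
    if case_label not in CASES:
        raise ValueError(f"unknown case {case_label!r}; expected one of {CASES}")
    tails = field.positions
    reach = 2.0 * field.R
    if case_label == "circle":
        tree = cKDTree(tails)
        pairs = tree.query_pairs(reach, output_type="ndarray")
        return ConnectivityGraph(field.N, _undirected_unique(pairs), directed=False)
    heads = field.head_positions
    if case_label == "dipole":
        # Overlap of any of the 4 (head|tail) x (head|tail) circle pairs:
        # treat all 2N circles as points, map back to cell index mod N.
        pts = np.vstack([tails, heads])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(reach, output_type="ndarray")
        cell_pairs = pairs % field.N
        return ConnectivityGraph(field.N, _undirected_unique(cell_pairs), directed=False)
    # vector: head of i within 2R of tail of j
    tail_tree = cKDTree(tails)
    neighbours = tail_tree.query_ball_point(heads, reach)
    src: list[int] = []
    dst: list[int] = []
    for i, js in enumerate(neighbours):
        for j in js:
            if j != i:
                src.append(i)
                dst.append(j)
    edges = (
        np.column_stack([src, dst]).astype(np.int64)
        if src
        else np.empty((0, 2), dtype=np.int64)
    )
    return ConnectivityGraph(field.N, edges, directed=True)


def _boundary_touch(field: CellField, use_heads: bool) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of cells whose tail- (or head-) circle reaches the
    left (x <= R) or right (x >= 1 - R) edge of the square."""
    x = field.positions[:, 0]
    left = x <= field.R
    right = x >= 1.0 - field.R
    if use_heads and field.H > 0:
        hx = field.head_positions[:, 0]
        left |= hx <= field.R
        right |= hx >= 1.0 - field.R
    return left, right


def spanning_cluster_exists(graph: ConnectivityGraph, field: CellField) -> bool:
    """True iff a connected cluster touches both the left and the right
    boundary of the unit square.

    Connectivity is taken in the undirected sense for all cases (the
    directed ``vector`` graph is symmetrised; the edge list keeps its
    directions so stricter variants remain possible downstream).
    """
    n = graph.node_count
    if n == 0:
        return False
    left, right = _boundary_touch(field, use_heads=graph.directed or field.H > 0)
    if not left.any() or not right.any():
        return False
    if len(graph.edges) == 0:
        return bool(np.any(left & right))
    rows, cols = graph.edges[:, 0], graph.edges[:, 1]
    adj = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return bool(np.intersect1d(labels[left], labels[right]).size > 0)


def _radius_for(B: float, N: int) -> float:
    # B = pi R^2 n with n = N per unit area  =>  R = sqrt(B / (pi N))
    return math.sqrt(B / (math.pi * N))


def spanning_probability(
    case_label: str,
    B: float,
    H_over_R: float,
    N: int,
    n_realizations: int,
    seed: int,
) -> float:
    """Fraction of independent fields at occupancy ``B`` that span."""
    R = _radius_for(B, N)
    H = H_over_R * R
    seeds = np.random.SeedSequence(seed).generate_state(n_realizations)
    hits = 0
    for s in seeds:
        fld = sample_field(N, R, H, int(s))
        g = build_connectivity(fld, case_label)
        if spanning_cluster_exists(g, fld):
            hits += 1
    return hits / n_realizations


def estimate_Bc(
    case_label: str,
    H_over_R: float,
    N: int,
    n_realizations: int,
    B_grid,
    seed: int,
) -> PercolationEstimate:
    """Estimate the percolation threshold ``B_c`` for one geometry.

    For each occupancy ``B`` in the increasing grid, the dendrite radius is
    set from ``B = pi R**2 N`` (unit square, so density n = N), the axon
    length from the fixed ratio ``H/R``, and the spanning probability is
    measured over ``n_realizations`` independent fields.  ``B_c`` is where
    linear interpolation of the spanning curve first crosses 1/2.

    Raises
    ------
    ValueError
        If the grid is not increasing/positive, or the spanning curve
        never brackets 1/2 within the grid.
    """
    if case_label not in CASES:
        raise ValueError(f"unknown case {case_label!r}")
    B_grid = np.asarray(B_grid, dtype=float)
    if B_grid.ndim != 1 or len(B_grid) == 0:
        raise ValueError("B_grid must be a non-empty 1-D sequence")
    if np.any(B_grid <= 0) or np.any(np.diff(B_grid) <= 0):
        raise ValueError("B_grid must be positive and strictly increasing")

    # independent substream per grid point, reproducible given seed
    point_seeds = np.random.SeedSequence(seed).generate_state(len(B_grid))
    probs = np.array(
        [
            spanning_probability(case_label, B, H_over_R, N, n_realizations, int(s))
            for B, s in zip(B_grid, point_seeds)
        ]
    )

    above = probs >= 0.5
    if not above.any():
        raise ValueError(
            f"spanning curve does not cross 0.5 within B grid "
            f"[{B_grid[0]}, {B_grid[-1]}]: probabilities span "
            f"[{probs.min():.3f}, {probs.max():.3f}] — widen the grid"
        )
    hi = int(np.argmax(above))  # first grid point at/above 0.5
    if hi == 0:
        raise ValueError(
            "spanning probability already >= 0.5 at the smallest grid B "
            f"({B_grid[0]}): lower bracket missing"
        )
    lo = hi - 1
    p0, p1 = probs[lo], probs[hi]
    B_c = B_grid[lo] + (0.5 - p0) / (p1 - p0) * (B_grid[hi] - B_grid[lo])
    return PercolationEstimate(
        case_label=case_label,
        H_over_R=float(H_over_R),
        B_c_hat=float(B_c),
        spanning_curve=list(zip(B_grid.tolist(), probs.tolist())),
        n_realizations=n_realizations,
        seed=seed,
    )
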