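"""Virtual chain-tape rugosity over a TIN.

The in-situ chain-and-tape method drapes a chain of length L over the
substrate and divides by the taped straight-line distance D between its
ends; rugosity R = L / D >= 1, with 1 on flat ground.  The virtual
equivalent slices the mesh with a vertical plane through two endpoints,
collects the vertices lying within a threshold gamma of that plane,
orders them into a chain and takes the same length ratio.

Chain segments are full 3D Euclidean distances between consecutive
selected vertices (a physical chain lies on the terrain, not in the
slicing plane); the in-plane projected length is also reported for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, EmptyChainError
from .mesh import Plane, TriangleMesh, edge_length_stats, point_plane_distance

__all__ = [
    "Chain",
    "define_vertical_plane",
    "select_chain_vertices",
    "trace_chain",
    "chain_rugosity",
    "chain_transect",
]

#: endpoint coincidence tolerance (m)
_COINCIDE_TOL = 1e-9
#: warn when the largest along-transect gap exceeds this many gammas
_GAP_FACTOR = 10.0


@dataclass
class Chain:
    """An ordered virtual chain from ``v_s`` to ``v_e``.

    ``points`` runs from within gamma of the start point to within gamma
    of the end point, with no repeated consecutive positions.
    """

    points: np.ndarray
    v_s: np.ndarray
    v_e: np.ndarray
    gamma: float
    max_gap: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.v_s = np.asarray(self.v_s, dtype=np.float64).reshape(3)
        self.v_e = np.asarray(self.v_e, dtype=np.float64).reshape(3)

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Chain length L: sum of consecutive 3D segment lengths (m)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def tape_distance(self) -> float:
        """Tape distance D: straight-line 3D distance start to end (m)."""
        return float(np.linalg.norm(self.v_e - self.v_s))

    @property
    def in_plane_length(self) -> float:
        """Chain length with each segment projected into the slicing plane.

        Differs from :attr:`length` by at most gamma-order terms; reported
        so the two summation conventions can be compared.
        """
        if len(self.points) < 2:
            return 0.0
        plane = define_vertical_plane(self.v_s, self.v_e)
        offsets = self.points @ plane.normal
        proj = self.points - (offsets - offsets.mean())[:, None] * plane.normal
        return float(np.linalg.norm(np.diff(proj, axis=0), axis=1).sum())


def define_vertical_plane(v_s, v_e) -> Plane:
    """Vertical slicing plane through the two transect endpoints.

    The plane contains ``v_s``, ``v_e`` and a point directly above
    ``v_s``, so its normal is horizontal.

    Raises
    ------
    DegenerateGeometryError
        If the endpoints coincide in the E-N projection (the vertical
        plane is then undefined).
    """
    v_s = np.asarray(v_s, dtype=np.float64).reshape(3)
    v_e = np.asarray(v_e, dtype=np.float64).reshape(3)
    d_en = v_e[:2] - v_s[:2]
    if np.linalg.norm(d_en) <= _COINCIDE_TOL:
        raise DegenerateGeometryError(
            "transect endpoints coincide in the E-N projection; vertical plane undefined"
        )
    # cross((v_e - v_s), up) is horizontal and normal to the span
    normal = np.array([d_en[1], -d_en[0], 0.0])
    normal /= np.linalg.norm(normal)
    return Plane(normal=normal, offset=-float(normal @ v_s))


def select_chain_vertices(
    mesh: TriangleMesh, plane: Plane, gamma: float, v_s, v_e
) -> np.ndarray:
    """Mesh vertices within ``gamma`` of the slicing plane, between endpoints.

    A vertex is selected when its point-plane distance is <= gamma AND its
    projection onto the horizontal start-to-end direction lies within
    [0, |v_e - v_s|_EN] — candidates beyond the tape ends are excluded so
    the chain cannot overshoot.  ``v_s`` and ``v_e`` are appended as
    virtual points if no selected mesh vertex coincides with them.

    Returns the unordered candidate positions as an (k, 3) array.

    Raises
    ------
    EmptyChainError
        If no mesh vertex satisfies the selection (the message names
        gamma so the caller can widen it).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    v_s = np.asarray(v_s, dtype=np.float64).reshape(3)
    v_e = np.asarray(v_e, dtype=np.float64).reshape(3)
    d = point_plane_distance(mesh.vertices, plane)
    direction = v_e[:2] - v_s[:2]
    span = np.linalg.norm(direction)
    direction = direction / span
    t = (mesh.vertices[:, :2] - v_s[:2]) @ direction
    mask = (d <= gamma) & (t >= -_COINCIDE_TOL) & (t <= span + _COINCIDE_TOL)
    selected = mesh.vertices[mask]
    if len(selected) == 0:
        raise EmptyChainError(
            f"no mesh vertices within gamma={gamma:g} m of the slicing plane "
            "between the endpoints; increase gamma or check the transect location"
        )
    out = [selected]
    for endpoint in (v_s, v_e):
        if np.min(np.linalg.norm(selected - endpoint, axis=1)) > _COINCIDE_TOL:
            out.append(endpoint[None, :])
    return np.concatenate(out, axis=0)


def _along_transect(points: np.ndarray, v_s: np.ndarray, v_e: np.ndarray) -> np.ndarray:
    direction = v_e[:2] - v_s[:2]
    direction = direction / np.linalg.norm(direction)
    return (points[:, :2] - v_s[:2]) @ direction


def trace_chain(
    candidates: np.ndarray,
    v_s,
    v_e,
    gamma: float = np.nan,
    ordering: str = "projection",
) -> Chain:
    """Order candidate vertices into a chain from ``v_s`` to ``v_e``.

    ordering="projection" (default) sorts by the scalar projection of each
    candidate onto the horizontal start-to-end direction, with ties broken
    by vertical coordinate then input index — a deterministic total order.
    ordering="greedy" reproduces the distance-matrix walk (repeatedly link
    the nearest unvisited candidate, starting at the start point and
    stopping at the end point); it agrees with the projection order on
    clean transects but can stall or jump on noisy ribbons.

    Consecutive duplicate positions are dropped.  If the largest
    along-transect gap between consecutive chain points exceeds
    10 x gamma a warning is emitted (the chain bridges unsampled terrain)
    but the chain is still returned.
    """
    cand = np.atleast_2d(np.asarray(candidates, dtype=np.float64))
    v_s = np.asarray(v_s, dtype=np.float64).reshape(3)
    v_e = np.asarray(v_e, dtype=np.float64).reshape(3)
    if len(cand) == 0:
        raise EmptyChainError("no candidate vertices to trace")
    if ordering == "projection":
        t = _along_transect(cand, v_s, v_e)
        order = np.lexsort((np.arange(len(cand)), cand[:, 2], t))
        pts = cand[order]
    elif ordering == "greedy":
        pts = _greedy_walk(cand, v_s, v_e)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    # drop consecutive duplicates
    if len(pts) > 1:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > _COINCIDE_TOL
        pts = pts[keep]
    t_sorted = np.sort(_along_transect(pts, v_s, v_e))
    max_gap = float(np.max(np.diff(t_sorted))) if len(t_sorted) > 1 else 0.0
    if np.isfinite(gamma) and max_gap > _GAP_FACTOR * gamma:
        warnings.warn(
            f"largest along-transect gap {max_gap:.3g} m exceeds {_GAP_FACTOR:g} x gamma "
            f"({gamma:g} m); the chain bridges unsampled terrain",
            stacklevel=2,
        )
    return Chain(points=pts, v_s=v_s, v_e=v_e, gamma=gamma, max_gap=max_gap)


def _greedy_walk(cand: np.ndarray, v_s: np.ndarray, v_e: np.ndarray) -> np.ndarray:
    """Nearest-unvisited-neighbour walk over the Euclidean distance matrix."""
    start = int(np.argmin(np.linalg.norm(cand - v_s, axis=1)))
    end = int(np.argmin(np.linalg.norm(cand - v_e, axis=1)))
    dmat = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=2)
    visited = np.zeros(len(cand), dtype=bool)
    path = [start]
    visited[start] = True
    current = start
    while current != end and not visited.all():
        dists = np.where(visited, np.inf, dmat[current])
        current = int(np.argmin(dists))
        visited[current] = True
        path.append(current)
    return cand[path]


def chain_rugosity(chain: Chain) -> float:
    """Chain-tape rugosity R = L / D for one chain.

    L is the chain length (sum of consecutive 3D segment lengths) and D
    the straight-line 3D distance between the endpoints.  R >= 1 up to
    floating-point rounding.
    """
    d = chain.tape_distance
    if d <= _COINCIDE_TOL:
        raise DegenerateGeometryError("zero tape distance; rugosity undefined")
    return chain.length / d


def chain_transect(
    mesh: TriangleMesh,
    v_s,
    v_e,
    gamma: float | None = None,
    ordering: str = "projection",
) -> Chain:
    """Full virtual chain pipeline: plane, selection, trace.

    ``gamma`` defaults to half the mesh's median edge length — fine enough
    to stay a near-continuous ribbon on the mesh, coarse enough not to
    capture parallel vertex rows on regular grids.
    """
    if gamma is None:
        gamma = 0.5 * edge_length_stats(mesh)["median"]
    plane = define_vertical_plane(v_s, v_e)
    candidates = select_chain_vertices(mesh, plane, gamma, v_s, v_e)
    return trace_chain(candidates, v_s, v_e, gamma=gamma, ordering=ordering)
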