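"""Layer-boundary segmentation of ultrasound images by gradient-weighted shortest paths.

An ultrasound B-mode image of layered tissue shows a bright transducer
contact stripe near the top and an intensity transition at the tissue-tissue
boundary. Both are recovered as minimal-cost left-to-right pixel paths on a
graph whose edge weights decrease with the vertical image gradient, so the
cheapest path hugs the strongest horizontal edge. Costs are minimized with
Dijkstra's algorithm; one extra column of minimal-weight nodes is padded on
each side so the fixed corner endpoints do not constrain where the path
enters or leaves the image.

The contact surface is searched in the top 20 pixel rows only. Below it,
the three cheapest non-overlapping candidate boundaries are extracted
(speckle and fibrous texture sometimes make an incorrect path the cheapest,
so keeping three candidates retains the true boundary). The six-feature
descriptor read off at the image center column: three contact-to-boundary
distances in mm and the three gradient values at the boundary pixels.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .spectral_features import FeatureVector

__all__ = [
    "W_MIN",
    "USImage",
    "BoundaryPath",
    "SegmentationError",
    "gradient_image",
    "best_path",
    "find_contact_surface",
    "find_boundaries",
    "us_features",
]

#: Additive edge-weight floor keeping all Dijkstra weights strictly positive.
W_MIN = 1e-5

#: Contact stripe search depth (pixel rows) and guard band below the contact.
CONTACT_ROWS = 20
CONTACT_GUARD_ROWS = 3

#: Vertical exclusion half-width around an already-selected boundary path.
PATH_EXCLUSION_MARGIN = 2


class SegmentationError(RuntimeError):
    """No feasible boundary path exists (e.g. a fully excluded column)."""


@dataclass(frozen=True)
class USImage:
    """2-D grayscale ultrasound image: rows are depth, columns lateral."""

    intensities: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be a finite 2-D array")
        if arr.shape[0] < CONTACT_ROWS + 5:
            raise ValueError(
                f"image needs at least {CONTACT_ROWS + 5} rows for contact search"
            )
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class BoundaryPath:
    """One boundary trace: a row index per image column, plus its path cost.

    Adjacent columns differ by at most one row (8-connected traversal).
    ``low_confidence`` marks paths found on essentially gradient-free input.
    """

    rows_by_column: np.ndarray
    cost: float
    low_confidence: bool = field(default=False)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows_by_column, dtype=int)
        if rows.ndim != 1:
            raise ValueError("rows_by_column must be 1-D")
        if len(rows) > 1 and np.any(np.abs(np.diff(rows)) > 1):
            raise ValueError("adjacent columns must differ by at most one row")
        if self.cost < 0:
            raise ValueError("path cost must be non-negative")
        object.__setattr__(self, "rows_by_column", rows)


def gradient_image(img: USImage) -> np.ndarray:
    """Smooth with a 5x5 Gaussian (sigma=1) and take the vertical first-difference
    magnitude, min-max rescaled to [0, 1] over the whole image.

    The gradient at row r is |smoothed[r] - smoothed[r-1]|, i.e. an intensity
    step between rows r-1 and r registers at row r; row 0 replicates row 1.
    A constant image yields an all-zero gradient.
    """
    # truncate=2.0 with sigma=1 gives a radius-2 (5x5) kernel
    smoothed = ndimage.gaussian_filter(img.intensities, sigma=1.0, truncate=2.0)
    grad = np.empty_like(smoothed)
    grad[1:] = np.abs(np.diff(smoothed, axis=0))
    grad[0] = grad[1]
    lo, hi = grad.min(), grad.max()
    if hi > lo:
        grad = (grad - lo) / (hi - lo)
    else:
        grad = np.zeros_like(grad)
    return grad


def _edge_weight(g_a: float, g_b: float) -> float:
    return 2.0 - (g_a + g_b) + W_MIN


def best_path(
    gradient: np.ndarray, excluded: np.ndarray | None = None
) -> BoundaryPath:
    """Minimal-cost left-to-right path through a [0, 1] gradient grid.

    Pixels are graph nodes; an edge between pixels a, b costs
    ``2 - (g_a + g_b) + W_MIN`` so high-gradient pairs are cheapest. One
    column of gradient-1 nodes is padded on each side and Dijkstra runs from
    the padded upper-left to the padded bottom-right corner; vertical moves
    are free only inside the pad columns, while image columns are traversed
    strictly left to right with row steps of at most one (8-connected).
    Cost ties are broken toward the shallower path (smaller row sum).

    ``excluded`` is a boolean mask of unreachable pixels.
    """
    g = np.asarray(gradient, dtype=float)
    if g.ndim != 2 or g.size == 0:
        raise ValueError("gradient must be a nonempty 2-D grid")
    n_rows, n_cols = g.shape
    if excluded is not None:
        excluded = np.asarray(excluded, dtype=bool)
        if excluded.shape != g.shape:
            raise ValueError("excluded mask must match the gradient shape")

    def blocked(r: int, c: int) -> bool:
        return excluded is not None and 0 <= c < n_cols and excluded[r, c]

    def grad_at(c: int, r: int) -> float:
        return 1.0 if c < 0 or c >= n_cols else g[r, c]

    # node id over the padded grid: columns -1 .. n_cols
    def nid(r: int, c: int) -> int:
        return (c + 1) * n_rows + r

    n_nodes = n_rows * (n_cols + 2)
    INF = np.inf
    dist = np.full(n_nodes, INF)
    rowsum = np.full(n_nodes, INF)
    pred = np.full(n_nodes, -1, dtype=int)
    start = nid(0, -1)
    goal = nid(n_rows - 1, n_cols)
    dist[start] = 0.0
    rowsum[start] = 0.0
    heap: list[tuple[float, float, int]] = [(0.0, 0.0, start)]
    while heap:
        d, rs, node = heapq.heappop(heap)
        if (d, rs) > (dist[node], rowsum[node]):
            continue
        if node == goal:
            break
        c, r = node // n_rows - 1, node % n_rows
        neighbors: list[tuple[int, int]] = []
        if c < 0 or c >= n_cols:  # pad columns: free vertical movement
            if r + 1 < n_rows:
                neighbors.append((r + 1, c))
            if r - 1 >= 0:
                neighbors.append((r - 1, c))
        if c <= n_cols - 1:  # advance one column (possibly into the right pad)
            for dr in (-1, 0, 1):
                rr = r + dr
                if 0 <= rr < n_rows:
                    neighbors.append((rr, c + 1))
        for rr, cc in neighbors:
            if blocked(rr, cc):
                continue
            w = _edge_weight(grad_at(c, r), grad_at(cc, rr))
            node2 = nid(rr, cc)
            cand = (d + w, rs + rr)
            if cand < (dist[node2], rowsum[node2]):
                dist[node2], rowsum[node2] = cand
                pred[node2] = node
                heapq.heappush(heap, (cand[0], cand[1], node2))
    if not np.isfinite(dist[goal]):
        raise SegmentationError("no feasible path through the gradient grid")

    rows = np.full(n_cols, -1, dtype=int)
    node = goal
    while node != start:
        c, r = node // n_rows - 1, node % n_rows
        if 0 <= c < n_cols:
            rows[c] = r
        node = pred[node]
    return BoundaryPath(rows, float(dist[goal]))


def find_contact_surface(gradient: np.ndarray) -> BoundaryPath:
    """Locate the transducer contact stripe: best path over the top 20 rows only.

    On essentially flat input (max on-path gradient < 0.1) the returned path
    is flagged ``low_confidence``.
    """
    g = np.asarray(gradient, dtype=float)
    if g.shape[0] < CONTACT_ROWS:
        raise ValueError(f"need at least {CONTACT_ROWS} rows")
    sub = best_path(g[:CONTACT_ROWS])
    max_grad = float(g[sub.rows_by_column, np.arange(g.shape[1])].max())
    return BoundaryPath(sub.rows_by_column, sub.cost, low_confidence=max_grad < 0.1)


def find_boundaries(
    gradient: np.ndarray,
    contact: BoundaryPath,
    k: int = 3,
    guard_rows: int = CONTACT_GUARD_ROWS,
    exclusion_margin: int = PATH_EXCLUSION_MARGIN,
) -> list[BoundaryPath]:
    """The ``k`` cheapest non-overlapping candidate tissue boundaries below the contact.

    Each candidate is a best_path run restricted to rows strictly below the
    contact path plus a ``guard_rows`` guard band (so the bright contact
    stripe is never re-detected); after each selection the path's pixels and
    a +/- ``exclusion_margin`` row margin become unreachable. Paths are
    returned in selection (non-decreasing cost) order; fewer than ``k`` are
    returned, with a warning, if the grid runs out of feasible paths.
    """
    g = np.asarray(gradient, dtype=float)
    n_rows, n_cols = g.shape
    rows_grid = np.arange(n_rows)[:, None]
    excluded = rows_grid <= (contact.rows_by_column[None, :] + guard_rows)
    paths: list[BoundaryPath] = []
    for _ in range(k):
        try:
            path = best_path(g, excluded=excluded)
        except SegmentationError:
            break
        paths.append(path)
        band_lo = path.rows_by_column[None, :] - exclusion_margin
        band_hi = path.rows_by_column[None, :] + exclusion_margin
        excluded = excluded | ((rows_grid >= band_lo) & (rows_grid <= band_hi))
    if len(paths) < k:
        warnings.warn(
            f"only {len(paths)} of {k} boundary paths are feasible", stacklevel=2
        )
    return paths


def us_features(img: USImage, k: int = 3) -> FeatureVector:
    """Six-feature ultrasound descriptor read at the image center column.

    Features 1-3: contact-to-boundary distance in mm for the three candidate
    boundaries (a missing candidate contributes the full image depth in mm
    as a sentinel). Features 4-6: the rescaled vertical-gradient value at
    each candidate's center-column pixel (0 for missing candidates).
    """
    grad = gradient_image(img)
    contact = find_contact_surface(grad)
    boundaries = find_boundaries(grad, contact, k=k)
    n_rows, n_cols = img.intensities.shape
    center = n_cols // 2
    contact_row = int(contact.rows_by_column[center])
    depth_mm = n_rows * img.pixel_mm
    dists, grads = [], []
    for i in range(k):
        if i < len(boundaries):
            row = int(boundaries[i].rows_by_column[center])
            dists.append((row - contact_row) * img.pixel_mm)
            grads.append(float(grad[row, center]))
        else:
            dists.append(depth_mm)
            grads.append(0.0)
    names = tuple(f"us_dist{i + 1}" for i in range(k)) + tuple(
        f"us_grad{i + 1}" for i in range(k)
    )
    return FeatureVector("ultrasound", names, np.array(dists + grads))
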