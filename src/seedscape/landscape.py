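"""Class-level landscape metrics inside circular buffers.

Six metrics are computed for the focal class (old-growth forest, code 1,
unless stated otherwise) within circular buffers clipped from a classified
raster:

==========  =====================================================  =========
metric      definition                                             units
==========  =====================================================  =========
FC          percentage of buffer area covered by old-growth        percent
SF          percentage covered by secondary forest                 percent
PD          same-class patches per hectare of buffer area          n/ha
AI          like-adjacency percentage of the maximum possible      percent
PI          mean nearest-neighbour distance among patches          metres
EC          area-weighted mean edge contrast of the class's        percent
            patches against their neighbouring cover types
==========  =====================================================  =========

Conventions (the usual ones in class-level landscape-metric software):
patches are 8-connected components of the class mask; adjacency and edge
counts use rook (4-neighbour) contiguity; buffer membership is decided by
the cell-centre-in-circle test; components clipped by the buffer rim count
fully, but rim edges never enter EC denominators; edge-contrast weights come
from a seven-point habitat-quality ranking, linearly rescaled so that the
focal class against water (rank gap 6) scores 1 and against itself scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import (
    BufferError,
    ConfigError,
    DEFAULT_QUALITY_RANKING,
    DEFAULT_RADII,
    LandCoverRaster,
    MetricRecord,
)

__all__ = [
    "BufferView",
    "clip_buffer",
    "percent_cover",
    "label_patches",
    "patch_density",
    "aggregation_index",
    "patch_isolation",
    "edge_contrast",
    "metric_table",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class BufferView:
    """Cells of a raster whose centres fall within a circle.

    ``classes`` is the rectangular crop bounding the circle and ``mask``
    flags which of its cells are members; cells outside the mask are outside
    the landscape for every metric.
    """

    classes: np.ndarray
    mask: np.ndarray
    cell_size: float
    centre: tuple[float, float]
    radius_m: float

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @property
    def area_m2(self) -> float:
        return self.n_cells * self.cell_size**2

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0


def clip_buffer(
    raster: LandCoverRaster, centre: tuple[float, float], radius_m: float
) -> BufferView:
    """Clip the circular buffer of ``radius_m`` around ``centre``.

    Raises :class:`BufferError` if the circle extends past the raster edge:
    a truncated buffer would silently bias every metric.
    """
    if radius_m <= 0:
        raise ConfigError("radius must be positive")
    x0, y0 = raster.origin
    cx, cy = centre
    cs = raster.cell_size
    nrows, ncols = raster.grid.shape
    if (
        cx - radius_m < x0
        or cx + radius_m > x0 + ncols * cs
        or cy - radius_m < y0
        or cy + radius_m > y0 + nrows * cs
    ):
        raise BufferError(
            f"buffer r={radius_m} m at {centre} exceeds the raster extent"
        )
    # bounding rows/cols of the circle (cell-centre test)
    col_lo = int(np.floor((cx - radius_m - x0) / cs - 0.5))
    col_hi = int(np.ceil((cx + radius_m - x0) / cs + 0.5))
    row_lo = int(np.floor(((y0 + nrows * cs) - (cy + radius_m)) / cs - 0.5))
    row_hi = int(np.ceil(((y0 + nrows * cs) - (cy - radius_m)) / cs + 0.5))
    col_lo, col_hi = max(col_lo, 0), min(col_hi, ncols)
    row_lo, row_hi = max(row_lo, 0), min(row_hi, nrows)
    crop = raster.grid[row_lo:row_hi, col_lo:col_hi]
    rows = np.arange(row_lo, row_hi)
    cols = np.arange(col_lo, col_hi)
    ys = y0 + (nrows - rows - 0.5) * cs
    xs = x0 + (cols + 0.5) * cs
    d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
    mask = d2 <= radius_m**2
    if not mask.any():
        raise BufferError("buffer contains no cell centres")
    return BufferView(
        classes=crop, mask=mask, cell_size=cs, centre=centre, radius_m=radius_m
    )


def percent_cover(view: BufferView, class_code: int) -> float:
    """Percentage of the buffer's landscape area in ``class_code``."""
    if class_code not in range(1, 8):
        raise ConfigError(f"invalid class code {class_code}")
    member = view.mask
    return 100.0 * np.count_nonzero((view.classes == class_code) & member) / member.sum()


def label_patches(view: BufferView, class_code: int) -> tuple[np.ndarray, int]:
    """8-connected components of the class mask within the buffer."""
    focal = (view.classes == class_code) & view.mask
    labels, n = ndimage.label(focal, structure=_EIGHT)
    return labels, int(n)


def patch_density(view: BufferView, class_code: int) -> float:
    """Same-class patches per hectare of buffer area."""
    _, n = label_patches(view, class_code)
    return n / view.area_ha


def _like_adjacencies(focal: np.ndarray) -> int:
    """Shared rook edges between same-class member cells, counted once."""
    horiz = np.count_nonzero(focal[:, :-1] & focal[:, 1:])
    vert = np.count_nonzero(focal[:-1, :] & focal[1:, :])
    return int(horiz + vert)


def _max_like_adjacencies(area_cells: int) -> int:
    """Maximum single-count like-adjacencies for a class of given cell area.

    The maximum is attained by the most square-like arrangement: with
    n = floor(sqrt(A)) and m = A − n², g_max is 2n(n−1) for m = 0,
    plus 2m−1 when m ≤ n and 2m−2 when m > n.
    """
    n = int(np.floor(np.sqrt(area_cells)))
    m = area_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def aggregation_index(view: BufferView, class_code: int) -> float:
    """Like-adjacency percentage of the class-area maximum (0–100).

    100 means a single maximally compact patch; 0 means no two cells of the
    class share an edge. Returns NaN when the class is absent from the
    buffer and 0 for a single-cell class (no adjacency is possible).
    """
    focal = (view.classes == class_code) & view.mask
    area = int(focal.sum())
    if area == 0:
        return float("nan")
    g_max = _max_like_adjacencies(area)
    if g_max == 0:
        return 0.0
    return 100.0 * _like_adjacencies(focal) / g_max


def patch_isolation(view: BufferView, class_code: int) -> float:
    """Mean nearest-neighbour distance (m) between the class's patches.

    Distances are minima over pairs of cell centres of distinct 8-connected
    components. A buffer holding fewer than two patches has no defined
    isolation and returns NaN (a zero would fake maximal connectivity).
    """
    labels, n = label_patches(view, class_code)
    if n < 2:
        return float("nan")
    cs = view.cell_size
    # the minimum cell-centre distance between components is attained at
    # boundary cells, so interior cells can be discarded up front
    focal = labels > 0
    interior = ndimage.binary_erosion(focal, structure=_EIGHT, border_value=0)
    boundary = focal & ~interior
    rr, cc = np.nonzero(boundary)
    pts = np.column_stack([cc * cs, -rr * cs]).astype(float)
    owner = labels[rr, cc]
    tree = cKDTree(pts)
    m = len(pts)
    # nearest foreign-component point per boundary point, found by doubling
    # the k-NN horizon until a different owner appears
    nearest_foreign = np.full(m, np.inf)
    unresolved = np.arange(m)
    kq = 8
    while unresolved.size:
        kq = min(kq, m)
        dist, idx = tree.query(pts[unresolved], k=kq)
        dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
        foreign = owner[idx] != owner[unresolved][:, None]
        hit = foreign.any(axis=1)
        first = np.argmax(foreign[hit], axis=1)
        nearest_foreign[unresolved[hit]] = dist[hit, first]
        unresolved = unresolved[~hit]
        if kq == m:
            break
        kq *= 4
    nn = np.full(n + 1, np.inf)
    np.minimum.at(nn, owner, nearest_foreign)
    return float(nn[1:].mean())


def edge_contrast(
    view: BufferView,
    class_code: int,
    ranking: Mapping[int, int] = DEFAULT_QUALITY_RANKING,
) -> float:
    """Area-weighted mean edge-contrast percentage of the class's patches.

    Each patch's contrast is the mean, over its boundary edges inside the
    buffer, of the quality-rank gap to the neighbouring cover type rescaled
    to [0, 1]: ``d = (rank_focal − rank_neighbour) / 6``. Patches with no
    boundary inside the buffer (fully interior) contribute 0. Edges at the
    buffer rim are not counted. Returns NaN when the class is absent.
    """
    labels, n = label_patches(view, class_code)
    if n == 0:
        return float("nan")
    rank_focal = ranking[class_code]
    span = max(ranking.values()) - min(ranking.values())
    # rank lookup per cell; non-member cells excluded via the mask
    rank_grid = np.zeros_like(view.classes, dtype=float)
    for code, rank in ranking.items():
        rank_grid[view.classes == code] = rank
    member = view.mask
    focal = labels > 0
    ec_num = np.zeros(n + 1)
    ec_den = np.zeros(n + 1)

    def tally(lab_a, foc_a, mem_a, lab_b, foc_b, mem_b, rank_b):
        # edges from focal cells in slice a to non-focal member cells in slice b
        sel = foc_a & mem_b & ~foc_b
        if not sel.any():
            return
        d = np.abs(rank_focal - rank_b[sel]) / span
        np.add.at(ec_num, lab_a[sel], d)
        np.add.at(ec_den, lab_a[sel], 1.0)

    for (sa, sb) in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),  # right
        ((slice(None), slice(1, None)), (slice(None), slice(None, -1))),  # left
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),  # down
        ((slice(1, None), slice(None)), (slice(None, -1), slice(None))),  # up
    ):
        tally(
            labels[sa], focal[sa], member[sa],
            labels[sb], focal[sb], member[sb],
            rank_grid[sb],
        )

    areas = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ec_k = np.where(ec_den[1:] > 0, ec_num[1:] / np.maximum(ec_den[1:], 1), 0.0)
    return float(100.0 * np.sum(ec_k * areas[1:]) / areas[1:].sum())


_METRIC_FUNCS = {
    "FC": lambda v, ranking: percent_cover(v, 1),
    "SF": lambda v, ranking: percent_cover(v, 2),
    "PD": lambda v, ranking: patch_density(v, 1),
    "AI": lambda v, ranking: aggregation_index(v, 1),
    "PI": lambda v, ranking: patch_isolation(v, 1),
    "EC": lambda v, ranking: edge_contrast(v, 1, ranking),
}


def compute_metric(
    view: BufferView,
    metric: str,
    ranking: Mapping[int, int] = DEFAULT_QUALITY_RANKING,
) -> float:
    """Evaluate one named metric (focal class = old-growth forest)."""
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ConfigError(f"unknown metric {metric!r}") from None
    return func(view, ranking)


def metric_table(
    raster: LandCoverRaster,
    centres: Mapping[str, tuple[float, float]],
    radii: Sequence[float] = DEFAULT_RADII,
    ranking: Mapping[int, int] = DEFAULT_QUALITY_RANKING,
    metrics: Sequence[str] = tuple(_METRIC_FUNCS),
) -> list[MetricRecord]:
    """All requested metrics for every patch centre and buffer radius."""
    records = []
    for patch_id, centre in centres.items():
        for radius in radii:
            view = clip_buffer(raster, centre, radius)
            for metric in metrics:
                records.append(
                    MetricRecord(
                        patch_id=patch_id,
                        radius_m=float(radius),
                        metric=metric,
                        value=compute_metric(view, metric, ranking),
                    )
                )
    return records
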