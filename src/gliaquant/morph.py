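"""Morphometry of Iba-1+ microglia: area fraction, soma, arbor, puncta.

Four measures of activation state:

* **Iba1-RA** - the fraction of the field occupied by Iba-1+ signal, used
  in the NFL-GCL where overlapping cells cannot be individualised.
* **Soma area** - cell-body cross-section (um^2); enlarges on activation.
* **Arbor area** - area of the polygon through the most distal tips of a
  cell's processes (um^2); shrinks on activation.  The automated
  realisation is the convex hull of the tip set.
* **Vertical processes** - processes crossing between OPL and OS, seen as
  puncta in the interface plane and counted with the spot chain.

The original soma contours, arbor polygons and punctum clicks were manual;
this module accepts such annotations (polygons / point sets in um) and also
provides automated extractors (soma core mask, skeleton-endpoint tips).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

from . import detect
from .detect import DetectionParams, PUNCTA_PARAMS
from .io import FieldImage


@dataclass
class AreaFractionResult:
    fraction: float  # labelled pixels / total pixels, in [0, 1]
    area_um2: float  # same measure in absolute units
    flags: tuple[str, ...] = ()


@dataclass
class ArborAreaResult:
    area_um2: float
    degenerate: bool = False  # fewer than 3 tips, or all collinear


@dataclass
class MorphometryRecord:
    """Per-field morphometry summary."""

    field_id: str
    iba1_ra_fraction: float | None = None
    soma_areas_um2: list[float] | None = None
    arbor_areas_um2: list[float] | None = None
    n_vertical_processes: int | None = None
    pathway: str = "automated"  # or "annotated"


def area_fraction(
    img: FieldImage,
    params: DetectionParams | None = None,
    method: str = "fixed",
) -> AreaFractionResult:
    """Iba1-RA: fraction of pixels above threshold after normalisation.

    ``method="fixed"`` applies the same normalise-then-threshold rule as
    cell counting (default 0.2 of the per-image maximum); ``"otsu"``
    substitutes an Otsu threshold on the normalised field.  Invariant to
    global brightness scaling; an empty field yields fraction 0.
    """
    params = params or DetectionParams()
    norm = detect.normalize_field(img)
    if "empty_field" in norm.flags:
        return AreaFractionResult(0.0, 0.0, flags=norm.flags)
    if method == "fixed":
        mask = detect.apply_threshold(norm, params)
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        mask = norm.pixels >= threshold_otsu(norm.pixels)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    frac = float(mask.sum()) / mask.size
    return AreaFractionResult(
        fraction=frac,
        area_um2=float(mask.sum()) * img.pixel_size_um**2,
        flags=norm.flags,
    )


def soma_area(
    contour_um: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> float:
    """Cell-body area in um^2, from a traced contour or a soma mask.

    A contour is a closed simple polygon of (y, x) vertices in um; the
    area is computed with the shoelace formula.  A mask is a boolean soma
    core whose area is its pixel count times the pixel area.
    """
    if (contour_um is None) == (mask is None):
        raise ValueError("pass exactly one of contour_um or mask")
    if contour_um is not None:
        return _shoelace(np.asarray(contour_um, dtype=np.float64))
    if pixel_size_um is None:
        raise ValueError("pixel_size_um required with a mask")
    if not mask.any():
        raise ValueError("soma mask is empty")
    return float(mask.sum()) * pixel_size_um**2


def _shoelace(poly: np.ndarray) -> float:
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon needs >= 3 (y, x) vertices")
    # drop an explicitly repeated closing vertex
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if len(poly) < 3:
        raise ValueError("polygon needs >= 3 distinct vertices")
    if _self_intersects(poly):
        raise ValueError("polygon is self-intersecting")
    y, x = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)

    def segs_cross(p, q, r, s) -> bool:
        def orient(a, b, c):
            v = (b[1] - a[1]) * (c[0] - a[0]) - (b[0] - a[0]) * (c[1] - a[1])
            return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

        o1, o2 = orient(p, q, r), orient(p, q, s)
        o3, o4 = orient(r, s, p), orient(r, s, q)
        return o1 != o2 and o3 != o4

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if segs_cross(poly[i], poly[(i + 1) % n], poly[j], poly[(j + 1) % n]):
                return True
    return False


def arbor_area(tips_um: np.ndarray) -> ArborAreaResult:
    """Arbor territory: convex-hull area of the process-tip set, um^2.

    The convex hull is the deterministic automated stand-in for the
    hand-drawn polygon through the most distal process tips.  Fewer than
    three tips, or a collinear tip set, gives area 0 with the degenerate
    flag set.
    """
    pts = np.asarray(tips_um, dtype=np.float64).reshape(-1, 2)
    if len(pts) < 3:
        return ArborAreaResult(0.0, degenerate=True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return ArborAreaResult(0.0, degenerate=True)
    # for 2-D point sets ConvexHull.volume is the enclosed area
    return ArborAreaResult(float(hull.volume), degenerate=False)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def extract_tips(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Process-tip points of a single-cell mask, in um.

    Skeletonises the mask and returns every skeleton pixel with exactly
    one 8-connected skeleton neighbour (an endpoint).  An isolated
    skeleton pixel (degenerate round cell) is returned as a single tip.
    """
    if not mask.any():
        raise ValueError("cell mask is empty")
    skel = skeletonize(mask.astype(bool))
    if not skel.any():
        return np.empty((0, 2))
    nbrs = ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    endpoints = skel & ((nbrs == 1) | (nbrs == 0))
    ys, xs = np.nonzero(endpoints)
    return np.column_stack([ys, xs]).astype(np.float64) * pixel_size_um


def soma_core_mask(
    norm_pixels: np.ndarray, cell_mask: np.ndarray, core_threshold: float = 0.6
) -> np.ndarray:
    """Automated soma segmentation: the high-intensity core of a cell.

    Somata are brighter than processes; within the cell's mask, pixels of
    the normalised field at or above ``core_threshold`` form the soma
    core.  Returns the largest connected core component.
    """
    core = cell_mask & (norm_pixels >= core_threshold)
    if not core.any():
        return core
    labels, n = ndimage.label(core, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return core
    sizes = ndimage.sum_labels(core, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def automated_morphometry(
    img: FieldImage,
    params: DetectionParams | None = None,
    core_threshold: float = 0.6,
    min_cell_px: int = 20,
) -> tuple[list[float], list[float]]:
    """Automated per-cell soma and arbor areas for one mosaic-layer field.

    Segments the field with the counting chain's mask, treats each
    sufficiently large 8-connected component as one cell, and measures
    (a) the soma as the component's high-intensity core and (b) the arbor
    as the convex hull of the component's skeleton endpoints.  Returns
    (soma_areas_um2, arbor_areas_um2); degenerate arbors (under 3 tips)
    are skipped.
    """
    params = params or DetectionParams()
    norm = detect.normalize_field(img)
    if "empty_field" in norm.flags:
        return [], []
    mask = detect.apply_threshold(norm, params)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    somas: list[float] = []
    arbors: list[float] = []
    px = img.pixel_size_um
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == sl_idx
        if comp.sum() < max(min_cell_px, params.min_segment_px):
            continue
        core = soma_core_mask(norm.pixels[sl], comp, core_threshold)
        if core.any():
            somas.append(float(core.sum()) * px**2)
        tips = extract_tips(comp, px)
        res = arbor_area(tips)
        if not res.degenerate:
            arbors.append(res.area_um2)
    return somas, arbors


def count_vertical_processes(
    plane: FieldImage, params: DetectionParams | None = None
) -> int:
    """Count vertical-process puncta in the OPL-OS interface plane.

    Processes connecting the OPL and OS appear as points in this plane;
    they are counted with the detection chain at punctum scale (small
    minimum segment, punctum-sized merge radius).
    """
    return detect.count_cells(plane, params or PUNCTA_PARAMS).n_cells
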