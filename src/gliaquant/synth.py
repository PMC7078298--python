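"""Synthetic retinal whole-mount fields with exact ground truth.

Emulates the appearance the quantification pipeline was designed for:

* **OPL / IPL** - ramified microglia tiling the layer in a regular,
  territory-respecting mosaic: somata placed by minimum-distance rejection
  sampling, radiating processes whose extent is clipped to half the
  spacing so neighbouring cells never touch (quiescent microglia occupy
  exclusive territories).
* **NFL-GCL** - dense, overlapping signal where individual cells cannot be
  resolved; placement allows overlap and the layer is quantified by area
  fraction.
* **OS** - sparse isolated cells with short irregular processes.
* **OPL-OS interface** - vertical processes appearing as point-like puncta.

Every drawn object is catalogued in a :class:`GroundTruth`: soma centroids
and rasterised soma areas, process-tip coordinates and analytic convex-hull
arbor areas, punctum centroids, the labelled-pixel fraction of the clean
image and the planted mean intensity.  Identical specs and seeds produce
bit-identical pixels.

Cohort generation maps a (group x day x layer) parameter profile - whose
defaults encode the qualitative ocular-hypertension time course (cell
count and area fraction peaking at days 3-5, hypertensive soma maximal at
day 1, contralateral soma maximal at day 3, P2RY12 trough at days 3-5) -
onto per-animal field specs with deterministic seed derivation.  The
profile is plain configuration: the generator never injects effects that
are not spelled out in it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage import draw as skdraw

from .io import FIELD_SIDE_UM, FieldImage, ImageStack, write_stack

LAYERS = ("OS", "OPL", "IPL", "NFL-GCL")
#: pseudo-layer for the plane between OPL and OS where vertical processes
#: appear as puncta
VP_LAYER = "OPL-OS"
GROUPS = ("naive", "OHT", "contralateral")
DAYS = (1, 3, 5, 8, 15)
ZONES = ("superior", "inferior", "nasal", "temporal")


class InfeasiblePackingError(ValueError):
    """Requested object count cannot be placed at the requested spacing."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters for rendering one synthetic field.

    Geometric quantities are micrometres; intensities are 8-bit levels.
    ``soma_radius_um`` and ``arbor_radius_um`` are (mean, sd) pairs;
    ``n_processes_per_cell`` an inclusive (lo, hi) integer range.
    """

    layer: str = "OPL"
    n_cells: int = 18
    soma_radius_um: tuple[float, float] = (4.0, 0.4)
    arbor_radius_um: tuple[float, float] = (16.0, 1.5)
    n_processes_per_cell: tuple[int, int] = (4, 6)
    min_spacing_um: float = 37.0
    n_puncta: int = 0
    intensity_mean: float | None = None  # green-channel level, 0-255
    background_level: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0
    # rendering geometry
    field_side_um: float = FIELD_SIDE_UM
    field_side_px: int = 512
    n_planes: int = 5
    bit_depth: int = 8
    # rendering appearance
    cell_amplitude: float = 200.0
    process_amplitude: float = 120.0
    punctum_radius_um: float = 1.3
    antialias: bool = True
    allow_overlap: bool = False
    clip_arbor_to_spacing: bool = True
    green_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_puncta < 0:
            raise ValueError("object counts must be >= 0")
        if self.min_spacing_um < 0:
            raise ValueError("min_spacing_um must be >= 0")
        if self.intensity_mean is not None and not 0 <= self.intensity_mean <= 255:
            raise ValueError("intensity_mean must be in [0, 255]")
        if self.field_side_px < 16 or self.field_side_um <= 0:
            raise ValueError("field geometry invalid")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        # crude feasibility screen; exact feasibility is decided by the
        # bounded rejection sampler at render time
        if self.n_cells > 0 and self.min_spacing_um > 0 and not self.allow_overlap:
            packed = self.n_cells * np.pi * (self.min_spacing_um / 2.0) ** 2
            if packed > 0.75 * self.field_side_um**2:
                raise InfeasiblePackingError(
                    f"{self.n_cells} cells at spacing {self.min_spacing_um} um "
                    f"cannot tile a {self.field_side_um:.0f} um field"
                )

    @property
    def pixel_size_um(self) -> float:
        return self.field_side_um / self.field_side_px


@dataclass
class CellTruth:
    centroid_um: tuple[float, float]  # (y, x)
    soma_radius_um: float
    soma_area_um2: float  # rasterised: drawn soma pixels x pixel area
    tips_um: list[tuple[float, float]]
    arbor_area_um2: float  # analytic convex-hull area of the tip set
    z_plane: int


@dataclass
class GroundTruth:
    """Exact catalogue of everything a synthetic field contains."""

    field_id: str
    layer: str
    pixel_size_um: float
    field_side_um: float
    cells: list[CellTruth] = field(default_factory=list)
    puncta_um: list[tuple[float, float]] = field(default_factory=list)
    area_fraction: float = 0.0  # labelled fraction of the clean projection
    mean_intensity_percent: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_puncta(self) -> int:
        return len(self.puncta_um)

    @property
    def centroids_um(self) -> np.ndarray:
        if not self.cells:
            return np.empty((0, 2))
        return np.array([c.centroid_um for c in self.cells])

    def validate(self) -> None:
        for c in self.cells:
            pts = [c.centroid_um, *c.tips_um]
            for y, x in pts:
                if not (0 <= y <= self.field_side_um and 0 <= x <= self.field_side_um):
                    raise ValueError("ground-truth coordinate outside field")
        for y, x in self.puncta_um:
            if not (0 <= y <= self.field_side_um and 0 <= x <= self.field_side_um):
                raise ValueError("punctum outside field")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        cells = [
            CellTruth(
                centroid_um=tuple(c["centroid_um"]),
                soma_radius_um=c["soma_radius_um"],
                soma_area_um2=c["soma_area_um2"],
                tips_um=[tuple(t) for t in c["tips_um"]],
                arbor_area_um2=c["arbor_area_um2"],
                z_plane=c["z_plane"],
            )
            for c in raw.pop("cells")
        ]
        raw["puncta_um"] = [tuple(p) for p in raw["puncta_um"]]
        return cls(cells=cells, **raw)


def _place_points(
    rng: np.random.Generator,
    n: int,
    side_um: float,
    margin_um: float,
    min_spacing_um: float,
    allow_overlap: bool,
) -> np.ndarray:
    """Dart-throwing placement with a pairwise minimum distance."""
    if n == 0:
        return np.empty((0, 2))
    lo, hi = margin_um, side_um - margin_um
    if hi <= lo:
        raise InfeasiblePackingError("margin exceeds field size")
    pts: list[np.ndarray] = []
    max_attempts = 400 * n
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasiblePackingError(
                f"could not place {n} objects at spacing {min_spacing_um} um "
                f"after {max_attempts} attempts"
            )
        cand = rng.uniform(lo, hi, size=2)
        if not allow_overlap and min_spacing_um > 0 and pts:
            d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
            if (d < min_spacing_um).any():
                continue
        pts.append(cand)
    return np.asarray(pts)


def _hull_area(points: np.ndarray) -> float:
    """Convex-hull area by the monotone-chain + shoelace route (analytic)."""
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if len(pts) < 3:
        return 0.0
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.asarray(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        return 0.0
    y, x = hull[:, 0], hull[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _draw_cell(
    canvas: np.ndarray,
    spec: FieldSpec,
    center_um: np.ndarray,
    soma_r_um: float,
    tips_um: np.ndarray,
) -> float:
    """Draw one cell (soma disc + processes) onto a 2-D float canvas.

    Returns the rasterised soma area in um^2.
    """
    px = spec.pixel_size_um
    shape = canvas.shape
    cy, cx = center_um / px - 0.5
    rr, cc = skdraw.disk((cy, cx), max(soma_r_um / px, 1.0), shape=shape)
    for ty, tx in tips_um:
        ty_px, tx_px = int(round(ty / px - 0.5)), int(round(tx / px - 0.5))
        ty_px = min(max(ty_px, 0), shape[0] - 1)
        tx_px = min(max(tx_px, 0), shape[1] - 1)
        if spec.antialias:
            lr, lc, val = skdraw.line_aa(int(round(cy)), int(round(cx)), ty_px, tx_px)
            keep = (lr >= 0) & (lr < shape[0]) & (lc >= 0) & (lc < shape[1])
            lr, lc, val = lr[keep], lc[keep], val[keep]
            canvas[lr, lc] = np.maximum(canvas[lr, lc], val * spec.process_amplitude)
        else:
            lr, lc = skdraw.line(int(round(cy)), int(round(cx)), ty_px, tx_px)
            keep = (lr >= 0) & (lr < shape[0]) & (lc >= 0) & (lc < shape[1])
            canvas[lr[keep], lc[keep]] = np.maximum(
                canvas[lr[keep], lc[keep]], spec.process_amplitude
            )
    canvas[rr, cc] = np.maximum(canvas[rr, cc], spec.cell_amplitude)
    return len(rr) * px**2


def _sample_cell_geometry(
    rng: np.random.Generator, spec: FieldSpec, center_um: np.ndarray
) -> tuple[float, np.ndarray]:
    """Soma radius and process-tip coordinates for one cell."""
    soma_m, soma_sd = spec.soma_radius_um
    arbor_m, arbor_sd = spec.arbor_radius_um
    soma_r = max(float(rng.normal(soma_m, soma_sd)), 1.0)
    lo, hi = spec.n_processes_per_cell
    k = int(rng.integers(lo, hi + 1))
    tips = []
    if k > 0:
        base = rng.uniform(0, 2 * np.pi)
        angles = base + np.arange(k) * 2 * np.pi / k + rng.normal(0, 0.25, size=k)
        for ang in angles:
            reach = max(float(rng.normal(arbor_m, arbor_sd)), soma_r + 2.0)
            if spec.clip_arbor_to_spacing and not spec.allow_overlap and spec.min_spacing_um > 0:
                # exclusive territories: a cell never reaches past half the
                # inter-soma spacing, so neighbouring cells stay disjoint
                reach = min(reach, spec.min_spacing_um / 2.0 - spec.pixel_size_um)
                reach = max(reach, soma_r + 1.0)
            tip = center_um + reach * np.array([np.sin(ang), np.cos(ang)])
            tip = np.clip(tip, 0.0, spec.field_side_um)
            tips.append(tip)
    return soma_r, np.asarray(tips).reshape(-1, 2)


def _finalize_planes(
    rng: np.random.Generator, spec: FieldSpec, planes: np.ndarray, noise_sd: float
) -> np.ndarray:
    maxval = 2**spec.bit_depth - 1
    out = planes + spec.background_level
    if noise_sd > 0:
        noise = rng.standard_normal(out.shape, dtype=np.float32) * noise_sd
        out = out + noise
    out = np.clip(np.rint(out), 0, maxval)
    return out.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)


def render_field(spec: FieldSpec, field_id: str = "") -> tuple[ImageStack, GroundTruth]:
    """Render one field as a z-stack, with its exact object catalogue.

    Each cell is drawn in a single randomly chosen plane (soma disc at
    ``cell_amplitude``, radiating process segments at
    ``process_amplitude``); background and per-plane Gaussian noise are
    added afterwards and clipped to the bit depth.  If ``intensity_mean``
    is set, a P2RY12 channel is added as a homogeneous Gaussian field of
    that mean level drawn in a single plane, so the planted whole-field
    mean is exact.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    shape = (spec.field_side_px, spec.field_side_px)
    margin = spec.soma_radius_um[0] + 2.0
    centers = _place_points(
        rng,
        spec.n_cells,
        spec.field_side_um,
        margin,
        spec.min_spacing_um,
        spec.allow_overlap,
    )
    clean = np.zeros((spec.n_planes, *shape), dtype=np.float64)
    cells: list[CellTruth] = []
    for center in centers:
        soma_r, tips = _sample_cell_geometry(rng, spec, center)
        z = int(rng.integers(spec.n_planes))
        soma_area = _draw_cell(clean[z], spec, center, soma_r, tips)
        cells.append(
            CellTruth(
                centroid_um=(float(center[0]), float(center[1])),
                soma_radius_um=soma_r,
                soma_area_um2=soma_area,
                tips_um=[(float(t[0]), float(t[1])) for t in tips],
                arbor_area_um2=_hull_area(tips) if len(tips) else 0.0,
                z_plane=z,
            )
        )
    labelled = clean.max(axis=0) > 0
    truth = GroundTruth(
        field_id=field_id,
        layer=spec.layer,
        pixel_size_um=px,
        field_side_um=spec.field_side_um,
        cells=cells,
        area_fraction=float(labelled.sum()) / labelled.size,
    )
    channels = {"iba1": _finalize_planes(rng, spec, clean, spec.noise_sd)}
    if spec.intensity_mean is not None:
        green = np.zeros((spec.n_planes, *shape), dtype=np.float64)
        sd = min(spec.green_noise_sd, spec.intensity_mean / 3.0)
        if sd > 0:
            green[0] = rng.normal(spec.intensity_mean, sd, size=shape)
        else:
            green[0] = spec.intensity_mean
        maxval = 2**spec.bit_depth - 1
        green = np.clip(np.rint(green), 0, maxval)
        channels["p2ry12"] = green.astype(
            np.uint8 if spec.bit_depth == 8 else np.uint16
        )
        truth.mean_intensity_percent = 100.0 * spec.intensity_mean / 255.0
    stack = ImageStack(
        channels=channels,
        pixel_size_um=px,
        bit_depth=spec.bit_depth,
        stack_id=field_id,
    )
    truth.validate()
    return stack, truth


def render_puncta_plane(
    spec: FieldSpec, field_id: str = ""
) -> tuple[FieldImage, GroundTruth]:
    """Render the OPL-OS interface plane: vertical processes as puncta.

    Small isotropic spots of radius ``punctum_radius_um`` at rejection-
    sampled positions separated by at least ``min_spacing_um``.
    """
    if spec.n_puncta < 0:
        raise ValueError("n_puncta must be >= 0")
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    shape = (spec.field_side_px, spec.field_side_px)
    centers = _place_points(
        rng,
        spec.n_puncta,
        spec.field_side_um,
        spec.punctum_radius_um + 1.0,
        spec.min_spacing_um,
        allow_overlap=False,
    )
    canvas = np.zeros(shape, dtype=np.float64)
    for cy_um, cx_um in centers:
        rr, cc = skdraw.disk(
            (cy_um / px - 0.5, cx_um / px - 0.5),
            max(spec.punctum_radius_um / px, 1.0),
            shape=shape,
        )
        canvas[rr, cc] = spec.cell_amplitude
    planes = _finalize_planes(rng, spec, canvas[None], spec.noise_sd)
    truth = GroundTruth(
        field_id=field_id,
        layer=VP_LAYER,
        pixel_size_um=px,
        field_side_um=spec.field_side_um,
        puncta_um=[(float(y), float(x)) for y, x in centers],
        area_fraction=float((canvas > 0).sum()) / canvas.size,
    )
    truth.validate()
    img = FieldImage(
        pixels=planes[0].astype(np.float64),
        pixel_size_um=px,
        provenance=f"puncta_plane:{field_id}",
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_cohort_profile() -> dict:
    """Qualitative ocular-hypertension time-course as generator parameters.

    Keys are ``(group, day, layer)`` with day 0 for the naive group.  The
    planted effects follow the published qualitative findings: in
    hypertensive eyes cell counts peak at days 3-5 (day 5 in the OS),
    soma size is maximal at day 1, arbors are most retracted at days 3-5,
    area fraction in the NFL-GCL peaks at days 3-5 and P2RY12 intensity
    collapses at days 3-5; contralateral eyes respond more mildly with a
    peak at day 3.  Intensity percentages are the published group means.
    """
    counts = {
        "OS": {"naive": 8, "OHT": {1: 12, 3: 18, 5: 24, 8: 16, 15: 12},
               "contralateral": {1: 10, 3: 16, 5: 14, 8: 12, 15: 10}},
        "OPL": {"naive": 18, "OHT": {1: 26, 3: 38, 5: 38, 8: 30, 15: 24},
                "contralateral": {1: 20, 3: 28, 5: 26, 8: 24, 15: 21}},
        "IPL": {"naive": 20, "OHT": {1: 28, 3: 40, 5: 40, 8: 32, 15: 26},
                "contralateral": {1: 22, 3: 30, 5: 28, 8: 26, 15: 23}},
        "NFL-GCL": {"naive": 35, "OHT": {1: 45, 3: 65, 5: 65, 8: 50, 15: 42},
                    "contralateral": {1: 38, 3: 50, 5: 46, 8: 42, 15: 38}},
    }
    soma = {
        "naive": 4.0,
        "OHT": {1: 6.0, 3: 5.5, 5: 5.0, 8: 4.6, 15: 4.2},
        "contralateral": {1: 4.4, 3: 5.2, 5: 4.9, 8: 4.5, 15: 4.1},
    }
    arbor = {
        "naive": 16.0,
        "OHT": {1: 10.0, 3: 9.0, 5: 9.0, 8: 12.0, 15: 14.0},
        "contralateral": {1: 15.0, 3: 12.0, 5: 13.0, 8: 14.0, 15: 15.0},
    }
    # published P2RY12 group means, percent of 255, per (OPL, IPL, NFL-GCL)
    p2ry12 = {
        "naive": {"OPL": 18.47, "IPL": 32.21, "NFL-GCL": 14.35},
        "OHT": {
            1: {"OPL": 25.62, "IPL": 33.63, "NFL-GCL": 12.63},
            3: {"OPL": 5.47, "IPL": 1.33, "NFL-GCL": 2.99},
            5: {"OPL": 5.95, "IPL": 2.78, "NFL-GCL": 1.28},
            8: {"OPL": 16.65, "IPL": 22.30, "NFL-GCL": 6.80},
            15: {"OPL": 18.81, "IPL": 33.91, "NFL-GCL": 13.44},
        },
        "contralateral": {
            1: {"OPL": 23.21, "IPL": 28.03, "NFL-GCL": 12.75},
            3: {"OPL": 25.45, "IPL": 37.64, "NFL-GCL": 13.96},
            5: {"OPL": 26.35, "IPL": 38.40, "NFL-GCL": 12.97},
            8: {"OPL": 23.35, "IPL": 31.13, "NFL-GCL": 14.51},
            15: {"OPL": 19.22, "IPL": 34.86, "NFL-GCL": 11.69},
        },
    }
    puncta = {
        "naive": 15,
        "OHT": {1: 20, 3: 32, 5: 32, 8: 24, 15: 18},
        "contralateral": {1: 16, 3: 24, 5: 20, 8: 18, 15: 16},
    }

    def pick(table, group, day):
        return table[group] if group == "naive" else table[group][day]

    profile: dict = {}
    for group in GROUPS:
        days = (0,) if group == "naive" else DAYS
        for day in days:
            soma_m = pick(soma, group, day)
            arbor_m = pick(arbor, group, day)
            for layer in LAYERS:
                n = pick(counts[layer], group, day)
                entry = {
                    "n_cells": n,
                    "soma_radius_um": (soma_m, 0.4),
                    "arbor_radius_um": (arbor_m, 1.0),
                    "n_processes_per_cell": (4, 6),
                    "intensity_percent": None,
                    "n_puncta": 0,
                    "allow_overlap": False,
                }
                if layer == "OS":
                    entry.update(
                        soma_radius_um=(3.5, 0.4),
                        arbor_radius_um=(6.0, 1.0),
                        n_processes_per_cell=(2, 3),
                        min_spacing_um=22.0,
                    )
                elif layer == "NFL-GCL":
                    entry.update(allow_overlap=True, min_spacing_um=0.0)
                else:
                    # exclusive mosaic territories: spacing tracks arbor reach
                    # but always clears the 25 um dedup radius with margin
                    entry["min_spacing_um"] = max(round(2.0 * (arbor_m + 2.5), 1), 28.0)
                if layer in ("OPL", "IPL", "NFL-GCL"):
                    entry["intensity_percent"] = (
                        p2ry12["naive"][layer]
                        if group == "naive"
                        else p2ry12[group][day][layer]
                    )
                profile[(group, day, layer)] = entry
            profile[(group, day, VP_LAYER)] = {
                "n_cells": 0,
                "n_puncta": pick(puncta, group, day),
                "soma_radius_um": (3.5, 0.4),
                "arbor_radius_um": (6.0, 1.0),
                "n_processes_per_cell": (0, 0),
                "min_spacing_um": 12.0,
                "intensity_percent": None,
                "allow_overlap": False,
            }
    return profile


@dataclass
class CohortSpec:
    """Study design for a synthetic cohort.

    One naive group plus one laser group per day; each laser animal
    contributes a hypertensive and a contralateral eye (paired), each
    imaged in every layer.  Per-animal seeds derive deterministically from
    the master seed.
    """

    n_animals_per_group: int = 8
    days: tuple[int, ...] = DAYS
    layers: tuple[str, ...] = LAYERS
    include_vertical_processes: bool = True
    fields_per_animal_per_layer: int = 4
    field_side_px: int = 512
    n_planes: int = 5
    noise_sd: float = 6.0
    green_noise_sd: float = 8.0
    between_animal_cv: float = 0.06
    between_animal_intensity_sd: float = 1.2  # percent points
    master_seed: int = 0
    profile: dict = field(default_factory=default_cohort_profile)

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("need at least one animal per group")
        # every (group, day, layer) must resolve to a valid FieldSpec
        for group in GROUPS:
            days = (0,) if group == "naive" else self.days
            for day in days:
                for layer in self.all_layers:
                    self.field_params(group, day, layer)

    @property
    def all_layers(self) -> tuple[str, ...]:
        extra = (VP_LAYER,) if self.include_vertical_processes else ()
        return self.layers + extra

    def field_params(self, group: str, day: int, layer: str) -> dict:
        key = (group, day, layer)
        if key not in self.profile:
            raise KeyError(f"no profile entry for {key}")
        return self.profile[key]

    def build_field_spec(
        self, group: str, day: int, layer: str, seed: int, jitter: dict | None = None
    ) -> FieldSpec:
        """Resolve a profile entry (plus per-animal jitter) to a FieldSpec."""
        p = dict(self.field_params(group, day, layer))
        jitter = jitter or {}
        n_cells = max(int(round(p["n_cells"] * jitter.get("count_mult", 1.0))), 0)
        n_puncta = max(int(round(p["n_puncta"] * jitter.get("count_mult", 1.0))), 0)
        soma_m, soma_sd = p["soma_radius_um"]
        soma_m = max(soma_m + jitter.get("soma_shift", 0.0), 1.5)
        arbor_m, arbor_sd = p["arbor_radius_um"]
        arbor_m = max(arbor_m + jitter.get("arbor_shift", 0.0), soma_m + 2.0)
        pct = p["intensity_percent"]
        intensity = None
        if pct is not None:
            pct = float(np.clip(pct + jitter.get("intensity_shift", 0.0), 0.3, 100.0))
            intensity = pct * 255.0 / 100.0
        return FieldSpec(
            layer=layer,
            n_cells=n_cells,
            soma_radius_um=(soma_m, soma_sd),
            arbor_radius_um=(arbor_m, arbor_sd),
            n_processes_per_cell=tuple(p["n_processes_per_cell"]),
            min_spacing_um=p["min_spacing_um"],
            n_puncta=n_puncta,
            intensity_mean=intensity,
            noise_sd=self.noise_sd,
            green_noise_sd=self.green_noise_sd,
            seed=seed,
            field_side_px=self.field_side_px,
            n_planes=self.n_planes,
            allow_overlap=p["allow_overlap"],
        )


def _derived_seed(master_seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class CohortDataset:
    """In-memory synthetic cohort: manifest plus per-field data."""

    spec: CohortSpec
    manifest: pd.DataFrame
    fields: dict  # field_id -> (ImageStack | FieldImage, GroundTruth)


#: between-animal SD of the soma-radius and arbor-radius offsets (um)
BETWEEN_ANIMAL_SOMA_SD_UM = 0.15
BETWEEN_ANIMAL_ARBOR_SD_UM = 0.5


def _animal_jitter(rng: np.random.Generator, spec: CohortSpec) -> dict:
    return {
        "count_mult": max(float(rng.normal(1.0, spec.between_animal_cv)), 0.5),
        "soma_shift": float(rng.normal(0.0, BETWEEN_ANIMAL_SOMA_SD_UM)),
        "arbor_shift": float(rng.normal(0.0, BETWEEN_ANIMAL_ARBOR_SD_UM)),
        "intensity_shift": float(rng.normal(0.0, spec.between_animal_intensity_sd)),
    }


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None, keep_in_memory: bool = True
) -> CohortDataset:
    """Generate a full cohort of synthetic fields with ground truth.

    Iterates groups x days x animals x layers x fields, deriving each
    field's seed deterministically from the master seed, so the whole
    dataset (manifest and pixels) is reproducible bit for bit.  When
    ``out_dir`` is given, TIFFs, per-field ground-truth JSON, the manifest
    CSV and the cohort spec YAML are written there.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "fields").mkdir(parents=True, exist_ok=True)
    rows = []
    store: dict = {}
    units: list[tuple[str, int, str]] = [("naive", 0, f"naive_a{i}") for i in range(spec.n_animals_per_group)]
    for day in spec.days:
        for i in range(spec.n_animals_per_group):
            units.append(("laser", day, f"d{day}_a{i}"))
    unit_idx = 0
    field_idx = 0
    for kind, day, animal in units:
        eyes = ("naive",) if kind == "naive" else ("OHT", "contralateral")
        for eye in eyes:
            jitter_rng = np.random.default_rng(
                _derived_seed(spec.master_seed, 1, unit_idx, GROUPS.index(eye))
            )
            jitter = _animal_jitter(jitter_rng, spec)
            for layer in spec.all_layers:
                for f in range(spec.fields_per_animal_per_layer):
                    zone = ZONES[f % len(ZONES)]
                    seed = _derived_seed(spec.master_seed, 2, field_idx)
                    fspec = spec.build_field_spec(eye, day, layer, seed, jitter)
                    field_id = f"{animal}_{eye}_{layer}_f{f}"
                    if layer == VP_LAYER:
                        obj, truth = render_puncta_plane(fspec, field_id)
                    else:
                        obj, truth = render_field(fspec, field_id)
                    file_rel = None
                    if out_path is not None:
                        if layer == VP_LAYER:
                            plane = ImageStack(
                                channels={"iba1": obj.pixels.astype(np.uint8)[None]},
                                pixel_size_um=obj.pixel_size_um,
                                bit_depth=8,
                                stack_id=field_id,
                            )
                            write_stack(out_path / "fields" / f"{field_id}.tif", plane)
                        else:
                            write_stack(out_path / "fields" / f"{field_id}.tif", obj)
                        (out_path / "fields" / f"{field_id}.json").write_text(
                            truth.to_json()
                        )
                        file_rel = f"fields/{field_id}.tif"
                    if keep_in_memory:
                        store[field_id] = (obj, truth)
                    rows.append(
                        {
                            "field_id": field_id,
                            "animal": animal,
                            "group": eye,
                            "day": day,
                            "layer": layer,
                            "zone": zone,
                            "seed": seed,
                            "file": file_rel,
                            "n_cells_planted": truth.n_cells,
                            "n_puncta_planted": truth.n_puncta,
                            "intensity_percent_planted": truth.mean_intensity_percent,
                        }
                    )
                    field_idx += 1
            unit_idx += 1
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        cfg = dataclasses.asdict(spec)
        cfg["profile"] = {
            "|".join(map(str, k)): _yamlable(v) for k, v in spec.profile.items()
        }
        (out_path / "cohort_spec.yaml").write_text(yaml.safe_dump(cfg))
    return CohortDataset(spec=spec, manifest=manifest, fields=store)


def _yamlable(entry: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in entry.items()}
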