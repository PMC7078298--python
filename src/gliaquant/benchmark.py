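"""Ground-truth benchmarks of the quantification chain.

Every function here evaluates one component of the package against an
independent reference on synthetic data: brute-force geometry and
clustering oracles, enumeration null distributions, Monte-Carlo
calibration, and planted-effect recovery on whole synthetic cohorts.
These are the checks a user can run to convince themselves the pipeline
measures what it claims to measure; ``scripts/acceptance.py`` simply runs
them and reports the numbers.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import detect, intensity, morph, pipeline, stats, synth
from .detect import DetectionParams
from .io import FieldImage, max_project

# ---------------------------------------------------------------------------
# centroid-merging oracle
# ---------------------------------------------------------------------------

def _single_linkage_bruteforce(points: np.ndarray, min_distance: float) -> int:
    """O(n^2) union-find single-linkage cluster count (reference)."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(points[i, 0] - points[j, 0], points[i, 1] - points[j, 1]))
            if d < min_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(n)})


def dedup_oracle_agreement(n_sets: int = 500, n_max: int = 200, seed: int = 0) -> dict:
    """Compare dedup_centroids with the brute-force single-linkage count."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sets):
        n = int(rng.integers(0, n_max + 1))
        pts = rng.uniform(0, 400, size=(n, 2))
        min_d = float(rng.uniform(1, 60))
        params = DetectionParams(min_distance_um=min_d)
        got = detect.dedup_centroids(pts, params).n_cells
        ref = _single_linkage_bruteforce(pts, min_d)
        agree += got == ref
    return {"agreement_rate": agree / n_sets, "n": n_sets}


# ---------------------------------------------------------------------------
# exact count recovery on synthetic mosaic fields
# ---------------------------------------------------------------------------

def count_recovery(
    n_fields: int = 100,
    noise: bool = False,
    seed: int = 0,
    field_side_px: int = 512,
) -> dict:
    """Fraction of synthetic OPL fields counted exactly right.

    Fields carry 10-40 cells whose whole territories (soma plus process
    tips) are separated by more than the 25 um merge radius - the
    counting rule's contract: any two fragments of one cell lie within
    the merge radius while parts of different cells never do.  With
    ``noise=True`` each field gets additive Gaussian noise of SD drawn up
    to 10% of the cell amplitude; fields are rendered single-plane so the
    stated noise SD is the noise of the image the counting chain sees.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    for i in range(n_fields):
        n = int(rng.integers(10, 41))
        sd = float(rng.uniform(0.0, 20.0)) if noise else 0.0
        spec = synth.FieldSpec(
            layer="OPL",
            n_cells=n,
            min_spacing_um=45.0,
            arbor_radius_um=(8.0, 1.0),
            noise_sd=sd,
            seed=int(rng.integers(2**31)),
            field_side_px=field_side_px,
            n_planes=1,
        )
        stack, truth = synth.render_field(spec)
        got = detect.count_cells(max_project(stack)).n_cells
        exact += got == truth.n_cells
    return {"exact_rate": exact / n_fields, "n": n_fields}


# ---------------------------------------------------------------------------
# closed-form morphometry / intensity checks
# ---------------------------------------------------------------------------

def _lattice_polygon(rng: np.random.Generator, n_pts: int = 8, span: int = 12) -> np.ndarray:
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.integers(0, span, size=(n_pts, 2)).astype(float)
        if len(np.unique(pts, axis=0)) < 3:
            continue
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        return pts[hull.vertices]


def _pick_area(poly: np.ndarray) -> float:
    """Pick's theorem area of a lattice polygon: A = I + B/2 - 1."""
    from matplotlib.path import Path

    edges = np.roll(poly, -1, axis=0) - poly
    boundary = sum(int(np.gcd(int(abs(dy)), int(abs(dx)))) for dy, dx in edges)
    lo = poly.min(axis=0).astype(int) - 1
    hi = poly.max(axis=0).astype(int) + 2
    grid = np.array(
        [(y, x) for y in range(lo[0], hi[0]) for x in range(lo[1], hi[1])], dtype=float
    )
    path = Path(poly)
    inside = path.contains_points(grid, radius=-1e-9)
    on_edge = np.zeros(len(grid), dtype=bool)
    for k in range(len(poly)):
        a, c = poly[k], poly[(k + 1) % len(poly)]
        ab = c - a
        ap = grid - a
        cross = ab[0] * ap[:, 1] - ab[1] * ap[:, 0]
        t = (ap @ ab) / (ab @ ab)
        on_edge |= (np.abs(cross) < 1e-9) & (t >= -1e-9) & (t <= 1 + 1e-9)
    interior = int((inside & ~on_edge).sum())
    return interior + boundary / 2.0 - 1.0


def closed_form_checks(seed: int = 0, n_hulls: int = 200, n_polygons: int = 50) -> dict:
    """Machine-precision checks of area fraction, intensity, hull, shoelace."""
    rng = np.random.default_rng(seed)

    # planted area fraction recovered exactly on clean binary-rendered fields
    af_err = 0.0
    for i in range(10):
        spec = synth.FieldSpec(
            n_cells=int(rng.integers(5, 25)),
            min_spacing_um=37.0,
            antialias=False,
            noise_sd=0.0,
            seed=int(rng.integers(2**31)),
            field_side_px=256,
            n_planes=1,
        )
        stack, truth = synth.render_field(spec)
        got = morph.area_fraction(max_project(stack)).fraction
        af_err = max(af_err, abs(got - truth.area_fraction))

    # uniform-image intensity percent is exactly 100 u / 255
    int_err = 0.0
    for u in rng.integers(0, 256, size=20):
        img = FieldImage(np.full((32, 32), float(u)), pixel_size_um=1.0)
        int_err = max(
            int_err, abs(intensity.mean_intensity_percent(img) - 100.0 * u / 255.0)
        )

    # convex-hull arbor area vs an independent geometry library
    import shapely.geometry as sg

    hull_err = 0.0
    for _ in range(n_hulls):
        pts = rng.uniform(0, 100, size=(int(rng.integers(3, 21)), 2))
        got = morph.arbor_area(pts).area_um2
        ref = sg.MultiPoint([tuple(p) for p in pts]).convex_hull.area
        hull_err = max(hull_err, abs(got - ref))

    # shoelace soma area vs Pick's theorem on integer-vertex polygons
    pick_err = 0.0
    for _ in range(n_polygons):
        poly = _lattice_polygon(rng)
        got = morph.soma_area(contour_um=poly)
        pick_err = max(pick_err, abs(got - _pick_area(poly)))

    return {
        "area_fraction_max_abs_err": af_err,
        "intensity_percent_max_abs_err": int_err,
        "hull_area_max_abs_err": hull_err,
        "pick_area_max_abs_err": pick_err,
    }


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------

def mwu_enumeration_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full arrangement enumeration."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(a) + len(b)
    us = []
    for idx in itertools.combinations(range(n), n1):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        us.append((ga[:, None] > gb[None, :]).sum())
    us = np.asarray(us)
    u_obs = float((a[:, None] > b[None, :]).sum())
    p = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
    return u_obs, p


def mwu_exactness(seed: int = 0) -> dict:
    """Max |p - enumeration p| over all group-size configs n1, n2 <= 8."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_cfg = 0
    for n1 in range(2, 9):
        for n2 in range(2, 9):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            row = stats.compare_unpaired(a, b)
            u_ref, p_ref = mwu_enumeration_p(a, b)
            worst = max(worst, abs(row.p_raw - p_ref))
            if row.statistic != u_ref:
                worst = max(worst, 1.0)
            n_cfg += 1
    return {"max_abs_p_diff": worst, "n": n_cfg}


def null_rejection_rate(n_reps: int = 5000, n: int = 8, seed: int = 0) -> dict:
    """Type-I error of the unpaired comparison on a simulated null."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        rej += stats.compare_unpaired(a, b).p_raw < stats.ALPHA
    return {"rejection_rate": rej / n_reps, "n": n_reps}


def bonferroni_fwer(n_reps: int = 2000, n: int = 8, seed: int = 0) -> dict:
    """Family-wise error of Bonferroni pairwise contrasts, 3-group null."""
    rng = np.random.default_rng(seed)
    fw = 0
    for _ in range(n_reps):
        groups = [rng.normal(size=n) for _ in range(3)]
        p_adj = []
        for i, j in itertools.combinations(range(3), 2):
            t = sps.ttest_ind(groups[i], groups[j])
            p_adj.append(stats.bonferroni(float(t.pvalue), 3))
        fw += min(p_adj) < stats.ALPHA
    return {"fwer": fw / n_reps, "n": n_reps, "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps))}


def zone_null_calibration(n_reps: int = 100, n_per_zone: int = 8, seed: int = 0) -> dict:
    """Zone ANOVA on identically distributed zones: non-significance rate."""
    rng = np.random.default_rng(seed)
    nonsig = 0
    for _ in range(n_reps):
        df = pd.DataFrame(
            {
                "zone": np.repeat(stats.ZONES, n_per_zone),
                "value": rng.normal(10.0, 2.0, size=4 * n_per_zone),
            }
        )
        table = stats.zone_analysis(df)
        omnibus = table[table["contrast"].str.endswith("omnibus")]
        nonsig += not bool(omnibus["significant"].iloc[0])
    return {"nonsignificant_rate": nonsig / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# whole-cohort planted-effect recovery
# ---------------------------------------------------------------------------

#: (metric, layer, group) whose group-mean day curve should reproduce the
#: planted parameter ordering, and the profile key the ordering comes from
ORDERING_CHECKS = [
    ("cell_count", "OPL", "OHT", "n_cells"),
    ("cell_count", "IPL", "OHT", "n_cells"),
    ("cell_count", "OS", "OHT", "n_cells"),
    ("iba1_ra", "NFL-GCL", "OHT", "n_cells"),
    ("soma_area", "OPL", "OHT", "soma_radius_um"),
    ("soma_area", "OPL", "contralateral", "soma_radius_um"),
    ("arbor_area", "OPL", "OHT", "arbor_radius_um"),
    ("p2ry12_intensity", "IPL", "OHT", "intensity_percent"),
    ("p2ry12_intensity", "OPL", "OHT", "intensity_percent"),
]

#: contrasts the default profile plants large effects into; each should be
#: flagged significant by the pipeline
PLANTED_CONTRASTS = [
    ("cell_count", "OPL", 3, "OHT-vs-naive"),
    ("cell_count", "IPL", 3, "OHT-vs-naive"),
    ("cell_count", "OS", 5, "OHT-vs-naive"),
    ("iba1_ra", "NFL-GCL", 3, "OHT-vs-naive"),
    ("soma_area", "OPL", 1, "OHT-vs-naive"),
    ("p2ry12_intensity", "IPL", 3, "OHT-vs-naive"),
    ("p2ry12_intensity", "OPL", 5, "OHT-vs-naive"),
    ("vertical_processes", "OPL-OS", 3, "OHT-vs-naive"),
]


def _planted_value(profile_entry: dict, key: str) -> float:
    v = profile_entry[key]
    return float(v[0]) if isinstance(v, (tuple, list)) else float(v)


def _planted_sd(spec: synth.CohortSpec, key: str, mean_value: float) -> float:
    """Between-animal SD of a planted parameter, on the parameter scale."""
    if key == "n_cells":
        return spec.between_animal_cv * mean_value
    if key == "intensity_percent":
        return spec.between_animal_intensity_sd
    if key == "soma_radius_um":
        return synth.BETWEEN_ANIMAL_SOMA_SD_UM
    if key == "arbor_radius_um":
        return synth.BETWEEN_ANIMAL_ARBOR_SD_UM
    raise KeyError(key)


def ordering_concordance(
    per_animal: pd.DataFrame, spec: synth.CohortSpec,
    metric: str, layer: str, group: str, key: str,
) -> tuple[int, int]:
    """Concordant / tested well-separated day pairs for one metric curve.

    A day pair is tested when the planted parameters for the two days are
    at least one between-animal SD apart (the plant is well separated)
    and the measured group means also differ by at least one pooled
    between-animal SD (the measurement resolves them); it is concordant
    when the measured means are ordered the same way as the planted
    parameter.
    """
    sub = per_animal[
        (per_animal["metric"] == metric)
        & (per_animal["layer"] == layer)
        & (per_animal["group"] == group)
    ]
    days = sorted(sub["day"].unique())
    means = sub.groupby("day")["value"].mean()
    sds = sub.groupby("day")["value"].std(ddof=1)
    pooled_sd = float(np.sqrt(np.mean(sds.dropna() ** 2)))
    tested = concordant = 0
    for d1, d2 in itertools.combinations(days, 2):
        p1 = _planted_value(spec.field_params(group, d1, layer), key)
        p2 = _planted_value(spec.field_params(group, d2, layer), key)
        sep_sd = _planted_sd(spec, key, (p1 + p2) / 2.0)
        if abs(p1 - p2) < sep_sd:
            continue
        m1, m2 = float(means[d1]), float(means[d2])
        if abs(m1 - m2) < pooled_sd:
            continue
        tested += 1
        concordant += (p1 < p2) == (m1 < m2)
    return concordant, tested


def cohort_recovery_run(
    master_seed: int,
    n_animals: int = 8,
    fields_per_layer: int = 1,
    field_side_px: int = 256,
) -> dict:
    """One full pipeline run on the default cohort profile, summarised.

    Returns the ordering concordance over all curve checks and whether
    each planted contrast was flagged significant.
    """
    spec = synth.CohortSpec(
        n_animals_per_group=n_animals,
        fields_per_animal_per_layer=fields_per_layer,
        field_side_px=field_side_px,
        master_seed=master_seed,
    )
    bundle = pipeline.run_quantification(pipeline.RunConfig(cohort=spec))
    conc = tested = 0
    for metric, layer, group, key in ORDERING_CHECKS:
        c, t = ordering_concordance(bundle.per_animal, spec, metric, layer, group, key)
        conc += c
        tested += t
    comp = bundle.comparisons
    sig_flags = []
    for metric, layer, day, contrast in PLANTED_CONTRASTS:
        row = comp[
            (comp["metric"] == metric)
            & (comp["layer"] == layer)
            & (comp["day"] == day)
            & (comp["contrast"] == contrast)
        ]
        sig_flags.append(bool(row["significant"].iloc[0]) if len(row) else False)
    return {
        "concordant_pairs": conc,
        "tested_pairs": tested,
        "rank_agreement": conc / tested if tested else float("nan"),
        "planted_significant": sig_flags,
        "all_planted_significant": all(sig_flags),
    }


def determinism_check(master_seed: int = 0) -> bool:
    """Two identically configured runs must produce byte-identical tables."""
    import io as _io

    def tidy_bytes() -> bytes:
        spec = synth.CohortSpec(
            n_animals_per_group=2,
            fields_per_animal_per_layer=1,
            field_side_px=192,
            master_seed=master_seed,
        )
        bundle = pipeline.run_quantification(pipeline.RunConfig(cohort=spec))
        buf = _io.StringIO()
        bundle.tidy.to_csv(buf, index=False, float_format="%.10g")
        return buf.getvalue().encode()

    return tidy_bytes() == tidy_bytes()
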