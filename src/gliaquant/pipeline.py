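"""End-to-end orchestration: cohort -> measurements -> statistics -> report.

``run_quantification`` turns a cohort (synthetic, or a manifest of TIFF
fields on disk) into:

* a tidy field-level measurement table
  (field_id, animal, group, day, layer, zone, metric, value);
* a per-animal table (mean across each animal's fields - the default unit
  of analysis, which avoids pseudo-replicating fields within an animal);
* a ComparisonTable applying the full statistical scheme: hypertensive or
  contralateral vs naive (Mann-Whitney), hypertensive vs contralateral of
  the same animal (Wilcoxon signed-rank), time-course ANOVA with
  Bonferroni contrasts, and retinal-zone ANOVA for hypertensive eyes.

Everything is deterministic given the master seed; the run manifest
records parameters, seeds and package version so any field can be
re-executed in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, detect, intensity, morph, stats
from .detect import PUNCTA_PARAMS, SPOT_PARAMS, DetectionParams
from .io import FieldImage, ImageStack, max_project, read_stack
from .synth import VP_LAYER, CohortDataset, CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_DETECTION: dict[str, DetectionParams] = {
    "OS": SPOT_PARAMS,
    "OPL": DetectionParams(),
    "IPL": DetectionParams(),
    "NFL-GCL": DetectionParams(),
    VP_LAYER: PUNCTA_PARAMS,
}

#: layers in which P2RY12 intensity is measured
INTENSITY_LAYERS = ("OPL", "IPL", "NFL-GCL")
#: layers counted cell-by-cell
COUNT_LAYERS = ("OS", "OPL", "IPL")
#: layers with per-cell soma/arbor morphometry
MORPHO_LAYERS = ("OPL", "IPL")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    manifest_path: str | None = None  # read fields from disk instead
    out_dir: str | None = None
    detection: dict[str, DetectionParams] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION)
    )
    unit: str = "animal"  # or "field"
    write_images: bool = False
    measure_morphometry: bool = True

    def __post_init__(self) -> None:
        if self.unit not in ("animal", "field"):
            raise ValueError("unit must be 'animal' or 'field'")
        missing = [l for l in (*COUNT_LAYERS, "NFL-GCL", VP_LAYER) if l not in self.detection]
        if missing:
            raise ValueError(f"detection params missing for layers: {missing}")


@dataclass
class ResultsBundle:
    config: RunConfig
    manifest: pd.DataFrame
    tidy: pd.DataFrame  # field-level long table
    per_animal: pd.DataFrame
    comparisons: pd.DataFrame


def quantify_field(
    obj: ImageStack | FieldImage,
    layer: str,
    detection: dict[str, DetectionParams],
    measure_morphometry: bool = True,
) -> dict[str, float]:
    """All metrics for one field; keys are tidy-table metric names."""
    params = detection[layer]
    out: dict[str, float] = {}
    if layer == VP_LAYER:
        img = obj if isinstance(obj, FieldImage) else max_project(obj, "iba1")
        out["vertical_processes"] = morph.count_vertical_processes(img, params)
        return out
    img = max_project(obj, "iba1")
    if layer in COUNT_LAYERS:
        counter = detect.count_spots if layer == "OS" else detect.count_cells
        cells = counter(img, params)
        out["cell_count"] = cells.density_per_field
    if layer == "NFL-GCL":
        out["iba1_ra"] = morph.area_fraction(img, params).fraction
    if measure_morphometry and layer in MORPHO_LAYERS:
        somas, arbors = morph.automated_morphometry(img, params)
        if somas:
            out["soma_area"] = float(np.mean(somas))
        if arbors:
            out["arbor_area"] = float(np.mean(arbors))
    if layer in INTENSITY_LAYERS and isinstance(obj, ImageStack) and "p2ry12" in obj.channels:
        green = max_project(obj, "p2ry12")
        out["p2ry12_intensity"] = intensity.mean_intensity_percent(green)
    return out


def _load_dataset(config: RunConfig) -> CohortDataset:
    if config.manifest_path is not None:
        root = Path(config.manifest_path).parent
        manifest = pd.read_csv(config.manifest_path)
        fields = {}
        for row in manifest.itertuples():
            stack = read_stack(root / row.file)
            fields[row.field_id] = (stack, None)
        return CohortDataset(spec=config.cohort, manifest=manifest, fields=fields)
    out_dir = None
    if config.write_images and config.out_dir is not None:
        out_dir = Path(config.out_dir) / "cohort"
    return generate_cohort(config.cohort, out_dir=out_dir, keep_in_memory=True)


def build_tidy_table(dataset: CohortDataset, config: RunConfig) -> pd.DataFrame:
    rows = []
    n_failed = 0
    for row in dataset.manifest.itertuples():
        obj, _truth = dataset.fields[row.field_id]
        try:
            metrics = quantify_field(
                obj, row.layer, config.detection, config.measure_morphometry
            )
        except Exception:  # a bad field is logged and skipped, not fatal
            logger.exception("field %s failed; skipping", row.field_id)
            n_failed += 1
            continue
        for metric, value in metrics.items():
            rows.append(
                {
                    "field_id": row.field_id,
                    "animal": row.animal,
                    "group": row.group,
                    "day": int(row.day),
                    "layer": row.layer,
                    "zone": row.zone,
                    "metric": metric,
                    "value": float(value),
                }
            )
    if n_failed:
        logger.warning("%d field(s) failed quantification", n_failed)
    if not rows:
        raise RuntimeError("no fields could be quantified (empty manifest?)")
    tidy = pd.DataFrame(rows)
    return tidy.sort_values(["metric", "layer", "group", "day", "field_id"]).reset_index(
        drop=True
    )


def per_animal_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric across an animal's fields (the analysis unit)."""
    out = (
        tidy.groupby(["metric", "layer", "group", "day", "animal"], as_index=False)[
            "value"
        ]
        .mean()
        .sort_values(["metric", "layer", "group", "day", "animal"])
        .reset_index(drop=True)
    )
    return out


def _values(df: pd.DataFrame, **sel) -> pd.DataFrame:
    m = pd.Series(True, index=df.index)
    for k, v in sel.items():
        m &= df[k] == v
    return df[m]


def run_statistics(per_animal: pd.DataFrame, days) -> pd.DataFrame:
    """Apply the full comparison scheme to the per-animal table."""
    rows = []
    tables = []
    for (metric, layer), sub in per_animal.groupby(["metric", "layer"]):
        naive = _values(sub, group="naive")["value"].to_numpy()
        for day in days:
            oht = _values(sub, group="OHT", day=day)
            contra = _values(sub, group="contralateral", day=day)
            ctx = {"metric": metric, "layer": layer, "day": day}
            if len(naive) and len(oht):
                rows.append(
                    stats.compare_unpaired(
                        oht["value"], naive, contrast="OHT-vs-naive", **ctx
                    )
                )
            if len(naive) and len(contra):
                rows.append(
                    stats.compare_unpaired(
                        contra["value"], naive, contrast="contralateral-vs-naive", **ctx
                    )
                )
            if len(oht) and len(contra):
                merged = oht.merge(
                    contra, on="animal", suffixes=("_oht", "_contra")
                ).sort_values("animal")
                if len(merged):
                    rows.append(
                        stats.compare_paired(
                            merged["value_oht"],
                            merged["value_contra"],
                            contrast="OHT-vs-contralateral",
                            **ctx,
                        )
                    )
        # time-course ANOVA with Bonferroni contrasts, per eye group
        for grp in ("OHT", "contralateral"):
            groups, labels = [], []
            for day in days:
                vals = _values(sub, group=grp, day=day)["value"].to_numpy()
                if len(vals) >= 2:
                    groups.append(vals)
                    labels.append(f"d{day}")
            if len(groups) >= 2:
                tables.append(
                    stats.anova_bonferroni(
                        groups,
                        labels=labels,
                        metric=metric,
                        layer=layer,
                        day=None,
                        contrast=grp + ":time-course",
                        family=f"time_course|{grp}|{metric}|{layer}",
                    )
                )
    parts = [t for t in [stats.rows_to_table(rows), *tables] if not t.empty]
    if not parts:
        return stats.rows_to_table([])
    return pd.concat(parts, ignore_index=True)


def run_zone_statistics(tidy: pd.DataFrame) -> pd.DataFrame:
    """Zone comparison (superior/inferior/nasal/temporal) in OHT eyes."""
    tables = []
    zone_metrics = [
        ("cell_count", layer) for layer in COUNT_LAYERS
    ] + [("iba1_ra", "NFL-GCL")]
    for metric, layer in zone_metrics:
        sub = _values(tidy, metric=metric, layer=layer, group="OHT")
        if sub.empty:
            continue
        per_zone = (
            sub.groupby(["animal", "day", "zone"], as_index=False)["value"].mean()
        )
        counts = per_zone.groupby("zone")["value"].count()
        if (counts >= 2).sum() < 2:
            continue
        tables.append(
            stats.zone_analysis(
                per_zone,
                metric=metric,
                layer=layer,
                contrast="zones:OHT",
                family=f"zones|{metric}|{layer}",
            )
        )
    if not tables:
        return stats.rows_to_table([])
    return pd.concat(tables, ignore_index=True)


def run_quantification(config: RunConfig) -> ResultsBundle:
    """Execute the full pipeline and (optionally) write its outputs."""
    dataset = _load_dataset(config)
    if dataset.manifest.empty:
        raise RuntimeError("empty manifest")
    tidy = build_tidy_table(dataset, config)
    per_animal = per_animal_table(tidy) if config.unit == "animal" else tidy.rename(
        columns={"field_id": "animal"}
    )[["metric", "layer", "group", "day", "animal", "value"]]
    days = sorted(set(dataset.manifest.loc[dataset.manifest["group"] != "naive", "day"]))
    parts = [
        t for t in (run_statistics(per_animal, days), run_zone_statistics(tidy))
        if not t.empty
    ]
    comparisons = (
        pd.concat(parts, ignore_index=True) if parts else stats.rows_to_table([])
    )
    bundle = ResultsBundle(
        config=config,
        manifest=dataset.manifest,
        tidy=tidy,
        per_animal=per_animal,
        comparisons=comparisons,
    )
    if config.out_dir is not None:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def write_bundle(bundle: ResultsBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_csv(bundle.manifest, out_dir / "manifest.csv")
    _write_csv(bundle.tidy, out_dir / "tidy_table.csv")
    _write_csv(bundle.per_animal, out_dir / "per_animal.csv")
    _write_csv(bundle.comparisons, out_dir / "comparisons.csv")
    for metric, name in [
        ("cell_count", "counts.csv"),
        ("iba1_ra", "area_fraction.csv"),
        ("soma_area", "soma.csv"),
        ("arbor_area", "arbor.csv"),
        ("vertical_processes", "vertical_processes.csv"),
        ("p2ry12_intensity", "intensity.csv"),
    ]:
        sub = bundle.tidy[bundle.tidy["metric"] == metric]
        if not sub.empty:
            _write_csv(sub, out_dir / name)
    run_manifest = {
        "version": __version__,
        "master_seed": bundle.config.cohort.master_seed,
        "unit": bundle.config.unit,
        "detection": {
            layer: dataclasses.asdict(p) for layer, p in bundle.config.detection.items()
        },
        "n_fields": int(len(bundle.manifest)),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))


def group_mean_curves(per_animal: pd.DataFrame, metric: str, layer: str) -> pd.DataFrame:
    """Group mean +- SD of a metric per day (the report's curve data)."""
    sub = _values(per_animal, metric=metric, layer=layer)
    return (
        sub.groupby(["group", "day"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n="count")
        .reset_index(drop=True)
    )


def render_report(bundle: ResultsBundle, out_dir: str | Path) -> Path:
    """Write time-course figures and a markdown report.

    One figure per metric x layer: grouped bars (mean +- SD per day) for
    hypertensive and contralateral eyes with the naive mean as a dotted
    reference line, significance asterisks from the comparison table.
    Regeneration overwrites the same files (idempotent).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Quantification report", ""]
    combos = (
        bundle.tidy[["metric", "layer"]].drop_duplicates().itertuples(index=False)
    )
    for metric, layer in combos:
        curves = group_mean_curves(bundle.per_animal, metric, layer)
        days = sorted(set(curves.loc[curves["group"] != "naive", "day"]))
        fig, ax = plt.subplots(figsize=(5, 3.2))
        width = 0.35
        xs = np.arange(len(days))
        for off, grp, color in ((-width / 2, "OHT", "#b03030"), (width / 2, "contralateral", "#3060b0")):
            sub = curves[curves["group"] == grp].set_index("day")
            means = [sub["mean"].get(d, np.nan) for d in days]
            sds = [sub["sd"].get(d, 0.0) for d in days]
            ax.bar(xs + off, means, width, yerr=sds, capsize=2, label=grp, color=color)
        naive = curves[curves["group"] == "naive"]
        if not naive.empty:
            ax.axhline(float(naive["mean"].iloc[0]), ls=":", color="k", label="naive mean")
        _annotate_significance(ax, bundle.comparisons, metric, layer, days, xs, width)
        ax.set_xticks(xs, [f"{d} d" for d in days])
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} - {layer}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fname = f"{metric}_{layer.replace('/', '-')}.png"
        fig.savefig(fig_dir / fname, dpi=110)
        plt.close(fig)
        lines.append(f"## {metric} - {layer}\n\n![{metric} {layer}](figures/{fname})\n")
    sig = bundle.comparisons[bundle.comparisons["significant"]]
    if bundle.comparisons.empty:
        lines.append("\n_No statistical comparisons available._\n")
    else:
        lines.append(f"\n{len(sig)} of {len(bundle.comparisons)} contrasts significant at alpha=0.05.\n")
    report = out_dir / "report.md"
    report.write_text("\n".join(lines))
    return report


def _annotate_significance(ax, comparisons, metric, layer, days, xs, width) -> None:
    if comparisons.empty:
        return
    sub = comparisons[
        (comparisons["metric"] == metric)
        & (comparisons["layer"] == layer)
        & (comparisons["contrast"] == "OHT-vs-naive")
        & comparisons["significant"]
    ]
    sig_days = set(sub["day"])
    top = ax.get_ylim()[1]
    for x, d in zip(xs, days):
        if d in sig_days:
            ax.text(x - width / 2, top * 0.97, "*", ha="center", fontsize=10)
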