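"""Nonparametric group comparisons for the measurement tables.

The comparison scheme applied to every metric (cell counts, Iba1-RA,
arbor area, vertical processes, soma area, P2RY12 intensity):

* hypertensive vs contralateral eye of the same animal -> Wilcoxon
  signed-rank (paired);
* hypertensive or contralateral vs naive animals -> Mann-Whitney U
  (unpaired);
* across time points, and across retinal zones (superior / inferior /
  nasal / temporal) -> one-way ANOVA with Bonferroni-corrected pairwise
  contrasts.

All tests are two-sided; significance is declared at alpha = 0.05.  Exact
small-sample p-values are used where available (signed-rank n <= 25,
U with min group <= 8, no ties); ties fall back to the tie-corrected
normal approximation, recorded in the row's flags.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

TABLE_COLUMNS = [
    "metric",
    "layer",
    "day",
    "contrast",
    "test",
    "statistic",
    "p_raw",
    "p_adjusted",
    "n1",
    "n2",
    "significant",
    "family",
    "flags",
]


@dataclass
class TestRow:
    """One statistical contrast, one row of a ComparisonTable."""

    test: str
    statistic: float
    p_raw: float
    n1: int
    n2: int
    p_adjusted: float | None = None
    metric: str = ""
    layer: str = ""
    day: object = None
    contrast: str = ""
    family: str = ""
    flags: tuple[str, ...] = field(default=())

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return p < ALPHA

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "layer": self.layer,
            "day": self.day,
            "contrast": self.contrast,
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted if self.p_adjusted is not None else self.p_raw,
            "n1": self.n1,
            "n2": self.n2,
            "significant": self.significant,
            "family": self.family,
            "flags": ";".join(self.flags),
        }


def rows_to_table(rows) -> pd.DataFrame:
    """Assemble TestRows into a ComparisonTable DataFrame."""
    if not rows:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.DataFrame([r.as_dict() for r in rows], columns=TABLE_COLUMNS)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def compare_paired(a, b, **context) -> TestRow:
    """Wilcoxon signed-rank test for matched per-animal values.

    ``a`` and ``b`` must be matched by animal (e.g. hypertensive vs
    contralateral eye).  Exact p for n <= 25 when there are no zero
    differences or tied |differences|, else the tie-corrected normal
    approximation (flagged).  All-zero differences mean the test is
    undefined; p = 1 is reported with a flag.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty samples")
    d = a - b
    flags: list[str] = []
    if np.all(d == 0):
        return TestRow(
            test="wilcoxon_signed_rank",
            statistic=0.0,
            p_raw=1.0,
            n1=len(a),
            n2=len(b),
            flags=("all_differences_zero",),
            **context,
        )
    nz = d[d != 0]
    exact_ok = len(nz) <= 25 and not _has_ties(np.abs(nz)) and len(nz) == len(d)
    method = "exact" if exact_ok else "approx"
    if not exact_ok:
        flags.append("normal_approximation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(a, b, alternative="two-sided", method=method)
    return TestRow(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n1=len(a),
        n2=len(b),
        flags=tuple(flags),
        **context,
    )


def compare_unpaired(a, b, **context) -> TestRow:
    """Mann-Whitney U test for independent samples.

    Exact p (full enumeration of arrangements) when the smaller group has
    <= 8 observations and the pooled data has no ties; otherwise the
    tie-corrected normal approximation, flagged in the row.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group in unpaired comparison")
    flags: list[str] = []
    pooled = np.concatenate([a, b])
    exact_ok = min(len(a), len(b)) <= 8 and not _has_ties(pooled)
    method = "exact" if exact_ok else "asymptotic"
    if not exact_ok:
        flags.append("normal_approximation")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestRow(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n1=len(a),
        n2=len(b),
        flags=tuple(flags),
        **context,
    )


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("number of contrasts m must be >= 1")
    return min(1.0, m * p_raw)


def anova_bonferroni(
    groups, labels=None, m: int | None = None, **context
) -> pd.DataFrame:
    """One-way ANOVA with Bonferroni-corrected pairwise contrasts.

    ``groups`` is a sequence of k >= 2 samples.  Returns a ComparisonTable
    with one omnibus ANOVA row plus one row per pair of groups (two-sample
    t contrasts, p adjusted by ``m``; default m = number of pairs).  Every
    group needs n >= 2.  Identical constant groups make F undefined; the
    omnibus row is then flagged degenerate with p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels/groups length mismatch")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m_eff = m if m is not None else len(pairs)
    family = context.pop("family", f"bonferroni_m={m_eff}")
    prefix = context.pop("contrast", "")
    prefix = prefix + "|" if prefix else ""

    rows: list[TestRow] = []
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        rows.append(
            TestRow(
                test="anova_oneway",
                statistic=float("nan"),
                p_raw=1.0,
                n1=len(pooled),
                n2=len(groups),
                contrast=prefix + "omnibus",
                family=family,
                flags=("degenerate_constant_groups",),
                **context,
            )
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_res = sps.f_oneway(*groups)
        f_stat, f_p = float(f_res.statistic), float(f_res.pvalue)
        omni_flags: tuple[str, ...] = ()
        if not np.isfinite(f_p):
            # exactly equal group means can round to a tiny negative F
            f_stat, f_p = max(f_stat, 0.0), 1.0
            omni_flags = ("degenerate_zero_between_group_variance",)
        rows.append(
            TestRow(
                test="anova_oneway",
                statistic=f_stat,
                p_raw=f_p,
                flags=omni_flags,
                n1=len(pooled),
                n2=len(groups),
                contrast=prefix + "omnibus",
                family=family,
                **context,
            )
        )
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        flags: tuple[str, ...] = ()
        if np.all(np.concatenate([gi, gj]) == gi[0]):
            t_stat, p = float("nan"), 1.0
            flags = ("degenerate_constant_groups",)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_res = sps.ttest_ind(gi, gj)
            t_stat, p = float(t_res.statistic), float(t_res.pvalue)
            if np.isnan(p):
                p, flags = 1.0, ("degenerate_constant_groups",)
        rows.append(
            TestRow(
                test="t_contrast_bonferroni",
                statistic=t_stat,
                p_raw=p,
                p_adjusted=bonferroni(p, m_eff),
                n1=len(gi),
                n2=len(gj),
                contrast=f"{prefix}{labels[i]}-vs-{labels[j]}",
                family=family,
                flags=flags,
                **context,
            )
        )
    return rows_to_table(rows)


ZONES = ("superior", "inferior", "nasal", "temporal")


def zone_analysis(
    records: pd.DataFrame,
    value_col: str = "value",
    zone_col: str = "zone",
    subset: str = "all_fields",
    **context,
) -> pd.DataFrame:
    """Compare a metric across retinal zones in hypertensive eyes.

    Runs the 4-group (or however many zones are present) ANOVA with
    Bonferroni pairwise contrasts over per-animal values grouped by zone.
    ``subset`` labels which fields went in ("all_fields" or
    "nearest_optic_disc").  Requires >= 2 zones each with n >= 2 and no
    missing zone labels.
    """
    if zone_col not in records.columns:
        raise ValueError(f"records lack a {zone_col!r} column")
    if records[zone_col].isna().any():
        raise ValueError("missing zone labels in records")
    zones = [z for z in ZONES if z in set(records[zone_col])]
    extra = set(records[zone_col]) - set(ZONES)
    if extra:
        raise ValueError(f"unknown zone labels: {sorted(extra)}")
    if len(zones) < 2:
        raise ValueError("zone analysis needs >= 2 zones")
    groups = [records.loc[records[zone_col] == z, value_col].to_numpy() for z in zones]
    table = anova_bonferroni(groups, labels=zones, **context)
    table["family"] = table["family"] + f"|subset={subset}"
    return table
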