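import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from gliaquant import stats
from gliaquant.stats import (
    anova_bonferroni,
    bonferroni,
    compare_paired,
    compare_unpaired,
    rows_to_table,
    zone_analysis,
)


def signed_rank_enumeration(a, b):
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    ranks = rankdata(np.abs(d))
    t_pos = ranks[d > 0].sum()
    t_neg = ranks[d < 0].sum()
    t_obs = min(t_pos, t_neg)
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        tp = sum(r for r, s in zip(ranks, signs) if s)
        dist.append(min(tp, ranks.sum() - tp))
    dist = np.asarray(dist, float)
    return min(1.0, float((dist <= t_obs).mean()))


class TestPaired:
    def test_identical_samples_p_one(self):
        row = compare_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert row.p_raw == 1.0
        assert "all_differences_zero" in row.flags
        assert not row.significant

    def test_all_positive_differences_exact_tail(self):
        # n = 8, every difference positive: the most extreme of the 2^8
        # sign patterns, two-sided p = 2/256
        a = np.arange(1.0, 9.0)
        b = a - np.linspace(1.0, 2.0, 8)
        row = compare_paired(a, b)
        assert row.p_raw == pytest.approx(2.0 / 256.0)

    def test_statistic_matches_rank_oracle(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        row = compare_paired(a, b)
        d = a - b
        ranks = rankdata(np.abs(d))
        t_pos = ranks[d > 0].sum()
        t_neg = ranks[d < 0].sum()
        assert row.statistic == pytest.approx(min(t_pos, t_neg))

    def test_exact_p_matches_sign_enumeration(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            row = compare_paired(a, b)
            assert row.p_raw == pytest.approx(signed_rank_enumeration(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0], [1.0])


def mwu_enumeration(a, b):
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
    return u_obs, min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestUnpaired:
    def test_identical_values_symmetric_u(self):
        vals = [3.0, 1.0, 2.0]
        row = compare_unpaired(vals, vals)
        assert row.statistic == pytest.approx(len(vals) ** 2 / 2)

    def test_complete_separation_exact_p(self):
        row = compare_unpaired([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert row.statistic == 0.0
        assert row.p_raw == pytest.approx(0.1)  # 2 of C(6,3)=20 arrangements

    def test_matches_enumeration_oracle(self, rng):
        for n1 in (3, 5, 8):
            for n2 in (4, 8):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                row = compare_unpaired(a, b)
                u_ref, p_ref = mwu_enumeration(a, b)
                assert row.statistic == pytest.approx(u_ref)
                assert row.p_raw == pytest.approx(p_ref, abs=1e-12)

    def test_ties_fall_back_to_approximation(self):
        row = compare_unpaired([1.0, 1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 4.0])
        assert "normal_approximation" in row.flags

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_unpaired([], [1.0])


class TestAnovaBonferroni:
    def test_identical_constant_groups_degenerate(self):
        table = anova_bonferroni([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        omnibus = table[table["contrast"] == "omnibus"].iloc[0]
        assert "degenerate" in omnibus["flags"]
        assert omnibus["p_raw"] == 1.0

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 4) == pytest.approx(0.08)
        assert bonferroni(0.4, 4) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)

    def test_adjusted_monotone_and_at_least_raw(self, rng):
        groups = [rng.normal(loc=m, size=6) for m in (0.0, 0.3, 2.0)]
        table = anova_bonferroni(groups)
        pair = table[table["test"] == "t_contrast_bonferroni"]
        assert (pair["p_adjusted"] >= pair["p_raw"] - 1e-15).all()
        assert (pair["p_adjusted"] <= 1.0).all()
        order = pair.sort_values("p_raw")
        assert order["p_adjusted"].is_monotonic_increasing

    def test_strong_effect_detected(self, rng):
        groups = [rng.normal(0, 1, size=8), rng.normal(0, 1, size=8), rng.normal(8, 1, size=8)]
        table = anova_bonferroni(groups, labels=["a", "b", "c"])
        omnibus = table[table["contrast"] == "omnibus"].iloc[0]
        assert omnibus["significant"]
        ab = table[table["contrast"] == "a-vs-b"].iloc[0]
        assert not ab["significant"]

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0], [3.0]])


class TestZoneAnalysis:
    @staticmethod
    def zone_frame(rng, shift=None):
        rows = []
        for z in stats.ZONES:
            mu = 10.0 + (shift if shift and z == "nasal" else 0.0)
            for v in rng.normal(mu, 2.0, size=8):
                rows.append({"zone": z, "value": v})
        return pd.DataFrame(rows)

    def test_shifted_zone_detected(self, rng):
        table = zone_analysis(self.zone_frame(rng, shift=10.0))
        nasal_rows = table[
            table["contrast"].str.contains("nasal") & (table["test"] == "t_contrast_bonferroni")
        ]
        assert nasal_rows["significant"].all()

    def test_single_zone_rejected(self, rng):
        df = self.zone_frame(rng)
        with pytest.raises(ValueError, match=">= 2 zones"):
            zone_analysis(df[df["zone"] == "nasal"])

    def test_missing_or_unknown_labels_rejected(self, rng):
        df = self.zone_frame(rng)
        df.loc[0, "zone"] = None
        with pytest.raises(ValueError, match="missing zone"):
            zone_analysis(df)
        df2 = self.zone_frame(rng)
        df2.loc[0, "zone"] = "central"
        with pytest.raises(ValueError, match="unknown zone"):
            zone_analysis(df2)

    def test_null_zones_mostly_nonsignificant(self, rng):
        nonsig = 0
        reps = 40
        for _ in range(reps):
            table = zone_analysis(self.zone_frame(rng))
            omnibus = table[table["contrast"].str.endswith("omnibus")].iloc[0]
            nonsig += not omnibus["significant"]
        assert nonsig / reps >= 0.85


def test_rows_to_table_columns():
    row = compare_unpaired([1.0, 2.0, 5.0], [3.0, 4.0, 6.0], metric="cell_count", layer="OPL", day=3)
    table = rows_to_table([row])
    assert list(table.columns) == stats.TABLE_COLUMNS
    assert table.loc[0, "p_adjusted"] == table.loc[0, "p_raw"]
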