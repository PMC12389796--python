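"""Averaging, ART ANOVA, Wilcoxon/BY and regression statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nirsasym import (
    art_anova,
    average_levels,
    clinical_correlation,
    daily_slopes,
    pairwise_wilcoxon,
)
from nirsasym.group_stats import benjamini_yekutieli


def _table(rows):
    return pd.DataFrame(rows)


class TestAverageLevels:
    def _base(self):
        rows = []
        for session, day, val in [(0, 1, 0.1), (1, 1, 0.3)]:
            rows.append(
                {"subject": "S1", "session": session, "day": day, "unit": "u",
                 "hemisphere": "left", "chromophore": "HbO", "index_kind": "TRAC",
                 "value": val}
            )
        return _table(rows)

    def test_two_sessions_average(self):
        out = average_levels(self._base(), "sessions")
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(0.2)
        assert out["n_averaged"].iloc[0] == 2

    def test_single_session_identity(self):
        df = self._base().iloc[:1]
        out = average_levels(df, "sessions")
        assert out["value"].iloc[0] == pytest.approx(0.1)

    def test_within_day_keeps_day_column(self):
        out = average_levels(self._base(), "sessions_within_day")
        assert "day" in out.columns and "session" not in out.columns

    def test_averaging_order_commutes_on_balanced_table(self, rng):
        rows = []
        for s, u in itertools.product(range(4), range(5)):
            rows.append(
                {"subject": f"S{s}", "unit": f"u{u}", "hemisphere": "left",
                 "chromophore": "HbO", "index_kind": "TRAC", "value": rng.normal()}
            )
        df = _table(rows)
        a = average_levels(average_levels(df, "subjects"), "channels")
        b = average_levels(average_levels(df, "channels"), "subjects")
        assert a["value"].iloc[0] == pytest.approx(b["value"].iloc[0])

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            average_levels(self._base(), "nope")


def _factorial_frame(ns, na, nb, fill):
    rows = []
    for s, a, b in itertools.product(range(ns), range(na), range(nb)):
        rows.append(
            {"subject": f"S{s}", "factor_a": f"a{a}", "unit": f"b{b}",
             "value": fill(s, a, b)}
        )
    return _table(rows)


class TestArtAnova:
    def test_pure_factor_a_effect_strips_from_other_alignments(self, rng):
        # alignment-definition oracle on a 4-subject x 2 x 3 toy table
        df = _factorial_frame(4, 2, 3, lambda s, a, b: 2.0 * a)
        out = art_anova(df).set_index("effect")
        assert out.loc["factor_a", "F"] > 100
        assert out.loc["unit", "F"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc["factor_a:unit", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_patient_shaped_design_dfs(self, rng):
        df = _factorial_frame(15, 2, 14, lambda s, a, b: rng.normal())
        out = art_anova(df, include_subject_term=False)
        assert list(out["df"]) == [1, 13, 13]
        assert list(out["df_res"]) == [392, 392, 392]
        out_rm = art_anova(df, include_subject_term=True)
        assert list(out_rm["df_res"]) == [378, 378, 378]

    def test_healthy_shaped_design_dfs(self, rng):
        df = _factorial_frame(9, 2, 7, lambda s, a, b: rng.normal())
        out = art_anova(df, include_subject_term=True)
        assert list(out["df"]) == [1, 6, 6]
        assert list(out["df_res"]) == [104, 104, 104]

    def test_type_one_error_calibrated(self, rng):
        # null simulation at the study's patient design size
        n_sim, alpha = 400, 0.05
        df = _factorial_frame(15, 2, 14, lambda s, a, b: 0.0)
        rej = np.zeros(3)
        for _ in range(n_sim):
            df["value"] = rng.normal(size=len(df))
            rej += (art_anova(df)["p"] < alpha).to_numpy()
        rates = rej / n_sim
        assert np.all(rates > 0.02) and np.all(rates < 0.08)

    def test_affine_transform_leaves_f_invariant(self, rng):
        df = _factorial_frame(6, 2, 4, lambda s, a, b: rng.normal() + a - 0.3 * b)
        f1 = art_anova(df)["F"].to_numpy()
        df2 = df.assign(value=3.5 * df["value"] + 11.0)
        f2 = art_anova(df2)["F"].to_numpy()
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_unbalanced_design_instructs_averaging(self, rng):
        df = _factorial_frame(4, 2, 3, lambda s, a, b: rng.normal())
        with pytest.raises(ValueError, match="average"):
            art_anova(df.iloc[:-1])
        dup = pd.concat([df, df.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="average"):
            art_anova(dup)


def _exact_signflip_p(diffs):
    """Enumerate all sign assignments of |d| for the two-sided signed-rank p."""
    d = np.asarray(diffs, float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    mu = ranks.sum() / 2
    more_extreme = np.abs(ws - mu) >= np.abs(w_obs - mu) - 1e-12
    return more_extreme.mean()


class TestPairwiseWilcoxon:
    def test_all_positive_n6_exact_p(self):
        out = pairwise_wilcoxon({"pair": np.array([1, 2, 3, 4, 5, 6.0])})
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 64)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.normal(size=7)
            out = pairwise_wilcoxon({"p": d})
            assert out["p_raw"].iloc[0] == pytest.approx(_exact_signflip_p(d), abs=1e-12)

    def test_zeros_dropped_and_counted(self):
        out = pairwise_wilcoxon({"p": np.array([0.0, 0.0, 1, 2, 3, 4, 5, 6.0])})
        assert out["n_zero"].iloc[0] == 2
        assert out["n"].iloc[0] == 6
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 64)

    def test_all_zero_flagged_p_one(self):
        out = pairwise_wilcoxon({"p": np.zeros(6)})
        assert out["p_raw"].iloc[0] == 1.0
        assert out["flag"].iloc[0] == "all_zero"

    def test_underpowered_flag(self):
        out = pairwise_wilcoxon({"p": np.array([1.0, 2.0, 3.0])})
        assert out["flag"].iloc[0] == "underpowered"

    def test_by_adjustment_across_pairs(self):
        diffs = {
            "a": np.array([1, 2, 3, 4, 5, 6.0]),
            "b": np.array([1, -2, 3, -4, 5, -6.0]),
        }
        out = pairwise_wilcoxon(diffs).set_index("unit")
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()


def _brute_force_by(p):
    """Independent BY oracle: p * m * c(m) / rank with step-up monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    adj = np.empty(m)
    prev = np.inf
    for k in range(m - 1, -1, -1):
        i = order[k]
        val = min(p[i] * m * c_m / (k + 1), prev, 1.0)
        adj[i] = val
        prev = val
    return adj


class TestBenjaminiYekutieli:
    def test_worked_example_m2(self):
        adj = benjamini_yekutieli([0.01, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.06])

    def test_single_p_identity(self):
        np.testing.assert_allclose(benjamini_yekutieli([0.02]), [0.02])

    @pytest.mark.parametrize("m", range(2, 11))
    def test_matches_brute_force_all_lengths(self, m, rng):
        for _ in range(20):
            p = rng.uniform(size=m)
            np.testing.assert_allclose(
                benjamini_yekutieli(p), _brute_force_by(p), atol=1e-12
            )

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=8)
        assert np.all(benjamini_yekutieli(p) >= p - 1e-15)


def _day_table(values_by_day, unit="ch1", subject="S1"):
    rows = []
    for day, v in values_by_day.items():
        rows.append(
            {"subject": subject, "day": day, "unit": unit, "hemisphere": "left",
             "chromophore": "HbO", "index_kind": "TRAC", "value": v}
        )
    return _table(rows)


class TestDailySlopes:
    def test_perfect_line_recovered(self):
        df = _day_table({d: 0.5 - 0.05 * d for d in range(1, 11)})
        out = daily_slopes(df)
        assert out["slope"].iloc[0] == pytest.approx(-0.05, abs=1e-12)
        assert out["p_raw"].iloc[0] < 1e-10
        assert out["flag"].iloc[0] == "**"

    def test_constant_values_zero_slope(self):
        df = _day_table({d: 0.42 for d in range(1, 8)})
        out = daily_slopes(df)
        assert out["slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_raw_p_calibration(self, rng):
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            df = _day_table({d: rng.normal() for d in range(1, 11)})
            if daily_slopes(df)["p_raw"].iloc[0] < 0.05:
                hits += 1
        assert 0.02 < hits / n_sim < 0.08

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError):
            daily_slopes(_day_table({1: 0.1, 2: 0.2}))

    def test_by_families_within_index_and_chromophore(self, rng):
        rows = []
        for unit in ("ch1", "ch2", "ch3"):
            for day in range(1, 6):
                rows.append(
                    {"subject": "S1", "day": day, "unit": unit, "hemisphere": "left",
                     "chromophore": "HbO", "index_kind": "TRAC", "value": rng.normal()}
                )
        out = daily_slopes(_table(rows))
        assert len(out) == 3
        np.testing.assert_allclose(
            np.sort(out["p_adj"].to_numpy()),
            np.sort(_brute_force_by(out["p_raw"].to_numpy())),
            atol=1e-12,
        )


class TestClinicalCorrelation:
    def test_exact_linear_relation_r_one(self):
        clin = pd.DataFrame({"subject": list("abcde"), "arat": [10, 20, 30, 40, 50]})
        metr = pd.DataFrame({"subject": list("abcde"), "m": [21, 41, 61, 81, 101]})
        out = clinical_correlation(metr, clin)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_metric_mean_r_near_zero(self, rng):
        rs = []
        for _ in range(300):
            clin = pd.DataFrame({"subject": range(15), "arat": rng.normal(size=15)})
            metr = pd.DataFrame({"subject": range(15), "m": rng.normal(size=15)})
            rs.append(clinical_correlation(metr, clin)["r"].iloc[0])
        assert np.mean(rs) == pytest.approx(0.0, abs=0.05)

    def test_constant_metric_flagged_missing(self):
        clin = pd.DataFrame({"subject": list("abcd"), "arat": [1.0, 2, 3, 4]})
        metr = pd.DataFrame({"subject": list("abcd"), "m": [5.0, 5, 5, 5]})
        out = clinical_correlation(metr, clin)
        assert np.isnan(out["r"].iloc[0]) and out["flag"].iloc[0] == "zero_variance"

    def test_too_few_subjects_flagged(self):
        clin = pd.DataFrame({"subject": ["a", "b"], "arat": [1.0, 2.0]})
        metr = pd.DataFrame({"subject": ["a", "b"], "m": [3.0, 4.0]})
        out = clinical_correlation(metr, clin)
        assert out["flag"].iloc[0] == "too_few"
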