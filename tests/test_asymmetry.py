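"""LC/TRAC indices, reconstructed alternatives and the stability report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsasym import alt_laterality, compute_asymmetry_table, lc, stability_report, trac

finite = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
nonzero = finite.filter(lambda v: abs(v) > 1e-9)


class TestBoundedIndex:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (1.0, 1.0, 0.0),
            (1.0, -1.0, 1.0),
            (-1.0, 1.0, -1.0),
            (1.0, 0.0, 1 / np.sqrt(2)),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_lc_analytic_values(self, a, b, expected):
        assert lc(a, b) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "a,b,expected", [(0.5, 0.5, 0.0), (0.3, -0.3, 1.0), (0.0, 0.0, 0.0)]
    )
    def test_trac_analytic_values(self, a, b, expected):
        assert trac(a, b) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=300, deadline=None)
    @given(a=finite, b=finite)
    def test_always_bounded(self, a, b):
        assert abs(lc(a, b)) <= 1.0 + 1e-12
        assert abs(trac(a, b)) <= 1.0 + 1e-12

    @settings(max_examples=200, deadline=None)
    @given(a=finite, b=finite)
    def test_antisymmetry(self, a, b):
        assert lc(a, b) == pytest.approx(-lc(b, a), abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(a=nonzero, b=nonzero, c=nonzero)
    def test_scale_equivariance(self, a, b, c):
        assert lc(c * a, c * b) == pytest.approx(np.sign(c) * lc(a, b), rel=1e-6, abs=1e-9)

    def test_scale_equivariance_worked_example(self):
        a, b, c = 0.4, 0.1, -2.0
        assert trac(c * a, c * b) == pytest.approx(np.sign(c) * trac(a, b), abs=1e-12)

    def test_equality_attained_exactly_on_antisymmetric_pairs(self, rng):
        a = rng.normal(size=1000)
        vals = lc(a, -a)
        np.testing.assert_allclose(np.abs(vals), 1.0, atol=1e-12)
        # and nowhere else on generic pairs
        b = a + rng.normal(size=1000) * 0.3 + 0.01
        assert np.all(np.abs(lc(a, b)) < 1.0)

    def test_vectorized_matches_scalar(self, rng):
        a, b = rng.normal(size=(2, 100))
        vec = lc(a, b)
        for i in range(0, 100, 17):
            assert vec[i] == pytest.approx(lc(a[i], b[i]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            lc(np.nan, 1.0)
        with pytest.raises(ValueError):
            trac(np.inf, 0.0)


class TestReconstructedAlternatives:
    def test_eq1_polarity_insensitive_worked_example(self):
        assert alt_laterality(1.0, 0.5, "eq1") == pytest.approx(1 / 3)
        assert alt_laterality(-1.0, -0.5, "eq1") == pytest.approx(1 / 3)

    @settings(max_examples=200, deadline=None)
    @given(a=nonzero, b=nonzero)
    def test_eq1_even_under_joint_sign_flip(self, a, b):
        assert alt_laterality(a, b, "eq1") == pytest.approx(
            alt_laterality(-a, -b, "eq1"), rel=1e-9, abs=1e-12
        )

    def test_eq2_saturates_for_opposite_signs(self, rng):
        a = np.abs(rng.normal(size=500)) + 1e-6
        b = -(np.abs(rng.normal(size=500)) + 1e-6)
        np.testing.assert_allclose(np.abs(alt_laterality(a, b, "eq2")), 1.0, atol=1e-12)
        assert alt_laterality(0.5, -0.3, "eq2") == 1.0

    @settings(max_examples=200, deadline=None)
    @given(a=finite, b=finite)
    def test_eq2_always_bounded(self, a, b):
        v = alt_laterality(a, b, "eq2")
        if np.isfinite(v):
            assert abs(v) <= 1.0 + 1e-12

    def test_eq3_overflow_sentinel_on_exact_cancellation(self):
        v = alt_laterality(0.5, -0.5, "eq3")
        assert np.isinf(v)

    def test_eq3_unbounded_near_cancellation(self, rng):
        a = np.abs(rng.normal(size=200)) + 0.1
        b = -a * (1 + 1e-4 * rng.uniform(-1, 1, size=200))
        vals = alt_laterality(a, b, "eq3")
        assert np.all(np.abs(vals) > 1e3)

    def test_eq3_zeroed_clamps_negatives(self):
        # zeroing negative inputs loses polarity information but removes
        # the opposite-sign singularity
        assert alt_laterality(0.5, -0.5, "eq3_zeroed") == 1.0
        assert np.isnan(alt_laterality(-0.2, -0.4, "eq3_zeroed"))  # 0/0 case

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            alt_laterality(1, 2, "eq4")


class TestStabilityReport:
    def test_counting_examples(self):
        r = stability_report([1.0, -1.0, 0.5])
        assert r.frac_at_unity == pytest.approx(2 / 3)
        r2 = stability_report([0.995, 0.2])
        assert r2.frac_above_099 == 0.5 and r2.frac_at_unity == 0.0

    def test_continuous_draws_never_hit_unity(self, rng):
        r = stability_report(rng.uniform(-1, 1, size=1000))
        assert r.frac_at_unity == 0.0

    def test_overflow_counted_as_infinite_max(self):
        r = stability_report([0.5, 2.0], overflow_flags=[False, True])
        assert np.isinf(r.max_abs) and r.n_overflow == 1
        assert np.isfinite(r.p95_abs) or r.n_overflow > 0

    def test_percentile_ordering(self, rng):
        r = stability_report(rng.normal(size=500))
        assert r.p95_abs <= r.max_abs

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stability_report([])


def _full_responses(montage, lc_val=None, symmetric=False, same_tasks=False, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ch in montage.channels:
        for task in ("mi_left", "mi_right"):
            v = rng.normal()
            rows.append({"channel": ch, "task": task, "chromophore": "HbO", "coefficient": v})
            rows.append({"channel": ch, "task": task, "chromophore": "HbR", "coefficient": -v / 3})
    df = pd.DataFrame(rows)
    if symmetric:
        # copy left-channel values onto the right partner
        for lch, rch in montage.symmetric_pairs:
            for task in ("mi_left", "mi_right"):
                for chrom in ("HbO", "HbR"):
                    src = df[(df.channel == lch) & (df.task == task) & (df.chromophore == chrom)]
                    df.loc[
                        (df.channel == rch) & (df.task == task) & (df.chromophore == chrom),
                        "coefficient",
                    ] = src["coefficient"].to_numpy()
    if same_tasks:
        for ch in montage.channels:
            for chrom in ("HbO", "HbR"):
                src = df[(df.channel == ch) & (df.task == "mi_left") & (df.chromophore == chrom)]
                df.loc[
                    (df.channel == ch) & (df.task == "mi_right") & (df.chromophore == chrom),
                    "coefficient",
                ] = src["coefficient"].to_numpy()
    return df


class TestAsymmetryTable:
    def test_clinical_montage_row_counts(self, clinical_montage):
        df = _full_responses(clinical_montage)
        out = compute_asymmetry_table(df, clinical_montage)
        for chrom in ("HbO", "HbR"):
            sub = out[out.chromophore == chrom]
            assert len(sub[sub.index_kind == "LC_left"]) == 14
            assert len(sub[sub.index_kind == "LC_right"]) == 14
            assert len(sub[sub.index_kind == "TRAC"]) == 28

    def test_hemisphere_symmetric_responses_give_zero_lc(self, clinical_montage):
        df = _full_responses(clinical_montage, symmetric=True)
        out = compute_asymmetry_table(df, clinical_montage)
        lcs = out[out.index_kind.str.startswith("LC_")]
        np.testing.assert_allclose(lcs["value"], 0.0, atol=1e-12)

    def test_task_identical_responses_give_zero_trac(self, clinical_montage):
        df = _full_responses(clinical_montage, same_tasks=True)
        out = compute_asymmetry_table(df, clinical_montage)
        tracs = out[out.index_kind == "TRAC"]
        np.testing.assert_allclose(tracs["value"], 0.0, atol=1e-12)

    def test_affected_intact_axis_after_mirroring(self, clinical_montage):
        df = _full_responses(clinical_montage).replace(
            {"mi_left": "mi_affected", "mi_right": "mi_intact"}
        )
        out = compute_asymmetry_table(df, clinical_montage)
        assert {"LC_affected", "LC_intact", "TRAC"} == set(out.index_kind.unique())

    def test_alt_variants_reported_with_overflow_flags(self, clinical_montage):
        df = _full_responses(clinical_montage)
        out = compute_asymmetry_table(df, clinical_montage, alt_variants=("eq2", "eq3"))
        assert out[out.index_kind.str.startswith("alt_eq2")].shape[0] == 14 * 2 * 2
        assert out["overflow"].dtype == bool

    def test_trac_wiring_contra_minus_ipsi(self, clinical_montage):
        # left-hemisphere channel: contra hand is the right hand
        lch, rch = clinical_montage.symmetric_pairs[0]
        df = pd.DataFrame(
            [
                {"channel": lch, "task": "mi_right", "chromophore": "HbO", "coefficient": 1.0},
                {"channel": lch, "task": "mi_left", "chromophore": "HbO", "coefficient": 0.0},
            ]
        )
        out = compute_asymmetry_table(df, clinical_montage, index_kinds=("TRAC",))
        assert out["value"].iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_missing_task_skips_unit(self, clinical_montage):
        lch, _ = clinical_montage.symmetric_pairs[0]
        df = pd.DataFrame(
            [{"channel": lch, "task": "mi_right", "chromophore": "HbO", "coefficient": 1.0}]
        )
        out = compute_asymmetry_table(df, clinical_montage, index_kinds=("TRAC",))
        assert out.empty
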