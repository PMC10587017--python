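"""Paired statistics, multiplicity control and the cohort report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from spinemorph import (build_report, multiplicity, paired_t, pearson,
                        percent_change, significance_power)


class TestPercentChange:
    @pytest.mark.parametrize("nsp, esp, expect", [
        (45.0, 36.0, -20),    # coronal Cobb, neutral to extended
        (53.0, 36.0, -32),    # standing radiograph to extended
        (28.0, 23.0, -18),    # standing kyphosis to neutral supine
        (53.0, 45.0, -15),    # standing Cobb to neutral supine
    ])
    def test_reported_reductions(self, nsp, esp, expect):
        assert round(percent_change(nsp, esp)) == expect

    @given(st.floats(0.5, 100), st.floats(-0.9, 2.0))
    def test_relative_change_identity(self, a, f):
        assert percent_change(a, a * (1 + f)) == pytest.approx(100 * f,
                                                               abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero baseline"):
            percent_change(0.0, 5.0)


class TestPairedT:
    def test_equals_one_sample_t_on_differences(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            a = rng.normal(10, 3, n)
            b = a + rng.normal(-1, 2, n)
            t, p, df = paired_t(a, b)
            ref = stats.ttest_1samp(b - a, 0.0)
            assert t == pytest.approx(float(ref.statistic), abs=1e-10)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)
            assert df == n - 1

    def test_consistent_unit_shift_with_jitter_is_significant(self):
        rng = np.random.default_rng(0)
        nsp = np.array([10.0, 11.0, 9.5, 10.5])
        esp = nsp + 1.0 + rng.normal(0, 1e-3, 4)
        _, p, df = paired_t(nsp, esp)
        assert df == 3
        assert p < 0.05

    def test_zero_variance_differences_raise(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(a, a + 5.0)   # constant shift, no noise
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(a, a)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    def test_invariance_under_positive_affine_maps(self, scale, shift):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(0, 0.5, 12)
        r0, p0 = pearson(x, y)
        r1, p1 = pearson(scale * x + shift, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestMultiplicity:
    def test_bonferroni_with_four_outcomes(self):
        sig, alt = multiplicity([0.036, 0.001, 0.2, 0.0125], alpha=0.05)
        assert sig == [False, True, False, False]   # threshold 0.0125
        assert alt == [False, True, False, False]   # threshold 0.01
        # 0.036 would clear an uncorrected 0.05 level
        assert 0.036 < 0.05

    def test_single_outcome_keeps_raw_alpha(self):
        sig, _ = multiplicity([0.03], alpha=0.05)
        assert sig == [True]


def _synthetic_cohort(n=10, seed=4):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        kn = rng.normal(23, 2.6)
        cn = rng.normal(45, 7.8)
        an = rng.normal(16, 4)
        rows.append(dict(subject=f"S{i}", position="NSP", kyphosis_deg=kn,
                         cobb_deg=cn, periapical_rotation_deg=0.85 * an,
                         apical_rotation_deg=an,
                         ivd_asym_mm=rng.normal(2.0, 0.8),
                         np_asym_mm=rng.normal(2.1, 0.8),
                         cov_d_mm=rng.normal(4.0, 1.0),
                         cov_d_apical_mm=rng.normal(4.6, 1.0)))
        rows.append(dict(subject=f"S{i}", position="ESP",
                         kyphosis_deg=kn - rng.normal(10, 3),
                         cobb_deg=cn - rng.normal(9, 3),
                         periapical_rotation_deg=0.85 * an - rng.normal(4, 2),
                         apical_rotation_deg=an - rng.normal(7, 3),
                         ivd_asym_mm=rng.normal(1.3, 0.8),
                         np_asym_mm=rng.normal(1.1, 0.8),
                         cov_d_mm=rng.normal(3.5, 1.0),
                         cov_d_apical_mm=rng.normal(3.7, 1.0)))
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_report_shape_and_delta_percent(self):
        df = _synthetic_cohort()
        rep = build_report(df)
        angles = rep["angles"]
        assert list(angles["outcome"]) == ["Kyphosis", "Coronal Cobb",
                                           "Peri-apical rotation",
                                           "Apical rotation"]
        nsp = df[df.position == "NSP"].kyphosis_deg.mean()
        esp = df[df.position == "ESP"].kyphosis_deg.mean()
        assert int(angles.delta_pct.iloc[0]) == round(
            100 * (esp - nsp) / nsp)
        assert len(rep["discs"]) == 8
        assert len(rep["correlations"]) == 4

    def test_single_subject_rejected(self):
        df = _synthetic_cohort(n=1)
        with pytest.raises(ValueError, match="at least 2"):
            build_report(df)

    def test_incomplete_pairs_are_excluded_with_warning(self):
        df = _synthetic_cohort()
        df = df.drop(df[(df.subject == "S3") & (df.position == "ESP")].index)
        with pytest.warns(UserWarning, match="S3"):
            rep = build_report(df)
        assert rep["excluded"] == ["S3"]

    def test_identical_positions_flagged_as_undefined(self):
        df = _synthetic_cohort()
        nsp = df[df.position == "NSP"].copy()
        esp = nsp.copy()
        esp["position"] = "ESP"
        with pytest.raises(ValueError, match="zero variance"):
            build_report(pd.concat([nsp, esp], ignore_index=True))


def test_monte_carlo_power_of_the_kyphosis_effect():
    # change of -10 deg with 4 deg SD at n=10: overwhelmingly significant
    frac = significance_power(-10.0, 4.0, 10, alpha=0.0125,
                              n_replicates=200, rng=9)
    assert frac >= 0.95


def test_qq_plot_writes_a_file(tmp_path):
    from spinemorph.stats_report import qq_plot
    out = tmp_path / "qq.png"
    qq_plot(np.random.default_rng(0).normal(45, 8, 10), out)
    assert out.stat().st_size > 0
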