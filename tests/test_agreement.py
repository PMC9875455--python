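import numpy as np
import pytest

from cardiodti import (
    PairedSample,
    bland_altman,
    compare_conditions,
    icc,
    normality_test,
)
from cardiodti.errors import ParameterError


class TestPairedSample:
    def test_missing_pairs_dropped_and_logged(self):
        s = PairedSample(
            np.array([1.0, 2.0, np.nan, 4.0, 5.0]),
            np.array([1.0, np.nan, 3.0, 4.0, 5.0]),
            subjects=("a", "b", "c", "d", "e"),
        )
        assert s.n == 3
        assert set(s.dropped) == {"b", "c"}

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            PairedSample(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestNormality:
    def test_null_normal_passes_most_seeds(self):
        hits = sum(
            normality_test(np.random.default_rng(s).normal(size=50)).p > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_lognormal_rejected_most_seeds(self):
        hits = sum(
            normality_test(np.exp(np.random.default_rng(s).normal(size=50))).p < 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_constant_vector_degenerate(self):
        r = normality_test(np.full(10, 3.0))
        assert r.degenerate


class TestCompareConditions:
    def test_large_shift_detected_by_t_test(self):
        # the shift is found in every seed; the gate picks the t-test except
        # when Shapiro-Wilk (level ~5% per vector) happens to reject
        t_chosen = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            a = rng.normal(size=18)
            b = a + 2.0 + rng.normal(scale=0.3, size=18)
            r = compare_conditions(PairedSample(a, b))
            t_chosen += r.test == "paired t-test"
            assert r.p < 0.05
        assert t_chosen >= 15

    def test_identical_conditions_degenerate(self):
        a = np.arange(10, dtype=float)
        r = compare_conditions(PairedSample(a, a.copy()))
        assert r.degenerate and r.p == 1.0

    def test_skewed_data_routed_to_wilcoxon(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(size=30) * 2)
        b = np.exp(rng.normal(size=30) * 2)
        r = compare_conditions(PairedSample(a, b))
        assert r.test == "wilcoxon"

    def test_type_one_error_rate_near_alpha(self):
        # paired null: both conditions same distribution, n=18
        rejections = 0
        n_rep = 400
        for s in range(n_rep):
            rng = np.random.default_rng(10_000 + s)
            a = rng.normal(size=18)
            b = rng.normal(size=18)
            if compare_conditions(PairedSample(a, b)).p < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 < rate < 0.09


class TestICC:
    def test_identical_data_gives_one(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        r = icc(PairedSample(a, a.copy()))
        assert r.value == 1.0 and r.degenerate

    def test_systematic_bias_penalized(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        r = icc(PairedSample(a, a + 10.0))
        assert r.value < 0.2  # absolute agreement punishes constant offset

    def test_worked_six_pair_dataset(self):
        # frozen oracle: two-way ANOVA mean squares give ICC(2,1) = 29/34
        s = PairedSample(np.array([1, 2, 3, 4, 5, 6.0]), np.array([2, 1, 4, 3, 6, 5.0]))
        r = icc(s)
        assert r.value == pytest.approx(29 / 34, abs=1e-12)
        assert r.ci_low <= r.value <= r.ci_high

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        a = rng.normal(size=12)
        b = a + rng.normal(scale=0.4, size=12) + 0.2
        r = icc(PairedSample(a, b))
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["A"] * 12 + ["B"] * 12,
                "score": np.concatenate([a, b]),
            }
        )
        row = pg.intraclass_corr(df, "subject", "rater", "score").iloc[1]
        assert row["Type"] in ("ICC2", "ICC(A,1)")  # label varies across pingouin versions
        assert r.value == pytest.approx(row["ICC"], abs=1e-10)
        assert r.ci_low == pytest.approx(row["CI95"][0], abs=5e-3)
        assert r.ci_high == pytest.approx(row["CI95"][1], abs=5e-3)

    def test_symmetric_in_conditions(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(size=15)
        s = PairedSample(a, b)
        assert icc(s).value == pytest.approx(icc(s.swapped()).value, abs=1e-12)

    def test_noise_monotonically_degrades_expected_icc(self):
        rng = np.random.default_rng(3)
        means = []
        for sd in (0.1, 0.5, 1.5):
            vals = []
            for _ in range(100):
                a = rng.normal(size=15)
                vals.append(icc(PairedSample(a, a + rng.normal(scale=sd, size=15))).value)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestBlandAltman:
    def test_identical_data(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = bland_altman(PairedSample(a, a.copy()))
        assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r = bland_altman(PairedSample(a, a - 2.5))
        assert r.bias == pytest.approx(2.5)
        assert r.loa_low == pytest.approx(2.5) and r.loa_high == pytest.approx(2.5)

    def test_alternating_differences_hand_computed_loa(self):
        # d = (1,-1,1,-1): bias 0, sample SD 2/sqrt(3), LoA = +/-1.96*2/sqrt(3)
        b = np.array([1.0, 2.0, 3.0, 4.0])
        a = b + np.array([1.0, -1.0, 1.0, -1.0])
        r = bland_altman(PairedSample(a, b))
        assert r.bias == pytest.approx(0.0, abs=1e-15)
        assert r.loa_high == pytest.approx(1.96 * 2 / np.sqrt(3), abs=1e-12)
        assert r.loa_high == pytest.approx(2.263, abs=1e-3)

    def test_bias_antisymmetric(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=10)
        s = PairedSample(a, b)
        assert bland_altman(s).bias == pytest.approx(-bland_altman(s.swapped()).bias)
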