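"""CCC, dynamic range, repeatability/reproducibility screening, ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmi_radstab.stability import (
    ccc,
    compare_percentages,
    dynamic_range,
    repeatability_analysis,
    reproducibility_analysis,
)
from vmi_radstab.synthetic import FeatureTableSpec, generate_feature_table

finite_vectors = st.lists(
    st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=30
)


class TestCCC:
    def test_perfect_concordance(self):
        assert ccc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_discordance_with_symmetric_means(self):
        assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_value(self):
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4.0 / 7.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ccc([1, 2, 3], [1, 2])

    def test_degenerate_pair_returns_undefined(self):
        assert math.isnan(ccc([5, 5, 5], [5, 5, 5]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_affine_invariance_and_lin_bound(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.5, size=12)
        c = ccc(x, y)
        assert c == pytest.approx(ccc(y, x), abs=1e-12)
        # same affine map applied to both vectors leaves CCC unchanged
        assert ccc(2.0 * x + 3.0, 2.0 * y + 3.0) == pytest.approx(c, abs=1e-9)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(c) <= abs(r) + 1e-12  # Lin's inequality


class TestDynamicRange:
    def test_identical_vectors(self):
        assert dynamic_range([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_computed_values(self):
        assert dynamic_range([0, 10], [10, 0]) == pytest.approx(0.0, abs=1e-12)
        assert dynamic_range([0, 10], [1, 9]) == pytest.approx(0.9, abs=1e-12)

    def test_zero_range_rules(self):
        # pooled range over both vectors: zero range implies zero differences
        assert dynamic_range([5, 5], [5, 5]) == 1.0
        assert dynamic_range([5, 5], [6, 6]) == 0.0  # range 1, mean diff 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(finite_vectors, st.integers(0, 1000))
    def test_never_exceeds_one(self, x, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(x)
        y = x + rng.normal(size=len(x))
        d = dynamic_range(x, y)
        if not math.isnan(d):
            assert d <= 1.0 + 1e-12


class TestRepeatability:
    def test_identical_tables_give_100_percent(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(10, 6)), columns=[f"f{i}" for i in range(6)])
        records, pct = repeatability_analysis(t, t.copy())
        assert pct == 100.0
        assert all(r.repeatable for r in records)

    def test_repeatable_requires_both_cutoffs(self):
        # alternating offsets keep concordance high but inflate |x - y|
        x = np.arange(16.0)
        y = x + 1.8 * (-1.0) ** np.arange(16)
        c, d = ccc(x, y), dynamic_range(x, y)
        assert c >= 0.9 and d < 0.9  # construction sanity
        records, pct = repeatability_analysis(pd.DataFrame({"f": x}), pd.DataFrame({"f": y}))
        assert not records[0].repeatable  # conjunction: DR failed
        assert records[0].reproducible  # CCC alone passed
        assert pct == 0.0

    def test_catalogue_mismatch_names_offenders(self):
        a = pd.DataFrame({"f1": [1.0, 2, 3], "f2": [1.0, 2, 3]})
        b = pd.DataFrame({"f1": [1.0, 2, 3], "f3": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="f2|f3"):
            repeatability_analysis(a, b)

    def test_mixed_target_ccc_recovers_half_repeatable(self):
        """Half the features at CCC 0.95, half at 0.5 with no class effect:
        about half the catalogue should pass a CCC-only screen."""
        hits = []
        for seed in range(10):
            spec = FeatureTableSpec(
                n_objects=200,
                n_classes=4,
                n_features=40,
                target_ccc=tuple([0.95] * 20 + [0.5] * 20),
                seed=seed,
            )
            test, retest, _ = generate_feature_table(spec)
            records, _ = repeatability_analysis(test, retest, d_thr=-np.inf)
            hits.append(100.0 * np.mean([r.repeatable for r in records]))
        assert abs(np.mean(hits) - 50.0) < 10.0


class TestReproducibility:
    def test_identical_tables_full_matrix(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(10, 5)), columns=[f"f{i}" for i in range(5)])
        mat = reproducibility_analysis({"a": t, "b": t.copy(), "c": t.copy()})
        assert np.allclose(mat.pct, 100.0)

    def test_diagonal_always_100(self):
        rng = np.random.default_rng(3)
        tables = {
            k: pd.DataFrame(
                rng.normal(size=(8, 4)), columns=[f"f{i}" for i in range(4)]
            )
            for k in "ab"
        }
        mat = reproducibility_analysis(tables)
        assert np.allclose(np.diag(mat.pct), 100.0)
        assert np.allclose(mat.pct, mat.pct.T)

    def test_unrelated_tables_near_zero(self):
        rng = np.random.default_rng(4)
        cols = [f"f{i}" for i in range(50)]
        a = pd.DataFrame(rng.normal(size=(200, 50)), columns=cols)
        b = pd.DataFrame(rng.normal(size=(200, 50)), columns=cols)
        mat = reproducibility_analysis({"a": a, "b": b})
        assert mat.pct[0, 1] < 5.0


class TestComparePercentages:
    def test_identical_groups_early_return(self):
        comp = compare_percentages({"a": [80.0, 80.0], "b": [80.0, 80.0]})
        assert comp.f_statistic == 0.0
        assert comp.p_value == 1.0
        assert (comp.tukey["p_adj"] == 1.0).all()

    def test_two_group_f_equals_squared_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(5)
        a = rng.normal(80, 2, size=6)
        b = rng.normal(84, 2, size=6)
        comp = compare_percentages({"a": a, "b": b})
        t, p = ttest_ind(a, b)
        assert comp.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert comp.p_value == pytest.approx(p, rel=1e-10)

    def test_separated_groups_reject_at_tukey(self):
        """Groups with the contrast seen between a quiet and a noisy scan
        protocol (85.2 +/- 0.7 vs 80.1 +/- 0.2, n = 5) are clearly separated."""

        def exact_moments(rng, mean, sd, n):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        rng = np.random.default_rng(6)
        groups = {
            "high_dose": exact_moments(rng, 85.2, 0.7, 5),
            "low_dose": exact_moments(rng, 80.1, 0.2, 5),
        }
        comp = compare_percentages(groups)
        assert comp.tukey["p_adj"].iloc[0] < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_percentages({"a": [1.0, 2.0]})
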