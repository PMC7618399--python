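"""Regressions, AIC comparison, paired contrasts, correlations, phrase contrast."""

import numpy as np
import pandas as pd
import pytest

from numlot import (
    DegenerateContrastError,
    RegressionSpec,
    about_exactly_contrast,
    compare_aic,
    cross_language_correlation,
    divisibility_regression,
    loglog_regression,
    multiplicity_regression,
    paired_number_contrast,
)
from numlot.stats_analysis import design_matrix, _prime_multiplicity


def lstsq_oracle(y, X):
    """Closed-form least squares via the normal equations."""
    Xc = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


def synthetic_table(coef_fn, values=range(1, 100)):
    return {v: 10.0 ** coef_fn(v) for v in values}


class TestLogLog:
    def test_exact_power_law_recovered(self):
        table = synthetic_table(lambda v: -2.0 * np.log10(v) + 3.0)
        res = loglog_regression(table)
        assert res.coef["log10_magnitude"] == pytest.approx(-2.0, abs=1e-12)
        assert res.coef["const"] == pytest.approx(3.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = np.arange(1, rng.integers(10, 60))
            y = rng.normal(size=len(values))
            table = {int(v): 10.0**yi for v, yi in zip(values, y)}
            res = loglog_regression(table)
            beta = lstsq_oracle(y, np.log10(values))
            assert res.coef["const"] == pytest.approx(beta[0], abs=1e-10)
            assert res.coef["log10_magnitude"] == pytest.approx(beta[1], abs=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            loglog_regression({1: 1.0, 2: 0.5})


class TestDivisibility:
    def test_planted_coefficients_recovered_exactly(self):
        table = synthetic_table(
            lambda v: -2.0 * np.log10(v) + 1.0 * (v % 10 == 0) + 0.4 * (v % 5 == 0)
        )
        res = divisibility_regression(table)
        assert res.coef["log10_magnitude"] == pytest.approx(-2.0, abs=1e-10)
        assert res.coef["div10"] == pytest.approx(1.0, abs=1e-10)
        assert res.coef["div5"] == pytest.approx(0.4, abs=1e-10)
        for other in ("div2", "div3", "div7"):
            assert res.coef[other] == pytest.approx(0.0, abs=1e-10)

    def test_oracle_agreement_on_random_designs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            values = list(range(1, int(rng.integers(40, 100))))
            y = rng.normal(size=len(values))
            table = {v: 10.0**yi for v, yi in zip(values, y)}
            res = divisibility_regression(table)
            df = design_matrix(table)
            X = df[list(res.predictors)].to_numpy()
            beta = lstsq_oracle(y, X)
            for i, name in enumerate(res.predictors):
                assert res.coef[name] == pytest.approx(beta[i + 1], abs=1e-10)

    def test_hierarchical_entry_reports_incremental_fits(self):
        table = synthetic_table(lambda v: -2.0 * np.log10(v) + 0.8 * (v % 10 == 0))
        steps = divisibility_regression(table, hierarchical=True)
        assert [len(s.predictors) for s in steps] == [1, 2, 3, 4, 5, 6]
        assert steps[-1].r_squared >= steps[0].r_squared

    def test_word_length_orthogonal_covariate_leaves_planted_betas(self):
        """A word-length column constructed orthogonal to the planted
        predictors must not move their coefficients."""
        values = list(range(1, 100))
        table = synthetic_table(
            lambda v: -2.0 * np.log10(v) + 1.0 * (v % 10 == 0), values
        )
        df = design_matrix(table)
        X = np.column_stack(
            [np.ones(len(values)), df[["log10_magnitude", "div10", "div5",
                                       "div3", "div2", "div7"]].to_numpy()]
        )
        raw_len = np.array([3.0 + (v % 7) for v in values])
        resid = raw_len - X @ np.linalg.lstsq(X, raw_len, rcond=None)[0]
        word_lengths = dict(zip(values, resid))
        spec = RegressionSpec(
            ("log10_magnitude", "div10", "div5", "div3", "div2", "div7", "word_length")
        )
        res = divisibility_regression(table, spec, word_lengths=word_lengths)
        assert res.coef["log10_magnitude"] == pytest.approx(-2.0, abs=1e-8)
        assert res.coef["div10"] == pytest.approx(1.0, abs=1e-8)

    def test_collinear_design_names_columns(self):
        table = synthetic_table(lambda v: -np.log10(v), list(range(10, 140, 10)))
        # on multiples of 10 only, div2/div5/div10 are all-ones = constant
        with pytest.raises(ValueError, match="collinear"):
            divisibility_regression(table)


class TestMultiplicity:
    def test_prime_exponents_of_24(self):
        assert [_prime_multiplicity(24, p) for p in (2, 3, 5, 7)] == [3, 1, 0, 0]

    def test_identical_predictors_give_zero_delta_aic(self):
        table = synthetic_table(lambda v: -2.0 * np.log10(v) + 0.1 * (v % 2 == 0))
        a = multiplicity_regression(table)
        b = multiplicity_regression(table)
        cmp = compare_aic(a, b)
        assert cmp.delta_aic == 0.0
        assert not cmp.improved

    def test_row_mismatch_rejected(self):
        table = synthetic_table(lambda v: -np.log10(v))
        a = divisibility_regression(table)
        b = multiplicity_regression(table, rows=list(range(21, 100)))
        with pytest.raises(ValueError):
            compare_aic(a, b)

    def test_two_word_subset_runs(self):
        table = synthetic_table(lambda v: -2.0 * np.log10(v) + 0.2 * ((v % 2) == 0))
        res = multiplicity_regression(table, rows=list(range(21, 100)))
        assert res.n_rows == 79


class TestPairedContrast:
    def test_hand_t_statistic(self):
        # differences {0.1, 0.3}: mean 0.2, sd 0.1414 -> t = 2.0, df = 1
        tables = {
            "a": {24: 10 ** (0.1), 26: 1.0, 36: 1.0, 34: 1.0},
            "b": {24: 10 ** (0.3), 26: 1.0, 36: 1.0, 34: 1.0},
        }
        res = paired_number_contrast(tables, ((24, 26),))
        assert res.t_statistic == pytest.approx(2.0, rel=1e-12)
        assert res.df == 1

    def test_decade_pair_set_df_53(self):
        """Six languages x nine decade pairs pooled -> df = 53."""
        rng = np.random.default_rng(3)
        tables = {
            lang: {v: 10.0 ** rng.normal(0, 1) for v in range(1, 100)}
            for lang in ("en", "fr", "it", "de", "es", "ru")
        }
        res = paired_number_contrast(tables, "dec+1_vs_dec+2")
        assert res.df == 53
        assert len(res.differences) == 54

    def test_zero_variance_is_degenerate(self):
        tables = {"a": {24: 2.0, 26: 1.0}, "b": {24: 2.0, 26: 1.0}}
        with pytest.raises(DegenerateContrastError):
            paired_number_contrast(tables, ((24, 26),))

    def test_missing_values_listed(self):
        tables = {"a": {24: 2.0}, "b": {24: 2.0, 26: 1.0}}
        with pytest.raises(ValueError, match="26"):
            paired_number_contrast(tables, ((24, 26),))

    def test_unknown_pair_set(self):
        with pytest.raises(ValueError):
            paired_number_contrast({"a": {1: 1.0}}, "nope")


class TestCrossLanguageCorrelation:
    def test_identical_tables_r_one(self):
        t = {v: 100.0 / v**2 for v in range(1, 100)}
        corr, min_r = cross_language_correlation({"a": t, "b": dict(t)})
        assert min_r == pytest.approx(1.0, abs=1e-12)

    def test_multiplicative_offset_r_one(self):
        t = {v: 100.0 / v**2 for v in range(1, 100)}
        shifted = {v: f * 1e3 for v, f in t.items()}
        _, min_r = cross_language_correlation({"a": t, "b": shifted})
        assert min_r == pytest.approx(1.0, abs=1e-12)

    def test_three_point_closed_form(self):
        a = {1: 10.0**1.0, 2: 10.0**2.0, 3: 10.0**4.0}
        b = {1: 10.0**2.0, 2: 10.0**1.0, 3: 10.0**3.0}
        corr, min_r = cross_language_correlation({"a": a, "b": b})
        x, y = np.array([1.0, 2.0, 4.0]), np.array([2.0, 1.0, 3.0])
        expected = float(
            ((x - x.mean()) @ (y - y.mean()))
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert min_r == pytest.approx(expected, abs=1e-12)

    def test_range_intersection_used(self):
        long = {v: 1.0 / v for v in range(1, 100)}
        short = {v: 2.0 / v for v in range(1, 98)}
        corr, _ = cross_language_correlation({"en": long, "fr": short})
        assert corr.shape == (2, 2)

    def test_single_table_rejected(self):
        with pytest.raises(ValueError):
            cross_language_correlation({"a": {1: 1.0}})


class TestAboutExactly:
    def test_identical_columns_give_null_differences(self):
        values = np.arange(1, 101)
        base = 1.0 / values
        jitter = 1 + 0.001 * np.sin(values)  # avoid exact zero variance
        df = pd.DataFrame(
            {"value": values, "about": base * jitter, "exactly": base}
        )
        res = about_exactly_contrast(df)
        for r in res.values():
            assert abs(r.mean_difference) < 0.01

    def test_planted_decade_excess_recovered(self):
        values = np.arange(1, 101)
        base = 100.0 / values**2
        about = base.copy()
        mask = (values % 5 == 0) & (values >= 10)
        about[mask] *= 10.0  # decades' about share 10x their exactly share
        rng = np.random.default_rng(0)
        about *= 10 ** rng.normal(0, 0.001, 100)
        df = pd.DataFrame({"value": values, "about": about, "exactly": base})
        res = about_exactly_contrast(df)
        round_res = res["round_10n_10n+5"]
        # ~1 in raw log10 ratio, shifted by the renormalization constant
        norm_shift = np.log10(about.sum() / base.sum())
        assert round_res.mean_difference == pytest.approx(1.0 - norm_shift, abs=0.01)
        assert round_res.p_value < 1e-10

    def test_zero_cells_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        exactly = np.exp(rng.normal(size=100))
        exactly[0] = 0.0
        df = pd.DataFrame(
            {
                "value": np.arange(1, 101),
                "about": np.exp(rng.normal(size=100)),
                "exactly": exactly,
            }
        )
        with pytest.warns(UserWarning, match="dropping 1"):
            res = about_exactly_contrast(df)
        assert set(res) == {"round_10n_10n+5", "near_decade_10n±1"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            about_exactly_contrast(pd.DataFrame({"value": [1], "about": [1.0]}))
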