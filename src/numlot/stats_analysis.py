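"""Regression and contrast analyses of number-frequency tables.

Descriptive and inferential machinery for log10 frequency profiles:
the log-log magnitude regression, divisibility-indicator and
prime-multiplicity regressions with AIC comparison, an optional
word-length covariate, paired contrasts between matched numbers
(24 vs 26, decade neighbours, ...), cross-language correlations and
the "about n" vs "exactly n" phrase contrast.

All linear models are ordinary least squares with intercept, fitted
through statsmodels; p-values are two-sided from the t distribution
and no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .freq_data import CorrectedTable
from .lot_model import FrequencyVector

__all__ = [
    "RegressionSpec",
    "RegressionResult",
    "ContrastResult",
    "AicComparison",
    "DegenerateContrastError",
    "PAIR_SETS",
    "loglog_regression",
    "divisibility_regression",
    "multiplicity_regression",
    "compare_aic",
    "paired_number_contrast",
    "cross_language_correlation",
    "about_exactly_contrast",
    "design_matrix",
]

_DIV_PREDICTORS = ("div2", "div3", "div5", "div7", "div10")
_MULT_PREDICTORS = ("mult2", "mult3", "mult5", "mult7")
KNOWN_PREDICTORS = ("log10_magnitude",) + _DIV_PREDICTORS + _MULT_PREDICTORS + ("word_length",)

#: canned contrast pair sets
PAIR_SETS: dict[str, tuple[tuple[int, int], ...]] = {
    # simple- vs complex-factorization numbers built from the same words
    "24v26_36v34": ((24, 26), (36, 34)),
    "84v86_96v94": ((84, 86), (96, 94)),
    # decade successors vs their neighbours (rounding suppresses 10n+1)
    "dec+1_vs_dec+2": tuple((10 * n + 1, 10 * n + 2) for n in range(1, 10)),
    "dec+1_vs_dec+3": tuple((10 * n + 1, 10 * n + 3) for n in range(1, 10)),
}


class DegenerateContrastError(ValueError):
    """Paired contrast with zero variance in the differences."""


def _as_freq_map(table) -> dict[int, float]:
    if isinstance(table, CorrectedTable):
        return dict(table.freqs)
    if isinstance(table, FrequencyVector):
        return table.to_dict()
    if isinstance(table, dict):
        return {int(k): float(v) for k, v in table.items()}
    raise TypeError(f"cannot interpret {type(table).__name__} as a frequency table")


def _prime_multiplicity(v: int, p: int) -> int:
    m = 0
    while v % p == 0:
        v //= p
        m += 1
    return m


def design_matrix(
    table,
    rows: list[int] | None = None,
    word_lengths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-number response and predictor columns for the regressions.

    Columns: log10_freq (response), log10_magnitude, div2/3/5/7/10
    indicators, mult2/3/5/7 prime exponents, and word_length when a
    mapping is supplied.
    """
    freqs = _as_freq_map(table)
    values = sorted(freqs) if rows is None else sorted(rows)
    missing = [v for v in values if v not in freqs]
    if missing:
        raise ValueError(f"table missing values: {missing}")
    bad = [v for v in values if freqs[v] <= 0]
    if bad:
        raise ValueError(f"non-positive frequencies at values: {bad}")
    df = pd.DataFrame(index=values)
    df["log10_freq"] = [np.log10(freqs[v]) for v in values]
    df["log10_magnitude"] = np.log10(values)
    for d in (2, 3, 5, 7, 10):
        df[f"div{d}"] = [int(v % d == 0) for v in values]
    for p in (2, 3, 5, 7):
        df[f"mult{p}"] = [_prime_multiplicity(v, p) for v in values]
    if word_lengths is not None:
        df["word_length"] = [word_lengths[v] for v in values]
    return df


@dataclass(frozen=True)
class RegressionSpec:
    """Which predictors and which rows enter a regression."""

    predictors: tuple[str, ...]
    rows: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        unknown = [p for p in self.predictors if p not in KNOWN_PREDICTORS]
        if unknown:
            raise ValueError(f"unknown predictors {unknown}; known: {KNOWN_PREDICTORS}")


@dataclass
class RegressionResult:
    """OLS fit summary: per-predictor beta/SE/p plus r2 and AIC."""

    coef: dict[str, float]
    stderr: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    aic: float
    n_rows: int
    rows: tuple[int, ...]
    predictors: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "coef": self.coef,
            "stderr": self.stderr,
            "pvalues": self.pvalues,
            "r_squared": self.r_squared,
            "aic": self.aic,
            "n_rows": self.n_rows,
            "predictors": list(self.predictors),
        }


def _check_collinear(X: pd.DataFrame) -> None:
    """Raise naming the offending columns if the design is rank-deficient."""
    mat = X.to_numpy(float)
    if np.linalg.matrix_rank(mat) == mat.shape[1]:
        return
    offenders = []
    cols = list(X.columns)
    for i in range(1, len(cols)):  # skip the constant
        sub = mat[:, [j for j in range(len(cols)) if j != i]]
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(mat):
            offenders.append(cols[i])
    raise ValueError(f"collinear design; offending column(s): {offenders or cols}")


def _ols(df: pd.DataFrame, predictors: tuple[str, ...]) -> RegressionResult:
    if len(df) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} rows for {len(predictors)} "
            f"predictors, got {len(df)}"
        )
    X = sm.add_constant(df[list(predictors)], has_constant="add")
    _check_collinear(X)
    res = sm.OLS(df["log10_freq"], X).fit()
    return RegressionResult(
        coef=dict(res.params),
        stderr=dict(res.bse),
        pvalues=dict(res.pvalues),
        r_squared=float(res.rsquared),
        aic=float(res.aic),
        n_rows=int(res.nobs),
        rows=tuple(df.index),
        predictors=predictors,
    )


def loglog_regression(table, rows: list[int] | None = None) -> RegressionResult:
    """OLS of log10 frequency on log10 magnitude (the power-law slope)."""
    df = design_matrix(table, rows)
    if len(df) < 3:
        raise ValueError("loglog_regression needs at least 3 rows")
    return _ols(df, ("log10_magnitude",))


def divisibility_regression(
    table,
    spec: RegressionSpec | None = None,
    word_lengths: dict[int, int] | None = None,
    hierarchical: bool = False,
) -> RegressionResult | list[RegressionResult]:
    """OLS with log magnitude and divisibility indicators.

    Default predictors: log10_magnitude plus div10, div5, div3, div2,
    div7.  With ``hierarchical=True`` returns the sequence of fits as
    each predictor enters in the listed order (sequential-entry
    coefficients); otherwise the full simultaneous model.
    """
    if spec is None:
        spec = RegressionSpec(("log10_magnitude", "div10", "div5", "div3", "div2", "div7"))
    df = design_matrix(table, list(spec.rows) if spec.rows else None, word_lengths)
    if not hierarchical:
        return _ols(df, spec.predictors)
    return [
        _ols(df, spec.predictors[: k + 1]) for k in range(len(spec.predictors))
    ]


def multiplicity_regression(
    table,
    rows: list[int] | None = None,
    keep_div10: bool = True,
    word_lengths: dict[int, int] | None = None,
) -> RegressionResult:
    """OLS with prime-factor multiplicities (exponents of 2, 3, 5, 7).

    ``keep_div10`` retains the divisibility-by-10 indicator alongside
    the multiplicities (the default reporting choice).
    """
    predictors: tuple[str, ...] = ("log10_magnitude",) + _MULT_PREDICTORS
    if keep_div10:
        predictors += ("div10",)
    df = design_matrix(table, rows, word_lengths)
    return _ols(df, predictors)


@dataclass(frozen=True)
class AicComparison:
    """AIC difference between two fits on identical rows."""

    delta_aic: float
    improved: bool  # working threshold: improvement iff delta < -10


def compare_aic(
    divisibility: RegressionResult, multiplicity: RegressionResult
) -> AicComparison:
    """Delta AIC = AIC(multiplicity) - AIC(divisibility), on identical rows."""
    if divisibility.rows != multiplicity.rows:
        raise ValueError("AIC comparison requires fits on identical rows")
    delta = multiplicity.aic - divisibility.aic
    return AicComparison(delta_aic=float(delta), improved=delta < -10.0)


@dataclass
class ContrastResult:
    """Paired t-test on log10 frequency differences."""

    label: str
    differences: list[float]
    t_statistic: float
    df: int
    p_value: float

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.differences))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "differences": list(self.differences),
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
        }


def _paired_t(differences: list[float], label: str) -> ContrastResult:
    d = np.asarray(differences, float)
    if len(d) < 2:
        raise ValueError(f"contrast {label!r} needs >= 2 paired observations")
    if np.ptp(d) == 0.0:
        raise DegenerateContrastError(
            f"contrast {label!r}: all differences identical ({d[0]:.6g}); "
            "t statistic undefined"
        )
    t, p = stats.ttest_1samp(d, 0.0)
    return ContrastResult(
        label=label,
        differences=[float(x) for x in d],
        t_statistic=float(t),
        df=len(d) - 1,
        p_value=float(p),
    )


def paired_number_contrast(
    tables_by_language: dict[str, object],
    pairs: tuple[tuple[int, int], ...] | str,
) -> ContrastResult:
    """Paired t-test on log10 f(a) - log10 f(b), pooled across languages and pairs.

    ``pairs`` is a list of (a, b) value pairs or the name of a canned
    set in :data:`PAIR_SETS`.  Each (language, pair) combination
    contributes one difference; df = #differences - 1.
    """
    if isinstance(pairs, str):
        try:
            label, pair_list = pairs, PAIR_SETS[pairs]
        except KeyError:
            raise ValueError(
                f"unknown pair set {pairs!r}; known: {sorted(PAIR_SETS)}"
            ) from None
    else:
        pair_list = tuple(pairs)
        label = ",".join(f"{a}v{b}" for a, b in pair_list)
    diffs = []
    missing = []
    for lang, table in tables_by_language.items():
        freqs = _as_freq_map(table)
        for a, b in pair_list:
            if a not in freqs or b not in freqs:
                missing.append((lang, a, b))
                continue
            diffs.append(np.log10(freqs[a]) - np.log10(freqs[b]))
    if missing:
        raise ValueError(f"missing values for contrast pairs: {missing}")
    return _paired_t(diffs, label)


def cross_language_correlation(
    tables: dict[str, object],
) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson r of log10 frequencies across languages.

    Tables are aligned on the intersection of their value ranges (so a
    1..97 French table truncates the comparison to 1..97).  Returns the
    symmetric correlation matrix and the minimal off-diagonal r.
    """
    if len(tables) < 2:
        raise ValueError("need at least two language tables")
    maps = {lang: _as_freq_map(t) for lang, t in tables.items()}
    shared = sorted(set.intersection(*(set(m) for m in maps.values())))
    if not shared:
        raise ValueError("no shared values across the supplied tables")
    logf = pd.DataFrame(
        {lang: [np.log10(m[v]) for v in shared] for lang, m in maps.items()},
        index=shared,
    )
    corr = logf.corr(method="pearson")
    off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
    return corr, float(off_diag.min())


def about_exactly_contrast(
    phrase_table: pd.DataFrame,
) -> dict[str, ContrastResult]:
    """Compare normalized "about n" vs "exactly n" phrase frequencies.

    ``phrase_table`` needs columns ``value``, ``about`` and
    ``exactly``.  Each context's frequencies are normalized to sum to 1
    over n (zero cells are dropped with a warning), and paired t-tests
    compare the per-number log10 differences (about - exactly) for two
    number classes: round numbers (10n and 10n+5) and decade
    neighbours (10n+1 and 10n-1).
    """
    required = {"value", "about", "exactly"}
    if not required <= set(phrase_table.columns):
        raise ValueError(f"phrase_table needs columns {sorted(required)}")
    df = phrase_table.copy()
    zero = (df["about"] <= 0) | (df["exactly"] <= 0)
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} value(s) with zero phrase frequency",
            stacklevel=2,
        )
        df = df[~zero]
    diff_values = np.log10(df["about"].to_numpy() / df["about"].sum()) - np.log10(
        df["exactly"].to_numpy() / df["exactly"].sum()
    )
    diffs = pd.Series(diff_values, index=df["value"].to_numpy())
    v = diffs.index.to_numpy()
    classes = {
        "round_10n_10n+5": (v % 5 == 0) & (v >= 10),
        "near_decade_10n±1": (((v % 10 == 1) & (v >= 11)) | ((v % 10 == 9) & (v >= 9))),
    }
    return {
        label: _paired_t(list(diffs[mask]), label) for label, mask in classes.items()
    }
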