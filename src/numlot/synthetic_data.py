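"""Seeded synthetic inputs for the whole pipeline.

Generators with known ground truth stand in for live corpus queries:

* ``simulate_frequencies`` — frequency vectors drawn from the LoT
  model (optionally with the approximation stage) with multiplicative
  lognormal noise, i.e. additive Gaussian noise on log10 frequency.
  That noise model matches the MSE-on-log10 fitting criterion, making
  the fit the maximum-likelihood estimator under the generator.
* ``simulate_raw_ngram_table`` — the constructed inverse of the
  containment correction: component-word counts inflated by every
  composite numeral containing them, split across spelling variants.
* ``shuffle_table`` / ``make_phrase_fixture`` — permutation-null input
  and "about n"/"exactly n" phrase tables with a planted round-number
  effect.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .approximation import ApproxConfig, redistribute
from .fitting import MODELS
from .freq_data import CorrectedTable, NumeralEntry, RawNgramTable, _contains, generate_numerals
from .lot_model import FrequencyVector, LoTParams

__all__ = [
    "SyntheticSpec",
    "simulate_frequencies",
    "simulate_raw_ngram_table",
    "shuffle_table",
    "make_phrase_fixture",
]

#: default ground truth for synthetic studies: parameters whose cumulative
#: model output has the canonical empirical shape — a ppm-scale table with a
#: log-log slope near -2 and decade peaks roughly an order of magnitude high
#: (obtained by fitting the model once to 1000/n^2 with decades raised, then
#: rounding to one significant digit)
DEFAULT_TRUE_PARAMS = LoTParams(f1=800.0, cost_add=3e-4, cost_mult=3e-5)
DEFAULT_APPROX = ApproxConfig(kappa=0.25, w=0.15)
DEFAULT_NOISE_SIGMA = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for one synthetic frequency table."""

    true_params: LoTParams = DEFAULT_TRUE_PARAMS
    approx: ApproxConfig | None = DEFAULT_APPROX
    model: str = "cumulative"
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    n_max: int = 99
    seed: int = 0
    language_for_fixture: str = "en"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {sorted(MODELS)}")


def simulate_frequencies(spec: SyntheticSpec) -> FrequencyVector:
    """Model-generated frequencies with lognormal (log10-Gaussian) noise."""
    pred = MODELS[spec.model](spec.true_params, spec.n_max)
    if spec.approx is not None:
        pred = redistribute(pred, spec.approx)
    values = pred.values
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * 10.0 ** rng.normal(0.0, spec.noise_sigma, size=len(values))
    return FrequencyVector(values, scale_note=f"synthetic seed={spec.seed}")


def simulate_raw_ngram_table(
    corrected: CorrectedTable,
    language: str | None = None,
    seed: int = 0,
    entries: list[NumeralEntry] | None = None,
) -> RawNgramTable:
    """Raw n-gram-style table whose containment correction is ``corrected``.

    Each numeral's raw count is its own corrected frequency plus the
    *raw* counts of every in-range numeral containing it — exactly the
    double counting the single-pass correction removes, so containment
    chains ("dix" inside "dix-sept" inside "soixante-dix-sept") invert
    correctly.  The total is split across spelling variants in seeded
    proportions drawn uniformly from [0.3, 0.7] (then normalized);
    merging the variants restores the per-value totals exactly.
    """
    language = language or corrected.language
    if entries is None:
        entries = generate_numerals(language)
    rng = np.random.default_rng(seed)
    by_value = {e.value: e for e in entries}
    missing = sorted(set(by_value) - set(corrected.freqs))
    if missing:
        raise ValueError(f"corrected table missing values: {missing}")

    raw_totals: dict[int, float] = {}

    def raw_total_of(v: int) -> float:
        # containment strictly increases token count, so this recursion
        # over the containment DAG terminates
        if v not in raw_totals:
            raw_totals[v] = corrected.freqs[v] + sum(
                raw_total_of(u)
                for u, other in by_value.items()
                if u != v and _contains(other.tokens, by_value[v].tokens)
            )
        return raw_totals[v]

    rows: dict[str, float] = {}
    for v, entry in sorted(by_value.items()):
        raw_total = raw_total_of(v)
        weights = rng.uniform(0.3, 0.7, size=len(entry.surface_forms))
        weights /= weights.sum()
        # write the largest share last so the rounding residual lands there
        shares = raw_total * weights
        shares[-1] = raw_total - shares[:-1].sum()
        for form, share in zip(entry.surface_forms, shares):
            rows[form] = share
    return RawNgramTable(language=language, rows=rows)


def shuffle_table(table, seed: int = 0) -> FrequencyVector:
    """Frequencies permuted uniformly across positions 1..n_max (seeded)."""
    if isinstance(table, CorrectedTable):
        fv = FrequencyVector.from_dict(table.freqs)
    elif isinstance(table, FrequencyVector):
        fv = table
    else:
        fv = FrequencyVector(np.asarray(table, float))
    rng = np.random.default_rng(seed)
    return FrequencyVector(rng.permutation(fv.values), scale_note=f"shuffled seed={seed}")


def make_phrase_fixture(
    effect_log10: float,
    seed: int = 0,
    n_max: int = 100,
    noise_sigma: float = 0.02,
) -> pd.DataFrame:
    """Phrase table with a planted round-number "about" excess.

    Both contexts share a smooth 1/n baseline (flat enough that no
    single value dominates the context totals); values of the form 10n
    and 10n+5 get their "about" frequency multiplied by
    ``10**effect_log10``.  Small seeded log10 noise keeps the paired
    contrasts non-degenerate.  Columns: value, about, exactly.

    Note that the per-context sum-to-one normalization applied by the
    contrast analysis dilutes the recovered class difference below the
    planted value by log10(1 + s*(10**effect - 1)), where s is the
    class's share of total mass: boosting the class's shares must
    depress everyone else's.
    """
    rng = np.random.default_rng(seed)
    values = np.arange(1, n_max + 1)
    baseline = 100.0 / values.astype(float)
    about = baseline * 10.0 ** rng.normal(0.0, noise_sigma, size=n_max)
    exactly = baseline * 10.0 ** rng.normal(0.0, noise_sigma, size=n_max)
    round_mask = (values % 5 == 0) & (values >= 10)
    about[round_mask] *= 10.0**effect_log10
    return pd.DataFrame({"value": values, "about": about, "exactly": exactly})
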