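"""Approximate-number usage: Gaussian log-scale kernel and decade redistribution.

Round numerals (decades, by default) are frequently used to convey
*approximate* quantities: "twenty" stands in for 19, 21, 23, ...  This
module converts the exact-concept frequencies predicted by the LoT
grammar into utterance frequencies by moving, for each round target
``n``, a fraction of every other number's mass onto ``n``.  The
probability that ``p`` is approximated by ``n`` follows the
approximate-number-system convention — a Gaussian in log ratio with
Weber fraction ``w``:

    P_approx(n, p) = kappa * exp(-0.5 * ((ln n - ln p) / w) ** 2)

``kappa`` scales the overall propensity to approximate; ``w`` defaults
to 0.15, the accepted Weber fraction for educated adults.  Mass is
moved, never created: redistribution conserves the total frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lot_model import (
    FrequencyVector,
    LoTParams,
    cumulative_frequencies,
    shortest_path_frequencies,
)

__all__ = ["ApproxConfig", "p_approx", "redistribute", "predict_with_approximation"]

DEFAULT_WEBER_FRACTION = 0.15


def default_targets(n_max: int) -> tuple[int, ...]:
    """Multiples of 10 in [10, n_max] — the default approximation sinks."""
    return tuple(range(10, n_max + 1, 10))


@dataclass(frozen=True)
class ApproxConfig:
    """Configuration of the approximation stage.

    kappa : overall approximation probability scale, in [0, 1].
    w : Weber fraction of the log-Gaussian kernel (natural-log scale).
    targets : numbers that attract approximated mass; ``None`` means
        all multiples of 10 within the range of the vector being
        processed.
    """

    kappa: float
    w: float = DEFAULT_WEBER_FRACTION
    targets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not (self.w > 0):
            raise ValueError(f"w must be > 0, got {self.w}")
        if self.targets is not None:
            object.__setattr__(self, "targets", tuple(sorted(set(int(t) for t in self.targets))))
            if any(t < 1 for t in self.targets):
                raise ValueError("targets must be >= 1")

    def resolve_targets(self, n_max: int) -> tuple[int, ...]:
        if self.targets is None:
            return default_targets(n_max)
        out_of_range = [t for t in self.targets if t > n_max]
        if out_of_range:
            raise ValueError(f"targets {out_of_range} exceed n_max={n_max}")
        return self.targets

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "w": self.w,
            "targets": list(self.targets) if self.targets is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ApproxConfig":
        targets = d.get("targets")
        return cls(
            kappa=float(d["kappa"]),
            w=float(d.get("w", DEFAULT_WEBER_FRACTION)),
            targets=tuple(targets) if targets is not None else None,
        )


def p_approx(n: int, n_prime: int, config: ApproxConfig) -> float:
    """Probability that quantity ``n_prime`` is voiced as numeral ``n``.

    Symmetric Gaussian kernel in log ratio:
    ``kappa * exp(-((ln n - ln n') / w)**2 / 2)``.
    """
    if n < 1 or n_prime < 1:
        raise ValueError("p_approx requires positive quantities")
    z = (math.log(n) - math.log(n_prime)) / config.w
    return config.kappa * math.exp(-0.5 * z * z)


def redistribute(freqs: FrequencyVector, config: ApproxConfig) -> FrequencyVector:
    """Move approximated mass onto the round-number targets.

    Targets are processed in increasing order.  For each target ``n``,
    every other number ``p`` donates ``f_p * P_approx(n, p)`` of its
    *current* (sequentially updated) frequency, and ``n`` gains the
    total donated mass.  The grand total is conserved exactly up to
    floating-point rounding; with ``kappa < 1`` all entries stay
    positive, and ``kappa = 0`` is the identity.
    """
    if np.any(freqs.values <= 0):
        raise ValueError("redistribute requires strictly positive frequencies")
    f = freqs.values.copy()
    targets = config.resolve_targets(freqs.n_max)
    if config.kappa == 0.0 or not targets:
        return FrequencyVector(f, freqs.scale_note)
    log_n = np.log(np.arange(1, freqs.n_max + 1, dtype=float))
    for n in targets:
        z = (log_n[n - 1] - log_n) / config.w
        kernel = config.kappa * np.exp(-0.5 * z * z)
        kernel[n - 1] = 0.0  # a number never donates to itself
        donated = f * kernel
        f -= donated
        f[n - 1] += donated.sum()
    return FrequencyVector(f, freqs.scale_note)


_MODEL_FUNCS = {
    "shortest": shortest_path_frequencies,
    "cumulative": cumulative_frequencies,
}


def predict_with_approximation(
    params: LoTParams,
    config: ApproxConfig,
    model: str = "cumulative",
    n_max: int = 99,
) -> FrequencyVector:
    """LoT prediction followed by decade redistribution."""
    try:
        base = _MODEL_FUNCS[model](params, n_max)
    except KeyError:
        raise ValueError(
            f"model must be one of {sorted(_MODEL_FUNCS)}, got {model!r}"
        ) from None
    return redistribute(base, config)
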