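"""Parameter estimation for the LoT frequency models.

Two routes to parameters:

* ``naive_parameters`` — closed-form values read off the first few
  numbers: f1 = freq(1), cost_add = freq(2)/freq(1)^2 and cost_mult
  from one of three anchors (freq(6)/(freq(3)*freq(2)),
  freq(8)/(freq(4)*freq(2)) or freq(9)/freq(3)^2).
* ``fit`` — Nelder-Mead minimisation of the mean squared error between
  predicted and observed log10 frequencies over the full range, started
  from the naive values (or a supplied point), with seeded jittered
  restarts.  Positive parameters are optimised as logs and kappa
  through a logit, so every evaluated candidate is valid.

``permutation_test`` refits the same model to seeded shuffles of the
observed frequencies and returns an add-one permutation p-value for
the quality of the real fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .approximation import ApproxConfig, redistribute
from .lot_model import (
    DegeneracyError,
    FrequencyVector,
    LoTParams,
    cumulative_frequencies,
    shortest_path_frequencies,
)

__all__ = [
    "FitResult",
    "PermutationResult",
    "naive_parameters",
    "mse_loss",
    "fit",
    "permutation_test",
]

MODELS = {
    "shortest": shortest_path_frequencies,
    "cumulative": cumulative_frequencies,
}

#: anchors for the naive multiplication cost: value -> (numerator, denominators)
_MULT_ANCHORS = {6: (6, (3, 2)), 8: (8, (4, 2)), 9: (9, (3, 3))}

_FAILURE_LOSS = 1e100  # sentinel for degenerate candidates inside the optimizer


def _as_vector(freqs) -> FrequencyVector:
    if isinstance(freqs, FrequencyVector):
        return freqs
    if isinstance(freqs, dict):
        return FrequencyVector.from_dict(freqs)
    return FrequencyVector(np.asarray(freqs, dtype=float))


def naive_parameters(freqs, mult_anchor: int = 6) -> LoTParams:
    """Closed-form parameters fixed by the first few observed numbers."""
    f = dict(freqs) if isinstance(freqs, dict) else _as_vector(freqs).to_dict()
    if mult_anchor not in _MULT_ANCHORS:
        raise ValueError(f"mult_anchor must be one of {sorted(_MULT_ANCHORS)}")
    num, (d1, d2) = _MULT_ANCHORS[mult_anchor]
    for n in {1, 2, num, d1, d2}:
        if f.get(n, 0.0) <= 0:
            raise ValueError(f"naive_parameters needs a positive frequency at {n}")
    f1 = f[1]
    return LoTParams(
        f1=f1,
        cost_add=f[2] / f1**2,
        cost_mult=f[num] / (f[d1] * f[d2]),
    )


def mse_loss(
    params: LoTParams,
    approx_config: ApproxConfig | None,
    observed,
    model: str = "cumulative",
) -> float:
    """Mean squared error between predicted and observed log10 frequencies."""
    obs = _as_vector(observed)
    if np.any(obs.values <= 0):
        raise ValueError("observed frequencies must be strictly positive")
    if model not in MODELS:
        raise ValueError(f"model must be one of {sorted(MODELS)}, got {model!r}")
    pred = MODELS[model](params, obs.n_max)
    if approx_config is not None:
        pred = redistribute(pred, approx_config)
    if np.any(pred.values <= 0):
        raise DegeneracyError("model produced non-positive predicted frequencies")
    resid = pred.log10 - obs.log10
    return float(np.mean(resid * resid))


@dataclass
class FitResult:
    """Outcome of an MSE fit: best parameters and bookkeeping."""

    params: LoTParams
    loss: float
    n_evaluations: int
    converged: bool
    seed: int | None = None
    model: str = "cumulative"
    approx_config: ApproxConfig | None = None

    @property
    def kappa(self) -> float | None:
        return self.approx_config.kappa if self.approx_config is not None else None

    def predictions(self, n_max: int | None = None) -> FrequencyVector:
        n = n_max if n_max is not None else 99
        pred = MODELS[self.model](self.params, n)
        if self.approx_config is not None:
            pred = redistribute(pred, self.approx_config)
        return pred

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "loss": self.loss,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
            "model": self.model,
        }
        if self.approx_config is not None:
            d["approx"] = self.approx_config.to_dict()
        return d


@dataclass
class PermutationResult:
    """Observed loss against a null of fits to shuffled frequencies."""

    observed_loss: float
    null_losses: list[float]
    p_value: float
    seed: int | None = None
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "observed_loss": self.observed_loss,
            "null_losses": list(self.null_losses),
            "p_value": self.p_value,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


def _clip_kappa(k: float) -> float:
    # keep the logit finite at the open ends of [0, 1]
    return float(np.clip(k, 1e-9, 1.0 - 1e-9))


def fit(
    observed,
    model: str = "cumulative",
    with_approx: bool = False,
    init: LoTParams | str = "naive",
    seed: int | None = None,
    *,
    n_restarts: int = 5,
    mult_anchor: int = 6,
    kappa_init: float = 0.3,
    w: float = 0.15,
    targets: tuple[int, ...] | None = None,
    max_evaluations: int = 20_000,
    loss_tol: float = 1e-10,
    jitter_scale: float = 0.5,
) -> FitResult:
    """Fit LoT parameters (and optionally kappa) by derivative-free MSE search.

    The first restart starts exactly at ``init`` (the naive closed-form
    point by default); the remaining ``n_restarts - 1`` starts jitter
    the unconstrained coordinates with seeded Gaussian noise.  The best
    restart is returned, so the final loss never exceeds the loss at
    the (un-jittered) initial point up to optimizer tolerance.
    """
    obs = _as_vector(observed)
    if model not in MODELS:
        raise ValueError(f"model must be one of {sorted(MODELS)}, got {model!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    if isinstance(init, str):
        if init != "naive":
            raise ValueError("init must be an LoTParams or the string 'naive'")
        init_params = naive_parameters(obs, mult_anchor=mult_anchor)
    else:
        init_params = init
    if init_params.cost_mult <= 0:
        # log-space search needs a positive starting cost; restart jitter
        # explores from a small value
        init_params = LoTParams(init_params.f1, init_params.cost_add, 1e-8)

    x0 = np.array(
        [
            np.log(init_params.f1),
            np.log(init_params.cost_add),
            np.log(init_params.cost_mult),
        ]
    )
    if with_approx:
        x0 = np.append(x0, logit(_clip_kappa(kappa_init)))

    def unpack(x: np.ndarray) -> tuple[LoTParams, ApproxConfig | None]:
        params = LoTParams(
            f1=float(np.exp(x[0])),
            cost_add=float(np.exp(x[1])),
            cost_mult=float(np.exp(x[2])),
        )
        cfg = (
            ApproxConfig(kappa=float(expit(x[3])), w=w, targets=targets)
            if with_approx
            else None
        )
        return params, cfg

    def objective(x: np.ndarray) -> float:
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                params, cfg = unpack(x)
                loss = mse_loss(params, cfg, obs, model)
        except (DegeneracyError, OverflowError, FloatingPointError, ValueError):
            return _FAILURE_LOSS
        return loss if np.isfinite(loss) else _FAILURE_LOSS

    rng = np.random.default_rng(seed)
    best = None
    total_evals = 0
    any_converged = False
    for r in range(n_restarts):
        start = x0 if r == 0 else x0 + rng.normal(0.0, jitter_scale, size=x0.shape)
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "fatol": loss_tol,
                "xatol": 1e-8,
                "maxfev": max_evaluations,
                "maxiter": max_evaluations,
            },
        )
        total_evals += res.nfev
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= _FAILURE_LOSS:
        raise RuntimeError(
            f"all {n_restarts} restarts diverged (best objective "
            f"{'none' if best is None else best.fun:g}); check the input table"
        )
    params, cfg = unpack(best.x)
    return FitResult(
        params=params,
        loss=float(best.fun),
        n_evaluations=total_evals,
        converged=any_converged,
        seed=seed,
        model=model,
        approx_config=cfg,
    )


def permutation_test(
    observed,
    model: str = "cumulative",
    with_approx: bool = False,
    n_shuffles: int = 1000,
    seed: int | None = None,
    *,
    exact_p: bool = False,
    **fit_kwargs,
) -> PermutationResult:
    """Permutation null for the fit quality.

    Shuffles the observed frequencies uniformly across positions
    1..n_max (seeded), refits the same model to each shuffle, and
    compares losses.  The p-value is the add-one estimator
    ``(1 + #{null <= observed}) / (n_shuffles + 1)``; ``exact_p=True``
    switches to the plain fraction ``#{null <= observed}/n_shuffles``.
    A shuffle whose fit fails outright counts as worse than observed.
    """
    obs = _as_vector(observed)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    # deterministic child seeds (< 2**31) for every fit
    child = lambda: int(rng.integers(0, 2**31))  # noqa: E731
    observed_loss = fit(
        obs, model=model, with_approx=with_approx, seed=child(), **fit_kwargs
    ).loss
    null_losses: list[float] = []
    n_failed = 0
    for _ in range(n_shuffles):
        shuffled = FrequencyVector(rng.permutation(obs.values), obs.scale_note)
        fit_seed = child()
        try:
            null_losses.append(
                fit(
                    shuffled,
                    model=model,
                    with_approx=with_approx,
                    seed=fit_seed,
                    **fit_kwargs,
                ).loss
            )
        except (RuntimeError, ValueError, DegeneracyError):
            n_failed += 1
            null_losses.append(float("inf"))
    k = sum(1 for nl in null_losses if nl <= observed_loss)
    p = k / n_shuffles if exact_p else (1 + k) / (n_shuffles + 1)
    return PermutationResult(
        observed_loss=observed_loss,
        null_losses=null_losses,
        p_value=p,
        seed=seed,
        n_failed=n_failed,
    )
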