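"""Language-of-thought (LoT) models of number-word frequency.

A number concept is built from the primitive 1 by binary addition and
multiplication.  Every symbol carries a multiplicative weight: the
frequency of 1 (``f1``) per leaf, and one operator cost per internal
node (``cost_add`` or ``cost_mult``).  An ordered binary expression
tree ``t`` evaluating to ``n`` therefore has

    weight(t) = f1 ** n_leaves * cost_add ** n_add * cost_mult ** n_mul

which is exactly a probabilistic context-free grammar with production
probabilities (f1, cost_add, cost_mult).

Two predicted-frequency models are implemented:

* *shortest path*: the frequency of ``n`` is the weight of the single
  best (highest-weight, i.e. cheapest) expression for ``n``;
* *cumulative*: the frequency of ``n`` is the summed weight of every
  expression for ``n``.

Both are computed by an O(n^2) recursion over ordered splits
``i + j = n`` and ordered factorizations ``i x j = n`` (i, j >= 2; the
trivial factor 1 is excluded to keep the recursion well-founded).
``enumerate_expressions`` provides a brute-force tree enumeration used
as an exact oracle for both recursions at small ``n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "DegeneracyError",
    "LoTParams",
    "FrequencyVector",
    "ExpressionTree",
    "Contribution",
    "shortest_path_frequencies",
    "cumulative_frequencies",
    "enumerate_expressions",
    "decomposition_contributions",
]

#: frequencies below this are treated as numerically degenerate
DEGENERACY_FLOOR = 1e-300

#: combinatorial guard for brute-force tree enumeration
ENUMERATION_LIMIT = 12


class DegeneracyError(ArithmeticError):
    """A predicted frequency underflowed the representable range."""


@dataclass(frozen=True)
class LoTParams:
    """Parameters of the LoT grammar.

    Parameters
    ----------
    f1
        Frequency assigned to the primitive 1 (in the units of the data
        being modelled, e.g. parts per million).
    cost_add
        Multiplicative cost of an addition node (dimensionless).
    cost_mult
        Multiplicative cost of a multiplication node; 0 disables
        multiplication entirely (pure successor/addition grammar).
    primitive_overrides
        Optional ``{5: f5, 10: f10}`` replacing the computed
        frequencies of 5 and/or 10 before any larger number is
        computed, treating them as extra primitives of the grammar.
    """

    f1: float
    cost_add: float
    cost_mult: float
    primitive_overrides: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if not (self.f1 > 0):
            raise ValueError(f"f1 must be > 0, got {self.f1}")
        if not (self.cost_add > 0):
            raise ValueError(f"cost_add must be > 0, got {self.cost_add}")
        if not (self.cost_mult >= 0):
            raise ValueError(f"cost_mult must be >= 0, got {self.cost_mult}")
        if self.primitive_overrides is not None:
            bad = set(self.primitive_overrides) - {5, 10}
            if bad:
                raise ValueError(
                    f"primitive_overrides keys restricted to {{5, 10}}, got {sorted(bad)}"
                )
            for k, v in self.primitive_overrides.items():
                if not (v > 0):
                    raise ValueError(f"override for {k} must be > 0, got {v}")

    def to_dict(self) -> dict:
        d = {"f1": self.f1, "cost_add": self.cost_add, "cost_mult": self.cost_mult}
        if self.primitive_overrides:
            d["f5"] = self.primitive_overrides.get(5)
            d["f10"] = self.primitive_overrides.get(10)
            d = {k: v for k, v in d.items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LoTParams":
        overrides = {
            k: d[name] for k, name in ((5, "f5"), (10, "f10")) if d.get(name) is not None
        }
        return cls(
            f1=float(d["f1"]),
            cost_add=float(d["cost_add"]),
            cost_mult=float(d["cost_mult"]),
            primitive_overrides=overrides or None,
        )


@dataclass
class FrequencyVector:
    """Per-number positive frequencies for n = 1..n_max.

    ``values[k]`` is the frequency of the number ``k + 1``; indexing by
    number is available through ``fv[n]``.
    """

    values: np.ndarray
    scale_note: str = "model units"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("values must be a non-empty 1-d array")

    @property
    def n_max(self) -> int:
        return len(self.values)

    @property
    def numbers(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def log10(self) -> np.ndarray:
        return np.log10(self.values)

    def __getitem__(self, n: int) -> float:
        if not 1 <= n <= self.n_max:
            raise KeyError(f"number {n} outside 1..{self.n_max}")
        return float(self.values[n - 1])

    def __len__(self) -> int:
        return self.n_max

    def to_dict(self) -> dict[int, float]:
        return {int(n): float(v) for n, v in zip(self.numbers, self.values)}

    def copy(self) -> "FrequencyVector":
        return FrequencyVector(self.values.copy(), self.scale_note)

    @classmethod
    def from_dict(cls, d: dict[int, float], scale_note: str = "model units") -> "FrequencyVector":
        n_max = max(d)
        if set(d) != set(range(1, n_max + 1)):
            raise ValueError("dictionary must cover every number 1..n_max")
        return cls(np.array([d[n] for n in range(1, n_max + 1)], float), scale_note)


@lru_cache(maxsize=None)
def _factor_pairs(n: int) -> tuple[tuple[int, int], ...]:
    """Unordered factorizations i*j = n with 2 <= i <= j (no trivial factor)."""
    pairs = []
    for i in range(2, int(math.isqrt(n)) + 1):
        if n % i == 0:
            pairs.append((i, n // i))
    return tuple(pairs)


def _check_args(params: LoTParams, n_max: int) -> None:
    if not isinstance(params, LoTParams):
        raise TypeError("params must be a LoTParams")
    if not (isinstance(n_max, (int, np.integer)) and n_max >= 1):
        raise ValueError(f"n_max must be an integer >= 1, got {n_max!r}")


def _apply_override(f: np.ndarray, n: int, params: LoTParams) -> None:
    if params.primitive_overrides and n in params.primitive_overrides:
        f[n] = params.primitive_overrides[n]


def shortest_path_frequencies(params: LoTParams, n_max: int) -> FrequencyVector:
    """Predicted frequencies under the shortest-path (best expression) model.

    ``f_1 = f1`` and, for n >= 2,

        f_n = max( max_{i+j=n}  f_i * f_j * cost_add,
                   max_{i*j=n, i,j>=2} f_i * f_j * cost_mult )

    i.e. each number inherits the weight of its single cheapest
    expression.  Primitive overrides for 5/10, if present, replace the
    computed value before larger numbers are derived.
    """
    _check_args(params, n_max)
    f = np.empty(n_max + 1)
    f[0] = np.nan  # unused; numbers are 1-based
    f[1] = params.f1
    ca, cm = params.cost_add, params.cost_mult
    for n in range(2, n_max + 1):
        left = f[1:n]
        best = ca * float(np.max(left * left[::-1]))
        if cm > 0:
            for i, j in _factor_pairs(n):
                cand = cm * f[i] * f[j]
                if cand > best:
                    best = cand
        f[n] = best
        _apply_override(f, n, params)
        if f[n] < DEGENERACY_FLOOR:
            raise DegeneracyError(f"frequency of {n} underflowed ({f[n]:.3g})")
    return FrequencyVector(f[1:])


def cumulative_frequencies(params: LoTParams, n_max: int) -> FrequencyVector:
    """Predicted frequencies under the cumulative (summed expressions) model.

    ``f_1 = f1`` and, for n >= 2,

        f_n = sum_{i+j=n} f_i * f_j * cost_add
            + sum_{i*j=n, i,j>=2} f_i * f_j * cost_mult

    with both sums running over *ordered* pairs, which makes ``f_n``
    exactly the total weight of all ordered binary expression trees
    evaluating to n.
    """
    _check_args(params, n_max)
    f = np.empty(n_max + 1)
    f[0] = np.nan
    f[1] = params.f1
    ca, cm = params.cost_add, params.cost_mult
    for n in range(2, n_max + 1):
        left = f[1:n]
        total = ca * float(np.dot(left, left[::-1]))
        if cm > 0:
            for i, j in _factor_pairs(n):
                term = cm * f[i] * f[j]
                total += term if i == j else 2.0 * term
        f[n] = total
        _apply_override(f, n, params)
        if f[n] < DEGENERACY_FLOOR:
            raise DegeneracyError(f"frequency of {n} underflowed ({f[n]:.3g})")
    return FrequencyVector(f[1:])


@dataclass(frozen=True)
class ExpressionTree:
    """Ordered binary expression over the leaf 1 and operators add/mul."""

    op: str  # "leaf" | "add" | "mul"
    left: "ExpressionTree | None" = None
    right: "ExpressionTree | None" = None
    value: int = 1
    n_leaves: int = 1
    n_add: int = 0
    n_mul: int = 0

    @classmethod
    def leaf(cls) -> "ExpressionTree":
        return cls("leaf")

    @classmethod
    def combine(cls, op: str, left: "ExpressionTree", right: "ExpressionTree") -> "ExpressionTree":
        if op not in ("add", "mul"):
            raise ValueError(f"unknown operator {op!r}")
        value = left.value + right.value if op == "add" else left.value * right.value
        return cls(
            op,
            left,
            right,
            value=value,
            n_leaves=left.n_leaves + right.n_leaves,
            n_add=left.n_add + right.n_add + (op == "add"),
            n_mul=left.n_mul + right.n_mul + (op == "mul"),
        )

    def weight(self, params: LoTParams) -> float:
        return (
            params.f1**self.n_leaves
            * params.cost_add**self.n_add
            * params.cost_mult**self.n_mul
        )

    def __str__(self) -> str:
        if self.op == "leaf":
            return "1"
        sym = "+" if self.op == "add" else "x"
        return f"({self.left} {sym} {self.right})"


@lru_cache(maxsize=None)
def _all_trees(n: int) -> tuple[ExpressionTree, ...]:
    if n == 1:
        return (ExpressionTree.leaf(),)
    trees: list[ExpressionTree] = []
    for i in range(1, n):  # ordered additive splits
        for lt in _all_trees(i):
            for rt in _all_trees(n - i):
                trees.append(ExpressionTree.combine("add", lt, rt))
    for i, j in _factor_pairs(n):  # ordered factorizations, both orders
        orders = [(i, j)] if i == j else [(i, j), (j, i)]
        for a, b in orders:
            for lt in _all_trees(a):
                for rt in _all_trees(b):
                    trees.append(ExpressionTree.combine("mul", lt, rt))
    return tuple(trees)


def enumerate_expressions(
    n: int, params: LoTParams
) -> list[tuple[ExpressionTree, float]]:
    """Every ordered expression tree evaluating to ``n``, with its weight.

    Serves as the brute-force oracle: the weights sum to the cumulative
    model's ``f_n`` and their maximum is the shortest-path ``f_n``.
    Refuses ``n`` above the combinatorial guard, and refuses primitive
    overrides (with overrides the recursions are no longer a sum or max
    over expression trees).
    """
    if not (1 <= n <= ENUMERATION_LIMIT):
        raise ValueError(
            f"enumeration limited to 1 <= n <= {ENUMERATION_LIMIT}, got {n}"
        )
    if params.primitive_overrides:
        raise ValueError(
            "enumerate_expressions is defined for the pure three-parameter "
            "grammar; primitive_overrides are not supported"
        )
    return [(t, t.weight(params)) for t in _all_trees(n)]


@dataclass(frozen=True)
class Contribution:
    """One top-level decomposition of a number and its share of f_n."""

    number: int
    expression_label: str
    mass: float
    share: float


def decomposition_contributions(
    n: int, params: LoTParams, top_k: int = 8
) -> list[Contribution]:
    """Rank top-level decompositions of ``n`` by cumulative-model mass.

    Each unordered additive split ``{i, j}`` (labelled ``"j + i"`` with
    the larger operand first, e.g. ``"23 + 1"``) and each unordered
    factorization (labelled ``"i x j"`` with the smaller factor first,
    e.g. ``"4 x 6"``) aggregates its two ordered variants.  Shares are
    masses divided by the cumulative ``f_n``; with no primitive
    override at ``n`` the shares of all entries sum to 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if n == 1:
        return []
    freqs = cumulative_frequencies(params, n)
    f = freqs.values  # f[k-1] is frequency of k
    ca, cm = params.cost_add, params.cost_mult
    entries: list[tuple[float, int, int, Contribution]] = []

    def add_entry(label: str, mass: float, op_rank: int, operand: int) -> None:
        entries.append(
            (mass, op_rank, operand, Contribution(n, label, mass, mass / freqs[n]))
        )

    for i in range(1, n // 2 + 1):
        j = n - i
        mass = ca * f[i - 1] * f[j - 1] * (1.0 if i == j else 2.0)
        add_entry(f"{j} + {i}", mass, 0, i)
    if cm > 0:
        for i, j in _factor_pairs(n):
            mass = cm * f[i - 1] * f[j - 1] * (1.0 if i == j else 2.0)
            add_entry(f"{i} x {j}", mass, 1, i)
    # descending mass; ties broken addition-first then smallest operand
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    return [c for *_, c in entries[:top_k]]
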