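"""Analytic Hierarchy Process weight derivation.

Indicator weights for the composite pollution index come from pairwise
importance judgments: a positive reciprocal matrix ``A`` with ``A[i][j]``
the importance of indicator ``i`` relative to ``j``.  The weight vector is
the normalized principal eigenvector of ``A`` (found by power iteration),
and judgment coherence is measured by the consistency ratio
``CR = CI / RI(n)`` with ``CI = (lambda_max - n) / (n - 1)``; matrices with
``CR < 0.1`` are conventionally accepted.  A matrix can also be built from
a 1..5 verbal importance score per indicator (general .. absolute
importance), which yields a consistent matrix by construction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "JudgmentMatrix",
    "WeightScheme",
    "matrix_from_scores",
    "weights_from_matrix",
    "check_consistency",
    "consistency_ratio",
    "RANDOM_INDEX",
]

#: Saaty's random consistency index for n = 1..10
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)

_RECIPROCAL_RTOL = 1e-9


class AHPError(ValueError):
    """Invalid judgment matrix or weight scheme."""


class WeightSource(str, enum.Enum):
    DIRECT = "direct"
    AHP = "ahp"


@dataclass(frozen=True)
class JudgmentMatrix:
    """A positive reciprocal pairwise-comparison matrix over named indicators."""

    indicators: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        n = len(self.indicators)
        if n < 2:
            raise AHPError("need at least two indicators")
        if len(set(self.indicators)) != n:
            raise AHPError("duplicate indicator names")
        if a.shape != (n, n):
            raise AHPError(f"matrix shape {a.shape} does not match {n} indicators")
        if not np.all(np.isfinite(a)) or np.any(a <= 0):
            raise AHPError("entries must be positive and finite")
        if not np.allclose(np.diag(a), 1.0, rtol=_RECIPROCAL_RTOL, atol=0):
            raise AHPError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, rtol=_RECIPROCAL_RTOL, atol=0):
            raise AHPError("matrix is not reciprocal (A[j,i] != 1/A[i,j])")

    @property
    def n(self) -> int:
        return len(self.indicators)


@dataclass(frozen=True)
class WeightScheme:
    """Indicator -> weight mapping summing to one (the Wi of the index)."""

    weights: Mapping[str, float]
    source: WeightSource = WeightSource.DIRECT
    consistency_ratio: float | None = None

    def __post_init__(self) -> None:
        w = {k: float(v) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        if not w:
            raise AHPError("empty weight scheme")
        if any(not math.isfinite(v) or v < 0 for v in w.values()):
            raise AHPError("weights must be nonnegative and finite")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise AHPError(f"weights must sum to 1, got {total!r}")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.weights)

    @classmethod
    def direct(cls, weights: Mapping[str, float]) -> "WeightScheme":
        return cls(dict(weights), WeightSource.DIRECT, None)


def matrix_from_scores(scores: Mapping[str, int]) -> JudgmentMatrix:
    """Build a judgment matrix from per-indicator 1..5 importance scores.

    The ratio between two indicators is one plus their score difference
    (differences 0..4 map to ratios 1..5), reciprocal on the weaker side —
    a consistent matrix by construction.
    """
    if len(scores) < 2:
        raise AHPError("need at least two indicators")
    names = tuple(scores)
    vals = []
    for name in names:
        s = scores[name]
        if not isinstance(s, int) or isinstance(s, bool) or not 1 <= s <= 5:
            raise AHPError(f"score for {name!r} must be an integer in 1..5, got {s!r}")
        vals.append(s)
    n = len(names)
    a = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            d = vals[i] - vals[j]
            a[i, j] = (d + 1) if d >= 0 else 1.0 / (1 - d)
    return JudgmentMatrix(names, a)


def _principal_eigenvector(
    a: np.ndarray, rtol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    """Power iteration; returns (normalized eigenvector, lambda_max)."""
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.allclose(nxt, w, rtol=rtol, atol=0):
            w = nxt
            break
        w = nxt
    else:
        raise AHPError(f"power iteration did not converge in {max_iter} iterations")
    lam = float(np.mean((a @ w) / w))
    return w, lam


def _geometric_mean_weights(a: np.ndarray) -> np.ndarray:
    g = np.exp(np.mean(np.log(a), axis=1))
    return g / g.sum()


def consistency_ratio(matrix: JudgmentMatrix) -> float:
    """CR = CI / RI(n); defined as 0 for n <= 2."""
    n = matrix.n
    if n <= 2:
        return 0.0
    if n > len(RANDOM_INDEX):
        raise AHPError(f"no random-index constant for n = {n}")
    _, lam = _principal_eigenvector(matrix.entries)
    ci = (lam - n) / (n - 1)
    return ci / RANDOM_INDEX[n - 1]


def weights_from_matrix(
    matrix: JudgmentMatrix, method: str = "eigenvector"
) -> WeightScheme:
    """Derive a weight scheme from a judgment matrix.

    ``method`` is ``"eigenvector"`` (principal eigenvector via power
    iteration; the default) or ``"geometric_mean"`` (row geometric means);
    the two agree on consistent matrices.
    """
    if method == "eigenvector":
        w, lam = _principal_eigenvector(matrix.entries)
    elif method == "geometric_mean":
        w = _geometric_mean_weights(matrix.entries)
        _, lam = _principal_eigenvector(matrix.entries)
    else:
        raise AHPError(f"unknown method {method!r}")
    n = matrix.n
    if n <= 2:
        cr = 0.0
    else:
        cr = ((lam - n) / (n - 1)) / RANDOM_INDEX[n - 1]
    weights = dict(zip(matrix.indicators, (float(x) for x in w)))
    # renormalize away float dust so the scheme invariant holds exactly
    total = sum(weights.values())
    weights = {k: v / total for k, v in weights.items()}
    return WeightScheme(weights, WeightSource.AHP, cr)


def check_consistency(matrix: JudgmentMatrix, threshold: float = 0.1) -> bool:
    """True iff the matrix's consistency ratio is below ``threshold``."""
    if not threshold > 0:
        raise AHPError("threshold must be positive")
    return consistency_ratio(matrix) < threshold
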