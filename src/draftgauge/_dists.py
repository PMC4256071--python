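"""Small seeded length/count distributions used by the generators.

Every distribution draws from a caller-supplied :class:`numpy.random.Generator`
so that determinism is controlled in one place.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_KINDS = ("constant", "uniform", "lognormal", "geometric", "categorical", "pareto")


@dataclass(frozen=True)
class LengthDist:
    """A positive-integer distribution with an optional lower bound.

    kind:
        ``constant(v)``, ``uniform(lo, hi)`` (inclusive ints),
        ``lognormal(mu, sigma)`` (of the underlying normal),
        ``geometric(p)`` (support 1, 2, ...),
        ``categorical(values, probs)``,
        ``pareto(alpha, scale)`` (heavy-tailed; ``scale * (1 + pareto(alpha))``).
    """

    kind: str
    params: tuple = ()
    low: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.low < 1:
            raise ValueError("low must be >= 1")
        if self.kind == "constant" and int(self.params[0]) < self.low:
            raise ValueError("constant value below lower bound")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if size < 0:
            raise ValueError("size must be >= 0")
        if self.kind == "constant":
            out = np.full(size, int(self.params[0]), dtype=np.int64)
        elif self.kind == "uniform":
            lo, hi = (int(p) for p in self.params)
            out = rng.integers(lo, hi + 1, size=size)
        elif self.kind == "lognormal":
            mu, sigma = self.params
            out = np.rint(rng.lognormal(mu, sigma, size=size)).astype(np.int64)
        elif self.kind == "geometric":
            (p,) = self.params
            out = rng.geometric(p, size=size).astype(np.int64)
        elif self.kind == "categorical":
            values, probs = self.params
            out = rng.choice(np.asarray(values, dtype=np.int64), size=size,
                             p=np.asarray(probs, dtype=float))
        else:  # pareto
            alpha, scale = self.params
            out = np.rint(scale * (1.0 + rng.pareto(alpha, size=size))).astype(np.int64)
        return np.maximum(out, self.low)

    def pmf(self, k: int) -> float:
        """Exact pmf where available (constant, uniform, geometric, categorical).

        Clipping at ``low`` is ignored; intended for goodness-of-fit checks on
        distributions whose support already respects the bound.
        """
        if self.kind == "constant":
            return 1.0 if k == int(self.params[0]) else 0.0
        if self.kind == "uniform":
            lo, hi = (int(p) for p in self.params)
            return 1.0 / (hi - lo + 1) if lo <= k <= hi else 0.0
        if self.kind == "geometric":
            (p,) = self.params
            return p * (1 - p) ** (k - 1) if k >= 1 else 0.0
        if self.kind == "categorical":
            values, probs = self.params
            for v, pr in zip(values, probs):
                if int(v) == k:
                    return float(pr)
            return 0.0
        raise NotImplementedError(f"no closed-form pmf for {self.kind}")


def constant(v: int) -> LengthDist:
    return LengthDist("constant", (v,))


def uniform(lo: int, hi: int) -> LengthDist:
    return LengthDist("uniform", (lo, hi))


def lognormal(mu: float, sigma: float, low: int = 1) -> LengthDist:
    return LengthDist("lognormal", (mu, sigma), low=low)


def geometric(p: float) -> LengthDist:
    return LengthDist("geometric", (p,))


def categorical(values: Sequence[int], probs: Sequence[float]) -> LengthDist:
    probs = np.asarray(probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("categorical probabilities must sum to 1")
    return LengthDist("categorical", (tuple(int(v) for v in values), tuple(probs)))
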