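"""The stochastic sampling operator ``Sa``.

``Sa`` at fraction ``f`` draws ``round(f*m)`` elements uniformly without
replacement from the ``m`` element instances of a library, so the vector of
sampled copy numbers follows the multivariate hypergeometric law.  The
operator conserves the draw size (property I), yields non-negative integer
counts (property III), never creates sequences absent from the input
(``Sa_i(0) = 0``) and is non-deterministic across seeds while reproducible
for a fixed seed.

:func:`enumerate_outcomes` is the exact brute-force oracle for small
multisets: it enumerates every admissible outcome vector with its exact
probability, against which simulated draw frequencies can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .multiset import SequenceMultiset, sum_total

__all__ = [
    "SamplingSpec",
    "OutcomeDistribution",
    "draw_size",
    "sample",
    "sample_counts",
    "enumerate_outcomes",
    "average_of_samples",
    "count_distribution",
]


@dataclass(frozen=True)
class SamplingSpec:
    """Parameters of one application of the sampling operator."""

    fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")


@dataclass
class OutcomeDistribution:
    """Exact outcome law of ``Sa`` on a small multiset.

    ``outcomes[j]`` is one admissible sampled count vector and
    ``probabilities[j]`` its exact multivariate hypergeometric probability.
    """

    outcomes: np.ndarray  # shape (n_outcomes, n_sequences), int64
    probabilities: np.ndarray  # shape (n_outcomes,), sums to 1

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def marginal(self, element_index: int, max_count: int) -> np.ndarray:
        """Exact marginal pmf of one element's sampled count over 0..max_count."""
        pmf = np.zeros(max_count + 1)
        for vec, p in zip(self.outcomes, self.probabilities):
            pmf[vec[element_index]] += p
        return pmf


def draw_size(fraction: float, total: int) -> int:
    """Sample size ``round(f*m)``, ties to even."""
    return int(round(fraction * total))


def sample_counts(
    ms: SequenceMultiset,
    fraction: float,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``k`` independent applications of ``Sa`` as a (k, N) count matrix.

    Vectorized workhorse behind :func:`sample`, the confidence-band
    estimator and the diagnostics.  Uses the marginals decomposition of the
    multivariate hypergeometric distribution, whose cost is independent of
    the library's total size ``m``.
    """
    counts = ms.counts
    m = int(counts.sum())
    s = draw_size(fraction, m)
    if m == 0 or s == 0:
        return np.zeros((k, len(counts)), dtype=np.int64)
    if s == m:
        return np.tile(counts, (k, 1))
    return rng.multivariate_hypergeometric(counts, s, size=k, method="marginals")


def sample(ms: SequenceMultiset, spec: SamplingSpec) -> SequenceMultiset:
    """Apply ``Sa`` once: draw ``round(f*m)`` elements without replacement.

    The output is aligned with the input's sequence order; its counts B
    satisfy 0 <= B_i <= n_i and sum(B) = round(f*m).
    """
    rng = np.random.default_rng(spec.seed)
    out = sample_counts(ms, spec.fraction, 1, rng)[0]
    # conservation and no-creation are structural guarantees; assert anyway
    assert int(out.sum()) == draw_size(spec.fraction, sum_total(ms))
    assert np.all(out <= ms.counts) and np.all(out >= 0)
    return ms.with_counts(out)


def enumerate_outcomes(
    ms: SequenceMultiset, fraction: float, guard: int = 30
) -> OutcomeDistribution:
    """Exact outcome distribution of ``Sa`` on a small multiset.

    Enumerates all integer vectors B with 0 <= B_i <= n_i and
    sum(B) = round(f*m); each has probability
    prod_i C(n_i, B_i) / C(m, round(f*m)).  Intended as the independent
    oracle for :func:`sample`; guarded against combinatorial blow-up.
    """
    counts = [int(c) for c in ms.counts]
    m = sum(counts)
    if m > guard:
        raise ValueError(
            f"multiset has {m} > {guard} total elements; "
            "enumerate_outcomes is an exact small-multiset oracle — "
            "use simulation (sample_counts) instead"
        )
    s = draw_size(fraction, m)
    denom = math.comb(m, s)
    suffix_totals = np.cumsum([0] + counts[::-1])[::-1]  # sum of counts[i:]

    outcomes: list[list[int]] = []
    weights: list[int] = []

    def recurse(i: int, remaining: int, prefix: list[int], weight: int) -> None:
        if i == len(counts):
            if remaining == 0:
                outcomes.append(list(prefix))
                weights.append(weight)
            return
        if remaining > suffix_totals[i]:
            return
        lo = max(0, remaining - int(suffix_totals[i + 1]))
        hi = min(counts[i], remaining)
        for b in range(lo, hi + 1):
            prefix.append(b)
            recurse(i + 1, remaining - b, prefix, weight * math.comb(counts[i], b))
            prefix.pop()

    recurse(0, s, [], 1)
    probs = np.array(weights, dtype=float) / denom
    return OutcomeDistribution(np.array(outcomes, dtype=np.int64), probs)


def average_of_samples(
    ms: SequenceMultiset, fraction: float, k: int, seed: int | None = None
) -> np.ndarray:
    """Element-wise mean of ``k`` independent ``Sa`` draws.

    Converges to ``f * n`` as k grows: averaged over many applications the
    sampling operator behaves as scalar multiplication by f (the identity
    up to scale), which is what makes confidence estimation meaningful.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return sample_counts(ms, fraction, k, rng).mean(axis=0)


def count_distribution(
    ms: SequenceMultiset,
    fraction: float,
    k: int,
    element_index: int,
    seed: int | None = None,
) -> np.ndarray:
    """Empirical pmf of one element's sampled count over 0..n_i.

    For small multisets this converges (in total variation) to the exact
    hypergeometric marginal as k grows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    draws = sample_counts(ms, fraction, k, rng)[:, element_index]
    n_i = int(ms.counts[element_index])
    return np.bincount(draws, minlength=n_i + 1) / k
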