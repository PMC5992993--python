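"""First-order Markov surrogate sequences.

A first-order Markov chain is fully specified by an initial distribution pi
and a transition matrix T.  Surrogates sharing the empirical (pi, T) of a
microstate sequence provide the null ensemble against which non-Markovian
structure (e.g. oscillatory autoinformation peaks) is judged.

Sampling is by the inverse-CDF rule on the unit interval: the cumulative
probabilities partition [0, 1) and a uniform draw r selects index j with
sum_{i<j} p_i <= r < sum_{i<=j} p_i.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .markov_stats import LabelSequence, transition_matrix

__all__ = ["SurrogateSpec", "synthesize_markov_chain", "surrogate_from_sequence"]


@dataclass
class SurrogateSpec:
    pi: np.ndarray
    T: np.ndarray
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        self.T = np.asarray(self.T, dtype=float)
        ns = self.pi.size
        if ns < 1 or self.T.shape != (ns, ns):
            raise ValueError("pi and T dimensions are inconsistent")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("T rows must sum to 1")
        if np.any(self.pi < 0) or np.any(self.T < 0):
            raise ValueError("probabilities must be non-negative")


def _index_from_uniform(cum: list[float], r: float) -> int:
    """Index j with cum[j-1] <= r < cum[j]; the last index absorbs r >= cum[-1]."""
    return min(bisect_right(cum, r), len(cum) - 1)


def synthesize_markov_chain(spec: SurrogateSpec) -> LabelSequence:
    """Generate a Markov chain of length ``spec.n``; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n)
    cum_pi = np.cumsum(spec.pi).tolist()
    cum_rows = [np.cumsum(row).tolist() for row in spec.T]
    labels = np.empty(spec.n, dtype=np.int64)
    j = _index_from_uniform(cum_pi, u[0])
    labels[0] = j
    for t in range(1, spec.n):
        j = _index_from_uniform(cum_rows[j], u[t])
        labels[t] = j
    return LabelSequence(labels=labels, n_s=spec.pi.size)


def surrogate_from_sequence(seq: LabelSequence, n: int | None = None,
                            seed: int | None = None) -> LabelSequence:
    """Surrogate matching the empirical symbol distribution and T of ``seq``.

    The initial distribution is the empirical symbol distribution (which for
    long sequences differs from the eigen-stationary distribution of T only
    at order 1/n).
    """
    model = transition_matrix(seq)
    spec = SurrogateSpec(pi=model.pi, T=model.T, n=n or seq.n, seed=seed)
    out = synthesize_markov_chain(spec)
    out.fs = seq.fs
    return out
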