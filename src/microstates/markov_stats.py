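"""Symbol statistics and likelihood-ratio (G) tests for label sequences.

A microstate sequence is a categorical time series X_t with values in
{0, ..., n_s - 1}.  Its memory structure is probed by a battery of G-tests,
each comparing observed transition counts f with the counts expected under
a null hypothesis, via G = 2 * sum f * log(f / e).  Under the null, G is
asymptotically chi-square with the degrees of freedom listed per test.
All logarithms are natural (entropies in nats); empty cells contribute
zero (the x*log x -> 0 limit).

Tests provided:

* Markov order 0   -- successive symbols independent.
* Markov order 1   -- next symbol depends on the current one only.
* geometric lifetimes -- per-state run lengths memoryless (equivalent
  formulation of first-order Markovianity).
* Markov order 2   -- one further step into the past adds nothing.
* stationarity     -- one-step transition probabilities constant across
  non-overlapping blocks (conditional homogeneity).
* symmetry         -- each transition as likely as its reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "LabelSequence",
    "TransitionModel",
    "GTestResult",
    "LifetimeDistribution",
    "symbol_distribution",
    "transition_matrix",
    "shannon_entropy",
    "max_entropy",
    "test_markov0",
    "test_markov1",
    "test_markov2",
    "lifetime_distribution",
    "geometric_lifetime_gtest",
    "test_geometric_lifetimes",
    "test_stationarity",
    "test_symmetry",
    "results_to_frame",
]


@dataclass
class LabelSequence:
    """Integer-coded label sequence with alphabet {0, ..., n_s - 1}.

    Externally produced sequences must be recoded to this range first.
    ``fs`` (Hz) is optional and only used to convert lags to time.
    """

    labels: np.ndarray
    n_s: int
    fs: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.labels.size < 2:
            raise ValueError("need at least 2 samples")
        if self.n_s < 1:
            raise ValueError("n_s must be >= 1")
        if self.labels.min() < 0 or self.labels.max() >= self.n_s:
            raise ValueError("labels out of range 0..n_s-1")

    @classmethod
    def from_labels(cls, labels, fs: float | None = None) -> "LabelSequence":
        labels = np.asarray(labels, dtype=np.int64)
        return cls(labels=labels, n_s=int(labels.max()) + 1, fs=fs)

    @property
    def n(self) -> int:
        return self.labels.size


@dataclass
class TransitionModel:
    """Symbol distribution pi, row-stochastic T, and raw transition counts."""

    pi: np.ndarray
    T: np.ndarray
    counts: np.ndarray
    n: int
    uniform_rows: tuple[int, ...] = field(default=())
    """States never observed as a transition source; their T row was set uniform."""


@dataclass
class GTestResult:
    statistic: float
    dof: int
    p: float
    name: str = ""
    state: int | None = None  # set for per-state lifetime tests


@dataclass
class LifetimeDistribution:
    """Empirical run-length distribution of one state vs its geometric model.

    ``p_emp[k-1]`` is the observed probability of a run of length k
    (k = 1..m); ``q_geom[k-1] = (1 - T_ii) * T_ii**(k-1)`` is the
    first-order Markov prediction, unnormalized over the truncated support.
    """

    state: int
    m: int
    p_emp: np.ndarray
    q_geom: np.ndarray
    n_runs: int


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

def symbol_distribution(seq: LabelSequence) -> np.ndarray:
    """Empirical symbol probabilities f_i / n (the 'ratio of time covered')."""
    return np.bincount(seq.labels, minlength=seq.n_s) / seq.n


def transition_matrix(seq: LabelSequence) -> TransitionModel:
    """First-order transition counts and row-normalized matrix.

    Rows of states never seen as a transition source are set uniform and
    flagged in ``uniform_rows``.
    """
    x = seq.labels
    ns = seq.n_s
    counts = np.bincount(ns * x[:-1] + x[1:], minlength=ns * ns).reshape(ns, ns)
    row_sums = counts.sum(axis=1)
    T = np.empty((ns, ns), dtype=float)
    empty = row_sums == 0
    T[~empty] = counts[~empty] / row_sums[~empty, None]
    T[empty] = 1.0 / ns
    return TransitionModel(pi=symbol_distribution(seq), T=T, counts=counts,
                           n=seq.n, uniform_rows=tuple(np.flatnonzero(empty)))


def shannon_entropy(p) -> float:
    """Shannon entropy of a probability vector, in nats (0*log 0 := 0)."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0):
        raise ValueError("negative probabilities")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def max_entropy(n_s: int) -> float:
    """log(n_s): the entropy of the uniform distribution over n_s symbols."""
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    return float(np.log(n_s))


# ---------------------------------------------------------------------------
# G-test machinery
# ---------------------------------------------------------------------------

def _g_sum(observed: np.ndarray, expected: np.ndarray) -> float:
    """2 * sum f log(f/e) over cells with f > 0."""
    mask = observed > 0
    f = observed[mask].astype(float)
    e = expected[mask].astype(float)
    return float(2.0 * np.sum(f * np.log(f / e)))


def _finish(name: str, g: float, dof: int, state: int | None = None) -> GTestResult:
    g = max(g, 0.0)
    return GTestResult(statistic=g, dof=dof, p=float(chi2.sf(g, dof)),
                       name=name, state=state)


def _window_counts(x: np.ndarray, ns: int, order: int) -> np.ndarray:
    """Counts of overlapping windows of ``order`` consecutive symbols."""
    code = np.zeros(x.size - order + 1, dtype=np.int64)
    for j in range(order):
        code = code * ns + x[j: x.size - order + 1 + j]
    return np.bincount(code, minlength=ns ** order).reshape((ns,) * order)


def test_markov0(seq: LabelSequence) -> GTestResult:
    """Zero-order Markov test: are successive symbols independent?

    G0 = 2 sum_ij f_ij log(n f_ij / (f_i f_j)) with marginals taken over
    the n-1 transition windows; dof = (n_s - 1)^2.
    """
    ns = seq.n_s
    f = _window_counts(seq.labels, ns, 2)
    fi = f.sum(axis=1)
    fj = f.sum(axis=0)
    n = f.sum()
    expected = np.outer(fi, fj) / n
    return _finish("markov0", _g_sum(f, expected), (ns - 1) ** 2)


def test_markov1(seq: LabelSequence) -> GTestResult:
    """First-order Markov test on triplet windows.

    G1a = 2 sum_ijk f_ijk log(f_ijk f_j / (f_ij f_jk));
    dof = n_s (n_s - 1)^2.
    """
    ns = seq.n_s
    if seq.n < 3:
        raise ValueError("need n >= 3")
    f3 = _window_counts(seq.labels, ns, 3)
    f_ij = f3.sum(axis=2)
    f_jk = f3.sum(axis=0)
    f_j = f3.sum(axis=(0, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = (f_ij[:, :, None] * f_jk[None, :, :]
                    / np.where(f_j, f_j, 1)[None, :, None])
    return _finish("markov1", _g_sum(f3, expected), ns * (ns - 1) ** 2)


def test_markov2(seq: LabelSequence) -> GTestResult:
    """Second-order Markov test on quadruplet windows.

    G2 = 2 sum_ijkl f_ijkl log(f_ijkl f_jk / (f_ijk f_jkl));
    dof = n_s^2 (n_s - 1)^2.
    """
    ns = seq.n_s
    if seq.n < 4:
        raise ValueError("need n >= 4")
    f4 = _window_counts(seq.labels, ns, 4)
    f_ijk = f4.sum(axis=3)
    f_jkl = f4.sum(axis=0)
    f_jk = f4.sum(axis=(0, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = (f_ijk[:, :, :, None] * f_jkl[None, :, :, :]
                    / np.where(f_jk, f_jk, 1)[None, :, :, None])
    return _finish("markov2", _g_sum(f4, expected), ns ** 2 * (ns - 1) ** 2)


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

def _run_lengths(x: np.ndarray, state: int) -> np.ndarray:
    """Lengths of maximal contiguous runs of ``state`` in ``x``."""
    is_state = np.concatenate(([0], (x == state).astype(np.int8), [0]))
    d = np.diff(is_state)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def lifetime_distribution(seq: LabelSequence, state: int) -> LifetimeDistribution:
    """Observed run-length histogram of one state and its geometric model."""
    runs = _run_lengths(seq.labels, state)
    if runs.size == 0:
        raise ValueError(f"state {state} does not occur")
    m = int(runs.max())
    p_emp = np.bincount(runs, minlength=m + 1)[1:] / runs.size
    t_ii = transition_matrix(seq).T[state, state]
    k = np.arange(1, m + 1)
    q_geom = (1.0 - t_ii) * t_ii ** (k - 1) if t_ii < 1 else np.zeros(m)
    return LifetimeDistribution(state=state, m=m, p_emp=p_emp, q_geom=q_geom,
                                n_runs=int(runs.size))


def geometric_lifetime_gtest(dist: LifetimeDistribution) -> GTestResult:
    """G-test of one state's run lengths against the geometric distribution.

    The geometric model is renormalized over the observed support 1..m and
    the divergence is scaled by the number of runs so the statistic is
    asymptotically chi-square with m - 1 degrees of freedom.
    """
    q = dist.q_geom
    qs = q.sum()
    if qs <= 0:
        raise ValueError("degenerate geometric model (T_ii >= 1)")
    q = q / qs
    mask = dist.p_emp > 0
    g = 2.0 * dist.n_runs * float(
        np.sum(dist.p_emp[mask] * np.log(dist.p_emp[mask] / q[mask])))
    return _finish("geometric", g, max(dist.m - 1, 1), state=dist.state)


def test_geometric_lifetimes(seq: LabelSequence) -> list[GTestResult]:
    """Per-state geometric lifetime tests, for every state present in ``seq``.

    A state with fewer than two runs cannot be tested and raises.
    """
    present = np.flatnonzero(np.bincount(seq.labels, minlength=seq.n_s))
    results = []
    for state in present:
        dist = lifetime_distribution(seq, int(state))
        if dist.n_runs < 2:
            raise ValueError(f"state {state} has fewer than 2 runs")
        results.append(geometric_lifetime_gtest(dist))
    return results


# ---------------------------------------------------------------------------
# stationarity and symmetry
# ---------------------------------------------------------------------------

def test_stationarity(seq: LabelSequence, block_len: int) -> GTestResult:
    """Conditional homogeneity of T across non-overlapping blocks.

    The sequence is cut into r = floor(n / L) blocks (remainder discarded)
    and, per source state, the block-by-target transition table is tested
    for independence: expected counts are the block's source count times
    the pooled transition probability.  dof = (r - 1)(n_s - 1) n_s.
    """
    if block_len < 2:
        raise ValueError("block_len must be >= 2")
    ns = seq.n_s
    r = seq.n // block_len
    if r < 2:
        raise ValueError("need at least 2 blocks")
    f = np.zeros((r, ns, ns))
    for b in range(r):
        xb = seq.labels[b * block_len:(b + 1) * block_len]
        f[b] = np.bincount(ns * xb[:-1] + xb[1:], minlength=ns * ns).reshape(ns, ns)
    pooled = f.sum(axis=0)                 # f_ij over all blocks
    src_block = f.sum(axis=2)              # (r, ns): source counts per block
    src_total = pooled.sum(axis=1)         # f_i over all blocks
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = (src_block[:, :, None] * pooled[None, :, :]
                    / np.where(src_total, src_total, 1)[None, :, None])
    dof = (r - 1) * (ns - 1) * ns
    return _finish("stationarity", _g_sum(f, expected), dof)


def test_symmetry(seq: LabelSequence) -> GTestResult:
    """Are transitions i->j and j->i equally frequent?

    G4 = 2 sum_{i != j} f_ij log(2 f_ij / (f_ij + f_ji));
    dof = n_s (n_s - 1) / 2.
    """
    ns = seq.n_s
    f = _window_counts(seq.labels, ns, 2).astype(float)
    off = ~np.eye(ns, dtype=bool)
    mask = off & (f > 0)
    fij = f[mask]
    fsym = (f + f.T)[mask]
    g = float(2.0 * np.sum(fij * np.log(2.0 * fij / fsym)))
    return _finish("symmetry", g, ns * (ns - 1) // 2)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def results_to_frame(results: list[GTestResult]) -> pd.DataFrame:
    """One row per test: name, state (if per-state), statistic, dof, p."""
    return pd.DataFrame(
        [{"name": res.name, "state": res.state, "statistic": res.statistic,
          "dof": res.dof, "p": res.p} for res in results]
    )
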