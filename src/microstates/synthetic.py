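"""Synthetic EEG and label-process generation.

Emulates the structure of resting-state EEG that the microstate pipeline
assumes: a hidden label process switching between a few spatial
topographies, carried by amplitude-modulated alpha-band (8-12 Hz)
oscillations, plus white spatial noise at a controlled SNR.  Everything is
deterministic given a seed, so full pipelines can be exercised end-to-end
without any recorded EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import MicrostateMaps
from .eeg_io import EEGRecord, ElectrodeLayout
from .markov_stats import LabelSequence
from .surrogates import SurrogateSpec, synthesize_markov_chain

__all__ = [
    "LabelProcessSpec",
    "SyntheticEEGSpec",
    "synthetic_layout",
    "synth_maps",
    "synth_labels",
    "synth_eeg",
]

_MODES = ("markov", "semi_markov", "higher_order", "periodic")


@dataclass
class LabelProcessSpec:
    """Parameters of a hidden label process.

    mode "markov": first-order chain from (pi, T).
    mode "semi_markov": embedded state sequence from T (diagonal ignored),
        run lengths from ``lifetime`` = ("fixed", k) or ("poisson", mu)
        (poisson shifted by one so lifetimes are >= 1).
    mode "higher_order": sampled from ``tables``[i, j] = P(next | prev2=i, prev=j).
    mode "periodic": ``cycle`` repeated with ``dwell`` samples per state.
    """

    mode: str
    n_states: int
    T: np.ndarray | None = None
    pi: np.ndarray | None = None
    lifetime: tuple | None = None
    tables: np.ndarray | None = None
    cycle: tuple | None = None
    dwell: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode in ("markov", "semi_markov") and self.T is None:
            raise ValueError(f"mode {self.mode!r} requires T")
        if self.mode == "higher_order" and self.tables is None:
            raise ValueError("mode 'higher_order' requires conditional tables")
        if self.mode == "periodic":
            if not self.cycle:
                raise ValueError("mode 'periodic' requires a cycle")
            if self.dwell < 1:
                raise ValueError("dwell must be >= 1")
        if self.mode == "semi_markov" and self.lifetime is None:
            raise ValueError("mode 'semi_markov' requires a lifetime law")


@dataclass
class SyntheticEEGSpec:
    """Ground truth for a synthetic EEG record.

    ``snr`` is the ratio of map-signal variance to noise variance over the
    whole record; ``carrier_band`` locates the amplitude-modulated
    oscillation (defaults to the alpha band).
    """

    maps: MicrostateMaps
    labels: LabelSequence
    fs: float = 250.0
    carrier_band: tuple[float, float] = (8.0, 12.0)
    snr: float = 5.0
    amplitude_uv: float = 15.0
    amplitude_floor: float = 0.3
    """Minimum topography amplitude relative to the carrier peak.  Real GFP
    never decays to zero (broadband background activity persists between
    alpha bursts), so the map signal keeps a positive floor; a floor of 0
    would make labels unrecoverable in principle at carrier zero-crossings."""
    seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not 0 <= self.amplitude_floor < 1:
            raise ValueError("amplitude_floor must be in [0, 1)")


def synthetic_layout(n_ch: int = 30, prefix: str = "E") -> ElectrodeLayout:
    """Deterministic cap-like layout: a Fibonacci grid on the upper hemisphere.

    Convention: x to the right, y to the front, z up; unit head radius.
    """
    if n_ch < 2:
        raise ValueError("need at least 2 electrodes")
    i = np.arange(n_ch)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n_ch          # keep all points above the equator
    rad = np.sqrt(1 - z ** 2)
    theta = 2 * np.pi * i / golden
    entries = [(f"{prefix}{j + 1:02d}",
                float(rad[j] * np.cos(theta[j])),
                float(rad[j] * np.sin(theta[j])),
                float(z[j])) for j in range(n_ch)]
    return ElectrodeLayout(entries)


def synth_maps(layout: ElectrodeLayout, n_maps: int = 4,
               seed: int | None = None) -> MicrostateMaps:
    """Smooth, near-orthogonal random topographies over an electrode layout.

    White noise per electrode is smoothed with a spatial Gaussian kernel,
    the resulting fields are orthonormalized, then centered and rescaled to
    zero-mean unit-norm rows.  Pairwise |correlation| stays well below 0.5.
    """
    coords = layout.coordinates
    n_ch = coords.shape[0]
    if n_maps < 2 or n_maps > n_ch:
        raise ValueError("need 2 <= n_maps <= n_ch")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    sigma = np.median(d[d > 0])
    kernel = np.exp(-(d ** 2) / (2 * sigma ** 2))
    rng = np.random.default_rng(seed)
    fields = kernel @ rng.standard_normal((n_ch, n_maps))
    fields -= fields.mean(axis=0, keepdims=True)   # common-average reference
    q, _ = np.linalg.qr(fields)                    # orthonormal, still zero-mean
    return MicrostateMaps(q.T)


def _semi_markov(spec: LabelProcessSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    T = np.asarray(spec.T, dtype=float).copy()
    np.fill_diagonal(T, 0.0)
    T = T / T.sum(axis=1, keepdims=True)
    kind, param = spec.lifetime
    labels = np.empty(n, dtype=np.int64)
    state = int(rng.integers(spec.n_states))
    pos = 0
    while pos < n:
        if kind == "fixed":
            run = int(param)
        elif kind == "poisson":
            run = 1 + int(rng.poisson(param))
        else:
            raise ValueError(f"unknown lifetime law {kind!r}")
        labels[pos: pos + run] = state
        pos += run
        state = int(rng.choice(spec.n_states, p=T[state]))
    return labels[:n]


def _higher_order(spec: LabelProcessSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    tables = np.asarray(spec.tables, dtype=float)
    ns = spec.n_states
    if tables.shape != (ns, ns, ns):
        raise ValueError("tables must have shape (n_s, n_s, n_s)")
    if not np.allclose(tables.sum(axis=2), 1.0, atol=1e-9):
        raise ValueError("conditional tables must be row-stochastic")
    labels = np.empty(n, dtype=np.int64)
    labels[0] = rng.integers(ns)
    if n > 1:
        labels[1] = rng.integers(ns)
    for t in range(2, n):
        labels[t] = rng.choice(ns, p=tables[labels[t - 2], labels[t - 1]])
    return labels


def synth_labels(spec: LabelProcessSpec, n: int) -> LabelSequence:
    """Generate ``n`` labels from the process described by ``spec``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "markov":
        pi = spec.pi
        if pi is None:
            pi = np.full(spec.n_states, 1.0 / spec.n_states)
        return synthesize_markov_chain(
            SurrogateSpec(pi=pi, T=spec.T, n=n, seed=spec.seed))
    if spec.mode == "semi_markov":
        labels = _semi_markov(spec, n, rng)
    elif spec.mode == "higher_order":
        labels = _higher_order(spec, n, rng)
    else:  # periodic
        period = np.repeat(np.asarray(spec.cycle, dtype=np.int64), spec.dwell)
        reps = int(np.ceil(n / period.size))
        labels = np.tile(period, reps)[:n]
    return LabelSequence(labels=labels, n_s=spec.n_states)


def synth_eeg(spec: SyntheticEEGSpec) -> EEGRecord:
    """Render a label process as a multichannel EEG record.

    x_t = a_t * map_{label_t} + noise, with a_t a rectified sinusoid at the
    carrier-band center frequency under a slow random envelope, and white
    spatial noise scaled so that var(signal)/var(noise) equals ``spec.snr``.
    """
    labels = spec.labels.labels
    n_t = labels.size
    n_ch = spec.maps.n_ch
    rng = np.random.default_rng(spec.seed)

    f_c = 0.5 * (spec.carrier_band[0] + spec.carrier_band[1])
    t = np.arange(n_t) / spec.fs
    carrier = spec.amplitude_floor + \
        (1.0 - spec.amplitude_floor) * np.abs(np.sin(2 * np.pi * f_c * t))
    # slow random envelope: positive values interpolated at ~1 Hz nodes
    n_nodes = max(int(np.ceil(t[-1])) + 2, 2)
    nodes = 0.5 + rng.random(n_nodes)
    envelope = np.interp(t, np.arange(n_nodes), nodes)
    a = spec.amplitude_uv * carrier * envelope

    signal = a[:, None] * spec.maps.maps[labels]
    var_s = signal.var()
    if np.isfinite(spec.snr):
        noise = rng.standard_normal((n_t, n_ch)) * np.sqrt(var_s / spec.snr)
    else:
        noise = 0.0
    names = [f"E{j + 1:02d}" for j in range(n_ch)]
    return EEGRecord(data=signal + noise, fs=spec.fs, channel_names=names)
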