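"""Polarity-invariant (modified) K-means microstate segmentation.

A microstate map is a normalized scalp topography.  Modified K-means differs
from vanilla K-means in two respects: similarity between a sample and a
cluster is the *squared* spatial correlation, so a topography and its
mirror-polarity twin belong to the same state, and each cluster is
represented by the first principal component of its member topographies
rather than their mean.

Clustering runs on the topographies at GFP peaks only; the full-length
label sequence is then obtained by competitively back-fitting the maps
into every EEG sample.  Among ``n_runs`` random restarts, the run with the
lowest electrode-corrected residual variance (CV criterion) wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import EEGRecord, ElectrodeLayout
from .preprocessing import average_reference, gfp, find_gfp_peaks

__all__ = [
    "MicrostateMaps",
    "KMeansConfig",
    "SegmentationResult",
    "modified_kmeans",
    "backfit_labels",
    "global_explained_variance",
    "cv_criterion",
    "reorder_maps",
    "match_maps",
    "canonical_templates",
]


@dataclass
class MicrostateMaps:
    """Microstate topographies, one per row, zero-mean and unit-norm."""

    maps: np.ndarray  # (n_maps, n_ch)

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError("maps must be a (n_maps >= 2, n_ch) array")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm map")
        m = m - m.mean(axis=1, keepdims=True)
        self.maps = m / np.linalg.norm(m, axis=1, keepdims=True)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_ch(self) -> int:
        return self.maps.shape[1]


@dataclass
class KMeansConfig:
    n_maps: int = 4
    n_runs: int = 10
    maxerr: float = 1e-6
    maxiter: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_maps < 2:
            raise ValueError("n_maps must be >= 2")
        if self.n_runs < 1 or self.maxiter < 1:
            raise ValueError("n_runs and maxiter must be >= 1")
        if not self.maxerr > 0:
            raise ValueError("maxerr must be positive")


@dataclass
class SegmentationResult:
    """Output of :func:`modified_kmeans`.

    ``gev`` holds the global explained variance per map; its sum is the
    total GEV of the segmentation.  ``cv`` is the minimum CV criterion over
    runs, ``seed`` the seed that makes the result reproducible.
    """

    maps: MicrostateMaps
    labels: np.ndarray
    gfp_peaks: np.ndarray
    gev: np.ndarray
    cv: float
    seed: int | None = field(default=None)

    @property
    def total_gev(self) -> float:
        return float(np.sum(self.gev))


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return x / norms


def _principal_map(v: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of sum of outer products of the rows of ``v``."""
    s = v.T @ v
    _, vecs = np.linalg.eigh(s)
    return vecs[:, -1]


def modified_kmeans(record: EEGRecord, cfg: KMeansConfig | None = None) -> SegmentationResult:
    """Segment an EEG record into microstates.

    The average-referenced topographies at the GFP peaks are clustered by
    polarity-invariant K-means with ``cfg.n_runs`` random restarts; the run
    minimizing the CV criterion is kept and its maps are back-fitted into
    every time sample.
    """
    cfg = cfg or KMeansConfig()
    x = average_reference(record.data)
    n_t, n_ch = x.shape
    if n_ch <= cfg.n_maps + 1:
        raise ValueError("need n_ch > n_maps + 1 for the CV criterion")

    g = gfp(x)
    peaks = find_gfp_peaks(g)
    if len(peaks) < cfg.n_maps:
        raise ValueError(
            f"only {len(peaks)} GFP peaks for {cfg.n_maps} maps")

    xp = x[peaks]                      # raw peak topographies (zero-mean rows)
    v = _normalize_rows(xp)            # unit-norm versions used for clustering
    sum_sq = float(np.sum(xp ** 2))

    rng = np.random.default_rng(cfg.seed)
    best_cv = np.inf
    best_maps = None

    for _ in range(cfg.n_runs):
        idx = rng.choice(len(peaks), size=cfg.n_maps, replace=False)
        maps = v[idx].copy()
        ev_prev = 0.0
        for _ in range(cfg.maxiter):
            c = v @ maps.T
            assign = np.argmax(c * c, axis=1)
            for k in range(cfg.n_maps):
                members = v[assign == k]
                if len(members) == 0:
                    # dead cluster: reseed from a random peak topography
                    maps[k] = v[rng.integers(len(v))]
                else:
                    maps[k] = _principal_map(members)
            c = v @ maps.T
            ev = float(np.mean(np.max(c * c, axis=1)))
            if abs(ev - ev_prev) / max(ev, 1e-12) < cfg.maxerr:
                break
            ev_prev = ev

        # residual variance of the polarity-invariant fit, over peak samples
        c_raw = xp @ maps.T
        assign = np.argmax(c_raw * c_raw, axis=1)
        fitted = c_raw[np.arange(len(xp)), assign] ** 2
        sigma2 = (sum_sq - float(np.sum(fitted))) / (len(xp) * (n_ch - 1))
        cv = cv_criterion(sigma2, n_ch, cfg.n_maps)
        if cv < best_cv:
            best_cv = cv
            best_maps = maps.copy()

    result_maps = MicrostateMaps(best_maps)
    labels = backfit_labels(result_maps, x)
    gev = global_explained_variance(result_maps, x, labels)
    return SegmentationResult(maps=result_maps, labels=labels, gfp_peaks=peaks,
                              gev=gev, cv=best_cv, seed=cfg.seed)


def backfit_labels(maps: MicrostateMaps, data: np.ndarray) -> np.ndarray:
    """Competitive assignment: label of the map with maximal squared correlation.

    Polarity is ignored (squared correlation); ties resolve to the lowest
    map index.  Data are average-referenced before fitting.
    """
    x = average_reference(np.asarray(data, dtype=float))
    if x.shape[1] != maps.n_ch:
        raise ValueError("data and maps disagree on channel count")
    c = x @ maps.maps.T
    # maps are unit-norm & zero-mean, so argmax of (x.a)^2 == argmax corr^2
    return np.argmax(c * c, axis=1)


def global_explained_variance(maps: MicrostateMaps, data: np.ndarray,
                              labels: np.ndarray) -> np.ndarray:
    """GFP-weighted fraction of variance each map explains.

    gev[k] = sum over samples labelled k of GFP_t^2 * corr^2(x_t, map_k),
    normalized by the total sum of GFP_t^2.
    """
    x = average_reference(np.asarray(data, dtype=float))
    labels = np.asarray(labels)
    if x.shape[0] != labels.shape[0] or x.shape[1] != maps.n_ch:
        raise ValueError("inconsistent shapes")
    g = gfp(x)
    denom = float(np.sum(g ** 2))
    if denom == 0:
        raise ValueError("zero total GFP")
    n_ch = x.shape[1]
    # gfp_t^2 * corr^2 = (x_t . a)^2 / n_ch  because |x_t|^2 = n_ch gfp_t^2
    dots = np.einsum("tc,tc->t", x, maps.maps[labels])
    contrib = dots ** 2 / n_ch
    gev = np.zeros(maps.n_maps)
    np.add.at(gev, labels, contrib)
    return gev / denom


def cv_criterion(residual_variance: float, n_ch: int, n_maps: int) -> float:
    """Electrode-corrected residual variance used to rank K-means runs.

    CV = sigma^2 * ((n_ch - 1) / (n_ch - 1 - n_maps))^2.  Requires
    n_ch > n_maps + 1 so the penalty factor is finite and > 1.
    """
    if n_ch <= n_maps + 1:
        raise ValueError("CV criterion requires n_ch > n_maps + 1")
    return float(residual_variance) * ((n_ch - 1) / (n_ch - 1 - n_maps)) ** 2


def reorder_maps(result: SegmentationResult, permutation) -> SegmentationResult:
    """Relabel a segmentation: new map ``i`` is old map ``permutation[i]``.

    Labels and per-map GEV are permuted consistently, so back-fitting the
    reordered maps reproduces the permuted labels.
    """
    perm = np.asarray(permutation, dtype=int)
    n = result.maps.n_maps
    if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
        raise ValueError("permutation must be a bijection on 0..n_maps-1")
    inverse = np.empty(n, dtype=int)
    inverse[perm] = np.arange(n)
    return SegmentationResult(
        maps=MicrostateMaps(result.maps.maps[perm]),
        labels=inverse[result.labels],
        gfp_peaks=result.gfp_peaks,
        gev=result.gev[perm],
        cv=result.cv,
        seed=result.seed,
    )


def match_maps(maps: MicrostateMaps, templates: MicrostateMaps) -> np.ndarray:
    """Greedy permutation aligning ``maps`` to ``templates`` by max |correlation|.

    Returns ``perm`` such that ``reorder_maps(result, perm)`` puts the map
    most similar to template 0 first, and so on.  Greedy: the globally best
    (template, map) pair is fixed first, then the next best among the rest.
    """
    if maps.n_maps != templates.n_maps or maps.n_ch != templates.n_ch:
        raise ValueError("maps and templates must agree in shape")
    corr = np.abs(templates.maps @ maps.maps.T)
    n = maps.n_maps
    perm = np.full(n, -1, dtype=int)
    free_t, free_m = set(range(n)), set(range(n))
    for _ in range(n):
        t_best, m_best, c_best = -1, -1, -1.0
        for t in free_t:
            for m in free_m:
                if corr[t, m] > c_best:
                    t_best, m_best, c_best = t, m, corr[t, m]
        perm[t_best] = m_best
        free_t.discard(t_best)
        free_m.discard(m_best)
    return perm


def canonical_templates(layout: ElectrodeLayout) -> MicrostateMaps:
    """Synthetic idealized templates for the canonical A-D map geometry.

    These are *synthetic* stand-ins constructed from the electrode
    coordinates, not empirical group-average maps: A and B are the two
    diagonal dipolar patterns, C has an anterior-posterior axis, and D is a
    radial (circular) pattern.  They order maps consistently across runs;
    they are not meant for quantitative comparison with normative data.

    Coordinate convention: x to the right, y to the front, z up.
    """
    xyz = layout.coordinates
    x, y = xyz[:, 0], xyz[:, 1]
    sx = x / max(np.abs(x).max(), 1e-12)
    sy = y / max(np.abs(y).max(), 1e-12)
    a = sy - sx          # left-frontal vs right-occipital diagonal
    b = sy + sx          # right-frontal vs left-occipital diagonal
    c = sy               # anterior-posterior
    d = -(sx ** 2 + sy ** 2)  # central/circular
    return MicrostateMaps(np.vstack([a, b, c, d]))
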