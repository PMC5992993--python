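# microstates

EEG microstate segmentation and information-theoretical analysis of the
resulting label sequences.

Resting-state EEG can be compressed into a sequence of *microstates*: a small
set of quasi-stable scalp potential topographies (conventionally labelled
A–D) such that, at every time sample, the data is represented by the label of
the most similar map. This package implements the full pipeline for
continuous resting-state recordings:

1. **I/O** — a basic EDF/EDF+C reader and writer, and electrode coordinate
   (`label x y z`) files.
2. **Preprocessing** — zero-phase Butterworth band-pass, common average
   reference, global field power (GFP) and its local maxima.
3. **Segmentation** — modified (polarity-invariant) K-means on the
   topographies at GFP peaks: samples are assigned by maximal *squared*
   spatial correlation, each cluster is represented by the first principal
   component of its members, the best of `n_runs` restarts is chosen by the
   electrode-corrected residual variance CV = σ̂²·((n_ch−1)/(n_ch−1−n_maps))²,
   and the maps are back-fitted competitively into every sample to produce
   the label sequence. Global explained variance (GEV) is reported per map.
4. **Sequence statistics** — symbol distribution p_i = f_i/n, Shannon
   entropy H = −Σ p_i log p_i (nats), transition matrix T, and a battery of
   likelihood-ratio G-tests, each asymptotically χ²: Markov order 0, 1 and 2,
   per-state geometric lifetime tests, stationarity of T across blocks, and
   symmetry of T.
5. **Surrogates** — first-order Markov chains matching the empirical (π, T),
   sampled by inverse-CDF partitioning of the unit interval.
6. **Autoinformation** — the time-lagged mutual information
   I(k) = H(X_{t+k}) − H(X_{t+k}|X_t), its closed form for a Markov chain
   Î(k) = H(π) + Σ_i π_i Σ_j (T^k)_ij log (T^k)_ij (via diagonalization of
   T), and pointwise confidence bands from Markov surrogate ensembles.
   Oscillatory peaks of I(k) that escape the band reveal non-Markovian
   memory, e.g. periodicities tied to the alpha rhythm.
7. **Synthetic data** — generators for smooth topographies, hidden label
   processes (Markov, semi-Markov, higher-order, periodic) and full
   amplitude-modulated alpha-band EEG at controlled SNR, so every stage is
   testable end-to-end without recorded EEG.

The intended audience is EEG researchers analyzing resting-state recordings
who want the microstate transform *and* statistics beyond the one-step
transition matrix: tests of Markovianity, stationarity and symmetry, and the
autoinformation function as the categorical analogue of the autocorrelation
function.

## Worked example

```python
import numpy as np
from microstates import *

# 1. synthesize a 60 s, 30-channel resting-state-like record, save as EDF
layout = synthetic_layout(30)
truth  = synth_maps(layout, n_maps=4, seed=1)
T = np.full((4, 4), 0.1 / 3); np.fill_diagonal(T, 0.9)   # 40 ms mean dwell
labels = synth_labels(LabelProcessSpec(mode="markov", n_states=4, T=T, seed=2), 15_000)
write_edf(synth_eeg(SyntheticEEGSpec(maps=truth, labels=labels, snr=5.0, seed=3)), "demo.edf")

# 2. read, band-pass, segment
record = bandpass_filter(read_edf("demo.edf"), 1.0, 35.0)
seg = modified_kmeans(record, KMeansConfig(n_maps=4, seed=4))

# 3. information-theoretical analysis of the label sequence
seq = LabelSequence(seg.labels, n_s=4, fs=record.fs)
p = symbol_distribution(seq)

# 4. autoinformation with a 10-surrogate Markov band
aif = surrogate_confidence_band(seq, k_max=50, n_surr=10, alpha=0.01, seed=5)
```

Output:

```
GFP peaks/s : 29.18
total GEV   : 0.82   CV: 0.714
p           : [0.255 0.245 0.253 0.247]
H = 1.39 nats (max 1.39)
Markov-0 p  : 0
Markov-1 p  : 2.53e-36
symmetry p  : 0.917
AIF lags outside Markov band: 30/50
```

Reading the numbers: the four recovered maps explain 82% of the GFP-weighted
variance; the labels cover the four states almost uniformly, so the entropy
reaches its maximum log 4 ≈ 1.39 nats. The Markov-0 test rejects (successive
labels are strongly dependent — states persist), and although the *hidden*
process generating the data is first-order Markov, the back-fitted sequence
also rejects Markov-1: the amplitude modulation of the alpha-band carrier
imprints extra temporal structure on the labels, which is exactly what the
autoinformation function makes visible as lags escaping the Markov surrogate
band. The symmetry test accepts, matching the symmetric generating matrix.

## Command line

```sh
microstates -d /data/eeg_study --outdir reports -m 10 --seed 7
```

processes every `.edf` in the directory (`-i FILE` for a single file,
`-f LIST` for a row-wise file list) and writes, per file, `maps.csv`,
`labels.csv`, `tests.csv`/`tests.json`, `aif.csv` and `metadata.json`, plus a
batch summary with Benjamini–Hochberg adjusted q-values. `-m` sets the number
of Markov surrogates for the AIF confidence band.

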