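# Methods

This note documents the models and procedures implemented in `microstates`,
the numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Microstate segmentation

**Model.** At each time sample the average-referenced scalp potential
x_t ∈ R^{n_ch} is approximated by a scaled copy of one of n_maps unit-norm,
zero-mean topographies a_k. Polarity is deliberately ignored: similarity is
the *squared* spatial correlation, so a topography and its sign-flipped twin
are the same state. This is the defining difference between modified K-means
and vanilla K-means, together with the cluster representative being the
first principal component (dominant eigenvector of Σ x x^T over members)
instead of the mean.

**Procedure.** Clustering uses only the topographies at GFP peaks, where
topographic SNR is highest; the full-length label sequence is then produced
by competitively back-fitting the final maps into *every* sample. Each of
`n_runs` (default 10) restarts initializes the maps from distinct GFP-peak
topographies chosen uniformly at random; iterations alternate assignment
(argmax squared correlation) and principal-component updates until the
relative change of explained variance falls below `maxerr` (default 1e−6) or
`maxiter` (default 500) is reached. The winning run minimizes the
electrode-corrected residual variance

    CV = σ̂² · ((n_ch − 1) / (n_ch − 1 − n_maps))²,

where σ̂² is the mean residual variance of the polarity-invariant fit over
the peak topographies (per-peak residuals; the estimator requires
n_ch > n_maps + 1). Per-map global explained variance is

    gev_k = Σ_{t: L_t = k} GFP_t² corr²(x_t, a_k) / Σ_t GFP_t².

**Numerical choices.**
- Peak topographies are normalized to unit norm before clustering; with a
  polarity- and scale-invariant similarity this only removes amplitude
  weighting *within* the peak set, and keeps the eigenvector update a pure
  orientation statistic.
- Dead clusters (no members after an assignment step) are reseeded from a
  random peak topography.
- Assignment ties resolve to the lowest map index; plateau GFP maxima count
  once at their first sample; series endpoints are never peaks.
- Fixed seed ⇒ bit-identical results; the seed is stored in the result.
- No temporal smoothing or minimum-duration constraint is applied to the
  label sequence.

**Canonical ordering.** K-means returns maps in random order. For batch use
the package relabels non-interactively: either with a user-supplied
permutation (`reorder_maps`) or by greedy |correlation| matching
(`match_maps`) against `canonical_templates(layout)` — *synthetic* idealized
A–D patterns (two diagonal dipoles, an anterior–posterior gradient, a radial
map) built from the electrode coordinates. These templates fix an ordering
convention; they are not normative group-average maps and should not be used
for quantitative comparisons with published template sets.

## Filtering and GFP

The band-pass is a 4th-order Butterworth applied forward–backward
(zero-phase), so GFP-peak timing is not shifted; only the pass band is a
free parameter (CLI default 1–40 Hz). GFP is the population standard
deviation across channels (divisor n_ch) after average referencing.

## G-test battery

All tests are likelihood-ratio statistics G = 2 Σ f log(f/e) over transition
count tables, with natural logarithms; empty cells contribute zero
(x log x → 0), and p-values are χ² upper tails at the stated degrees of
freedom with no small-sample correction. Marginals are always taken over the
same windows as the numerator counts (n−1 pairs, n−2 triplets, …), which
keeps each table internally consistent.

| test | null hypothesis | dof |
|---|---|---|
| Markov-0 | X_{t+1} independent of X_t | (n_s−1)² |
| Markov-1 | P(X_{t+1}\|X_t, X_{t−1}) = P(X_{t+1}\|X_t) | n_s(n_s−1)² |
| geometric | run lengths of state i geometric with T_ii | m−1 per state |
| Markov-2 | one further past step adds nothing | n_s²(n_s−1)² |
| stationarity | T identical across r blocks of length L | (r−1)(n_s−1)n_s |
| symmetry | f_ij and f_ji exchangeable | n_s(n_s−1)/2 |

Design notes:

- The divergence inside each G statistic is the standard non-negative
  Kullback–Leibler form.
- The geometric test compares the empirical run-length distribution of each
  state against the geometric law q_i(k) = (1 − T_ii) T_ii^{k−1}. The model
  is renormalized over the observed support 1..m (m = longest observed run),
  avoiding zero expected mass in the truncated tail, and the divergence is
  scaled by the number of runs R_i so the statistic is asymptotically
  χ²(m−1). This scaling is a design choice of this package, validated by
  the calibration suite: on first-order chains (n = 10⁵, 500 replicates)
  its rejection rate at α = 0.01 sits inside the exact binomial 99%
  interval, as do those of the Markov-1/2 and stationarity tests.
- Stationarity follows the conditional-homogeneity form: per source state, a
  blocks × targets table is tested for independence (expected counts =
  per-block source count × pooled transition probability); the trailing
  n mod L samples are discarded.
- Rows of T for states never observed as a transition source are set uniform
  and flagged, rather than left undefined.
- Individual tests carry no multiple-testing correction; the CLI's batch
  summary adds Benjamini–Hochberg q-values across all tests of a run.

## Markov surrogates

A surrogate is generated state by state via inverse-CDF sampling: a uniform
draw r selects index j with Σ_{i<j} p_i ≤ r < Σ_{i≤j} p_i, first from the
initial distribution π, then from the current state's row of T. π is taken
as the *empirical* symbol distribution of the source sequence, not the
eigen-stationary distribution of T; the difference is O(1/n). One uniform
draw is consumed per emitted state, and a given seed reproduces the sequence
bitwise. Floating-point cumulative sums can leave the last partition
boundary marginally below 1; draws beyond it clamp to the last state.

## Autoinformation function

The empirical AIF is the plug-in estimate from the joint histogram of
(X_t, X_{t+k}) over the n−k overlapping pairs; I(0) is the sequence entropy.
No bias correction is applied; the plug-in bias is of order (n_s−1)²/(2n)
per lag, which the tests use as the natural error scale. The Markov closed
form computes T^k by eigendecomposition (complex arithmetic, real part
taken, imaginary residue required < 1e−10, reconstruction verified against
T itself); defective or numerically unstable cases fall back to iterated
multiplication. Both routes agree to 1e−10 for k ≤ 50 in the test suite.

The surrogate confidence band is pointwise. With n_surr ≤ 1/α the empirical
(α/2, 1−α/2) quantiles are unsupported, so the band is the min–max envelope
of the ensemble (the conventional 10 surrogates at α = 0.01 fall in this
regime, and a min–max band of 10 i.i.d. draws is escaped by a lag of a true
Markov sequence with probability ≈ 2/11); larger ensembles use empirical
quantiles.

## Synthetic data generator

The generator emulates the features of resting-state EEG that the pipeline
relies on: a hidden categorical process (first-order Markov, semi-Markov
with non-geometric lifetimes, explicit second-order tables, or periodic),
per-state smooth spatial topographies, an amplitude-modulated alpha-band
(8–12 Hz) carrier, and white spatial noise at a controlled SNR (signal
variance / noise variance over the whole record).

Choices and defaults:

- Topographies: spatially smoothed Gaussian fields over the electrode
  layout, common-average referenced and orthonormalized — mutually exactly
  orthogonal, which makes recovery scoring unambiguous.
- Amplitude: a_t = A·(floor + (1−floor)·|sin 2πf_c t|)·env_t with carrier
  f_c the band centre (10 Hz), a slow random envelope (≈1 Hz nodes,
  0.5–1.5×) and a relative amplitude floor of 0.3. The floor reflects that
  real GFP never decays to zero between alpha bursts (broadband background
  persists); with a floor of 0 the label would be unrecoverable *in
  principle* at carrier zero-crossings, and no segmentation method could
  close the loop on the generating transition matrix.
- Default SNR 5, sampling rate 250 Hz, 30-channel hemispheric layout,
  4 maps; the full-pipeline closure fixture uses a transition matrix with
  diagonal 0.9 (mean dwell 40 ms at 250 Hz, within the realistic microstate
  lifetime range).
- Noise is spatially and temporally white. Real EEG noise is spatially
  correlated and 1/f-colored; passing the closure tests therefore
  demonstrates correctness of the algorithms, not expected performance on
  recorded EEG, where GEV and map recovery will be lower and the G-tests
  typically reject their nulls.

## Problem sizes used in verification

The calibration suite uses 500 replicates of length-10⁵ chains (rejection
rates at α = 0.01 compared against exact binomial 99% intervals); estimator
consistency uses single 10⁶-sample chains (surrogate T within 0.01 max-abs;
empirical vs analytic AIF within 2×10⁻³ nats for lags ≤ 50); segmentation
recovery uses 12 000-sample records at SNR 5. These sizes give stable
statistics while keeping the whole verification run in the minutes range.

## Known limitations

- EDF support covers plain EDF and continuous EDF+C with one shared sampling
  rate; BDF (24-bit), discontinuous EDF+D and annotation *parsing* (beyond
  dropping annotation channels) are out of scope.
- The CV criterion assumes n_ch > n_maps + 1 and is not meaningful for
  high-density montages without spatial downsampling, which is not
  implemented.
- Only the modified K-means family is provided (no AAHC, no probabilistic
  clustering) and only single-record segmentation (no multi-subject map
  aggregation).
- The geometric test's χ²(m−1) reference ignores the estimation of T_ii;
  the calibration results show the effect is mildly conservative at the
  studied sizes.
- ERP-style epoching/averaging and plotting are not included.
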