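# Methods

This note documents the models, estimators, defaults and known
limitations of the package, stage by stage.

## Generative model and its assumptions

The observable is the heartbeat-interval series `x(t)` indexed by beat
number. The model assumes a bank of `M` FIR filters `h_i` of length at
most `N` beats, each excited within an `N`-beat observation window by a
single Dirac impulse of unknown amplitude `s_i` and arrival time `t_i`:
`x = Σ_i s_i h_i(t − t_i)`. Three assumptions make the filters
identifiable from windows of `x` alone:

1. **Sparsity/heavy tails** — impulse amplitudes are non-Gaussian
   (Laplace by default; the data only require "impulsive").
2. **Non-overlap** — within a window, distinct sources never fire at
   the same beat, which renders the filter outputs statistically
   independent.
3. **Stable arrival times** — each source keeps a characteristic
   arrival time across windows (optionally jittered). This is the
   condition under which the window ensemble is an *instantaneous*
   mixture with a constant mixing matrix, the regime in which
   fixed-point ICA provably separates the sources. With fully random
   per-window arrival times the problem becomes a union-of-shifts
   dictionary with many more atoms than components, and measured filter
   recovery collapses (fraction of filters recovered at |corr| > 0.9
   drops from 1.0 to ≈ 0.45 in our tests); the residual time-shift
   ambiguity of the stable-arrival design is absorbed by the
   shift-tolerant filter matching (±5 samples by default).

Impulses are placed early in the window (default delay range
`max(M−1, N/8)` samples) so filter supports are not truncated at the
window end; convolution is truncated linear, never circular.

## Frequency conventions

Beat-indexed signals use cycles/beat; the Nyquist limit is 0.5
cycles/beat. Numerically these behave exactly like Hz at 1 Hz sampling,
and the canonical band partition is VLF 0.00–0.03, LF 0.03–0.15, HF
0.15–0.5 cycles/beat. For decoding, beat-indexed filters are mapped to
seconds through the mean RR interval (default 1.0 s/beat, configurable)
and resampled band-limitedly; a spectral peak at `f` cycles/beat then
sits at `f/mean_RR` Hz.

## Preprocessing

- **Artifact correction** is a running-median rule: an interval is
  replaced by the local median (window 11 beats) when it deviates by
  more than 4 local robust scales. The robust scale is the scaled MAD
  floored at 5% of the local median; the floor keeps ordinary
  variability (< 20% of the interval level at the defaults) from being
  flagged in quiet stretches where the MAD collapses, while
  halved/doubled ectopic-like intervals (50–100% deviations) stay far
  above threshold. This is a deliberately simple, fully parameterized
  stand-in for adaptive ectopic correction; it reports its replacement
  count and never changes the series length.
- **Segmentation** takes non-overlapping `N = 256`-beat windows
  (remainder discarded) and removes each window's mean; the removed
  offsets are stored, so segmentation is lossless.
- **Whitening** eigendecomposes the window covariance. The default is
  full-dimension whitening: per-window centering confines the data to
  the `N−1`-dimensional zero-sum subspace, so the achievable rank is at
  most `N−1 = 255`, and the pipeline whitens at the full achievable
  rank before learning. Reducing dimension below the data rank is
  destructive here — cutting 256-dimensional band-structured windows to
  128 principal components before ICA collapses the learned filters to
  narrowband Fourier-like vectors (measured median bandwidth ≈ 0.003
  instead of ≈ 0.04 cycles/beat).

## Learning

Fixed-point ICA with parallel one-unit updates and symmetric
orthogonalization; contrast `g = tanh` (log-cosh) by default, `u³`
(kurtosis) as an option. Convergence is declared when
`max_i (1 − |⟨w_i, w_i_old⟩|) < 10⁻⁴` (default), with a 1000-iteration
budget; non-convergence raises an error carrying the per-iteration
deltas. Gaussian data — for which the model is unidentifiable — reaches
that error in dimensions ≥ 8; in very low dimensions finite-sample
fluctuations can create spurious fixed points, which is why the
unidentifiability test in the suite uses 8 dimensions. The decoding
bank is `A = V⁺Wᵀ` (dewhitening composed with the transposed orthogonal
unmixing); its columns are the impulse responses of the generative
reading and are reported unit-normalized unless the analysis needs the
native scales (the power-law stage does). Outputs are defined only up
to sign, scale and permutation; all comparisons go through the
Hungarian-assignment matcher with sign flips and bounded time shifts.

## Characterization

The filter PSD is the squared magnitude of the zero-padded FFT (pad
4096), giving a deterministic, resolution-controlled estimate. The −3 dB
bandwidth is the width of the contiguous half-power region around the
PSD maximum; `Q = f_c/BW`, `ζ = 1/(2Q)` hold as identities. The
envelope is the modulus of the analytic signal (Hilbert transform); its
width is the contiguous region of the squared envelope within 3 dB
(factor 10^(−3/10)) of its peak. A filter is *localized* when the
half-power region around the global peak holds ≥ 80% of all
above-half-maximum power; non-localized filters are excluded from
population summaries, mirroring the exclusion of filters whose power is
not concentrated in one peak. Time–frequency tiles come from a
short-time spectrogram of the analytic signal (window `N/8`, 75%
overlap) thresholded at 95% of its peak — a standard-spectrogram
substitute for the Cohen-class estimate sometimes used for such tiles;
only the tile extents are consumed downstream.

## Clustering

Gaussian mean shift in the raw `(f_c, BW)` plane (no standardization,
matching how the plane is usually drawn; a scaling switch exists). The
kernel bandwidth is the mean distance to the k-th nearest neighbor with
`k = round(√n)` by default — the original analysis used a KNN rule but
its `k` is not recoverable, so the standard heuristic is exposed as a
parameter. Modes within `0.5·bandwidth` are merged; ties in labeling
break to the nearest mode; the Gaussian-kernel iteration is a density
ascent, and the KDE value along every trajectory is tracked and
asserted non-decreasing.

## Gabor matching

Each filter is summarized by its best single Gabor atom. The search is
a coarse dictionary — `u` on a 4-beat grid, `s` log-spaced in `[2, N]`,
`f` on a 0.005 cycles/beat grid, phase solved in closed form per cell by
projecting onto the cosine/sine quadrature pair — refined by bounded
nonlinear least squares over all five parameters. If refinement fails
to improve the dictionary fit, the dictionary atom is returned flagged
unrefined. The correlation index is the absolute normalized inner
product on unit-normalized signals (sign- and scale-invariant).
Self-fits of generated atoms are exact to float precision; only the
single best atom is reported (no multi-atom decompositions).

## Power-law analysis

The population spectrum is the average of per-filter PSDs (each
normalized to unit total power unless native scales are requested). The
white-noise response convolves fresh Gaussian noise with every filter,
drops the leading transient, and Bartlett-averages Hann periodograms of
the steady-state segments over segments, filters and repetitions; by
the convolution theorem its expectation is the filter-average `|H(f)|²`.
The log-log slope is an OLS line through the means of `log₁₀ P` in 20
log-spaced bins of `[f_lo, f_hi]`, default 0.005–0.4 cycles/beat.
Frequencies below ~2/N are excluded from fits: the finite window
precludes reliable filter estimation at the low end (the same
time–frequency limitation that caps the frequency resolution near
1/N ≈ 0.004 cycles/beat at N = 256).

For power-law *recovery* studies the sub-band generator is run with
band width 0.025 (a finer tiling approximates a continuous `1/f^γ`
spectrum better than the 0.05 bias-test tiling) at N = 128, P = 2048,
64 learned units, with the response measured over 30 repetitions of
4096-sample noise and fitted over 0.01–0.4. Across disjoint seeds the
recovered slopes sit within ≈ 0.15 of `−γ` for γ ∈ {0.5, 1.0, 1.5}.

## Decoding and scoring

The best-filter search convolves the stimulus causally with every
(interpolated) filter, fits the least-squares scale
`a = ⟨y, ŷ⟩/⟨ŷ, ŷ⟩`, and picks the filter minimizing the squared error
(ties to the lowest index). SNR is `10·log₁₀(P_signal/P_residual)` over
270-second sliding windows (step 1 s; tail windows dropped) and over
the whole record; an exactly zero residual reports a documented 300 dB
cap instead of infinity. Percent accuracy uses the two-alternative
psychophysics law `100·Φ(√SNR_lin/√2)` implemented with the error
function — chance 50% at vanishing SNR, → 100% at high SNR, strictly
increasing — and the mapping is pluggable because the exact printed
arrangement of the accuracy formula in the source analysis is not
recoverable. Decoding with the *same* bank that generated a noiseless
target recovers the generating filter and scale essentially exactly;
decoding across banks inherits the arrival-time ambiguity of the
learned filters (no lag search is performed), which lowers reported
SNRs in the cross-bank pipeline demo.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure the analysis
assumes*: sparsity, band structure, non-overlap, VLF/LF/HF band powers,
band-limited flat-spectrum stimuli (flat to 0.5 Hz, Gaussian roll-off
reaching 1/10 amplitude ≈ 0.3 Hz past the corner), and responses at
controlled SNR around a rabbit-like 240 beats/min baseline. The
sub-band bias dataset uses order-2 Butterworth bandpass generators —
their passband edges are the −3 dB (half-power) points, so the
generator's half-power bandwidth equals the design value exactly — with
centers tiling the band contiguously (10 bands of width 0.05 across
0.01–0.5) and one Bernoulli–Laplace event per band per window on
average (`p = 1/N`), i.e. the generative model's own excitation regime.
Not emulated: baroreflex feedback loops, respiration mechanics beyond
HF band power, circadian nonstationarity, pathophysiological dynamics,
and any hemodynamics of the stimulated-nerve preparation. Passing tests
therefore demonstrate correctness of the estimators under the model's
assumptions, not physiological validity on real recordings.

## Numerical choices and degenerate inputs

- All generators and stochastic stages take explicit seeds; identical
  seeds give bit-identical outputs.
- Whitening uses `eigh` on the sample covariance with a relative rank
  threshold of 1e-10; requesting more components than the numerical
  rank raises an error naming the achievable rank.
- An all-zero filter cannot be characterized, normalized or fitted
  (explicit errors); a single-bin half-power region falls back to one
  grid-bin width rather than zero bandwidth.
- KNN bandwidth on duplicate-dominated points returns a floored value
  with a warning; mean-shift mode merging uses `0.5·bandwidth`.
- The SNR of an exactly-zero residual is capped (300 dB); a zero-signal
  window reports the negative cap.

## Problem sizes

Default study sizes are desk-scale by design: the bias test learns 128
filters from 4096 × 256-sample windows (seconds to a few minutes on one
CPU), identifiability uses M = 16, N = 64, P = 4000, and power-law
recovery uses N = 128, P = 2048 per exponent. The pipeline's simulate
stage defaults to 16 filters × 2000 windows of 256 beats.

## Known limitations

- The artifact filter is a surrogate with its own parameters, not a
  reproduction of any specific published adaptive method; counts of
  corrected beats are not comparable across methods.
- Filter recovery is only defined up to sign/scale/permutation and
  small time shifts; no attempt is made to resolve the arrival-time
  ambiguity, and cross-bank decoding SNR suffers accordingly.
- Filters below ~2/N cycles/beat are not identifiable from centered
  windows; generators used for recovery tests start at 2/N.
- No convolutive/frequency-domain ICA, no phase-response modeling, no
  DFA/wavelet scaling exponents — the analysis is intentionally limited
  to the instantaneous-mixture framing and spectral-slope measure.
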