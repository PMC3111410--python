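# cardiocode

Efficient-coding analysis of heartbeat intervals: learn a population of
FIR *decoding filters* from RR-interval windows, characterize the
population's time–frequency organization, and use it to decode
time-varying stimuli into heart-rate responses.

## The scientific problem

Beat-to-beat heart-period (RR-interval) fluctuations reflect the
sympathetic and parasympathetic messages arriving at the sinoatrial (SA)
node, traditionally summarized by three spectral bands (VLF 0.00–0.03,
LF 0.03–0.15, HF 0.15–0.5 cycles/beat). This package treats the interval
series as the output of a generative model in the spirit of efficient
(redundancy-reducing) population codes in sensory neuroscience: a bank
of `M` linear filters `h_i` excited by sparse, non-overlapping
neuroregulatory impulses `s_i δ(t − t_i)`,

```
x(t) = Σ_i  s_i · h_i(t − t_i),      t within a window of N beats
```

Because the impulses are sparse and non-overlapping, the filter outputs
are statistically independent, and the mixing can be framed as an
instantaneous ICA problem on the matrix of `N`-beat windows: whiten the
windows, run fixed-point ICA with symmetric orthogonalization

```
w⁺ = E{z g(wᵀz)} − E{g′(wᵀz)} w ,     W ← (WWᵀ)^(−1/2) W
```

(`g = tanh` for the log-cosh negentropy contrast), and read the decoding
filters off the columns of the mixing matrix `A = V⁺Wᵀ` in window
space. The package then:

- characterizes each filter (center frequency `f_c`, −3 dB bandwidth
  `BW`, quality factor `Q = f_c/BW`, damping ratio `ζ = 1/(2Q)`,
  Hilbert-envelope width, spectral-localization flag, 95%-energy
  time–frequency tile);
- clusters the population in the `(f_c, BW)` plane by Gaussian mean
  shift with a KNN-estimated kernel bandwidth (no preset cluster count);
- fits every filter with a Gabor atom
  `a·exp(−(t−u)²/2s²)·cos(2πf(t−u)+φ)` and reports the correlation
  index;
- verifies 1/f behavior: the binned log-log slope of the bank's average
  response to white noise;
- decodes a stimulus `u` against a measured heart-rate response `y` by
  choosing the filter and least-squares scale `a` minimizing
  `‖y − a·(u∗h_k)‖²`, scoring the fit by sliding-window SNR (dB) and an
  erf-based percent reconstruction accuracy.

A synthetic-data module generates every input the pipeline needs —
Dirac excitations, ground-truth Gabor banks, sub-band sparse ensembles,
RR-like series with VLF/LF/HF structure, and band-limited Gaussian
stimulus/response pairs — so the entire analysis is testable without any
data download. Real RR data (e.g. PhysioNet normal-sinus-rhythm interval
exports) can be supplied as plain-text interval lists.

## Worked example

Learn a 128-filter population from the sub-band sparse benchmark (sparse
heavy-tailed sources through 0.05-cycles/beat-wide bandpass generators
tiling 0.01–0.5), then characterize it:

```python
from cardiocode import (
    gen_subband_sparse_dataset, whiten, fastica,
    decoding_filters, characterize_bank,
)

ens = gen_subband_sparse_dataset(n_windows=2048, window_len=256, seed=0)
Z, wh = whiten(ens, n_components=255)        # full-rank whitening
um = fastica(Z, n_components=128, seed=1)
bank = decoding_filters(um, wh)
props = characterize_bank(bank)
print(f"median -3 dB bandwidth: {props['bandwidth_3db'].median():.4f} cycles/beat")
print(f"localized filters: {props['localized'].sum()}/{len(props)}")
print(f"median Q factor: {props['q_factor'].median():.2f}")
```

prints

```
median -3 dB bandwidth: 0.0347 cycles/beat
localized filters: 112/128
median Q factor: 6.80
```

The learned median bandwidth sits near the 0.05 cycles/beat design
bandwidth of the generators (the learned filters concentrate on the
higher-power center of each band, so the median lands slightly below the
nominal width), 112 of 128 filters are spectrally localized in a single
peak, and the population is strongly underdamped (median ζ ≈ 0.07) —
oscillatory, band-selective responses.

The same stages run from the shell:

```sh
cardiocode all --out runs/demo        # simulate → … → decode
cardiocode fixtures --out fixtures/tiny --seed 0
```

Each run directory contains delimited-text tables (`properties.tsv`,
`clusters.tsv`, `gabor_fits.tsv`, `powerlaw.tsv`, `decoding.tsv`), a
`config.yaml` echo and a `run.log`; identical configs reproduce
byte-identical tables.

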