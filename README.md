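# fiddec — FID signal deconvolution and noise factor analysis for 1D-NMR

`fiddec` cleans single free induction decays (FIDs) from one-dimensional
NMR. It is aimed at metabolomics / molecular-complexity work where
spectra of mixtures are accumulated in bulk and limited by noise: it
raises the signal-to-noise ratio (SNR) of a spectrum from one FID alone
(no repeated measurements, no hardware change), splits diffusion-edited
spectra into macromolecule and small-molecule signals by their T2\*
relaxation, and correlates SNR with acquisition parameters across whole
dataset collections to find the experimental factors that cost
sensitivity.

## The method

A measured FID is modelled as signal plus noise,

```
S(t) = S_signal(t) + S_noise(t),
```

where the signal is a sum of decaying oscillations, one per resonance
line — amplitude γ, frequency ω, effective transverse relaxation time
T2\* (Fourier transforming one line gives a Lorentzian of width
1/(πT2\*)):

```
γ · exp(i(ωt + φ)) · exp(−t/T2*).
```

The short-time Fourier transform (STFT)

```
STFT_S(τ, ω) = ∫ S(t) g(t − τ) exp(−iωt) dt
```

turns the FID into a time–frequency spectrogram whose rows (frequency
bins) decay at the rate of the resonance living there, while the noise
floor stays flat. After magnitude and log compression,

```
|z| = sqrt(Re² + Im²),     V = log10(|z| + 1),
```

the nonnegative matrix V (frequency × time segment) is factorized as

```
V = W·H + residuals = W_signal·H_signal + W_noise·H_noise + residuals
```

by probabilistic sparse matrix factorization (PSMF) — a variational
scheme with per-frequency-bin factor assignments, a frequency-flat
noise-floor basis and per-bin noise variances; plain NMF, sparse NMF
and probabilistic (ridge) NMF are provided for comparison. Components
are classified by the decay of their time coefficients: flat tail ⇒
noise; otherwise signal, ranked short/long T2\* in rank-3 mode. Each
component's reconstruction becomes a ratio mask on the original complex
spectrogram (phases untouched, components sum exactly to the original),
and inverse STFT by overlap-add plus a standard Fourier transform yield
component FIDs and spectra. The gain is summarized as

```
relative SNR = SNR_denoised / SNR_original,
```

whose square is the factor of acquisition time that signal averaging
would have needed for the same improvement.

The noise-factor analysis walks a directory tree of Bruker-style
datasets, harvests acquisition parameters (RG, NS, D1, SW, AT, TD, O1,
TE, BF1, GPZ, cryoprobe flag) from the JCAMP-DX `acqus` files, computes
a theoretical SNR index (∝ BF1^{3/2}·√NS), Pearson-correlates each
parameter with SNR, and exports the signed weighted correlation network
as GML.

## Worked example

```python
import numpy as np
from fiddec import preset, denoise

truth = preset("sucrose_like", seed=0)        # 33,280-point synthetic FID, 20 lines
result = denoise(truth.noisy_fid, window_size=1024, seed=0)

rep = result.snr_report
print(f"window: {result.provenance['window_percent']}% of the FID")
print(f"SNR {rep.snr_original:.1f} -> {rep.snr_denoised:.1f}"
      f" (relative SNR {rep.relative_snr:.2f})")
print(f"equivalent acquisition-time factor: {rep.time_equivalent_factor:.0f}")
```

prints

```
window: 3.1% of the FID
SNR 19.9 -> 543.9 (relative SNR 27.36)
equivalent acquisition-time factor: 749
```

The window is 1024 points, 3.1% of the FID. The weak original spectrum
(SNR ≈ 20) gains a factor ≈ 27 in SNR; reaching that by accumulating
scans would have taken ≈ 749 times the measurement time. On this
synthetic fixture the ground truth is known, and the denoised spectrum
correlates at 0.956 with the noise-free spectrum. `result` also carries
the component FIDs/spectra (`signal`, `noise`) and the classification
report (here the signal component's fitted decay constant is 0.59 s
against a true amplitude-weighted T2\* of 0.59 s).

The same pipeline at rank 3 (`separate_t2`, or `fiddec separate` on the
command line) splits a diffusion-edited-like FID into `noise`,
`short_t2` and `long_t2` components.

From a shell:

```bash
fiddec simulate --preset sucrose_like --seed 0 --out fid.txt
fiddec denoise fid.txt --window 1024 --seed 0 --out deconvolved/
fiddec harvest /path/to/datasets --out parameters.csv
fiddec network parameters.csv --target snr --threshold 0.2 --out net.gml
```

`denoise`/`separate` accept Bruker-style dataset directories (binary
`fid` + JCAMP-DX `acqus`, digital-filter group delay removed on read)
or the plain-text two-column FID format.

## Documentation

`docs/methods.md` describes the model, the defaults and their
rationale, what the synthetic fixtures do and do not emulate, and known
limitations.
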