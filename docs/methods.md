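# Methods

## Signal model

A quadrature-detected 1D-NMR free induction decay is modelled as a sum
of resonance lines plus additive noise:

```
S(t_k) = Σ_lines γ exp(i(2π f t_k + φ)) exp(−t_k / T2*) + ε_k,
t_k = k · dwell,
```

with independent Gaussian noise of standard deviation σ on the real and
imaginary channels (white and stationary — the simplest model
consistent with a thermal-noise floor; colored noise is not simulated).
Each line's Fourier transform is a Lorentzian of full width at half
maximum 1/(πT2\*). All randomness flows through numpy's PCG64
generator, so a seed fixes every dataset bit-for-bit across platforms.

## Short-time Fourier transform

The FID is cut into windowed segments of `window_size` points advanced
by `hop`; each segment's unnormalized FFT is one spectrogram column.
Design choices:

* **Window.** The instrument literature on this method does not fix a
  taper; the default is a Hann-family window in the half-sample-shifted
  periodic form `w[n] = sin²(π(n+½)/N)`. At 50% hop the shifted copies
  sum to exactly 1 (sin²+cos²), and `w > 0` everywhere, so the very
  first FID sample — the signal maximum — survives the inverse
  transform. Periodic Hamming and rectangular windows are selectable.
* **Boundary segments** (default on). Zero-padding on both sides gives
  every signal sample its full complement of overlapping windows. This
  matters only for *modified* spectrograms: after masking, the
  per-segment signals are no longer mutually consistent, and without
  full coverage the inverse transform divides leakage terms by a
  near-zero window tail at the signal edges, producing spurious spikes
  about 10⁵ times the signal amplitude. With `boundary=False` the
  first segment starts exactly at sample 0 (the configuration used
  when comparing against the brute-force DFT oracle).
* **Inverse transform.** Overlap-add of per-segment inverse FFTs
  divided by the overlap-added window (checked for constant overlap-add
  to 1e-10). For any unmodified spectrogram the round trip is exact to
  machine precision; the test suite asserts ≤ 1e-8 relative.
* **Pipeline hop** is `window_size/4` (the plain transform default is
  `window_size/2`): the decay is sampled four times per window, which
  sharpens component classification and the short/long-T2\* split, and
  the initial-segment reassignment then moves a quarter-window rather
  than half a window of noise back into the signal.

Magnitude and log compression follow the factorization's needs:
`V = log10(|z| + 1)` is nonnegative with zero mapping to zero. Before
compression the magnitudes are scaled so max |z| = 100 (two decades of
log range); raw spectrometer intensities of order 10⁶ would otherwise
saturate the compression. The scale is undone by the ratio masking.

## Matrix factorization

`V ≈ W·H` with rank 2 (denoise) or 3 (T2\* separation). Four variants:

* **NMF** — Lee–Seung multiplicative updates on the Frobenius
  objective; monotone non-increasing.
* **SNMF** — adds an L1 penalty `β Σ H` (default β = 0.1) shrinking the
  time coefficients; fit + penalty remains monotone.
* **PMF** — Gaussian likelihood with Gaussian priors on both factors
  (precision λ = 0.01), maximized a posteriori by multiplicative
  updates; the residual variance is re-estimated every iteration.
* **PSMF** (pipeline default) — variational EM over per-frequency-row
  binary factor assignments `s_nk ~ Bernoulli(π)` (π = 1/rank by
  default) with per-row noise variances ψ_n. Mean-field posteriors
  ρ_nk gate the basis (`W ← ρ∘W` on output); W rows are per-row least
  squares clipped at zero; H uses a variance-weighted multiplicative
  update with an assignment-uncertainty ridge. ψ is floored at
  1e-4·mean(V²) so rows that happen to be fit exactly cannot acquire
  unbounded weight. The **flat-noise constraint** (default on) ties
  the last component's basis to a single level shared by all frequency
  bins and keeps it active in every row: white quadrature noise has a
  frequency-flat magnitude floor, and without the constraint slowly
  decaying resonances — nearly flat over the record — are absorbed
  into the noise component and lost from the signal.

**Initialization.** The default is deterministic and structured: the
coefficient rows start as a ladder of exponential decays (time
constants log-spaced over the record; a single 0.15-of-record constant
at rank 2) plus one flat row, and the basis is the nonnegative
least-squares projection of V onto them. Seeded uniform-random init is
available (`init="random"`), but from a random start the multiplicative
and EM dynamics frequently converge to a tilted pair — a global decay
plus a *rising* compensator — whose "noise" coefficients grow with
time; the structured start reliably yields the decaying-signal /
flat-noise decomposition the classification contract expects. Both
inits are bit-reproducible for a fixed seed.

## Component classification and splitting

Diagnostics are computed on each component's linear-magnitude time
profile `Σ_f (10^(W[f,k]·H[k,j]) − 1)`: the factorization lives in the
log domain, where an exponential envelope is a straight line, so
fitting the H row directly cannot recover a decay constant. The first
segment is excluded throughout (the noise component's first coefficient
is atypically high — it soaks up signal energy). Per component:

* `decay_ratio` — early-quarter over late-quarter mean of the profile;
* `fitted_tau` — least-squares exponential time constant over segment
  centre times.

The component with decay ratio nearest 1 is the noise floor (ties break
toward lower reconstruction energy, deterministically; all-zero
components count as flat). If every component is flat the pipeline
raises "no decaying component found" with guidance to shrink the
window. In T2\*-separation mode the non-noise components are ranked by
fitted tau (short vs long; at rank > 3 a geometric-mean cut assigns the
middle components).

Per-label reconstructions `Σ_k W[:,k]H[k,:]` are split out, and the
first `reassign_initial_segments` columns of the noise matrix (default
1; 3 in the large-scale profile) are moved into the signal-bearing
matrices pro-rata by column content and zeroed in the noise matrix —
the noise component's first coefficients carry genuine signal energy.
The move preserves the total reconstruction column-for-column.

## Masking and reconstruction

Each label's log-domain matrix maps back to linear magnitude; the
ratio masks `A_c / Σ A_c` (entries where every component is zero share
the energy equally) multiply the *original complex* spectrogram.
Original phases are untouched and the component spectrograms sum to the
original exactly, so component FIDs sum to the input FID and component
spectra sum to the original spectrum (asserted at 1e-6 relative;
measured at machine precision). Magnitude-only resynthesis with phase
estimation was deliberately avoided.

The standard Fourier transform zero-fills to twice the next power of
two, halves the first point (removing the one-sided transform's
constant baseline offset), and returns a centred Hz axis with ppm
attached when the spectrometer frequency is known. No apodization is
applied — the deconvolution itself plays the role a T2\*-matched filter
would, without favouring any single line width.

A degenerate configuration (too few segments to factorize, e.g. a
full-length window without boundary segments) skips the factorization
and labels everything signal: the STFT has collapsed to a plain Fourier
transform, there is nothing to separate, and the relative SNR is 1.

## SNR evaluation

`SNR = max Re(intensity in peak region) / (2 sd)`, with sd the standard
deviation of the real intensities in a signal-free noise region after
removing a linear trend fitted to that region. The multiplier 2 is a
convention; every reported figure of merit is a ratio of two SNRs and
does not depend on it. The automatic noise region is the outer 5% edge
of the axis with the lower mean absolute intensity (ties to the
high-frequency edge); the pipeline's peak search window is the interior
of the axis with a 7% margin, which keeps it disjoint from either
edge. `relative SNR = SNR_denoised / SNR_original`; its square is the
acquisition-time factor, since SNR grows with the square root of the
number of accumulated scans.

## Noise factor analysis

`harvest` walks a directory tree, treats any directory containing an
`acqus`-style JCAMP-DX file as a dataset, and tabulates the main-text
acquisition parameters (missing keys explicit as NaN, unreadable files
flagged per-row, rows sorted by path so the result is
traversal-independent). The acquisition time is derived as
`TD/2 / SW_h` when not recorded. The cryoprobe indicator is coded 4 if
the probe string mentions a cryoprobe, else 0. `calc_snr` is a
theoretical *index*, `conc · BF1^{3/2} · √NS` — the canonical
field-strength and scan-count sensitivity scaling — not an absolute
SNR prediction; output metadata labels it as an index. Pearson
correlations use pairwise-complete observations with at least 3 pairs;
zero-variance and categorical columns are skipped. The network is a
star around the target with edges kept at |r| ≥ 0.2 by default, sign
and |r| stored as GML edge attributes (positive/red, negative/blue,
width = |r|); no p-values or multiple-testing machinery, as only
correlation magnitudes are interpreted.

## What the synthetic fixtures do and do not emulate

`sucrose_like` (33,280 points, dwell 125 µs, 15–25 sharp lines with
T2\* 0.1–1 s, noise σ = 1.55 chosen so the original spectrum's SNR is
≈ 20) stands in for a small-molecule presaturation acquisition;
`diffusion_edited_like` (8,192 points, 8 broad lines T2\* 2–10 ms + 5
sharp lines T2\* 0.1–1 s) for a diffusion-edited acquisition with
incompletely suppressed small molecules. They reproduce the decay
structure the method exploits but none of the complications of real
data: no J-coupling multiplets, phase errors, baseline roll, solvent
signals, field drift, or colored/correlated noise, and all fixture
lines are zero-phase. Passing tests therefore demonstrate the
machinery and its behaviour under the assumed model, not performance on
instrument data.

## Numerical choices

* COLA check tolerance 1e-10; istft divides only where window coverage
  is positive.
* Multiplicative updates guard denominators with 1e-12.
* Factorization stops at `max_iter` (200) or relative objective change
  below `tol` (1e-6).
* Exponential fits use `log(x + 1e-12)`; flatness threshold for a
  noise candidate is decay ratio < 1.5.
* Window sizes from percentages round to the nearest power of two.
* Display rounding of window percentages is one-decimal half-up
  (6.25% reads as 6.3%).
* Bruker reader: int32 or float64 per `DTYPA`, byte order per
  `BYTORDA`, digital-filter group delay (`GRPDLY` points) dropped from
  the front by default.

## Problem sizes

The shipped study conditions are a 33,280-point FID (spectrogram
1024 × 133 at the default quarter-window hop, boundary segments
included) and an 8,192-point FID (512 × 67). A full rank-2 deconvolution of the former takes well
under a second on one CPU; the acceptance script, which re-simulates
everything and runs both pipelines, completes in a few seconds.

## Known limitations

* One global coefficient row per component cannot represent a broad
  T2\* distribution exactly; lines far from the component's effective
  decay constant lose some late-time amplitude to the mask (mitigated,
  not removed, by the flat-noise constraint).
* The ratio mask is magnitude-based; in bins where signal and noise
  have comparable magnitude the split is soft, not exact.
* The SNR estimator assumes a phase-corrected (absorption-mode)
  spectrum for peak picking; fixtures are zero-phase by construction.
* The automatic noise region assumes at least one signal-free spectral
  edge.
* Rank selection is fixed (2 or 3) per the method's design; no
  automatic model order selection is attempted.
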