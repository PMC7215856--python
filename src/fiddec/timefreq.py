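"""Short-time Fourier transform and the magnitude/log bridge to factorization.

The STFT slides a taper g along the FID, Fourier-transforming each
windowed segment; columns of the resulting spectrogram are per-segment
spectra and rows trace how each frequency's intensity decays with time
(the T2* signature the factorization exploits).  The inverse transform
overlap-adds the per-segment inverse FFTs and divides by the
overlap-added window, so any spectrogram produced here round-trips to
the exact signal.

Window convention: "hann" is the half-sample-shifted periodic Hann
w[n] = sin^2(pi (n+1/2) / N).  At 50% hop the shifted copies sum to
exactly 1 (sin^2 + cos^2), and w > 0 everywhere, so even the first FID
sample — the signal maximum — is recovered by the inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .fid import FID

__all__ = [
    "STFTConfig",
    "Spectrogram",
    "make_window",
    "window_percentage",
    "stft",
    "istft",
    "magnitude",
    "to_log",
    "from_log",
]

#: tolerance for the constant-overlap-add check
_COLA_TOL = 1e-10


def make_window(name: str, size: int) -> np.ndarray:
    """Return the named analysis taper of the given length.

    Supported: ``hann`` (half-sample-shifted periodic, strictly positive),
    ``hamming`` (periodic), ``rect``.
    """
    if size < 1:
        raise ValueError("window size must be positive")
    n = np.arange(size)
    if name == "hann":
        return np.sin(np.pi * (n + 0.5) / size) ** 2
    if name == "hamming":
        return 0.54 - 0.46 * np.cos(2 * np.pi * n / size)
    if name in ("rect", "rectangular", "boxcar"):
        return np.ones(size)
    raise ValueError(f"unknown window {name!r}; choose hann, hamming or rect")


@dataclass(frozen=True)
class STFTConfig:
    """Analysis configuration: window length, hop (segment stride), taper.

    With ``boundary`` (the default) the transform adds leading/trailing
    segments over zero-padding so every signal sample has full window
    coverage.  This matters for modified (masked) spectrograms: without
    it, samples near the signal edges are covered only by the tail of a
    single window, and resynthesis there divides spectral-leakage terms
    by a nearly-zero coverage, producing large spurious spikes in the
    component signals.  ``boundary=False`` gives the bare segmentation
    (first segment starts exactly at sample 0).
    """

    window_size: int
    hop: int | None = None
    window_name: str = "hann"
    boundary: bool = True

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be positive")
        if self.hop is None:
            object.__setattr__(self, "hop", max(self.window_size // 2, 1))
        if not (1 <= self.hop <= self.window_size):
            raise ValueError(f"hop must be in [1, window_size], got {self.hop}")

    @property
    def window(self) -> np.ndarray:
        return make_window(self.window_name, self.window_size)

    def validate_cola(self) -> None:
        """Check the constant-overlap-add condition for (window, hop).

        The overlap-added window sum over one interior period must be
        constant; otherwise the inverse transform's normalization would
        ripple at the hop rate.
        """
        w = self.window
        # tile enough copies that the centre period is fully covered
        reps = 3 * (self.window_size // self.hop + 1)
        acc = np.zeros(self.hop * reps + self.window_size)
        for j in range(reps):
            acc[j * self.hop : j * self.hop + self.window_size] += w
        core = acc[self.window_size : -2 * self.window_size]
        if core.size == 0 or np.ptp(core) > _COLA_TOL * max(core.max(), 1e-300):
            raise ValueError(
                f"window {self.window_name!r} with hop {self.hop} violates the "
                "constant-overlap-add condition: overlap-added window sum is "
                f"not constant (peak-to-peak {np.ptp(core):.3g})"
            )


@dataclass
class Spectrogram:
    """Complex time–frequency matrix (frequency bins x time segments).

    ``values[:, j]`` is the FFT of the windowed segment starting at sample
    ``j * hop``; the final segment is zero-padded past ``original_length``.
    Frequency bins are in FFT-natural order.
    """

    values: np.ndarray
    config: STFTConfig
    original_length: int
    dwell: float
    spectrometer_freq: float | None = None
    label: str = ""
    pad_left: int = 0

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    @property
    def segment_times(self) -> np.ndarray:
        """Centre time of each segment in seconds (negative for boundary)."""
        starts = np.arange(self.n_segments) * self.config.hop - self.pad_left
        return (starts + (self.config.window_size - 1) / 2.0) * self.dwell

    def copy_with(self, values: np.ndarray) -> "Spectrogram":
        return Spectrogram(
            values=values,
            config=self.config,
            original_length=self.original_length,
            dwell=self.dwell,
            spectrometer_freq=self.spectrometer_freq,
            label=self.label,
            pad_left=self.pad_left,
        )


def window_percentage(window_size: int, fid_length: int) -> float:
    """Window length as a percentage of the FID length (the 'time width')."""
    if window_size < 1 or fid_length < 1:
        raise ValueError("window_size and fid_length must be positive")
    if window_size > fid_length:
        raise ValueError(
            f"window_size {window_size} exceeds FID length {fid_length}"
        )
    return 100.0 * window_size / fid_length


def _layout(length: int, window: int, hop: int, boundary: bool) -> tuple[int, int]:
    """(pad_left, n_segments) for the chosen segmentation.

    Without boundary segments, segment j starts at sample j*hop and the
    final segment is zero-padded past the end.  With boundary segments,
    zero-padding on both sides guarantees every signal sample is covered
    by the full complement of overlapping windows.
    """
    if not boundary:
        if length <= window:
            return 0, 1
        return 0, 1 + int(np.ceil((length - window) / hop))
    pad_left = (int(np.ceil(window / hop)) - 1) * hop
    last_needed = pad_left + length - 1  # last sample needing a window start
    return pad_left, last_needed // hop + 1


def stft(fid: FID, config: STFTConfig) -> Spectrogram:
    """Short-time Fourier transform of an FID.

    Moves the analysis window in hop-sized strides; each column is the
    unnormalized FFT of one windowed segment.  Column j covers samples
    starting at ``j*hop - pad_left`` (pad_left is 0 when
    ``config.boundary`` is off).
    """
    x = fid.samples
    n, hop = config.window_size, config.hop
    if n > x.size:
        raise ValueError(
            f"window_size {n} exceeds FID length {x.size}; shorten the window"
        )
    w = config.window
    pad_left, n_seg = _layout(x.size, n, hop, config.boundary)
    padded = np.zeros((n_seg - 1) * hop + n, dtype=complex)
    padded[pad_left : pad_left + x.size] = x
    segments = np.lib.stride_tricks.sliding_window_view(padded, n)[::hop]
    cols = sp_fft.fft(segments * w, axis=1)
    return Spectrogram(
        values=cols.T.copy(),
        config=config,
        original_length=x.size,
        dwell=fid.dwell,
        spectrometer_freq=fid.spectrometer_freq,
        label=fid.label,
        pad_left=pad_left,
    )


def istft(spec: Spectrogram) -> FID:
    """Inverse STFT by overlap-adding per-segment inverse FFTs.

    The overlap-added segments equal x .* (overlap-added window); dividing
    by the window coverage recovers x exactly wherever coverage is
    positive.  The configuration must satisfy constant overlap-add.
    """
    spec.config.validate_cola()
    n, hop = spec.config.window_size, spec.config.hop
    w = spec.config.window
    n_seg = spec.n_segments
    total = (n_seg - 1) * hop + n
    acc = np.zeros(total, dtype=complex)
    cov = np.zeros(total)
    segments = sp_fft.ifft(spec.values.T, axis=1)
    for j in range(n_seg):
        acc[j * hop : j * hop + n] += segments[j]
        cov[j * hop : j * hop + n] += w
    out = np.zeros(total, dtype=complex)
    nz = cov > 0
    out[nz] = acc[nz] / cov[nz]
    lo = spec.pad_left
    return FID(
        out[lo : lo + spec.original_length],
        dwell=spec.dwell,
        spectrometer_freq=spec.spectrometer_freq,
        label=spec.label,
    )


def magnitude(spec: Spectrogram) -> np.ndarray:
    """Entry-wise modulus |z| = sqrt(Re^2 + Im^2) of the spectrogram."""
    return np.abs(spec.values)


def to_log(mag: np.ndarray) -> np.ndarray:
    """Compress a nonnegative magnitude matrix as log10(x + 1).

    Zero maps to zero, so the result is nonnegative and factorizable.
    """
    mag = np.asarray(mag, dtype=float)
    if np.any(mag < 0):
        raise ValueError("to_log requires nonnegative input (a magnitude matrix)")
    return np.log10(mag + 1.0)


def from_log(V: np.ndarray) -> np.ndarray:
    """Invert :func:`to_log`: entry-wise 10^v - 1."""
    return np.power(10.0, np.asarray(V, dtype=float)) - 1.0
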