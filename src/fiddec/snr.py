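"""Spectrum signal-to-noise evaluation.

SNR is the maximum real intensity inside a peak region divided by twice
the standard deviation of the real intensities in a signal-free noise
region (the noise region is linearly detrended first, so a sloped
baseline does not inflate the noise estimate).  The relative SNR —
denoised over original — is the figure of merit for denoising, and its
square is the factor by which the acquisition time would have to grow
to reach the same SNR by signal averaging alone (SNR scales with the
square root of the number of scans).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["SNRReport", "compute_snr", "relative_snr", "default_noise_region"]

#: minimum number of points a noise region must contain
MIN_NOISE_POINTS = 32


@dataclass
class SNRReport:
    """Original vs denoised SNR and the implied acquisition-time saving."""

    snr_original: float
    snr_denoised: float
    relative_snr: float
    peak_region: tuple[float, float]
    noise_region: tuple[float, float]
    noise_sd: float
    time_equivalent_factor: float

    def to_dict(self) -> dict:
        return asdict(self)


def _region_mask(axis: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = min(region), max(region)
    if lo < axis.min() - 1e-12 or hi > axis.max() + 1e-12:
        raise ValueError(f"region {region} lies outside the axis range "
                         f"[{axis.min():.6g}, {axis.max():.6g}]")
    return (axis >= lo) & (axis <= hi)


def compute_snr(
    spectrum,
    peak_region: tuple[float, float],
    noise_region: tuple[float, float],
) -> float:
    """Peak-over-noise SNR of a spectrum.

    ``SNR = max Re(intensity in peak_region) / (2 * sd)`` where ``sd`` is
    the standard deviation of the real intensities in ``noise_region``
    after removing a linear trend fitted to that region.  The regions
    must be disjoint and the noise region must hold at least
    ``MIN_NOISE_POINTS`` samples.
    """
    axis = np.asarray(spectrum.frequency_axis, dtype=float)
    intens = np.real(np.asarray(spectrum.intensities))
    pmask = _region_mask(axis, peak_region)
    nmask = _region_mask(axis, noise_region)
    if not pmask.any():
        raise ValueError("peak region contains no points")
    if np.any(pmask & nmask):
        raise ValueError("noise region overlaps the peak region")
    if nmask.sum() < MIN_NOISE_POINTS:
        raise ValueError(
            f"noise region holds {int(nmask.sum())} points; "
            f"need at least {MIN_NOISE_POINTS}"
        )
    peak = float(np.max(intens[pmask]))
    x = axis[nmask]
    y = intens[nmask]
    trend = np.polyval(np.polyfit(x, y, 1), x)
    sd = float(np.std(y - trend))
    if sd == 0.0:
        raise ValueError("noise region is constant; cannot estimate noise")
    return peak / (2.0 * sd)


def relative_snr(snr_denoised: float, snr_original: float) -> tuple[float, float]:
    """Ratio of denoised to original SNR, and its square.

    The square is the time-equivalent factor: reaching the denoised SNR
    purely by accumulating scans would take that many times longer.
    """
    if snr_denoised <= 0 or snr_original <= 0:
        raise ValueError("SNR values must be positive")
    ratio = snr_denoised / snr_original
    return ratio, ratio**2


def default_noise_region(spectrum, fraction: float = 0.05) -> tuple[float, float]:
    """Deterministic signal-free region: the quieter outer 5% edge.

    Takes the edge interval (low- or high-frequency end of the axis)
    with the lower mean absolute intensity; ties go to the
    high-frequency edge.  A documented stand-in for interactive noise
    region selection.
    """
    axis = np.asarray(spectrum.frequency_axis, dtype=float)
    intens = np.real(np.asarray(spectrum.intensities))
    n = axis.size
    if n < 256:
        raise ValueError("spectrum too short for automatic noise-region choice")
    k = max(int(n * fraction), MIN_NOISE_POINTS)
    order = np.argsort(axis)
    low_idx, high_idx = order[:k], order[-k:]
    low_mean = float(np.mean(np.abs(intens[low_idx])))
    high_mean = float(np.mean(np.abs(intens[high_idx])))
    idx = high_idx if high_mean <= low_mean else low_idx
    return (float(axis[idx].min()), float(axis[idx].max()))
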