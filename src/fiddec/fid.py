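"""Free induction decay container and dataset I/O.

The FID is the complex time-domain signal a pulsed NMR spectrometer
records: a sum of exponentially decaying sinusoids (one per resonance
line, decay constant T2*) plus additive noise.  Two on-disk forms are
supported: a plain-text two-column format used for fixtures and CLI
output, and Bruker-style dataset directories (binary ``fid`` plus a
JCAMP-DX ``acqus`` parameter file).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FID",
    "read_txt",
    "write_txt",
    "read_bruker",
    "write_bruker",
    "parse_jcamp",
]


@dataclass
class FID:
    """Complex time-domain NMR signal with sampling metadata.

    Parameters
    ----------
    samples : ndarray of complex
        Quadrature-detected signal, one complex value per dwell period.
    dwell : float
        Sampling interval in seconds (inverse of the spectral width in Hz).
    spectrometer_freq : float or None
        Basic transmitter frequency in MHz; enables a ppm axis downstream.
    label : str
        Free-text provenance tag.
    """

    samples: np.ndarray
    dwell: float
    spectrometer_freq: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("FID requires a one-dimensional, non-empty sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("FID samples must be finite")
        if self.dwell <= 0:
            raise ValueError(f"dwell must be positive, got {self.dwell}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times t_k = k * dwell in seconds."""
        return np.arange(self.samples.size) * self.dwell

    @property
    def sweep_width(self) -> float:
        """Spectral width in Hz (1/dwell)."""
        return 1.0 / self.dwell

    def copy(self, **overrides) -> "FID":
        kwargs = dict(
            samples=self.samples.copy(),
            dwell=self.dwell,
            spectrometer_freq=self.spectrometer_freq,
            label=self.label,
        )
        kwargs.update(overrides)
        return FID(**kwargs)


# ---------------------------------------------------------------------------
# plain-text fixture format: '# key=value' header lines, then "real imag" rows
# ---------------------------------------------------------------------------

def write_txt(fid: FID, path: str | Path) -> None:
    """Write an FID as header comments plus two columns (real, imaginary)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dwell={fid.dwell!r}\n")
        if fid.spectrometer_freq is not None:
            fh.write(f"# sfo={fid.spectrometer_freq!r}\n")
        if fid.label:
            fh.write(f"# label={fid.label}\n")
        for z in fid.samples:
            fh.write(f"{z.real:.17g} {z.imag:.17g}\n")


def read_txt(path: str | Path) -> FID:
    """Read the plain-text FID format written by :func:`write_txt`."""
    path = Path(path)
    dwell = None
    sfo = None
    label = ""
    rows: list[tuple[float, float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(.+)", line)
                if m:
                    key, value = m.group(1), m.group(2).strip()
                    if key == "dwell":
                        dwell = float(value)
                    elif key == "sfo":
                        sfo = float(value)
                    elif key == "label":
                        label = value
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"expected two columns in {path}, got: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if dwell is None:
        raise ValueError(f"missing '# dwell=' header in {path}")
    if not rows:
        raise ValueError(f"no samples in {path}")
    arr = np.array(rows)
    return FID(arr[:, 0] + 1j * arr[:, 1], dwell=dwell, spectrometer_freq=sfo, label=label)


# ---------------------------------------------------------------------------
# JCAMP-DX acquisition parameter records (##$KEY= value)
# ---------------------------------------------------------------------------

_JCAMP_RE = re.compile(r"^##\$?(?P<key>[^=]+)=\s*(?P<value>.*)$")


def parse_jcamp(path: str | Path) -> dict[str, object]:
    """Parse ``##$KEY= value`` records from a JCAMP-DX parameter file.

    Values are converted to int or float when possible; bracketed strings
    like ``<PA BBO 400>`` keep their text without the brackets.  Array
    records spanning multiple lines (``##$GPZ= (0..31)`` followed by
    numbers) are returned as lists.
    """
    path = Path(path)
    params: dict[str, object] = {}
    lines = path.read_text(errors="replace").splitlines()
    i = 0
    while i < len(lines):
        m = _JCAMP_RE.match(lines[i].strip())
        if not m:
            i += 1
            continue
        key = m.group("key").strip()
        raw = m.group("value").strip()
        if raw.startswith("("):  # array header, values on following lines
            values: list[str] = []
            i += 1
            while i < len(lines) and not lines[i].startswith("##"):
                values.extend(lines[i].split())
                i += 1
            params[key] = [_coerce(v) for v in values]
            continue
        params[key] = _coerce(raw)
        i += 1
    return params


def _coerce(raw: str) -> object:
    raw = raw.strip()
    if raw.startswith("<") and raw.endswith(">"):
        return raw[1:-1]
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


# ---------------------------------------------------------------------------
# Bruker-style dataset directories: binary 'fid' + JCAMP-DX 'acqus'
# ---------------------------------------------------------------------------

def read_bruker(directory: str | Path, remove_group_delay: bool = True) -> FID:
    """Read a Bruker-style dataset directory.

    The ``fid`` file holds interleaved real/imaginary integers (or doubles
    when ``DTYPA=2``); byte order follows ``BYTORDA``.  The digital-filter
    group delay (``GRPDLY`` pre-charge points) is rotated off the front by
    default, so sample 0 is the true start of the decay.
    """
    directory = Path(directory)
    acqus = directory / "acqus"
    fid_file = directory / "fid"
    if not acqus.exists() or not fid_file.exists():
        raise FileNotFoundError(f"{directory} is not a Bruker-style dataset (need 'fid' and 'acqus')")
    params = parse_jcamp(acqus)

    byte_order = "<" if int(params.get("BYTORDA", 0) or 0) == 0 else ">"
    dtypa = int(params.get("DTYPA", 0) or 0)
    dtype = np.dtype(f"{byte_order}f8") if dtypa == 2 else np.dtype(f"{byte_order}i4")
    raw = np.frombuffer(fid_file.read_bytes(), dtype=dtype).astype(float)
    if raw.size % 2:
        raw = raw[:-1]
    samples = raw[0::2] + 1j * raw[1::2]

    sw_h = float(params.get("SW_h", 0) or 0)
    if sw_h <= 0:
        raise ValueError(f"{acqus}: missing or non-positive SW_h")
    dwell = 1.0 / sw_h
    sfo = params.get("SFO1") or params.get("BF1")
    sfo = float(sfo) if sfo else None

    if remove_group_delay:
        grpdly = params.get("GRPDLY", 0)
        try:
            shift = int(round(float(grpdly)))
        except (TypeError, ValueError):
            shift = 0
        if 0 < shift < samples.size:
            samples = samples[shift:]

    return FID(samples, dwell=dwell, spectrometer_freq=sfo, label=str(directory))


def write_bruker(fid: FID, directory: str | Path, extra_params: dict | None = None) -> None:
    """Write an FID as a Bruker-style directory (int32 'fid' + 'acqus').

    Intended for fixtures and round-trip tests; intensities are scaled to
    use the int32 range, so absolute scale is not preserved (shape is).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = max(np.abs(fid.samples.real).max(), np.abs(fid.samples.imag).max(), 1e-30)
    scale = 2**28 / peak
    interleaved = np.empty(2 * fid.samples.size)
    interleaved[0::2] = fid.samples.real * scale
    interleaved[1::2] = fid.samples.imag * scale
    (directory / "fid").write_bytes(interleaved.astype("<i4").tobytes())

    params = {
        "TD": 2 * fid.samples.size,
        "SW_h": fid.sweep_width,
        "BYTORDA": 0,
        "DTYPA": 0,
        "GRPDLY": 0,
    }
    if fid.spectrometer_freq is not None:
        params["SFO1"] = fid.spectrometer_freq
        params["BF1"] = fid.spectrometer_freq
    if extra_params:
        params.update(extra_params)
    with (directory / "acqus").open("w") as fh:
        fh.write("##TITLE= synthetic acquisition parameters\n##JCAMPDX= 5.0\n")
        for key, value in params.items():
            if isinstance(value, str):
                fh.write(f"##${key}= <{value}>\n")
            else:
                fh.write(f"##${key}= {value}\n")
        fh.write("##END=\n")
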