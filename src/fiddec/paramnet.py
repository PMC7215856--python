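"""Noise factor analysis over collections of NMR datasets.

Four steps: (1) harvest acquisition parameters from every Bruker-style
dataset directory under a root into a table; (2) attach a measured SNR
per dataset (and a theoretical index, calcSNR); (3) Pearson-correlate
every numeric parameter with SNR; (4) export the correlations as a
signed, weighted star network in GML for graph tools.

The harvested parameters are the ones that plausibly drive SNR:
receiver gain (RG), number of scans (NS), relaxation delay (D1),
spectral width (SW/SW_h), acquisition time (AT), time-domain size (TD),
transmitter offset (O1), temperature (TE), base frequency (BF1),
gradient strength (GPZ), and a cryoprobe indicator (PROBHD: 4 if the
probe string mentions a cryoprobe, else 0).
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PARAMETERS",
    "harvest",
    "calc_snr",
    "correlate",
    "build_network",
    "export_gml",
]

from .fid import parse_jcamp

#: JCAMP keys harvested by default, mapped to table column names
DEFAULT_PARAMETERS = {
    "RG": "rg",
    "NS": "ns",
    "D1": "d1",
    "SW": "sw",
    "SW_h": "sw_h",
    "AT": "at",
    "TD": "td",
    "O1": "o1",
    "TE": "te",
    "BF1": "bf1",
    "GPZ": "gpz",
}

#: optional sample descriptors accepted when present in the parameter file
SAMPLE_DESCRIPTORS = {
    "CSTD": "cstd",
    "CCOMP": "ccomp",
    "WATER_POS": "water_pos",
    "WATER_NEG": "water_neg",
    "INTENSITY": "intensity",
    "FWHM": "fwhm",
    "AREA": "area",
}


def _probhd_flag(value: object) -> float:
    """4 for a cryoprobe, 0 otherwise (matching the vendor coding)."""
    text = str(value or "").lower()
    return 4.0 if "cryo" in text else 0.0


def _first_number(value: object) -> float:
    if isinstance(value, (list, tuple)):
        for v in value:
            if isinstance(v, (int, float)):
                return float(v)
        return math.nan
    if isinstance(value, (int, float)):
        return float(value)
    return math.nan


def harvest(root: str | Path, extra_keys: list[str] | None = None) -> pd.DataFrame:
    """Walk ``root`` and tabulate acquisition parameters per dataset.

    A dataset directory is one that contains an ``acqus``-style
    parameter file.  Unreadable files flag the row (``error`` column)
    rather than aborting the harvest; missing keys are NaN.  Rows are
    sorted by path, so the result is independent of traversal order.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"harvest root {root} does not exist")
    extra_keys = extra_keys or []
    rows = []
    for acqus in sorted(root.rglob("acqus")):
        row: dict[str, object] = {"path": str(acqus.parent)}
        try:
            params = parse_jcamp(acqus)
        except OSError as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        for key, col in DEFAULT_PARAMETERS.items():
            row[col] = _first_number(params.get(key, math.nan))
        for key, col in SAMPLE_DESCRIPTORS.items():
            if key in params:
                row[col] = _first_number(params[key])
        for key in extra_keys:
            row[key.lower()] = _first_number(params.get(key, math.nan))
        # derive AT from TD and SW_h when not recorded (AT = TD/2 / SW_h)
        if (not np.isfinite(row.get("at", math.nan))) and np.isfinite(row.get("td", math.nan)):
            sw_h = row.get("sw_h", math.nan)
            if np.isfinite(sw_h) and sw_h > 0:
                row["at"] = row["td"] / 2.0 / sw_h
        row["probhd_flag"] = _probhd_flag(params.get("PROBHD"))
        row["pulse_program"] = str(params.get("PULPROG", ""))
        rows.append(row)
    if not rows:
        import warnings

        warnings.warn(f"no datasets found under {root}", stacklevel=2)
        cols = ["path", *DEFAULT_PARAMETERS.values(), "probhd_flag", "pulse_program"]
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows).sort_values("path").reset_index(drop=True)
    return table


def calc_snr(params: dict | pd.Series) -> float:
    """Theoretical SNR *index* from acquisition parameters.

    Uses the canonical sensitivity scaling SNR ~ c * B0^(3/2) * sqrt(NS)
    (field strength to the three-halves, square root of the number of
    scans), optionally scaled by the compound concentration.  This is a
    relative index for correlation analysis, not an absolute SNR.
    """
    ns = params.get("ns", math.nan)
    bf1 = params.get("bf1", math.nan)
    if not (isinstance(ns, (int, float)) and isinstance(bf1, (int, float))):
        return math.nan
    if not (np.isfinite(ns) and np.isfinite(bf1)) or ns < 1 or bf1 <= 0:
        return math.nan
    ccomp = params.get("ccomp", math.nan)
    conc = float(ccomp) if isinstance(ccomp, (int, float)) and np.isfinite(ccomp) else 1.0
    return conc * float(bf1) ** 1.5 * math.sqrt(float(ns))


def add_calc_snr(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``calc_snr`` column (the theoretical index) to a table."""
    table = table.copy()
    table["calc_snr"] = [calc_snr(row) for _, row in table.iterrows()]
    return table


def correlate(
    table: pd.DataFrame, target: str = "snr", min_n: int = 3
) -> list[tuple[str, float, int]]:
    """Pearson correlation of every numeric column against ``target``.

    Uses pairwise-complete observations; columns with fewer than
    ``min_n`` complete pairs or zero variance are skipped.  Returns
    (parameter, r, n) tuples sorted by |r| descending.
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} is not in the table")
    y_all = pd.to_numeric(table[target], errors="coerce")
    results = []
    for col in table.columns:
        if col in (target, "path", "pulse_program", "error"):
            continue
        x_all = pd.to_numeric(table[col], errors="coerce")
        mask = x_all.notna() & y_all.notna()
        n = int(mask.sum())
        if n < min_n:
            continue
        x = x_all[mask].to_numpy(dtype=float)
        y = y_all[mask].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # zero variance: correlation undefined
        r = float(np.corrcoef(x, y)[0, 1])
        results.append((col, r, n))
    results.sort(key=lambda item: (-abs(item[1]), item[0]))
    return results


def build_network(
    correlations: list[tuple[str, float, int]],
    threshold: float = 0.2,
    target: str = "snr",
) -> nx.Graph:
    """Signed weighted star network of parameters around the target.

    Edges keep parameters with |r| >= threshold (and n >= 3); each edge
    stores the coefficient (``r``), its magnitude as the drawing width
    (``width``), the sample count (``n``) and a color tag (positive ->
    red, negative -> blue, the usual correlation-network convention).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    g = nx.Graph()
    g.add_node(target, kind="target")
    for name, r, n in correlations:
        if abs(r) < threshold or n < 3 or name == target:
            continue
        g.add_node(name, kind="parameter")
        g.add_edge(
            target,
            name,
            r=float(r),
            width=float(abs(r)),
            n=int(n),
            sign="positive" if r >= 0 else "negative",
            color="red" if r >= 0 else "blue",
        )
    return g


def export_gml(network: nx.Graph, path: str | Path) -> None:
    """Write the network as GML, loadable by igraph/Cytoscape/networkx."""
    nx.write_gml(network, str(path))
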