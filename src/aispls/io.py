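"""Spectrum file I/O: two-column CSV/TSV in, corrected-spectrum CSV out.

Floats are written with shortest-round-trip precision so a write/read
cycle reproduces the arrays exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .result import CorrectionResult
from .simulate import SimulatedSpectrum, Spectrum

__all__ = ["read_spectrum", "write_spectrum", "write_result", "write_simulation"]


def _dialect_sep(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_spectrum(path: str | Path, dialect: str | None = None) -> Spectrum:
    """Read a spectrum from a delimited text file.

    The first two numeric columns are interpreted as (wavenumber,
    intensity).  A header row is auto-detected, ``#`` comment lines are
    skipped, rows are sorted by wavenumber, and duplicate wavenumbers
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _dialect_sep(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", header=None, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns, found {df.shape[1]}")
    first = df.iloc[0, :2]
    header_like = any(not _is_number(v) for v in first)
    if header_like:
        df = df.iloc[1:]
    raw = df.iloc[:, :2]
    try:
        # numpy's string->float conversion is exactly rounding, unlike
        # pandas' fast to_numeric path, so round trips stay bit-exact
        data = raw.to_numpy(dtype=float)
    except (TypeError, ValueError):
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = int(coerced.isna().any(axis=1).sum())
        raise ValueError(f"{path}: {bad} row(s) contain non-numeric cells") from None
    if np.isnan(data).any():
        bad = int(np.isnan(data).any(axis=1).sum())
        raise ValueError(f"{path}: {bad} row(s) contain non-numeric cells")
    if len(data) < 3:
        raise ValueError(f"{path}: a spectrum needs at least 3 rows, found {len(data)}")
    x = data[:, 0]
    y = data[:, 1]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        dupes = x[1:][np.diff(x) == 0]
        raise ValueError(f"{path}: duplicate wavenumbers: {np.unique(dupes)[:5]}")
    return Spectrum(x, y)


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def _write_table(path: Path, header_comment: str | None, columns: dict[str, np.ndarray]) -> None:
    names = list(columns)
    arrays = [np.asarray(columns[c]) for c in names]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(",".join(names) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def write_spectrum(spectrum: Spectrum, path: str | Path, comment: str | None = None) -> Path:
    """Write a spectrum as CSV columns ``wavenumber,intensity``."""
    path = Path(path)
    _write_table(path, comment, {"wavenumber": spectrum.x, "intensity": spectrum.y})
    return path


def write_result(
    result: CorrectionResult,
    spectrum: Spectrum,
    path: str | Path,
    provenance: str | None = None,
) -> Path:
    """Write a correction result: ``wavenumber,raw,baseline,corrected``."""
    if len(spectrum) != result.baseline.size:
        raise ValueError("result and spectrum lengths differ")
    path = Path(path)
    _write_table(
        path,
        provenance,
        {
            "wavenumber": spectrum.x,
            "raw": spectrum.y,
            "baseline": result.baseline,
            "corrected": result.corrected,
        },
    )
    return path


def write_simulation(
    sim: SimulatedSpectrum, path: str | Path, sidecar: bool = True
) -> Path:
    """Write a simulated spectrum with its decomposition, plus a JSON
    sidecar recording the generating configuration."""
    path = Path(path)
    _write_table(
        path,
        None,
        {
            "wavenumber": sim.grid,
            "intensity": sim.composite,
            "pure": sim.pure,
            "baseline": sim.baseline,
            "noise": sim.noise,
        },
    )
    if sidecar:
        config = {
            "snr_db": sim.snr_db if np.isfinite(sim.snr_db) else "inf",
            "seed": sim.seed,
            "n_points": int(sim.grid.size),
            "grid_start": float(sim.grid[0]),
            "grid_stop": float(sim.grid[-1]),
            "achieved_snr_db": sim.achieved_snr_db()
            if np.isfinite(sim.snr_db)
            else "inf",
        }
        Path(str(path) + ".config.json").write_text(json.dumps(config, indent=2) + "\n")
    return path
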