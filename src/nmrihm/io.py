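"""Spectrum file I/O: two-column text plus a JSON acquisition sidecar.

A spectrum is stored as CSV with columns (ppm, intensity) in the axis
order (descending ppm) next to a sidecar ``<name>.json`` holding
{spectrometer_frequency_MHz, carrier_ppm, spectral_width_Hz, n_points}.
Values are written with 17 significant digits so the text representation
round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .lineshape import AcquisitionGrid, Spectrum

__all__ = ["write_spectrum", "read_spectrum", "sidecar_path"]


def sidecar_path(csv_path) -> Path:
    return Path(str(csv_path) + ".json")


def write_spectrum(spec: Spectrum, csv_path) -> None:
    csv_path = Path(csv_path)
    ax = spec.ppm_axis
    with open(csv_path, "w", encoding="utf-8") as fh:
        fh.write("ppm,intensity\n")
        for p, y in zip(ax, spec.intensities):
            fh.write(f"{p:.17g},{y:.17g}\n")
    meta = {
        "spectrometer_frequency_MHz": spec.grid.spectrometer_frequency,
        "carrier_ppm": spec.grid.carrier_ppm,
        "spectral_width_Hz": spec.grid.spectral_width,
        "n_points": spec.grid.n_points,
    }
    with open(sidecar_path(csv_path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def read_spectrum(csv_path) -> Spectrum:
    csv_path = Path(csv_path)
    side = sidecar_path(csv_path)
    if not side.exists():
        raise FileNotFoundError(f"missing acquisition sidecar {side}")
    with open(side, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    grid = AcquisitionGrid(
        spectrometer_frequency=float(meta["spectrometer_frequency_MHz"]),
        carrier_ppm=float(meta["carrier_ppm"]),
        spectral_width=float(meta["spectral_width_Hz"]),
        n_points=int(meta["n_points"]),
    )
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape != (grid.n_points, 2):
        raise ValueError(
            f"{csv_path}: expected {grid.n_points} rows of (ppm, intensity)"
        )
    ppm, y = data[:, 0], data[:, 1]
    if not np.allclose(ppm, grid.ppm_axis, rtol=0, atol=1e-9 * grid.ppm_step):
        raise ValueError(f"{csv_path}: ppm column disagrees with the sidecar grid")
    return Spectrum(grid, y)
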