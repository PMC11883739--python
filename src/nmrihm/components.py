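"""Pure-component hard models: multiplets of pseudo-Voigt lines.

A component is a named collection of multiplets.  Each multiplet keeps a
central chemical shift plus fixed internal offsets for its fine-structure
features, so J-coupling patterns move rigidly when the center is
adjusted during alignment.  Feature intensities are stored as relative
amplitudes (normalized within the multiplet); multiplet weights are
normalized across the component so the component spectrum integrates to
the component's total amplitude A_k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .lineshape import (
    AcquisitionGrid,
    Spectrum,
    fid_signals,
    ppm_to_hz,
    spectrum_from_fid,
)

__all__ = [
    "Feature",
    "Multiplet",
    "ComponentModel",
    "component_fid",
    "component_spectrum",
    "parse_peaklist",
    "write_peaklist",
    "PeaklistError",
]


@dataclass(frozen=True)
class Feature:
    """One line of a multiplet's fine structure."""

    offset_hz: float  # relative to the multiplet center
    rel_amplitude: float
    fwhm_hz: float
    gauss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rel_amplitude > 0):
            raise ValueError(f"rel_amplitude must be > 0, got {self.rel_amplitude}")
        if not (self.fwhm_hz > 0):
            raise ValueError(f"fwhm_hz must be > 0, got {self.fwhm_hz}")
        if not (0.0 <= self.gauss_fraction <= 1.0):
            raise ValueError(
                f"gauss_fraction must be in [0, 1], got {self.gauss_fraction}"
            )


@dataclass(frozen=True)
class Multiplet:
    """A center shift plus fine-structure features at fixed offsets.

    ``features`` are stored with rel_amplitudes normalized to sum to 1;
    the raw (pre-normalization) values are preserved in
    ``raw_rel_amplitudes`` for lossless serialization.  ``amplitude`` is
    the multiplet's weight within the component (e.g. a proton count);
    weights are normalized across the component unless the component
    opts out.  A singlet is a multiplet with one feature at offset 0.
    """

    center_ppm: float
    features: tuple[Feature, ...]
    label: str = ""
    amplitude: float = 1.0
    raw_rel_amplitudes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("a multiplet needs at least one feature")
        if not (self.amplitude > 0):
            raise ValueError("multiplet amplitude must be > 0")
        raw = tuple(f.rel_amplitude for f in self.features)
        total = sum(raw)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-12):
            normed = tuple(
                replace(f, rel_amplitude=f.rel_amplitude / total) for f in self.features
            )
            object.__setattr__(self, "features", normed)
        if not self.raw_rel_amplitudes:
            object.__setattr__(self, "raw_rel_amplitudes", raw)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def shifted(self, delta_ppm: float) -> "Multiplet":
        return replace(self, center_ppm=self.center_ppm + delta_ppm)


@dataclass(frozen=True)
class ComponentModel:
    """Hard model of one pure component.

    ``total_amplitude`` (A_k) is the intrinsic spectral integral per unit
    amount; ``nuclei`` (H_k) the number of protons contributing to the
    modeled signals, used for per-proton amount normalization.  When
    ``normalize_multiplets`` is true (the default) multiplet weights are
    rescaled to sum to 1, so the component integral equals A_k; dummy
    components disable this so each dummy line's amplitude is free.
    """

    name: str
    multiplets: tuple[Multiplet, ...]
    total_amplitude: float = 1.0
    nuclei: int = 1
    normalize_multiplets: bool = True
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if len(self.multiplets) < 1:
            raise ValueError("a component needs at least one multiplet")
        if not (self.total_amplitude > 0):
            raise ValueError("total_amplitude must be > 0")
        if self.nuclei < 1:
            raise ValueError("nuclei must be >= 1")
        object.__setattr__(self, "multiplets", tuple(self.multiplets))

    @property
    def n_peaks(self) -> int:
        return sum(m.n_features for m in self.multiplets)

    def multiplet_weights(self) -> np.ndarray:
        w = np.array([m.amplitude for m in self.multiplets], dtype=float)
        if self.normalize_multiplets:
            w = w / w.sum()
        return w

    def peak_arrays(self, grid: AcquisitionGrid):
        """Flatten to per-line (K, nu, fwhm, beta) arrays on a grid."""
        weights = self.multiplet_weights()
        K, nu, G, b = [], [], [], []
        for m, w in zip(self.multiplets, weights):
            center_hz = float(ppm_to_hz(m.center_ppm, grid))
            for f in m.features:
                off = center_hz + f.offset_hz
                if not grid.contains_offset(off):
                    raise ValueError(
                        f"component {self.name!r}, multiplet {m.label!r}: feature at "
                        f"{m.center_ppm} ppm + {f.offset_hz} Hz falls outside the "
                        f"spectral window"
                    )
                K.append(self.total_amplitude * w * f.rel_amplitude)
                nu.append(off)
                G.append(f.fwhm_hz)
                b.append(f.gauss_fraction)
        return (np.array(K), np.array(nu), np.array(G), np.array(b))


def component_fid(comp: ComponentModel, grid: AcquisitionGrid) -> np.ndarray:
    """Time-domain signal of a component: the sum of its line FIDs."""
    K, nu, G, b = comp.peak_arrays(grid)
    return fid_signals(K, nu, G, b, grid)


def component_spectrum(comp: ComponentModel, grid: AcquisitionGrid) -> Spectrum:
    """Frequency-domain spectrum of a component (integral = A_k)."""
    return spectrum_from_fid(component_fid(comp, grid), grid)


class PeaklistError(ValueError):
    """Malformed peak-list file; message carries the offending line number."""


_COLUMNS = (
    "component",
    "multiplet",
    "center_ppm",
    "offset_hz",
    "rel_amplitude",
    "fwhm_hz",
    "beta",
    "nuclei",
)


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def parse_peaklist(path) -> ComponentModel:
    """Read one component from a tab-separated peak-list file.

    The dialect is one row per line (feature) with the columns
    component, multiplet, center_ppm, offset_hz, rel_amplitude, fwhm_hz,
    beta, nuclei; a mandatory header row; '#' comment lines.  A comment
    of the form ``# amplitude: <x>`` sets the component's total
    amplitude A_k (default 1).  Multiplets are grouped by label; their
    center_ppm must agree within a group.
    """
    amplitude = 1.0
    mult_amplitudes: dict[str, float] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("amplitude:"):
                    amplitude = float(body.split(":", 1)[1])
                elif body.startswith("multiplet_amplitude "):
                    _, lbl, val = body.split(None, 2)
                    mult_amplitudes[lbl.rstrip(":")] = float(val)
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise PeaklistError(
                        f"{path}: line {lineno}: missing column(s) {', '.join(missing)}"
                    )
                continue
            if len(cells) != len(header):
                raise PeaklistError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(cells)}"
                )
            rows.append((lineno, cells))
    if header is None or not rows:
        raise PeaklistError(f"{path}: no data rows found")

    col = {name: header.index(name) for name in _COLUMNS}
    comp_name = None
    nuclei = None
    groups: dict[str, dict] = {}
    order: list[str] = []
    for lineno, cells in rows:
        def get(name: str) -> str:
            return cells[col[name]].strip()

        name = get("component")
        if comp_name is None:
            comp_name = name
        elif name != comp_name:
            raise PeaklistError(
                f"{path}: line {lineno}: component name {name!r} differs from "
                f"{comp_name!r}; one component per file"
            )
        try:
            center = float(get("center_ppm"))
            offset = float(get("offset_hz"))
            rel = float(get("rel_amplitude"))
            fwhm = float(get("fwhm_hz"))
            beta = float(get("beta"))
            h = int(get("nuclei"))
        except ValueError as exc:
            raise PeaklistError(f"{path}: line {lineno}: {exc}") from None
        if not (0.0 <= beta <= 1.0):
            raise PeaklistError(
                f"{path}: line {lineno}: beta must be in [0, 1], got {beta}"
            )
        if not (fwhm > 0):
            raise PeaklistError(
                f"{path}: line {lineno}: fwhm_hz must be > 0, got {fwhm}"
            )
        if not (rel > 0):
            raise PeaklistError(
                f"{path}: line {lineno}: rel_amplitude must be > 0, got {rel}"
            )
        if nuclei is None:
            nuclei = h
        elif h != nuclei:
            raise PeaklistError(
                f"{path}: line {lineno}: nuclei {h} disagrees with earlier value "
                f"{nuclei}; the count is per component"
            )
        label = get("multiplet")
        if label not in groups:
            groups[label] = {"center": center, "features": [], "line": lineno}
            order.append(label)
        elif groups[label]["center"] != center:
            raise PeaklistError(
                f"{path}: line {lineno}: multiplet {label!r} center {center} "
                f"disagrees with {groups[label]['center']} on line "
                f"{groups[label]['line']}"
            )
        groups[label]["features"].append(Feature(offset, rel, fwhm, beta))

    multiplets = tuple(
        Multiplet(
            center_ppm=groups[lbl]["center"],
            features=tuple(groups[lbl]["features"]),
            label=lbl,
            amplitude=mult_amplitudes.get(lbl, 1.0),
        )
        for lbl in order
    )
    return ComponentModel(
        name=comp_name,
        multiplets=multiplets,
        total_amplitude=amplitude,
        nuclei=int(nuclei),
    )


def write_peaklist(comp: ComponentModel, path) -> None:
    """Write a component to the tab-separated peak-list dialect."""
    lines = [f"# amplitude: {_fmt(comp.total_amplitude)}"]
    for m in comp.multiplets:
        if m.amplitude != 1.0:
            lines.append(f"# multiplet_amplitude {m.label}: {_fmt(m.amplitude)}")
    lines.append("\t".join(_COLUMNS))
    for m in comp.multiplets:
        for f, raw in zip(m.features, m.raw_rel_amplitudes):
            lines.append(
                "\t".join(
                    [
                        comp.name,
                        m.label,
                        _fmt(m.center_ppm),
                        _fmt(f.offset_hz),
                        _fmt(raw),
                        _fmt(f.fwhm_hz),
                        _fmt(f.gauss_fraction),
                        str(comp.nuclei),
                    ]
                )
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
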