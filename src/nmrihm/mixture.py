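"""Mixture model: a concentration-weighted sum of component spectra.

The mixture trace is f = sum_k c_k * S_k, optionally plus a dummy
component that soaks up unassigned features; the dummy participates in
the fit but never in the reported composition.  Regions of interest
restrict all targets to the ppm intervals that contain the signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .components import ComponentModel, Feature, Multiplet, component_fid
from .lineshape import AcquisitionGrid, Peak, Spectrum, hz_to_ppm, spectrum_from_fid

__all__ = ["MixtureModel", "RegionSet", "mixture_spectrum", "select_regions",
           "add_dummy_component"]


@dataclass
class MixtureModel:
    """M components with nonnegative concentrations, plus optional dummy."""

    components: list[ComponentModel]
    concentrations: np.ndarray
    grid: AcquisitionGrid
    dummy: ComponentModel | None = None

    def __post_init__(self) -> None:
        self.components = list(self.components)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.components) < 1:
            raise ValueError("a mixture needs at least one component")
        if self.concentrations.shape != (len(self.components),):
            raise ValueError(
                f"{len(self.components)} components but "
                f"{self.concentrations.size} concentrations"
            )
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.dummy is not None and not self.dummy.is_dummy:
            raise ValueError("dummy component must be flagged is_dummy")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def copy(self) -> "MixtureModel":
        return MixtureModel(
            components=list(self.components),
            concentrations=self.concentrations.copy(),
            grid=self.grid,
            dummy=self.dummy,
        )


def mixture_fid(model: MixtureModel) -> np.ndarray:
    """Time-domain trace of the whole mixture (dummy included)."""
    fid = np.zeros(model.grid.n_points, dtype=complex)
    for c, comp in zip(model.concentrations, model.components):
        if c != 0.0:
            fid += c * component_fid(comp, model.grid)
    if model.dummy is not None:
        fid += component_fid(model.dummy, model.grid)
    return fid


def mixture_spectrum(model: MixtureModel) -> Spectrum:
    """Model trace f = sum_k c_k S_k (+ dummy), as a Spectrum."""
    return spectrum_from_fid(mixture_fid(model), model.grid)


@dataclass
class RegionSet:
    """Non-overlapping ppm intervals selecting the points to fit.

    Intervals are given as (high_ppm, low_ppm) pairs (either order is
    accepted and normalized); they are closed, inclusive on the discrete
    grid, and kept sorted by descending high edge.
    """

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        normed = [(max(a, b), min(a, b)) for a, b in self.intervals]
        normed.sort(key=lambda iv: -iv[0])
        for (h1, l1), (h2, l2) in zip(normed, normed[1:]):
            if h2 > l1:
                raise ValueError(
                    f"regions ({h1}, {l1}) and ({h2}, {l2}) overlap after "
                    f"normalization"
                )
        self.intervals = normed

    @classmethod
    def full_axis(cls, grid: AcquisitionGrid) -> "RegionSet":
        ax = grid.ppm_axis
        return cls([(float(ax[0]), float(ax[-1]))])

    def masks(self, grid: AcquisitionGrid) -> list[np.ndarray]:
        """Per-interval index arrays on the descending ppm axis."""
        ax = grid.ppm_axis
        out = []
        for high, low in self.intervals:
            idx = np.nonzero((ax <= high) & (ax >= low))[0]
            if idx.size == 0:
                raise ValueError(
                    f"region ({high}, {low}) ppm selects no points on the axis "
                    f"[{ax[0]:.4f}, {ax[-1]:.4f}]"
                )
            out.append(idx)
        return out

    def mask(self, grid: AcquisitionGrid) -> np.ndarray:
        """Concatenated indices over all intervals, descending ppm order."""
        return np.concatenate(self.masks(grid))


def select_regions(spec: Spectrum, regions: RegionSet):
    """Restrict a spectrum to the regions of interest.

    Returns (masked intensities, masked ppm axis), points concatenated
    per interval in descending-ppm order.
    """
    idx = regions.mask(spec.grid)
    return spec.intensities[idx], spec.ppm_axis[idx]


def add_dummy_component(model: MixtureModel, peaks: list[Peak]) -> MixtureModel:
    """Attach dummy lines absorbing unassigned features.

    Each dummy peak becomes its own singlet multiplet whose amplitude is
    individually adjustable in the fit; the dummy never enters the
    relative-concentration report.  With an empty peak list the model is
    returned unchanged.
    """
    if not peaks:
        return model
    multiplets = []
    for i, p in enumerate(peaks):
        center = float(hz_to_ppm(p.offset_hz, model.grid))
        multiplets.append(
            Multiplet(
                center_ppm=center,
                features=(Feature(0.0, 1.0, p.fwhm_hz, p.gauss_fraction),),
                label=f"dummy_{i}",
                amplitude=p.amplitude if p.amplitude > 0 else 1.0,
            )
        )
    dummy = ComponentModel(
        name="_dummy",
        multiplets=tuple(multiplets),
        total_amplitude=1.0,
        nuclei=1,
        normalize_multiplets=False,
        is_dummy=True,
    )
    out = model.copy()
    out.dummy = dummy
    return out
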