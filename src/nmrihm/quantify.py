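"""Relative concentrations, purity factors and the integration baseline.

Signal integrals in 1H NMR are proportional to amount of substance times
the number of contributing protons, so fitted concentrations convert to
relative molar composition through per-proton normalization:
amount_k ~ c_k * A_k / H_k, with A_k the component model's intrinsic
integral per unit amount and H_k its proton count.  A purity check
compares the observed analyte/standard intensity ratio against the
theoretical ratio from the weighed masses: kappa = observed/theoretical.

The classical alternative — direct trapezoidal integration of isolated
regions — is provided as the comparison baseline, including the rule
that a centered window of 64 linewidths captures 99% of a Lorentzian's
area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lineshape import Spectrum
from .mixture import RegionSet

__all__ = [
    "CompositionReport",
    "relative_concentrations",
    "amount_from_mass",
    "purity_factor",
    "classical_integration",
    "compare_with_integration",
]


@dataclass
class CompositionReport:
    """Relative molar composition over the quantified (non-dummy) components."""

    names: list[str]
    fractions: np.ndarray
    reference: str | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.names) != self.fractions.size:
            raise ValueError("names and fractions differ in length")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be >= 0")
        total = self.fractions.sum()
        if total <= 0:
            raise ValueError("all component amounts are zero")
        if not np.isclose(total, 1.0, rtol=0, atol=1e-12):
            self.fractions = self.fractions / total

    def fraction(self, name: str) -> float:
        return float(self.fractions[self.names.index(name)])

    def ratios_to(self, reference: str) -> dict[str, float]:
        """Per-component intensity ratios to a reference component."""
        ref = self.fraction(reference)
        if ref <= 0:
            raise ValueError(f"reference component {reference!r} has zero amount")
        return {n: float(x) / ref for n, x in zip(self.names, self.fractions)}

    def as_dict(self) -> dict[str, float]:
        return {n: float(x) for n, x in zip(self.names, self.fractions)}


def relative_concentrations(fit_or_model) -> CompositionReport:
    """Per-proton-normalized molar fractions from a fitted mixture.

    Accepts a FitResult or a MixtureModel.  amount_k = c_k * A_k / H_k,
    normalized to fractions over the non-dummy components.
    """
    model = getattr(fit_or_model, "model", fit_or_model)
    amounts = np.array(
        [
            c * comp.total_amplitude / comp.nuclei
            for c, comp in zip(model.concentrations, model.components)
        ]
    )
    if not np.any(amounts > 0):
        raise ValueError("all component amounts are zero")
    names = [comp.name for comp in model.components]
    return CompositionReport(names=names, fractions=amounts / amounts.sum())


def amount_from_mass(mass, molar_mass, purity_fraction=1.0) -> float:
    """Amount of substance from a weighed mass: mass * purity / molar_mass.

    Unit-agnostic: the result is in whatever amount unit the mass and
    molar-mass units imply (mg and g/mol give mmol * 10^-3, i.e. umol
    when multiplied by 1000).
    """
    if mass <= 0 or molar_mass <= 0:
        raise ValueError("mass and molar_mass must be > 0")
    if not (0 < purity_fraction <= 1):
        raise ValueError("purity_fraction must be in (0, 1]")
    return mass * purity_fraction / molar_mass


def purity_factor(observed_ratio: float, theoretical_ratio: float) -> float:
    """kappa: observed intensity ratio over theoretical (gravimetric) ratio."""
    if theoretical_ratio <= 0:
        raise ValueError("theoretical_ratio must be > 0")
    return observed_ratio / theoretical_ratio


def classical_integration(
    spec: Spectrum,
    regions_per_component: dict[str, list[tuple[float, float]]],
    nuclei_per_component: dict[str, int],
) -> CompositionReport:
    """Composition by direct integration of per-component regions.

    Each component's regions are integrated (trapezoid on the Hz axis),
    summed, divided by its proton count and normalized to fractions.
    Regions must not overlap across components.
    """
    names = list(regions_per_component)
    missing = [n for n in names if n not in nuclei_per_component]
    if missing:
        raise ValueError(f"no nuclei count for component(s): {', '.join(missing)}")
    all_intervals = [
        iv for ivs in regions_per_component.values() for iv in ivs
    ]
    RegionSet(all_intervals)  # raises on overlap
    amounts = []
    for name in names:
        rs = RegionSet(list(regions_per_component[name]))
        total = sum(spec.integral(idx) for idx in rs.masks(spec.grid))
        amounts.append(total / nuclei_per_component[name])
    amounts = np.asarray(amounts, dtype=float)
    if np.any(amounts < 0):
        amounts = np.clip(amounts, 0.0, None)
    if amounts.sum() <= 0:
        raise ValueError("all integrated amounts are zero")
    return CompositionReport(names=names, fractions=amounts / amounts.sum())


def compare_with_integration(
    ihm: CompositionReport, integ: CompositionReport
) -> dict[str, float]:
    """Absolute composition differences |x_ihm - x_integ| in percent."""
    if set(ihm.names) != set(integ.names):
        raise ValueError(
            f"component sets differ: {sorted(ihm.names)} vs {sorted(integ.names)}"
        )
    return {
        n: abs(ihm.fraction(n) - integ.fraction(n)) * 100.0 for n in ihm.names
    }
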