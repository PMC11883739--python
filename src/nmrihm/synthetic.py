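"""Seeded synthetic mixtures with known ground truth.

Every stage of the pipeline is testable without measured data: the
presets build multiplet-bearing pure-component models, a simulator
assembles a mixture spectrum with per-component chemical-shift drift,
linewidth scaling and additive white Gaussian noise on the real trace,
and a perturber produces the realistic misaligned starting guess the
alignment step exists for.

The noise is added in the frequency domain rather than on the FID; this
is a deliberate simplification (white in both domains, but a physical
acquisition also correlates noise with apodization and phasing, which
are outside the model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .components import ComponentModel, Feature, Multiplet
from .lineshape import AcquisitionGrid, Spectrum
from .mixture import MixtureModel, mixture_spectrum

__all__ = [
    "TruthRecord",
    "default_grid",
    "fig1_grid",
    "make_component_library",
    "simulate_mixture",
    "perturb_guess",
]


def default_grid(n_points: int = 8192) -> AcquisitionGrid:
    """500 MHz, 10 ppm window centered at 5 ppm — a routine 1H setup."""
    return AcquisitionGrid(
        spectrometer_frequency=500.0,
        carrier_ppm=5.0,
        spectral_width=5000.0,
        n_points=n_points,
    )


def fig1_grid(n_points: int = 8192) -> AcquisitionGrid:
    """700 MHz, 1 ppm window around 5 ppm for the worked multiplet example."""
    return AcquisitionGrid(
        spectrometer_frequency=700.0,
        carrier_ppm=5.0,
        spectral_width=700.0,
        n_points=n_points,
    )


@dataclass
class TruthRecord:
    """Everything needed to regenerate a synthetic spectrum exactly."""

    components: list[ComponentModel]
    concentrations: np.ndarray
    drifts_ppm: np.ndarray
    lw_factors: np.ndarray
    noise_sigma: float
    seed: int
    grid: AcquisitionGrid

    def as_dict(self) -> dict:
        return {
            "components": [c.name for c in self.components],
            "concentrations": [float(x) for x in self.concentrations],
            "drifts_ppm": [float(x) for x in self.drifts_ppm],
            "lw_factors": [float(x) for x in self.lw_factors],
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


def _doublet(J: float, fwhm: float, beta: float) -> tuple[Feature, ...]:
    return (Feature(-J / 2, 0.5, fwhm, beta), Feature(J / 2, 0.5, fwhm, beta))


def _triplet(J: float, fwhm: float, beta: float) -> tuple[Feature, ...]:
    return (
        Feature(-J, 0.25, fwhm, beta),
        Feature(0.0, 0.5, fwhm, beta),
        Feature(J, 0.25, fwhm, beta),
    )


def _quartet(J: float, fwhm: float, beta: float) -> tuple[Feature, ...]:
    return tuple(
        Feature(off * J, amp, fwhm, beta)
        for off, amp in ((-1.5, 0.125), (-0.5, 0.375), (0.5, 0.375), (1.5, 0.125))
    )


def _singlet(fwhm: float, beta: float) -> tuple[Feature, ...]:
    return (Feature(0.0, 1.0, fwhm, beta),)


def _doublet_of_triplets(J1: float, J2: float, fwhm: float, beta: float):
    """J1 doublet splitting, each line a 1:2:1 triplet with spacing J2."""
    feats = []
    for side in (-J1 / 2, J1 / 2):
        for off, amp in ((-J2, 0.125), (0.0, 0.25), (J2, 0.125)):
            feats.append(Feature(side + off, amp, fwhm, beta))
    return tuple(feats)


def _component(name, mult_specs, nuclei):
    """mult_specs: list of (label, center_ppm, features, proton_weight)."""
    mults = tuple(
        Multiplet(center_ppm=c, features=f, label=lbl, amplitude=w)
        for lbl, c, f, w in mult_specs
    )
    return ComponentModel(
        name=name, multiplets=mults, total_amplitude=float(nuclei), nuclei=nuclei
    )


def make_component_library(
    preset: str, grid: AcquisitionGrid | None = None
) -> list[ComponentModel]:
    """Pure-component hard models for a named scenario.

    Presets
    -------
    ``fig1``
        One component: a doublet of triplets (J = 15 and 10 Hz, six
        features, 1 Hz linewidth) centered at 5 ppm — the worked
        shift-alignment example.
    ``two_standards``
        Two quantifiable internal standards plus a solvent line:
        an aromatic acid (three multiplets, 5 protons), a symmetric
        diester (aromatic singlet + methyl singlet, 10 protons), and a
        solvent singlet.
    ``mock_urine_10``
        Ten simplified metabolite models plus a reference singlet at
        0 ppm (11 components).  Patterns are plausible singlets,
        doublets, triplets and quartets, not spin-system-accurate.
    """
    if preset == "fig1":
        return [
            _component(
                "dt_multiplet",
                [("dt", 5.0, _doublet_of_triplets(15.0, 10.0, 1.0, 0.0), 1.0)],
                nuclei=1,
            )
        ]
    if preset == "two_standards":
        lw, b = 1.2, 0.15
        aromatic_acid = _component(
            "aromatic_acid",
            [
                ("ortho_d", 7.95, _doublet(7.8, lw, b), 2.0),
                ("para_t", 7.62, _triplet(7.5, lw, b), 1.0),
                ("meta_t", 7.49, _triplet(7.7, lw, b), 2.0),
            ],
            nuclei=5,
        )
        diester = _component(
            "diester",
            [
                ("aromatic_s", 8.08, _singlet(lw, b), 4.0),
                ("methyl_s", 3.91, _singlet(lw, b), 6.0),
            ],
            nuclei=10,
        )
        solvent = _component(
            "solvent", [("residual_s", 2.50, _singlet(1.5, 0.3), 1.0)], nuclei=6
        )
        return [aromatic_acid, diester, solvent]
    if preset == "mock_urine_10":
        lw, b = 1.0, 0.1
        specs = [
            ("formate", [("s", 8.45, _singlet(lw, b), 1.0)], 1),
            ("acetate", [("s", 1.92, _singlet(lw, b), 3.0)], 3),
            (
                "citrate",
                [("d1", 2.54, _doublet(15.0, lw, b), 2.0),
                 ("d2", 2.66, _doublet(15.0, lw, b), 2.0)],
                4,
            ),
            (
                "lactate",
                [("d", 1.33, _doublet(7.0, lw, b), 3.0),
                 ("q", 4.11, _quartet(7.0, lw, b), 1.0)],
                4,
            ),
            ("alanine", [("d", 1.48, _doublet(7.2, lw, b), 3.0)], 3),
            ("glutamine", [("t", 2.45, _triplet(7.6, lw, b), 2.0)], 2),
            (
                "creatinine",
                [("s1", 3.04, _singlet(lw, b), 3.0),
                 ("s2", 4.06, _singlet(lw, b), 2.0)],
                5,
            ),
            ("alpha_glucose", [("d", 5.23, _doublet(3.7, lw, b), 1.0)], 1),
            ("beta_glucose", [("d", 4.64, _doublet(7.9, lw, b), 1.0)], 1),
            ("urea", [("s", 5.79, _singlet(2.0, b), 2.0)], 2),
            ("reference", [("s", 0.0, _singlet(0.8, 0.0), 9.0)], 9),
        ]
        return [_component(n, m, h) for n, m, h in specs]
    raise ValueError(f"unknown preset {preset!r}")


def simulate_mixture(
    library: list[ComponentModel],
    concentrations,
    drift_ppm: float = 0.0,
    lw_scale: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: AcquisitionGrid | None = None,
) -> tuple[Spectrum, TruthRecord]:
    """Simulate a mixture spectrum with known ground truth.

    Each component receives a uniform random center drift in
    [-drift_ppm, +drift_ppm] applied to all its multiplets, all
    linewidths are multiplied by ``lw_scale``, and white Gaussian noise
    of standard deviation ``noise_sigma`` is added to the real spectrum.
    Fully deterministic given the seed.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.shape != (len(library),):
        raise ValueError("library and concentrations differ in length")
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")
    if drift_ppm < 0 or lw_scale <= 0 or noise_sigma < 0:
        raise ValueError("invalid perturbation settings")
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(seed)
    drifts = rng.uniform(-drift_ppm, drift_ppm, size=len(library))
    true_comps = []
    for comp, d in zip(library, drifts):
        mults = []
        for m in comp.multiplets:
            feats = tuple(
                replace(f, fwhm_hz=f.fwhm_hz * lw_scale) for f in m.features
            )
            mults.append(replace(m, center_ppm=m.center_ppm + d, features=feats))
        true_comps.append(replace(comp, multiplets=tuple(mults)))
    model = MixtureModel(
        components=true_comps, concentrations=concentrations, grid=grid
    )
    spec = mixture_spectrum(model)
    if noise_sigma > 0:
        spec = Spectrum(
            grid, spec.intensities + rng.normal(0.0, noise_sigma, grid.n_points)
        )
    truth = TruthRecord(
        components=true_comps,
        concentrations=concentrations.copy(),
        drifts_ppm=drifts,
        lw_factors=np.full(len(library), lw_scale),
        noise_sigma=noise_sigma,
        seed=seed,
        grid=grid,
    )
    return spec, truth


def perturb_guess(
    truth: TruthRecord, seed: int = 0, shift_window_ppm: float = 0.02
) -> MixtureModel:
    """Build the misaligned starting guess for an alignment + fit run.

    Multiplet centers are displaced by seeded uniform offsets within
    +-shift_window_ppm and all concentrations are reset to a uniform
    value, leaving structure, linewidths and amplitudes at their true
    values (the pure-component hard model is assumed known).
    """
    rng = np.random.default_rng(seed)
    comps = []
    for comp in truth.components:
        mults = tuple(
            m.shifted(float(rng.uniform(-shift_window_ppm, shift_window_ppm)))
            for m in comp.multiplets
        )
        comps.append(replace(comp, multiplets=mults))
    uniform = np.full(len(comps), 1.0)
    return MixtureModel(components=comps, concentrations=uniform, grid=truth.grid)
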