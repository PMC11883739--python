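"""Staged least-squares optimization of the mixture model.

The fit minimizes the sum of squared pointwise differences between the
experimental spectrum and the model trace on the region mask.  Two
default modes follow common practice for this problem: ``fast`` runs a
single Levenberg-Marquardt pass; ``tight`` precedes it with a
Nelder-Mead simplex stage that walks the parameters toward the global
basin before the gradient refinement.  ``custom`` runs a user-supplied
optimizer sequence (e.g. one simplex followed by two
Levenberg-Marquardt passes for crowded spectra).

By default only concentrations, multiplet centers, linewidths and
Gaussian fractions are free; fine-structure offsets and relative
amplitudes stay frozen, which keeps the covariance between peak
positions and intensities from destabilizing the fit.  Both can be
unfrozen through :class:`FitConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import nnls

from .components import ComponentModel, Feature, Multiplet, component_fid
from .lineshape import Spectrum, spectrum_from_fid
from .mixture import MixtureModel, RegionSet

__all__ = [
    "FitConfig",
    "FitResult",
    "MixtureEvaluator",
    "pack_parameters",
    "unpack_parameters",
    "residual_vector",
    "difference_target_value",
    "estimate_concentrations",
    "run_fit",
]

log = logging.getLogger(__name__)

_METHODS = {"simplex": "nelder", "levenberg_marquardt": "leastsq"}

DEFAULT_BOUNDS = {
    "conc_max_factor": 5.0,  # c_k in [0, factor * guess]
    "center_window_ppm": 0.03,  # multiplet centers around the aligned value
    "offset_window_hz": 2.0,  # fine-structure offsets around the guess
    "fwhm_factors": (0.25, 4.0),  # linewidths relative to the guess
    "rel_amp_window": 0.2,  # +-20% of guess, renormalized per multiplet
}


@dataclass
class FitConfig:
    """Controls for the staged optimization."""

    mode: str = "tight"  # fast | tight | custom
    custom_sequence: tuple[str, ...] = ()
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_iterations: int = 1000  # function evaluations per gradient stage
    simplex_max_iterations: int = 5000
    seed: int = 0
    vary_concentrations: bool = True
    vary_centers: bool = True
    vary_fwhm: bool = True
    vary_beta: bool = True
    vary_offsets: bool = False
    vary_rel_amplitudes: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("fast", "tight", "custom"):
            raise ValueError(f"unknown fit mode {self.mode!r}")
        if self.mode == "custom" and not self.custom_sequence:
            raise ValueError("custom mode requires a non-empty custom_sequence")
        for name in self.custom_sequence:
            if name not in _METHODS:
                raise ValueError(f"unknown optimizer {name!r}")
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds)
        self.bounds = merged

    @property
    def sequence(self) -> tuple[str, ...]:
        if self.mode == "fast":
            return ("levenberg_marquardt",)
        if self.mode == "tight":
            return ("simplex", "levenberg_marquardt")
        return tuple(self.custom_sequence)


@dataclass
class FitResult:
    """Outcome of one staged fit."""

    model: MixtureModel
    target_initial: float
    target_final: float
    residual: np.ndarray
    parameters: dict
    bound_hits: dict
    stage_log: list
    regions: RegionSet

    def __post_init__(self) -> None:
        if self.target_final > self.target_initial * (1 + 1e-12):
            raise ValueError("final target exceeds initial target")


class MixtureEvaluator:
    """Fast masked-trace evaluation of a mixture model.

    Flattens the model once into per-feature arrays so each optimizer
    evaluation is a vectorized FID synthesis plus one FFT, without
    rebuilding the dataclass tree.
    """

    def __init__(self, model: MixtureModel, regions: RegionSet):
        self.model = model
        self.grid = model.grid
        self.regions = regions
        self.masks = regions.masks(self.grid)
        self.mask = np.concatenate(self.masks)

        comps = list(model.components)
        if model.dummy is not None:
            comps = comps + [model.dummy]
        self.all_components = comps
        self.n_quantified = len(model.components)

        mult_conc_idx = []  # index into [c_0..c_{M-1}, 1.0]
        mult_base_scale = []  # A_k * normalized multiplet weight (1 for dummy)
        self.mult_is_dummy = []
        self.mult_centers0 = []
        feat_mult_idx = []
        feat_offsets = []
        feat_rel = []
        feat_fwhm = []
        feat_beta = []
        group_starts = []
        j = 0
        for k, comp in enumerate(comps):
            weights = comp.multiplet_weights()
            dummy = comp.is_dummy
            for m, w in zip(comp.multiplets, weights):
                mult_conc_idx.append(self.n_quantified if dummy else k)
                mult_base_scale.append(1.0 if dummy else comp.total_amplitude * w)
                self.mult_is_dummy.append(dummy)
                self.mult_centers0.append(m.center_ppm)
                group_starts.append(len(feat_offsets))
                for f in m.features:
                    feat_mult_idx.append(j)
                    feat_offsets.append(f.offset_hz)
                    feat_rel.append(f.rel_amplitude)
                    feat_fwhm.append(f.fwhm_hz)
                    feat_beta.append(f.gauss_fraction)
                j += 1
        self.n_multiplets = j
        self.mult_conc_idx = np.array(mult_conc_idx)
        self.mult_base_scale = np.array(mult_base_scale)
        self.feat_mult_idx = np.array(feat_mult_idx)
        self.group_starts = np.array(group_starts)
        self.feat_offsets0 = np.array(feat_offsets)
        self.feat_rel0 = np.array(feat_rel)
        self.feat_fwhm0 = np.array(feat_fwhm)
        self.feat_beta0 = np.array(feat_beta)
        self.n_features = len(feat_offsets)

        sf = self.grid.spectrometer_frequency
        self._carrier = self.grid.carrier_ppm
        self._sf = sf
        self._t = self.grid.times
        self._scale = 2.0 * self.grid.dwell

    def masked_trace(
        self,
        conc: np.ndarray,
        centers_ppm: np.ndarray,
        dummy_amp: np.ndarray,
        offsets: np.ndarray,
        rel: np.ndarray,
        fwhm: np.ndarray,
        beta: np.ndarray,
        renormalize_rel: bool,
    ) -> np.ndarray:
        if renormalize_rel:
            sums = np.add.reduceat(rel, self.group_starts)
            rel = rel / sums[self.feat_mult_idx]
        conc_ext = np.append(conc, 1.0)
        mult_amp = conc_ext[self.mult_conc_idx] * self.mult_base_scale * dummy_amp
        K = mult_amp[self.feat_mult_idx] * rel
        nu = (centers_ppm[self.feat_mult_idx] - self._carrier) * self._sf + offsets
        t = self._t
        phase = np.exp(2j * math.pi * nu[:, None] * t)
        lor = np.exp(-math.pi * fwhm[:, None] * t)
        gau = np.exp(
            -(math.pi**2) * (fwhm[:, None] ** 2) * t**2 / (4.0 * math.log(2.0))
        )
        env = (1.0 - beta[:, None]) * lor + beta[:, None] * gau
        fid = np.einsum("p,pt->t", K, phase * env)
        fid[0] *= 0.5
        spec = (np.fft.fftshift(np.fft.fft(fid)) * self._scale).real[::-1]
        return spec[self.mask]


def pack_parameters(model: MixtureModel, config: FitConfig) -> lmfit.Parameters:
    """Flatten a mixture model into a bounded lmfit parameter record.

    Parameter classes: concentrations ``c_k``, multiplet centers
    ``mc_j``, dummy multiplet amplitudes ``da_j``, and per-feature
    offsets/relative amplitudes/linewidths/Gaussian fractions
    ``fo_i``/``fa_i``/``fw_i``/``fb_i``.  The record is the exact
    inverse image of :func:`unpack_parameters`.
    """
    b = config.bounds
    params = lmfit.Parameters()
    comps = list(model.components)
    if model.dummy is not None:
        comps = comps + [model.dummy]
    for k, c in enumerate(model.concentrations):
        cmax = b["conc_max_factor"] * max(float(c), 1e-12)
        params.add(f"c_{k}", value=float(c), min=0.0, max=cmax,
                   vary=config.vary_concentrations)
    j = 0
    i = 0
    for comp in comps:
        for m in comp.multiplets:
            win = b["center_window_ppm"]
            params.add(
                f"mc_{j}", value=m.center_ppm,
                min=m.center_ppm - win, max=m.center_ppm + win,
                vary=config.vary_centers,
            )
            if comp.is_dummy:
                params.add(f"da_{j}", value=m.amplitude, min=0.0, vary=True)
            for f in m.features:
                ow = b["offset_window_hz"]
                params.add(
                    f"fo_{i}", value=f.offset_hz,
                    min=f.offset_hz - ow, max=f.offset_hz + ow,
                    vary=config.vary_offsets,
                )
                win_a = b["rel_amp_window"]
                params.add(
                    f"fa_{i}", value=f.rel_amplitude,
                    min=f.rel_amplitude * (1 - win_a),
                    max=f.rel_amplitude * (1 + win_a),
                    vary=config.vary_rel_amplitudes,
                )
                lo, hi = b["fwhm_factors"]
                params.add(
                    f"fw_{i}", value=f.fwhm_hz,
                    min=lo * f.fwhm_hz, max=hi * f.fwhm_hz,
                    vary=config.vary_fwhm,
                )
                params.add(f"fb_{i}", value=f.gauss_fraction, min=0.0, max=1.0,
                           vary=config.vary_beta)
                i += 1
            j += 1
    return params


def unpack_parameters(params: lmfit.Parameters, template: MixtureModel) -> MixtureModel:
    """Rebuild a mixture model from a flat parameter record.

    The template provides the structure (component/multiplet/feature
    layout, names, nuclei); parameter values override the numbers.
    Relative amplitudes are renormalized per multiplet.
    """
    comps_in = list(template.components)
    if template.dummy is not None:
        comps_in = comps_in + [template.dummy]
    conc = np.array(
        [float(params[f"c_{k}"].value) for k in range(len(template.components))]
    )
    new_comps: list[ComponentModel] = []
    j = 0
    i = 0
    for comp in comps_in:
        mults = []
        for m in comp.multiplets:
            center = float(params[f"mc_{j}"].value)
            amp = m.amplitude
            if comp.is_dummy:
                amp = max(float(params[f"da_{j}"].value), 1e-300)
            feats = []
            for _f in m.features:
                feats.append(
                    Feature(
                        offset_hz=float(params[f"fo_{i}"].value),
                        rel_amplitude=float(params[f"fa_{i}"].value),
                        fwhm_hz=float(params[f"fw_{i}"].value),
                        gauss_fraction=float(params[f"fb_{i}"].value),
                    )
                )
                i += 1
            mults.append(
                Multiplet(center_ppm=center, features=tuple(feats), label=m.label,
                          amplitude=amp)
            )
            j += 1
        new_comps.append(replace(comp, multiplets=tuple(mults)))
    out = template.copy()
    if template.dummy is not None:
        out.dummy = new_comps.pop()
    out.components = new_comps
    out.concentrations = conc
    return out


def residual_vector(
    model: MixtureModel, exp: Spectrum, regions: RegionSet | None = None
) -> np.ndarray:
    """exp - model on the region mask; its sum of squares is the target."""
    if exp.grid != model.grid:
        raise ValueError("model and experimental grids differ")
    if regions is None:
        regions = RegionSet.full_axis(model.grid)
    ev = MixtureEvaluator(model, regions)
    conc = model.concentrations
    centers = np.array(ev.mult_centers0)
    dummy_amp = np.array(
        [m.amplitude if d else 1.0
         for m, d in zip(_all_multiplets(model), ev.mult_is_dummy)]
    )
    trace = ev.masked_trace(
        conc, centers, dummy_amp, ev.feat_offsets0, ev.feat_rel0, ev.feat_fwhm0,
        ev.feat_beta0, renormalize_rel=False,
    )
    return exp.intensities[ev.mask] - trace


def difference_target_value(
    model: MixtureModel, exp: Spectrum, regions: RegionSet | None = None
) -> float:
    r = residual_vector(model, exp, regions)
    return float(np.dot(r, r))


def estimate_concentrations(
    model: MixtureModel,
    exp: Spectrum,
    regions: RegionSet | None = None,
    broaden_hz: float = 0.0,
) -> np.ndarray:
    """Linear nonnegative least-squares estimate of the concentrations.

    With all shape parameters held fixed the mixture trace is linear in
    the concentrations, so c solves min ||exp - sum_k c_k S_k|| with
    c >= 0 directly.  With ``broaden_hz`` both the data and the
    component traces are Gaussian-broadened first; convolution is linear
    and area-preserving, so the estimate stays valid while becoming
    insensitive to chemical-shift misalignments smaller than the
    broadening — the coarse calibration used before alignment.  A
    present dummy component is treated as a fixed contribution.
    """
    if regions is None:
        regions = RegionSet.full_axis(model.grid)
    idx = regions.mask(model.grid)
    sigma_pts = broaden_hz * model.grid.n_points / model.grid.spectral_width

    def prep(y: np.ndarray) -> np.ndarray:
        if sigma_pts > 0:
            y = gaussian_filter1d(y, sigma_pts, mode="nearest")
        return y[idx]

    cols = []
    for comp in model.components:
        spec = spectrum_from_fid(component_fid(comp, model.grid), model.grid)
        cols.append(prep(spec.intensities))
    A = np.column_stack(cols)
    b = exp.intensities.astype(float)
    if model.dummy is not None:
        dspec = spectrum_from_fid(component_fid(model.dummy, model.grid), model.grid)
        b = b - dspec.intensities
    conc, _ = nnls(A, prep(b))
    return conc


def _all_multiplets(model: MixtureModel):
    for comp in model.components:
        yield from comp.multiplets
    if model.dummy is not None:
        yield from model.dummy.multiplets


def _param_arrays(params: lmfit.Parameters, ev: MixtureEvaluator):
    conc = np.array([params[f"c_{k}"].value for k in range(ev.n_quantified)], float)
    centers = np.array([params[f"mc_{j}"].value for j in range(ev.n_multiplets)], float)
    dummy_amp = np.array(
        [params[f"da_{j}"].value if ev.mult_is_dummy[j] else 1.0
         for j in range(ev.n_multiplets)],
        float,
    )
    offsets = np.array([params[f"fo_{i}"].value for i in range(ev.n_features)], float)
    rel = np.array([params[f"fa_{i}"].value for i in range(ev.n_features)], float)
    fwhm = np.array([params[f"fw_{i}"].value for i in range(ev.n_features)], float)
    beta = np.array([params[f"fb_{i}"].value for i in range(ev.n_features)], float)
    return conc, centers, dummy_amp, offsets, rel, fwhm, beta


def run_fit(
    model: MixtureModel,
    exp: Spectrum,
    regions: RegionSet | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Execute the configured optimizer sequence on the mixture model.

    Every stage starts from the best parameters seen so far and can only
    improve the reported target; a failing stage is logged and its
    result discarded.
    """
    if config is None:
        config = FitConfig()
    if regions is None:
        regions = RegionSet.full_axis(model.grid)
    ev = MixtureEvaluator(model, regions)
    exp_masked = exp.intensities[ev.mask]
    if not np.any(exp_masked):
        raise ValueError("experimental spectrum is all zero on the region mask")

    renorm = config.vary_rel_amplitudes

    def residual(p: lmfit.Parameters) -> np.ndarray:
        conc, centers, dummy_amp, offsets, rel, fwhm, beta = _param_arrays(p, ev)
        trace = ev.masked_trace(
            conc, centers, dummy_amp, offsets, rel, fwhm, beta, renorm
        )
        return exp_masked - trace

    def target(p: lmfit.Parameters) -> float:
        r = residual(p)
        return float(np.dot(r, r))

    params = pack_parameters(model, config)
    best_params = params
    best_target = target(params)
    target_initial = best_target
    stage_log = []
    for stage_no, name in enumerate(config.sequence, start=1):
        method = _METHODS[name]
        max_nfev = (
            config.simplex_max_iterations if name == "simplex"
            else config.max_iterations
        )
        entry = {"stage": stage_no, "optimizer": name, "target_initial": best_target}
        try:
            result = lmfit.minimize(
                residual, best_params.copy(), method=method, max_nfev=max_nfev,
                calc_covar=False,
            )
            stage_target = target(result.params)
            entry["success"] = bool(result.success)
            entry["nfev"] = int(result.nfev)
            entry["message"] = str(result.message)
        except Exception as exc:  # optimizer failure: keep best-so-far
            log.warning("stage %d (%s) failed: %s", stage_no, name, exc)
            entry["success"] = False
            entry["message"] = str(exc)
            stage_target = best_target
            result = None
        if result is not None and stage_target <= best_target:
            best_params = result.params
            best_target = stage_target
        entry["target_final"] = best_target
        log.info(
            "fit stage %d (%s): target %.6g -> %.6g",
            stage_no, name, entry["target_initial"], best_target,
        )
        stage_log.append(entry)

    fitted = unpack_parameters(best_params, model)
    final_residual = residual(best_params)
    bound_hits = {}
    for nm, p in best_params.items():
        if not p.vary:
            continue
        span = (p.max - p.min) if np.isfinite(p.max) and np.isfinite(p.min) else 1.0
        tol = 1e-6 * max(abs(span), 1e-12)
        at_min = np.isfinite(p.min) and abs(p.value - p.min) <= tol
        at_max = np.isfinite(p.max) and abs(p.value - p.max) <= tol
        bound_hits[nm] = bool(at_min or at_max)
    return FitResult(
        model=fitted,
        target_initial=target_initial,
        target_final=best_target,
        residual=final_residual,
        parameters={nm: float(p.value) for nm, p in best_params.items()},
        bound_hits=bound_hits,
        stage_log=stage_log,
        regions=regions,
    )
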