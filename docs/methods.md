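# Methods

This note defines the model implemented by `nmrihm`, the meaning and
default treatment of every parameter, the scope of the synthetic data
generator, the numerical choices that matter for reproducing results,
and the known limitations.

## 1. Signal model

### 1.1 Lineshape

Every spectral line is a pseudo-Voigt profile synthesized in the time
domain.  For a line of integrated intensity `K`, offset `ν` (Hz from
the carrier), full width at half maximum `Γ` (Hz) and Gaussian fraction
`β ∈ [0, 1]`, the free-induction decay is

```
s(t) = K · exp(2πiνt) · [(1−β)·exp(−πΓt) + β·exp(−π²Γ²t² / (4 ln 2))]
```

Both envelopes are parameterized so that the frequency-domain FWHM is
`Γ`: the Lorentzian envelope `exp(−πΓt)` transforms to a Lorentzian of
FWHM `Γ`, and the Gaussian envelope to a Gaussian of FWHM `Γ`.  `β = 0`
is pure Lorentzian, `β = 1` pure Gaussian; the profile is the convex
combination of the two, not a true Voigt convolution.  The sum form
keeps the area exactly `K` for every `β` and is linear in `β`.

The FID is sampled at `t_j = j / SW` for `j = 0 … N−1` (`SW` = spectral
width in Hz, `N` = points).  The spectrum is obtained by discrete
Fourier transform with the first point halved (the standard correction
that removes the constant baseline offset of a one-sided DFT), scaled
by `2·dwell`, shifted to a centered frequency axis, and read in
descending-ppm order (NMR convention).  With this normalization:

* trapezoidal integral of the real spectrum over the full axis = `K`
  (up to truncation of tails at the window edges),
* peak height of a pure Lorentzian = `2K/(πΓ)`,
* FWHM = `Γ`.

These closed forms are the lineshape test oracles.

### 1.2 Components and mixtures

A **component** is a named set of **multiplets**.  A multiplet has one
chemical-shift center (ppm) and fixed fine-structure **features**
(offset in Hz from the center, relative amplitude, `Γ`, `β`), so a
J-coupling pattern moves rigidly when the center moves.  Feature
relative amplitudes are normalized to sum to 1 within each multiplet.
Multiplet weights (typically proton counts) are normalized across the
component, so the component spectrum integrates to the component's
total amplitude `A_k` (by default its proton count `H_k`).

The mixture model is `M(ν) = Σ_k c_k · S_k(ν)`; concentrations `c_k`
are the only inter-component degrees of freedom.  An optional *dummy
component* — individually scaled extra lines — absorbs unmodeled
interferents; it is fitted but excluded from quantification.

Components serialize to a tab-separated peak-list dialect (one feature
per row, `# amplitude:` and `# multiplet_amplitude <label>:` comments)
with 17-significant-digit floats so round trips are bit-exact.

## 2. Shift alignment

Chemical shifts drift with solution conditions, so the guess model is
misaligned with the measurement.  The pointwise least-squares target is
rugged in the shifts: partial superposition of fine-structure features
creates local minima that trap gradient optimizers.  Alignment instead
minimizes the cumulative-integral target

```
φ_algn = Σ_i ( cumsum(exp)_i − cumsum(model)_i )²
```

computed independently per fit region (so an offset in one region
cannot leak into another through the running total).  On the worked
doublet-of-triplets example (J = 15/10 Hz, six 1 Hz lines, 700 MHz,
scanned ±0.05 ppm), this target has a single local minimum at the true
shift while the pointwise target has several — the property the
acceptance scan checks.

`align_shifts` minimizes φ_algn with Levenberg–Marquardt over one shift
per multiplet (or one rigid shift per component), bounded by
`max_delta_ppm` (default ±0.05 ppm).  Because φ_algn compares running
integrals, a wrong overall concentration biases the shift optimum, so
by default the step also calibrates concentrations:

1. a nonnegative least-squares solve on Gaussian-broadened traces
   (broadening ≥ the alignment window, default
   `max(5 Hz, 2·max_delta_ppm·SF)`) seeds the concentrations —
   convolution is linear and area-preserving, so the linear estimate
   stays valid while becoming insensitive to misalignment below the
   broadening width;
2. per-component scale factors are then optimized *jointly* with the
   shifts on the same cumulative residual.  (A fixed mis-scaled
   concentration displaces the shift optimum; alternating sharp
   re-estimation and shift optimization does not contract, which is
   why the joint fit is used.)

The final φ is never allowed to exceed the initial one; if the
optimizer fails, the zero-shift model is returned.

The diagnostic scanner `scan_shift_surface` rescales the model trace to
the experimental masked sum at each trial shift (`match_scale=True`),
because the scan is a position diagnostic and an amplitude mismatch
would drag the integral-target argmin sideways.  When the experimental
amplitude already matches the model the rescaling is the identity.

## 3. Staged fitting

`run_fit` minimizes the pointwise target `Σ (exp − model)²` on the
region mask.  Optimizer sequences:

* `fast` — Levenberg–Marquardt (MINPACK `leastsq` via lmfit);
* `tight` — Nelder–Mead simplex, then Levenberg–Marquardt;
* `custom` — any user-given sequence of the two.

Each stage starts from the best parameters seen so far; a stage that
worsens the target (or raises) is discarded, so per-stage reported
targets are monotone non-increasing.  Function-evaluation caps: 1000
per gradient stage, 5000 for the simplex.

Free parameters and default bounds:

| parameter | default | bounds |
| --- | --- | --- |
| concentrations `c_k` | free | `[0, 5 × guess]` |
| multiplet centers | free | guess ± 0.03 ppm |
| linewidths `Γ` | free | `[0.25, 4] × guess` |
| Gaussian fractions `β` | free | `[0, 1]` |
| feature offsets | frozen | guess ± 2 Hz when freed |
| relative amplitudes | frozen | guess ± 20 %, renormalized, when freed |
| dummy line amplitudes | free | `≥ 0` |

Offsets and relative amplitudes are frozen by default because they are
strongly covariant with centers and concentrations; freeing them is a
deliberate user decision for imperfect hard models.

The fit result records initial/final targets, the residual trace,
per-stage logs, and which parameters ended at a bound (a flag for an
under-sized bound or a mis-specified model).

## 4. Quantification

Signal area is proportional to amount of substance times contributing
protons, so relative molar amounts are `amount_k ∝ c_k·A_k/H_k`,
normalized to fractions over the non-dummy components.  For purity
checks against a weighed internal standard:
`amount_from_mass(m, M, purity)` = `m·purity/M`, the theoretical
intensity ratio is the ratio of weighed amounts, and the purity factor
is `κ = observed ratio / theoretical ratio`.

`classical_integration` implements the baseline method — trapezoidal
integration of user-assigned, non-overlapping regions, per-proton
normalized — and `compare_with_integration` reports absolute
composition differences in percent.  A centered window of `w`
linewidths captures `(2/π)·arctan(w)` of a Lorentzian's area (99 % at
`w = 64`), which bounds the accuracy of narrow-window integration.

## 5. Synthetic data generator

`simulate_mixture` builds a ground-truth mixture from a component
library and applies, in order: a per-component uniform random center
drift in `±drift_ppm` (rigid across the component's multiplets), a
global multiplicative linewidth factor, and additive white Gaussian
noise on the real frequency-domain trace.  All randomness comes from
one `numpy.random.default_rng(seed)`, so spectra are bit-reproducible.
`perturb_guess` displaces each multiplet independently and resets
concentrations to a uniform value, producing the realistic starting
point the alignment step exists for.

Scope and deliberate simplifications:

* noise is added in the frequency domain (white in both domains; a
  physical acquisition correlates noise with apodization and phasing,
  which are outside the model);
* presets (`fig1`, `two_standards`, `mock_urine_10`) use plausible
  first-order patterns (singlets, doublets, triplets, quartets, a
  doublet of triplets), not spin-system-accurate simulations — they
  exercise the pipeline, they do not predict real spectra;
* no baseline distortion, phase error, solvent suppression artifacts,
  or ¹³C satellites are simulated.

## 6. Numerical choices

* Time-domain synthesis + FFT rather than closed-form frequency-domain
  profiles: one vectorized `exp`/`einsum` pass plus one FFT evaluates
  the whole model, and every line is smooth in its parameters.
* First-point halving and `2·dwell` scaling fix normalization so the
  trapezoidal integral equals `K` (Section 1.1).
* The alignment residual vector handed to Levenberg–Marquardt is the
  per-region cumulative-sum difference itself (length = number of
  masked points), not the scalar φ — this preserves the least-squares
  structure the algorithm expects.
* Nonnegative linear concentration estimates use `scipy.optimize.nnls`;
  broadening uses `scipy.ndimage.gaussian_filter1d` (σ converted from
  Hz to points as `σ·N/SW`, `nearest` boundary).
* Optimization is delegated to `lmfit` (`leastsq`, `nelder`) with
  covariance estimation disabled; all iteration caps are function
  evaluation counts (`max_nfev`).
* Reports are written with sorted keys and fixed float formatting, so
  reruns are byte-identical.

## 7. Limitations

* **Sampling**: lineshapes must be resolved by the acquisition grid
  (FWHM ≳ 2 grid spacings).  On under-resolved grids the sampled trace
  — and hence the cumulative target — oscillates with the sub-grid line
  position, and alignment can stall in spurious minima.  Real
  acquisitions satisfy this; coarse synthetic grids may not.
* The pseudo-Voigt sum is an approximation to the Voigt convolution;
  for strongly mixed profiles the fitted `β` compensates in shape but
  the wings differ slightly.
* Alignment assumes the hard model's internal structure is correct;
  rigid multiplet motion cannot follow J-coupling changes or
  higher-order (strong-coupling) pattern distortions.
* The cumulative-integral target is robust to misalignment but not to
  gross amplitude errors outside the calibrated scale factors, nor to
  large unmodeled signals inside the fit regions (use regions and/or a
  dummy component).
* Concentration accuracy at low SNR is statistics-limited: with free
  linewidth and `β`, weak multiplets at SNR ≈ 100 show a few percent
  scatter even when the optimizer reaches the noise floor (observed in
  the seeded recovery suite: median ≈ 1 %, worst components ≈ 8 %).
* One spectrum, one fit: no multi-spectrum joint fitting, no 2D data,
  no automatic peak picking to build hard models from pure-compound
  spectra.
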