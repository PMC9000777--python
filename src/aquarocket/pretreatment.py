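"""Spectral pretreatment operators and the aquaphotomic normalization.

Operators
---------
* ``moving_average`` -- centered boxcar smoothing (window in points).
* ``sg_derivative`` -- Savitzky-Golay polynomial smoothing / differentiation;
  derivatives are scaled by the actual nm grid spacing (units AU * nm^-d).
* ``norris_gap`` -- gap-segment first derivative: the symmetric finite
  difference over a fixed wavelength gap, classically used to sharpen
  overlapped NIR bands.
* ``snv`` -- Standard Normal Variate: per-spectrum standardization.
* ``msc`` -- Multiplicative Scatter Correction: per-spectrum affine
  regression on a reference spectrum, then inversion of slope and offset.
* ``aqua_normalize`` -- column-wise standardization over the whole spectra
  set, z(lambda) = (A(lambda) - mu(lambda)) / sigma(lambda); this is the
  scale on which water absorbance spectral patterns are compared.

All windowed operators trim the affected edge points rather than padding:
padding would invent data next to the 1300/1600 nm boundaries where the
water absorbance bands of interest live.  Every operator preserves sample
metadata unchanged and never reorders rows.

Named pipeline presets bundle the three standard chains (exploratory PCA,
damage-index PLS, aquagram construction); arbitrary chains can be declared
in YAML as an ordered list of ``{kind, params}`` maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence
import warnings

import numpy as np
from scipy.signal import savgol_coeffs

from .dataset import SpectralDataError, SpectralDataset
from . import spectra_io


class PretreatmentError(ValueError):
    """Raised for invalid pretreatment parameters or degenerate inputs."""


@dataclass(frozen=True)
class NormalizationStats:
    """Per-wavelength mean/sd recorded by :func:`aqua_normalize` so that new
    spectra can be projected into (or recovered from) the normalized space."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape:
            raise PretreatmentError("mu and sigma must have equal length")
        if np.any(self.sigma < 0):
            raise PretreatmentError("sigma must be non-negative")


def _check_window(window: int, n: int, name: str = "window") -> None:
    if window < 3 or window % 2 == 0:
        raise PretreatmentError(f"{name} must be odd and >= 3, got {window}")
    if window > n:
        raise PretreatmentError(f"{name} {window} exceeds grid size {n}")


def moving_average(ds: SpectralDataset, window: int) -> SpectralDataset:
    """Centered boxcar mean per spectrum; edges trimmed by (window-1)/2."""
    _check_window(window, ds.n_wavelengths)
    h = (window - 1) // 2
    kernel = np.full(window, 1.0 / window)
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, ds.values)
    return ds.replace(wavelengths=ds.wavelengths[h : ds.n_wavelengths - h], values=out)


def sg_derivative(
    ds: SpectralDataset, window: int, polyorder: int, deriv: int
) -> SpectralDataset:
    """Savitzky-Golay smoothing/derivative; exact on polynomials up to
    ``polyorder``.  Requires a uniform grid; the derivative is scaled by the
    nm spacing so values are comparable across grids."""
    _check_window(window, ds.n_wavelengths)
    if not 0 <= deriv <= polyorder:
        raise PretreatmentError(
            f"derivative order {deriv} must satisfy 0 <= deriv <= polyorder={polyorder}"
        )
    if polyorder >= window:
        raise PretreatmentError(f"polyorder {polyorder} must be < window {window}")
    delta = ds.wavelength_spacing()  # raises on nonuniform grids
    coeffs = savgol_coeffs(window, polyorder, deriv=deriv, delta=delta, use="dot")
    h = (window - 1) // 2
    out = np.apply_along_axis(lambda r: np.convolve(r, coeffs[::-1], mode="valid"), 1, ds.values)
    return ds.replace(wavelengths=ds.wavelengths[h : ds.n_wavelengths - h], values=out)


def norris_gap(ds: SpectralDataset, gap: int, deriv: int = 1) -> SpectralDataset:
    """Gap-segment first derivative.

    ``gap`` is the total span in points (odd), so the symmetric difference
    uses g = (gap - 1) // 2 points on each side:
    d(lambda_i) = (A_{i+g} - A_{i-g}) / (lambda_{i+g} - lambda_{i-g}).
    The convention for "gap size" varies between chemometrics packages; the
    total-span reading is used here and ``gap`` is fully configurable.
    """
    if deriv != 1:
        raise PretreatmentError("only the first Norris gap derivative is supported")
    if gap < 3 or gap % 2 == 0:
        raise PretreatmentError(f"gap must be odd and >= 3, got {gap}")
    g = (gap - 1) // 2
    n = ds.n_wavelengths
    if 2 * g >= n:
        raise PretreatmentError(f"gap {gap} too large for grid of {n} points")
    wl = ds.wavelengths
    num = ds.values[:, 2 * g :] - ds.values[:, : n - 2 * g]
    den = wl[2 * g :] - wl[: n - 2 * g]
    return ds.replace(wavelengths=wl[g : n - g], values=num / den)


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard Normal Variate: each spectrum to zero mean, unit sd."""
    mean = ds.values.mean(axis=1, keepdims=True)
    sd = ds.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise PretreatmentError(f"constant spectrum (sample {flat[0]}): SNV undefined")
    return ds.replace(values=(ds.values - mean) / sd)


def msc(
    ds: SpectralDataset, reference: Optional[np.ndarray] = None
) -> tuple[SpectralDataset, np.ndarray]:
    """Multiplicative Scatter Correction.

    Each spectrum x is regressed on the reference (dataset mean spectrum by
    default): x ~ a * ref + b by ordinary least squares over wavelengths, and
    corrected to (x - b) / a.  Returns the corrected dataset and the
    ``n_spectra x 2`` array of fitted ``(a, b)`` pairs.
    """
    if reference is None:
        if ds.n_spectra < 2:
            raise PretreatmentError("MSC needs >= 2 spectra when no reference is given")
        reference = ds.values.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ds.n_wavelengths,):
        raise PretreatmentError("reference length does not match the wavelength grid")
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise PretreatmentError("MSC reference has zero variance")
    a = (ds.values - ds.values.mean(axis=1, keepdims=True)) @ ref_c / denom
    b = ds.values.mean(axis=1) - a * reference.mean()
    if np.any(a <= 0):
        warnings.warn(
            f"MSC fitted nonpositive slope for sample(s) "
            f"{np.flatnonzero(a <= 0).tolist()}; corrected spectra are suspect",
            RuntimeWarning,
            stacklevel=2,
        )
    corrected = (ds.values - b[:, None]) / a[:, None]
    return ds.replace(values=corrected), np.column_stack([a, b])


def aqua_normalize(ds: SpectralDataset) -> tuple[SpectralDataset, NormalizationStats]:
    """Column-wise standardization z = (A - mu) / sigma over the spectra set.

    mu and sigma are the per-wavelength mean and standard deviation of all
    spectra.  Returns the normalized dataset and the stats, so further
    spectra can be projected into the same normalized space.
    """
    if ds.n_spectra < 2:
        raise PretreatmentError("normalization needs >= 2 spectra")
    mu = ds.values.mean(axis=0)
    sigma = ds.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        raise PretreatmentError(
            f"zero spectral variance at {ds.wavelengths[zero[0]]:.2f} nm"
        )
    stats = NormalizationStats(mu=mu, sigma=sigma, n=ds.n_spectra)
    return ds.replace(values=(ds.values - mu) / sigma), stats


def aqua_project(ds: SpectralDataset, stats: NormalizationStats) -> SpectralDataset:
    """Project spectra into an existing normalized space."""
    return ds.replace(values=(ds.values - stats.mu) / stats.sigma)


def aqua_denormalize(ds: SpectralDataset, stats: NormalizationStats) -> SpectralDataset:
    """Inverse of :func:`aqua_normalize`: x = z * sigma + mu."""
    return ds.replace(values=ds.values * stats.sigma + stats.mu)


# ---------------------------------------------------------------------------
# declarative pipeline steps and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PretreatStep:
    """One declarative pretreatment step: ``kind`` plus its parameters."""

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = (
        "moving_average",
        "sg_derivative",
        "norris_gap",
        "snv",
        "msc",
        "aqua_normalize",
        "truncate",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise PretreatmentError(f"unknown pretreatment kind {self.kind!r}")


#: The three standard chains:
#: * ``pca_prep``: boxcar(15) -> Norris gap first derivative (span 21) on the
#:   1300-1600 nm first overtone of water, for exploratory PCA;
#: * ``pls_prep``: SNV -> Savitzky-Golay 2nd derivative (window 11, order 2),
#:   for damage-index PLS regression;
#: * ``aqua_prep``: Savitzky-Golay 2nd derivative (window 21, order 2) ->
#:   MSC -> truncation to 1300-1600 nm -> column standardization, for
#:   aquagram construction (truncation placed before the normalization
#:   statistics so mu/sigma are estimated on the analysis range only).
PRESETS: dict[str, tuple[PretreatStep, ...]] = {
    "pca_prep": (
        PretreatStep("moving_average", {"window": 15}),
        PretreatStep("norris_gap", {"gap": 21, "deriv": 1}),
        PretreatStep("truncate", {"lo": 1300.0, "hi": 1600.0}),
    ),
    "pls_prep": (
        PretreatStep("snv"),
        PretreatStep("sg_derivative", {"window": 11, "polyorder": 2, "deriv": 2}),
    ),
    "aqua_prep": (
        PretreatStep("sg_derivative", {"window": 21, "polyorder": 2, "deriv": 2}),
        PretreatStep("msc"),
        PretreatStep("truncate", {"lo": 1300.0, "hi": 1600.0}),
        PretreatStep("aqua_normalize"),
    ),
    # alternative damage-index chain for heterogeneous (second-harvest) data
    "pls_prep_smooth": (
        PretreatStep("moving_average", {"window": 15}),
        PretreatStep("norris_gap", {"gap": 21, "deriv": 1}),
    ),
}


def apply_step(ds: SpectralDataset, step: PretreatStep):
    """Apply one step; returns (dataset, side_info or None)."""
    p = step.params
    if step.kind == "moving_average":
        return moving_average(ds, **p), None
    if step.kind == "sg_derivative":
        return sg_derivative(ds, **p), None
    if step.kind == "norris_gap":
        return norris_gap(ds, **p), None
    if step.kind == "snv":
        return snv(ds), None
    if step.kind == "msc":
        out, coeffs = msc(ds, **p)
        return out, coeffs
    if step.kind == "aqua_normalize":
        out, stats = aqua_normalize(ds)
        return out, stats
    if step.kind == "truncate":
        return spectra_io.truncate(ds, **p), None
    raise PretreatmentError(f"unknown pretreatment kind {step.kind!r}")


def apply_pipeline(
    ds: SpectralDataset, steps: Sequence[PretreatStep] | str
) -> tuple[SpectralDataset, dict]:
    """Apply a chain of steps (or a preset name).

    Returns the final dataset and a dict of side information keyed by
    ``"{index}:{kind}"`` (MSC coefficients, normalization stats).
    """
    if isinstance(steps, str):
        if steps not in PRESETS:
            raise PretreatmentError(
                f"unknown preset {steps!r}; available: {sorted(PRESETS)}"
            )
        steps = PRESETS[steps]
    side: dict[str, object] = {}
    for i, step in enumerate(steps):
        ds, info = apply_step(ds, step)
        if info is not None:
            side[f"{i}:{step.kind}"] = info
    return ds, side


def steps_from_config(config: Sequence[dict]) -> list[PretreatStep]:
    """Build a step chain from a YAML-style list of {kind, params} maps."""
    steps = []
    for entry in config:
        if "kind" not in entry:
            raise PretreatmentError(f"pipeline entry missing 'kind': {entry}")
        params = {k: v for k, v in entry.items() if k != "kind"}
        params.update(params.pop("params", {}) if isinstance(params.get("params"), dict) else {})
        steps.append(PretreatStep(entry["kind"], params))
    return steps
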