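"""Spectral conditioning chain: QC, baseline removal, smoothing, normalization.

The chain runs in fixed order: (1) quality control rejects oversaturated
or non-finite spectra; (2) an iterative modified polynomial fit
(Lieber-style peak clipping) removes the degree-4 autofluorescence
background; (3) Savitzky-Golay smoothing suppresses detector noise;
(4) intensities are normalized over the 200-1800 cm^-1 region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_filter

from .core import SpectraCohort, Spectrum
from .errors import ConfigError, DegenerateInputError, StateError

REJECT_NONFINITE = "nonfinite"
REJECT_SATURATED = "saturated"


@dataclass
class PreprocessConfig:
    """Tunables of the conditioning chain.

    saturation_ceiling_quantile
        Fraction of the cohort-wide maximum intensity above which a point
        counts as saturated.
    saturation_run_length
        Minimum number of consecutive saturated points that rejects a spectrum.
    baseline_degree
        Polynomial degree of the autofluorescence model (default 4).
    sg_window, sg_polyorder
        Savitzky-Golay window (odd number of points) and fit order.
    normalization
        'area' (unit trapezoidal integral, default), 'vector' (unit L2 norm)
        or 'minmax' (range [0, 1]) over ``normalization_region``.
    """

    saturation_ceiling_quantile: float = 0.99
    saturation_run_length: int = 12
    baseline_degree: int = 4
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    sg_window: int = 11
    sg_polyorder: int = 3
    normalization: str = "area"
    normalization_region: tuple[float, float] = (200.0, 1800.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ConfigError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must exceed sg_polyorder")
        if self.baseline_degree < 1:
            raise ConfigError("baseline_degree must be >= 1")
        if self.normalization not in ("area", "vector", "minmax"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if not 0.0 < self.saturation_ceiling_quantile <= 1.0:
            raise ConfigError("saturation_ceiling_quantile must be in (0, 1]")


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def qc_filter(
    cohort: SpectraCohort, config: PreprocessConfig | None = None
) -> tuple[SpectraCohort, list[tuple[str, str]]]:
    """Partition a cohort into kept spectra and rejected (id, reason) pairs.

    A spectrum is rejected iff it contains any non-finite value or a run of
    at least ``saturation_run_length`` points at or above the ceiling
    (cohort-wide maximum intensity times ``saturation_ceiling_quantile``).
    """
    config = config or PreprocessConfig()
    if len(cohort) == 0:
        raise DegenerateInputError("cannot QC an empty cohort")
    finite_maxima = [
        float(np.nanmax(s.intensity)) for s in cohort.spectra if np.isfinite(s.intensity).any()
    ]
    ceiling = config.saturation_ceiling_quantile * max(finite_maxima)
    kept, rejected = [], []
    for s in cohort.spectra:
        if not np.isfinite(s.intensity).all():
            rejected.append((s.meta.spectrum_id, REJECT_NONFINITE))
        elif _longest_run(s.intensity >= ceiling) >= config.saturation_run_length:
            rejected.append((s.meta.spectrum_id, REJECT_SATURATED))
        else:
            clone = s.with_intensity(s.intensity, new_state="qc_passed")
            kept.append(clone)
    patients = {p: g for p, g in cohort.patients.items() if any(s.meta.patient_id == p for s in kept)}
    return SpectraCohort(kept, patients), rejected


def remove_baseline(
    spectrum: Spectrum, config: PreprocessConfig | None = None
) -> tuple[Spectrum, Spectrum]:
    """Subtract the autofluorescence background; returns (corrected, baseline).

    Iterative modified polyfit: fit a degree-``baseline_degree`` polynomial,
    clip the working signal to the fit wherever it lies above it, and
    refit until the clipped signal changes by less than ``baseline_tol``
    (relative to the signal maximum) or ``baseline_max_iter`` iterations.
    Exact when the true background is a polynomial of at most that degree
    and peaks cover a minority of points.  The corrected spectrum is
    floored at zero.
    """
    config = config or PreprocessConfig()
    if spectrum.has_state("baseline_corrected"):
        raise StateError(f"spectrum {spectrum.meta.spectrum_id!r} is already baseline-corrected")
    y = spectrum.intensity
    if y.size < config.baseline_degree + 1:
        raise DegenerateInputError("fewer points than polynomial degree + 1")
    x = np.linspace(-1.0, 1.0, y.size)  # scaled abscissa for conditioning
    scale = float(np.max(np.abs(y))) or 1.0
    work = y.copy()
    fit_vals = work
    for _ in range(config.baseline_max_iter):
        coef = npoly.polyfit(x, work, config.baseline_degree)
        fit_vals = npoly.polyval(x, coef)
        clipped = np.minimum(work, fit_vals)
        if float(np.max(np.abs(clipped - work))) / scale < config.baseline_tol:
            work = clipped
            break
        work = clipped
    corrected = np.clip(y - fit_vals, 0.0, None)
    corrected_s = spectrum.with_intensity(corrected, new_state="baseline_corrected")
    baseline_meta = spectrum.meta.copy()
    baseline_meta.spectrum_id += ":baseline"
    baseline_s = Spectrum(grid=spectrum.grid, intensity=fit_vals, meta=baseline_meta)
    return corrected_s, baseline_s


def smooth(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay smoothing; edges use the boundary polynomial fits."""
    config = config or PreprocessConfig()
    if config.sg_window > spectrum.intensity.size:
        raise ConfigError("sg_window exceeds spectrum length")
    y = savgol_filter(spectrum.intensity, config.sg_window, config.sg_polyorder, mode="interp")
    return spectrum.with_intensity(y, new_state="smoothed")


def normalize(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Normalize intensities over ``normalization_region`` (default 200-1800)."""
    config = config or PreprocessConfig()
    w = spectrum.grid.values
    lo, hi = config.normalization_region
    mask = (w >= lo) & (w <= hi)
    if not mask.any():
        raise ConfigError("normalization region does not intersect the grid")
    y = spectrum.intensity
    region = y[mask]
    if not np.any(region != 0.0):
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    if config.normalization == "area":
        area = float(np.trapezoid(region, w[mask]))
        if area == 0.0:
            raise DegenerateInputError("zero integral over normalization region")
        out = y / area
    elif config.normalization == "vector":
        out = y / float(np.linalg.norm(region))
    else:  # minmax
        mn, mx = float(region.min()), float(region.max())
        if mx == mn:
            raise DegenerateInputError("constant spectrum cannot be min-max normalized")
        out = (y - mn) / (mx - mn)
    return spectrum.with_intensity(out, new_state="normalized")


def preprocess_cohort(
    cohort: SpectraCohort,
    config: PreprocessConfig | None = None,
    return_rejected: bool = False,
):
    """Run the full chain (QC -> baseline -> smoothing -> normalization).

    Deterministic; refuses cohorts that have already been processed.
    """
    config = config or PreprocessConfig()
    for s in cohort.spectra:
        if len(s.meta.preprocessing_state) > 1:
            raise StateError(
                f"spectrum {s.meta.spectrum_id!r} has state {s.meta.preprocessing_state}; "
                "preprocess_cohort expects raw spectra"
            )
    kept, rejected = qc_filter(cohort, config)
    out = []
    for s in kept.spectra:
        corrected, _ = remove_baseline(s, config)
        out.append(normalize(smooth(corrected, config), config))
    result = SpectraCohort(out, kept.patients)
    if return_rejected:
        return result, rejected
    return result


__all__ = [
    "PreprocessConfig",
    "qc_filter",
    "remove_baseline",
    "smooth",
    "normalize",
    "preprocess_cohort",
    "REJECT_NONFINITE",
    "REJECT_SATURATED",
]
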