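"""Synthetic serum-SERS cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
shared 200-1800 cm^-1 axis at 2 cm^-1 steps, pseudo-Voigt serum bands at
the catalogue positions, group-specific band intensities following the
effect lists, a smooth degree-4 polynomial autofluorescence background,
additive Gaussian detector noise, and a per-patient log-normal amplitude
multiplier shared by all of a patient's spectra.  The patient random effect
is the minimal structure that makes leave-one-patient-out validation
genuinely harder than leave-one-spectrum-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev

from .catalogue import PeakCatalogue, default_catalogue
from .core import GROUPS, SpectraCohort, Spectrum, SpectrumMeta, WavenumberGrid
from .errors import ConfigError

#: Patients per group in the reference cohort design.
DEFAULT_PATIENTS = {"PA": 20, "WT": 21, "MEC": 19, "Normal": 31}

#: Spectra per group in the reference cohort (4-6 acquisitions per patient).
DEFAULT_SPECTRA_TOTALS = {"PA": 101, "WT": 105, "MEC": 95, "Normal": 153}

#: Baseline band heights (a.u.) keyed by canonical band position (cm^-1).
#: The 723-727 cm^-1 hypoxanthine band dominates serum SERS spectra.
DEFAULT_BASE_AMPLITUDES = {
    294.0: 40.0,
    450.0: 30.0,
    545.5: 55.0,
    725.0: 120.0,
    745.5: 85.0,
    933.0: 50.0,
    1084.0: 55.0,
    1094.0: 50.0,
    1127.0: 45.0,
    1140.0: 40.0,
    1262.5: 45.0,
    1327.5: 65.0,
    1370.5: 55.0,
    1443.0: 75.0,
    1546.0: 50.0,
    1607.0: 45.0,
    1698.5: 45.0,
}

_EFFECT_MATCH_TOL = 3.0  # cm^-1; links an effect-list position to its catalogue band


@dataclass
class SyntheticConfig:
    """Parameters of the generative model; defaults mirror the reference cohort."""

    patients_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PATIENTS))
    spectra_per_patient: tuple[int, int] = (4, 6)
    target_spectra_totals: dict[str, int] | None = None  # None: reference totals when patient counts match
    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    baseline_degree: int = 4
    baseline_amplitude: float = 300.0
    peak_shape: str = "pseudo_voigt"  # or "lorentzian", "gaussian"
    peak_fwhm: float = 12.0
    voigt_eta: float = 0.5
    base_amplitudes: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_BASE_AMPLITUDES))
    effect_size: float = 1.5
    patient_sd: float = 0.2
    spectrum_jitter_sd: float = 0.0
    noise_sd: float = 2.0
    saturation_fraction: float = 0.0
    seed: int = 0
    catalogue: PeakCatalogue = field(default_factory=default_catalogue)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.patients_per_group.values()):
            raise ConfigError("patient counts must be positive")
        for g in self.patients_per_group:
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
        lo, hi = self.spectra_per_patient
        if not (1 <= lo <= hi <= 20):
            raise ConfigError("spectra_per_patient must lie within [1, 20]")
        if not 0.0 <= self.saturation_fraction < 1.0:
            raise ConfigError("saturation_fraction must be in [0, 1)")
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be positive")
        if self.peak_shape not in ("pseudo_voigt", "lorentzian", "gaussian"):
            raise ConfigError(f"unknown peak_shape {self.peak_shape!r}")

    def resolved_totals(self) -> dict[str, int] | None:
        if self.target_spectra_totals is not None:
            return self.target_spectra_totals
        if self.patients_per_group == DEFAULT_PATIENTS:
            return dict(DEFAULT_SPECTRA_TOTALS)
        return None


def _profile(x: np.ndarray, center: float, fwhm: float, shape: str, eta: float) -> np.ndarray:
    """Unit-height band profile."""
    t = (x - center) / fwhm
    lorentz = 1.0 / (1.0 + 4.0 * t * t)
    gauss = np.exp(-4.0 * np.log(2.0) * t * t)
    if shape == "lorentzian":
        return lorentz
    if shape == "gaussian":
        return gauss
    return eta * lorentz + (1.0 - eta) * gauss


def group_peak_table(config: SyntheticConfig, group: str) -> list[tuple[float, float]]:
    """(position, amplitude) pairs of the noiseless mean model for ``group``.

    Every band sits at its catalogue range center in every group, so the
    effect lists act purely on amplitude: a band named in the group's
    effect list is multiplied (increase) or divided (decrease) by
    ``effect_size``.  Effect positions matching no catalogue band (e.g. the
    WT band at 450 cm^-1) are modelled as extra bands present in all groups
    at base amplitude.
    """
    cat = config.catalogue
    if group != "Normal" and group not in cat.effect_lists:
        raise ConfigError(f"group {group!r} has no effect list and is not Normal")
    eff = cat.effect_lists.get(group)
    signed: dict[float, float] = {}
    if eff is not None:
        for p in eff.increased:
            signed[float(p)] = config.effect_size
        for p in eff.decreased:
            signed[float(p)] = 1.0 / config.effect_size

    # positions of effect-list bands outside every catalogue range
    extra_positions = sorted(
        {
            float(p)
            for g_eff in cat.effect_lists.values()
            for p in (*g_eff.increased, *g_eff.decreased)
            if cat.find_entry(p, _EFFECT_MATCH_TOL) is None
        }
    )

    table: list[tuple[float, float]] = []
    for entry in cat.entries:
        amp = config.base_amplitudes.get(entry.center, 50.0)
        factor = 1.0
        for p, f in signed.items():
            if entry.contains(p, _EFFECT_MATCH_TOL):
                factor = f
                break
        table.append((entry.center, amp * factor))
    for p in extra_positions:
        amp = config.base_amplitudes.get(p, 30.0)
        table.append((p, amp * signed.get(p, 1.0)))
    return sorted(table)


def _random_baseline(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive polynomial background of degree ``baseline_degree``."""
    xs = np.linspace(-1.0, 1.0, config.grid.n_points)
    coef = rng.normal(size=config.baseline_degree + 1) / (1.0 + np.arange(config.baseline_degree + 1))
    vals = chebyshev.chebval(xs, coef)
    spread = float(np.ptp(vals))
    if spread == 0.0:
        return np.full(config.grid.n_points, config.baseline_amplitude)
    # affine rescale keeps the curve polynomial; range [0.3, 1.3] * amplitude
    return config.baseline_amplitude * ((vals - vals.min()) / spread + 0.3)


def generate_patient(
    group: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    patient_id: str = "P01",
    n_spectra: int | None = None,
) -> list[Spectrum]:
    """Generate one patient's spectra.

    All of the patient's spectra share a single log-normal amplitude
    multiplier; each spectrum gets its own baseline, jitter and noise.
    """
    lo, hi = config.spectra_per_patient
    if n_spectra is None:
        n_spectra = int(rng.integers(lo, hi + 1))
    x = config.grid.values
    table = group_peak_table(config, group)
    patient_mult = float(np.exp(config.patient_sd * rng.normal()))
    spectra = []
    for k in range(n_spectra):
        baseline = _random_baseline(config, rng)
        jitter = float(np.exp(config.spectrum_jitter_sd * rng.normal()))
        y = baseline.copy()
        for pos, amp in table:
            y += amp * patient_mult * jitter * _profile(
                x, pos, config.peak_fwhm, config.peak_shape, config.voigt_eta
            )
        y += config.noise_sd * rng.normal(size=x.size)
        np.clip(y, 0.0, None, out=y)
        meta = SpectrumMeta(
            spectrum_id=f"{patient_id}-S{k + 1}",
            patient_id=patient_id,
            group=group,
        )
        spectra.append(Spectrum(grid=config.grid, intensity=y, meta=meta))
    return spectra


def _spectra_counts(
    n_patients: int, bounds: tuple[int, int], target: int | None, rng: np.random.Generator
) -> list[int]:
    lo, hi = bounds
    counts = list(rng.integers(lo, hi + 1, size=n_patients))
    if target is None:
        return [int(c) for c in counts]
    if not lo * n_patients <= target <= hi * n_patients:
        raise ConfigError(
            f"target of {target} spectra infeasible for {n_patients} patients with {lo}-{hi} each"
        )
    while sum(counts) != target:
        i = int(rng.integers(n_patients))
        if sum(counts) < target and counts[i] < hi:
            counts[i] += 1
        elif sum(counts) > target and counts[i] > lo:
            counts[i] -= 1
    return [int(c) for c in counts]


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> SpectraCohort:
    """Generate a full cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    totals = config.resolved_totals()
    spectra: list[Spectrum] = []
    patients: dict[str, str] = {}
    for group in GROUPS:
        n_pat = config.patients_per_group.get(group, 0)
        if n_pat == 0:
            continue
        target = totals.get(group) if totals else None
        counts = _spectra_counts(n_pat, config.spectra_per_patient, target, rng)
        for i, n_spec in enumerate(counts):
            pid = f"{group}-P{i + 1:02d}"
            patients[pid] = group
            spectra.extend(generate_patient(group, config, rng, patient_id=pid, n_spectra=n_spec))
    cohort = SpectraCohort(spectra, patients)
    if config.saturation_fraction > 0:
        cohort = inject_saturation(cohort, config.saturation_fraction, rng)
    return cohort


def inject_saturation(
    cohort: SpectraCohort,
    fraction: float,
    rng: np.random.Generator,
    run_length: int = 40,
) -> SpectraCohort:
    """Clamp a contiguous region of randomly chosen spectra to a ceiling.

    Emulates detector oversaturation for QC testing; affected spectra carry
    ``flags['saturated'] = True`` so tests can compare against ground truth.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return cohort
    ceiling = 1.2 * max(float(s.intensity.max()) for s in cohort.spectra)
    out = []
    for s in cohort.spectra:
        if rng.random() < fraction:
            y = s.intensity.copy()
            n = y.size
            length = min(run_length, n)
            start = int(rng.integers(0, n - length + 1))
            y[start : start + length] = ceiling
            clone = s.with_intensity(y)
            clone.meta.flags["saturated"] = True
            out.append(clone)
        else:
            out.append(s)
    return SpectraCohort(out, cohort.patients)


__all__ = [
    "DEFAULT_PATIENTS",
    "DEFAULT_SPECTRA_TOTALS",
    "DEFAULT_BASE_AMPLITUDES",
    "SyntheticConfig",
    "group_peak_table",
    "generate_patient",
    "generate_cohort",
    "inject_saturation",
]
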