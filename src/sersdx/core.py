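"""Core containers: wavenumber grid, single spectrum, cohort.

A SERS acquisition is a vector of scattered-light intensities sampled on a
uniform Raman-shift axis.  The default axis is 200-1800 cm^-1 at 2 cm^-1
resolution (801 points), the acquisition window used throughout the
serum-diagnostic workflow this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import FormatError, ValidationError

#: The four diagnostic classes: pleomorphic adenoma, Warthin's tumor,
#: mucoepidermoid carcinoma, and normal controls.
GROUPS = ("PA", "WT", "MEC", "Normal")

#: Processing states a spectrum moves through, in order.
PREPROCESSING_STATES = ("raw", "qc_passed", "baseline_corrected", "smoothed", "normalized")


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift axis in cm^-1.

    Parameters
    ----------
    start, stop : float
        First and last Raman shift (inclusive), cm^-1.
    step : float
        Spacing between adjacent points, cm^-1.
    """

    start: float = 200.0
    stop: float = 1800.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise FormatError(f"grid step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise FormatError("grid stop must exceed start")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-6:
            raise FormatError(
                f"grid span {self.start}-{self.stop} is not an integer number of steps of {self.step}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wavenumbers: np.ndarray, rtol: float = 1e-6) -> "WavenumberGrid":
        """Build a grid from a sorted axis, requiring uniform spacing."""
        w = np.asarray(wavenumbers, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise FormatError("axis must be a 1-D array with at least 2 points")
        d = np.diff(w)
        if np.any(d <= 0):
            raise FormatError("axis must be strictly increasing")
        step = float(np.median(d))
        if np.max(np.abs(d - step)) > rtol * max(abs(step), 1.0):
            raise FormatError("axis spacing is not uniform")
        return cls(start=float(w[0]), stop=float(w[-1]), step=step)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(round((wavenumber - self.start) / self.step))


@dataclass
class SpectrumMeta:
    spectrum_id: str = ""
    patient_id: str = ""
    group: str = ""
    preprocessing_state: list[str] = field(default_factory=lambda: ["raw"])
    flags: dict = field(default_factory=dict)

    def copy(self) -> "SpectrumMeta":
        return SpectrumMeta(
            spectrum_id=self.spectrum_id,
            patient_id=self.patient_id,
            group=self.group,
            preprocessing_state=list(self.preprocessing_state),
            flags=dict(self.flags),
        )


@dataclass
class Spectrum:
    """One acquisition: intensities on a shared wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size != self.grid.n_points:
            raise FormatError(
                f"intensity length {self.intensity.size} does not match grid "
                f"({self.grid.n_points} points)"
            )

    @property
    def state(self) -> list[str]:
        return self.meta.preprocessing_state

    def has_state(self, state: str) -> bool:
        return state in self.meta.preprocessing_state

    def with_intensity(self, intensity: np.ndarray, new_state: str | None = None) -> "Spectrum":
        """Copy with replaced intensities, optionally appending a processing state."""
        meta = self.meta.copy()
        if new_state is not None:
            meta.preprocessing_state.append(new_state)
        return Spectrum(grid=self.grid, intensity=np.asarray(intensity, dtype=float), meta=meta)


class SpectraCohort:
    """A set of spectra with patient identities and group labels.

    Invariants: every spectrum's patient maps to exactly one group; all
    spectra share one wavenumber grid.
    """

    def __init__(self, spectra: Iterable[Spectrum], patients: dict[str, str] | None = None):
        self.spectra: list[Spectrum] = list(spectra)
        if patients is None:
            patients = {}
            for s in self.spectra:
                prev = patients.get(s.meta.patient_id)
                if prev is not None and prev != s.meta.group:
                    raise ValidationError(
                        f"patient {s.meta.patient_id!r} appears under groups {prev!r} and {s.meta.group!r}"
                    )
                patients[s.meta.patient_id] = s.meta.group
        self.patients: dict[str, str] = dict(patients)
        self._validate()

    def _validate(self) -> None:
        for group in self.patients.values():
            if group not in GROUPS:
                raise ValidationError(f"unknown group label {group!r}; expected one of {GROUPS}")
        for s in self.spectra:
            if s.meta.patient_id not in self.patients:
                raise ValidationError(f"spectrum {s.meta.spectrum_id!r} references unknown patient")
            if self.patients[s.meta.patient_id] != s.meta.group:
                raise ValidationError(
                    f"spectrum {s.meta.spectrum_id!r} group {s.meta.group!r} disagrees with "
                    f"patient mapping {self.patients[s.meta.patient_id]!r}"
                )
        grids = {(s.grid.start, s.grid.stop, s.grid.step) for s in self.spectra}
        if len(grids) > 1:
            raise ValidationError("cohort spectra do not share a single wavenumber grid")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise ValidationError("empty cohort has no grid")
        return self.spectra[0].grid

    @property
    def groups(self) -> set[str]:
        return set(self.patients.values())

    def group_spectra(self, group: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.meta.group == group]

    def spectra_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spectra:
            counts[s.meta.group] = counts.get(s.meta.group, 0) + 1
        return counts

    def patient_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.patients.values():
            counts[g] = counts.get(g, 0) + 1
        return counts

    def subset_groups(self, groups: Iterable[str]) -> "SpectraCohort":
        keep = set(groups)
        spectra = [s for s in self.spectra if s.meta.group in keep]
        patients = {p: g for p, g in self.patients.items() if g in keep}
        return SpectraCohort(spectra, patients)


__all__ = [
    "GROUPS",
    "PREPROCESSING_STATES",
    "WavenumberGrid",
    "SpectrumMeta",
    "Spectrum",
    "SpectraCohort",
    "replace",
]
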