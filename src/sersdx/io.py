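"""Reading and writing spectra and cohort manifests.

Spectra are plain two-column delimited text (Raman shift in cm^-1,
intensity), comma or tab separated, with an optional header line.  Cohort
metadata lives in a CSV manifest with columns ``file, spectrum_id,
patient_id, group``; spectrum files themselves stay metadata-free.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GROUPS, SpectraCohort, Spectrum, SpectrumMeta, WavenumberGrid
from .errors import DegenerateInputError, FormatError, ParseError, RangeError, ValidationError

MANIFEST_COLUMNS = ("file", "spectrum_id", "patient_id", "group")
_HEADER_TOKENS = {"wavenumber", "raman_shift", "shift", "cm-1", "intensity", "counts"}


def _detect_delimiter(line: str, dialect: str | None) -> str:
    if dialect == "two-column-csv":
        return ","
    if dialect == "two-column-tsv":
        return "\t"
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_spectrum(path: str | Path, dialect: str | None = None) -> Spectrum:
    """Read one two-column spectrum file.

    The axis is sorted ascending; duplicate wavenumbers are rejected.  The
    spectrum id defaults to the file stem.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    rows: list[tuple[float, float]] = []
    delim: str | None = None
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if delim is None:
            delim = _detect_delimiter(line, dialect)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, found {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            lowered = {p.lower() for p in parts}
            if lineno == 1 and (lowered & _HEADER_TOKENS or not rows):
                continue  # header line
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if len(rows) < 8:
        raise ParseError(f"{path}: expected at least 8 data rows, found {len(rows)}")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise FormatError(f"{path}: duplicate wavenumber {dup}")
    grid = WavenumberGrid.from_values(arr[:, 0])
    meta = SpectrumMeta(spectrum_id=path.stem)
    return Spectrum(grid=grid, intensity=arr[:, 1], meta=meta)


def _harmonize(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Linearly interpolate onto ``target``; a no-op for an identical grid."""
    g = spectrum.grid
    if (g.start, g.stop, g.step) == (target.start, target.stop, target.step):
        return spectrum
    if g.start > target.start or g.stop < target.stop:
        raise RangeError(
            f"spectrum {spectrum.meta.spectrum_id!r} spans {g.start}-{g.stop} cm^-1 and cannot "
            f"cover the target range {target.start}-{target.stop} without extrapolation"
        )
    y = np.interp(target.values, g.values, spectrum.intensity)
    return Spectrum(grid=target, intensity=y, meta=spectrum.meta.copy())


def read_cohort(manifest_path: str | Path) -> SpectraCohort:
    """Load a cohort from a manifest CSV; harmonize axes onto the first grid."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{manifest_path}: manifest missing columns {missing}")
    if len(table) == 0:
        raise DegenerateInputError(f"{manifest_path}: manifest has no rows")

    patients: dict[str, str] = {}
    spectra: list[Spectrum] = []
    base = manifest_path.parent
    target: WavenumberGrid | None = None
    for row in table.itertuples(index=False):
        if row.group not in GROUPS:
            raise ValidationError(f"unknown group label {row.group!r} for spectrum {row.spectrum_id!r}")
        prev = patients.get(row.patient_id)
        if prev is not None and prev != row.group:
            raise ValidationError(
                f"patient {row.patient_id!r} mapped to both {prev!r} and {row.group!r}"
            )
        patients[row.patient_id] = row.group
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        s = read_spectrum(fpath)
        s.meta.spectrum_id = row.spectrum_id
        s.meta.patient_id = row.patient_id
        s.meta.group = row.group
        if target is None:
            target = s.grid
        spectra.append(_harmonize(s, target))
    return SpectraCohort(spectra, patients)


def write_cohort(cohort: SpectraCohort, out_dir: str | Path) -> Path:
    """Write each spectrum as a two-column CSV plus a manifest; returns the manifest path.

    Round-trips to full precision: ``read_cohort(write_cohort(c))`` reproduces
    axes and intensities exactly.
    """
    if len(cohort) == 0:
        raise DegenerateInputError("cannot write an empty cohort")
    cohort._validate()  # catch post-construction mutation before touching disk
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.spectra:
        fname = f"{s.meta.spectrum_id}.csv"
        with open(out_dir / fname, "w", newline="") as fh:
            fh.write("wavenumber,intensity\n")
            for w, y in zip(s.grid.values, s.intensity):
                fh.write(f"{w:.17g},{y:.17g}\n")
        rows.append((fname, s.meta.spectrum_id, s.meta.patient_id, s.meta.group))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


__all__ = ["read_spectrum", "read_cohort", "write_cohort", "MANIFEST_COLUMNS"]
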