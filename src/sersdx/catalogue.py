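"""Serum SERS band catalogue and group effect lists.

The catalogue maps Raman-shift ranges to biochemical assignments drawn from
the serum-SERS literature (hypoxanthine, nucleic-acid bases, protein and
lipid vibrations).  The effect lists record, per tumor group, which bands
rise or fall relative to the normal-control mean spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CatalogueEntry:
    shift_lo: float
    shift_hi: float
    assignment: str

    def __post_init__(self) -> None:
        if self.shift_lo > self.shift_hi:
            raise ValidationError(f"entry {self.assignment!r}: shift_lo > shift_hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.shift_lo + self.shift_hi)

    def contains(self, position: float, tolerance: float = 0.0) -> bool:
        return self.shift_lo - tolerance <= position <= self.shift_hi + tolerance

    def distance(self, position: float) -> float:
        if position < self.shift_lo:
            return self.shift_lo - position
        if position > self.shift_hi:
            return position - self.shift_hi
        return 0.0


@dataclass(frozen=True)
class EffectList:
    """Peak positions (cm^-1) that increase / decrease in a group vs Normal."""

    increased: tuple[float, ...] = ()
    decreased: tuple[float, ...] = ()


@dataclass
class PeakCatalogue:
    entries: list[CatalogueEntry]
    effect_lists: dict[str, EffectList] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = sorted(self.entries, key=lambda e: e.shift_lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.shift_lo <= a.shift_hi:
                raise ValidationError(f"overlapping entries {a.assignment!r} / {b.assignment!r}")
        for group, eff in self.effect_lists.items():
            for p in (*eff.increased, *eff.decreased):
                if not 200.0 <= p <= 1800.0:
                    raise ValidationError(f"{group}: effect position {p} outside 200-1800 cm^-1")

    def find_entry(self, position: float, tolerance: float = 0.0) -> CatalogueEntry | None:
        """Entry whose (tolerance-widened) range contains ``position``; nearest wins."""
        hits = [e for e in self.entries if e.contains(position, tolerance)]
        if not hits:
            return None
        return min(hits, key=lambda e: e.distance(position))

    def assignment_for(self, position: float, tolerance: float = 0.0) -> str:
        entry = self.find_entry(position, tolerance)
        return entry.assignment if entry is not None else UNASSIGNED

    def unassigned_effect_positions(self, tolerance: float = 3.0) -> dict[str, list[float]]:
        """Effect-list positions that map to no catalogue entry (within tolerance)."""
        out: dict[str, list[float]] = {}
        for group, eff in self.effect_lists.items():
            orphans = [
                p
                for p in (*eff.increased, *eff.decreased)
                if self.find_entry(p, tolerance) is None
            ]
            if orphans:
                out[group] = orphans
        return out


_ENTRIES = [
    (292, 296, "Au-S band"),
    (543, 548, "S-S disulfide stretching in proteins"),
    (723, 727, "Hypoxanthine"),
    (744, 747, "Thymine in DNA"),
    (933, 933, "C-C stretching mode, C-C alpha-helix in proteins"),
    (1084, 1084, "C-C stretching mode in phospholipids"),
    (1094, 1094, "C-N stretching mode in D-mannose"),
    (1127, 1127, "C-C stretching in lipids, C-N stretching in D-mannose"),
    (1140, 1140, "Carotenoids"),
    (1261, 1264, "CH bending in lipids"),
    (1326, 1329, "CH vibration in DNA/RNA, CH2 twisting in lipids"),
    (1368, 1373, "Guanine in DNA, tryptophan in proteins"),
    (1441, 1445, "CH2, CH3 bending in proteins and lipids"),
    (1541, 1551, "C-N stretching, Amide II"),
    (1607, 1607, "C=C band in phenylalanine or tyrosine"),
    (1698, 1699, "Amide I"),
]

_EFFECTS = {
    "PA": EffectList(
        increased=(548, 724, 747, 933, 1094, 1328, 1371, 1445, 1698),
        decreased=(295, 1551, 1607),
    ),
    "WT": EffectList(
        increased=(296, 450, 543, 727, 744, 1084, 1140, 1264, 1326, 1373, 1444, 1699),
        decreased=(1548,),
    ),
    "MEC": EffectList(
        increased=(548, 723, 934, 1127, 1329, 1368, 1441),
        decreased=(292, 1261, 1541, 1607),
    ),
}


def default_catalogue() -> PeakCatalogue:
    """The 16-band serum catalogue plus the three per-group effect lists.

    The WT list contains one band (450 cm^-1) with no catalogue assignment;
    it is generated and reported but flagged unassigned.
    """
    entries = [CatalogueEntry(float(lo), float(hi), a) for lo, hi, a in _ENTRIES]
    return PeakCatalogue(entries=entries, effect_lists=dict(_EFFECTS))


__all__ = [
    "UNASSIGNED",
    "CatalogueEntry",
    "EffectList",
    "PeakCatalogue",
    "default_catalogue",
]
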