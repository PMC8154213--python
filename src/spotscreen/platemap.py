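"""Membrane grid geometry, well labelling, and m/z channel assignment.

A screening membrane is a rectangular grid of square cells (default
5 mm x 5 mm, one quenched reaction spotted per cell).  Coordinates are in
millimetres with the origin at the membrane's top-left corner, x to the
right and y down, matching raster-scan imaging conventions.  Wells carry
A1-style labels, row-major.

Channel assignment turns a species table (well -> molecular formula +
adduct) into the minimal set of narrow m/z detection windows: species whose
ions fall within one window-width of each other are multiplexed onto a
single channel — this is what lets isomeric substrates across many wells be
read out from one extracted-ion image.  Assignment also predicts isotope
interference between channels (e.g. a substrate's M+2 peak inside the
product channel) so downstream correction knows what to subtract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    AdductSpec,
    ElementComposition,
    interference_fraction,
    isotope_envelope,
    monoisotopic_mz,
    parse_formula,
)

__all__ = [
    "PlateLayout",
    "ChannelSpec",
    "SpeciesEntry",
    "SpeciesTable",
    "ChannelAssignment",
    "build_layout",
    "assign_channels",
]

DISPLAY_COLORS = ("red", "green", "blue", "gray")


def _row_letters(row: int) -> str:
    """A..Z, then AA..AZ for plates taller than 26 rows."""
    letters = ""
    row += 1
    while row > 0:
        row, rem = divmod(row - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


@dataclass(frozen=True)
class PlateLayout:
    """Rectangular grid of square sample cells on a membrane."""

    n_rows: int
    n_cols: int
    cell_size: float = 5.0  # mm
    origin: tuple[float, float] = (0.0, 0.0)  # mm offset of cell (0,0) corner
    format_tag: str = "custom"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width_mm(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height_mm(self) -> float:
        return self.n_rows * self.cell_size

    def label(self, row: int, col: int) -> str:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"well ({row}, {col}) outside {self.n_rows}x{self.n_cols} plate")
        return f"{_row_letters(row)}{col + 1}"

    def well_labels(self) -> list[str]:
        """All labels, row-major (A1, A2, ..., B1, ...)."""
        return [self.label(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def well_index(self, label: str) -> tuple[int, int]:
        i = 0
        while i < len(label) and label[i].isalpha():
            i += 1
        letters, digits = label[:i], label[i:]
        if not letters or not digits:
            raise ValueError(f"malformed well label: {label!r}")
        row = 0
        for ch in letters.upper():
            row = row * 26 + (ord(ch) - ord("A") + 1)
        row -= 1
        col = int(digits) - 1
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"well {label!r} outside {self.n_rows}x{self.n_cols} plate")
        return row, col

    def well_center(self, label: str) -> tuple[float, float]:
        """Cell center in mm (x right, y down)."""
        row, col = self.well_index(label)
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] + (row + 0.5) * self.cell_size,
        )

    def cell_bounds(self, label: str) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the cell, half-open on the upper edges."""
        row, col = self.well_index(label)
        x0 = self.origin[0] + col * self.cell_size
        y0 = self.origin[1] + row * self.cell_size
        return x0, y0, x0 + self.cell_size, y0 + self.cell_size

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_rows": self.n_rows, "n_cols": self.n_cols,
            "cell_size_mm": self.cell_size, "origin_mm": list(self.origin),
            "format_tag": self.format_tag,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlateLayout":
        d = json.loads(Path(path).read_text())
        return cls(d["n_rows"], d["n_cols"], d.get("cell_size_mm", 5.0),
                   tuple(d.get("origin_mm", (0.0, 0.0))), d.get("format_tag", "custom"))


def build_layout(n_rows: int, n_cols: int, cell_size: float = 5.0,
                 origin: tuple[float, float] = (0.0, 0.0)) -> PlateLayout:
    """Construct a plate layout; tags the standard 96/384 formats."""
    tag = {(8, 12): "96", (16, 24): "384"}.get((n_rows, n_cols), "custom")
    return PlateLayout(n_rows, n_cols, cell_size, origin, tag)


@dataclass(frozen=True)
class ChannelSpec:
    """A narrow m/z detection window rendered as one ion image."""

    label: str
    target_mz: float
    window: float = 0.2  # Da
    polarity: int = 1
    display_color: str = "gray"
    species_role: str = "other"  # substrate | product | other

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("channel window must be positive")
        if self.target_mz <= 0:
            raise ValueError("channel target m/z must be positive")
        if self.display_color not in DISPLAY_COLORS:
            raise ValueError(f"display_color must be one of {DISPLAY_COLORS}")


@dataclass(frozen=True)
class SpeciesEntry:
    well: str
    role: str  # substrate | product | other
    composition: ElementComposition
    adduct: AdductSpec
    drift_ms: float | None = None

    @property
    def mz(self) -> float:
        return monoisotopic_mz(self.composition, self.adduct)


class SpeciesTable:
    """Per-well species identities: role, formula, adduct, optional drift time.

    ``role`` is "substrate", "product" or "other"; wells whose rows are all
    "other" (or that carry no rows at all in the ground truth) serve as
    blank/control wells downstream.
    """

    def __init__(self, entries: Iterable[SpeciesEntry], layout: PlateLayout | None = None):
        self.entries: list[SpeciesEntry] = list(entries)
        if layout is not None:
            valid = set(layout.well_labels())
            bad = sorted({e.well for e in self.entries} - valid)
            if bad:
                raise ValueError(f"species table references wells absent from layout: {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def wells(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.well, None)
        return list(seen)

    def for_well(self, well: str) -> list[SpeciesEntry]:
        return [e for e in self.entries if e.well == well]

    def blank_wells(self) -> list[str]:
        """Wells declared with only non-substrate/product roles."""
        roles: dict[str, set[str]] = {}
        for e in self.entries:
            roles.setdefault(e.well, set()).add(e.role)
        return [w for w, rs in roles.items() if rs <= {"other"}]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.well, e.role, e.composition.hill_formula(), e.adduct.kind, e.drift_ms)
             for e in self.entries],
            columns=["well", "role", "formula", "adduct", "drift_ms"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layout: PlateLayout | None = None) -> "SpeciesTable":
        entries = []
        for _, row in df.iterrows():
            drift = row.get("drift_ms")
            drift = None if pd.isna(drift) else float(drift)
            entries.append(SpeciesEntry(
                well=str(row["well"]), role=str(row["role"]),
                composition=parse_formula(str(row["formula"])),
                adduct=AdductSpec.parse(str(row["adduct"])),
                drift_ms=drift,
            ))
        return cls(entries, layout)

    @classmethod
    def from_csv(cls, path: str | Path, layout: PlateLayout | None = None) -> "SpeciesTable":
        return cls.from_frame(pd.read_csv(path), layout)

    @classmethod
    def from_json(cls, path: str | Path, layout: PlateLayout | None = None) -> "SpeciesTable":
        rows = json.loads(Path(path).read_text())
        return cls.from_frame(pd.DataFrame(rows), layout)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_frame().to_json(orient="records", indent=2))


@dataclass
class ChannelAssignment:
    """Channels plus per-channel well membership and predicted cross-talk."""

    channels: list[ChannelSpec]
    wells_by_channel: dict[str, list[str]]
    # (source channel, target channel, predicted leakage fraction of the
    # source base peak inside the target window)
    interference: list[tuple[str, str, float]] = field(default_factory=list)

    def channel(self, label: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(label)

    def channel_for_role(self, role: str) -> ChannelSpec:
        matches = [ch for ch in self.channels if ch.species_role == role]
        if len(matches) != 1:
            raise KeyError(f"expected exactly one {role!r} channel, found {len(matches)}")
        return matches[0]


_ROLE_COLOR = {"substrate": "red", "product": "green", "other": "blue"}


def assign_channels(species: SpeciesTable, window: float = 0.2,
                    interference_threshold: float = 1e-3) -> ChannelAssignment:
    """Group species onto the minimal set of m/z channels.

    Species (of one polarity) whose monoisotopic m/z values fall within one
    ``window`` of each other share a channel: entries are sorted by m/z and
    merged greedily while the span of the growing cluster stays within the
    window.  The channel target is the abundance-unweighted mean m/z of its
    members.  Isotope-envelope leakage from every channel's species into every
    other channel is predicted and reported for fractions above
    ``interference_threshold``.

    Deterministic and invariant to the input row order.
    """
    if len(species) == 0:
        raise ValueError("empty species table")
    if window <= 0:
        raise ValueError("window must be positive")

    rows = sorted(species, key=lambda e: (e.adduct.polarity, e.mz, e.well, e.role))
    clusters: list[list[SpeciesEntry]] = []
    for e in rows:
        if (clusters
                and e.adduct.polarity == clusters[-1][0].adduct.polarity
                and e.mz - clusters[-1][0].mz <= window):
            clusters[-1].append(e)
        else:
            clusters.append([e])

    channels: list[ChannelSpec] = []
    wells_by_channel: dict[str, list[str]] = {}
    reps: list[SpeciesEntry] = []
    used_colors: list[str] = []
    for members in clusters:
        mzs = sorted({e.mz for e in members})
        target = sum(mzs) / len(mzs)
        roles = {e.role for e in members}
        role = roles.pop() if len(roles) == 1 else "other"
        color = _ROLE_COLOR.get(role, "gray")
        if color in used_colors:
            remaining = [c for c in DISPLAY_COLORS if c not in used_colors]
            color = remaining[0] if remaining else "gray"
        used_colors.append(color)
        label = f"mz{target:.3f}"
        channels.append(ChannelSpec(label=label, target_mz=target, window=window,
                                    polarity=members[0].adduct.polarity,
                                    display_color=color, species_role=role))
        well_seen: dict[str, None] = {}
        for e in sorted(members, key=lambda e: e.well):
            well_seen.setdefault(e.well, None)
        wells_by_channel[label] = list(well_seen)
        reps.append(members[0])

    interference: list[tuple[str, str, float]] = []
    for src_ch, src in zip(channels, reps):
        env = isotope_envelope(src.composition, src.adduct)
        for dst_ch in channels:
            if dst_ch.label == src_ch.label or dst_ch.polarity != src_ch.polarity:
                continue
            frac = interference_fraction(env, dst_ch.target_mz, dst_ch.window)
            if frac > interference_threshold:
                interference.append((src_ch.label, dst_ch.label, frac))

    return ChannelAssignment(channels=channels, wells_by_channel=wells_by_channel,
                             interference=interference)
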