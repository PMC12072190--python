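"""Damage channels and the energy × channel cross-section table.

The table mirrors the layout in which these measurements are reported:
one row per electron energy (eV), one column per damage channel, each
cell an uncertain value in units of 10⁻¹⁵ cm² or a missing marker
"n.d." (not detected/determined).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import UsageError
from .uncertain import UncertainValue

__all__ = ["DamageChannel", "CrossSectionTable", "MISSING_MARKER"]

MISSING_MARKER = "n.d."


class DamageChannel(str, enum.Enum):
    """Lesion categories resolved by the gel/enzyme assay.

    ``CL``, ``DSB``, ``SSB`` are conformational damages read directly
    from the gel; ``LS`` (loss of supercoiled) is the total
    conformational-damage observable.  ``BD_CL``, ``NDCD`` and
    ``ISOLATED_BD`` are revealed by base-excision-enzyme treatment.
    ``TOTAL_BD`` and ``TOTAL_DAMAGE`` are aggregates; ``OND`` (other
    non-detected damage) is a residual category with no measurement
    path and is always stored as missing.
    """

    CL = "CL"
    DSB = "DSB"
    SSB = "SSB"
    LS = "LS"
    BD_CL = "BD_CL"
    NDCD = "NDCD"
    ISOLATED_BD = "ISOLATED_BD"
    TOTAL_BD = "TOTAL_BD"
    TOTAL_DAMAGE = "TOTAL_DAMAGE"
    OND = "OND"


AGGREGATE_CHANNELS = (DamageChannel.LS, DamageChannel.TOTAL_BD,
                      DamageChannel.TOTAL_DAMAGE)

#: column order used by the text format
_CHANNEL_ORDER = [c for c in DamageChannel if c is not DamageChannel.OND]


@dataclass
class CrossSectionTable:
    """Absolute cross sections per energy and damage channel.

    Entries are keyed ``(energy_eV, DamageChannel)``; a key that is
    absent means "n.d.".  ``units`` applies to every entry.  ``flags``
    carries per-entry annotations (e.g. a negative revealed yield kept
    for visibility).
    """

    entries: dict[tuple[float, DamageChannel], UncertainValue] = field(default_factory=dict)
    units: str = "1e-15 cm2"
    metadata: dict[str, str] = field(default_factory=dict)
    flags: dict[tuple[float, DamageChannel], str] = field(default_factory=dict)

    @property
    def energies(self) -> list[float]:
        return sorted({e for e, _ in self.entries})

    @property
    def channels(self) -> list[DamageChannel]:
        present = {c for _, c in self.entries}
        return [c for c in DamageChannel if c in present]

    def get(self, energy: float, channel: DamageChannel | str) -> UncertainValue | None:
        return self.entries.get((float(energy), DamageChannel(channel)))

    def set(self, energy: float, channel: DamageChannel | str,
            value: UncertainValue, flag: str | None = None) -> None:
        key = (float(energy), DamageChannel(channel))
        self.entries[key] = value.with_units(self.units)
        if flag:
            self.flags[key] = flag

    def __contains__(self, key: tuple[float, DamageChannel | str]) -> bool:
        energy, channel = key
        return (float(energy), DamageChannel(channel)) in self.entries

    def merge(self, other: "CrossSectionTable") -> "CrossSectionTable":
        """New table with this table's entries updated by ``other``'s."""
        if other.units != self.units:
            raise UsageError(f"units mismatch: {self.units!r} vs {other.units!r}")
        merged = CrossSectionTable(units=self.units,
                                   metadata={**self.metadata, **other.metadata})
        merged.entries = {**self.entries, **other.entries}
        merged.flags = {**self.flags, **other.flags}
        return merged

    def to_dataframe(self) -> pd.DataFrame:
        """Values only (no sds), energies as index, channels as columns."""
        cols = self.channels
        data = {c.value: [getattr(self.get(e, c), "value", None)
                          for e in self.energies] for c in cols}
        return pd.DataFrame(data, index=pd.Index(self.energies, name="energy_eV"))

    # -- text format -----------------------------------------------------
    # tab-separated columns; each cell "value sd" (space-separated) or "n.d.";
    # "# key: value" metadata header.

    def write(self, path: str | Path) -> None:
        cols = [c for c in _CHANNEL_ORDER if c in self.channels] or list(_CHANNEL_ORDER)
        lines = [f"# units: {self.units}"]
        lines += [f"# {k}: {v}" for k, v in sorted(self.metadata.items())]
        lines.append("\t".join(["energy_eV"] + [c.value for c in cols]))
        for e in self.energies:
            cells = [f"{e:.12g}"]
            for c in cols:
                uv = self.get(e, c)
                cells.append(MISSING_MARKER if uv is None
                             else f"{uv.value:.12g} {uv.sd:.12g}")
            lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "CrossSectionTable":
        meta: dict[str, str] = {}
        header: list[str] | None = None
        table = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                key, _, value = line.lstrip().lstrip("#").strip().partition(":")
                meta[key.strip()] = value.strip()
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0] != "energy_eV":
                    raise UsageError(f"unexpected header in {path}: {cells[:2]}")
                header = cells[1:]
                continue
            energy = float(cells[0])
            for name, cell in zip(header, cells[1:]):
                cell = cell.strip()
                if cell == MISSING_MARKER or not cell:
                    continue
                parts = re.split(r"\s+", cell)
                if len(parts) != 2:
                    raise UsageError(f"malformed cell {cell!r} in {path}")
                table.set(energy, DamageChannel(name),
                          UncertainValue(float(parts[0]), float(parts[1])))
        table.units = meta.pop("units", table.units)
        # re-tag entries with the file's units
        table.entries = {k: v.with_units(table.units) for k, v in table.entries.items()}
        table.metadata = meta
        return table
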