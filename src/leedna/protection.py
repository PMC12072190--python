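"""Protection factors: bare DNA versus ligand-bound DNA.

Histone proteins shield genomic DNA from radiation; arginine, one of
their major constituents, reproduces part of that shielding when
intercalated with plasmids in a film.  The protection factor for a
damage channel is the ratio of the bare-DNA to the complex-DNA
absolute cross section, PF = σ_DNA / σ_complex: a PF above 1 means the
ligand suppresses that lesion.  Percent increases express the same
comparison as 100·(σ_DNA/σ_complex − 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UsageError
from .table import CrossSectionTable, DamageChannel
from .uncertain import UncertainValue

__all__ = ["ProtectionFactorTable", "protection_factors", "percent_increase"]

logger = logging.getLogger(__name__)


@dataclass
class ProtectionFactorTable:
    """Dimensionless per-energy, per-channel protection factors."""

    entries: dict[tuple[float, DamageChannel], UncertainValue] = field(default_factory=dict)
    reference_tag: str = "DNA"
    comparison_tag: str = "complex"
    flags: dict[tuple[float, DamageChannel], str] = field(default_factory=dict)

    @property
    def energies(self) -> list[float]:
        return sorted({e for e, _ in self.entries})

    def get(self, energy: float, channel: DamageChannel | str) -> UncertainValue | None:
        return self.entries.get((float(energy), DamageChannel(channel)))

    def as_cross_section_table(self) -> CrossSectionTable:
        """Re-use the cross-section text format for writing PF tables."""
        table = CrossSectionTable(units="dimensionless", metadata={
            "quantity": "protection factor",
            "reference": self.reference_tag,
            "comparison": self.comparison_tag,
        })
        table.entries = dict(self.entries)
        table.flags = dict(self.flags)
        return table

    def write(self, path: str | Path) -> None:
        self.as_cross_section_table().write(path)


def protection_factors(dna: CrossSectionTable,
                       complex_table: CrossSectionTable) -> ProtectionFactorTable:
    """Per-channel, per-energy PF = σ_DNA / σ_complex.

    Only energies present in both tables are compared (no
    interpolation; energies present in one table only are dropped with
    a logged notice).  Relative sds combine in quadrature.  A zero
    denominator leaves the entry missing with a flag.  Display rounding
    is one decimal; full precision is stored.
    """
    if dna.units != complex_table.units:
        raise UsageError(f"units mismatch: {dna.units!r} vs {complex_table.units!r}")
    shared = [e for e in dna.energies if e in complex_table.energies]
    if not shared:
        raise UsageError("tables share no energies")
    dropped = sorted(set(dna.energies) ^ set(complex_table.energies))
    if dropped:
        logger.info("energies present in only one table dropped: %s", dropped)

    pf = ProtectionFactorTable(
        reference_tag=dna.metadata.get("source", "DNA"),
        comparison_tag=complex_table.metadata.get("source", "complex"))
    for energy in shared:
        for channel in DamageChannel:
            a = dna.get(energy, channel)
            b = complex_table.get(energy, channel)
            if a is None or b is None:
                continue
            if b.value == 0:
                pf.flags[(energy, channel)] = "zero_denominator"
                continue
            pf.entries[(energy, channel)] = (a / b).with_units("dimensionless")
    return pf


def percent_increase(dna: UncertainValue, complex_value: UncertainValue) -> UncertainValue:
    """How much larger the bare-DNA ACS is, 100·(σ_DNA/σ_complex − 1), percent.

    The sd is that of the ratio (quadrature of relative sds) scaled by
    100 — the subtraction of the exact constant 1 adds no uncertainty.
    """
    if complex_value.value <= 0:
        raise UsageError(f"comparison value must be positive, got {complex_value.value}")
    ratio = dna / complex_value
    return UncertainValue(100.0 * (ratio.value - 1.0), 100.0 * ratio.sd, "%")
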