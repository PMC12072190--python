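"""Packaged reference cross-section tables and their validation.

Ships the published 1–20 eV absolute cross sections for bare plasmid
DNA (19 energies; 19 eV was not measured and the grid is stored
as-printed, without gap filling) and for arginine–DNA complexes at 5
and 10 eV.  Cells printed "n.d." are preserved as missing.  The files
are verified against recorded SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import IntegrityError
from .table import CrossSectionTable, DamageChannel
from .uncertain import UncertainValue

__all__ = ["load_table1", "validate_table", "ValidationReport"]

_BARE = "table1_bare.tsv"
_ARG = "table1_argdna.tsv"
_CHECKSUMS = "checksums.sha256"

#: |LS + TOTAL_BD − TOTAL_DAMAGE| tolerance for the sum rule, in
#: 1e-15 cm2.  Set just above the worst-case discrepancy attributable
#: to rounding the three columns independently to one decimal (0.15),
#: so genuine inconsistencies in a printed table are flagged.
SUM_RULE_TOLERANCE = 0.25


def _data_path(name: str) -> Path:
    return Path(resources.files("leedna.data").joinpath(name))  # type: ignore[arg-type]


def _verify_checksum(name: str) -> None:
    recorded = {}
    for line in _data_path(_CHECKSUMS).read_text().splitlines():
        digest, _, fname = line.strip().partition("  ")
        recorded[fname] = digest
    actual = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
    if recorded.get(name) != actual:
        raise IntegrityError(
            f"packaged file {name} checksum mismatch: {actual} != {recorded.get(name)}")


def load_table1() -> tuple[CrossSectionTable, CrossSectionTable]:
    """Load the packaged reference tables (bare DNA, arginine-DNA).

    Every printed value and one-sigma uncertainty is reproduced
    exactly; raises :class:`IntegrityError` if a packaged file has been
    altered.
    """
    tables = []
    for name in (_BARE, _ARG):
        _verify_checksum(name)
        tables.append(CrossSectionTable.read(_data_path(name)))
    return tables[0], tables[1]


@dataclass
class ValidationReport:
    """Per-rule pass/fail with the energies that violate each rule."""

    results: dict[str, bool] = field(default_factory=dict)
    details: dict[str, list[float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.results.values())

    def __str__(self) -> str:
        lines = []
        for rule, ok in self.results.items():
            status = "pass" if ok else "FAIL"
            extra = f" (energies: {self.details[rule]})" if self.details.get(rule) else ""
            lines.append(f"{rule}: {status}{extra}")
        lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)


def validate_table(table: CrossSectionTable,
                   sum_tolerance: float = SUM_RULE_TOLERANCE) -> ValidationReport:
    """Consistency checks on a cross-section table (report-only, never raises).

    Rules: all present values non-negative; a units tag is set; LS is at
    least as large as SSB wherever both are present (a single-strand
    break always removes the supercoiled form); and the aggregate sum
    rule |LS + TOTAL_BD − TOTAL_DAMAGE| ≤ ``sum_tolerance``.  Energies
    violating a rule are listed; an empty table passes vacuously with a
    warning.
    """
    report = ValidationReport()
    if not table.entries:
        report.warnings.append("table is empty; all checks vacuous")
        for rule in ("non_negative", "units_tag", "ls_ge_ssb", "sum_rule"):
            report.results[rule] = True
        return report

    negative = sorted({e for (e, c), v in table.entries.items() if v.value < 0})
    report.results["non_negative"] = not negative
    report.details["non_negative"] = negative

    report.results["units_tag"] = bool(table.units)

    ls_violations = []
    for e in table.energies:
        ls, ssb = table.get(e, DamageChannel.LS), table.get(e, DamageChannel.SSB)
        if ls is not None and ssb is not None and ls.value < ssb.value:
            ls_violations.append(e)
    report.results["ls_ge_ssb"] = not ls_violations
    report.details["ls_ge_ssb"] = ls_violations

    outliers = []
    checked = 0
    for e in table.energies:
        ls = table.get(e, DamageChannel.LS)
        bd = table.get(e, DamageChannel.TOTAL_BD)
        total = table.get(e, DamageChannel.TOTAL_DAMAGE)
        if ls is None or bd is None or total is None:
            continue
        checked += 1
        if abs(ls.value + bd.value - total.value) > sum_tolerance:
            outliers.append(e)
    if checked == 0:
        report.warnings.append("sum rule not checkable: no complete LS/TOTAL_BD/TOTAL_DAMAGE rows")
    report.results["sum_rule"] = not outliers
    report.details["sum_rule"] = outliers
    return report
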