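"""Scalar values with one-sigma uncertainties.

Every yield, cross section and derived factor in this package is carried
as an :class:`UncertainValue` — a number, its standard deviation, and a
free-text units tag.  Arithmetic propagates uncertainties to first order
assuming independent errors: absolute standard deviations combine in
quadrature under addition/subtraction, relative standard deviations
combine in quadrature under multiplication/division.  Correlations are
never tracked; where that convention matters (aggregate totals, ratios
of related quantities) it is stated at the call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UncertainValue:
    """A scalar with a one-sigma uncertainty and a units tag."""

    value: float
    sd: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")

    @property
    def relsd(self) -> float:
        """Relative standard deviation; infinite for a zero value with sd > 0."""
        if self.value == 0:
            return 0.0 if self.sd == 0 else math.inf
        return abs(self.sd / self.value)

    # -- combinators -----------------------------------------------------

    def __add__(self, other: "UncertainValue") -> "UncertainValue":
        self._check_units(other)
        return UncertainValue(self.value + other.value,
                              math.hypot(self.sd, other.sd), self.units)

    def __sub__(self, other: "UncertainValue") -> "UncertainValue":
        self._check_units(other)
        return UncertainValue(self.value - other.value,
                              math.hypot(self.sd, other.sd), self.units)

    def __mul__(self, other):
        if isinstance(other, UncertainValue):
            value = self.value * other.value
            sd = math.hypot(other.value * self.sd, self.value * other.sd)
            return UncertainValue(value, sd, _combine_units(self.units, other.units, "*"))
        return UncertainValue(self.value * other, self.sd * abs(other), self.units)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, UncertainValue):
            if other.value == 0:
                raise ZeroDivisionError("division by an UncertainValue with value 0")
            value = self.value / other.value
            sd = math.hypot(self.sd / other.value,
                            self.value * other.sd / other.value**2)
            return UncertainValue(value, sd, _combine_units(self.units, other.units, "/"))
        return UncertainValue(self.value / other, self.sd / abs(other), self.units)

    def __neg__(self) -> "UncertainValue":
        return UncertainValue(-self.value, self.sd, self.units)

    def __abs__(self) -> "UncertainValue":
        return UncertainValue(abs(self.value), self.sd, self.units)

    def with_units(self, units: str) -> "UncertainValue":
        return UncertainValue(self.value, self.sd, units)

    def round(self, ndigits: int = 1) -> "UncertainValue":
        """Display rounding; full precision should be kept for arithmetic."""
        return UncertainValue(round(self.value, ndigits), round(self.sd, ndigits), self.units)

    def _check_units(self, other: "UncertainValue") -> None:
        if self.units and other.units and self.units != other.units:
            raise ValueError(f"units mismatch: {self.units!r} vs {other.units!r}")

    def __format__(self, spec: str) -> str:
        spec = spec or "g"
        return f"{self.value:{spec}} ± {self.sd:{spec}}"

    def __str__(self) -> str:
        tag = f" {self.units}" if self.units else ""
        return f"{self.value:g} ± {self.sd:g}{tag}"


def _combine_units(u1: str, u2: str, op: str) -> str:
    if not u2 or u2 == "dimensionless":
        return u1
    if not u1 or u1 == "dimensionless":
        return u2 if op == "*" else f"1/({u2})"
    if op == "/" and u1 == u2:
        return "dimensionless"
    return f"({u1}){op}({u2})"
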