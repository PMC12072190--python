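"""Conversion of effective yields to absolute cross sections.

An effective yield measured on a thin film understates the absolute
cross section because deeper layers see an attenuated beam; dividing by
the film's penetration factor ``f`` removes that bias, σ = Y_eff / f.
The conversion is linear, so it applies channel by channel: the
conformational channels (SSB, DSB, CL and the loss-of-supercoiled
total LS) convert directly, the enzyme-revealed channels
(isolated base damage, base-damage crosslinks, non-DSB clustered
damage) convert identically from treated-minus-untreated yields, and
totals aggregate with uncertainties combined in quadrature.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .curves import (EffectiveYieldSet, FluenceResponseCurve, Treatment,
                     curve_to_yields, enzyme_reveal, pool_yield_sets)
from .errors import DomainError, UsageError
from .table import MISSING_MARKER, CrossSectionTable, DamageChannel
from .uncertain import UncertainValue

__all__ = [
    "DEFAULT_F",
    "effective_to_acs",
    "decompose_conformational",
    "decompose_nd",
    "aggregate_totals",
    "channel_maxima",
    "analyze_curves",
]

#: Penetration factor for the film geometry these measurements use,
#: deduced from the ratio of the effective to the absolute
#: loss-of-supercoiled cross section at 10 eV.  Thickness-dependent but
#: energy-independent, so a single value serves the whole 1-20 eV scan.
DEFAULT_F = UncertainValue(0.25, 0.02, "dimensionless")

#: table scale: entries are stored in units of 1e-15 cm2
TABLE_UNIT_CM2 = 1e-15


def effective_to_acs(y_eff: UncertainValue, f: UncertainValue) -> UncertainValue:
    """Absolute cross section σ = Y_eff / f (cm²).

    Relative uncertainties of the yield and of the penetration factor
    combine in quadrature, so the result's relative sd is never smaller
    than either input's.
    """
    if not 0 < f.value <= 1:
        raise DomainError(f"penetration factor must lie in (0, 1], got {f.value}")
    if y_eff.value < 0:
        raise DomainError(f"effective yield must be non-negative, got {y_eff.value}")
    sigma = y_eff.value / f.value
    sd = abs(sigma) * math.hypot(y_eff.relsd if y_eff.value else 0.0, f.relsd)
    if y_eff.value == 0:
        sd = y_eff.sd / f.value
    return UncertainValue(sigma, sd, y_eff.units)


def _convert_channels(yields: EffectiveYieldSet, f: UncertainValue,
                      mapping: Mapping[str, DamageChannel],
                      required: Sequence[str]) -> CrossSectionTable:
    missing = [ch for ch in required if ch not in yields]
    if missing:
        raise UsageError(f"yield set lacks required channels: {missing}")
    table = CrossSectionTable(metadata={"f": f"{f.value:g} {f.sd:g}"})
    for name, channel in mapping.items():
        if name not in yields:
            continue
        sigma = effective_to_acs(yields[name], f)
        scaled = UncertainValue(sigma.value / TABLE_UNIT_CM2,
                                sigma.sd / TABLE_UNIT_CM2)
        table.set(yields.energy, channel, scaled, flag=yields.flags.get(name))
    return table


def decompose_conformational(yields: EffectiveYieldSet,
                             f: UncertainValue = DEFAULT_F) -> CrossSectionTable:
    """ACSs for the conformational channels {SSB, DSB, CL, LS} at one energy.

    Each channel converts independently (the yield-to-ACS map is
    linear).  LS, the loss-of-supercoiled total, is taken from the
    supercoiled-band slope when present.
    """
    mapping = {"SSB": DamageChannel.SSB, "DSB": DamageChannel.DSB,
               "CL": DamageChannel.CL, "LS": DamageChannel.LS}
    return _convert_channels(yields, f, mapping, required=("SSB", "DSB", "CL"))


def decompose_nd(revealed: EffectiveYieldSet,
                 f: UncertainValue = DEFAULT_F) -> CrossSectionTable:
    """ACSs for the enzyme-revealed channels {isolated BD, BD-CL, NDCD}.

    The residual "other non-detected damage" (OND) term has no
    measurement path — the gel only sees what the enzymes convert — so
    it is left missing rather than imputed.  A revealed yield flagged
    negative is converted on its magnitude's scale, carries its flag,
    and is excluded from totals downstream.
    """
    mapping = {"isolated_BD": DamageChannel.ISOLATED_BD,
               "BD_CL": DamageChannel.BD_CL, "NDCD": DamageChannel.NDCD}
    missing = [ch for ch in mapping if ch not in revealed]
    if missing:
        raise UsageError(f"revealed yield set lacks channels: {missing}")
    table = CrossSectionTable(metadata={"f": f"{f.value:g} {f.sd:g}"})
    for name, channel in mapping.items():
        uv = revealed[name]
        flag = revealed.flags.get(name)
        if uv.value < 0:
            # keep the negative value visible; propagate on its magnitude
            sigma = effective_to_acs(abs(uv), f)
            scaled = UncertainValue(-sigma.value / TABLE_UNIT_CM2,
                                    sigma.sd / TABLE_UNIT_CM2)
        else:
            sigma = effective_to_acs(uv, f)
            scaled = UncertainValue(sigma.value / TABLE_UNIT_CM2,
                                    sigma.sd / TABLE_UNIT_CM2)
        table.set(revealed.energy, channel, scaled, flag=flag)
    return table


def aggregate_totals(table: CrossSectionTable) -> CrossSectionTable:
    """Fill the TOTAL_DAMAGE column as LS + TOTAL_BD, sds in quadrature.

    TOTAL_BD must come from its own measurement (the pooled
    enzyme-revealed total), never from summing ISOLATED_BD + BD_CL +
    NDCD — those columns are independent measurements whose sum need not
    match.  Where TOTAL_BD is absent, TOTAL_DAMAGE falls back to LS
    alone and is flagged.  Entries flagged negative are excluded.
    """
    out = table.merge(CrossSectionTable(units=table.units))
    for energy in table.energies:
        ls = table.get(energy, DamageChannel.LS)
        if ls is None:
            raise UsageError(f"missing LS at {energy} eV; cannot aggregate totals")
        bd = table.get(energy, DamageChannel.TOTAL_BD)
        if bd is not None and table.flags.get((energy, DamageChannel.TOTAL_BD)) == "negative":
            bd = None
        if bd is None:
            out.set(energy, DamageChannel.TOTAL_DAMAGE, ls, flag="LS_only")
        else:
            out.set(energy, DamageChannel.TOTAL_DAMAGE, ls + bd)
    return out


def channel_maxima(table: CrossSectionTable,
                   channels: Iterable[DamageChannel] | None = None
                   ) -> dict[DamageChannel, tuple[float, UncertainValue, bool]]:
    """Energy of the maximum ACS per channel, ignoring missing entries.

    Returns ``{channel: (energy_eV, value, tied)}``; ties break toward
    the lower energy with ``tied=True``.
    """
    result: dict[DamageChannel, tuple[float, UncertainValue, bool]] = {}
    for channel in (channels or table.channels):
        channel = DamageChannel(channel)
        present = [(e, table.get(e, channel)) for e in table.energies
                   if (e, channel) in table]
        if not present:
            raise UsageError(f"channel {channel.value} has no entries")
        best = max(v.value for _, v in present)
        winners = [e for e, v in present if v.value == best]
        energy = min(winners)
        result[channel] = (energy, table.get(energy, channel), len(winners) > 1)
    return result


def analyze_curves(curves: Sequence[FluenceResponseCurve],
                   f: UncertainValue = DEFAULT_F,
                   pooling: str = "ivw",
                   **fit_kwargs) -> CrossSectionTable:
    """Full analysis: fluence-response curves → per-energy ACS table.

    Per energy: slopes are fitted per replicate and combined by
    inverse-variance weighting (respecting per-gel calibration
    differences); enzyme-treated minus untreated differences give the
    revealed channels, pooled across enzymes; the total base-damage
    yield is measured independently as the treated-minus-untreated
    difference of the loss-of-supercoiled yield; totals then aggregate
    as LS + TOTAL_BD.
    """
    if not curves:
        raise UsageError("no curves to analyze")
    by_energy: dict[float, dict[Treatment, list[FluenceResponseCurve]]] = defaultdict(
        lambda: defaultdict(list))
    for c in curves:
        by_energy[c.energy][c.treatment].append(c)

    result = CrossSectionTable(metadata={"f": f"{f.value:g} {f.sd:g}"})
    for energy, groups in sorted(by_energy.items()):
        if Treatment.NONE not in groups:
            raise UsageError(f"no untreated curves at {energy} eV")
        untreated = pool_yield_sets(
            [curve_to_yields(c, **fit_kwargs) for c in groups[Treatment.NONE]],
            mode=pooling)
        partial = decompose_conformational(untreated, f)

        revealed_sets: list[EffectiveYieldSet] = []
        total_bd_yields: list[UncertainValue] = []
        for treatment in (Treatment.NTH, Treatment.FPG, Treatment.BOTH):
            if treatment not in groups:
                continue
            treated = pool_yield_sets(
                [curve_to_yields(c, **fit_kwargs) for c in groups[treatment]],
                mode=pooling)
            revealed_sets.append(enzyme_reveal(treated, untreated))
            total_bd_yields.append(treated["LS"] - untreated["LS"])
        if revealed_sets:
            pooled_revealed = pool_yield_sets(revealed_sets, mode=pooling)
            partial = partial.merge(decompose_nd(pooled_revealed, f))
            pooled_bd = pool_yield_sets(
                [EffectiveYieldSet(energy, {"TOTAL_BD": y}) for y in total_bd_yields],
                mode=pooling)["TOTAL_BD"]
            if pooled_bd.value < 0:
                pooled_bd = UncertainValue(0.0, pooled_bd.sd, pooled_bd.units)
            sigma_bd = effective_to_acs(pooled_bd, f)
            partial.set(energy, DamageChannel.TOTAL_BD,
                        UncertainValue(sigma_bd.value / TABLE_UNIT_CM2,
                                       sigma_bd.sd / TABLE_UNIT_CM2))
        result = result.merge(partial)
    return aggregate_totals(result)
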