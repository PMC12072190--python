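"""Fluence-response curves and zero-fluence yield extraction.

An irradiation series records, at each electron fluence, the percentage
of the plasmid population in each agarose-gel band: supercoiled
(intact), circular (single-strand break), linear (double-strand break)
and crosslink dimer (two plasmids covalently joined).  Damage yields
are read off as the slopes of these band percentages at zero fluence,
where the response is linear and every lesion is attributable to a
single electron.  Base damages are invisible to the gel until a base
excision repair enzyme (Nth or Fpg) converts them to strand breaks; the
treated-minus-untreated difference of yields therefore measures the
base-damage-related channels.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import UsageError
from .uncertain import UncertainValue

__all__ = [
    "BANDS",
    "Treatment",
    "FluenceResponseCurve",
    "SlopeEstimate",
    "EffectiveYieldSet",
    "read_curve",
    "write_curve",
    "fit_zero_fluence_slope",
    "effective_yield",
    "curve_to_yields",
    "enzyme_reveal",
    "pool_yield_sets",
]

BANDS = ("supercoiled", "circular", "linear", "crosslink")

#: gel band that detects each damage channel in an untreated sample
BAND_TO_CHANNEL = {"circular": "SSB", "linear": "DSB", "crosslink": "CL",
                   "supercoiled": "LS"}


class Treatment(str, enum.Enum):
    """Base-excision-enzyme treatment applied before electrophoresis."""

    NONE = "none"
    NTH = "Nth"
    FPG = "Fpg"
    BOTH = "both"


@dataclass
class FluenceResponseCurve:
    """One irradiation series: band percentages against electron fluence.

    ``fluence`` is strictly increasing and starts at 0 (the unirradiated
    control); ``bands`` maps each of :data:`BANDS` to a percentage array
    of the same length.  Band percentages must lie in [0, 100] and each
    row must sum to at most 100 plus a small noise allowance.
    """

    energy: float                       # eV
    thickness: float                    # nm
    treatment: Treatment
    fluence: np.ndarray                 # electrons cm^-2
    bands: dict[str, np.ndarray]        # percent, keys = BANDS
    replicate: str = "r1"
    J: float | None = None              # electrons cm^-2 s^-1
    sum_tolerance: float = 3.0          # percentage points

    def __post_init__(self) -> None:
        self.fluence = np.asarray(self.fluence, dtype=float)
        self.bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}
        self.treatment = Treatment(self.treatment)
        if self.fluence.ndim != 1 or len(self.fluence) == 0:
            raise UsageError("fluence must be a non-empty 1-D array")
        if self.fluence[0] != 0:
            raise UsageError("fluence grid must start at 0")
        if np.any(np.diff(self.fluence) <= 0):
            raise UsageError("fluence must be strictly increasing")
        missing = [b for b in BANDS if b not in self.bands]
        if missing:
            raise UsageError(f"missing band columns: {missing}")
        for name, arr in self.bands.items():
            if arr.shape != self.fluence.shape:
                raise UsageError(f"band {name!r} length mismatch")
            if np.any(arr < 0) or np.any(arr > 100):
                raise UsageError(f"band {name!r} outside [0, 100]")
        totals = sum(self.bands[b] for b in BANDS)
        if np.any(totals > 100 + self.sum_tolerance):
            raise UsageError(
                f"band percentages sum above 100 + {self.sum_tolerance} at some fluences")

    @property
    def n_points(self) -> int:
        return len(self.fluence)

    @property
    def P0(self) -> float:
        """Intact percentage at zero fluence."""
        return float(self.bands["supercoiled"][0])


@dataclass(frozen=True)
class SlopeEstimate:
    """An OLS zero-fluence slope for one gel band.

    Units: percent per (electrons cm⁻²).
    """

    slope: float
    stderr: float
    window: int            # number of leading fluence points used
    fit_quality: float     # coefficient of determination of the line
    channel: str

    def __post_init__(self) -> None:
        if self.window < 3:
            raise UsageError(f"slope window must cover >= 3 points, got {self.window}")
        if self.stderr < 0:
            raise UsageError("stderr must be non-negative")

    def as_uncertain(self, units: str = "%/(e cm^-2)") -> UncertainValue:
        return UncertainValue(self.slope, self.stderr, units)


@dataclass
class EffectiveYieldSet:
    """Per-channel effective yields (= effective cross sections, cm²) at one energy."""

    energy: float
    yields: dict[str, UncertainValue]
    provenance: tuple[str, ...] = ()
    flags: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> UncertainValue:
        return self.yields[channel]

    def __contains__(self, channel: str) -> bool:
        return channel in self.yields


# ---------------------------------------------------------------------------
# curve file I/O: "# key: value" header + delimited table
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"energy_eV": "energy", "thickness_nm": "thickness",
                "treatment": "treatment", "replicate": "replicate", "J": "J"}
_COLUMNS = ("fluence", "pct_supercoiled", "pct_circular", "pct_linear",
            "pct_crosslink")


def write_curve(curve: FluenceResponseCurve, path: str | Path,
                delimiter: str = "\t") -> None:
    """Write a curve as delimited text with a ``# key: value`` metadata header.

    Values are printed with 12 significant digits, so a round trip is
    lossless at that precision.
    """
    lines = [
        f"# energy_eV: {curve.energy:.12g}",
        f"# thickness_nm: {curve.thickness:.12g}",
        f"# treatment: {curve.treatment.value}",
        f"# replicate: {curve.replicate}",
    ]
    if curve.J is not None:
        lines.append(f"# J: {curve.J:.12g}")
    lines.append(delimiter.join(_COLUMNS))
    for i in range(curve.n_points):
        row = [curve.fluence[i]] + [curve.bands[b][i] for b in BANDS]
        lines.append(delimiter.join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> FluenceResponseCurve:
    """Read a curve written by :func:`write_curve` (tab or comma delimited)."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header_seen = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition(":")
            meta[key.strip()] = value.strip()
            continue
        fields = re.split(r"[\t,]", line)
        if not header_seen:
            if [f.strip() for f in fields] != list(_COLUMNS):
                raise UsageError(f"unexpected column header in {path}: {fields}")
            header_seen = True
            continue
        rows.append([float(f) for f in fields])
    if "energy_eV" not in meta or "treatment" not in meta:
        raise UsageError(f"curve file {path} lacks required metadata")
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(_COLUMNS):
        raise UsageError(f"malformed data table in {path}")
    return FluenceResponseCurve(
        energy=float(meta["energy_eV"]),
        thickness=float(meta.get("thickness_nm", "nan")),
        treatment=Treatment(meta["treatment"]),
        fluence=data[:, 0],
        bands={b: data[:, i + 1] for i, b in enumerate(BANDS)},
        replicate=meta.get("replicate", "r1"),
        J=float(meta["J"]) if "J" in meta else None,
    )


# ---------------------------------------------------------------------------
# zero-fluence slope fitting
# ---------------------------------------------------------------------------

def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, slope stderr and R² of an ordinary least-squares line."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - ym) ** 2))
    dof = n - 2
    stderr = math.sqrt(rss / dof / sxx) if dof > 0 else 0.0
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return slope, stderr, r2


def _quadratic_lack_of_fit_p(x: np.ndarray, y: np.ndarray) -> float:
    """p-value of the quadratic coefficient against a straight-line null."""
    n = len(x)
    if n < 4:
        return 1.0
    # scale x to avoid ill-conditioning at fluences ~1e13
    xs = x / x.max()
    X = np.column_stack([np.ones(n), xs, xs**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 3
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    if s2 == 0:
        return 1.0
    cov = s2 * np.linalg.inv(X.T @ X)
    tstat = beta[2] / math.sqrt(cov[2, 2])
    return float(2 * stats.t.sf(abs(tstat), dof))


def fit_zero_fluence_slope(
    curve: FluenceResponseCurve,
    band: str,
    window: int | None = None,
    max_loss_fraction: float = 0.20,
    lack_of_fit_alpha: float = 0.05,
    min_points: int = 3,
) -> SlopeEstimate:
    """Fit the zero-fluence slope of one gel band by ordinary least squares.

    The fitting window guards the single-hit regime: by default it is
    the largest leading run of points over which the supercoiled loss
    stays below ``max_loss_fraction`` of its initial value *and* a
    quadratic alternative shows no significant lack of fit
    (p ≥ ``lack_of_fit_alpha``), with at least ``min_points`` points.
    Pass ``window`` to fix the number of leading points instead.
    """
    if band not in BANDS:
        raise UsageError(f"unknown band {band!r}; expected one of {BANDS}")
    if curve.n_points < min_points:
        raise UsageError(
            f"need >= {min_points} fluence points, curve has {curve.n_points}")
    y_all = curve.bands[band]
    x_all = curve.fluence

    if window is not None:
        if window < min_points or window > curve.n_points:
            raise UsageError(f"window {window} outside [{min_points}, {curve.n_points}]")
        n_sel = window
    else:
        sc = curve.bands["supercoiled"]
        loss = curve.P0 - sc
        within = np.flatnonzero(loss <= max_loss_fraction * curve.P0)
        # leading run only
        n_max = int(within[-1] + 1) if len(within) and within[0] == 0 else 0
        n_max = min(max(n_max, min_points), curve.n_points)
        n_sel = min_points
        for n in range(n_max, min_points - 1, -1):
            if _quadratic_lack_of_fit_p(x_all[:n], y_all[:n]) >= lack_of_fit_alpha:
                n_sel = n
                break

    x, y = x_all[:n_sel], y_all[:n_sel]
    if np.all(y == 0):
        return SlopeEstimate(0.0, 0.0, n_sel, 1.0, BAND_TO_CHANNEL[band])
    slope, stderr, r2 = _ols_line(x, y)
    return SlopeEstimate(slope, stderr, n_sel, r2, BAND_TO_CHANNEL[band])


def effective_yield(slope: SlopeEstimate, P0: float) -> UncertainValue:
    """Effective yield |slope|/P0 of one channel, in cm² (per unit fluence).

    With fluence-domain slopes the current density J is already absorbed
    into the fluence axis; with time-domain slopes divide additionally
    by J.
    """
    if P0 <= 0:
        raise UsageError(f"P0 must be positive, got {P0}")
    return UncertainValue(abs(slope.slope) / P0, slope.stderr / P0, "cm^2")


def curve_to_yields(curve: FluenceResponseCurve, **fit_kwargs) -> EffectiveYieldSet:
    """Per-channel effective yields of one curve.

    Product bands (circular, linear, crosslink) map to SSB, DSB and CL;
    the magnitude of the supercoiled-band slope gives the
    loss-of-supercoiled (LS) total-conformational-damage yield.
    """
    yields: dict[str, UncertainValue] = {}
    for band, channel in BAND_TO_CHANNEL.items():
        est = fit_zero_fluence_slope(curve, band, **fit_kwargs)
        yields[channel] = effective_yield(est, curve.P0)
    return EffectiveYieldSet(
        energy=curve.energy, yields=yields,
        provenance=(f"{curve.replicate}/{curve.treatment.value}",))


# ---------------------------------------------------------------------------
# enzyme-revealed channels and pooling
# ---------------------------------------------------------------------------

#: treated-minus-untreated differences per gel channel and what they reveal
REVEALED_FROM = {"isolated_BD": "SSB", "BD_CL": "CL", "NDCD": "DSB"}


def enzyme_reveal(treated: EffectiveYieldSet,
                  untreated: EffectiveYieldSet) -> EffectiveYieldSet:
    """Base-damage-related yields from treated-minus-untreated differences.

    Enzyme treatment converts isolated base damages to extra SSBs,
    base-damage crosslinks to extra CLs and non-DSB clustered damages to
    extra DSBs, so the per-channel yield differences measure
    ``isolated_BD``, ``BD_CL`` and ``NDCD``.  Uncertainties combine in
    quadrature.  A negative difference within one combined sd is clipped
    to 0 and flagged ``clipped_negative`` (small negatives are noise);
    a negative beyond one sd is retained and flagged ``negative`` so
    data problems stay visible.
    """
    if treated.energy != untreated.energy:
        raise UsageError(
            f"energy mismatch: {treated.energy} eV vs {untreated.energy} eV")
    yields: dict[str, UncertainValue] = {}
    flags: dict[str, str] = {}
    for revealed, channel in REVEALED_FROM.items():
        diff = treated[channel] - untreated[channel]
        if diff.value < 0:
            if abs(diff.value) <= diff.sd:
                yields[revealed] = UncertainValue(0.0, diff.sd, diff.units)
                flags[revealed] = "clipped_negative"
                continue
            flags[revealed] = "negative"
        yields[revealed] = diff
    return EffectiveYieldSet(
        energy=treated.energy, yields=yields,
        provenance=treated.provenance + untreated.provenance, flags=flags)


def pool_yield_sets(sets: Sequence[EffectiveYieldSet],
                    mode: str = "ivw") -> EffectiveYieldSet:
    """Combine yield sets at one energy across replicates or enzymes.

    ``mode="ivw"`` (default) takes the inverse-variance-weighted mean of
    each channel — appropriate for replicate measurements of the same
    quantity and the conservative way to pool per-enzyme revealed
    yields.  ``mode="sum"`` adds channels with quadrature sds — only
    meaningful when the inputs measure disjoint lesion populations.
    """
    if not sets:
        raise UsageError("nothing to pool")
    energies = {s.energy for s in sets}
    if len(energies) > 1:
        raise UsageError(f"cannot pool across energies {sorted(energies)}")
    if mode not in ("ivw", "sum"):
        raise UsageError(f"unknown pooling mode {mode!r}")
    channels: list[str] = []
    for s in sets:
        channels.extend(c for c in s.yields if c not in channels)
    pooled: dict[str, UncertainValue] = {}
    for ch in channels:
        members = [s[ch] for s in sets if ch in s]
        if mode == "sum":
            total = members[0]
            for m in members[1:]:
                total = total + m
            pooled[ch] = total
            continue
        if len(members) == 1:
            pooled[ch] = members[0]
            continue
        if all(m.sd > 0 for m in members):
            w = np.array([1.0 / m.sd**2 for m in members])
        else:
            w = np.ones(len(members))
        vals = np.array([m.value for m in members])
        mean = float(np.sum(w * vals) / np.sum(w))
        sd = float(1.0 / math.sqrt(np.sum(w))) if all(m.sd > 0 for m in members) else 0.0
        pooled[ch] = UncertainValue(mean, sd, members[0].units)
    prov = tuple(p for s in sets for p in s.provenance)
    flags: dict[str, str] = {}
    for s in sets:
        flags.update(s.flags)
    return EffectiveYieldSet(energy=sets[0].energy, yields=pooled,
                             provenance=prov, flags=flags)
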