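"""Synthetic fluence-response experiments with known ground truth.

Emulates the statistical structure of the plasmid-film irradiation
assay so the whole analysis chain can be exercised end to end: lesions
arrive as independent Poisson processes per channel with rates
proportional to the local effective fluence (beam charging saturates
the fluence over the charging time constant; depth attenuation reduces
it as ``exp(-x/λ)``, handled by binning plasmids into equal depth
slices); a plasmid's gel band follows migration precedence
DSB → linear, crosslink → dimer, SSB → circular, else supercoiled;
base-damage channels stay invisible until enzyme treatment converts
them (isolated BD → extra SSB, BD-CL → extra CL, NDCD → extra DSB)
with a configurable conversion efficiency; band percentages from a
finite plasmid population receive additive truncated Gaussian readout
noise.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize

from .curves import BANDS, FluenceResponseCurve, Treatment, write_curve
from .errors import DomainError, UsageError
from .film import FilmParameters, penetration_factor
from .pipeline import DEFAULT_F, TABLE_UNIT_CM2
from .reference import load_table1
from .table import DamageChannel
from .uncertain import UncertainValue

__all__ = ["SyntheticTruth", "simulate_experiment", "make_truth_from_table1",
            "default_film", "write_experiment"]

#: channels a SyntheticTruth must specify, cm^2
TRUTH_CHANNELS = ("SSB", "DSB", "CL", "ISOLATED_BD", "BD_CL", "NDCD")

#: expected lesion count per plasmid at the film surface (the most
#: exposed depth) at the largest design fluence when the fluence grid is
#: chosen automatically.  The surface, not the depth average, is what
#: must stay in the single-hit regime: at 0.25 expected hits, fewer than
#: 12% of damaged surface plasmids carry more than one lesion.
TARGET_SURFACE_EXPOSURE = 0.25


def default_film(f: float = DEFAULT_F.value, h: float = 20.0,
                 tau: float | None = 100.0, J: float = 1e12,
                 P0: float = 100.0) -> FilmParameters:
    """Film with thickness ``h`` whose attenuation length reproduces ``f``.

    Solves f(h, λ) = f for λ, so forward simulation and analysis share
    a consistent penetration factor.  Defaults describe a 20 nm film
    with a mildly charging beam and a fully supercoiled prep (P0 = 100;
    with P0 < 100 the pre-damaged circular plasmids also feed the
    linear and dimer bands, and the per-``P0`` yield normalization then
    overstates product yields by the factor 100/P0 — the same
    convention bias an impure prep causes in the real assay).
    """
    if not 0 < f < 1:
        raise DomainError(f"penetration factor must lie in (0, 1), got {f}")
    lam = optimize.brentq(lambda l: penetration_factor(h, l) - f, 1e-3 * h, 1e6 * h)
    return FilmParameters(h=h, lambda_att=float(lam), tau=tau, J=J, P0=P0)


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic irradiation experiment."""

    energy: float                                  # eV (label only)
    sigma: dict[str, float]                        # channel -> cm^2
    film: FilmParameters
    noise_sd: float = 0.5                          # percentage points
    seed: int = 0
    fluence_design: np.ndarray | None = None       # e cm^-2; None = auto
    enzyme_efficiency: float = 1.0
    n_plasmids: int | None = 100_000   # None: exact expected percentages
    n_depth_slices: int = 50
    n_replicates: int = 3
    n_fluences: int = 8                            # used when design is auto

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_CHANNELS if c not in self.sigma]
        if missing:
            raise UsageError(f"truth lacks channels: {missing}")
        if any(v < 0 for v in self.sigma.values()):
            raise DomainError("true cross sections must be non-negative")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if not 0 <= self.enzyme_efficiency <= 1:
            raise DomainError("enzyme_efficiency must lie in [0, 1]")
        if self.fluence_design is not None:
            self.fluence_design = np.asarray(self.fluence_design, dtype=float)
            if self.fluence_design[0] != 0 or np.any(np.diff(self.fluence_design) <= 0):
                raise UsageError("fluence design must start at 0 and increase strictly")

    def visible_sigma(self, treatment: Treatment) -> float:
        """Total cross section removing plasmids from the supercoiled band."""
        s = self.sigma
        total = s["SSB"] + s["DSB"] + s["CL"]
        if treatment is not Treatment.NONE:
            total += self.enzyme_efficiency * (
                s["ISOLATED_BD"] + s["BD_CL"] + s["NDCD"])
        return total


def _design_fluence(truth: SyntheticTruth, treatment: Treatment) -> np.ndarray:
    if truth.fluence_design is not None:
        return truth.fluence_design
    sigma_vis = truth.visible_sigma(treatment)
    if sigma_vis == 0:
        return np.linspace(0.0, 1e13, truth.n_fluences)
    fmax = TARGET_SURFACE_EXPOSURE / sigma_vis
    return np.linspace(0.0, fmax, truth.n_fluences)


def _charged_fluence(fluence: np.ndarray, film: FilmParameters) -> np.ndarray:
    """Surface effective fluence after charge buildup, e cm^-2."""
    if film.charging_disabled:
        return fluence
    t = fluence / film.J
    return -film.J * film.tau * np.expm1(-t / film.tau)


def _band_counts(truth: SyntheticTruth, treatment: Treatment,
                 fluence: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Expected band probabilities per depth slice, sampled multinomially."""
    film = truth.film
    eps = truth.enzyme_efficiency if treatment is not Treatment.NONE else 0.0
    s = truth.sigma
    # per-band lesion rates: what sends a plasmid to linear / dimer / circular
    sig_lin = s["DSB"] + eps * s["NDCD"]
    sig_cross = s["CL"] + eps * s["BD_CL"]
    sig_circ = s["SSB"] + eps * s["ISOLATED_BD"]

    x_mid = (np.arange(truth.n_depth_slices) + 0.5) * film.h / truth.n_depth_slices
    depth_kernel = np.exp(-x_mid / film.lambda_att)            # (slices,)
    phi = _charged_fluence(fluence, film)[:, None] * depth_kernel[None, :]

    p_lin = -np.expm1(-sig_lin * phi)
    p_cross = np.exp(-sig_lin * phi) * (-np.expm1(-sig_cross * phi))
    p_circ_hit = np.exp(-(sig_lin + sig_cross) * phi) * (-np.expm1(-sig_circ * phi))
    p_sc = np.exp(-(sig_lin + sig_cross + sig_circ) * phi)

    w_intact = film.P0 / 100.0
    w_pre = 1.0 - w_intact
    if truth.n_plasmids is None:
        # exact expected percentages, averaged over depth slices;
        # pre-damaged (already circular) plasmids can still pick up a
        # DSB or crosslink but never return to supercoiled
        return {
            "supercoiled": 100.0 * w_intact * p_sc.mean(axis=1),
            "circular": 100.0 * (w_intact * p_circ_hit.mean(axis=1)
                                 + w_pre * (1 - p_lin - p_cross).mean(axis=1)),
            "linear": 100.0 * (w_intact * p_lin + w_pre * p_lin).mean(axis=1),
            "crosslink": 100.0 * (w_intact * p_cross + w_pre * p_cross).mean(axis=1),
        }
    n_intact = int(round(truth.n_plasmids * w_intact / truth.n_depth_slices))
    n_pre = int(round(truth.n_plasmids * w_pre / truth.n_depth_slices))
    counts = {b: np.zeros(len(fluence)) for b in BANDS}
    for i in range(len(fluence)):
        for j in range(truth.n_depth_slices):
            if n_intact:
                probs = np.array([p_sc[i, j], p_circ_hit[i, j],
                                  p_lin[i, j], p_cross[i, j]])
                probs = np.clip(probs, 0, None)
                probs /= probs.sum()
                drawn = rng.multinomial(n_intact, probs)
                counts["supercoiled"][i] += drawn[0]
                counts["circular"][i] += drawn[1]
                counts["linear"][i] += drawn[2]
                counts["crosslink"][i] += drawn[3]
            if n_pre:
                q_lin = p_lin[i, j]
                q_cross = p_cross[i, j]
                probs = np.array([max(1 - q_lin - q_cross, 0.0), q_lin, q_cross])
                probs /= probs.sum()
                drawn = rng.multinomial(n_pre, probs)
                counts["circular"][i] += drawn[0]
                counts["linear"][i] += drawn[1]
                counts["crosslink"][i] += drawn[2]
    population = truth.n_depth_slices * (n_intact + n_pre)
    return {b: counts[b] / population * 100.0 for b in BANDS}


def simulate_experiment(
    truth: SyntheticTruth,
    treatments: Sequence[Treatment | str] = (Treatment.NONE, Treatment.BOTH),
) -> list[FluenceResponseCurve]:
    """Simulate fluence-response curves for each treatment and replicate.

    Each treatment uses its own fluence grid (separate irradiations are
    run for enzyme-treated analysis, so the grid can be scaled to keep
    the faster-depleting treated films in the single-hit regime) unless
    ``truth.fluence_design`` fixes one.  Output order and random draws
    are fixed by ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    curves: list[FluenceResponseCurve] = []
    for treatment in [Treatment(t) for t in treatments]:
        fluence = _design_fluence(truth, treatment)
        for rep in range(truth.n_replicates):
            bands = _band_counts(truth, treatment, fluence, rng)
            if truth.noise_sd > 0:
                for b in BANDS:
                    noisy = bands[b] + rng.normal(0.0, truth.noise_sd, len(fluence))
                    bands[b] = np.clip(noisy, 0.0, 100.0)
                # gel quantification reports relative lane intensities: a
                # lane whose noisy bands total above 100% is renormalized
                totals = sum(bands[b] for b in BANDS)
                over = totals > 100.0
                if np.any(over):
                    scale = np.where(over, 100.0 / totals, 1.0)
                    for b in BANDS:
                        bands[b] = bands[b] * scale
            curves.append(FluenceResponseCurve(
                energy=truth.energy,
                thickness=truth.film.h,
                treatment=treatment,
                fluence=fluence.copy(),
                bands=bands,
                replicate=f"sim{truth.seed}-r{rep + 1}",
                J=truth.film.J,
                sum_tolerance=max(3.0, 4.0 * truth.noise_sd),
            ))
    return curves


def make_truth_from_table1(energy: float,
                           f: UncertainValue = DEFAULT_F,
                           seed: int = 0,
                           **overrides) -> SyntheticTruth:
    """Ground truth seeded from the packaged bare-DNA reference table.

    Channel cross sections are the printed ACS values converted from
    10⁻¹⁵ cm² to cm²; "n.d." cells become 0.  The film geometry is
    constructed so its penetration factor equals ``f.value``.
    """
    bare, _ = load_table1()
    if float(energy) not in bare.energies:
        raise UsageError(
            f"energy {energy} eV not in the packaged table (have {bare.energies})")
    channel_map = {"SSB": DamageChannel.SSB, "DSB": DamageChannel.DSB,
                   "CL": DamageChannel.CL, "ISOLATED_BD": DamageChannel.ISOLATED_BD,
                   "BD_CL": DamageChannel.BD_CL, "NDCD": DamageChannel.NDCD}
    sigma = {}
    for name, channel in channel_map.items():
        uv = bare.get(energy, channel)
        sigma[name] = 0.0 if uv is None else uv.value * TABLE_UNIT_CM2
    film = overrides.pop("film", None) or default_film(f.value)
    return SyntheticTruth(energy=float(energy), sigma=sigma, film=film,
                          seed=seed, **overrides)


def write_experiment(truth: SyntheticTruth, outdir: str | Path,
                     treatments: Sequence[Treatment | str] = (Treatment.NONE,
                                                              Treatment.BOTH),
                     ) -> list[Path]:
    """Write simulated curves plus a manifest recording truth and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves = simulate_experiment(truth, treatments)
    paths = []
    for curve in curves:
        name = (f"curve_{curve.energy:g}eV_{curve.treatment.value}"
                f"_{curve.replicate}.tsv")
        write_curve(curve, outdir / name)
        paths.append(outdir / name)
    manifest = {
        "energy_eV": truth.energy,
        "sigma_cm2": truth.sigma,
        "film": {"h_nm": truth.film.h, "lambda_nm": truth.film.lambda_att,
                 "tau_s": truth.film.tau, "J_e_per_cm2_s": truth.film.J,
                 "P0_percent": truth.film.P0},
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "enzyme_efficiency": truth.enzyme_efficiency,
        "n_plasmids": truth.n_plasmids,
        "n_replicates": truth.n_replicates,
        "curves": [p.name for p in paths],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return paths + [manifest_path]
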