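# Methods

## Survival model for an irradiated plasmid film

A film of thickness `h` (nm) on a metal substrate is exposed to a
uniform low-energy-electron beam of current density `J`
(electrons cm⁻² s⁻¹). Writing `σ` (cm²) for the absolute cross section
of the lesion of interest, the fraction of initially intact
(supercoiled) plasmids surviving to time `t` is modeled as

    P(t) = (P0/h) ∫₀ʰ exp(−σ · Jτ(1 − e^(−t/τ)) · e^(−x/λ)) dx

with three phenomenological film parameters: the attenuation length
`λ` (nm) over which the beam's damaging effect decays with depth, the
charging time constant `τ` (s) over which trapped charge saturates the
effective fluence, and the initial intact percentage `P0`. The model
assumes a first-order (single-hit exponential) loss process at every
depth, uniform current density, and separable charging and attenuation
kernels. The exponent's grouping — charging factor times depth factor —
is the reading consistent with the charging-independent initial slope

    P'(0) = −P0 · σ · J · f(h, λ),   f(h, λ) = (λ/h)(1 − e^(−h/λ)),

a property verified numerically in the test suite (the analytic slope
matches the central-difference derivative of the quadrature to 1e−4
relative for τ spanning three orders of magnitude).

Because `P'(0)` is charging-independent, extrapolating fluence-response
curves to zero fluence gives an effective yield `Y_eff = |P'(0)|/P0`
(per unit fluence, i.e. cm²) that equals `σ·f`; dividing by the
penetration factor removes the film-geometry bias: `σ = Y_eff / f`.
The conversion is linear, so it applies channel by channel to SSB,
DSB, CL, the loss-of-supercoiled total (LS), and the enzyme-revealed
channels.

Numerics: the survival integral is evaluated by adaptive quadrature
(relative tolerance 1e−10, Simpson fallback on 10⁴ panels); the
penetration factor is computed as `−expm1(−h/λ)/(h/λ)`, which is stable
in both the thin-film (f → 1) and thick-film (f → λ/h) limits without
a series-expansion branch. Disabling charging (`τ = None`) replaces
`Jτ(1 − e^(−t/τ))` by its limit `J·t`.

## Zero-fluence slopes and the single-hit window

"Near zero fluence" is not a sharp notion; the default window policy
makes it reproducible: the largest leading run of points over which
the supercoiled loss stays below 20% of its initial value *and* a
quadratic alternative shows no significant lack of fit (p ≥ 0.05),
with at least 3 points; a fixed point count can be forced instead.
Slopes are ordinary least squares; an all-zero band returns slope 0.
Replicates are fitted separately and combined by inverse-variance
weighting, respecting per-gel calibration differences, rather than by
pooling raw points.

## Enzyme-revealed base damage

Nth/Fpg treatment converts base lesions into gel-visible ones, so
treated-minus-untreated yield differences measure: isolated base
damages (extra SSBs), base-damage crosslinks (extra CLs), and non-DSB
clustered damages (extra DSBs). Differences carry quadrature
uncertainties. A negative difference within one combined sd is clipped
to zero and flagged (small negatives are noise); one beyond a sd is
retained and flagged so data problems stay visible. When several
enzyme conditions are present their revealed yields are pooled by
inverse-variance weighting (a conservative choice; summation is
available where the conditions are known to probe disjoint lesion
classes). The total base-damage yield (TOTAL_BD) is measured
independently as the treated-minus-untreated difference of the LS
yield, never as the sum of the revealed components — the reference
table's columns are independent measurements whose sums need not
match. The residual "other non-detected damage" term is represented
but never estimated: the assay gives it no measurement path, and
honesty beats imputation.

Totals aggregate as TOTAL_DAMAGE = LS + TOTAL_BD with quadrature sds.
Validation of a table checks non-negativity, a units tag, LS ≥ SSB
where both are present, and the sum rule
|LS + TOTAL_BD − TOTAL_DAMAGE| ≤ 0.25 × 10⁻¹⁵ cm² — just above the
worst-case discrepancy from rounding the three columns independently
to one decimal, so genuine inconsistencies are flagged. On the
packaged bare-DNA table this flags exactly four energies (6, 7, 13 and
18 eV); the validator reports rather than rejects them.

## Attenuation-length estimation

Ratios of initial LS slopes between film thicknesses depend only on λ,
so λ̂ minimizes the inverse-variance-weighted sum of squared log-ratio
residuals over λ ∈ [0.1, 1000] nm (bounded 1-D minimization).
Log-ratios make the objective symmetric under index exchange and
stabilize heteroscedastic slopes. The sd comes from first-order
(delta-method) propagation of slope uncertainties through the
estimating equation, with the curvature evaluated by finite
differences. Identical thicknesses or a flat/boundary objective raise
an estimation error rather than returning a number.

## Penetration-factor uncertainty

When `f` is supplied as a measured constant (default 0.25 ± 0.02, the
value deduced for 10–20 nm films from the ratio of the effective to
the absolute LS cross section at 10 eV; thickness-dependent but
energy-independent) it is treated as an independent multiplicative
error. When derived from λ̂ it is propagated by the delta method. In
either case the relative sd of σ is the quadrature of the yield's and
f's relative sds, and can never be smaller than either.

## Protection factors

PF = σ_DNA / σ_complex per channel and energy, on shared energies only
(no interpolation — the arginine–DNA data exist only at 5 and 10 eV);
relative sds in quadrature. Percent increases are 100·(ratio − 1) with
the ratio's sd scaled by 100. Naive quadrature of the table sds
reproduces the conventionally quoted PF uncertainties (e.g. SSB at
5 eV: 4.5 ± 0.7) without correlation corrections.

## Synthetic experiment generator

The generator emulates the statistical structure the analysis assumes,
with true cross sections either specified directly or seeded from the
packaged reference table:

- lesions arrive as independent Poisson processes per channel, with
  rates proportional to the local effective fluence; charging and
  depth attenuation enter through the same kernel as the survival
  model, with depth discretized into 50 equal slices;
- a plasmid's band follows gel-migration precedence DSB → linear,
  else CL → dimer, else SSB → circular, else supercoiled; base-damage
  channels are invisible untreated and convert under enzyme treatment
  (isolated BD → SSB, BD-CL → CL, NDCD → DSB) with efficiency 1.0 by
  default (complete conversion);
- band percentages come from a finite population (10⁵ plasmids by
  default; `n_plasmids=None` gives exact expectations for noiseless
  checks) plus additive Gaussian readout noise (default 0.5 percentage
  points, truncated to [0, 100]); a lane whose noisy bands total above
  100% is renormalized, as gel quantification reports relative
  intensities;
- three replicates per condition (triplicate irradiations are standard
  for this assay); everything is deterministic under a fixed seed;
- the automatic fluence grid is 8 points from zero up to the fluence at
  which the *most exposed* depth reaches 0.25 expected lesions — a
  single-hit criterion; targeting a depth-averaged loss instead lets
  the film surface go multi-hit and visibly curves the response.
  Enzyme-treated films deplete faster and get their own grid, as
  separate irradiations do in practice. Multi-thickness λ experiments
  use a lower exposure (0.1) since they specifically probe the linear
  region.

What the generator does not emulate: resonance physics (energies are
labels; the energy dependence enters only through the supplied σ
values), gel densitometry and band-calibration errors, lane-to-lane
correlated drifts, dose-rate effects, and any interaction between
lesions on the same plasmid beyond band precedence. Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimator chain under the assumed error model, not the fidelity of
that model to a particular instrument.

## Problem sizes and test design

Recovery tests run at 10⁵ plasmids, 8 fluences, 3 replicates and
0.2-point band noise, at 10 eV truth values; noiseless round-trip
checks use exact expectations and a deep single-hit grid (surface
exposure 0.05), where all six channels return within 2%. At the
stochastic design the high-signal channels (SSB, isolated BD,
~45–54 × 10⁻¹⁵ cm²) recover within ~10%, but the difference channels
BD-CL and NDCD (~3–5 × 10⁻¹⁵ cm²) have sampling sds of roughly 30–60%
of their true values — their estimates are statistically consistent
(within ~1 sd) yet cannot meet few-tens-of-percent accuracy targets at
this design; the suite asserts 3-sd consistency for all channels and
tight recovery only where the design's information content supports
it. The λ check compares the median of five seeded simulations against
the true 12 nm, since a single draw carries ~5% sampling noise.

## Known limitations

- Uncertainties are propagated to first order assuming independence;
  correlations (e.g. between LS and SSB fitted on the same gel) are
  not tracked.
- The window policy's lack-of-fit test has limited power at realistic
  noise, so a small curvature bias (of order the surface exposure
  times the depth-kernel variance ratio) survives in fitted slopes;
  the single-hit fluence design keeps it below the stochastic error.
- λ estimation assumes the same σ at all thicknesses (valid when films
  differ only in geometry).
- The energy–temperature conversion is a linear room-temperature
  scaling convention (0.026 eV ↔ 298 K), not a thermodynamic
  statement.
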