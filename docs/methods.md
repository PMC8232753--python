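# Methods

This note documents the models implemented in `multifission`, the
parameter defaults and how they were chosen, the numerical conventions,
and the limitations a user should know before trusting a simulation.

## Light field

The mean intensity experienced by an average cell in a self-shading
suspension is the Beer–Lambert logarithmic mean
`I_m = (I_i − I_t)/ln(I_i/I_t)` of the incident and transmitted
intensities (µmol photons m⁻²s⁻¹ throughout). The formula is inverted
for `I_t` by monotone bisection (absolute tolerance 1e−10, ≤200
iterations); near `I_t → I_i` the continuity limit `I_m = I_i` is used
(threshold `|I_i − I_t|/I_i < 1e−9`).

Transmission as a function of dry-matter density `X` (µg mL⁻¹) is
modelled with a *saturating* optical depth `τ(X) = c1·X/(1 + c2·X)`.
A plain Beer–Lambert law (τ linear in X) is inconsistent with the
measured endpoints: at incident 500 µE the culture grows from 100 to
1600 µg mL⁻¹ while the mean intensity only falls from 360 to 160 µE,
whereas constant specific attenuation would predict ≈45 µE. The
saturation (`c2`) captures package and multiple-scattering effects at
high density. Calibration inverts each (I_i, I_m, X) anchor to an
implied optical depth and least-squares fits (c1, c2); on the six
packaged endpoint anchors the fit (c1 ≈ 0.00876 µg⁻¹mL,
c2 ≈ 0.00236 µg⁻¹mL) reproduces every anchor within 1.9% and implies
~50% transmission at the reference density of 100 µg mL⁻¹. Only the
endpoint anchors are authoritative; the intermediate curve shape is the
model's interpolation.

## Growth steps and commitment

Within a growth step, biomass proxies (RNA, dry matter, cell volume,
all relative to their initial values) grow exponentially at the Monod
rate `µ = µ_max·I_m/(K_I + I_m)`; there is no growth in the dark. Cell
volume is the sizer reference: the moment it reaches exactly twice its
value at step start, the step completes, a commitment point (CP) fires,
and every proxy is snapped to exactly `2^k` — this keeps the
growth-step arithmetic exact (a four-step scenario ends at exactly
16× the initial biomass, so 100 µg mL⁻¹ becomes exactly
1600 µg mL⁻¹). After each completed step the cell idles for
`idle_base/(1 + s·I_m/K_I)` hours, reproducing the observed no-growth
intervals (4–6 h at low light) that shrink with light. Commitment
requires light; a doubling that would complete exactly at lights-off is
resolved in favour of the dark (no commitment).

Defaults: `µ_max = 0.6 h⁻¹`, `K_I = 200 µE`, `idle_base = 4 h`,
`idle_light_scaling = 3`. These were calibrated against three observed
timing/count constraints: (a) under the standard 18 h : 7 h regime the
culture completes 4/3/2 growth doublings at incident 500/250/110 µE,
with the fourth commitment at 250 µE landing just inside the light
period (the mixed population there is half `n = 3`, half `n = 4`);
(b) the first DNA replication starts ≈10 h after inoculation at
500 µE; (c) replication start is delayed at lower light. The calibrated
engine gives first-S times of 9.4 / 10.1 / 11.9 h at 500 / 250 / 110 µE;
the observed delays (≈2 h and ≈4 h) are reproduced qualitatively but
compressed, a consequence of the single Monod light response — see
Limitations.

Fast-growing cells complete one doubling fewer in RNA than in volume
and dry matter; proxies therefore carry per-proxy caps on doublings
(volume and dry matter capped at the cohort's `n`, RNA at `min(n, 3)`).

**Cohorts.** Population heterogeneity is deterministic: the scenario
assigns fractions of the population to cohorts by their number of
reproductive sequences `n`, and each cohort's `n` caps its growth steps
and commitments. There is no per-cell stochasticity anywhere in the
engine.

## Reproductive sequence scheduling

Given the commitment times, each pattern lays out its events:

* **Consecutive replication rounds** (*Parachlorella* and
  *Haematococcus* types): the first round starts a full pre-replication
  lag `pS` after the first CP; each later round starts as soon as its
  own CP plus a short preparation `pS_later` allows, but no earlier
  than `inter_S_gap` after the previous round ended. The 2-h gap
  between successive DNA doublings is the observed spacing; `pS`
  carries the ~7.5 h lag between first commitment and first
  replication.
* ***Parachlorella***: after the last S plus G2, nuclear divisions and
  protoplast fissions alternate with no G3; the transient binuclear
  state lasts exactly the fission duration `C`, so successive fissions
  (into 2, 4, 8, 16 protoplasts) are spaced `M + C` — 1 h at the
  defaults, matching the observed 14 h/15 h/16 h fission cascade.
* ***Haematococcus***: all S rounds, then all nuclear divisions (the
  cell becomes 2ⁿ-nuclear), then all fissions.
* **Clustered (*Chlamydomonas*)**: nothing before the last CP + pS,
  then rapid S→M alternations, then the fissions.
* **Consecutive (*Scenedesmus*)**: every sequence runs pS→S→G2→M
  independently (multinuclear intermediates), fissions deferred to the
  end.

Phase-duration defaults (h): pS 7.5, pS_later 1, S 0.75, G2 1, M 0.25,
G3 0.5 (forced 0 in the *Parachlorella* pattern), C 0.75, inter-S gap 2.
Only the 2-h gap and the event landmarks are measured; the individual
phase durations are calibration choices constrained by them.

Nuclear bookkeeping uses one algebra for all patterns: S-round end
doubles per-nucleus ploidy; M doubles nuclei and halves ploidy; fission
doubles protoplasts and halves per-protoplast nuclei. Total DNA per
mother (protoplasts × nuclei × ploidy × 0.1 pg) is therefore conserved
exactly through every division event, and DNA only increases during S
phases (linear ramp within each round). At daughter release the cell
concentration multiplies by `2^m` (m = committed sequences), per-cell
quantities divide by `2^m`, and culture-level dry matter is continuous.

Committed sequences always run to completion regardless of light — a
culture darkened at the moment of first fission releases the same
number of daughters as one kept in the light, with biomass frozen.

## Starch balance

Net starch (culture basis, µg mL⁻¹) integrates
`ds/dt = B·(σ_max·I_m/(K_σ + I_m) − m_light)` in the light (B = culture
dry matter), decays first-order at `m_dark` in the dark, and loses the
fraction `division_cost` at every protoplast fission. The
biomass-proportional drain `m_light` represents consumption by the
synthetic machinery; it is what suppresses net accumulation at low
light (a pure synthesis term cannot produce both a ~8-fold net gain at
250 µE and only ~2-fold at 110 µE — the maximum achievable ratio of a
Monod-in-light source over these trajectories is about 4.4, against the
required ~7).

Defaults: `σ_max = 0.023 h⁻¹`, `K_σ = 100 µE`,
`m_light = 0.00687 h⁻¹` (both per unit dry matter),
`m_dark = 0.01 h⁻¹`, `division_cost = 0.05`, initial starch
5 µg mL⁻¹ (5% of initial dry matter). σ_max and m_light were solved so
the 250 µE and 110 µE scenarios give net folds of 8 and 2; the other
three values are plausible round numbers fixed beforehand. After the
last fission in the dark the pool is strictly nonincreasing (the
post-division plateau).

## Heavy-water stress

Deuterated medium is modelled by two scalar factors: `rho_growth`
divides the growth rate and `rho_division` multiplies every phase
duration. The presets take them from the mean fold retardations of the
mass and cell-number doubling times across the four tested light
intensities (70%: 1.20 / 1.55; 99%: 18.28 / 14.40; 99% pre-adapted:
3.93 / 4.27). Photosystem stress-recovery dynamics (Fv/Fm) and neutral
lipid accumulation are deliberately not modelled.

## Statistics and detectors

Division number is the cell-count ratio over one cycle; doubling times
assume exponential change, `Δt·ln2/ln(ratio)`. Percent-of-control and
fold-retardation are presented with half-up rounding to two decimals
(raw values are also returned); the packaged comparison tables'
derived cells recompute exactly under this convention, except one cell
whose published value was evidently computed from unrounded inputs
(documented in the fixture test).

The growth-step counter log₂-transforms the series, smooths with a
5-sample moving median, takes the nearest integer to the maximum as the
step count and the first crossings of each `k − 0.1` level as step
times, requiring a trailing plateau (|slope| < 0.02 doublings/h for
≥1.5 h) after every non-final crossing. These defaults were chosen so
the 4–6 h idle intervals are detectable at 1–2 h sampling. The
replication-round estimator uses a 3-sample window and the smoothed
maximum as the final level because the fully replicated DNA level
persists only ~2 h before the fission cascade halves it stepwise.
Under the emulated assay noise (5% CV, triplicates, 1-h sampling) both
detectors recover the true n for every scenario in ≥95% of noise
realizations.

## Synthetic observations

Measurement noise is multiplicative lognormal with unit mean
(σ² = ln(1 + cv²)), cv defaulting to 5% — a stand-in, since the source
experiments do not tabulate assay SDs — with 3 replicates at 1-h
sampling. The OD₇₅₀ proxy is dry matter scaled to OD 0.25 at the
initial 100 µg mL⁻¹; only relative OD factors are meaningful. The
generator reproduces replicate structure and sampling cadence but not
instrument-specific artifacts (counter binning, plate-reader
saturation), so detector performance on synthetic data bounds, rather
than guarantees, performance on real assays.

## Numerics and determinism

Fixed-step integration at 0.05 h; event times are snapped to the
earliest grid point at or after their exact value; simultaneous events
order as CP < S < M < FISSION < RELEASE. Step completions are located
analytically inside a step and proxies snapped to exact powers of two.
The engine contains no randomness; identical configurations produce
byte-identical CSV outputs. Randomness enters only through the
observation generator's seed. A horizon that ends before every
committed sequence completes sets a truncation flag rather than
failing. Default scenario horizons are one full 25-h cycle; the
acceptance script runs three such simulations (501 grid points each)
in well under a second.

## Limitations

* **Net starch at the highest light is overpredicted** (~20-fold vs the
  observed ~10-fold at 500 µE, with 250/110 µE calibrated to 8/2). The
  observed profile implies a *higher* net accumulation per unit biomass
  at 250 µE than at 500 µE, which no light-monotone,
  biomass-proportional balance can produce; candidate mechanisms
  (photoinhibition of starch synthesis, division-phase shutdown of
  photosynthesis) are out of scope.
* The light-driven delays of replication onset at lower light are
  compressed (≈0.7/2.5 h vs the observed ≈2/4 h); a single Monod light
  response cannot simultaneously match the delay spread and fit four
  doublings into the photoperiod at 250 µE.
* One cycle per mother: released daughters do not start a new cycle, so
  multi-day sequential-dilution experiments are represented only by
  their per-cycle statistics.
* Whether the polyploid nuclei are polytene or endomitotic is
  biologically open; the engine tracks only total ploidy per nucleus.
* No spatial structure, vessel geometry, spectral resolution or
  per-cell size distributions; cohort fractions are scenario inputs,
  not predictions.
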