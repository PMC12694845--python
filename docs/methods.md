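# Model and methods

`biofilmsig` simulates electrochemical signaling in a two-dimensional
*Bacillus subtilis* flow-cell biofilm as an agent-based model: every cell is
an individual agent on a hexagonal lattice, carrying its own membrane
potential, internal glutamate and potassium pools, and a heritable signaling
threshold.  Colony-wide membrane-potential oscillations are not imposed —
they emerge during growth from the interplay of nutrient transport,
voltage-dependent uptake, and threshold-triggered potassium release.

## State variables

Per cell: membrane potential `V` (mV), internal glutamate `G_i` (mM),
internal potassium `K_i` (mM), local extracellular glutamate `G_e` (mM),
signaling threshold `T` (mM), ThT reporter intensity (arbitrary units in
[0, 1]), and lineage links.  Shared by the colony: one extracellular
potassium pool `K_e` (mM) — potassium diffuses fast relative to the 1.2 min
tick, so it is mixed across the biofilm every tick, whereas glutamate is
transported gradually by the shell scheme below.

## Kinetics (one explicit update per tick)

* **Uptake.**  `u = a · f(V) · G_e / (K_m + G_e)`, capped at `G_e`.  The
  voltage gate `f(V) = 1/(1 + exp((V − V_h)/s))` is a sigmoid: the glutamate
  transporter works at full rate in hyperpolarized cells and shuts down over
  a few millivolts of depolarization.  The steepness of this gate is what
  lets a modest rise in extracellular potassium throttle uptake colony-wide.
* **Metabolism.**  First-order consumption: `G_i ← G_i + u − δ·G_i`,
  clamped at zero.
* **Signaling.**  A cell signals exactly while `G_i < T` (level-triggered,
  re-evaluated every tick; thresholds ≤ 0 can never be crossed because
  `G_i ≥ 0`).
* **Potassium release.**  While signaling, a cell releases
  `γ_r · max(K_i − K_floor, 0)` into the shared pool: a fresh signaler dumps
  a strong burst that decays as its releasable store (the ~150 mM above the
  non-releasable floor) drains.  The release flux is an outward current, so
  it also hyperpolarizes the releasing cell by `κ` mV per mM/tick — this is
  the membrane-potential spike at signaling onset, and the reason signalers
  are ThT-bright while the colony around them is depolarized.
* **Potassium recovery.**  An importer pump relaxes `K_i` back toward its
  set point at rate `γ_u`, gated by a saturating function of `G_i`
  (half-saturation 0.02 mM): importing K⁺ against its gradient takes
  metabolic energy, so starved cells cannot refill their stores and fall
  silent once drained instead of trickling potassium forever.  The pump
  draws from the shared pool, so with media exchange disabled the total
  `ΣK_i + n·K_e` is conserved exactly (the half-volume assumption: cell and
  extracellular volumes are equal, so concentration fluxes transfer 1:1).
* **Membrane potential.**  `V` relaxes toward a conductance-weighted mix of
  a leak potential and the potassium Nernst potential
  `V_K = (RT/F)·ln(K_e/K_i)` with `RT/F = 26.1` mV at 30 °C; signaling opens
  an extra potassium conductance, and the release current described above
  adds its transient hyperpolarization.  Raising `K_e` depolarizes every
  cell through the Nernst term — that is how one cell's stress propagates.
* **ThT reporter.**  A per-cell asymmetric low-pass filter over a sharp
  sigmoid of `V`: dye accumulates quickly while a cell is strongly
  hyperpolarized and washes out slowly (rates 0.5 and 0.08 per tick), so a
  cell that fired at any point of the current wave is still bright at the
  wave's peak.  There is no spatial ThT diffusion.  "Signalers" in all
  analyses are cells whose ThT exceeds the exterior-region median plus a
  fixed offset of 0.35 — the distribution at peaks is bimodal and the cutoff
  falls between the modes.

### Pool exchange with the media

Released potassium washes out into the flowing media at 0.34 per tick;
a pool depleted below basal is resupplied at 0.9 per tick.  The asymmetry
reflects the flow cell: fresh media replenishes the boundary layer much
faster than released ions accumulate, and without it the colony-wide
store-refill demand after each wave would hold the pool far below basal for
hundreds of ticks and stretch the oscillation period by an order of
magnitude.

## Glutamate transport: attenuated-shell heuristic

Cells are grouped into shells by breadth-first-search depth from the colony
perimeter (depth 0 = edge), which handles the rough grown boundary.  Every
tick each cell's `G_e` relaxes (rate 0.5) toward a per-shell target

    target(k) = max( G_m − φ · Σ_{j<k} n(j)·ū(j) / n_ref , 0 )

where `ū(j)` is shell *j*'s mean realized uptake on the previous tick,
`n(j)` its population, and `n_ref` the boundary-ring population (taken at
depth 3, below the roughness of the outermost rings).  The count weighting
is the disc geometry: nutrients enter through a perimeter that grows like
the radius while demand grows like the area, so a small colony is fed to its
center while a large one develops a depleted core — this single term ties
together the oscillation onset radius (~110 cells) and the size of the
starved core in non-signaling colonies (>11,000 cells at radius ~145).
Delivery is rationed outermost-shell-first against a boundary supply cap of
`0.44 · n(0) · G_m` per tick; the cap is slack at rest and binds during
waves, limiting how much glutamate a single depolarization episode can
carry inward.  When a target falls below a cell's local `G_e` the excess
washes out at the same rate.

The penetration depth `d*` — how deep media glutamate reaches a resting,
non-signaling colony before falling below a 0.5 mM floor — is computed once
per run on an idealized column of shells and defines the analysis regions:
*exterior* is depth < `d*` (33 at default parameters), *interior* is depth ≥
`d*` + 8, with the 8-cell band between them excluded as a buffer.

An explicit 1-D radial diffusion–uptake PDE, integrated to steady state, is
kept as a validation oracle: the two profiles agree in depth ordering
(rank correlation ≥ 0.95) while the heuristic cuts off more abruptly near
the interior boundary.

## Growth and inheritance

Growth starts from a 7-cell hexagon with thresholds uniform on the
configured bounds, grows to radius 40 with all physiology frozen (the
nutrient-free phase), then proceeds at one-fortieth of the perimeter per
tick (selected uniformly with replacement, count rounded up) until the
population cap of 51,000.  A daughter occupies an empty neighbor site of
its parent chosen with probability proportional to the site's
occupied-neighbor count, is otherwise a clone of the parent, and draws its
threshold from a normal centered on the parent's value (σ = 1) truncated to
[0, 3].  Cells never die or move.

## How the oscillation works

Between waves the fed exterior sits at a glutamate balance of ~3.3 mM —
just above the threshold ceiling — while cells in the band around the
penetration depth slowly starve as local glutamate runs out.  Starving band
cells cross their thresholds, release potassium bursts, and nudge `K_e`
upward; the Nernst depolarization throttles uptake for everyone, pushing
more cells below threshold in a cascade that sweeps the colony within a few
ticks.  The wave self-terminates as releasable stores drain and the pool
washes out; meanwhile the near-total suppression of uptake lets the shell
targets reach the colony center, refilling the interior.  Everyone then
repolarizes, re-feeds, and re-starves on the band's timescale — the cycle
repeats every ~42 ticks.  Which cells participate is set almost entirely by
the heritable threshold relative to the local glutamate level, which is why
wave membership is strongly consistent across cycles and weakly heritable
across divisions.

## Parameters

All rates are per tick (1 tick = 1.2 min); concentrations mM, potentials mV.

| parameter | value | meaning |
|---|---|---|
| `uptake_rate` | 0.79 | maximal uptake flux at full polarization |
| `uptake_km` | 2.0 | glutamate half-saturation of uptake |
| `uptake_v_half`, `uptake_v_slope` | −75, 3 | transporter voltage gate |
| `consumption_rate` | 0.18 | first-order glutamate consumption |
| `release_rate` | 0.10 | release of the store above the floor while signaling |
| `k_i_setpoint`, `k_i_floor` | 300, 150 | internal potassium set point / non-releasable floor |
| `recovery_rate`, `recovery_km` | 0.15, 0.02 | store refill rate and its metabolic gate |
| `pool_exchange_rate`, `pool_resupply_rate` | 0.34, 0.9 | pool washout / resupply |
| `g_leak`, `g_k`, `g_signal` | 0.06, 0.24, 0.40 | leak, baseline K, signaling K conductances |
| `v_leak`, `nernst_mv` | −20, 26.1 | leak reversal; RT/F at 30 °C |
| `release_v_gain` | 1.0 | hyperpolarization per unit release flux |
| `tht_rise_rate`, `tht_decay_rate` | 0.5, 0.08 | ThT accumulation / washout |
| `tht_v_half`, `tht_v_slope` | −84, 2.5 | ThT uptake curve |
| `tht_cutoff_offset` | 0.35 | signaler classification offset above the median |
| `shell_rate`, `shell_attenuation` | 0.5, 1.73 | transport relaxation; attenuation coefficient |
| `supply_coeff` | 0.44 | boundary supply cap (fraction of `G_m` per perimeter cell) |
| `penetration_floor` | 0.5 | `G_e` floor defining the exterior/interior split |

The kinetic *forms* are the package's own construction to the published
behavioral contracts (monotonicities, conservation, signs, fixed points).
The rate constants were calibrated once against two observables of the
default full-scale run — oscillation period ≈ 45 ticks and exterior peak
signaling fraction ≈ 0.42 — and then frozen.  Everything else reported by
the analysis layer (onset radius, recurrence and consistency rates,
starvation censuses, synchronization indices) is emergent.

## What the simulations do and do not capture

The synthetic colonies reproduce, at the stated tolerances: the onset of
oscillations near radius 110 (earlier at 20 mM glutamate), the ~45-tick
period, the exterior peak signaling fraction (~0.42), mother–daughter
recurrence (~0.63 / ~0.73), pairwise and 30-oscillation consistency, the
starved-core census of non-signaling colonies, perturbation responses
(glutamate raise damps oscillations; a potassium flood fires an immediate
colony-wide wave), and entrainment to a neighbor's potassium oscillations
(asynchrony ≈ 0.13 of the null at 2000 μm, weakening with distance).

Known limitations:

* Potassium is a single colony-wide pool, so signaling waves have no
  spatial propagation front; anything that depends on cell-to-cell
  percolation is outside the model.  A visible consequence is that the
  threshold-bound regime boundaries are shifted: at bounds [−0.4, 2.5] and
  [0.3, 2.9] the simulated colonies still oscillate stably, whereas the
  reduced-ceiling regime should produce only minimal interior signaling and
  the raised-floor regime a potassium-driven collapse.  Both regimes exist
  in the model, but at more extreme bounds.
* For the same reason, entrainment at long donor distances is somewhat
  stronger than observed (asynchrony ≈ 0.7 rather than ≈ 0.8 of the null at
  4000 μm).
* Signaling bouts are short flickers (release hyperpolarizes the cell,
  which briefly rescues its glutamate balance), so the instantaneous
  `G_i < T` flag underestimates wave participation; all participation
  statistics therefore use the ThT classifier, which integrates over a
  wave.  The raw flag fractions are recorded in the trace alongside the
  classified ("bright") fractions.
* Cells never die, move, or push; the lattice is strictly 2-D; reproduction
  is independent of a cell's internal glutamate; extracellular potassium
  carries no spatial structure; ThT does not influence physiology.

## Numerical choices

One explicit update per tick throughout (the model's time grid is
deliberately coarse); no sub-stepping.  The depth map is refreshed every 10
growth ticks (the boundary advances ~0.5 cell per refresh) and is exact
once growth stops.  Uptake is capped at local `G_e` and the pool pump at
the available pool, so all concentrations stay non-negative under the
coarse grid.  Oscillation extrema are found on a 5-tick boxcar-smoothed
trace with a 0.08 prominence and 25-tick separation floor; trough times are
refined by parabolic interpolation for the synchronization statistic.
Thresholds are drawn by inverse-CDF sampling of the truncated normal
(verified against `scipy.stats.truncnorm` in the tests).  A run is fully
determined by its `(config, seed)` pair: a single generator is consumed in
a fixed order (selection draws, placement draws, one batched inheritance
draw, per tick).

## Problem sizes

The default analysis run grows to ~51,000 cells (radius ~147) and simulates
4,200 ticks (~30 post-growth oscillations) in well under a minute on one
CPU.  The synchronization experiment uses one donor colony plus a 10-replicate
unforced ensemble and one forced ensemble per distance, each replicate a
full-size colony — the paper-scale protocol at half the replicate count.
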