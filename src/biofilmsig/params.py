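"""Model parameters and simulation configuration.

All rate constants are expressed per tick (one tick = 1.2 minutes of real
time).  Concentrations are mM, membrane potential is mV.  The defaults below
are the package's default study conditions: a flow-cell biofilm in msgg-like
media with 30 mM basal glutamate and 8 mM basal potassium, heritable
signaling thresholds on [0, 3], and growth to ~51,000 cells.

The kinetic rates were calibrated once so that a default full-scale run
produces colony-wide signaling oscillations with a period of about 45 ticks
and a peak exterior signaling fraction of about 0.42; everything else is an
emergent consequence of the model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional


@dataclass
class ModelParameters:
    """Per-cell kinetic constants and environment-coupling rates (per tick)."""

    #: real-time duration of one tick, minutes (reporting convention only)
    tick_minutes: float = 1.2

    # --- glutamate uptake (voltage-dependent transporter) and metabolism
    #: maximal uptake rate at full polarization, mM/tick
    uptake_rate: float = 0.79
    #: half-saturation of uptake in local extracellular glutamate, mM
    uptake_km: float = 2.0
    #: transporter gating midpoint: membrane potential of half-maximal uptake, mV
    uptake_v_half: float = -75.0
    #: steepness of the transporter voltage gate, mV
    uptake_v_slope: float = 3.0
    #: first-order internal glutamate consumption rate, 1/tick
    consumption_rate: float = 0.18

    # --- potassium handling
    #: fraction of internal potassium released per tick while signaling, 1/tick
    release_rate: float = 0.10
    #: first-order recovery of internal potassium toward its set point, 1/tick
    recovery_rate: float = 0.15
    #: half-saturation of the metabolic gate on potassium recovery, mM internal
    #: glutamate (the pump needs metabolic activity; starved cells cannot refill)
    recovery_km: float = 0.02
    #: internal potassium set point, mM
    k_i_setpoint: float = 300.0
    #: non-releasable internal potassium floor, mM (release stops here)
    k_i_floor: float = 150.0
    #: first-order washout of excess pool potassium into the flowing media, 1/tick
    pool_exchange_rate: float = 0.34
    #: first-order resupply from the flowing media when the pool is depleted
    #: below basal, 1/tick (flow replenishes much faster than it washes out)
    pool_resupply_rate: float = 0.9

    # --- membrane potential (leak + potassium Nernst term)
    #: leak conductance (relaxation toward the leak potential), 1/tick
    g_leak: float = 0.06
    #: baseline potassium conductance, 1/tick
    g_k: float = 0.24
    #: extra potassium conductance while the cell is signaling, 1/tick
    g_signal: float = 0.40
    #: leak reversal potential, mV
    v_leak: float = -20.0
    #: Nernst prefactor RT/F at 30 degC, mV
    nernst_mv: float = 26.1
    #: hyperpolarization per unit of potassium release flux, mV per (mM/tick)
    #: (the efflux is an outward current acting on the releasing cell itself)
    release_v_gain: float = 1.0

    # --- ThT polarization reporter (per-cell low-pass filter, no diffusion)
    #: uptake rate of the ThT proxy when polarization rises, 1/tick
    tht_rise_rate: float = 0.5
    #: washout rate of the ThT proxy, 1/tick (dye leaves much more slowly
    #: than it accumulates, as for the stain in vivo)
    tht_decay_rate: float = 0.08
    #: membrane potential of half-maximal ThT uptake, mV (only strongly
    #: hyperpolarized cells take up appreciable dye)
    tht_v_half: float = -84.0
    #: steepness of the ThT uptake curve, mV
    tht_v_slope: float = 2.5
    #: signaler classification cutoff above the colony median, ThT units
    tht_cutoff_offset: float = 0.35

    # --- shell-based glutamate transport heuristic
    #: per-tick relaxation of local glutamate toward the attenuated target, 1/tick
    shell_rate: float = 0.5
    #: attenuation of the inward target per unit of upstream uptake, dimensionless
    shell_attenuation: float = 1.73
    #: boundary supply cap per perimeter cell, fraction of basal glutamate per tick
    supply_coeff: float = 0.44
    #: extracellular glutamate floor defining the penetration depth, mM
    penetration_floor: float = 0.5

    # --- analysis-facing constants
    #: extracellular potassium above which signaling is classified as collapsed, mM
    collapse_k_e: float = 100.0
    #: time-averaged internal glutamate below which a cell counts as starved, mM
    starvation_g_i: float = 1e-3

    # --- initial per-cell state at the end of the nutrient-free phase
    g_i_init: float = 3.0

    #: master switch for potassium release (False reproduces the no-signaling runs)
    signaling_enabled: bool = True

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("v_leak", "uptake_v_half", "tht_v_half") or isinstance(v, bool):
                continue
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"parameter {f.name} must be non-negative, got {v}")
        if self.g_leak + self.g_k + self.g_signal >= 1.0:
            raise ValueError("total membrane conductance per tick must be < 1 for stability")


@dataclass
class ThresholdDistribution:
    """Truncated-normal inheritance of the signaling threshold.

    A daughter's threshold is drawn from a normal with mean equal to the
    parent's threshold and standard deviation ``sigma`` (of the underlying
    non-truncated normal), truncated to [lower, upper].  Cells with a
    threshold <= 0 can never signal since internal glutamate is non-negative.
    """

    lower: float = 0.0
    upper: float = 3.0
    sigma: float = 1.0

    def validate(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"threshold bounds must satisfy lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def sample(self, means, rng):
        """Draw one threshold per entry of ``means`` (vectorized).

        Inverse-CDF sampling: map a uniform draw into the normal CDF mass
        between the truncation bounds.  Matches scipy's truncnorm (which is
        the cross-check used in the tests) at a fraction of the call cost.
        """
        import numpy as np
        from scipy.special import ndtr, ndtri

        means = np.asarray(means, dtype=float)
        if self.sigma == 0:
            return np.clip(means, self.lower, self.upper)
        a = ndtr((self.lower - means) / self.sigma)
        b = ndtr((self.upper - means) / self.sigma)
        u = rng.random(means.shape)
        x = ndtri(a + u * (b - a))
        return np.clip(means + self.sigma * x, self.lower, self.upper)


@dataclass
class GrowthPolicy:
    """Perimeter-reproduction growth rules."""

    #: fraction of perimeter cells selected (with replacement) to reproduce per tick
    fraction: float = 1.0 / 40.0
    #: radius of the initial nutrient-free growth phase, cells
    nutrient_free_radius: int = 40
    #: population at which growth halts permanently
    population_cap: int = 51_000
    #: optional radius cap (used by the low-glutamate protocol), cells
    radius_cap: Optional[int] = None

    def validate(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("growth fraction must be in (0, 1]")
        if self.population_cap <= 0 or self.nutrient_free_radius <= 0:
            raise ValueError("growth caps must be positive")
        if self.radius_cap is not None and self.radius_cap <= 0:
            raise ValueError("radius cap must be positive")


@dataclass
class SimulationConfig:
    """A complete, reproducible description of one simulation run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    thresholds: ThresholdDistribution = field(default_factory=ThresholdDistribution)
    growth: GrowthPolicy = field(default_factory=GrowthPolicy)
    #: basal media glutamate, mM (constant unless an environment schedule overrides it)
    g_m: float = 30.0
    #: basal media potassium, mM
    k_m: float = 8.0
    #: total number of ticks simulated after the nutrient-free phase
    n_ticks: int = 3000
    #: refresh cadence of the depth map during growth, ticks
    depth_refresh_every: int = 10
    #: record per-cell ThT/signaling history from this tick on (None = off,
    #: "post_growth" resolves to the tick growth stops)
    record_cells_from: Optional[object] = "post_growth"

    def validate(self) -> None:
        self.params.validate()
        self.thresholds.validate()
        self.growth.validate()
        if self.g_m < 0 or self.k_m < 0:
            raise ValueError("basal media concentrations must be non-negative")
        if self.n_ticks <= 0:
            raise ValueError("n_ticks must be positive")
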