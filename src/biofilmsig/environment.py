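"""Time-varying basal media conditions: perturbation presets and the
potassium forcing exerted by a neighboring oscillating biofilm.

An :class:`EnvironmentSchedule` resolves, for every tick, the basal media
glutamate ``G_m(t)`` and potassium ``K_m(t)`` seen at the colony boundary.
Defaults are 30 mM glutamate and 8 mM potassium; presets overlay step
changes (the perturbation protocols) or sampled series (the neighbor-biofilm
forcing).  Overlays compose last-writer-wins, and overlapping presets on the
same channel raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

DEFAULT_G_M = 30.0
DEFAULT_K_M = 8.0

#: potassium diffusivity in media, um^2/tick (1.96e-9 m^2/s at ~30 degC,
#: converted with 72 s per tick)
K_DIFFUSIVITY_UM2_PER_TICK = 1.96e-9 * 1e12 * 72.0


@dataclass
class _Window:
    start: int
    end: int  # exclusive; None-like large for open-ended
    channel: str  # "g_m" or "k_m"
    value: Callable[[int], float]
    tag: str


@dataclass
class EnvironmentSchedule:
    """Piecewise basal-media schedule with preset overlays."""

    g_m: float = DEFAULT_G_M
    k_m: float = DEFAULT_K_M
    preset: str = "default"
    _windows: list = field(default_factory=list)

    def overlay(self, start: int, end: int, channel: str, value, tag: str) -> "EnvironmentSchedule":
        if channel not in ("g_m", "k_m"):
            raise ValueError(f"unknown channel {channel!r}")
        for w in self._windows:
            if w.channel == channel and start < w.end and w.start < end:
                raise ValueError(
                    f"preset {tag!r} overlaps {w.tag!r} on channel {channel}"
                )
        fn = value if callable(value) else (lambda t, v=value: v)
        self._windows.append(_Window(start, end, channel, fn, tag))
        return self

    def at(self, tick: int) -> tuple[float, float]:
        """Resolve (G_m, K_m) for a tick; overlays win over the base values."""
        g, k = self.g_m, self.k_m
        for w in self._windows:
            if w.start <= tick < w.end:
                v = float(w.value(tick))
                if v < 0:
                    raise ValueError(f"schedule produced negative concentration at tick {tick}")
                if w.channel == "g_m":
                    g = v
                else:
                    k = v
        return g, k

    def to_table(self, n_ticks: int):
        import pandas as pd

        rows = [self.at(t) for t in range(n_ticks)]
        return pd.DataFrame(rows, columns=["g_m", "k_m"]).assign(tick=range(n_ticks))


# ------------------------------------------------------------------ presets

def preset_default() -> EnvironmentSchedule:
    return EnvironmentSchedule(preset="default")


def preset_glutamate_raise(start: int = 100, duration: int = 200,
                           high: float = 35.0) -> EnvironmentSchedule:
    """Basal glutamate stepped 30 -> 35 mM for 200 ticks (ticks 100-300),
    applied to a stably oscillating biofilm."""
    sched = EnvironmentSchedule(preset="glu-raise")
    sched.overlay(start, start + duration, "g_m", high, "glu-raise")
    return sched


def preset_potassium_shock(start: int = 1100, duration: int = 5,
                           high: float = 300.0) -> EnvironmentSchedule:
    """Basal potassium pulsed 8 -> 300 mM for five ticks in a growing biofilm."""
    sched = EnvironmentSchedule(preset="k-shock")
    sched.overlay(start, start + duration, "k_m", high, "k-shock")
    return sched


def preset_low_glutamate(g_m: float = 20.0) -> tuple[EnvironmentSchedule, int]:
    """Constant reduced glutamate; growth is capped at radius ~90 cells.

    Returns ``(schedule, radius_cap)`` — the caller applies the cap to the
    growth policy.
    """
    return EnvironmentSchedule(g_m=g_m, preset="glu-low"), 90


def attenuation(distance_um: float, period_ticks: float = 45.0,
                diffusivity: float = K_DIFFUSIVITY_UM2_PER_TICK) -> float:
    """Amplitude attenuation of a periodic potassium source at a distance.

    The steady periodic solution of 1-D diffusion from an oscillating
    boundary decays as ``exp(-d sqrt(omega / 2D))`` with ``omega`` the
    angular frequency of the source — the standard damped diffusion wave.
    """
    if distance_um <= 0:
        raise ValueError("distance must be positive")
    omega = 2.0 * np.pi / period_ticks
    decay_len = np.sqrt(2.0 * diffusivity / omega)
    return float(np.exp(-distance_um / decay_len))


def neighbor_potassium_oscillation(distance_um: float, donor_trace: np.ndarray,
                                   onset: int = 200, ramp: int = 400,
                                   basal: float = DEFAULT_K_M,
                                   donor_period: float = 45.0) -> EnvironmentSchedule:
    """Basal-potassium forcing from a neighboring biofilm a given distance away.

    ``donor_trace`` is the extracellular potassium trace of a reference
    oscillating colony (one value per tick, same tick grid as the recipient
    run).  The forcing waveform is the donor's excursion above basal,
    attenuated by distance per the diffusion calculation, and ramped in
    linearly over ``ramp`` ticks starting at ``onset`` — a biofilm that has
    just begun weakly signaling nearby.
    """
    donor = np.asarray(donor_trace, dtype=float)
    att = attenuation(distance_um, period_ticks=donor_period)
    excursion = np.clip(donor - basal, 0.0, None)

    def k_m_at(t: int) -> float:
        if t < onset:
            return basal
        ramp_f = min((t - onset) / ramp, 1.0)
        i = min(t - onset, excursion.size - 1)
        return basal + att * ramp_f * excursion[i]

    sched = EnvironmentSchedule(preset=f"sync-k@{distance_um:g}um")
    sched.overlay(onset, 10**9, "k_m", k_m_at, sched.preset)
    return sched


def glutamate_oscillation(magnitude_mm: float, period_ticks: float,
                          start: int = 0, basal: float = DEFAULT_G_M) -> EnvironmentSchedule:
    """Sinusoidal basal glutamate about 30 mM with the given amplitude."""
    if magnitude_mm < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude_mm > basal:
        raise ValueError("oscillation amplitude cannot exceed basal glutamate")

    def g_m_at(t: int) -> float:
        return basal + magnitude_mm * np.sin(2.0 * np.pi * (t - start) / period_ticks)

    sched = EnvironmentSchedule(preset="sync-glu")
    if magnitude_mm > 0:
        sched.overlay(start, 10**9, "g_m", g_m_at, "sync-glu")
    return sched


def load_donor_trace() -> np.ndarray:
    """The packaged reference donor extracellular-potassium trace (K_e, mM)."""
    from importlib import resources

    path = resources.files("biofilmsig").joinpath("data", "donor_ke.csv")
    with path.open() as fh:
        import pandas as pd

        return pd.read_csv(fh)["k_e"].to_numpy()


def green_function_attenuation(distance_um: float, period_ticks: float = 45.0,
                               diffusivity: float = K_DIFFUSIVITY_UM2_PER_TICK,
                               n_cycles: int = 200, dt: float = 0.05) -> float:
    """Numeric cross-check of :func:`attenuation` via the 1-D Green's function.

    Convolves a unit sinusoidal point source with the free-space heat kernel
    and returns the steady-state amplitude ratio at the given distance.
    Quadratic in cost; used only in tests.
    """
    omega = 2.0 * np.pi / period_ticks
    t_end = n_cycles * period_ticks
    tau = np.arange(dt, t_end, dt)
    kernel = np.exp(-(distance_um ** 2) / (4.0 * diffusivity * tau)) / np.sqrt(
        4.0 * np.pi * diffusivity * tau
    )
    kernel0 = 1.0 / np.sqrt(4.0 * np.pi * diffusivity * tau)

    def amplitude(k: np.ndarray) -> float:
        # steady-state response amplitude via two quadrature observation times
        a = np.sum(np.sin(omega * (t_end - tau)) * k) * dt
        b = np.sum(np.cos(omega * (t_end - tau)) * k) * dt
        return float(np.hypot(a, b))

    return amplitude(kernel) / amplitude(kernel0)
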