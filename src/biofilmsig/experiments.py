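"""Canned simulation protocols: the default control run and the derived
statistics pipelines, the perturbation and synchronization experiments, and
the threshold-bound phase sweep.

These functions glue the simulator to the analysis layer in the exact
protocols used for validation, so the CLI, the test-suite and the
acceptance script all run one shared implementation.
"""

from __future__ import annotations

import numpy as np

from . import analysis, environment, runio
from .params import SimulationConfig, ThresholdDistribution


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


# --------------------------------------------------------------- default run

def exterior_trace(result: runio.RunResult) -> np.ndarray:
    """Per-tick ThT-classified signaling fraction among exterior cells."""
    return result.trace["frac_bright_exterior"].to_numpy()


def post_growth_peaks(result: runio.RunResult, max_peaks: int | None = None) -> np.ndarray:
    """Absolute ticks of exterior signaling peaks after growth has ended."""
    g_end = result.growth_end_tick
    if g_end is None:
        raise ValueError("run did not reach the end of growth")
    tr = exterior_trace(result)[g_end:]
    ev = analysis.detect_oscillations(tr)
    peaks = ev.peaks + g_end
    if max_peaks is not None:
        peaks = peaks[:max_peaks]
    return peaks


def peak_signaler_masks(result: runio.RunResult,
                        max_peaks: int | None = None) -> list[np.ndarray]:
    """ThT-classifier signaler masks (all cells) at each post-growth peak.

    The classification cutoff (median + offset) is computed over the
    exterior cells — the region imaged in vitro — and applied colony-wide.
    """
    offset = result.config.params.tht_cutoff_offset
    ext = result.regions().exterior
    masks = []
    for t in post_growth_peaks(result, max_peaks):
        tht = result.tht_at(int(t))
        cut = np.median(tht[ext]) + offset
        masks.append(tht > cut)
    return masks


def table1_statistics(result: runio.RunResult) -> dict:
    """Exterior-cell signaling statistics at oscillation peaks.

    Returns peak signaling fraction (mean over peaks), mother-daughter
    recurrence rates, and pairwise consistency fractions across consecutive
    peak pairs — the simulated column of the in-vitro comparison table.
    """
    ext = result.regions().exterior
    masks = peak_signaler_masks(result)
    if len(masks) < 2:
        raise ValueError("need at least two oscillation peaks")
    peak_fraction = float(np.mean([m[ext].mean() for m in masks]))
    sig_rec, nonsig_rec = analysis.recurrence_rates(
        result.cells["parent_id"].to_numpy(), masks, include=ext
    )
    pairs = [
        analysis.consistency_fractions(masks[i], masks[i + 1], include=ext)
        for i in range(len(masks) - 1)
    ]
    both, neither, switched = (float(np.mean([p[i] for p in pairs])) for i in range(3))
    ev = analysis.detect_oscillations(exterior_trace(result)[result.growth_end_tick:])
    return {
        "peak_signaling_fraction": peak_fraction,
        "signaler_recurrence": sig_rec,
        "nonsignaler_recurrence": nonsig_rec,
        "consistent_signaling": both,
        "consistent_nonsignaling": neither,
        "inconsistent": switched,
        "period_ticks": ev.period,
        "n_peaks": len(masks),
    }


def per_oscillation_participation(result: runio.RunResult,
                                  n_oscillations: int = 30) -> np.ndarray:
    """(cells x oscillations) boolean: whether each cell was ThT-classified
    as a signaler at any tick of each trough-to-trough oscillation cycle.

    Using the whole cycle rather than the single peak tick makes the call
    robust to when exactly within the wave a cell fired.
    """
    g_end = result.growth_end_tick
    if g_end is None:
        raise ValueError("run did not reach the end of growth")
    ev = analysis.detect_oscillations(exterior_trace(result)[g_end:])
    troughs = ev.troughs + g_end
    n_osc = min(n_oscillations, len(troughs) - 1)
    if n_osc < 2:
        raise ValueError("too few oscillations recorded")
    offset = result.config.params.tht_cutoff_offset
    ext = result.regions().exterior
    start = result.record_start
    hist = result.tht_history
    out = np.zeros((hist.shape[1], n_osc), dtype=bool)
    for k in range(n_osc):
        seg = hist[troughs[k] - start:troughs[k + 1] - start].astype(np.float32)
        cuts = np.median(seg[:, ext], axis=1) + offset
        out[:, k] = (seg > cuts[:, None]).any(axis=0)
    return out


def long_run_consistency_stats(result: runio.RunResult,
                               n_oscillations: int = 30,
                               region: str = "exterior") -> tuple[float, float, float]:
    """Fractions of cells signaling in >90% / <10% / in between of ~30
    oscillations (cycle-window ThT classification).

    ``region`` selects exterior (the convention used for all the cell-level
    comparison statistics), interior, or all cells.
    """
    part = per_oscillation_participation(result, n_oscillations)
    if region != "all":
        part = part[getattr(result.regions(), region)]
    return analysis.long_run_consistency(part)


def onset_radius_of(result: runio.RunResult):
    return analysis.onset_radius(
        exterior_trace(result), result.trace["radius"].to_numpy()
    )


# ---------------------------------------------------------------- starvation

def starved_count(result: runio.RunResult) -> int:
    floor = result.config.params.starvation_g_i
    return analysis.starved_census(result.mean_g_i_post_growth, floor)


def no_signaling_run(seed: int, n_ticks: int = 3000, **overrides) -> runio.RunResult:
    cfg = default_config(n_ticks=n_ticks, record_cells_from=None, **overrides)
    cfg.params.signaling_enabled = False
    return runio.run(cfg, seed)


# -------------------------------------------------------------- phase diagram

def phase_point(lower: float, upper: float, seed: int,
                n_ticks: int | None = None) -> str:
    """Run one threshold-bound pair and classify its regime."""
    cfg = default_config(record_cells_from=None)
    cfg.thresholds = ThresholdDistribution(lower=lower, upper=upper)
    if n_ticks:
        cfg.n_ticks = n_ticks
    res = runio.run(cfg, seed)
    g_end = res.growth_end_tick or 0
    return analysis.classify_regime(
        res.trace["frac_bright"].to_numpy()[g_end:],
        res.trace["k_e"].to_numpy()[g_end:],
        collapse_k_e=cfg.params.collapse_k_e,
    )


# ------------------------------------------------------------ synchronization

class DonorTrace:
    """A reference oscillating colony's extracellular potassium record."""

    def __init__(self, k_e_segment: np.ndarray, period: float, growth_end_tick: int):
        self.k_e_segment = np.asarray(k_e_segment, dtype=float)
        self.period = float(period)
        self.growth_end_tick = int(growth_end_tick)


def make_donor(seed: int, settle: int = 300, length: int = 1200,
               n_ticks: int = 4400) -> DonorTrace:
    """Record a stably oscillating reference colony's K_e trace.

    The returned segment starts ``settle`` ticks after the donor's growth
    ends, by which time oscillations are stable.
    """
    cfg = default_config(n_ticks=n_ticks, record_cells_from=None)
    res = runio.run(cfg, seed)
    g_end = res.growth_end_tick
    if g_end is None:
        raise RuntimeError("donor run did not finish growth")
    k_e = res.trace["k_e"].to_numpy()
    seg = k_e[g_end + settle:g_end + settle + length]
    ev = analysis.detect_oscillations(exterior_trace(res)[g_end:])
    return DonorTrace(seg, ev.period, g_end)


def _trace_only(cfg: SimulationConfig, n_ticks: int | None = None) -> SimulationConfig:
    import copy

    c = copy.deepcopy(cfg)
    c.record_cells_from = None
    if n_ticks is not None:
        c.n_ticks = n_ticks
    return c


def _replicate_troughs(results, onset: int, window) -> list[np.ndarray]:
    lo, hi = onset + window[0], onset + window[1]
    return [
        analysis.trough_times_in_window(exterior_trace(r), lo, hi)
        for r in results
    ]


def _run_ensemble(cfg, seeds, donor: DonorTrace, distance_um, window,
                  settle: int = 150, onset_offset: int = 200, ramp: int = 400):
    """Run one replicate ensemble, forced from the donor at a distance
    (unforced when ``distance_um`` is None).  Forcing onset is scheduled
    ``settle + onset_offset`` ticks after the donor's growth end, by which
    time every replicate is stably oscillating."""
    onset = donor.growth_end_tick + settle + onset_offset
    n_ticks = onset + window[1] + 3 * int(donor.period)
    c = _trace_only(cfg, n_ticks=n_ticks)
    if distance_um is None:
        sched = None
    else:
        sched = environment.neighbor_potassium_oscillation(
            distance_um, donor.k_e_segment, onset=onset, ramp=ramp,
            basal=cfg.k_m, donor_period=donor.period,
        )
    runs = runio.ensemble(c, len(seeds), seeds, env=sched)
    return {"runs": runs, "onset": onset}


def asynchrony_sweep(distances_um, replicates: int, seed: int,
                     cfg: SimulationConfig | None = None,
                     donor: DonorTrace | None = None,
                     window: tuple[int, int] = (600, 750)) -> dict:
    """Asynchrony index at several donor distances, sharing one donor run and
    one unforced (null) ensemble.

    Protocol: every replicate grows independently to full size; once all are
    stably oscillating, basal potassium starts following the donor's
    distance-attenuated excursion (linear 400-tick onset ramp); trough times
    are collected 600-750 ticks after forcing onset and their
    per-oscillation IQR across replicates is scaled by the unforced
    ensemble's value.
    """
    base = cfg or default_config()
    seeds = runio.spawn_seeds(seed, replicates + 1)
    donor_seed, rep_seeds = seeds[0], seeds[1:]
    if donor is None:
        donor = make_donor(donor_seed)

    # the unforced spread is time-invariant: measure it over a long span of
    # the null ensemble so the normalization is stable
    null = _run_ensemble(base, rep_seeds, donor, None, window)
    null_troughs = _replicate_troughs(
        null["runs"], null["onset"], (150, window[1] + 150)
    )

    out = {}
    for d in distances_um:
        forced = _run_ensemble(base, rep_seeds, donor, d, window)
        troughs = _replicate_troughs(forced["runs"], forced["onset"], window)
        out[d] = analysis.asynchrony_index(troughs, null_troughs)
    return out


def asynchrony_experiment(cfg: SimulationConfig | None, distance_um: float,
                          replicates: int, seed: int,
                          donor: DonorTrace | None = None) -> float:
    """Asynchrony index of a forced replicate ensemble at one donor distance."""
    return asynchrony_sweep([distance_um], replicates, seed, cfg=cfg,
                            donor=donor)[distance_um]


def glutamate_sync_experiment(cfg: SimulationConfig | None, magnitude_mm: float,
                              replicates: int, seed: int,
                              window: tuple[int, int] = (600, 750)) -> float:
    """Asynchrony index under sinusoidal basal-glutamate forcing.

    Same replicate/null design as the potassium experiment, but the shared
    schedule oscillates media glutamate about its basal value with the given
    amplitude and the colony's own oscillation period.
    """
    base = cfg or default_config()
    seeds = runio.spawn_seeds(seed, replicates + 1)
    donor = make_donor(seeds[0])
    onset = donor.growth_end_tick + 350
    n_ticks = onset + window[1] + 3 * int(donor.period)
    c = _trace_only(base, n_ticks=n_ticks)

    null_runs = runio.ensemble(c, replicates, seeds[1:])
    null_troughs = _replicate_troughs(null_runs, onset, (150, window[1] + 150))

    sched = environment.glutamate_oscillation(magnitude_mm, donor.period,
                                              start=onset, basal=base.g_m)
    forced = runio.ensemble(c, replicates, seeds[1:], env=sched)
    troughs = _replicate_troughs(forced, onset, window)
    return analysis.asynchrony_index(troughs, null_troughs)
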