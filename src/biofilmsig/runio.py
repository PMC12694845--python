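"""Configuration loading, reproducible execution, and trace/snapshot I/O.

A run is fully determined by ``(config, seed)``: all randomness flows from a
single seeded generator consumed in a fixed order (growth selection draws,
then placement draws, then one batched inheritance draw, per tick), so the
same pair always reproduces the same trace bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import analysis, diffusion
from .dynamics import step_biofilm
from .environment import EnvironmentSchedule
from .growth import initialize_biofilm, lineage_table
from .params import (GrowthPolicy, ModelParameters, SimulationConfig,
                     ThresholdDistribution)

__version__ = "0.1.0"


# ----------------------------------------------------------------- config I/O

def _from_mapping(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data or {})
    kwargs = {}
    if "params" in data:
        kwargs["params"] = _from_mapping(ModelParameters, data.pop("params"), "params")
    if "thresholds" in data:
        kwargs["thresholds"] = _from_mapping(
            ThresholdDistribution, data.pop("thresholds"), "thresholds"
        )
    if "growth" in data:
        kwargs["growth"] = _from_mapping(GrowthPolicy, data.pop("growth"), "growth")
    top = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs.update(data)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> SimulationConfig:
    """Load a YAML config; unspecified values take the package defaults."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return config_from_dict(data)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    preset: str
    n_ticks: int
    growth_end_tick: Optional[int]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ------------------------------------------------------------------ execution

@dataclass
class RunResult:
    """Everything one run produces: colony trace, per-cell data, manifest."""

    trace: pd.DataFrame                    # one row per tick
    cells: pd.DataFrame                    # static per-cell table (lineage + geometry)
    manifest: RunManifest
    d_star: int                            # penetration depth used for regions
    depth: np.ndarray                      # final per-cell depth
    tht_history: Optional[np.ndarray] = None   # (ticks, cells) float16
    sig_history: Optional[np.ndarray] = None   # (ticks, cells) bool
    record_start: Optional[int] = None         # tick of tht_history[0]
    mean_g_i_post_growth: Optional[np.ndarray] = None
    config: Optional[SimulationConfig] = None

    @property
    def growth_end_tick(self) -> Optional[int]:
        return self.manifest.growth_end_tick

    def regions(self) -> analysis.RegionPartition:
        return analysis.partition_regions(self.depth, self.d_star)

    def tht_at(self, tick: int) -> np.ndarray:
        if self.tht_history is None:
            raise ValueError("per-cell history was not recorded for this run")
        return self.tht_history[tick - self.record_start].astype(float)


TRACE_COLUMNS = [
    "tick", "population", "radius", "frac_signaling", "frac_signaling_interior",
    "frac_signaling_exterior", "frac_bright", "frac_bright_interior",
    "frac_bright_exterior", "k_e", "mean_g_i", "g_m", "k_m", "births",
]


def run(config: SimulationConfig, seed: int,
        env: Optional[EnvironmentSchedule] = None,
        progress: bool = False) -> RunResult:
    """Execute one simulation: nutrient-free growth, then ``n_ticks`` of dynamics."""
    config.validate()
    rng = np.random.default_rng(seed)
    env = env or EnvironmentSchedule(g_m=config.g_m, k_m=config.k_m)

    state = initialize_biofilm(config, rng)
    d_star = diffusion.penetration_depth(config.g_m, config.params, k_m=config.k_m)
    cap = config.growth.population_cap + 4000
    n_ticks = config.n_ticks

    rows = np.empty((n_ticks, len(TRACE_COLUMNS)))
    tht_hist = None
    sig_hist = None
    record_start = None
    record_from = config.record_cells_from

    for t in range(n_ticks):
        g_m, k_m = env.at(t)
        pop_before = state.n
        step_biofilm(state, g_m, k_m, config, rng)
        n = state.n
        depth = state.depths()
        sig = state.signaling[:n]
        ext = depth < d_star
        interior = depth >= d_star + 8
        frac = sig.mean()
        frac_ext = sig[ext].mean() if ext.any() else np.nan
        frac_int = sig[interior].mean() if interior.any() else np.nan
        # ThT-classified ("bright") fractions: the cutoff is the exterior
        # median plus the fixed offset, the region imaged in vitro
        tht = state.tht[:n]
        cut = np.median(tht[ext]) + config.params.tht_cutoff_offset if ext.any() else np.inf
        bright = tht > cut
        rows[t] = (
            t, n, state.lattice.radius(), frac, frac_int, frac_ext,
            bright.mean(),
            bright[interior].mean() if interior.any() else np.nan,
            bright[ext].mean() if ext.any() else np.nan,
            state.k_e, state.g_i[:n].mean(), g_m, k_m, n - pop_before,
        )

        start_rec = (
            record_from == t
            if isinstance(record_from, int)
            else (record_from == "post_growth" and not state.growing)
        )
        if tht_hist is None and start_rec:
            record_start = t
            tht_hist = np.zeros((n_ticks - record_start, cap), dtype=np.float16)
            sig_hist = np.zeros((n_ticks - record_start, cap), dtype=bool)
        if tht_hist is not None:
            i = t - record_start
            tht_hist[i, :n] = state.tht[:n]
            sig_hist[i, :n] = state.signaling[:n]
        if progress and t % 200 == 0:
            import sys

            print(f"tick {t} pop {n} K_e {state.k_e:.1f} sig {frac:.2f}",
                  file=sys.stderr)

    if state._depth_stale:
        state.refresh_depth()
    n = state.n
    trace = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    for c in ("tick", "population", "radius", "births"):
        trace[c] = trace[c].astype(int)
    cells = lineage_table(state)
    cells["q"] = state.lattice.q[:n]
    cells["r"] = state.lattice.r[:n]
    cells["depth"] = state.depths()

    manifest = RunManifest(
        config_hash=config_hash(config), seed=seed, version=__version__,
        preset=env.preset, n_ticks=n_ticks,
        growth_end_tick=state.growth_end_tick,
    )
    mean_gi = None
    if state._gi_accum_ticks > 0:
        mean_gi = state.mean_g_i_post_growth()
    if tht_hist is not None:
        tht_hist = tht_hist[:, :n]
        sig_hist = sig_hist[:, :n]
    return RunResult(
        trace=trace, cells=cells, manifest=manifest, d_star=d_star,
        depth=state.depths().copy(), tht_history=tht_hist, sig_history=sig_hist,
        record_start=record_start, mean_g_i_post_growth=mean_gi, config=config,
    )


def ensemble(config: SimulationConfig, n: int, seeds,
             env: Optional[EnvironmentSchedule] = None,
             envs: Optional[list] = None, **kwargs) -> list[RunResult]:
    """Independent runs sharing an environment schedule.

    Results depend only on each run's own seed, so they are independent of
    execution order.  Duplicate seeds get a warning.
    """
    seeds = list(seeds)
    if n < 1 or len(seeds) != n:
        raise ValueError("need one seed per replicate")
    if len(set(seeds)) != n:
        warnings.warn("duplicate seeds in ensemble", stacklevel=2)
    if envs is not None and len(envs) != n:
        raise ValueError("need one environment per replicate")
    return [
        run(config, s, env=envs[i] if envs is not None else env, **kwargs)
        for i, s in enumerate(seeds)
    ]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# -------------------------------------------------------------- serialization

def write_trace(trace: pd.DataFrame, path) -> None:
    # %.17g guarantees float64 round-trip through text
    trace.to_csv(path, index=False, float_format="%.17g")


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_snapshot(result: RunResult, outdir, every: int = 50) -> None:
    """Per-cell ThT/signaling snapshots at a cadence, as compressed arrays."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.tht_history is None:
        raise ValueError("run recorded no per-cell history")
    idx = np.arange(0, result.tht_history.shape[0], every)
    np.savez_compressed(
        outdir / "snapshots.npz",
        ticks=idx + result.record_start,
        tht=result.tht_history[idx].astype(np.float32),
        signaling=result.sig_history[idx],
    )
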