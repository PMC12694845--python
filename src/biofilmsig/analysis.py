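"""Derived statistics: signaler classification, region partition, oscillation
detection, recurrence/consistency, asynchrony, starvation, phase diagram.

Conventions mirror the in-vitro measurements the simulator is compared
against: "signalers" at an oscillation peak are cells whose ThT proxy
exceeds the colony median by a fixed offset (the ThT distribution at peaks
is bimodal); the colony *exterior* is the region media glutamate would reach
in the absence of signaling, the *interior* everything more than 8 cells
deeper, with the 8-cell buffer dropped from region statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal as _signal


# ------------------------------------------------------------- classification

def classify_signalers(tht: np.ndarray, cutoff_offset: float = 0.35) -> np.ndarray:
    """Signaler mask at a peak: ThT above the median plus a fixed offset."""
    tht = np.asarray(tht, dtype=float)
    if tht.size < 2:
        raise ValueError("need at least two cells to classify signalers")
    return tht > (np.median(tht) + cutoff_offset)


@dataclass
class RegionPartition:
    """Exterior / interior / buffer masks from the penetration depth."""

    d_star: int                 # exterior depth bound (cells)
    buffer_width: int           # cells between exterior and interior
    exterior: np.ndarray        # depth < d_star
    interior: np.ndarray        # depth >= d_star + buffer
    buffer: np.ndarray


def partition_regions(depth: np.ndarray, d_star: int, buffer_width: int = 8) -> RegionPartition:
    """Split cells into exterior (depth < d*), interior (>= d* + 8), buffer.

    If the colony is shallower than ``d* + buffer`` the interior is empty and
    a warning is emitted (all-exterior partition).
    """
    depth = np.asarray(depth)
    exterior = depth < d_star
    interior = depth >= d_star + buffer_width
    buffer = ~exterior & ~interior
    if not interior.any():
        warnings.warn(
            "colony shallower than the penetration depth + buffer: all-exterior partition",
            stacklevel=2,
        )
    return RegionPartition(d_star, buffer_width, exterior, interior, buffer)


# ----------------------------------------------------------------- oscillation

@dataclass
class OscillationEvents:
    """Peak/trough ticks of a signaling-fraction trace and the period estimate."""

    peaks: np.ndarray           # integer ticks of maxima
    troughs: np.ndarray         # integer ticks of minima
    trough_times: np.ndarray    # sub-tick trough times (parabolic interpolation)
    peak_values: np.ndarray
    trough_values: np.ndarray
    period: float               # mean peak-to-peak interval, ticks (nan if < 2 peaks)

    @property
    def n_oscillations(self) -> int:
        return len(self.peaks)


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + len(x)]


def _parabolic_time(x: np.ndarray, i: int) -> float:
    """Sub-sample extremum location by a parabola through 3 points."""
    if i == 0 or i >= len(x) - 1:
        return float(i)
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (x[i - 1] - x[i + 1]) / denom)


def detect_oscillations(trace: np.ndarray, smooth: int = 5,
                        min_prominence: float = 0.08,
                        min_distance: int = 25) -> OscillationEvents:
    """Locate signaling-fraction peaks and troughs.

    The trace is boxcar-smoothed, extrema found with a prominence criterion,
    and trough times refined by parabolic interpolation for sub-tick
    resolution.  A flat trace yields no events.
    """
    x = _smooth(np.asarray(trace, dtype=float), smooth)
    peaks, _ = _signal.find_peaks(x, prominence=min_prominence, distance=min_distance)
    troughs, _ = _signal.find_peaks(-x, prominence=min_prominence, distance=min_distance)
    trough_times = np.array([_parabolic_time(-x, i) for i in troughs])
    period = float(np.mean(np.diff(peaks))) if len(peaks) >= 2 else float("nan")
    return OscillationEvents(
        peaks=peaks, troughs=troughs, trough_times=trough_times,
        peak_values=x[peaks], trough_values=x[troughs], period=period,
    )


def stable_range(trace: np.ndarray, window: int = 200) -> float:
    """Peak-to-trough range of the signaling fraction over the last window."""
    x = np.asarray(trace, dtype=float)
    w = x[-window:]
    return float(w.max() - w.min())


def is_stably_oscillating(trace: np.ndarray, window: int = 200,
                          range_criterion: float = 0.20) -> bool:
    """Stable oscillation: range > 20 percentage points over the window,
    with genuine alternation (>= 2 detected peaks)."""
    x = np.asarray(trace, dtype=float)[-window:]
    if stable_range(x, window) <= range_criterion:
        return False
    return detect_oscillations(x).n_oscillations >= 2


def onset_radius(signaling_trace: np.ndarray, radius_trace: np.ndarray,
                 window: int = 90, range_criterion: float = 0.20):
    """Radius at which sustained oscillations first appear during growth.

    Scans a rolling window over the signaling-fraction trace and returns the
    colony radius at the first tick where the peak-to-trough range criterion
    is met; ``None`` if it never is.
    """
    x = np.asarray(signaling_trace, dtype=float)
    r = np.asarray(radius_trace)
    if len(x) < window:
        return None
    # rolling min/max via stride tricks would be fine too; this is clear enough
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    rng = maximum_filter1d(x, window, origin=-(window // 2)) - minimum_filter1d(
        x, window, origin=-(window // 2)
    )
    hits = np.nonzero(rng[: len(x) - window] > range_criterion)[0]
    if hits.size == 0:
        return None
    # report the tick by which the windowed range criterion has been observed
    return int(r[min(hits[0] + window, len(r) - 1)])


# ----------------------------------------------------------- cell-level rates

def recurrence_rates(parent_ids: np.ndarray, signaler_masks: list[np.ndarray],
                     include: np.ndarray | None = None) -> tuple[float, float]:
    """Mother-daughter signaling concordance at oscillation peaks.

    Returns ``(P(daughter signals | mother signals),
    P(daughter silent | mother silent))`` pooled over the given per-peak
    signaler masks.  ``include`` restricts pairs to a region (both cells must
    be included); by default all mother-daughter pairs are used.
    """
    parent_ids = np.asarray(parent_ids)
    child = np.nonzero(parent_ids >= 0)[0]
    mother = parent_ids[child]
    if include is not None:
        keep = include[child] & include[mother]
        child, mother = child[keep], mother[keep]
    if child.size == 0:
        raise ValueError("no mother-daughter pairs available")
    ss = sn = ns = nn = 0
    for mask in signaler_masks:
        m = mask[mother]
        c = mask[child]
        ss += int(np.sum(m & c))
        sn += int(np.sum(m & ~c))
        ns += int(np.sum(~m & c))
        nn += int(np.sum(~m & ~c))
    if ss + sn == 0 or ns + nn == 0:
        raise ValueError("a signaling class is empty at every peak")
    return ss / (ss + sn), nn / (nn + ns)


def consistency_fractions(mask_a: np.ndarray, mask_b: np.ndarray,
                          include: np.ndarray | None = None) -> tuple[float, float, float]:
    """Fractions of cells signaling in both, neither, or exactly one of two peaks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if include is not None:
        a, b = a[include], b[include]
    n = a.size
    both = float(np.sum(a & b)) / n
    neither = float(np.sum(~a & ~b)) / n
    switched = 1.0 - both - neither
    return both, neither, switched


def long_run_consistency(per_oscillation_signaled: np.ndarray,
                         hi: float = 0.9, lo: float = 0.1) -> tuple[float, float, float]:
    """Fractions of cells signaling in >90%, <10%, or in between, of all
    oscillations.

    ``per_oscillation_signaled`` is (cells x oscillations) boolean: whether
    the cell signaled at any point during each oscillation.
    """
    m = np.asarray(per_oscillation_signaled, dtype=bool)
    frac = m.mean(axis=1)
    always = float(np.mean(frac > hi))
    never = float(np.mean(frac < lo))
    return always, never, 1.0 - always - never


# ------------------------------------------------------------------ asynchrony

def trough_times_in_window(trace: np.ndarray, start: int, end: int,
                           **detect_kwargs) -> np.ndarray:
    """Sub-tick trough times of a signaling trace restricted to a window."""
    ev = detect_oscillations(np.asarray(trace, dtype=float), **detect_kwargs)
    t = ev.trough_times
    return t[(t >= start) & (t < end)]


def _matched_trough_spreads(trough_lists: list[np.ndarray], spread) -> np.ndarray:
    """Per-oscillation spread of trough times across replicates.

    Troughs are grouped across replicates by proximity rather than by index:
    each oscillation's reference time starts as the median of the k-th sorted
    troughs and is refined once, and every replicate contributes its closest
    trough within half a typical period.  Index-free matching keeps one
    missed trough from shifting a replicate's whole series by a period.
    """
    lists = [np.sort(np.asarray(t, dtype=float)) for t in trough_lists if len(t)]
    if not lists:
        return np.asarray([])
    n_osc = int(np.median([len(t) for t in lists]))
    spacing = np.median(np.concatenate(
        [np.diff(t) for t in lists if len(t) > 1] or [np.asarray([np.inf])]
    ))
    tol = spacing / 2 if np.isfinite(spacing) else np.inf
    out = []
    for k in range(n_osc):
        ref = float(np.median([t[k] for t in lists if len(t) > k]))
        for _ in range(2):  # refine the reference once
            times = []
            for t in lists:
                j = int(np.argmin(np.abs(t - ref)))
                if abs(t[j] - ref) <= tol:
                    times.append(float(t[j]))
            if not times:
                break
            ref = float(np.median(times))
        if len(times) < len(trough_lists):
            warnings.warn(
                f"{len(trough_lists) - len(times)} replicate(s) missing a trough "
                f"near t={ref:.0f}: excluded",
                stacklevel=3,
            )
        if len(times) >= 3:
            out.append(spread(np.asarray(times)))
    return np.asarray(out)


def asynchrony_index(forced_troughs: list[np.ndarray],
                     null_troughs: list[np.ndarray]) -> float:
    """Mean IQR of trough times across replicates, scaled by the unforced value.

    0 means perfect synchrony; 1 means the spread of the unforced ensemble
    (the null is 1 by construction).  The null trough lists may span a longer
    unforced stretch than the forced analysis window — the unforced spread is
    time-invariant, and averaging over more oscillations stabilizes the
    normalization.
    """
    def iqr(x: np.ndarray) -> float:
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)

    forced = _matched_trough_spreads(forced_troughs, iqr)
    null = _matched_trough_spreads(null_troughs, iqr)
    if forced.size == 0 or null.size == 0 or null.mean() == 0:
        raise ValueError("not enough troughs in the analysis window")
    return float(forced.mean() / null.mean())


# ------------------------------------------------------------------ starvation

def starved_census(mean_g_i: np.ndarray, floor: float = 1e-3) -> int:
    """Cells whose post-growth time-averaged internal glutamate is below floor."""
    return int(np.sum(np.asarray(mean_g_i) < floor))


# ---------------------------------------------------------------- phase diagram

def classify_regime(signaling_trace: np.ndarray, k_e_trace: np.ndarray,
                    window: int = 200, range_criterion: float = 0.20,
                    collapse_k_e: float = 100.0) -> str:
    """Classify a run as ``stable`` / ``minimal`` / ``collapse``.

    Collapse: extracellular potassium reaches implausible levels and
    colony-wide signaling ceases.  Stable: the peak-to-trough range criterion
    is met in the late window.  Minimal: persistent low-level signaling
    without colony-wide waves.
    """
    k_e = np.asarray(k_e_trace, dtype=float)
    if k_e[-window:].max() > collapse_k_e:
        return "collapse"
    if is_stably_oscillating(signaling_trace, window, range_criterion):
        return "stable"
    return "minimal"


def phase_diagram(results: dict) -> dict:
    """Classify a grid of runs keyed by (lower, upper) threshold bounds.

    ``results`` maps bound pairs to ``(signaling_trace, k_e_trace)`` tuples;
    the return maps the same keys to regime labels.
    """
    return {
        bounds: classify_regime(np.asarray(tr), np.asarray(ke))
        for bounds, (tr, ke) in results.items()
    }
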