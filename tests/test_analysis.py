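"""Derived statistics on synthetic inputs with known answers."""

import numpy as np
import pytest

from biofilmsig import analysis


# ----------------------------------------------------------- classification

def test_all_equal_tht_classifies_nobody():
    assert not analysis.classify_signalers(np.full(100, 0.7)).any()


def test_classifier_recovers_a_separated_mixture():
    rng = np.random.default_rng(0)
    lo = rng.normal(0.2, 0.03, 600)
    hi = rng.normal(0.9, 0.03, 400)
    tht = np.concatenate([lo, hi])
    labels = analysis.classify_signalers(tht)
    assert labels[600:].all()
    assert not labels[:600].any()


def test_classifier_needs_two_cells():
    with pytest.raises(ValueError):
        analysis.classify_signalers(np.array([1.0]))


# ----------------------------------------------------------------- partition

def test_partition_masks_are_disjoint_and_exhaustive():
    depth = np.arange(60)
    part = analysis.partition_regions(depth, d_star=20)
    assert not (part.exterior & part.interior).any()
    assert not (part.exterior & part.buffer).any()
    assert (part.exterior | part.interior | part.buffer).all()
    assert part.exterior.sum() == 20
    assert part.interior.sum() == 60 - 28


def test_shallow_colony_warns_and_is_all_exterior():
    depth = np.arange(10)
    with pytest.warns(UserWarning, match="all-exterior"):
        part = analysis.partition_regions(depth, d_star=15)
    assert part.exterior.all()
    assert not part.interior.any()


# --------------------------------------------------------------- oscillation

def test_sinusoid_yields_events_at_the_known_period():
    t = np.arange(450)
    x = 0.3 + 0.2 * np.sin(2 * np.pi * t / 45)
    ev = analysis.detect_oscillations(x)
    assert 8 <= ev.n_oscillations <= 10
    assert np.isclose(ev.period, 45, atol=1.0)


def test_flat_trace_yields_no_events():
    ev = analysis.detect_oscillations(np.full(300, 0.4))
    assert ev.n_oscillations == 0
    assert len(ev.troughs) == 0


def test_noisy_sinusoid_trough_times_within_two_ticks():
    rng = np.random.default_rng(3)
    t = np.arange(450)
    x = 0.3 - 0.2 * np.cos(2 * np.pi * t / 45) + rng.normal(0, 0.015, t.size)
    ev = analysis.detect_oscillations(x)
    truth = np.array([k * 45.0 for k in range(1, 10)])
    for tt in ev.trough_times:
        assert np.abs(truth - tt).min() <= 2.0


def test_onset_radius_detection_on_synthetic_growth_trace():
    t = np.arange(3000)
    x = np.where(t > 2000, 0.25 + 0.2 * np.sin(2 * np.pi * t / 45), 0.02)
    radius = t // 20  # radius grows linearly with time
    onset = analysis.onset_radius(x, radius)
    assert onset is not None
    assert abs(onset - 100) <= 5  # oscillation starts at tick 2000, radius 100
    assert analysis.onset_radius(np.full(3000, 0.1), radius) is None


def test_stability_criterion_requires_twenty_point_range():
    t = np.arange(400)
    weak = 0.3 + 0.05 * np.sin(2 * np.pi * t / 45)
    strong = 0.3 + 0.2 * np.sin(2 * np.pi * t / 45)
    assert analysis.is_stably_oscillating(strong)
    assert not analysis.is_stably_oscillating(weak)


# ------------------------------------------------------ recurrence/consistency

def _masks_from_threshold(T, cut):
    return [T > cut]


def test_perfect_inheritance_gives_unit_recurrence():
    """In the zero-noise limit daughters share the mother's threshold, so
    signaling state at a peak is perfectly concordant."""
    n = 400
    T = np.zeros(n)
    T[:100] = np.linspace(0, 3, 100)
    parent = np.concatenate([[-1] * 100, np.arange(n - 100) % 100])
    T[100:] = T[parent[100:]]  # exact inheritance from the founders
    masks = _masks_from_threshold(T, 1.7)
    sig, nonsig = analysis.recurrence_rates(parent, masks)
    assert sig == 1.0 and nonsig == 1.0


def test_shuffled_lineage_recurrence_converges_to_marginals():
    """Permuting parent links destroys heritability: both recurrence rates
    approach the marginal signaling fractions."""
    rng = np.random.default_rng(1)
    n = 60_000
    mask = rng.random(n) < 0.43
    parent = np.concatenate([[-1] * 100, rng.integers(0, 100, n - 100)])
    parent[100:] = rng.permutation(np.arange(n - 100))  # arbitrary links
    sig, nonsig = analysis.recurrence_rates(parent, [mask])
    assert abs(sig - 0.43) < 0.02
    assert abs(nonsig - 0.57) < 0.02


def test_consistency_fractions_identities():
    rng = np.random.default_rng(2)
    a = rng.random(1000) < 0.4
    b = rng.random(1000) < 0.4
    both, neither, switched = analysis.consistency_fractions(a, b)
    assert np.isclose(both + neither + switched, 1.0)
    same = analysis.consistency_fractions(a, a)
    assert same[2] == 0.0  # identical masks: nobody switches


def test_independent_masks_product_of_marginals():
    """Independent participation at p = 0.43 gives 'both' near p^2 ~ 0.18."""
    rng = np.random.default_rng(4)
    n = 200_000
    a = rng.random(n) < 0.43
    b = rng.random(n) < 0.43
    both, _, _ = analysis.consistency_fractions(a, b)
    assert abs(both - 0.43 ** 2) < 0.005


def test_long_run_consistency_partitions_cells():
    part = np.zeros((300, 30), dtype=bool)
    part[:100] = True                      # always
    part[100:150, :3] = True               # sometimes (10%)
    always, never, mid = analysis.long_run_consistency(part)
    assert np.isclose(always, 1 / 3)
    assert np.isclose(always + never + mid, 1.0)


# ------------------------------------------------------------------ asynchrony

def test_identical_trough_times_give_zero_index():
    troughs = [np.array([610.0, 655.0, 700.0, 745.0])] * 10
    null = [np.array([600.0, 645.0, 690.0, 735.0]) + 10 * k for k in range(10)]
    assert analysis.asynchrony_index(troughs, null) == 0.0


def test_null_ensemble_is_unity_by_construction():
    rng = np.random.default_rng(5)
    null = [np.sort(600 + 150 * rng.random(4)) for _ in range(12)]
    assert np.isclose(analysis.asynchrony_index(null, null), 1.0)


def test_missing_troughs_warn_and_are_excluded():
    rng = np.random.default_rng(6)
    full = [np.array([610.0, 655.0, 700.0, 745.0]) + rng.normal(0, 4, 4)
            for _ in range(9)]
    short = [np.array([612.0, 657.0])]
    with pytest.warns(UserWarning, match="missing a trough"):
        idx = analysis.asynchrony_index(full + short, full + short)
    assert np.isfinite(idx) and idx > 0


# ------------------------------------------------------------------ starvation

def test_starved_census_counts_below_floor():
    g = np.array([0.0, 5e-4, 1e-3, 0.1, 2.0])
    assert analysis.starved_census(g) == 2


# ---------------------------------------------------------------- regime label

def test_classify_regime_categories():
    t = np.arange(400)
    stable = 0.3 + 0.25 * np.sin(2 * np.pi * t / 45)
    flatlow = np.full(400, 0.08)
    k_normal = np.full(400, 9.0)
    k_blown = np.concatenate([np.full(200, 9.0), np.full(200, 400.0)])
    assert analysis.classify_regime(stable, k_normal) == "stable"
    assert analysis.classify_regime(flatlow, k_normal) == "minimal"
    assert analysis.classify_regime(flatlow, k_blown) == "collapse"
    out = analysis.phase_diagram({(0.0, 3.0): (stable, k_normal),
                                  (-0.4, 2.5): (flatlow, k_normal)})
    assert out == {(0.0, 3.0): "stable", (-0.4, 2.5): "minimal"}
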