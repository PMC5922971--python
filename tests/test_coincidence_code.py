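"""Coincidence-code thresholds: pools, Hamming criterion, paired experiment."""

from __future__ import annotations

import math

import numpy as np
import pytest

from edgecode import (
    EdgeStimulus,
    activation_vector,
    contactable_pool,
    contactable_pool_sweep,
    discrimination_threshold,
    rf_reach_pool,
    run_paired_experiment,
)
from edgecode.afferent_population import (
    AfferentUnit,
    FingertipModel,
    PopulationConfig,
    ReceptorElement,
)


def _handmade_population() -> FingertipModel:
    """7 uniform-style units in a ring plus center, radii 1 mm."""
    units = []
    pts = [(10.0, 10.0)] + [
        (10.0 + 3.0 * math.cos(a), 10.0 + 3.0 * math.sin(a))
        for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)
    ]
    for i, p in enumerate(pts):
        units.append(
            AfferentUnit(i, p, 1.0, elements=[ReceptorElement(p, 1.0)])
        )
    return FingertipModel(units, "uniform", 20.0, 20.0)


def test_contactable_pool_handmade_oracle():
    pop = _handmade_population()
    c = (10.0, 10.0)
    # ring units sit 3 mm out with radius 1: reachable iff L/2 + 1 > 3
    assert contactable_pool(pop, c, 1.0) == 1  # center unit only
    assert contactable_pool(pop, c, 4.001) == 7
    assert contactable_pool(pop, c, 3.999) == 1  # strict inequality
    assert contactable_pool(pop, c, 44.0) == 7


def test_rf_reach_pool_equals_activation_pool_for_uniform():
    pop = _handmade_population()
    c = (10.0, 10.0)
    for length in (1.0, 4.001, 44.0):
        assert rf_reach_pool(pop, c, length) == contactable_pool(pop, c, length)


def test_rf_reach_pool_dominates_activation_pool(small_pair):
    sub, _ = small_pair
    c = sub.patch_center
    for length in (1.0, 4.0, 44.0):
        assert rf_reach_pool(sub, c, length) >= contactable_pool(sub, c, length)


def test_analytic_pool_matches_sweep_small(small_pair):
    sub, uni = small_pair
    c = sub.patch_center
    for pop in (sub, uni):
        for length in (1.0, 44.0):
            assert contactable_pool(pop, c, length) == contactable_pool_sweep(
                pop, c, length, step_deg=0.1
            )


def test_threshold_handmade_uniform_ring():
    # A single off-center unit (radius 1 at distance 3): a centered 8 mm
    # edge at 0 deg passes through it; it deactivates once the perpendicular
    # distance from its center to the edge line reaches 1 mm, i.e. at
    # rotation asin(1/3) = 19.47 deg.  Pool = {center, east}: center never
    # changes, so the threshold needs 5% * 2 = 0.1 -> 1 flip.
    units = [
        AfferentUnit(0, (10.0, 10.0), 1.0, elements=[ReceptorElement((10.0, 10.0), 1.0)]),
        AfferentUnit(1, (13.0, 10.0), 1.0, elements=[ReceptorElement((13.0, 10.0), 1.0)]),
    ]
    pop = FingertipModel(
        units + [AfferentUnit(i, (1.0 + i, 1.0), 0.5, elements=[ReceptorElement((1.0 + i, 1.0), 0.5)]) for i in range(2, 7)],
        "uniform",
        20.0,
        20.0,
    )
    edge = EdgeStimulus((10.0, 10.0), 8.0, 0.0)
    res = discrimination_threshold(pop, edge, step_deg=0.5)
    expected = math.degrees(math.asin(1.0 / 3.0))  # 19.47 deg
    assert res.threshold == pytest.approx(math.ceil(expected / 0.5) * 0.5)
    assert res.pool_size == 2
    assert res.hamming_profile[0] == 0.0
    assert res.hamming_profile[-1] >= 0.1 * res.pool_size / 2  # reached 1 flip


def test_dot_stimulus_has_no_threshold(small_pair):
    # a point stimulus is rotation invariant: no rotation changes anything
    sub, uni = small_pair
    for pop in (sub, uni):
        res = discrimination_threshold(pop, EdgeStimulus(pop.patch_center, 0.0, 0.0))
        assert res.threshold is None
        assert np.all(res.hamming_profile == 0.0)


def test_threshold_profile_monotone_until_hit(small_pair):
    sub, _ = small_pair
    res = discrimination_threshold(sub, EdgeStimulus(sub.patch_center, 44.0, 0.0))
    assert res.threshold is not None
    assert res.threshold % 0.5 == 0.0
    # last profile entry is the first to satisfy the criterion
    assert res.hamming_profile[-1] >= 0.05 * res.pool_size
    assert np.all(res.hamming_profile[:-1] < 0.05 * res.pool_size)


def test_pool_override_scales_required_flips():
    pop = _handmade_population()
    edge = EdgeStimulus((10.0, 10.0), 44.0, 0.0)
    base = discrimination_threshold(pop, edge)
    harder = discrimination_threshold(pop, edge, pool_override=1000)
    assert harder.pool_size == 1000
    # requiring 50 flips from 7 units is impossible
    assert harder.threshold is None
    assert base.threshold is not None


def test_activation_vector_changes_with_rotation(small_pair):
    sub, _ = small_pair
    edge = EdgeStimulus(sub.patch_center, 44.0, 0.0)
    a0 = activation_vector(sub, edge)
    a90 = activation_vector(sub, edge.rotated(90.0))
    assert a0.dtype == bool and a0.shape == (sub.n_units,)
    assert np.any(a0 != a90)


@pytest.fixture(scope="module")
def small_experiment():
    cfg = PopulationConfig(patch_width=10.0, patch_height=10.0)
    return run_paired_experiment(
        [1.0, 4.0, math.inf], repetitions=8, seed=123, config=cfg
    )


def test_experiment_reproducible(small_experiment):
    cfg = PopulationConfig(patch_width=10.0, patch_height=10.0)
    again = run_paired_experiment(
        [1.0, 4.0, math.inf], repetitions=8, seed=123, config=cfg
    )
    assert small_experiment.records.equals(again.records)
    assert small_experiment.summary.equals(again.summary)


def test_experiment_structure_and_pairing(small_experiment):
    rec = small_experiment.records
    assert set(rec.variant) == {"subfield", "uniform"}
    assert len(rec) == 2 * 3 * 8
    # the activation pool is shared geometry: the uniform twin's pool can
    # only be >= the subfield pool (every element hit implies an RF hit)
    piv = rec.pivot_table(
        index=["rep", "length_mm"], columns="variant", values="pool_size"
    )
    assert (piv["uniform"] >= piv["subfield"]).all()


def test_experiment_summary_accounts_for_all_reps(small_experiment):
    s = small_experiment.summary
    assert ((s["n"] + s["n_none"]) == 8).all()
    ok = s.dropna(subset=["mean_deg"])
    assert (ok["ci_low"] <= ok["mean_deg"]).all()
    assert (ok["mean_deg"] <= ok["ci_high"]).all()


def test_experiment_mean_accessor(small_experiment):
    s = small_experiment
    v = s.mean_threshold("subfield", 1.0)
    manual = np.nanmean(s.thresholds("subfield", 1.0))
    assert v == pytest.approx(manual)


def test_rf_reach_convention_shares_pool_between_variants():
    cfg = PopulationConfig(patch_width=10.0, patch_height=10.0)
    res = run_paired_experiment(
        [4.0], repetitions=4, seed=5, config=cfg, nc_convention="rf_reach"
    )
    piv = res.records.pivot_table(index="rep", columns="variant", values="pool_size")
    assert (piv["uniform"] == piv["subfield"]).all()


def test_experiment_input_validation():
    with pytest.raises(ValueError):
        run_paired_experiment([])
    with pytest.raises(ValueError):
        run_paired_experiment([1.0], repetitions=1, nc_convention="bogus")
    with pytest.raises(ValueError):
        run_paired_experiment([1.0], repetitions=1, stimulus_location="corner")
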