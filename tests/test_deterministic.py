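"""Deterministic release model: fixed points, invariance, solver behaviour."""

import math

import numpy as np
import pytest

from ylepop.deterministic import (
    DemographyParams,
    PopulationState,
    ReleaseSchedule,
    required_release_rate,
    sensitivity_curve,
    simulate,
    step,
)
from ylepop.genetics import GenotypeSpace, PhenotypeParams
from ylepop.strategies import strategy_preset
from dataclasses import replace


def _simulate_preset(name, rate, rm=6.0, horizon=36, **schedule_kwargs):
    pre = strategy_preset(name)
    space = GenotypeSpace(pre.loci)
    demo = DemographyParams(rm=rm, horizon=horizon)
    schedule = ReleaseSchedule(rate, pre.released, **schedule_kwargs)
    return simulate(space, pre.editing, pre.phen, demo, schedule)


def test_equilibrium_is_stationary_for_100_generations():
    res = _simulate_preset("yle_dsx_b", 0.0, horizon=100)
    assert np.max(np.abs(res.fertile_females - 1.0)) < 1e-10
    assert np.max(np.abs(res.total_females - 1.0)) < 1e-10


def test_step_fixed_point_and_negative_release():
    pre = strategy_preset("yle_dsx_b")
    space = GenotypeSpace(pre.loci)
    state = PopulationState.equilibrium(space)
    demo = DemographyParams()
    out = step(state, pre.editing, pre.phen, demo)
    np.testing.assert_allclose(out.F, state.F, atol=1e-14)
    np.testing.assert_allclose(out.M, state.M, atol=1e-14)
    with pytest.raises(ValueError):
        step(state, pre.editing, pre.phen, demo, release_amount=-0.5,
             released_genotype=pre.released)


@pytest.mark.parametrize("rm", [2.0, 6.0, 12.0])
@pytest.mark.parametrize("r_frac", [0.5, 0.9])
def test_sit_fixed_points_match_closed_form(rm, r_frac):
    """Sustained sterile-male releases below threshold settle on the upper
    root of (Rm-1)x^2 - (Rm-1)x + r = 0."""
    r = r_frac * (rm - 1.0) / 4.0 * 0.9
    res = _simulate_preset("optimal_sit", r, rm=rm, horizon=400)
    expected = 0.5 * (1 + math.sqrt(1 - 4 * r / (rm - 1)))
    assert res.fertile_females[-1] == pytest.approx(expected, abs=1e-6)


def test_sit_above_threshold_eliminates():
    rm = 6.0
    res = _simulate_preset("optimal_sit", (rm - 1) / 4 * 1.1, rm=rm, horizon=400)
    assert res.fertile_females[-1] < 1e-6


def test_costfree_yle_frequency_is_invariant():
    """A single release of cost-free YLE males leaves the YLE-male frequency
    at the released value indefinitely."""
    pre = strategy_preset("yle_dsx_b")
    space = GenotypeSpace(pre.loci)
    phen = replace(pre.phen, yle_male_cost=0.0)
    res = simulate(
        space, pre.editing, phen, DemographyParams(rm=6.0, horizon=50),
        ReleaseSchedule(0.5, pre.released, single_release=True),
    )
    np.testing.assert_allclose(res.yle_male_freq[1:], 1.0 / 3.0, atol=1e-10)


def test_single_release_declines_then_rebounds():
    res = _simulate_preset("yle_dsx_b", 1.0, single_release=True)
    f = res.fertile_females
    t_min = int(np.argmin(f))
    assert 0 < t_min < len(f) - 1
    assert f[t_min] < 0.6
    # monotone rebound after the minimum
    assert np.all(np.diff(f[t_min:]) >= -1e-12)
    # YLE-male frequency decays under the fitness cost
    assert res.yle_male_freq[5] < res.yle_male_freq[1]


def test_sustained_releases_suppress_and_accumulate_recessives():
    res = _simulate_preset("yle_dsx_b", 0.20)
    assert res.fertile_females[-1] < 0.05
    # recessive resistant alleles accumulate through the suppression phase
    # while the dominant allele plateaus
    assert np.all(np.diff(res.resistant_freq[:16]) > 0)
    assert res.resistant_freq[15] > 3 * res.resistant_freq[5]
    assert np.nanmax(res.dom_r_freq) < 0.5


def test_zero_rate_schedule_is_flat():
    res = _simulate_preset("optimal_sit", 0.0)
    np.testing.assert_allclose(res.fertile_females, 1.0, atol=1e-12)


def test_required_rate_monotone_in_target_cost_and_horizon(strain_b):
    space = GenotypeSpace(strain_b.loci)
    demo = DemographyParams(rm=6.0, horizon=36)
    rates = [
        required_release_rate(
            space, strain_b.editing, strain_b.phen, demo, strain_b.released, t
        )
        for t in (0.5, 0.95, 0.99)
    ]
    assert rates[0] < rates[1] < rates[2]

    for lo_cost, hi_cost in [(0.0, 0.22), (0.22, 0.5)]:
        r_lo = required_release_rate(
            space, strain_b.editing, replace(strain_b.phen, yle_male_cost=lo_cost),
            demo, strain_b.released, 0.95,
        )
        r_hi = required_release_rate(
            space, strain_b.editing, replace(strain_b.phen, yle_male_cost=hi_cost),
            demo, strain_b.released, 0.95,
        )
        assert r_lo < r_hi

    shorter = required_release_rate(
        space, strain_b.editing, strain_b.phen,
        DemographyParams(rm=6.0, horizon=18), strain_b.released, 0.95,
    )
    longer = required_release_rate(
        space, strain_b.editing, strain_b.phen,
        DemographyParams(rm=6.0, horizon=72), strain_b.released, 0.95,
    )
    rate36 = required_release_rate(
        space, strain_b.editing, strain_b.phen, demo, strain_b.released, 0.95
    )
    assert shorter > rate36 > longer


def test_required_rate_edge_cases(strain_b):
    space = GenotypeSpace(strain_b.loci)
    demo = DemographyParams(rm=6.0, horizon=36)
    tiny = required_release_rate(
        space, strain_b.editing, strain_b.phen, demo, strain_b.released, 1e-3
    )
    assert tiny < 0.01
    unreachable = required_release_rate(
        space, strain_b.editing, strain_b.phen, demo, strain_b.released, 0.99,
        rate_max=0.01,
    )
    assert math.isinf(unreachable)
    with pytest.raises(ValueError):
        required_release_rate(
            space, strain_b.editing, strain_b.phen, demo, strain_b.released, 1.5
        )


def test_final_generation_deadline_needs_no_more_than_anytime(strain_b):
    """Requiring suppression exactly at the final generation can never demand
    a lower rate than reaching it at any generation."""
    space = GenotypeSpace(strain_b.loci)
    demo = DemographyParams(rm=6.0, horizon=36)
    anytime = required_release_rate(
        space, strain_b.editing, strain_b.phen, demo, strain_b.released, 0.95
    )
    at_end = required_release_rate(
        space, strain_b.editing, strain_b.phen, demo, strain_b.released, 0.95,
        at_final_generation=True,
    )
    assert at_end >= anytime - 1e-4
    # under sustained releases the trajectory keeps declining, so both
    # deadline readings agree here
    assert at_end == pytest.approx(anytime, abs=2e-4)


def test_strategy_preset_names_and_errors():
    with pytest.raises(ValueError, match="optimal_sit"):
        strategy_preset("not_a_strategy")
    sit = strategy_preset("optimal_sit")
    assert sit.phen.sterile_males and sit.phen.yle_male_cost == 0.0
    opt = strategy_preset("optimal_yle")
    assert opt.editing.cleave_het == 1.0 and opt.editing.nhej_given_cleave == 0.0
    b = strategy_preset("yle_dsx_b")
    assert b.phen.yle_male_cost == pytest.approx(0.22)


def test_sit_and_fs_ridl_transgenes_are_self_limiting():
    """After a single release the construct vanishes and females rebound."""
    for name in ("optimal_sit", "optimal_fs_ridl"):
        res = _simulate_preset(name, 1.0, horizon=50, single_release=True)
        assert res.construct_freq[-1] < 1e-6
        assert res.fertile_females[-1] > 0.99


def test_sensitivity_curves_are_monotone():
    grid = [0.5, 0.75, 1.0]
    cleave = sensitivity_curve("cleave_het", grid, rm_list=[6.0])
    sweep = cleave[~cleave.is_baseline].sort_values("value")["required_rate"].to_numpy()
    assert np.all(np.diff(sweep) <= 1e-4)

    cost = sensitivity_curve("yle_male_cost", [0.0, 0.22, 0.5], rm_list=[6.0])
    sweep = cost[~cost.is_baseline].sort_values("value")["required_rate"].to_numpy()
    assert np.all(np.diff(sweep) >= -1e-4)
    base = cost[cost.is_baseline]
    assert base["value"].iloc[0] == pytest.approx(0.22)

    with pytest.raises(ValueError, match="unknown sensitivity parameter"):
        sensitivity_curve("not_a_param", grid)
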