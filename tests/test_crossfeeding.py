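"""Cross-feeding auxotroph community model."""

import numpy as np
import pytest

from chamberlink import crossfeeding as cf
from chamberlink.lattice import build_lattice


def test_growth_rate_spans_basal_to_max():
    p = cf.AuxotrophParameters()
    assert cf.growth_rate("metA", 0.0, p) == pytest.approx(p.mu_basal_metA)
    assert cf.growth_rate("metA", 1e6, p) == pytest.approx(p.mu_max_metA, rel=1e-4)
    # at the half-saturation constant the Monod factor is 1/2
    mid = cf.growth_rate("metA", p.K_M, p)
    expect = p.mu_basal_metA + 0.5 * (p.mu_max_metA - p.mu_basal_metA)
    assert mid == pytest.approx(expect)


def test_internal_reserve_substitutes_for_external_supply():
    p = cf.AuxotrophParameters()
    # full reserve alone gives maximal growth; reserve and external combine
    assert cf.growth_rate("pheA", 0.0, p, reserve=1.0) == \
        pytest.approx(p.mu_max_pheA)
    low = cf.growth_rate("pheA", 0.0, p, reserve=0.0)
    mixed = cf.growth_rate("pheA", 0.0, p, reserve=0.5)
    assert low < mixed < p.mu_max_pheA


def test_release_is_inverse_for_meta_and_proportional_for_phea():
    p = cf.AuxotrophParameters()
    # starved dMetA releases F maximally; fast-growing dMetA releases none
    assert cf.release_rate("metA", 0.0, p) == pytest.approx(p.r_F_max)
    assert cf.release_rate("metA", p.mu_max_metA, p) == pytest.approx(0.0)
    # dPheA releases M in proportion to growth
    assert cf.release_rate("pheA", 0.0, p) == pytest.approx(0.0)
    assert cf.release_rate("pheA", p.mu_max_pheA, p) == pytest.approx(p.r_M_max)


def test_unknown_strain_is_rejected():
    p = cf.AuxotrophParameters()
    with pytest.raises(ValueError):
        cf.growth_rate("lacZ", 0.0, p)
    with pytest.raises(ValueError):
        cf.scenario_parameters(p, "no_such_medium")


def test_saturating_media_gives_distance_independent_fast_growth():
    res = cf.predicted_doubling_times(cf.AuxotrophParameters(),
                                      (25.0, 250.0), "all_aa")
    for strain in ("metA", "pheA"):
        near, far = res["doubling_time_min"][strain]
        assert abs(far - near) / near < 0.02
    # both strains close to their intrinsic doubling times
    assert res["doubling_time_min"]["metA"][0] < 100.0
    assert res["doubling_time_min"]["pheA"][0] < 100.0


def test_phea_doubling_time_increases_with_distance_without_feeding():
    res = cf.predicted_doubling_times(cf.AuxotrophParameters(),
                                      (25.0, 50.0, 100.0, 250.0), "no_M_no_F")
    dts = res["doubling_time_min"]["pheA"]
    assert all(a < b for a, b in zip(dts, dts[1:]))
    # dMetA stays near-basal everywhere (little M reaches it)
    meta = res["doubling_time_min"]["metA"]
    assert min(meta) > 4 * max(res["doubling_time_min"]["pheA"])


def test_phea_peak_growth_comes_later_at_larger_distance():
    res = cf.predicted_doubling_times(cf.AuxotrophParameters(),
                                      (25.0, 250.0), "no_M_no_F")
    t_near, t_far = res["time_of_max_growth_min"]["pheA"]
    assert t_far > t_near


def test_rescuing_meta_flattens_phea_distance_dependence():
    res = cf.predicted_doubling_times(cf.AuxotrophParameters(),
                                      (25.0, 250.0), "plus_M_no_F")
    near, far = res["doubling_time_min"]["pheA"]
    assert abs(far - near) / near < 0.02


def test_biomass_respects_chamber_capacity():
    p = cf.scenario_parameters(cf.AuxotrophParameters(), "all_aa")
    g = build_lattice(25.0, 1.0)
    traj = cf.simulate_community(p, g, cf.scenario_initial(g, "all_aa"),
                                 t_end=2000.0)
    assert np.max(traj.biomass_metA) <= p.capacity * 1.01
    assert np.max(traj.biomass_pheA) <= p.capacity * 1.01
    assert traj.biomass_metA[-1] == pytest.approx(p.capacity, rel=0.05)


def test_rescue_scenario_growth_is_biphasic_reserve_then_partner_fed():
    p = cf.scenario_parameters(cf.AuxotrophParameters(), "plus_M_no_F")
    g = build_lattice(25.0, 1.0)
    traj = cf.simulate_community(p, g, cf.scenario_initial(g, "plus_M_no_F"),
                                 t_end=1500.0)
    mu = traj.mu_pheA
    # early reserve-driven rate exceeds the late partner-fed plateau,
    # and the plateau stays above basal (cross-feeding does arrive)
    assert mu[0] > 1.5 * mu[-1]
    assert mu[-1] > 1.5 * p.mu_basal_pheA


def test_scenario_initial_loads_reserve_only_for_rescue():
    g = build_lattice(25.0, 1.0)
    rescue = cf.scenario_initial(g, "plus_M_no_F")
    starved = cf.scenario_initial(g, "no_M_no_F")
    assert rescue.reserve_pheA > 0.0
    assert starved.reserve_pheA == 0.0 and starved.reserve_metA == 0.0
    assert starved.M.size == g.n_compartments
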