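"""Sender/receiver circuit: Hill kinetics, delay chains, distance response."""

import numpy as np
import pytest
from scipy import stats

from chamberlink import circuit as circ
from chamberlink.lattice import build_lattice


def test_hill_transcription_limits_and_half_max():
    assert circ.hill_transcription(0.0, 5.0, 1.0, 2.0) == pytest.approx(0.0)
    assert circ.hill_transcription(1.0, 5.0, 1.0, 2.0) == pytest.approx(2.5)
    assert circ.hill_transcription(1e9, 5.0, 1.0, 2.0) == pytest.approx(5.0, rel=1e-6)


def test_hill_transcription_rejects_invalid_parameters():
    with pytest.raises(ValueError):
        circ.hill_transcription(1.0, 5.0, -1.0, 2.0)
    with pytest.raises(ValueError):
        circ.hill_transcription(-1.0, 5.0, 1.0, 2.0)


def test_delay_chain_mean_delay_is_stages_over_rate():
    # mean of the impulse response (Erlang) equals N/a
    chain = circ.DelayChain(N=4, a=0.25)
    t = np.linspace(0.0, 200.0, 4001)
    h = circ.delay_chain_impulse_response(chain, t)
    mean_delay = np.trapezoid(t * h, t) / np.trapezoid(h, t)
    assert mean_delay == pytest.approx(16.0, rel=1e-3)


@pytest.mark.parametrize("N,a", [(1, 0.3), (5, 0.5), (20, 1.0)])
def test_delay_chain_impulse_response_is_erlang_density(N, a):
    t = np.linspace(0.0, max(200.0, 8 * N / a), 4001)
    h = circ.delay_chain_impulse_response(circ.DelayChain(N, a), t)
    erl = stats.gamma.pdf(t, N, scale=1.0 / a)
    assert np.trapezoid(np.abs(h - erl), t) < 1e-3


def test_delay_chain_rhs_relaxes_each_stage_toward_input():
    chain = circ.DelayChain(N=3, a=0.5)
    stages = np.array([0.0, 1.0, 2.0])
    d = circ.delay_chain_rhs(chain, stages, input_value=4.0)
    assert np.allclose(d, [2.0, -0.5, -0.5])


def test_steady_state_ahl_profile_balances_lattice_fluxes():
    params = circ.CircuitParameters()
    g = build_lattice(50.0, 1.0)
    ss = circ.steady_state_response(params, g, ara=0.1)
    ahl = ss["AHL_profile"]
    # interior nodes: diffusive exchange exactly balances degradation
    residual = (params.D1 * (ahl[:-2] - 2.0 * ahl[1:-1] + ahl[2:])
                - params.gamma_AHL * ahl[1:-1])
    assert np.max(np.abs(residual)) < 1e-8 * np.max(ahl)


def test_simulation_converges_to_analytic_steady_state():
    params = circ.CircuitParameters()
    g = build_lattice(25.0, 1.0)
    sig = circ.InputSignal("step", 0.1, onset_min=0.0)
    traj = circ.simulate_circuit(params, g, sig, t_end=3000.0)
    ss = circ.steady_state_response(params, g, ara=0.1)
    assert traj.RFP_p[-1] == pytest.approx(ss["RFP_p"], rel=1e-3)
    assert traj.GFP_p[-1] == pytest.approx(ss["GFP_p"], rel=1e-3)


def test_receiver_output_decreases_with_separation():
    params = circ.CircuitParameters()
    rfp = []
    for L in (25.0, 50.0, 100.0, 250.0):
        g = build_lattice(L, 1.0)
        rfp.append(circ.steady_state_response(params, g, ara=0.1)["RFP_p"])
    assert all(a > b for a, b in zip(rfp, rfp[1:]))


def test_sender_output_is_insensitive_to_separation():
    params = circ.CircuitParameters()
    gfp = [circ.steady_state_response(params, build_lattice(L, 1.0), 0.1)["GFP_p"]
           for L in (25.0, 250.0)]
    assert gfp[0] == pytest.approx(gfp[1], rel=1e-6)


def test_receiver_responds_later_at_larger_separation():
    params = circ.CircuitParameters()
    sig = circ.InputSignal("step", 0.1, onset_min=0.0)
    t50 = {}
    for L in (25.0, 250.0):
        traj = circ.simulate_circuit(params, build_lattice(L, 1.0), sig,
                                     t_end=700.0)
        t50[L] = circ.response_time(traj.times, traj.RFP_p, switch_time=0.0)
    assert t50[250.0] > t50[25.0]


def test_dose_response_is_monotone_and_saturating():
    params = circ.CircuitParameters()
    ahl = np.logspace(-1, 5, 30)
    resp = circ.dose_response(params, ahl)
    assert np.all(np.diff(resp) > 0)
    # doubling a saturating dose barely moves the output
    top = circ.dose_response(params, np.array([1e6, 2e6]))
    assert top[1] / top[0] < 1.001


def test_activated_receptor_is_bounded_by_total_luxr():
    params = circ.CircuitParameters()
    assert circ.activated_receptor(0.0, params) == pytest.approx(0.0)
    assert circ.activated_receptor(1e9, params) <= params.LuxR_tot * (1 + 1e-9)


def test_response_time_of_known_first_order_rise():
    # value(t) = 1 - exp(-t/tau): half-rise at tau*ln 2
    tau = 30.0
    t = np.linspace(0.0, 400.0, 2001)
    v = 1.0 - np.exp(-t / tau)
    t50 = circ.response_time(t, v, switch_time=0.0)
    assert t50 == pytest.approx(tau * np.log(2.0), rel=1e-3)


def test_input_signal_shapes():
    step = circ.InputSignal("step", 0.2, onset_min=100.0)
    assert step.value(50.0) == 0.0 and step.value(150.0) == 0.2
    sq = circ.InputSignal("square_wave", 0.2, period_min=120.0, onset_min=0.0)
    assert sq.value(10.0) == 0.2      # first half-cycle on
    assert sq.value(70.0) == 0.0      # second half-cycle off
    with pytest.raises(ValueError):
        circ.InputSignal("square_wave", 0.2)        # period required
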