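"""Sender/receiver quorum-sensing circuit on the diffusion lattice.

A sender strain in the source chamber carries an arabinose-inducible operon
expressing GFP and the AHL synthase LuxI.  AHL produced by the sender diffuses
through the interaction channel (rate D1), degrades (gamma_AHL), and leaks
into the main flow channels (D2).  In the receiver chamber AHL binds LuxR; the
activated complex (LuxRAHL, treated as a quasi-steady Hill function of local
AHL bounded by LuxR_tot) drives RFP transcription.

Transcription uses the activating Hill form

    dB_m/dt = alpha * A^n / (K^n + A^n) - gamma_m * B_m

and every slow multi-step process (arabinose transport, protein
assembly/maturation of GFP, LuxI and RFP) is a linear chain of N first-order
stages with per-stage rate a,

    dy_j/dt = a * (y_{j-1} - y_j),   j = 1..N,

whose mean delay is N/a and whose impulse response is the Erlang(N, a)
density.

All rates are per minute; concentrations are in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from chamberlink.lattice import (
    DiffusibleField,
    LatticeGeometry,
    build_lattice,
    diffusion_rhs,
)

__all__ = [
    "DelayChain",
    "CircuitParameters",
    "InputSignal",
    "CircuitTrajectory",
    "hill_transcription",
    "delay_chain_rhs",
    "delay_chain_impulse_response",
    "circuit_rhs",
    "simulate_circuit",
    "simulate_step_response",
    "simulate_periodic_input",
    "steady_state_response",
    "response_time",
    "distance_sensitivity",
    "dose_response",
    "transmission_distance",
    "activated_receptor",
]


def hill_transcription(A: float, alpha: float, K: float, n: float) -> float:
    """Activating Hill transcription rate alpha * A^n / (K^n + A^n)."""
    if K <= 0:
        raise ValueError("Hill half-max K must be positive")
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("activator concentration must be non-negative")
    An = np.power(A, n)
    out = alpha * An / (K**n + An)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DelayChain:
    """Linear chain of N first-order stages with rate a; mean delay N/a min."""

    N: int
    a: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("delay chain needs at least one stage")
        if self.a <= 0:
            raise ValueError("per-stage rate a must be positive")

    @property
    def delay_min(self) -> float:
        return self.N / self.a


def delay_chain_rhs(chain: DelayChain, stages: np.ndarray, input_value: float) -> np.ndarray:
    """Stage derivatives a*(y_{j-1} - y_j) with y_0 = input_value."""
    stages = np.asarray(stages, dtype=float)
    if stages.shape != (chain.N,):
        raise ValueError(f"expected {chain.N} stages, got shape {stages.shape}")
    prev = np.concatenate(([input_value], stages[:-1]))
    return chain.a * (prev - stages)


def delay_chain_impulse_response(chain: DelayChain, times: np.ndarray,
                                 rtol: float = 1e-9, atol: float = 1e-12) -> np.ndarray:
    """Final-stage response to a unit impulse at t=0 (equals the Erlang density).

    A Dirac input kicks the first stage to ``a``; thereafter the chain runs
    input-free.  Integrated numerically so tests can compare it against the
    closed-form Erlang(N, a) density as an independent check.
    """
    times = np.asarray(times, dtype=float)
    y0 = np.zeros(chain.N)
    y0[0] = chain.a
    sol = solve_ivp(lambda t, y: delay_chain_rhs(chain, y, 0.0),
                    (times[0], times[-1]), y0, t_eval=times,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"delay-chain integration failed: {sol.message}")
    return sol.y[-1]


@dataclass(frozen=True)
class CircuitParameters:
    """All rate constants of the sender/receiver model.

    Defaults are plausible placeholder values that reproduce the qualitative
    behaviour of the device: distance-decreasing receiver steady states,
    few-minute 25-vs-250 um response-time differences, and low-pass filtering
    of periodic inputs.  ``D1`` is the lattice-scaled channel diffusion rate
    (per min at the geometry's node spacing), ``D2`` the chamber leak into the
    main channel.
    """

    # transcription (AU/min) and promoter constants
    alpha_GFP: float = 10.0
    alpha_LuxI: float = 10.0
    alpha_RFP: float = 10.0
    K_ara: float = 0.05          # % arabinose
    n_ara: float = 2.0
    K_LuxR: float = 150.0        # AHL half-binding (AU)
    n_LuxR: float = 1.0
    K_RFP: float = 100.0         # LuxRAHL half-activation (AU)
    n_RFP: float = 2.0
    LuxR_tot: float = 100.0
    # synthesis / turnover (per min)
    k_AHL: float = 0.5
    k_tl: float = 1.0
    gamma_m: float = 0.1
    gamma_p: float = 0.0231      # dilution at ~30 min doubling
    gamma_AHL: float = 0.3
    # transport
    D1: float = 20000.0          # lattice-scaled (per min, 1 um spacing)
    D2: float = 0.2
    # delay chains (N stages, per-stage rate a)
    delay_ara: DelayChain = DelayChain(3, 0.3)
    delay_GFP: DelayChain = DelayChain(5, 0.5)
    delay_LuxI: DelayChain = DelayChain(5, 0.5)
    delay_RFP: DelayChain = DelayChain(5, 0.5)

    def __post_init__(self) -> None:
        for name in ("alpha_GFP", "alpha_LuxI", "alpha_RFP", "k_AHL", "k_tl",
                     "gamma_m", "gamma_p", "gamma_AHL", "D1", "D2", "LuxR_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K_ara", "K_LuxR", "K_RFP"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_ara", "n_LuxR", "n_RFP"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class InputSignal:
    """Arabinose induction program: a step or a 50%-duty square wave."""

    kind: str                     # "step" | "square_wave"
    amplitude: float
    period_min: float | None = None
    onset_min: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "square_wave"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.kind == "square_wave" and (self.period_min is None or self.period_min <= 0):
            raise ValueError("square_wave input needs a positive period")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def value(self, t: float) -> float:
        if t < self.onset_min:
            return 0.0
        if self.kind == "step":
            return self.amplitude
        half = self.period_min / 2.0
        phase = (t - self.onset_min) % self.period_min
        return self.amplitude if phase < half else 0.0

    def switch_times(self, t_end: float) -> np.ndarray:
        if self.kind == "step":
            sw = np.array([self.onset_min])
        else:
            half = self.period_min / 2.0
            sw = self.onset_min + half * np.arange(0, int((t_end - self.onset_min) / half) + 1)
        return sw[(sw > 0) & (sw < t_end)]


class _Layout:
    """Index map for the flat circuit state vector."""

    def __init__(self, params: CircuitParameters, geometry: LatticeGeometry):
        i = 0

        def block(size):
            nonlocal i
            sl = slice(i, i + size)
            i += size
            return sl

        self.ara_chain = block(params.delay_ara.N)
        self.GFP_m = block(1)
        self.GFP_chain = block(params.delay_GFP.N)
        self.GFP_p = block(1)
        self.LuxI_m = block(1)
        self.LuxI_chain = block(params.delay_LuxI.N)
        self.LuxI_p = block(1)
        self.AHL = block(geometry.n_compartments)
        self.RFP_m = block(1)
        self.RFP_chain = block(params.delay_RFP.N)
        self.RFP_p = block(1)
        self.size = i


def activated_receptor(AHL: float, params: CircuitParameters) -> float:
    """Quasi-steady activated complex LuxRAHL = LuxR_tot * Hill(AHL; K_LuxR, n_LuxR)."""
    return hill_transcription(AHL, params.LuxR_tot, params.K_LuxR, params.n_LuxR)


def circuit_rhs(y: np.ndarray, params: CircuitParameters,
                geometry: LatticeGeometry, ara_input: float,
                layout: _Layout | None = None) -> np.ndarray:
    """Full derivative vector of the sender/receiver model at one instant."""
    lay = layout or _Layout(params, geometry)
    y = np.asarray(y, dtype=float)
    if y.shape != (lay.size,):
        raise ValueError(f"state length {y.shape} does not match layout ({lay.size})")
    dy = np.empty_like(y)
    p = params

    ara_stages = y[lay.ara_chain]
    dy[lay.ara_chain] = delay_chain_rhs(p.delay_ara, ara_stages, ara_input)
    ara_d = ara_stages[-1]

    promoter = hill_transcription(ara_d, 1.0, p.K_ara, p.n_ara)
    GFP_m = y[lay.GFP_m][0]
    dy[lay.GFP_m] = p.alpha_GFP * promoter - p.gamma_m * GFP_m
    gfp_stages = y[lay.GFP_chain]
    dy[lay.GFP_chain] = delay_chain_rhs(p.delay_GFP, gfp_stages, GFP_m)
    dy[lay.GFP_p] = p.k_tl * gfp_stages[-1] - p.gamma_p * y[lay.GFP_p][0]

    LuxI_m = y[lay.LuxI_m][0]
    dy[lay.LuxI_m] = p.alpha_LuxI * promoter - p.gamma_m * LuxI_m
    luxi_stages = y[lay.LuxI_chain]
    dy[lay.LuxI_chain] = delay_chain_rhs(p.delay_LuxI, luxi_stages, LuxI_m)
    LuxI_p = y[lay.LuxI_p][0]
    dy[lay.LuxI_p] = p.k_tl * luxi_stages[-1] - p.gamma_p * LuxI_p

    ahl = y[lay.AHL]
    field = DiffusibleField(ahl, D=p.D1, gamma=p.gamma_AHL, D_leak=p.D2)
    dy[lay.AHL] = diffusion_rhs(field, geometry, ahl,
                                source_production=p.k_AHL * LuxI_p)

    LuxRAHL = activated_receptor(max(ahl[-1], 0.0), p)
    RFP_m = y[lay.RFP_m][0]
    dy[lay.RFP_m] = hill_transcription(LuxRAHL, p.alpha_RFP, p.K_RFP, p.n_RFP) \
        - p.gamma_m * RFP_m
    rfp_stages = y[lay.RFP_chain]
    dy[lay.RFP_chain] = delay_chain_rhs(p.delay_RFP, rfp_stages, RFP_m)
    dy[lay.RFP_p] = p.k_tl * rfp_stages[-1] - p.gamma_p * y[lay.RFP_p][0]
    return dy


def _jac_sparsity(params: CircuitParameters, geometry: LatticeGeometry,
                  lay: _Layout):
    """Structural Jacobian sparsity; keeps the stiff solver cheap."""
    S = lil_matrix((lay.size, lay.size), dtype=np.int8)

    def chain_block(sl: slice, input_idx: int | None):
        idx = range(sl.start, sl.stop)
        for k, j in enumerate(idx):
            S[j, j] = 1
            if k == 0:
                if input_idx is not None:
                    S[j, input_idx] = 1
            else:
                S[j, j - 1] = 1

    chain_block(lay.ara_chain, None)
    ara_out = lay.ara_chain.stop - 1
    for m_sl in (lay.GFP_m, lay.LuxI_m):
        S[m_sl.start, m_sl.start] = 1
        S[m_sl.start, ara_out] = 1
    chain_block(lay.GFP_chain, lay.GFP_m.start)
    S[lay.GFP_p.start, lay.GFP_p.start] = 1
    S[lay.GFP_p.start, lay.GFP_chain.stop - 1] = 1
    chain_block(lay.LuxI_chain, lay.LuxI_m.start)
    S[lay.LuxI_p.start, lay.LuxI_p.start] = 1
    S[lay.LuxI_p.start, lay.LuxI_chain.stop - 1] = 1
    a0, a1 = lay.AHL.start, lay.AHL.stop
    for j in range(a0, a1):
        S[j, j] = 1
        if j > a0:
            S[j, j - 1] = 1
        if j < a1 - 1:
            S[j, j + 1] = 1
    S[a0, lay.LuxI_p.start] = 1
    S[lay.RFP_m.start, lay.RFP_m.start] = 1
    S[lay.RFP_m.start, a1 - 1] = 1
    chain_block(lay.RFP_chain, lay.RFP_m.start)
    S[lay.RFP_p.start, lay.RFP_p.start] = 1
    S[lay.RFP_p.start, lay.RFP_chain.stop - 1] = 1
    return S.tocsr()


@dataclass
class CircuitTrajectory:
    """Solution of one circuit simulation at one separation distance."""

    times: np.ndarray
    GFP_p: np.ndarray
    RFP_p: np.ndarray
    AHL_receiver: np.ndarray
    channel_length_um: float
    cyclic_steady: bool = True    # False flags an unconverged periodic run

    def species(self, name: str) -> np.ndarray:
        return getattr(self, name)


def simulate_circuit(params: CircuitParameters, geometry: LatticeGeometry,
                     signal: InputSignal, t_end: float,
                     t_eval: Sequence[float] | None = None,
                     rtol: float = 1e-6, atol: float = 1e-9) -> CircuitTrajectory:
    """Integrate the circuit ODEs under the given induction program."""
    lay = _Layout(params, geometry)
    sparsity = _jac_sparsity(params, geometry, lay)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, max(int(t_end) + 1, 2))
    t_eval = np.asarray(t_eval, dtype=float)

    y0 = np.zeros(lay.size)
    breaks = np.concatenate(([0.0], signal.switch_times(t_end), [t_end]))
    breaks = np.unique(breaks)
    ts, gfp, rfp, ahl = [], [], [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        ara = signal.value((a + b) / 2.0)
        seg = t_eval[(t_eval >= a) & (t_eval <= b)]
        if seg.size == 0 or seg[-1] < b:
            seg = np.append(seg, b)
        sol = solve_ivp(lambda t, y: circuit_rhs(y, params, geometry, ara, lay),
                        (a, b), y0, method="BDF", t_eval=seg,
                        jac_sparsity=sparsity, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"circuit integration failed: {sol.message}")
        y0 = sol.y[:, -1]
        keep = np.isin(sol.t, t_eval)
        for t, col in zip(sol.t[keep], sol.y[:, keep].T):
            if ts and t == ts[-1]:
                continue
            ts.append(t)
            gfp.append(col[lay.GFP_p.start])
            rfp.append(col[lay.RFP_p.start])
            ahl.append(col[lay.AHL.stop - 1])
    return CircuitTrajectory(np.asarray(ts), np.asarray(gfp), np.asarray(rfp),
                             np.asarray(ahl), geometry.channel_length_um)


def steady_state_response(params: CircuitParameters, geometry: LatticeGeometry,
                          ara: float) -> dict:
    """Exact steady state under constant induction.

    The sender block is linear given the Hill promoter activity, the AHL
    lattice is linear given LuxI_p, and the receiver block is algebraic given
    receiver-chamber AHL, so the fixed point solves in closed form plus one
    linear system.
    """
    p = params
    promoter = hill_transcription(ara, 1.0, p.K_ara, p.n_ara)
    GFP_m = p.alpha_GFP * promoter / p.gamma_m
    GFP_p = p.k_tl * GFP_m / p.gamma_p
    LuxI_m = p.alpha_LuxI * promoter / p.gamma_m
    LuxI_p = p.k_tl * LuxI_m / p.gamma_p

    n = geometry.n_nodes
    m = n + 2
    A = np.zeros((m, m))
    b = np.zeros(m)
    D, g, leak = p.D1, p.gamma_AHL, p.D2
    v_s = geometry.source_volume_factor
    v_k = geometry.sink_volume_factor
    A[0, 0] = -D / v_s - leak - g
    A[0, 1] = D / v_s
    b[0] = -p.k_AHL * LuxI_p / v_s
    for i in range(1, n + 1):
        A[i, i] = -2.0 * D - g
        A[i, i - 1] = D
        A[i, i + 1] = D
    A[m - 1, m - 1] = -D / v_k - leak - g
    A[m - 1, m - 2] = D / v_k
    ahl = np.linalg.solve(A, b)

    LuxRAHL = activated_receptor(max(ahl[-1], 0.0), p)
    RFP_m = hill_transcription(LuxRAHL, p.alpha_RFP, p.K_RFP, p.n_RFP) / p.gamma_m
    RFP_p = p.k_tl * RFP_m / p.gamma_p
    return {"GFP_p": GFP_p, "RFP_p": RFP_p, "AHL_profile": ahl,
            "AHL_receiver": float(ahl[-1]), "LuxRAHL": LuxRAHL,
            "LuxI_p": LuxI_p}


def simulate_step_response(params: CircuitParameters,
                           channel_lengths_um: Sequence[float],
                           signal: InputSignal, t_end: float,
                           node_spacing_um: float = 1.0,
                           **geom_kwargs) -> dict[float, CircuitTrajectory]:
    """Step-induction trajectories, one per separation distance."""
    out = {}
    for L in channel_lengths_um:
        geom = build_lattice(L, node_spacing_um, **geom_kwargs)
        out[L] = simulate_circuit(params, geom, signal, t_end)
    return out


def simulate_periodic_input(params: CircuitParameters,
                            channel_lengths_um: Sequence[float],
                            signal: InputSignal, t_end: float,
                            node_spacing_um: float = 1.0,
                            **geom_kwargs) -> dict[float, dict]:
    """Square-wave forcing: trajectory plus steady-cycle mean and amplitude.

    The amplitude of the last full cycle before ``t_end`` is (max - min)/2;
    a run whose last two cycles still differ by more than 5% in amplitude is
    flagged as not cyclically steady (``cyclic_steady=False``).
    """
    if signal.kind != "square_wave":
        raise ValueError("simulate_periodic_input expects a square_wave signal")
    T = signal.period_min
    if t_end < signal.onset_min + 5 * T:
        raise ValueError("t_end must cover at least 5 input periods")
    out = {}
    for L in channel_lengths_um:
        geom = build_lattice(L, node_spacing_um, **geom_kwargs)
        traj = simulate_circuit(params, geom, signal, t_end)

        def cycle_stats(k_back: int) -> tuple[float, float]:
            hi = t_end - (k_back - 1) * T
            lo = hi - T
            mask = (traj.times >= lo) & (traj.times <= hi)
            seg = traj.RFP_p[mask]
            return (float(seg.max() + seg.min()) / 2.0,
                    float(seg.max() - seg.min()) / 2.0)

        mean1, amp1 = cycle_stats(1)
        _, amp2 = cycle_stats(2)
        steady = amp1 == amp2 or abs(amp1 - amp2) <= 0.05 * max(amp1, amp2, 1e-12)
        traj.cyclic_steady = steady
        out[L] = {"trajectory": traj, "mean": mean1, "amplitude": amp1,
                  "cyclic_steady": steady}
    return out


def response_time(times: np.ndarray, values: np.ndarray,
                  switch_time: float, settle_frac: float = 0.02) -> float:
    """Minutes from an input switch to 50% of the net steady-state change.

    The trajectory must settle: over its last 10% the excursion from the final
    value must stay within ``settle_frac`` of the net change.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times[-1] <= switch_time:
        raise ValueError("switch_time beyond trajectory end")
    v0 = float(np.interp(switch_time, times, values))
    v_inf = float(values[-1])
    net = v_inf - v0
    tail = values[times >= times[-1] - 0.1 * (times[-1] - switch_time)]
    if abs(net) < 1e-12:
        return 0.0
    if np.max(np.abs(tail - v_inf)) > settle_frac * abs(net):
        raise ValueError("trajectory has not settled; cannot define a response time")
    target = v0 + 0.5 * net
    after = times >= switch_time
    t_a, v_a = times[after], values[after]
    if net > 0:
        crossed = v_a >= target
    else:
        crossed = v_a <= target
    if not crossed.any():
        raise ValueError("trajectory never crosses 50% of its net change")
    k = int(np.argmax(crossed))
    if k == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    t1, t2 = t_a[k - 1], t_a[k]
    f = (target - v_a[k - 1]) / (v_a[k] - v_a[k - 1])
    return float(t1 + f * (t2 - t1) - switch_time)


def distance_sensitivity(params: CircuitParameters, ara: float = 0.1,
                         distance_pair_um: tuple[float, float] = (25.0, 250.0),
                         node_spacing_um: float = 1.0, **geom_kwargs) -> float:
    """Ratio of receiver steady states at the near vs far separation."""
    near, far = distance_pair_um
    r_near = steady_state_response(params, build_lattice(near, node_spacing_um,
                                                         **geom_kwargs), ara)
    r_far = steady_state_response(params, build_lattice(far, node_spacing_um,
                                                        **geom_kwargs), ara)
    if r_far["RFP_p"] <= 0:
        raise ZeroDivisionError("far-distance RFP_p steady state is zero")
    return r_near["RFP_p"] / r_far["RFP_p"]


def dose_response(params: CircuitParameters, AHL_levels: Sequence[float]) -> np.ndarray:
    """Steady RFP_p versus clamped receiver AHL (diffusion bypassed)."""
    levels = np.asarray(AHL_levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("AHL levels must be non-negative")
    p = params
    lux = hill_transcription(levels, p.LuxR_tot, p.K_LuxR, p.n_LuxR)
    rfp_m = hill_transcription(lux, p.alpha_RFP, p.K_RFP, p.n_RFP) / p.gamma_m
    return p.k_tl * np.atleast_1d(rfp_m) / p.gamma_p


def transmission_distance(params: CircuitParameters, ara: float = 0.1,
                          threshold: float = 0.01,
                          reference_length_um: float = 2.0,
                          node_spacing_um: float = 1.0,
                          max_length_um: float = 4000.0,
                          **geom_kwargs) -> float:
    """Separation at which receiver output falls to ``threshold`` of a
    near-contact (2 um) reference — how far one chamber of senders can
    transmit information."""

    def rfp_at(L: float) -> float:
        geom = build_lattice(round(L / node_spacing_um) * node_spacing_um,
                             node_spacing_um, **geom_kwargs)
        return steady_state_response(params, geom, ara)["RFP_p"]

    ref = rfp_at(reference_length_um)
    target = threshold * ref
    lo, hi = reference_length_um, max_length_um
    if rfp_at(hi) > target:
        raise ValueError("receiver output stays above threshold out to max_length_um")
    for _ in range(40):
        mid = round((lo + hi) / 2.0 / node_spacing_um) * node_spacing_um
        if mid in (lo, hi):
            break
        if rfp_at(mid) > target:
            lo = mid
        else:
            hi = mid
    return float((lo + hi) / 2.0)
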