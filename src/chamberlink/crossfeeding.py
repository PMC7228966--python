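"""Two-strain amino-acid cross-feeding model on the diffusion lattice.

A methionine auxotroph (dMetA) occupies the source chamber and a
phenylalanine auxotroph (dPheA) the sink chamber.  The model's assumptions:

1. each strain's growth is limited by the amino acid it cannot make
   (methionine M for dMetA, phenylalanine F for dPheA), with Monod
   saturation, on top of a small basal rate;
2. F release by dMetA is inversely proportional to its growth rate (a
   starving but metabolically active producer leaks the most);
3. M release by dPheA is proportional to its growth rate (and its maximal
   release is far smaller than dMetA's — M is barely detectable in dPheA
   supernatant except under full rescue);
4. the basal rate of dPheA exceeds that of dMetA.

Both amino acids diffuse through the interaction channel (lattice transport)
and exchange with the main flow channel, which holds the supplemented
external concentration of the current medium.  Chamber populations are capped
at the chamber's carrying capacity (~150 cells) because excess cells are
washed out by the continuous flow.

Each strain also carries an internal amino-acid reserve: a dimensionless
pool, loaded by the pre-culture medium, that fuels growth while it lasts
(first-order depletion) independently of the external supply.  The reserve
produces the transient first growth phase seen after a medium downshift; the
full-rescue pre-culture loads dPheA's pool, which is what makes its dilution
curve biphasic in that condition.

Units: time min, biomass in cells, amino acids in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from chamberlink.lattice import DiffusibleField, LatticeGeometry, build_lattice, diffusion_rhs

__all__ = [
    "AuxotrophParameters",
    "CommunityState",
    "CommunityTrajectory",
    "SCENARIOS",
    "growth_rate",
    "release_rate",
    "community_rhs",
    "simulate_community",
    "predicted_doubling_times",
    "scenario_parameters",
    "scenario_initial",
]

#: 1x supplemented concentrations: 0.2 mM methionine, 0.4 mM phenylalanine.
M_1X_MM = 0.2
F_1X_MM = 0.4

SCENARIOS = ("all_aa", "no_M_no_F", "plus_M_no_F", "trace_aa")


@dataclass(frozen=True)
class AuxotrophParameters:
    """Rate constants of the cross-feeding community.

    Maximal rates default to the fast-growth regime observed with full amino
    acid supplementation (doubling times near 80 and 86 min); basal rates give
    a near-stalled dMetA (~1100 min doubling) and a slow dPheA fallback, with
    ``mu_basal_pheA > mu_basal_metA`` enforced.  Release is strongly
    asymmetric: dMetA leaks F copiously when starving, dPheA releases only
    trace M.
    """

    mu_max_metA: float = np.log(2) / 80.0       # per min
    mu_max_pheA: float = np.log(2) / 86.0
    mu_basal_metA: float = np.log(2) / 1150.0
    mu_basal_pheA: float = np.log(2) / 600.0
    K_M: float = 0.02                           # mM
    K_F: float = 0.04
    r_F_max: float = 0.2                        # mM (node volume) per cell per min
    r_M_max: float = 2e-4                       # dPheA barely releases M
    y_M: float = 0.5                            # mM consumed per unit growth
    y_F: float = 0.5
    k_reserve: float = 0.008                    # internal-pool depletion (per min)
    D_aa: float = 2000.0                        # lattice-scaled, per min (1 um spacing)
    gamma_aa: float = 0.0
    D_leak_aa: float = 0.6                      # chamber <-> main channel exchange
    external_M: float = 0.0                     # mM in the main channel
    external_F: float = 0.0
    capacity: float = 150.0                     # cells per chamber

    def __post_init__(self) -> None:
        if self.mu_basal_pheA <= self.mu_basal_metA:
            raise ValueError("model assumes mu_basal_pheA > mu_basal_metA")
        for name in ("mu_max_metA", "mu_max_pheA", "mu_basal_metA",
                     "mu_basal_pheA", "K_M", "K_F", "r_F_max", "r_M_max",
                     "y_M", "y_F", "k_reserve", "D_aa", "gamma_aa",
                     "D_leak_aa", "external_M", "external_F", "capacity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CommunityState:
    """Chamber biomasses, internal reserves, and the two amino-acid fields."""

    biomass_metA: float
    biomass_pheA: float
    M: np.ndarray     # methionine concentration per compartment
    F: np.ndarray     # phenylalanine concentration per compartment
    reserve_metA: float = 0.0
    reserve_pheA: float = 0.0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.biomass_metA < 0 or self.biomass_pheA < 0:
            raise ValueError("biomass must be non-negative")
        if self.reserve_metA < 0 or self.reserve_pheA < 0:
            raise ValueError("reserves must be non-negative")


def growth_rate(strain: str, local_aa: float, params: AuxotrophParameters,
                reserve: float = 0.0) -> float:
    """Per-minute growth rate fuelled by external amino acid and reserves.

    The saturation term combines the Monod uptake fraction m = c/(K+c) with
    the internal reserve r as 1 - (1-m)(1-r): either source alone can drive
    full-speed growth, and the rate stays within [mu_basal, mu_max].
    """
    if local_aa < 0:
        raise ValueError("amino-acid concentration must be non-negative")
    if strain == "metA":
        lo, hi, K = params.mu_basal_metA, params.mu_max_metA, params.K_M
    elif strain == "pheA":
        lo, hi, K = params.mu_basal_pheA, params.mu_max_pheA, params.K_F
    else:
        raise ValueError(f"unknown strain {strain!r}")
    m = local_aa / (K + local_aa)
    r = min(max(reserve, 0.0), 1.0)
    s = 1.0 - (1.0 - m) * (1.0 - r)
    return lo + (hi - lo) * s


def release_rate(strain: str, current_mu: float, params: AuxotrophParameters) -> float:
    """Per-cell amino-acid release rate coupled to the producer's growth rate.

    dMetA releases F fastest when starving (inverse coupling); dPheA releases
    M in proportion to its own growth.
    """
    if strain == "metA":
        mu_max, r_max = params.mu_max_metA, params.r_F_max
        if not 0.0 <= current_mu <= mu_max * (1 + 1e-9):
            raise ValueError("growth rate outside [0, mu_max_metA]")
        return r_max * (1.0 - min(current_mu / mu_max, 1.0))
    if strain == "pheA":
        mu_max, r_max = params.mu_max_pheA, params.r_M_max
        if not 0.0 <= current_mu <= mu_max * (1 + 1e-9):
            raise ValueError("growth rate outside [0, mu_max_pheA]")
        return r_max * min(current_mu / mu_max, 1.0)
    raise ValueError(f"unknown strain {strain!r}")


def community_rhs(y: np.ndarray, params: AuxotrophParameters,
                  geometry: LatticeGeometry) -> np.ndarray:
    """Derivatives of [b_metA, b_pheA, res_metA, res_pheA, M field, F field].

    dMetA sits at the source chamber (index 0 of each field), dPheA at the
    sink (last index).  Consumption draws the uptake-fuelled growth component
    from the local chamber; release injects into it; logistic capping at
    chamber capacity models washout of excess cells; reserves decay first
    order.
    """
    n = geometry.n_compartments
    if y.shape != (4 + 2 * n,):
        raise ValueError("state length does not match geometry")
    b_met, b_phe = max(y[0], 0.0), max(y[1], 0.0)
    res_met, res_phe = max(y[2], 0.0), max(y[3], 0.0)
    M = y[4:4 + n]
    F = y[4 + n:]
    p = params

    c_M = max(M[0], 0.0)
    c_F = max(F[-1], 0.0)
    mu_met = growth_rate("metA", c_M, p, res_met)
    mu_phe = growth_rate("pheA", c_F, p, res_phe)

    db_met = mu_met * b_met * (1.0 - b_met / p.capacity)
    db_phe = mu_phe * b_phe * (1.0 - b_phe / p.capacity)
    dres_met = -p.k_reserve * res_met
    dres_phe = -p.k_reserve * res_phe

    rel_F = release_rate("metA", mu_met, p) * b_met          # into source chamber
    rel_M = release_rate("pheA", mu_phe, p) * b_phe          # into sink chamber
    # uptake draws only the externally fuelled growth component, which
    # vanishes smoothly as the local concentration goes to zero
    cons_M = p.y_M * (p.mu_max_metA - p.mu_basal_metA) \
        * (c_M / (p.K_M + c_M)) * b_met
    cons_F = p.y_F * (p.mu_max_pheA - p.mu_basal_pheA) \
        * (c_F / (p.K_F + c_F)) * b_phe

    M_field = DiffusibleField(M, D=p.D_aa, gamma=p.gamma_aa,
                              D_leak=p.D_leak_aa, external=p.external_M)
    F_field = DiffusibleField(F, D=p.D_aa, gamma=p.gamma_aa,
                              D_leak=p.D_leak_aa, external=p.external_F)
    dM = diffusion_rhs(M_field, geometry, M,
                       source_production=-cons_M, sink_production=rel_M)
    dF = diffusion_rhs(F_field, geometry, F,
                       source_production=rel_F, sink_production=-cons_F)
    return np.concatenate(([db_met, db_phe, dres_met, dres_phe], dM, dF))


def _community_sparsity(geometry: LatticeGeometry):
    n = geometry.n_compartments
    size = 4 + 2 * n
    S = lil_matrix((size, size), dtype=np.int8)
    iM0, iMk = 4, 4 + n - 1
    iF0, iFk = 4 + n, 4 + 2 * n - 1
    S[0, 0] = S[0, iM0] = S[0, 2] = 1
    S[1, 1] = S[1, iFk] = S[1, 3] = 1
    S[2, 2] = 1
    S[3, 3] = 1
    for base in (4, 4 + n):
        for j in range(base, base + n):
            S[j, j] = 1
            if j > base:
                S[j, j - 1] = 1
            if j < base + n - 1:
                S[j, j + 1] = 1
    S[iM0, 0] = 1                            # consumption by dMetA
    S[iMk, 1] = S[iMk, iFk] = S[iMk, 3] = 1  # release by dPheA (growth-coupled)
    S[iF0, 0] = S[iF0, iM0] = S[iF0, 2] = 1  # release by dMetA (growth-coupled)
    S[iFk, 1] = 1                            # consumption by dPheA
    return S.tocsr()


@dataclass
class CommunityTrajectory:
    """Biomass, growth-rate and amino-acid trajectories for one distance."""

    times: np.ndarray
    biomass_metA: np.ndarray
    biomass_pheA: np.ndarray
    mu_metA: np.ndarray
    mu_pheA: np.ndarray
    M_chamber_metA: np.ndarray
    F_chamber_pheA: np.ndarray
    channel_length_um: float

    def max_growth(self, strain: str) -> tuple[float, float]:
        """(max per-capita growth rate, time of that maximum) for a strain.

        The timing uses the statistic the dilution experiments measure: the
        peak of mu(t) * exp(-integral mu dt), i.e. the maximum rate of change
        of a stable diluting reporter.  The rate itself is the plain maximum
        of mu(t).
        """
        mu = self.mu_metA if strain == "metA" else self.mu_pheA
        integral = np.concatenate(([0.0], np.cumsum(
            0.5 * (mu[1:] + mu[:-1]) * np.diff(self.times))))
        dilution_signal = mu * np.exp(-integral)
        return (float(np.max(mu)),
                float(self.times[int(np.argmax(dilution_signal))]))


def simulate_community(params: AuxotrophParameters, geometry: LatticeGeometry,
                       initial: CommunityState, t_end: float,
                       t_eval: Sequence[float] | None = None,
                       rtol: float = 1e-6, atol: float = 1e-9) -> CommunityTrajectory:
    """Integrate the coupled growth / release / diffusion system."""
    n = geometry.n_compartments
    if initial.M.shape != (n,) or initial.F.shape != (n,):
        raise ValueError("initial amino-acid fields do not match geometry")
    y0 = np.concatenate(([initial.biomass_metA, initial.biomass_pheA,
                          initial.reserve_metA, initial.reserve_pheA],
                         initial.M, initial.F))
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, max(int(t_end // 5) + 1, 2))
    sol = solve_ivp(lambda t, y: community_rhs(y, params, geometry),
                    (0.0, t_end), y0, method="BDF", t_eval=np.asarray(t_eval),
                    jac_sparsity=_community_sparsity(geometry),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"community integration failed: {sol.message}")
    M0 = np.maximum(sol.y[4], 0.0)
    Fk = np.maximum(sol.y[4 + 2 * n - 1], 0.0)
    res_met = np.maximum(sol.y[2], 0.0)
    res_phe = np.maximum(sol.y[3], 0.0)
    mu_met = np.array([growth_rate("metA", c, params, r)
                       for c, r in zip(M0, res_met)])
    mu_phe = np.array([growth_rate("pheA", c, params, r)
                       for c, r in zip(Fk, res_phe)])
    return CommunityTrajectory(
        times=sol.t,
        biomass_metA=sol.y[0], biomass_pheA=sol.y[1],
        mu_metA=mu_met, mu_pheA=mu_phe,
        M_chamber_metA=M0, F_chamber_pheA=Fk,
        channel_length_um=geometry.channel_length_um,
    )


def scenario_parameters(params: AuxotrophParameters, scenario: str) -> AuxotrophParameters:
    """Set the main-channel amino-acid concentrations for a named medium.

    ``all_aa`` supplies saturating M and F (1x), ``no_M_no_F`` none,
    ``plus_M_no_F`` rescues dMetA only, ``trace_aa`` supplies a few percent of
    1x of both.
    """
    if scenario == "all_aa":
        return replace(params, external_M=M_1X_MM, external_F=F_1X_MM)
    if scenario == "no_M_no_F":
        return replace(params, external_M=0.0, external_F=0.0)
    if scenario == "plus_M_no_F":
        return replace(params, external_M=M_1X_MM, external_F=0.0)
    if scenario == "trace_aa":
        return replace(params, external_M=0.02 * M_1X_MM, external_F=0.02 * F_1X_MM)
    raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def scenario_initial(geometry: LatticeGeometry, scenario: str,
                     biomass: float = 30.0) -> CommunityState:
    """Initial community state for a scenario, including pre-culture reserves.

    The full-rescue pre-culture (dMetA fed, dPheA briefly fed F) loads
    dPheA's internal pool, which drives the distance-independent first growth
    phase after the downshift; the other scenarios start with depleted pools.
    """
    n = geometry.n_compartments
    reserve_phe = 0.8 if scenario == "plus_M_no_F" else 0.0
    return CommunityState(biomass_metA=biomass, biomass_pheA=biomass,
                          M=np.zeros(n), F=np.zeros(n),
                          reserve_metA=0.0, reserve_pheA=reserve_phe)


def predicted_doubling_times(params: AuxotrophParameters,
                             distances_um: Sequence[float], scenario: str,
                             t_end: float = 1500.0,
                             node_spacing_um: float = 1.0) -> dict:
    """Model doubling times per strain and distance for one medium scenario.

    Doubling time is ln 2 over the maximum simulated per-capita growth rate;
    a zero maximum is reported as ``inf`` and flagged.  Also returns the time
    at which the dilution signal of each strain peaks.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    p = scenario_parameters(params, scenario)
    out = {"scenario": scenario, "distances_um": list(distances_um),
           "doubling_time_min": {"metA": [], "pheA": []},
           "time_of_max_growth_min": {"metA": [], "pheA": []},
           "flags": []}
    for L in distances_um:
        geom = build_lattice(L, node_spacing_um)
        traj = simulate_community(p, geom, scenario_initial(geom, scenario), t_end)
        flag = None
        for strain in ("metA", "pheA"):
            mu_max, t_max = traj.max_growth(strain)
            if mu_max <= 0:
                out["doubling_time_min"][strain].append(float("inf"))
                flag = f"{strain}@{L}um: zero maximum growth"
            else:
                out["doubling_time_min"][strain].append(float(np.log(2) / mu_max))
            out["time_of_max_growth_min"][strain].append(t_max)
        out["flags"].append(flag)
    return out
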