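"""One-dimensional diffusion-degradation lattice for chamber-channel-chamber devices.

The microfluidic geometry is a pair of well-mixed growth chambers joined by a
shallow interaction channel (25-250 um long) that passes molecules but not
cells.  The channel is discretized into `node_spacing`-wide regions; each
region i obeys

    dx_i/dt = D (x_{i-1} + x_{i+1} - 2 x_i) - gamma x_i

with diffusion rate ``D`` (lattice-scaled, per minute) and linear degradation
``gamma`` (per minute).  The chambers are compartments that are much larger
than a channel node (``volume_factor`` node volumes); they exchange flux with
the adjacent end node and additionally exchange with the main flow channel at
rate ``D_leak`` toward an external concentration (zero unless the medium is
supplemented).

The same lattice carries fluorescein in dye-calibration experiments, the
quorum-sensing signal AHL in the sender/receiver circuit, and amino acids in
the cross-feeding model.

Units: time in minutes, space in micrometres, concentrations in arbitrary
units.  ``D`` relates to a continuum diffusivity ``D_cont`` (um^2/min) via
``D = D_cont / node_spacing**2`` (see :func:`lattice_diffusion_rate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LatticeGeometry",
    "DiffusibleField",
    "DiffusionResult",
    "build_lattice",
    "lattice_diffusion_rate",
    "diffusion_rhs",
    "simulate_diffusion",
    "steady_state_profile",
    "total_mass",
    "fit_decay_length",
    "geometry_from_config",
    "field_from_config",
]

CANONICAL_CHANNEL_LENGTHS = (25.0, 50.0, 100.0, 250.0)


@dataclass(frozen=True)
class LatticeGeometry:
    """Discretized chamber-channel-chamber domain.

    Parameters
    ----------
    channel_length_um:
        Interaction-channel length; must be an integer multiple of
        ``node_spacing_um``.
    node_spacing_um:
        Width of one discretization region (default 1 um).
    source_volume_factor, sink_volume_factor:
        Chamber volume expressed in channel-node volumes.  The growth chambers
        (10 x 50 x 1 um) are far larger than a sub-micron-tall channel node,
        so the default is 100.
    with_chambers:
        If False the lattice is a bare channel with reflective ends (used for
        stencil-level tests and pure-channel profiles).
    """

    channel_length_um: float
    node_spacing_um: float = 1.0
    source_volume_factor: float = 100.0
    sink_volume_factor: float = 100.0
    with_chambers: bool = True

    def __post_init__(self) -> None:
        if self.node_spacing_um <= 0:
            raise ValueError("node_spacing_um must be positive")
        n = self.channel_length_um / self.node_spacing_um
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                "channel_length_um must be a positive integer multiple of "
                f"node_spacing_um (got {self.channel_length_um}/{self.node_spacing_um})"
            )
        if self.source_volume_factor <= 0 or self.sink_volume_factor <= 0:
            raise ValueError("chamber volume factors must be positive")

    @property
    def n_nodes(self) -> int:
        """Number of interior channel nodes."""
        return int(round(self.channel_length_um / self.node_spacing_um))

    @property
    def n_compartments(self) -> int:
        """Total state length: interior nodes plus the two chambers (if any)."""
        return self.n_nodes + (2 if self.with_chambers else 0)

    @property
    def volumes(self) -> np.ndarray:
        """Per-compartment volume weights in node-volume units."""
        v = np.ones(self.n_compartments)
        if self.with_chambers:
            v[0] = self.source_volume_factor
            v[-1] = self.sink_volume_factor
        return v

    def positions_um(self) -> np.ndarray:
        """Node-centre coordinates; chambers sit just outside the channel."""
        dx = self.node_spacing_um
        nodes = (np.arange(self.n_nodes) + 0.5) * dx
        if not self.with_chambers:
            return nodes
        return np.concatenate(([-0.5 * dx], nodes, [self.channel_length_um + 0.5 * dx]))


@dataclass
class DiffusibleField:
    """A concentration profile on a lattice plus its transport constants.

    ``D`` is the lattice-scaled diffusion rate (per min), ``gamma`` the linear
    degradation rate (per min, applied everywhere), and ``D_leak`` the
    chamber-to-main-channel exchange rate (per min; chambers relax toward
    ``external`` at this rate).
    """

    concentrations: np.ndarray
    D: float
    gamma: float = 0.0
    D_leak: float = 0.0
    external: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.D < 0 or self.gamma < 0 or self.D_leak < 0:
            raise ValueError("D, gamma and D_leak must be non-negative")


def build_lattice(channel_length_um: float, node_spacing_um: float = 1.0,
                  **kwargs) -> LatticeGeometry:
    """Build the chamber-channel-chamber geometry for one separation distance."""
    return LatticeGeometry(channel_length_um, node_spacing_um, **kwargs)


def lattice_diffusion_rate(D_cont_um2_per_min: float, node_spacing_um: float) -> float:
    """Convert a continuum diffusivity (um^2/min) to the lattice rate (per min)."""
    return D_cont_um2_per_min / node_spacing_um**2


def diffusion_rhs(field: DiffusibleField, geometry: LatticeGeometry,
                  x: np.ndarray | None = None,
                  source_production: float = 0.0,
                  sink_production: float = 0.0) -> np.ndarray:
    """Time derivatives of every compartment.

    Interior nodes follow the three-point stencil with degradation; chamber
    compartments exchange volume-scaled flux with their end node, relax toward
    the external (main-channel) concentration at ``D_leak``, degrade at
    ``gamma``, and may receive a production flux (e.g. AHL synthesis or amino
    acid release by the resident strain).
    """
    if x is None:
        x = field.concentrations
    x = np.asarray(x, dtype=float)
    if x.shape != (geometry.n_compartments,):
        raise ValueError(
            f"concentration vector length {x.shape} does not match geometry "
            f"({geometry.n_compartments} compartments)"
        )
    D, gamma, D_leak = field.D, field.gamma, field.D_leak
    dx = np.empty_like(x)
    if geometry.with_chambers:
        nodes = x[1:-1]
        left = np.concatenate(([x[0]], nodes[:-1]))
        right = np.concatenate((nodes[1:], [x[-1]]))
        dx[1:-1] = D * (left + right - 2.0 * nodes) - gamma * nodes
        v_s = geometry.source_volume_factor
        v_k = geometry.sink_volume_factor
        dx[0] = (-D * (x[0] - x[1]) / v_s
                 + D_leak * (field.external - x[0])
                 - gamma * x[0] + source_production / v_s)
        dx[-1] = (-D * (x[-1] - x[-2]) / v_k
                  + D_leak * (field.external - x[-1])
                  - gamma * x[-1] + sink_production / v_k)
    else:
        left = np.concatenate(([x[0]], x[:-1]))     # reflective ends
        right = np.concatenate((x[1:], [x[-1]]))
        dx[:] = D * (left + right - 2.0 * x) - gamma * x
    return dx


def total_mass(x: np.ndarray, geometry: LatticeGeometry) -> float:
    """Volume-weighted total amount on the lattice."""
    return float(np.dot(geometry.volumes, np.asarray(x, dtype=float)))


@dataclass
class DiffusionResult:
    """Time-indexed concentration profiles from :func:`simulate_diffusion`."""

    times: np.ndarray
    profiles: np.ndarray          # shape (n_times, n_compartments)
    geometry: LatticeGeometry

    def to_frame(self):
        """Tidy long table: time_min, position_um, compartment, concentration."""
        import pandas as pd

        pos = self.geometry.positions_um()
        labels = [f"node_{i}" for i in range(self.geometry.n_nodes)]
        if self.geometry.with_chambers:
            labels = ["source"] + labels + ["sink"]
        rows = []
        for t, prof in zip(self.times, self.profiles):
            for p, lab, c in zip(pos, labels, prof):
                rows.append((t, p, lab, c))
        return pd.DataFrame(rows, columns=["time_min", "position_um",
                                           "compartment", "concentration"])


def simulate_diffusion(field: DiffusibleField, geometry: LatticeGeometry,
                       source_schedule: Callable[[float], float] | float | None,
                       t_end: float,
                       t_eval: Sequence[float] | None = None,
                       switch_times: Sequence[float] = (),
                       rtol: float = 1e-6, atol: float = 1e-9) -> DiffusionResult:
    """Integrate the lattice ODEs with the source chamber clamped per schedule.

    ``source_schedule`` maps time to the clamped source concentration; a bare
    float means a constant clamp, ``None`` (or a schedule returning ``nan``)
    leaves the source free (closed ends).  ``switch_times`` lists schedule
    discontinuities so the stiff integrator restarts cleanly at each one.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if callable(source_schedule):
        sched = source_schedule
    elif source_schedule is None:
        sched = lambda t: np.nan
    else:
        val = float(source_schedule)
        sched = lambda t: val

    def rhs(t, y):
        s = sched(t)
        clamped = np.isfinite(s)
        if clamped:
            y = y.copy()
            y[0] = s
        dy = diffusion_rhs(field, geometry, y)
        if clamped:
            dy[0] = 0.0
        return dy

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    breaks = np.concatenate(([0.0], np.sort(np.asarray(switch_times, float)), [t_end]))
    breaks = np.unique(breaks[(breaks >= 0.0) & (breaks <= t_end)])

    y0 = field.concentrations.astype(float).copy()
    s0 = sched(0.0)
    if np.isfinite(s0):
        y0[0] = s0
    times_out, profs_out = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        if seg_eval.size == 0 or seg_eval[-1] < b:
            seg_eval = np.append(seg_eval, b)
        sol = solve_ivp(rhs, (a, b), y0, method="LSODA", t_eval=seg_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"diffusion integration failed: {sol.message}")
        y0 = sol.y[:, -1].copy()
        s_b = sched(b + 1e-9)
        if np.isfinite(s_b):
            y0[0] = s_b
        keep = np.isin(sol.t, t_eval)
        for t, col in zip(sol.t[keep], sol.y[:, keep].T):
            if times_out and t == times_out[-1]:
                continue
            s = sched(t)
            col = col.copy()
            if np.isfinite(s):
                col[0] = s
            times_out.append(t)
            profs_out.append(col)
    return DiffusionResult(np.asarray(times_out), np.asarray(profs_out), geometry)


def steady_state_profile(field: DiffusibleField, geometry: LatticeGeometry,
                         source_value: float,
                         sink: str = "chamber") -> np.ndarray:
    """Steady concentrations with the source chamber clamped at ``source_value``.

    ``sink`` selects the far-end boundary: ``"chamber"`` (well-mixed
    compartment with its leak and degradation losses, the device geometry),
    ``"absorbing"`` (clamped to zero), or ``"reflective"`` (zero flux, no sink
    compartment losses).
    """
    if source_value < 0:
        raise ValueError("source_value must be non-negative")
    if not geometry.with_chambers:
        raise ValueError("steady_state_profile requires chamber geometry")
    n = geometry.n_nodes
    D, gamma, D_leak = field.D, field.gamma, field.D_leak
    # unknowns: nodes 0..n-1 plus (optionally) the sink chamber
    has_sink_var = sink == "chamber"
    m = n + (1 if has_sink_var else 0)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for i in range(n):
        A[i, i] = -2.0 * D - gamma
        if i > 0:
            A[i, i - 1] = D
        else:
            b[i] -= D * source_value
        if i < n - 1:
            A[i, i + 1] = D
        elif has_sink_var:
            A[i, n] = D
        elif sink == "absorbing":
            pass                              # neighbour fixed at 0
        elif sink == "reflective":
            A[i, i] += D                      # mirror the last node
        else:
            raise ValueError(f"unknown sink mode {sink!r}")
    if has_sink_var:
        v_k = geometry.sink_volume_factor
        A[n, n] = -D / v_k - D_leak - gamma
        A[n, n - 1] = D / v_k
        b[n] = -D_leak * field.external
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"steady-state system singular: {exc}") from exc
    full = np.empty(geometry.n_compartments)
    full[0] = source_value
    full[1:n + 1] = x[:n]
    full[-1] = x[n] if has_sink_var else (0.0 if sink == "absorbing" else x[n - 1])
    return full


def fit_decay_length(positions_um: np.ndarray, values: np.ndarray) -> float:
    """Exponential decay length (um) of a positive, decaying profile.

    Least-squares line through log(values) vs position; the decay length is
    the negative reciprocal slope.  In the continuum limit the lattice steady
    profile decays with length ``sqrt(D_cont / gamma)``.
    """
    positions_um = np.asarray(positions_um, float)
    values = np.asarray(values, float)
    mask = values > 0
    if mask.sum() < 2:
        raise ValueError("need at least two positive values to fit a decay length")
    slope = np.polyfit(positions_um[mask], np.log(values[mask]), 1)[0]
    if slope >= 0:
        raise ValueError("profile does not decay")
    return -1.0 / slope


def geometry_from_config(cfg: dict) -> LatticeGeometry:
    """Build a geometry from a config mapping (keys per the docs schema)."""
    return LatticeGeometry(
        channel_length_um=float(cfg["channel_length_um"]),
        node_spacing_um=float(cfg.get("node_spacing_um", 1.0)),
        source_volume_factor=float(cfg.get("source_volume_factor", 100.0)),
        sink_volume_factor=float(cfg.get("sink_volume_factor", 100.0)),
    )


def field_from_config(cfg: dict, geometry: LatticeGeometry) -> DiffusibleField:
    """Build a zero-initialized field from a config mapping."""
    return DiffusibleField(
        concentrations=np.zeros(geometry.n_compartments),
        D=float(cfg["D"]),
        gamma=float(cfg.get("gamma", 0.0)),
        D_leak=float(cfg.get("D_leak", 0.0)),
        external=float(cfg.get("external", 0.0)),
    )
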