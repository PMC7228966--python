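"""Synthetic chamber experiments with the statistical structure of the device.

Every analysis input the package consumes can be generated here: step and
square-wave induction of sender/receiver pairs at the four canonical
separations, growth-dilution decay of stable reporters after inducer removal
(driven by the cross-feeding model), replicate-to-replicate variability,
measurement noise, corrupted (outlier) chambers, and single-cell area tracks
with a planted growth/partner-abundance association.

Noise model: each chamber carries a multiplicative lognormal scale factor
(replicate variability) and every sample an additive Gaussian read error.
Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Sequence

import numpy as np

from chamberlink import circuit as circ
from chamberlink import crossfeeding as cf
from chamberlink.lattice import build_lattice
from chamberlink.metrics import ChamberTrace

__all__ = [
    "ExperimentSpec",
    "generate_step_experiment",
    "generate_oscillation_experiment",
    "generate_dilution_experiment",
    "generate_dilution_calibration_traces",
    "generate_single_cell_tracks",
    "inject_outliers",
]

CANONICAL_DISTANCES = (25.0, 50.0, 100.0, 250.0)


@dataclass
class ExperimentSpec:
    """Layout and noise settings for one synthetic experiment.

    Defaults follow the device conventions: ten biological replicates per
    interaction-channel length, 7-min sampling for quorum-sensing reporters
    and 10-min for auxotroph dilution runs (set ``sampling_interval_min``
    accordingly).
    """

    kind: str = "step"            # step | forced_oscillation | auxotroph_dilution | mixed_single_cell
    distances_um: tuple[float, ...] = CANONICAL_DISTANCES
    replicates: int = 10
    sampling_interval_min: float = 7.0
    duration_min: float = 700.0
    media_switch_min: float = 105.0
    input_period_min: float = 120.0
    ara_amplitude: float = 0.1    # % arabinose
    chamber_scale_sigma: float = 0.1     # lognormal replicate effect
    rate_jitter_sigma: float = 0.05      # lognormal per-chamber growth-rate effect
    read_noise_sd: float = 0.01          # additive, in max-normalized units
    phase_jitter_sd_min: float = 0.0
    background: float = 0.0
    node_spacing_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def time_grid(self) -> np.ndarray:
        n = int(self.duration_min // self.sampling_interval_min) + 1
        return np.arange(n) * self.sampling_interval_min

    def provenance(self) -> dict:
        return asdict(self)


def _noisy_replicates(spec: ExperimentSpec, rng: np.random.Generator,
                      model_values: np.ndarray) -> np.ndarray:
    """Stack of replicate traces: lognormal chamber scale + Gaussian read noise."""
    scale_ref = max(float(np.max(np.abs(model_values))), 1e-12)
    out = np.empty((spec.replicates, model_values.size))
    for r in range(spec.replicates):
        scale = rng.lognormal(mean=0.0, sigma=spec.chamber_scale_sigma)
        noise = rng.normal(0.0, spec.read_noise_sd * scale_ref, model_values.size)
        out[r] = model_values * scale + noise
    return out


def generate_step_experiment(spec: ExperimentSpec,
                             params: circ.CircuitParameters | None = None
                             ) -> list[ChamberTrace]:
    """Step-induction sender/receiver traces (GFP and RFP per chamber pair)."""
    params = params or circ.CircuitParameters()
    rng = spec.rng()
    t = spec.time_grid()
    signal = circ.InputSignal("step", spec.ara_amplitude,
                              onset_min=spec.media_switch_min)
    traces: list[ChamberTrace] = []
    for L in spec.distances_um:
        geom = build_lattice(L, spec.node_spacing_um)
        traj = circ.simulate_circuit(params, geom, signal, spec.duration_min,
                                     t_eval=t)
        for reporter, values in (("GFP", traj.GFP_p), ("RFP", traj.RFP_p)):
            reps = _noisy_replicates(spec, rng, values + spec.background)
            for r in range(spec.replicates):
                traces.append(ChamberTrace(
                    time_min=t, values=reps[r],
                    chamber_id=f"{reporter}_{int(L)}um_r{r}",
                    channel_length_um=L, reporter=reporter, replicate=r))
    return traces


def generate_oscillation_experiment(spec: ExperimentSpec,
                                    params: circ.CircuitParameters | None = None
                                    ) -> list[ChamberTrace]:
    """Square-wave-forced sender/receiver traces with optional phase jitter."""
    params = params or circ.CircuitParameters()
    rng = spec.rng()
    t = spec.time_grid()
    signal = circ.InputSignal("square_wave", spec.ara_amplitude,
                              period_min=spec.input_period_min,
                              onset_min=spec.media_switch_min)
    traces: list[ChamberTrace] = []
    for L in spec.distances_um:
        geom = build_lattice(L, spec.node_spacing_um)
        traj = circ.simulate_circuit(params, geom, signal, spec.duration_min,
                                     t_eval=t)
        for reporter, values in (("GFP", traj.GFP_p), ("RFP", traj.RFP_p)):
            for r in range(spec.replicates):
                if spec.phase_jitter_sd_min > 0:
                    shift = rng.normal(0.0, spec.phase_jitter_sd_min)
                    v = np.interp(t - shift, t, values)
                else:
                    v = values
                scale = rng.lognormal(0.0, spec.chamber_scale_sigma)
                ref = max(float(np.max(np.abs(values))), 1e-12)
                noise = rng.normal(0.0, spec.read_noise_sd * ref, t.size)
                traces.append(ChamberTrace(
                    time_min=t, values=v * scale + noise + spec.background,
                    chamber_id=f"{reporter}_{int(L)}um_r{r}",
                    channel_length_um=L, reporter=reporter, replicate=r))
    return traces


def generate_dilution_experiment(spec: ExperimentSpec,
                                 params: cf.AuxotrophParameters | None = None,
                                 scenario: str = "no_M_no_F",
                                 F0: float = 1.0) -> list[ChamberTrace]:
    """Reporter-dilution traces for the spatially separated auxotrophs.

    Before the media switch the induced reporter sits at its plateau; after
    the switch it decays as F0 * exp(-integral of the strain's growth rate),
    with the growth trajectory supplied by the cross-feeding model for the
    given medium scenario.  dMetA carries GFP, dPheA carries RFP.  Each
    replicate chamber's growth rate is scaled by a lognormal factor
    (``rate_jitter_sigma``), the biological replicate-to-replicate
    variability, on top of the optical scale factor and read noise.
    """
    params = params or cf.AuxotrophParameters()
    p = cf.scenario_parameters(params, scenario)
    rng = spec.rng()
    t = spec.time_grid()
    post = t >= spec.media_switch_min
    t_post = t[post] - spec.media_switch_min
    traces: list[ChamberTrace] = []
    for L in spec.distances_um:
        geom = build_lattice(L, spec.node_spacing_um)
        init = cf.scenario_initial(geom, scenario)
        horizon = max(float(t_post[-1]), 1.0)
        traj = cf.simulate_community(p, geom, init, horizon)
        for strain, reporter, mu in (("metA", "GFP", traj.mu_metA),
                                     ("pheA", "RFP", traj.mu_pheA)):
            mu_t = np.interp(t_post, traj.times, mu)
            integral = np.concatenate(([0.0], np.cumsum(
                0.5 * (mu_t[1:] + mu_t[:-1]) * np.diff(t_post))))
            for r in range(spec.replicates):
                rate_mult = rng.lognormal(0.0, spec.rate_jitter_sigma) \
                    if spec.rate_jitter_sigma > 0 else 1.0
                model = np.full(t.size, F0)
                model[post] = F0 * np.exp(-rate_mult * integral)
                model += spec.background
                scale = rng.lognormal(0.0, spec.chamber_scale_sigma)
                noise = rng.normal(0.0, spec.read_noise_sd * F0, t.size)
                traces.append(ChamberTrace(
                    time_min=t, values=model * scale + noise,
                    chamber_id=f"{strain}_{int(L)}um_r{r}",
                    channel_length_um=L, reporter=reporter, replicate=r,
                    strain=strain))
    return traces


def generate_dilution_calibration_traces(doubling_time_min: float,
                                         replicates: int = 5,
                                         duration_min: float = 1500.0,
                                         sampling_interval_min: float = 10.0,
                                         media_switch_min: float = 105.0,
                                         floor: float = 0.02,
                                         chamber_scale_sigma: float = 0.02,
                                         read_noise_sd: float = 5e-4,
                                         seed: int = 0) -> list[ChamberTrace]:
    """Calibration traces whose maximum dilution rate is known exactly.

    The trace holds a plateau until the media switch, then declines linearly
    at the generating rate ln(2)/doubling_time until it reaches ``floor``.
    A sustained linear segment is the shape on which a windowed straight-line
    slope is an exact estimator, so these traces give the growth-inference
    round trip a well-defined ground truth: the generating doubling time is
    ln(2) divided by the trace's maximum dilution rate.  (A pure exponential
    decay is *not* recoverable by any windowed linear slope: sustaining a
    slope of ln(2)/T for a w-minute window requires the max-normalized trace
    to drop by w·ln(2)/T, which exceeds its full range for short T.)
    """
    if doubling_time_min <= 0:
        raise ValueError("doubling time must be positive")
    rng = np.random.default_rng(seed)
    rate = np.log(2.0) / doubling_time_min
    t = np.arange(int(duration_min // sampling_interval_min) + 1) \
        * sampling_interval_min
    model = np.clip(1.0 - rate * (t - media_switch_min), floor, 1.0)
    traces = []
    for r in range(replicates):
        scale = rng.lognormal(0.0, chamber_scale_sigma)
        noise = rng.normal(0.0, read_noise_sd, t.size)
        traces.append(ChamberTrace(
            time_min=t, values=model * scale + noise,
            chamber_id=f"calib_{int(doubling_time_min)}min_r{r}",
            channel_length_um=25.0, reporter="GFP", replicate=r))
    return traces


def generate_single_cell_tracks(n_chambers: int = 10, n_cells: int = 12,
                                duration_min: float = 400.0,
                                sampling_interval_min: float = 10.0,
                                base_rate_per_min: float = 0.004,
                                rate_sd: float = 0.001,
                                association_strength: float = 0.0,
                                short_track_fraction: float = 0.2,
                                seed: int = 0) -> dict:
    """Per-cell area tracks plus partner-occupancy fractions.

    Each cell grows exponentially at a rate drawn around ``base_rate`` plus
    ``association_strength`` times its chamber's partner-occupancy fraction
    (the planted correlation); a fraction of tracks is cut shorter than the
    100-min analysis window to exercise downstream filtering.
    """
    rng = np.random.default_rng(seed)
    t_full = np.arange(int(duration_min // sampling_interval_min) + 1) \
        * sampling_interval_min
    occupancy = rng.uniform(0.1, 0.9, size=n_chambers)
    tracks = []
    for ch in range(n_chambers):
        for c in range(n_cells):
            rate = (base_rate_per_min
                    + association_strength * (occupancy[ch] - occupancy.mean())
                    + rng.normal(0.0, rate_sd))
            short = rng.random() < short_track_fraction
            n_keep = rng.integers(2, 10) if short else t_full.size
            t = t_full[:n_keep]
            area = 100.0 * np.exp(rate * t) * rng.lognormal(0.0, 0.02, t.size)
            tracks.append({"cell_id": f"ch{ch}_c{c}", "chamber_id": f"ch{ch}",
                           "time_min": t, "area": area,
                           "true_rate": rate, "short": bool(short)})
    return {"tracks": tracks,
            "occupancy": {f"ch{ch}": float(occupancy[ch]) for ch in range(n_chambers)},
            "seed": seed}


def inject_outliers(traces: Sequence[ChamberTrace], n_outliers: int,
                    mode: str = "level_drop", severity: float = 0.2,
                    seed: int = 0) -> tuple[list[ChamberTrace], list[str]]:
    """Corrupt a subset of chambers and return truth labels.

    ``level_drop`` emulates sudden loss of cells: from a random interior time
    the signal collapses to ``severity`` of its current level and stays flat,
    since with the cells gone the dilution dynamics end and only residual
    background remains.  ``spikes`` emulates transient segmentation failures
    (several isolated large excursions).  The returned labels list the
    corrupted chamber ids.
    """
    if n_outliers >= len(traces):
        raise ValueError("n_outliers must be smaller than the trace set")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(traces), size=n_outliers, replace=False)
    out: list[ChamberTrace] = []
    labels: list[str] = []
    for i, tr in enumerate(traces):
        v = tr.values.copy()
        if i in picks:
            labels.append(tr.chamber_id)
            n = v.size
            if mode == "level_drop":
                k = rng.integers(n // 4, 3 * n // 4)
                v[k:] = severity * v[k]
            elif mode == "spikes":
                idx = rng.choice(np.arange(2, n - 2), size=4, replace=False)
                v[idx] += 5.0 * max(np.ptp(v), np.max(np.abs(v)), 1e-9)
            else:
                raise ValueError(f"unknown corruption mode {mode!r}")
        out.append(ChamberTrace(tr.time_min.copy(), v, tr.chamber_id,
                                tr.channel_length_um, tr.reporter,
                                tr.replicate, tr.strain))
    return out, labels
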