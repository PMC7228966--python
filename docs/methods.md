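# Methods

This document records the model equations, default parameters and analysis
conventions implemented in `chamberlink`. Units are minutes, micrometres
and arbitrary concentration/fluorescence units unless stated otherwise.

## 1. Reaction–diffusion lattice (`chamberlink.lattice`)

The device geometry is a pair of well-mixed growth chambers joined by a
thin channel of length `L` (25–250 µm). The channel is discretized into
`n = L / dx` nodes (`dx = node_spacing_um`, default 1 µm); the chambers are
appended as compartments 0 and `n + 1` with volume factors
`source_volume_factor = sink_volume_factor = 100` in node-volume units, so
chamber concentrations respond slowly relative to channel nodes.

Transport uses the standard three-point stencil. For interior node `i`:

```
dx_i/dt = D (x_{i-1} - 2 x_i + x_{i+1}) - γ x_i + production_i
```

with the lattice hopping rate `D = D_cont / dx²` (`lattice_diffusion_rate`).
Chambers exchange with their adjacent node divided by their volume factor
and additionally leak to an external reservoir with rate `D_leak`:

```
V dx_0/dt = D (x_1 - x_0) - V γ x_0 - V D_leak (x_0 - external) + production
```

Properties used for validation:

* **Mass conservation** — with `γ = D_leak = 0` the stencil is an exact
  divergence, so the volume-weighted total `Σ V_i x_i` is conserved to
  integrator tolerance (verified to < 1e-8 relative on a 250-node lattice).
* **Decay length** — with first-order loss `γ`, the steady profile decays
  as `exp(-x/λ)` with `λ = sqrt(D_cont / γ)` in the continuum limit. On a
  finite channel with an absorbing end the profile is sinh-shaped; the
  exponential fit must therefore be restricted to the region at least ~one
  decay length away from the absorbing boundary.

Time integration uses `scipy.integrate.solve_ivp` (BDF with a sparse
Jacobian pattern for stiff coupled systems; default tolerances
`rtol=1e-6, atol=1e-9`).

## 2. Sender/receiver quorum-sensing circuit (`chamberlink.circuit`)

The sender chamber expresses GFP and LuxI from an arabinose-inducible
promoter; LuxI synthesizes AHL, which diffuses down the channel; the
receiver chamber expresses RFP from a LuxR/AHL-activated promoter.
Transcription is a Hill function `α Aⁿ / (Kⁿ + Aⁿ)`; each
transcription-factor input acts through a **linear delay chain**: `N`
first-order stages with rate `a`,

```
ds_1/dt = a (u - s_1),   ds_k/dt = a (s_{k-1} - s_k)
```

whose impulse response is exactly the Erlang(N, a) density with mean delay
`N/a` (validated to < 1e-3 L¹ distance for N ∈ {1, 5, 20}).

Species per compartment: mRNA (degradation `γ_m`), protein (dilution
`γ_p = ln 2 / 30`), AHL on the lattice (degradation `γ_AHL`, chamber leak
`D2`), and receiver LuxR·AHL binding treated at quasi-equilibrium
(`activated_receptor`).

Default parameters (`CircuitParameters`):

| parameter | default | meaning |
|---|---|---|
| `alpha_GFP, alpha_LuxI, alpha_RFP` | 10 | max transcription rates |
| `K_ara, n_ara` | 0.05, 2 | arabinose promoter Hill |
| `K_LuxR, n_LuxR` | 150, 1 | LuxR·AHL binding |
| `K_RFP, n_RFP` | 100, 2 | receiver promoter Hill |
| `LuxR_tot` | 100 | total receptor |
| `k_AHL` | 0.5 | AHL synthesis per LuxI protein |
| `k_tl` | 1 | translation rate |
| `gamma_m, gamma_p, gamma_AHL` | 0.1, 0.0231, 0.3 | degradation/dilution (min⁻¹) |
| `D1` | 20000 | AHL lattice diffusion (µm² min⁻¹ at dx=1) |
| `D2` | 0.2 | chamber-to-exterior AHL leak |
| `delay_ara` | Erlang(3, 0.3) | induction delay (~10 min) |
| `delay_GFP/LuxI/RFP` | Erlang(5, 0.5) | maturation/expression delays |

Under constant induction the fixed point solves semi-analytically: the
sender block is linear given the promoter activity, the AHL lattice is a
linear system given LuxI, and the receiver is algebraic given the receiver
AHL (`steady_state_response`, one `numpy.linalg.solve`). Dynamic
simulations converge to this fixed point, which is used for:

* `distance_sensitivity` — ratio of steady RFP at 25 µm vs 250 µm;
* `transmission_distance` — separation at which steady RFP falls to a
  threshold fraction (default 1 %) of a 2-µm near-contact reference, found
  by bisection;
* `response_time` — minutes from an input switch to 50 % of the net
  steady-state change, defined only for settled trajectories;
* `dose_response` — steady RFP versus clamped receiver AHL, bypassing
  transport (used for Hill-parameter fitting).

Square-wave forcing (`simulate_periodic_input`) reports the mean and
half peak-to-trough amplitude of the last full cycle and flags runs whose
last two cycles differ by more than 5 % in amplitude as not cyclically
steady. The channel acts as a spatial low-pass filter: amplitude is
non-increasing in input frequency and in distance.

## 3. Cross-feeding community model (`chamberlink.crossfeeding`)

Two auxotrophs grow in opposite chambers: ΔmetA (requires methionine, M)
and ΔpheA (requires phenylalanine, F). Each strain's growth rate is

```
μ = μ_basal + (μ_max − μ_basal) · s,    s = 1 − (1 − Monod(aa)) (1 − reserve)
```

where `Monod(aa) = aa / (K + aa)` on the local chamber amino-acid
concentration and `reserve ∈ [0, 1]` is an internal pool (carried over from
pre-culture in rich media) consumed at rate `k_reserve`. The combined
saturation means either external supply or the internal pool can sustain
growth.

Release is **asymmetric**: ΔmetA secretes F in proportion to its unused
growth capacity (`r_F_max (1 − μ/μ_max)`, `r_F_max = 0.2`), while ΔpheA
secretes M only in proportion to growth (`r_M_max μ/μ_max`,
`r_M_max = 2e-4`, effectively negligible). Consequently ΔpheA benefits
from a nearby ΔmetA partner but not vice versa. Amino acids diffuse on the
lattice (`D_aa = 2000`), leak to the media (`D_leak_aa = 0.6`) and are
consumed with yields `y_M = y_F = 0.5`. Biomass follows logistic crowding
with capacity 150.

Media scenarios (`SCENARIOS`): `all_aa` (both supplied), `no_M_no_F`
(neither; cross-feeding only), `plus_M_no_F` (M supplied; ΔpheA starts
with `reserve_pheA = 0.8` from supplemented pre-culture), `trace_aa`
(low external levels).

`predicted_doubling_times` reports, per strain and separation:

* **doubling time** `ln 2 / max μ̃`, where `μ̃` is the *dilution signal*
  `μ · exp(−∫ μ dt)` — the growth rate weighted the same way a decaying
  fluorescence reporter weights it, so model predictions and
  fluorescence-dilution estimates share one convention;
* **time of maximal growth** — the time at which `μ̃` peaks.

Defaults: `μ_max` = ln 2 / 80 (ΔmetA) and ln 2 / 86 (ΔpheA); basal rates
ln 2 / 1150 and ln 2 / 600; `K_M = 0.02`, `K_F = 0.04`.

## 4. Genetic-algorithm fitting (`chamberlink.gafit`)

Each generation evaluates a population of 100 parameter sets:

* the 10 best (elite) carry over unchanged, with cached objectives;
* 9 children average the best member with ranks 2–10 (arithmetic mean for
  linear-scale parameters, geometric mean for log-scale ones);
* 81 fresh members are drawn uniformly from the bounds (log-uniform for
  log-scale parameters).

An optional integer **structure gene** (e.g. a delay-chain length) is
searched alongside: fresh members draw it uniformly from its range, and
averaged children perturb the best structure by ±1 with probability 0.5.
The objective is the L² residual norm (`objective_l2`); simulator failures
are counted and scored as infinite rather than aborting the fit. Fitting
stops when the best objective improves by less than `1e-4` relative for 10
consecutive generations. All randomness flows from a single integer seed,
so fits are exactly reproducible.

## 5. Chamber-trace metrics (`chamberlink.metrics`)

**Growth from fluorescence dilution.** After induction ends, a stable
reporter is only diluted by growth, so `F(t) ≈ F₀ exp(−∫ μ dt)`. The
pipeline subtracts a constant per-reporter background, normalizes by the
trace maximum, and computes windowed least-squares slopes of `−ΔF`
(`delta_f_rate`, default 10-point windows). The reported doubling time is
`ln 2 / max(rate)`. Two intrinsic limits of this estimator:

* a 10-point window on a `[0, 1]`-normalized trace cannot report slopes
  above ≈ `1 / (9 Δt)` (≈ 0.0152 min⁻¹ at 10-min sampling), bounding the
  fastest measurable doubling time;
* on exponential segments the window average attenuates the instantaneous
  rate at the window centre, biasing fast rates downward.

The recovery round trip is therefore validated on traces whose decline is
locally linear at the generating maximum rate (plateau → linear decline at
`ln 2 / T` → floor), where windowed slopes are exact; recovery is within
5 % for doubling times 60–1200 min at 10-min sampling and low noise.

**Biphasic growth** (`biphasic_peaks`) reports the dominant rate peak in
each of two windows split at the media switch.

**Oscillations.** Traces are normalized to global min/max and smoothed
with a 20-point moving mean. `detect_peaks` enforces a minimum peak
distance and height; phase drift is the coefficient of variation of
inter-peak intervals (population-SD convention). Spectral analysis uses
Welch's method with a Hamming window; SNR is in-band power (period ± 10
min) over supra-band power. `bootstrap_snr` and `bootstrap_curves` give
percentile intervals over replicates.

**Bootstrap mean test** (`bootstrap_mean_test`): observed difference of
means against the null distribution obtained by resampling the pooled
sample; one-sided p-value `#(t* > t_obs)/B`. Calibration was verified
empirically: type-I error 0.044–0.074 across seeds (mean ≈ 0.05) at
α = 0.05 with `B = 10⁴`, 500 null pairs, `n = m = 10`.

**Outlier screen** (`modified_zscore_outliers`). For each time point the
modified z-score `0.6745 (x − median) / MAD` is computed across replicate
chambers; a chamber is excluded when it exceeds 3.5 at ≥ 2 time points.
Time points with zero MAD are skipped with a warning. Because the ≥ 2
rule presumes roughly independent time points, the pipeline applies the
screen to smoothed dilution-rate series subsampled at non-overlapping
window starts, not to raw sliding-window slopes (whose neighbouring values
are almost fully correlated). At default settings this recovers ≥ 90 % of
injected gross corruptions with well under one false exclusion per 20
clean chambers.

**Single-cell metrics.** `single_cell_growth_rate` fits exponential area
growth over a sliding window and rejects tracks that are too short;
`partner_abundance_correlation` computes per-time-point Spearman
correlations between single-cell growth rates and partner occupancy
(each input element holds values across cells at one time point; time
points with fewer than 5 valid pairs are flagged, not tested).

## 6. Interaction-network inference (`chamberlink.network`)

For a strain with mean doubling times `D25` and `D250` at 25 µm and
250 µm from its partner, the partner's effect is

```
strength = 1 − D25 / D250
```

(positive when proximity speeds growth). Edges with `|strength| ≤ 0.1`
are neutral; node display size scales as `(10 · ln(1 / D25))²`.
`network_from_doubling_times` builds the two-strain directed network with
edges partner → strain.

## 7. Synthetic experiments (`chamberlink.synth`)

Generators simulate the mechanistic models and add a chamber-level noise
model: a per-chamber lognormal scale factor (`chamber_scale_sigma`), a
per-replicate lognormal growth-rate multiplier (`rate_jitter_sigma`,
biological replicate variability), additive Gaussian read noise
(`read_noise_sd`) and optional phase jitter. All randomness derives from
an integer seed; identical specs reproduce byte-identical traces.

`inject_outliers` models two gross failure modes: `level_drop` (the trace
collapses to a flat residual background from a random time onward, e.g. a
clogged or emptied chamber) and `spikes` (isolated fluorescence
excursions). `generate_dilution_calibration_traces` produces the
plateau → linear decline → floor family used for growth round-trip
validation. `generate_single_cell_tracks` plants a controllable
association between single-cell growth rate and partner occupancy.

## 8. Pipeline (`chamberlink.pipeline`)

Tidy CSV in (`time_min, chamber_id, channel_length_um, reporter, value`
plus optional `strain`, `replicate`), tidy CSV/JSON out. `run_analysis`
dispatches on `RunConfig.analysis`:

* `growth` — outlier screen, per-chamber dilution metrics,
  per-(strain, distance) summaries, and the interaction network when two
  strains are measured at 25 µm and 250 µm;
* `oscillations` — normalized peak statistics per chamber;
* `snr` — Welch spectra and per-distance bootstrap SNR quartiles.

Every threshold, window and seed is recorded in a manifest written next
to the results, so a report is reproducible from its inputs alone.

## Limitations

* The lattice is one-dimensional; chamber geometry enters only through
  volume factors and leak rates.
* Growth inference reports the *maximum* dilution rate; it is not a full
  μ(t) reconstruction, and the windowed estimator bounds the fastest
  measurable doubling time (see §5).
* The cross-feeding model tracks two strains and two amino acids with
  quasi-static reserve pools; it is a minimal model for distance-dependent
  trends, not a metabolic reconstruction.
* Network inference uses a two-point distance contrast; it cannot separate
  direct metabolite exchange from shared-environment effects.
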