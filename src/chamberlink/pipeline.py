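"""Tidy-CSV input/output and end-to-end analysis orchestration.

Chamber traces travel as long-format CSV with columns
``time_min, chamber_id, channel_length_um, reporter, value`` (plus optional
``strain`` and ``replicate``).  ``run_analysis`` chains trace loading or
generation, outlier screening, the per-experiment metric recipes, and
network inference, and writes a machine-readable manifest (seed and every
threshold used) so any run is reproducible from its outputs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from chamberlink import metrics as mx
from chamberlink import network as net
from chamberlink.metrics import ChamberTrace

__all__ = [
    "RunConfig",
    "read_chamber_traces",
    "traces_to_frame",
    "write_traces",
    "run_analysis",
    "write_report",
    "growth_table",
    "screen_outlier_chambers",
]

REQUIRED_COLUMNS = ("time_min", "chamber_id", "channel_length_um",
                    "reporter", "value")


@dataclass
class RunConfig:
    """Thresholds and settings for one analysis run (defaults per the device
    analysis conventions)."""

    analysis: str = "growth"            # growth | oscillations | snr
    input_period_min: float = 120.0     # snr analysis
    media_switch_min: float = 0.0
    background: float = 0.0             # per-reporter constant, subtracted pre-normalization
    slope_window_points: int = mx.SLOPE_WINDOW_POINTS
    moving_mean_points: int = mx.MOVING_MEAN_POINTS
    min_peak_distance_min: float = mx.OSCILLATOR_MIN_PEAK_DISTANCE_MIN
    min_peak_height: float = mx.OSCILLATOR_MIN_PEAK_HEIGHT
    forced_min_peak_distance_min: float = mx.FORCED_MIN_PEAK_DISTANCE_MIN
    bootstrap_B: int = mx.BOOTSTRAP_B
    outlier_threshold: float = mx.OUTLIER_THRESHOLD
    neutral_band: float = net.DEFAULT_NEUTRAL_BAND
    screen_outliers: bool = True
    seed: int = 0

    def manifest(self) -> dict:
        return asdict(self)


def read_chamber_traces(path: str | Path) -> list[ChamberTrace]:
    """Load and validate a tidy trace CSV into grouped chamber traces."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing required column(s): {', '.join(missing)}")
    if df.duplicated(subset=["time_min", "chamber_id"]).any():
        raise ValueError("duplicated (time_min, chamber_id) rows")
    traces = []
    for cid, grp in df.groupby("chamber_id", sort=True):
        grp = grp.sort_values("time_min")
        lengths = grp["channel_length_um"].unique()
        if len(lengths) != 1:
            raise ValueError(f"chamber {cid!r} has inconsistent channel_length_um")
        traces.append(ChamberTrace(
            time_min=grp["time_min"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            chamber_id=str(cid),
            channel_length_um=float(lengths[0]),
            reporter=str(grp["reporter"].iloc[0]),
            replicate=int(grp["replicate"].iloc[0]) if "replicate" in grp else 0,
            strain=str(grp["strain"].iloc[0]) if "strain" in grp else None,
        ))
    return traces


def traces_to_frame(traces: Sequence[ChamberTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for t, v in zip(tr.time_min, tr.values):
            rows.append({"time_min": t, "chamber_id": tr.chamber_id,
                         "channel_length_um": tr.channel_length_um,
                         "reporter": tr.reporter, "replicate": tr.replicate,
                         "strain": tr.strain, "value": v})
    return pd.DataFrame(rows)


def write_traces(traces: Sequence[ChamberTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def _normalized_dilution(tr: ChamberTrace, background: float = 0.0) -> np.ndarray:
    """Subtract the reporter background, then divide by the trace maximum.

    The background is a known per-reporter constant (default 0), not the
    trace minimum: subtracting the observed floor would silently rescale the
    rate axis of slowly decaying traces whose true floor lies above zero.
    """
    v = tr.values - background
    vmax = v.max()
    if vmax <= 0:
        raise ValueError(f"chamber {tr.chamber_id}: degenerate trace after background subtraction")
    return v / vmax


def growth_table(traces: Sequence[ChamberTrace], config: RunConfig) -> pd.DataFrame:
    """Per-chamber dilution growth metrics: max rate and doubling time."""
    rows = []
    for tr in traces:
        norm = _normalized_dilution(tr, config.background)
        rates = mx.delta_f_rate(norm, tr.dt_min, config.slope_window_points)
        rows.append({"chamber_id": tr.chamber_id,
                     "channel_length_um": tr.channel_length_um,
                     "reporter": tr.reporter, "strain": tr.strain,
                     "replicate": tr.replicate,
                     "max_rate_per_min": float(np.max(rates)),
                     "doubling_time_min": mx.doubling_time(rates)})
    return pd.DataFrame(rows)


def screen_outlier_chambers(traces: Sequence[ChamberTrace],
                            config: RunConfig) -> dict:
    """Flag chambers whose dilution-rate series are robust outliers.

    The modified z-score screen runs separately within each
    (reporter, channel length) replicate group, mirroring how replicates are
    comparable in the device.  Rate series are smoothed with the standard
    moving mean and screened only at non-overlapping window starts: the
    two-time-point exclusion rule presumes roughly independent time points,
    which adjacent sliding-window slopes are not, while smoothing spreads any
    single-sample artifact across at least two non-overlapping windows so
    transient corruption stays detectable.
    """
    excluded: list[str] = []
    details = {}
    groups: dict[tuple, list[ChamberTrace]] = {}
    for tr in traces:
        groups.setdefault((tr.reporter, tr.channel_length_um), []).append(tr)
    for key, grp in sorted(groups.items()):
        if len(grp) < 3:
            continue
        stride = max(config.slope_window_points, 1)
        rates = np.stack([
            mx.moving_mean(
                mx.delta_f_rate(_normalized_dilution(tr, config.background),
                                tr.dt_min, config.slope_window_points),
                config.moving_mean_points)[::stride]
            for tr in grp])
        res = mx.modified_zscore_outliers(rates, [tr.chamber_id for tr in grp],
                                          threshold=config.outlier_threshold)
        excluded.extend(res["excluded"])
        details[f"{key[0]}_{key[1]}um"] = res
    return {"excluded": sorted(excluded), "groups": details}


def run_analysis(traces: Sequence[ChamberTrace], config: RunConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Run the configured analysis over a trace set.

    ``growth``: outlier screen, then per-chamber dilution metrics and
    per-(strain, distance) mean doubling times plus the inferred two-strain
    interaction network when two strains are present.
    ``oscillations``: normalized peak statistics per chamber.
    ``snr``: Welch spectra and per-distance bootstrap SNR distributions.
    Writes tidy CSV/JSON plus a manifest when ``out_dir`` is given.
    """
    results: dict = {"manifest": config.manifest()}
    traces = list(traces)

    if config.analysis == "growth":
        if config.screen_outliers:
            screen = screen_outlier_chambers(traces, config)
            results["outliers"] = screen
            dropped = set(screen["excluded"])
            traces = [t for t in traces if t.chamber_id not in dropped]
        if not traces:
            raise ValueError("no chambers left to analyse after outlier screening")
        table = growth_table(traces, config)
        results["growth"] = table
        group_cols = ["strain", "channel_length_um"] \
            if table["strain"].notna().all() and (table["strain"] != "None").all() \
            else ["reporter", "channel_length_um"]
        summary = (table.groupby(group_cols)["doubling_time_min"]
                   .mean().reset_index())
        results["summary"] = summary
        strains = sorted(s for s in summary[group_cols[0]].unique() if s)
        if len(strains) == 2:
            stats = {}
            for s in strains:
                sub = summary[summary[group_cols[0]] == s]
                stats[s] = dict(zip(sub["channel_length_um"],
                                    sub["doubling_time_min"]))
            if all(25.0 in v and 250.0 in v for v in stats.values()):
                results["network"] = net.network_from_doubling_times(
                    stats, neutral_band=config.neutral_band)

    elif config.analysis == "oscillations":
        rows = []
        by_reporter: dict[str, list[ChamberTrace]] = {}
        for tr in traces:
            by_reporter.setdefault(tr.reporter, []).append(tr)
        for rep, grp in sorted(by_reporter.items()):
            gmin, gmax = mx.global_normalization_constants([t.values for t in grp])
            for tr in grp:
                norm = mx.normalize_oscillator_trace(
                    tr.values, gmin, gmax, smooth_points=config.moving_mean_points)
                after = tr.time_min >= config.media_switch_min
                summ = mx.detect_peaks(norm[after], tr.dt_min,
                                       config.min_peak_distance_min,
                                       config.min_peak_height)
                rows.append({"chamber_id": tr.chamber_id, "reporter": rep,
                             "channel_length_um": tr.channel_length_um,
                             "n_peaks": summ.n_peaks,
                             "interpeak_cv": summ.interpeak_cv,
                             "mean_peak_height": float(np.mean(summ.peak_amplitudes))
                             if summ.n_peaks else float("nan")})
        results["oscillations"] = pd.DataFrame(rows)

    elif config.analysis == "snr":
        rng = np.random.default_rng(config.seed)
        rows = []
        groups: dict[tuple, list[ChamberTrace]] = {}
        for tr in traces:
            groups.setdefault((tr.reporter, tr.channel_length_um), []).append(tr)
        for (rep, L), grp in sorted(groups.items()):
            spectra = []
            for tr in grp:
                sp = mx.welch_spectrum(tr.values, tr.dt_min,
                                       detrend_points=config.moving_mean_points)
                sp.band_from_period(config.input_period_min)
                spectra.append(sp)
            dist = mx.bootstrap_snr(spectra, B=config.bootstrap_B, rng=rng)
            rows.append({"reporter": rep, "channel_length_um": L,
                         "snr_median": float(np.median(dist)),
                         "snr_q25": float(np.percentile(dist, 25)),
                         "snr_q75": float(np.percentile(dist, 75))})
        results["snr"] = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown analysis {config.analysis!r}")

    if out_dir is not None:
        write_report(results, out_dir)
    return results


def write_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write tables as CSV and everything else as JSON; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    payload = {}
    for key, val in results.items():
        if isinstance(val, pd.DataFrame):
            p = out / f"{key}.csv"
            val.to_csv(p, index=False)
            written.append(p)
        elif isinstance(val, net.InteractionNetwork):
            p = out / f"{key}.json"
            p.write_text(val.to_json())
            written.append(p)
        else:
            payload[key] = val
    p = out / "report.json"
    p.write_text(json.dumps(payload, indent=2, default=_jsonable))
    written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
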