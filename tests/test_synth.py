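"""Synthetic-experiment generators: determinism, noise model, corruption."""

import numpy as np
import pytest

from chamberlink import synth
from chamberlink import metrics as mx


def small_spec(**kw):
    base = dict(kind="step", distances_um=(25.0, 250.0), replicates=3,
                sampling_interval_min=7.0, duration_min=350.0,
                media_switch_min=35.0, seed=5)
    base.update(kw)
    return synth.ExperimentSpec(**base)


def test_spec_validation():
    with pytest.raises(ValueError):
        synth.ExperimentSpec(replicates=0)
    with pytest.raises(ValueError):
        synth.ExperimentSpec(sampling_interval_min=0.0)


def test_same_seed_reproduces_traces_exactly():
    a = synth.generate_step_experiment(small_spec())
    b = synth.generate_step_experiment(small_spec())
    assert len(a) == len(b)
    for ta, tb in zip(a, b):
        assert ta.chamber_id == tb.chamber_id
        assert np.array_equal(ta.values, tb.values)


def test_different_seed_changes_noise():
    a = synth.generate_step_experiment(small_spec(seed=5))
    b = synth.generate_step_experiment(small_spec(seed=6))
    assert not np.array_equal(a[0].values, b[0].values)


def test_zero_noise_replicates_collapse_onto_model():
    spec = small_spec(chamber_scale_sigma=0.0, read_noise_sd=0.0)
    traces = synth.generate_step_experiment(spec)
    first = {}
    for tr in traces:
        key = (tr.reporter, tr.channel_length_um)
        if key in first:
            assert np.allclose(tr.values, first[key])
        else:
            first[key] = tr.values


def test_step_experiment_layout_and_metadata():
    spec = small_spec()
    traces = synth.generate_step_experiment(spec)
    # 2 distances x 2 reporters x 3 replicates
    assert len(traces) == 12
    assert {tr.reporter for tr in traces} == {"GFP", "RFP"}
    assert all(tr.time_min[1] - tr.time_min[0] == 7.0 for tr in traces)


def test_late_time_receiver_output_orders_by_distance():
    spec = small_spec(duration_min=700.0, replicates=4, seed=11)
    traces = synth.generate_step_experiment(spec)
    late = {}
    for tr in traces:
        if tr.reporter == "RFP":
            late.setdefault(tr.channel_length_um, []).append(tr.values[-10:].mean())
    assert np.mean(late[25.0]) > np.mean(late[250.0])


def test_provenance_block_records_spec_and_seed():
    spec = small_spec(seed=99)
    prov = spec.provenance()
    assert prov["seed"] == 99
    assert prov["distances_um"] == (25.0, 250.0)


def test_calibration_trace_maximum_dilution_rate_is_generating_rate():
    traces = synth.generate_dilution_calibration_traces(
        120.0, replicates=1, chamber_scale_sigma=0.0, read_noise_sd=0.0)
    tr = traces[0]
    norm = tr.values / tr.values.max()
    rates = mx.delta_f_rate(norm, tr.dt_min, 10)
    assert np.log(2.0) / rates.max() == pytest.approx(120.0, rel=0.01)


def test_outlier_injection_labels_match_corruption():
    spec = small_spec()
    traces = synth.generate_step_experiment(spec)
    corrupted, labels = synth.inject_outliers(traces, 3, mode="level_drop",
                                              seed=1)
    assert len(labels) == 3
    by_id = {tr.chamber_id: tr for tr in traces}
    changed = [tr.chamber_id for tr in corrupted
               if not np.array_equal(tr.values, by_id[tr.chamber_id].values)]
    assert sorted(changed) == sorted(labels)


def test_zero_injected_outliers_labels_empty():
    traces = synth.generate_step_experiment(small_spec())
    corrupted, labels = synth.inject_outliers(traces, 0, seed=1)
    assert labels == []
    for tr, orig in zip(corrupted, traces):
        assert np.array_equal(tr.values, orig.values)


def test_level_drop_collapses_to_flat_residual():
    traces = synth.generate_step_experiment(small_spec())
    corrupted, labels = synth.inject_outliers(traces, 1, mode="level_drop",
                                              severity=0.1, seed=3)
    bad = next(tr for tr in corrupted if tr.chamber_id == labels[0])
    tail = bad.values[-5:]
    assert np.ptp(tail) == pytest.approx(0.0, abs=1e-12)


def test_spike_corruption_adds_isolated_excursions():
    traces = synth.generate_step_experiment(small_spec())
    corrupted, labels = synth.inject_outliers(traces, 1, mode="spikes", seed=3)
    by_id = {tr.chamber_id: tr for tr in traces}
    bad = next(tr for tr in corrupted if tr.chamber_id == labels[0])
    orig = by_id[labels[0]]
    n_changed = int(np.sum(bad.values != orig.values))
    assert n_changed == 4


def test_single_cell_tracks_planted_association_and_short_tracks():
    data = synth.generate_single_cell_tracks(n_chambers=6, n_cells=8,
                                             association_strength=0.01,
                                             short_track_fraction=0.25,
                                             seed=2)
    tracks = data["tracks"]
    assert len(tracks) == 48
    n_short = sum(t["short"] for t in tracks)
    assert 0 < n_short < len(tracks)
    # high-occupancy chambers grow faster on average (planted signal)
    occ = data["occupancy"]
    rates = {}
    for t in tracks:
        rates.setdefault(t["chamber_id"], []).append(t["true_rate"])
    chamber_mean = {c: np.mean(v) for c, v in rates.items()}
    hi = max(occ, key=occ.get)
    lo = min(occ, key=occ.get)
    assert chamber_mean[hi] > chamber_mean[lo]
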