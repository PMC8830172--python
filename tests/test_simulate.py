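"""Generator: weights, arrival statistics, rendering, and trace round trips."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import synpore as sp
from synpore.simulate import SimulationWarning, ValidationError, filter_sigma_samples
from synpore.traceio import (
    TraceParseError,
    read_ground_truth,
    read_trace,
    write_ground_truth,
    write_trace,
)


def _classes(*specs):
    return [
        dict(label=lbl, weight=w, mean_blockade=mu, sd_blockade=sd, dwell_scale=tau)
        for lbl, w, mu, sd, tau in specs
    ]


class TestBuildConditionModel:
    def test_percentages_renormalized(self):
        # raw populations 66% translocation / 24% bumping -> weights p_i / sum(p)
        model = sp.build_condition_model(
            _classes(("translocation", 66, -85, 5, 0.52), ("bumping", 24, -30, 3, 0.05))
        )
        assert model.weights == pytest.approx([66 / 90, 24 / 90], abs=1e-12)
        assert model.metadata["weights_renormalized"]
        assert model.metadata["raw_weights"] == [66, 24]

    def test_single_class_weight_one(self):
        model = sp.build_condition_model(_classes(("bumping", 1.0, -30, 3, 0.05)))
        assert model.weights == pytest.approx([1.0])
        assert "weights_renormalized" not in model.metadata

    def test_renormalization_disabled_rejects_bad_sum(self):
        with pytest.raises(ValidationError):
            sp.build_condition_model(
                _classes(("translocation", 0.6, -85, 5, 0.5), ("bumping", 0.6, -30, 3, 0.05)),
                renormalize=False,
            )

    @pytest.mark.parametrize(
        "field,value",
        [("weight", -0.1), ("dwell_scale", 0.0), ("sd_blockade", -1.0)],
    )
    def test_invalid_class_fields_name_the_offender(self, field, value):
        spec = dict(label="bumping", weight=1.0, mean_blockade=-30, sd_blockade=3, dwell_scale=0.05)
        spec[field] = value
        with pytest.raises(ValidationError):
            sp.build_condition_model([spec])

    def test_blockade_deeper_than_baseline_rejected(self):
        with pytest.raises(ValidationError, match="baseline"):
            sp.build_condition_model(
                _classes(("translocation", 1.0, -150, 5, 0.5)),
                {"baseline_current": 100.0},
            )

    def test_undersampled_bandwidth_rejected(self):
        with pytest.raises(ValidationError, match="sampling_rate"):
            sp.build_condition_model(
                _classes(("bumping", 1.0, -30, 3, 0.05)),
                {"sampling_rate": 15000.0, "filter_bandwidth": 10000.0},
            )


class TestSimulateEvents:
    def test_zero_rate_empty(self):
        model = sp.condition_preset("full_length", seed=0, event_rate=0.0)
        assert sp.simulate_events(model) == []

    def test_too_short_duration_warns(self):
        model = sp.condition_preset("full_length", seed=3, duration=1e-4, event_rate=0.01)
        with pytest.warns(SimulationWarning):
            events = sp.simulate_events(model)
        assert events == []

    def test_poisson_event_count(self):
        model = sp.condition_preset("full_length", seed=5, event_rate=10.0, duration=100.0)
        n = len(sp.simulate_events(model))
        assert abs(n - 1000) <= 3 * math.sqrt(1000)

    def test_mean_dwell_converges(self):
        model = sp.build_condition_model(
            _classes(("translocation", 1.0, -85, 5, 0.5)),
            {"event_rate": 400.0, "duration": 30.0, "dead_time": 1e-4, "seed": 7},
        )
        events = sp.simulate_events(model)
        assert len(events) >= 2000
        mean_dwell = np.mean([e.dwell_ms for e in events])
        assert abs(mean_dwell - 0.5) / 0.5 < 0.05

    def test_reproducible_given_seed(self):
        model = sp.condition_preset("full_length", seed=11, duration=5.0)
        assert sp.simulate_events(model) == sp.simulate_events(model)
        t1 = sp.render_trace(sp.simulate_events(model), model)
        t2 = sp.render_trace(sp.simulate_events(model), model)
        assert np.array_equal(t1.samples, t2.samples)

    def test_class_fractions_match_weights(self):
        model = sp.condition_preset("full_length", seed=13, duration=60.0)
        events = sp.simulate_events(model)
        n = len(events)
        for cls in model.classes:
            frac = sum(e.label == cls.label for e in events) / n
            sd = math.sqrt(cls.weight * (1 - cls.weight) / n)
            assert abs(frac - cls.weight) <= 3 * sd

    def test_dwell_distribution_is_exponential(self):
        model = sp.build_condition_model(
            _classes(("bumping", 1.0, -30, 3, 0.05)),
            {"event_rate": 400.0, "duration": 30.0, "dead_time": 1e-4, "seed": 17},
        )
        dwells = [e.dwell_ms for e in sp.simulate_events(model)]
        assert len(dwells) >= 5000
        p = sps.kstest(dwells, "expon", args=(0, 0.05)).pvalue
        assert p > 0.01

    def test_events_never_overlap(self):
        model = sp.condition_preset("full_length", seed=19, duration=20.0, event_rate=100.0)
        events = sp.simulate_events(model)
        ends = np.array([e.start_s + e.dwell_ms * 1e-3 for e in events])
        starts = np.array([e.start_s for e in events])
        assert np.all(starts[1:] >= ends[:-1])


class TestRenderTrace:
    def test_no_events_no_noise_is_flat(self):
        model = sp.condition_preset("full_length", seed=0, duration=0.05, noise_sd=0.0)
        trace = sp.render_trace([], model)
        assert trace.samples == pytest.approx(np.full(trace.samples.size, 100.0), abs=1e-9)

    def test_long_event_interior_at_nominal_depth(self):
        model = sp.condition_preset("full_length", seed=0, duration=0.05, noise_sd=0.0)
        ev = [sp.GroundTruthEvent("translocation", 0.02, 1.0, -85.0)]
        trace = sp.render_trace(ev, model)
        fs = model.sampling_rate
        interior = trace.samples[int(0.02 * fs) + 20: int(0.021 * fs) - 20]
        assert interior == pytest.approx(np.full(interior.size, 15.0), abs=1e-3)

    def test_short_event_attenuated_per_filter_response(self):
        # 0.02 ms pulse at 10 kHz bandwidth: peak deflection should match the
        # analytic response of a Gaussian filter to a box, erf(w / (2 sqrt2 sigma))
        model = sp.condition_preset("full_length", seed=0, duration=0.05, noise_sd=0.0)
        ev = [sp.GroundTruthEvent("bumping", 0.02, 0.02, -85.0)]
        trace = sp.render_trace(ev, model)
        depth = 100.0 - trace.samples.min()
        sigma = filter_sigma_samples(model.sampling_rate, model.filter_bandwidth)
        w = 0.02e-3 * model.sampling_rate
        expected = 85.0 * math.erf(w / (2 * math.sqrt(2) * sigma))
        assert depth < 0.8 * 85.0  # clearly attenuated
        assert depth == pytest.approx(expected, rel=0.05)

    def test_overlapping_events_rejected(self):
        model = sp.condition_preset("full_length", seed=0, duration=0.05, noise_sd=0.0)
        ev = [
            sp.GroundTruthEvent("translocation", 0.010, 1.0, -85.0),
            sp.GroundTruthEvent("bumping", 0.0105, 1.0, -30.0),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            sp.render_trace(ev, model)


class TestTraceIO:
    def test_binary_round_trip_exact_float32(self, tmp_path):
        model = sp.condition_preset("full_length", seed=23, duration=0.2)
        trace, _ = sp.simulate_recording(model)
        path = tmp_path / "t.spt"
        write_trace(trace, path, format="binary")
        back = read_trace(path)
        assert np.max(np.abs(back.samples - trace.samples.astype(np.float32))) == 0
        assert back.sampling_rate == trace.sampling_rate
        assert back.metadata == trace.metadata

    def test_text_round_trip_within_tolerance(self, tmp_path):
        model = sp.condition_preset("full_length", seed=23, duration=0.02)
        trace, _ = sp.simulate_recording(model)
        path = tmp_path / "t.txt"
        write_trace(trace, path, format="text")
        back = read_trace(path)
        assert np.max(np.abs(back.samples - trace.samples)) < 1e-6
        assert back.metadata["condition"] == "full_length"

    def test_truncated_binary_raises_parse_error(self, tmp_path):
        model = sp.condition_preset("full_length", seed=23, duration=0.02)
        trace, _ = sp.simulate_recording(model)
        path = tmp_path / "t.spt"
        write_trace(trace, path, format="binary")
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 100])
        with pytest.raises(TraceParseError):
            read_trace(path)

    def test_text_sample_count_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            "# synpore trace v1\n# sampling_rate_Hz: 1000.0\n# n_samples: 5\n"
            "0.000\t100.0\n0.001\t100.0\n"
        )
        with pytest.raises(TraceParseError, match="declares 5"):
            read_trace(path)

    def test_ground_truth_csv_round_trip(self, tmp_path):
        model = sp.condition_preset("full_length", seed=29, duration=2.0)
        events = sp.simulate_events(model)
        path = tmp_path / "truth.csv"
        write_ground_truth(events, path)
        back = read_ground_truth(path)
        assert len(back) == len(events)
        assert back[0].label == events[0].label
        assert back[0].dwell_ms == pytest.approx(events[0].dwell_ms, rel=1e-8)
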