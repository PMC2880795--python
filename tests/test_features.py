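"""Template enumeration, extremum extraction, feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpica.features import (
    FeatureMatrix,
    FeatureSpec,
    FeatureTemplate,
    build_feature_matrix,
    enumerate_features,
    extract_feature,
    reference_templates,
)
from erpica.ica import MixingModel
from erpica.synth import SimConfig, make_ground_truth, simulate_dataset


def brute_force_window_count(start, end, window, step):
    n, t0 = 0, start
    while t0 + window <= end:
        n += 1
        t0 += step
    return n


class TestEnumeration:
    def test_single_window(self):
        t = FeatureTemplate(0, 600, 600, 4)
        assert len(enumerate_features(t, [("c", "Cz")])) == 1

    def test_126_windows_for_100ms_window_4ms_step(self):
        t = FeatureTemplate(0, 600, 100, 4)
        assert t.n_windows == 126
        assert len(enumerate_features(t, [("c", "Cz")])) == 126

    def test_reference_settings_enumerate_17584_features(self):
        comps = [(f"c{i}", "Cz") for i in range(7)]
        total = sum(len(enumerate_features(t, comps)) for t in reference_templates())
        assert total == 17584

    @settings(max_examples=60, derandomize=True)
    @given(
        start=st.integers(0, 100),
        span=st.integers(1, 400),
        window=st.integers(1, 400),
        step=st.integers(1, 50),
    )
    def test_count_matches_brute_force(self, start, span, window, step):
        end = start + span
        if window > span:
            window = span
        t = FeatureTemplate(start, end, window, step)
        assert t.n_windows == brute_force_window_count(start, end, window, step)

    def test_windows_ordered_and_within_range(self):
        t = FeatureTemplate(100, 300, 50, 30)
        specs = enumerate_features(t, [("c", "Cz")])
        starts = [s.t0_ms for s in specs]
        assert starts == sorted(starts)
        assert all(s.t0_ms >= 100 and s.t1_ms <= 300 for s in specs)

    def test_unmapped_component_raises(self):
        t = FeatureTemplate(0, 100, 50, 10)
        with pytest.raises(KeyError):
            enumerate_features(t, ["mystery"], channel_map={})

    @pytest.mark.parametrize(
        "kw",
        [
            dict(start_ms=10, end_ms=10, window_ms=5, step_ms=1),
            dict(start_ms=0, end_ms=100, window_ms=200, step_ms=1),
            dict(start_ms=0, end_ms=100, window_ms=50, step_ms=0),
            dict(start_ms=0, end_ms=100, window_ms=50, step_ms=4, extremum="median"),
        ],
    )
    def test_invalid_template(self, kw):
        with pytest.raises(ValueError):
            FeatureTemplate(**kw)


class TestExtraction:
    time = np.arange(150) * 4.0  # 250 Hz, 600 ms

    def test_planted_trough_latency(self):
        y = -np.exp(-0.5 * ((self.time - 200) / 20) ** 2)
        spec = FeatureSpec("c", "Cz", 112, 260, "min", "latency")
        assert extract_feature(spec, y, self.time) == 200.0

    def test_constant_waveform_ties_to_window_start(self):
        y = np.ones_like(self.time)
        spec = FeatureSpec("c", "Cz", 100, 300, "min", "latency")
        assert extract_feature(spec, y, self.time) == 100.0

    def test_sampled_gaussian_trough_amplitude_and_latency(self):
        depth = -3.5
        y = depth * np.exp(-0.5 * ((self.time - 500) / 30) ** 2)
        lat = extract_feature(FeatureSpec("c", "Cz", 440, 540, "min", "latency"), y, self.time)
        amp = extract_feature(FeatureSpec("c", "Cz", 440, 540, "min", "amplitude"), y, self.time)
        assert lat == 500.0
        assert amp == pytest.approx(depth, abs=1e-6)

    def test_window_outside_span_raises(self):
        with pytest.raises(ValueError, match="outside"):
            extract_feature(FeatureSpec("c", "Cz", 500, 700, "min", "latency"), self.time * 0, self.time)

    def test_latency_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=self.time.size)
        spec = FeatureSpec("c", "Cz", 0, 596, "min", "latency")
        assert extract_feature(spec, y, self.time) == extract_feature(spec, 7.3 * y, self.time)

    def test_amplitude_scales_linearly(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=self.time.size)
        spec = FeatureSpec("c", "Cz", 0, 596, "max", "amplitude")
        assert extract_feature(spec, 2.5 * y, self.time) == pytest.approx(
            2.5 * extract_feature(spec, y, self.time)
        )

    @settings(max_examples=30, derandomize=True)
    @given(delta=st.integers(-10, 10))
    def test_sample_shift_moves_latency_exactly(self, delta):
        center = 300.0
        y = -np.exp(-0.5 * ((self.time - center) / 20) ** 2)
        shifted = -np.exp(-0.5 * ((self.time - center - delta * 4.0) / 20) ** 2)
        spec = FeatureSpec("c", "Cz", 200, 440, "min", "latency")
        base = extract_feature(spec, y, self.time)
        moved = extract_feature(spec, shifted, self.time)
        assert moved - base == delta * 4.0


@pytest.fixture(scope="module")
def true_model():
    cfg = SimConfig(n_per_group=4, seed=13)
    gt = make_ground_truth(cfg, 7)
    ds = simulate_dataset(gt, cfg)
    model = MixingModel(
        U=np.linalg.pinv(gt.topographies),
        U_inv=gt.topographies,
        channel_order=cfg.channels,
    )
    return cfg, gt, ds, model


class TestFeatureMatrixAssembly:
    def test_shape_and_no_missing(self, true_model):
        cfg, gt, ds, model = true_model
        ch = cfg.channels[int(np.argmax(np.abs(gt.topographies[:, 4])))]
        specs = [
            FeatureSpec("premotor", ch, t0, t0 + 100, "min", "latency")
            for t0 in (200, 240, 260, 280, 300)
        ]
        fm = build_feature_matrix(ds, model, specs, component_index={"premotor": 4})
        assert fm.values.shape == (8, 5)
        assert not np.isnan(fm.values).any()

    def test_latency_values_lie_within_windows(self, true_model):
        cfg, gt, ds, model = true_model
        ch = cfg.channels[int(np.argmax(np.abs(gt.topographies[:, 4])))]
        spec = FeatureSpec("premotor", ch, 240, 380, "min", "latency")
        fm = build_feature_matrix(ds, model, [spec], component_index={"premotor": 4})
        assert np.all(fm.values >= 240) and np.all(fm.values <= 380)

    def test_group_shift_recovered_in_latency_feature(self):
        shift = 24.0
        cfg = SimConfig(n_per_group=6, group_latency_shift_ms=(0, 0, 0, 0, shift, 0, 0), seed=17)
        gt = make_ground_truth(cfg, 7)
        ds = simulate_dataset(gt, cfg)
        model = MixingModel(
            U=np.linalg.pinv(gt.topographies), U_inv=gt.topographies, channel_order=cfg.channels
        )
        ch = cfg.channels[int(np.argmax(np.abs(gt.topographies[:, 4])))]
        spec = FeatureSpec("premotor", ch, 240, 400, "min", "latency")
        fm = build_feature_matrix(ds, model, [spec], component_index={"premotor": 4})
        g = np.array(fm.group_labels)
        diff = fm.values[g == "case", 0].mean() - fm.values[g == "control", 0].mean()
        assert diff == pytest.approx(shift, abs=4.0)

    def test_missing_condition_error_names_subject(self, true_model):
        _, _, ds, model = true_model
        spec = FeatureSpec("premotor", "Cz", 240, 340, "min", "latency")
        with pytest.raises(KeyError, match="GO"):
            build_feature_matrix(
                ds, model, [spec], component_index={"premotor": 4}, default_condition="GO"
            )

    def test_matrix_validation_rejects_nan(self):
        with pytest.raises(ValueError, match="missing"):
            FeatureMatrix(
                subject_ids=["a"],
                group_labels=["control"],
                feature_ids=["f"],
                values=np.array([[np.nan]]),
            )
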