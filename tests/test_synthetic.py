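"""Generator contracts: breath timing, traces, diameter series, rendering, cohorts."""

import json

import numpy as np
import pytest

import veinmod as vm
from veinmod import synthetic
from veinmod.errors import ConfigError
from veinmod.types import Condition


class TestBreathPattern:
    def test_pb10_onsets_fixed(self, pb10_pattern):
        np.testing.assert_allclose(pb10_pattern.inspiration_onsets_s,
                                   [0, 10, 20, 30, 40])

    def test_pb3_onsets_fixed(self, pb3_pattern):
        assert pb3_pattern.n_breaths == 17
        np.testing.assert_allclose(pb3_pattern.inspiration_onsets_s,
                                   np.arange(0, 49, 3.0))

    def test_sb_seed_determinism(self):
        a = synthetic.make_breath_pattern("SB", 50, seed=1)
        b = synthetic.make_breath_pattern("SB", 50, seed=1)
        c = synthetic.make_breath_pattern("SB", 50, seed=2)
        np.testing.assert_array_equal(a.cycle_lengths_s, b.cycle_lengths_s)
        assert not np.array_equal(a.cycle_lengths_s, c.cycle_lengths_s)

    @pytest.mark.parametrize("dist", ["beta", "uniform", "triangular"])
    def test_sb_cycles_within_range(self, dist):
        for seed in range(20):
            p = synthetic.make_breath_pattern("SB", 50, seed=seed,
                                              sb_distribution=dist)
            assert np.all(p.cycle_lengths_s >= 2.0)
            assert np.all(p.cycle_lengths_s <= 8.0)

    def test_sb_beta_mean_cycle(self):
        cycles = np.concatenate([
            synthetic.make_breath_pattern("SB", 50, seed=s).cycle_lengths_s
            for s in range(300)])
        assert abs(cycles.mean() - 3.9) < 0.1

    def test_onset_spacing_equals_cycles(self, sb_pattern):
        np.testing.assert_allclose(np.diff(sb_pattern.inspiration_onsets_s),
                                   sb_pattern.cycle_lengths_s[:-1])

    def test_pattern_covers_duration(self, sb_pattern):
        assert (sb_pattern.inspiration_onsets_s[-1]
                + sb_pattern.cycle_lengths_s[-1]) >= sb_pattern.duration_s

    def test_unknown_condition_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.make_breath_pattern("PB5", 50)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.make_breath_pattern("PB10", 0)


class TestRespirationTrace:
    def test_pb10_maxima_at_onsets(self, pb10_pattern):
        tr = synthetic.make_respiration_trace(pb10_pattern, noise_sd=0.0)
        assert len(tr) == 5000
        for onset in [0, 10, 20, 30, 40]:
            i = int(onset * 100)
            window = tr.values[max(0, i - 50):i + 51]
            assert tr.values[i] >= window.max() - 1e-9

    def test_minima_count_matches_breaths(self, pb3_pattern):
        tr = synthetic.make_respiration_trace(pb3_pattern, noise_sd=0.0)
        # minima at the inspiration->expiration transition of each breath
        x = tr.values
        minima = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
        # consecutive flat samples can duplicate a minimum; count separated ones
        separated = np.split(minima, np.flatnonzero(np.diff(minima) > 10) + 1)
        assert len([g for g in separated if g.size]) == pb3_pattern.n_breaths

    def test_trace_max_amplitude(self, pb10_pattern):
        tr = synthetic.make_respiration_trace(pb10_pattern, temp_amp=0.8,
                                              temp_baseline=34.0, noise_sd=0.0)
        assert tr.values.max() == pytest.approx(34.4, abs=1e-6)
        assert tr.values.min() == pytest.approx(33.6, abs=1e-3)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.make_respiration_trace(None)


class TestDiameterSeries:
    def test_constant_series(self, pb10_pattern):
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4))
        np.testing.assert_allclose(s.values_mm, 2.4)

    def test_mean_with_slope(self, pb10_pattern):
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, slope=0.002))
        assert s.values_mm.mean() == pytest.approx(2.449, abs=1e-12)

    def test_sampled_cosine_variance(self, pb10_pattern):
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05))
        # half the squared half-amplitude, within 5% for the sampled cosine
        assert s.values_mm.var() == pytest.approx(0.05 ** 2 / 2, rel=0.05)

    def test_phase_lock_of_minima(self, pb10_pattern):
        """Noise-free paced series: each cycle's minimum at the same phase."""
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05))
        mins = [np.argmin(s.values_mm[k:k + 10]) for k in range(0, 50, 10)]
        assert max(mins) - min(mins) <= 1

    def test_contracts_with_inspiration(self, pb10_pattern):
        """End-inspiration diameter below end-expiration diameter."""
        s = synthetic.make_diameter_series(
            pb10_pattern, synthetic.GroundTruth(d0=2.4, amp=0.05))
        end_insp = s.values_mm[4::10]   # 40% through each 10-s cycle
        end_exp = s.values_mm[0::10]    # at onsets (end of previous expiration)
        assert np.all(end_insp < end_exp)

    def test_lumen_collapse_rejected(self, pb10_pattern):
        with pytest.raises(ConfigError):
            synthetic.make_diameter_series(
                pb10_pattern, synthetic.GroundTruth(d0=0.2, amp=0.1, slope=0.01))


class TestRenderFrames:
    def test_two_gray_levels_without_speckle(self, noise_free_scene):
        seq = synthetic.render_frames(vm.DiameterSeries([2.5]), noise_free_scene)
        assert set(np.unique(seq.frames)) == {30, 160}

    def test_seed_determinism(self):
        scene = synthetic.SceneParams(speckle_sd=10.0, seed=42)
        a = synthetic.render_frames(vm.DiameterSeries([2.5, 2.6]), scene)
        b = synthetic.render_frames(vm.DiameterSeries([2.5, 2.6]), scene)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_minor_axis_in_pixels(self, noise_free_scene):
        seq = synthetic.render_frames(vm.DiameterSeries([2.5]), noise_free_scene)
        lumen_rows = np.any(seq.frames[0] == 30, axis=1).sum()
        assert lumen_rows == pytest.approx(50, abs=2)  # 2.5 mm / 0.05 mm/px

    def test_oversized_ellipse_rejected(self):
        scene = synthetic.SceneParams(image_size_px=(60, 60))
        with pytest.raises(ConfigError):
            synthetic.render_frames(vm.DiameterSeries([4.0]), scene)


class TestCohort:
    def test_default_shape(self):
        cohort = synthetic.make_cohort(n_participants=4, n_reps=3, seed=0,
                                       include_respiration=False)
        assert len(cohort.recordings) == 4 * 3 * 3
        assert len(cohort.manifest()) == 36

    def test_condition_means_ordered(self):
        cohort = synthetic.make_cohort(n_participants=6, seed=3,
                                       include_respiration=False)
        means = {}
        for cond in (Condition.SB, Condition.PB3, Condition.PB10):
            vals = [r.series.values_mm.mean() for r in cohort.recordings
                    if r.condition == cond]
            means[cond] = np.mean(vals)
        assert means[Condition.SB] > means[Condition.PB3] > means[Condition.PB10]

    def test_manifest_roundtrip(self, tmp_path):
        cohort = synthetic.make_cohort(n_participants=2, n_reps=1, seed=5,
                                       include_respiration=False)
        text = cohort.manifest_json()
        parsed = json.loads(text)
        assert parsed["recordings"] == json.loads(cohort.manifest_json())["recordings"]
        cohort.save(tmp_path)
        reloaded = json.loads((tmp_path / "manifest.json").read_text())
        assert reloaded == parsed

    def test_master_seed_determinism(self):
        a = synthetic.make_cohort(n_participants=3, seed=9,
                                  include_respiration=False)
        b = synthetic.make_cohort(n_participants=3, seed=9,
                                  include_respiration=False)
        assert a.manifest_json() == b.manifest_json()
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.series.values_mm, rb.series.values_mm)

    def test_too_few_participants_rejected(self):
        with pytest.raises(ConfigError):
            synthetic.make_cohort(n_participants=1)
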