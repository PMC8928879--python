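"""Night generator, corruption model and toy renderer."""

import numpy as np
import pytest

from stablewatch.core import (BehaviorLabel, Task, map_total_to_binary,
                              segment_phases)
from stablewatch.synthetic import (EnclosureSpec, NoiseModel,
                                   SyntheticNightRenderer, SyntheticProfile,
                                   corrupt_prediction, load_scenario,
                                   sample_night_sequence)

from conftest import D, L, O, S, U, make_seq


class TestProfile:
    def test_demographic_presets(self):
        p = SyntheticProfile.for_demographic("adult_male")
        assert p.lying_median_min == 89.6
        assert p.standing_median_min == 30.8
        assert p.lhd_median_min == 4.6

    def test_unknown_demographic_rejected(self):
        with pytest.raises(ValueError):
            SyntheticProfile.for_demographic("calf")

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            SyntheticProfile(lying_median_min=0)


class TestSampleNight:
    def test_deterministic_per_seed(self):
        p = SyntheticProfile.for_demographic("adult_female")
        assert sample_night_sequence(p, 5).labels == \
            sample_night_sequence(p, 5).labels

    def test_different_seeds_differ(self):
        p = SyntheticProfile.for_demographic("adult_female")
        assert sample_night_sequence(p, 1).labels != \
            sample_night_sequence(p, 2).labels

    def test_night_length_exact(self):
        p = SyntheticProfile.for_demographic("adult_female")
        assert len(sample_night_sequence(p, 0)) == 7200  # 14 h at 7 s

    def test_single_state_profile_is_constant(self):
        p = SyntheticProfile(states=("standing",), out_bout_rate_per_h=0.0)
        seq = sample_night_sequence(p, 3)
        assert set(seq.labels) == {S}

    def test_lhd_entered_only_from_lhu(self):
        p = SyntheticProfile.for_demographic("nonadult")
        for seed in range(10):
            labels = sample_night_sequence(p, seed).labels
            for a, b in zip(labels, labels[1:]):
                if b is D:
                    assert a in (D, U)

    def test_out_bouts_overwrite_standing_only(self):
        """Out bouts start on Standing intervals of the behavioral
        backbone and never extend into a Lying bout: the animal must be
        on its feet to leave the camera's view.  The backbone is the same
        draw with the Out rate zeroed (Out placement consumes the RNG
        last)."""
        from dataclasses import replace

        p = SyntheticProfile.for_demographic("adult_female",
                                             out_bout_rate_per_h=2.0)
        p0 = replace(p, out_bout_rate_per_h=0.0)
        for seed in range(10):
            noisy = sample_night_sequence(p, seed).labels
            backbone = sample_night_sequence(p0, seed).labels
            assert len(noisy) == len(backbone)
            for got, base in zip(noisy, backbone):
                if got is O:
                    assert base is S  # Out only ever replaces Standing
                else:
                    assert got is base

    def test_median_dwell_recovered_at_small_scale(self):
        """Pooled Lying phase medians approach the profile median."""
        p = SyntheticProfile.for_demographic("adult_female",
                                             out_bout_rate_per_h=0.0)
        lengths = []
        for seed in range(40):
            seq = map_total_to_binary(sample_night_sequence(p, seed))
            lengths += [ph.duration_s / 60 for ph in segment_phases(seq)
                        if ph.label is L]
        med = float(np.median(lengths))
        assert abs(med - 59.3) / 59.3 < 0.15


class TestCorruption:
    def test_zero_noise_is_identity(self):
        p = SyntheticProfile.for_demographic("adult_female")
        truth = sample_night_sequence(p, 0)
        assert corrupt_prediction(truth, NoiseModel.none(), 1).labels == \
            truth.labels

    def test_deterministic_per_seed(self):
        truth = make_seq([S] * 500, task=Task.BINARY)
        noise = NoiseModel.flicker(Task.BINARY, flip_p=0.1)
        assert corrupt_prediction(truth, noise, 3).labels == \
            corrupt_prediction(truth, noise, 3).labels

    def test_flip_rate_within_binomial_bounds(self):
        flip_p, n = 0.05, 2000
        truth = make_seq([S] * n, task=Task.BINARY)
        noise = NoiseModel.flicker(Task.BINARY, flip_p=flip_p)
        rates = []
        for seed in range(20):
            pred = corrupt_prediction(truth, noise, seed)
            rates.append(
                sum(1 for a, b in zip(pred.labels, truth.labels)
                    if a is not b) / n)
        se = np.sqrt(flip_p * (1 - flip_p) / (n * 20))
        assert abs(np.mean(rates) - flip_p) < 4 * se

    def test_confusion_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            NoiseModel(confusion={S: {S: 0.5, L: 0.2}})

    def test_bursts_inject_wrong_label_runs(self):
        truth = make_seq([S] * 7200, task=Task.BINARY)
        noise = NoiseModel(burst_rate_per_h=5.0,
                           burst_length_mean_intervals=3.0,
                           burst_length_max_intervals=7)
        pred = corrupt_prediction(truth, noise, 0)
        wrong = [p for p in segment_phases(pred) if p.label is not S]
        assert wrong  # bursts landed
        # ~70 bursts of mean 3 intervals; adjacent bursts may coalesce,
        # but the corrupted mass stays a small fraction of the night
        total_wrong = sum(p.n_intervals for p in wrong)
        assert 50 < total_wrong < 600


class TestRenderer:
    def _renderer(self, labels, **kw):
        seq = make_seq(labels, task=Task.TOTAL)
        return SyntheticNightRenderer(seq, seed=1, **kw)

    def test_standing_box_taller_than_wide(self):
        r = self._renderer([S])
        x0, y0, x1, y1 = r.box(0)
        assert (y1 - y0) > (x1 - x0)

    def test_lying_boxes_wider_than_tall(self):
        for lab in (U, D):
            r = self._renderer([lab])
            x0, y0, x1, y1 = r.box(0)
            assert (x1 - x0) > (y1 - y0)

    def test_out_interval_has_no_box_and_no_xml(self, tmp_path):
        r = self._renderer([O, S])
        assert r.box(0) is None
        r.write_voc(tmp_path)
        assert not (tmp_path / "0.xml").exists()
        assert (tmp_path / "7.xml").exists()

    def test_gap_frames_render_black_without_boxes(self):
        r = self._renderer([S], gap_frames={0})
        assert r.get_frame(0).sum() == 0
        assert r.box(0) is None
        assert r.get_frame(1).sum() > 0

    def test_frames_deterministic_per_seed(self):
        a = self._renderer([S, U, D]).get_frame(8)
        b = self._renderer([S, U, D]).get_frame(8)
        assert (a == b).all()

    def test_box_encloses_all_foreground(self):
        r = self._renderer([U])
        img = r.get_frame(0)
        x0, y0, x1, y1 = r.box(0)
        fg = np.argwhere(img > 100)
        assert fg[:, 0].min() >= y0 and fg[:, 0].max() < y1
        assert fg[:, 1].min() >= x0 and fg[:, 1].max() < x1


class TestScenarioYaml:
    def test_load_scenario(self, tmp_path):
        p = tmp_path / "scenario.yaml"
        p.write_text(
            "profiles:\n"
            "  adult_female: {}\n"
            "  quiet_male:\n"
            "    demographic: adult_male\n"
            "    out_bout_rate_per_h: 0.0\n"
            "noise:\n"
            "  task: binary\n"
            "  flip_p: 0.01\n"
            "n_nights: 5\n"
            "seed: 42\n"
        )
        sc = load_scenario(p)
        assert sc["profiles"]["adult_female"].lying_median_min == 59.3
        assert sc["profiles"]["quiet_male"].out_bout_rate_per_h == 0.0
        assert sc["n_nights"] == 5 and sc["seed"] == 42
        assert sc["noise"].confusion is not None
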