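"""Synthetic generator: beat construction, class effects, dataset sampling."""

import numpy as np
import pytest
from dataclasses import replace

import groupecg as g
from groupecg.synthetic import (
    apply_deltas,
    class_effects,
    default_morphology,
    default_projection,
    st_window,
    _record_seed,
)
from groupecg.taxonomy import InvalidLabelError, TASK2_CLASSES


class TestGenerateBeat:
    def test_zero_amplitudes_give_zero_waveform(self):
        morph = replace(default_morphology(),
                        wave_amplitudes=(0.0,) * 5, st_offset=0.0)
        beat = g.generate_beat(morph, fs=500, rr=0.8)
        np.testing.assert_array_equal(beat, 0.0)

    def test_isolated_r_wave_peaks_at_its_center(self):
        morph = replace(default_morphology(),
                        wave_amplitudes=(0.0, 0.0, 1.0, 0.0, 0.0))
        beat = g.generate_beat(morph, fs=500, rr=0.8)
        peak = np.argmax(beat)
        center_sample = morph.wave_centers[2] * 500
        assert abs(peak - center_sample) <= 1
        np.testing.assert_allclose(beat[peak], 1.0, atol=1e-3)

    def test_length_is_rr_times_fs(self):
        beat = g.generate_beat(default_morphology(), fs=500, rr=0.8)
        assert beat.shape == (400,)

    @pytest.mark.parametrize("fs,rr", [(0, 0.8), (-500, 0.8), (500, 0), (500, -1)])
    def test_invalid_fs_rr_rejected(self, fs, rr):
        with pytest.raises(ValueError):
            g.generate_beat(default_morphology(), fs=fs, rr=rr)


class TestMorphologyInvariants:
    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            replace(default_morphology(), wave_widths=(0.02, 0.0, 0.01, 0.01, 0.05))

    def test_unordered_centers_rejected(self):
        with pytest.raises(ValueError):
            replace(default_morphology(), wave_centers=(0.3, 0.2, 0.25, 0.27, 0.45))

    def test_st_window_is_nonempty_and_between_s_and_t(self):
        morph = default_morphology()
        t0, t1 = st_window(morph)
        assert morph.wave_centers[3] < t0 < t1 <= morph.wave_centers[4]


class TestGenerateRecord:
    def test_shape_and_label(self):
        rec = g.generate_record("N", duration=10, fs=500, seed=1)
        assert rec.signal.shape == (12, 5000)
        assert rec.labels.task1 == "N" and rec.labels.task2 == "N"

    def test_identical_seed_gives_identical_bytes(self):
        a = g.generate_record("SA", seed=7)
        b = g.generate_record("SA", seed=7)
        assert a.signal.tobytes() == b.signal.tobytes()

    def test_different_seed_differs(self):
        a = g.generate_record("N", seed=1)
        b = g.generate_record("N", seed=2)
        assert not np.array_equal(a.signal, b.signal)

    def test_anterior_infarction_elevates_st_on_precordial_leads(self):
        # paired seeds: same noise process, only the class effect differs
        effect = class_effects()["AMI"]
        noise = g.NoiseParams(gaussian_sd=0.01, baseline_amp=0.0)
        normal = g.generate_record("N", seed=3, noise=noise)
        ami = g.generate_record("AMI", seed=3, noise=noise)
        v2 = normal.lead_names.index("V2")
        lead_i = normal.lead_names.index("I")
        diff_v2 = ami.signal[v2].mean() - normal.signal[v2].mean()
        diff_i = ami.signal[lead_i].mean() - normal.signal[lead_i].mean()
        # ST elevation contributes st_delta over the ST fraction of each beat
        t0, t1 = st_window(default_morphology())
        expected = effect.st_delta * (t1 - t0) / effect.rr_mean
        assert diff_v2 == pytest.approx(expected, abs=0.5 * expected)
        assert abs(diff_i) < 0.25 * expected     # lead I is unaffected

    def test_effects_confined_to_affected_leads(self):
        noise = g.NoiseParams(gaussian_sd=0.0, baseline_amp=0.0)
        normal = g.generate_record("N", seed=5, noise=noise)
        lvh = g.generate_record("LVH", seed=5, noise=noise)
        v5 = normal.lead_names.index("V5")
        v1 = normal.lead_names.index("V1")
        assert lvh.signal[v5].max() > 1.5 * normal.signal[v5].max()
        np.testing.assert_allclose(lvh.signal[v1], normal.signal[v1], atol=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidLabelError):
            g.generate_record("XYZ", seed=1)

    def test_seed_required(self):
        with pytest.raises(ValueError):
            g.generate_record("N")

    def test_duration_must_cover_two_beats(self):
        with pytest.raises(ValueError):
            g.generate_record("N", duration=1.0, seed=1)

    def test_lead_subset_generation(self):
        proj = default_projection(("I", "II", "V2"))
        rec = g.generate_record("N", seed=1, projection=proj)
        assert rec.lead_names == ("I", "II", "V2")
        assert rec.signal.shape[0] == 3


class TestTaxonomy:
    def test_normal_maps_to_normal(self):
        assert g.map_task2_to_task1("N") == "N"

    def test_anterior_infarction_maps_to_mi(self):
        assert g.map_task2_to_task1("AMI") == "MI"

    def test_preimage_sizes(self):
        from collections import Counter
        counts = Counter(g.map_task2_to_task1(c) for c in TASK2_CLASSES)
        assert sorted(counts.values()) == [1, 3, 3, 3, 5]
        assert counts["AR"] == 5 and counts["N"] == 1

    def test_unknown_label_raises(self):
        with pytest.raises(InvalidLabelError):
            g.map_task2_to_task1("Q")


class TestGenerateDataset:
    def test_one_hot_prior_gives_single_class(self):
        priors = np.zeros(15)
        priors[0] = 1.0        # N
        records, manifest = g.generate_dataset(10, class_priors=priors, seed=0,
                                               duration=2.0, fs=100.0)
        assert all(r.labels.task2 == "N" for r in records)
        assert len(manifest) == 10

    def test_clinical_prior_normal_fraction(self):
        priors = g.clinical_priors()
        np.testing.assert_allclose(priors[0], 0.6110, atol=1e-4)
        np.testing.assert_allclose(priors.sum(), 1.0, atol=1e-12)

    def test_uniform_prior_counts_within_multinomial_bound(self):
        # label sampling only; waveforms are not needed for this check
        n = 2000
        priors = np.full(15, 1 / 15)
        cum = np.cumsum(priors)
        labels = []
        for i in range(n):
            r = np.random.default_rng(
                np.random.SeedSequence(entropy=42, spawn_key=(i, 1))).random()
            labels.append(int(np.searchsorted(cum, r)))
        counts = np.bincount(labels, minlength=15)
        sd = np.sqrt(n * (1 / 15) * (14 / 15))
        assert np.all(np.abs(counts - n / 15) <= 3 * sd)

    def test_records_are_order_independent(self):
        a, _ = g.generate_dataset(3, seed=9, duration=2.0, fs=100.0)
        b, _ = g.generate_dataset(6, seed=9, duration=2.0, fs=100.0)
        np.testing.assert_array_equal(a[2].signal, b[2].signal)
        assert a[2].labels == b[2].labels

    def test_negative_prior_rejected(self):
        priors = np.full(15, 1 / 15)
        priors[0], priors[1] = -0.1, priors[1] + 0.1 + priors[0]
        with pytest.raises(ValueError):
            g.generate_dataset(5, class_priors=priors, seed=0)

    def test_label_hierarchy_holds_for_every_record(self, small_dataset):
        records, _ = small_dataset
        for r in records:
            assert r.labels.task1 == g.map_task2_to_task1(r.labels.task2)

    def test_per_record_seeds_are_deterministic(self):
        assert _record_seed(5, 3) == _record_seed(5, 3)
        assert _record_seed(5, 3) != _record_seed(5, 4)
        assert 0 <= _record_seed(5, 3) < 2 ** 31


class TestSeparability:
    def test_noise_free_classes_are_linearly_separable(self):
        """With noise off, per-lead means separate normal vs anterior MI."""
        noise = g.NoiseParams(gaussian_sd=0.0, baseline_amp=0.0)

        def features(label, seeds):
            return np.array([
                g.generate_record(label, seed=s, noise=noise).signal.mean(axis=1)
                for s in seeds])

        train_n = features("N", range(20))
        train_a = features("AMI", range(20))
        cn, ca = train_n.mean(axis=0), train_a.mean(axis=0)
        test = np.vstack([features("N", range(100, 150)),
                          features("AMI", range(100, 150))])
        truth = np.array([0] * 50 + [1] * 50)
        pred = (np.linalg.norm(test - ca, axis=1)
                < np.linalg.norm(test - cn, axis=1)).astype(int)
        assert (pred == truth).all()
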