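import itertools

import numpy as np
import pandas as pd
import pytest

import microdyn as md
from microdyn.clustering import _corr_matrix, normalize_maps


class TestSimulationConfig:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            md.SimulationConfig(
                n_classes=1,
                duration_means={g: (55.0,) for g in ("control", "patient")},
                occurrence_weights={g: (1.0,)
                                    for g in ("control", "patient")})

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ValueError, match="snr"):
            md.SimulationConfig(snr=0.0)

    def test_fractional_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            md.SimulationConfig(duration=10.001, sampling_rate=250.0)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError, match="dwell"):
            md.SimulationConfig(
                duration_means={"control": (50, 50, -1, 50, 50),
                                "patient": (50, 50, 50, 50, 50)})

    def test_roundtrip_through_dict(self):
        cfg = md.SimulationConfig(n_per_group=4, seed=9)
        assert md.SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestMakeTemplates:
    def test_normalisation_forced(self, montage64):
        t = md.make_templates(montage64, 5, seed=1)
        assert t.shape == (5, 64)
        np.testing.assert_allclose(t.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.sqrt(np.mean(t ** 2, axis=1)), 1,
                                   atol=1e-12)

    def test_pairwise_correlation_bound(self, montage64):
        for seed in range(5):
            t = md.make_templates(montage64, 5, seed=seed)
            for i, j in itertools.combinations(range(5), 2):
                assert md.abs_spatial_corr(t[i], t[j]) <= 0.7

    def test_antipodal_blobs_weakly_correlated(self, montage64):
        p = montage64.positions
        u = np.exp(-np.sum((p - [0, 1, 0]) ** 2, axis=1))
        v = np.exp(-np.sum((p - [0, -1, 0]) ** 2, axis=1))
        assert md.abs_spatial_corr(u, v) < 0.7

    def test_polarity_identity_of_outputs(self, montage64):
        t = md.make_templates(montage64, 3, seed=2)
        for row in t:
            assert md.abs_spatial_corr(row, -row) == pytest.approx(1.0)

    def test_montage_too_small_rejected(self):
        tiny = md.make_montage(3)
        with pytest.raises(ValueError):
            md.make_templates(tiny, 5)


class TestSimulateStateSequence:
    def test_labels_cover_every_sample(self):
        cfg = md.SimulationConfig(duration=20.0, seed=1)
        seq = md.simulate_state_sequence(cfg, "control", 2)
        assert seq.shape == (cfg.n_samples,)
        assert set(np.unique(seq)) <= set(range(5))

    def test_no_self_transitions(self):
        cfg = md.SimulationConfig(duration=30.0, seed=1)
        seq = md.simulate_state_sequence(cfg, "patient", 3)
        change = np.flatnonzero(np.diff(seq)) + 1
        starts = np.concatenate([[0], change])
        runs = seq[starts]
        assert np.all(np.diff(runs) != 0)

    def test_planted_group_difference_in_class_c_dwell(self):
        # class C (index 2): mean dwell 52.7 ms in patients vs 60.7 ms
        # in controls; counting dwell samples over many subjects must
        # recover the planted direction
        cfg = md.SimulationConfig(duration=30.0, seed=1)
        means = {}
        for group in ("control", "patient"):
            durations = []
            for s in range(100):
                seq = md.simulate_state_sequence(cfg, group, 1000 + s)
                f = md.true_features(seq, cfg.sampling_rate, 5)
                durations.append(f.loc[2, "mean_duration_ms"])
            means[group] = np.mean(durations)
        assert means["patient"] < means["control"]

    def test_determinism(self):
        cfg = md.SimulationConfig(duration=10.0, seed=5)
        a = md.simulate_state_sequence(cfg, "control", 7)
        b = md.simulate_state_sequence(cfg, "control", 7)
        assert np.array_equal(a, b)


class TestTrueFeatures:
    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(8)
        seq = rng.integers(0, 3, size=500)
        fs = 250.0
        f = md.true_features(seq, fs, 3)
        # independent oracle: itertools.groupby run-length counting
        runs = [(k, len(list(g))) for k, g in itertools.groupby(seq)]
        for c in range(3):
            lens = [n for k, n in runs if k == c]
            if lens:
                assert f.loc[c, "mean_duration_ms"] == pytest.approx(
                    np.mean(lens) / fs * 1000)
            assert f.loc[c, "occurrence_per_s"] == pytest.approx(
                len(lens) / (len(seq) / fs))
            assert f.loc[c, "coverage_pct"] == pytest.approx(
                100 * sum(lens) / len(seq))

    def test_coverage_sums_to_100(self):
        seq = np.random.default_rng(9).integers(0, 5, size=1000)
        f = md.true_features(seq, 250.0, 5)
        assert f["coverage_pct"].sum() == pytest.approx(100.0, abs=1e-9)


class TestRenderEeg:
    def test_noise_free_peaks_match_planted_template(self, montage16):
        cfg = md.SimulationConfig(n_channels=16, duration=20.0, snr=np.inf,
                                  template_jitter=0.0, n_mask_segments=0,
                                  seed=2)
        templates = md.make_templates(montage16, 5, seed=3)
        seq = md.simulate_state_sequence(cfg, "control", 4)
        rec, truth = md.render_eeg(seq, templates, cfg, 5, montage=montage16)
        gfp = md.compute_gfp(rec)
        peaks = md.find_gfp_peaks(gfp, rec.mask)
        assert peaks.size > 100
        for t in peaks:
            c = md.abs_spatial_corr(rec.data[:, t], templates[seq[t]])
            assert c == pytest.approx(1.0, abs=1e-9)

    def test_ground_truth_features_recomputable_exactly(self, montage16):
        cfg = md.SimulationConfig(n_channels=16, duration=15.0, seed=6)
        templates = md.make_templates(montage16, 5, seed=1)
        seq = md.simulate_state_sequence(cfg, "patient", 7)
        _, truth = md.render_eeg(seq, templates, cfg, 8, montage=montage16)
        recount = md.true_features(truth.state_sequence, cfg.sampling_rate, 5)
        pd.testing.assert_frame_equal(truth.features, recount)

    def test_output_average_referenced(self, montage16):
        cfg = md.SimulationConfig(n_channels=16, duration=10.0, seed=3)
        templates = md.make_templates(montage16, 5, seed=1)
        seq = md.simulate_state_sequence(cfg, "control", 2)
        rec, _ = md.render_eeg(seq, templates, cfg, 3, montage=montage16)
        assert np.abs(rec.data.mean(axis=0)).max() < 1e-9 * np.abs(
            rec.data).max() + 1e-12

    def test_snr_scaling(self, montage16):
        # render the same sequence at two SNRs: residual noise GFP halves
        templates = md.make_templates(montage16, 5, seed=1)
        cfg4 = md.SimulationConfig(n_channels=16, duration=10.0, snr=4.0,
                                   template_jitter=0.0, n_mask_segments=0,
                                   seed=3)
        seq = md.simulate_state_sequence(cfg4, "control", 2)
        rec4, _ = md.render_eeg(seq, templates, cfg4, 3, montage=montage16)
        cfginf = md.SimulationConfig(n_channels=16, duration=10.0, snr=np.inf,
                                     template_jitter=0.0, n_mask_segments=0,
                                     seed=3)
        recinf, _ = md.render_eeg(seq, templates, cfginf, 3,
                                  montage=montage16)
        noise = rec4.data - recinf.data
        ratio = (np.sqrt(np.mean(recinf.data ** 2))
                 / np.sqrt(np.mean(noise ** 2)))
        assert ratio == pytest.approx(4.0, rel=0.05)


class TestSimulateCohort:
    def test_fixed_seed_bit_identical(self):
        cfg = md.SimulationConfig(n_per_group=2, n_channels=16, duration=10.0,
                                  seed=12)
        r1, t1, s1 = md.simulate_cohort(cfg)
        r2, t2, s2 = md.simulate_cohort(cfg)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.data, b.data)
            assert np.array_equal(a.mask, b.mask)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.state_sequence, b.state_sequence)
        pd.testing.assert_frame_equal(s1, s2)

    def test_cohort_layout(self, cohort):
        cfg, recordings, truths, sheet = cohort
        assert len(recordings) == 2 * cfg.n_per_group
        assert sheet["group"].value_counts().to_dict() == {
            "control": cfg.n_per_group, "patient": cfg.n_per_group}
        assert sheet["subject"].is_unique

    def test_feature_recovery_within_15pct(self, fitted_cohort,
                                           planted_templates):
        """Planted mean durations are recovered by the full pipeline.

        At snr 4 over 20 subjects, per-class mean absolute error of the
        extracted mean duration must stay within 15% of the planted one.
        """
        _, recordings, truths, _, result = fitted_cohort
        gm = result.group_model
        assert gm.k_star == 5
        corr = np.abs(_corr_matrix(normalize_maps(gm.templates),
                                   normalize_maps(planted_templates)))
        match = corr.argmax(axis=1)
        assert sorted(match.tolist()) == [0, 1, 2, 3, 4]
        truth_by_subj = {t.subject: t for t in truths}
        table = result.features
        for ci in range(gm.k_star):
            pc = match[ci]
            rel_errors = []
            for subj, sub in table[table["class_index"] == ci].groupby(
                    "subject"):
                est = sub["mean_duration_ms"].iloc[0]
                planted = truth_by_subj[subj].features.loc[
                    pc, "mean_duration_ms"]
                rel_errors.append(abs(est - planted) / planted)
            assert np.mean(rel_errors) <= 0.15
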