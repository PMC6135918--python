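import itertools

import numpy as np
import pytest

import microdyn as md
from microdyn.clustering import (
    _corr_matrix, krzanowski_lai_select, modified_kmeans, normalize_maps,
)


def _orthogonal_templates(k, c, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((c, c)))
    # orthogonal vectors in the average-referenced subspace
    maps = q[:, 1:k + 1].T - q[:, 1:k + 1].T.mean(axis=1, keepdims=True)
    return normalize_maps(maps)


class TestAbsSpatialCorr:
    def test_polarity_identity(self):
        u = np.random.default_rng(0).standard_normal(16)
        assert md.abs_spatial_corr(u, -u) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        assert md.abs_spatial_corr(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, 1.0, 4.0, 3.0])
        # |r| by hand: centered u = (-1.5,-0.5,0.5,1.5),
        # centered v = (-0.5,-1.5,1.5,0.5); u.v = 3, |u||v| = 5 -> 0.6
        assert md.abs_spatial_corr(u, v) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            md.abs_spatial_corr(np.ones(4), np.arange(4.0))


class TestModifiedKmeans:
    def test_noise_free_recovery_orthogonal_templates(self):
        templates = _orthogonal_templates(3, 16, seed=1)
        rng = np.random.default_rng(2)
        signs = rng.choice([-1.0, 1.0], size=60)
        truth = rng.integers(0, 3, size=60)
        maps = templates[truth] * signs[:, None]
        t, labels, disp = md.modified_kmeans(maps, 3, n_restarts=5, seed=3)
        assert disp == pytest.approx(0.0, abs=1e-9)
        fit = np.abs(_corr_matrix(normalize_maps(maps), t))
        assert np.allclose(fit.max(axis=1), 1.0)

    def test_k1_matches_eigenvector_oracle(self):
        rng = np.random.default_rng(4)
        maps = normalize_maps(rng.standard_normal((40, 12)))
        t, labels, disp = md.modified_kmeans(maps, 1, n_restarts=1, seed=0)
        s = maps.T @ maps
        w, v = np.linalg.eigh(s)
        top = v[:, -1]
        assert md.abs_spatial_corr(t[0], top) == pytest.approx(1.0, abs=1e-9)
        oracle_disp = np.sum(1 - np.abs(maps @ top) / (
            12 * np.sqrt(np.mean(top ** 2))))
        assert disp == pytest.approx(float(oracle_disp), abs=1e-8)

    def test_exhaustive_oracle_8_maps_k2(self):
        rng = np.random.default_rng(5)
        maps = normalize_maps(rng.standard_normal((8, 10)))
        _, _, disp = md.modified_kmeans(maps, 2, n_restarts=20, seed=6)
        # every labeling, with the optimal (eigenvector) template per cluster
        best = np.inf
        for assign in itertools.product([0, 1], repeat=8):
            assign = np.array(assign)
            if len(set(assign)) < 2:
                continue
            total = 0.0
            for j in (0, 1):
                members = maps[assign == j]
                s = members.T @ members
                w, v = np.linalg.eigh(s)
                top = v[:, -1] / np.sqrt(np.mean(v[:, -1] ** 2))
                total += np.sum(1 - np.abs(members @ top) / 10)
            best = min(best, total)
        assert disp <= best + 1e-9

    def test_dispersion_monotone_descent(self):
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((120, 16))
        _, _, _, history = md.modified_kmeans(
            maps, 4, n_restarts=3, seed=8, return_history=True)
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-9)

    def test_polarity_invariance_of_clustering(self):
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((50, 12))
        flip = rng.choice([-1.0, 1.0], size=50)
        _, l1, d1 = md.modified_kmeans(maps, 3, n_restarts=4, seed=10)
        _, l2, d2 = md.modified_kmeans(maps * flip[:, None], 3,
                                       n_restarts=4, seed=10)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert np.array_equal(l1, l2)

    def test_k_exceeding_maps_rejected(self):
        maps = np.random.default_rng(11).standard_normal((4, 8))
        with pytest.raises(ValueError):
            md.modified_kmeans(maps, 5)


class TestKrzanowskiLai:
    def test_sharp_elbow_selected(self):
        W = {2: 100.0, 3: 60.0, 4: 30.0, 5: 10.0, 6: 9.5, 7: 9.2, 8: 9.0,
             9: 8.8, 10: 8.6, 11: 8.4, 12: 8.2}
        k, kl = krzanowski_lai_select(W, n_channels=64)
        assert k == 5
        # independent evaluation of the formula at every k
        p = 64.0
        diff = {k_: (k_ - 1) ** (2 / p) * W[k_ - 1] - k_ ** (2 / p) * W[k_]
                for k_ in range(3, 13)}
        oracle = {k_: abs(diff[k_]) / abs(diff[k_ + 1])
                  for k_ in range(3, 12)}
        assert max(oracle, key=oracle.get) == 5
        for k_ in oracle:
            assert kl[k_] == pytest.approx(oracle[k_])

    def test_linear_decline_is_deterministic_argmax(self):
        W = {k: 130.0 - 10 * k for k in range(2, 13)}
        k1, kl1 = krzanowski_lai_select(W, n_channels=32)
        k2, kl2 = krzanowski_lai_select(W, n_channels=32)
        assert k1 == k2 == max(kl1, key=lambda k: (kl1[k], -k))

    def test_missing_w_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            krzanowski_lai_select({2: 1.0, 3: 0.5}, n_channels=16)

    def test_zero_denominator_excluded(self):
        # flat tail makes DIFF vanish: those k drop out of the argmax
        W = {2: 100.0, 3: 50.0, 4: 20.0, 5: 10.0}
        W.update({k: 10.0 * k ** (-2 / 8) for k in range(6, 13)})
        k, kl = krzanowski_lai_select(W, n_channels=8)
        assert k in kl


class TestClusterSubject:
    def _noise_free_subject(self, montage, n_classes, seed=21):
        cfg = md.SimulationConfig(
            n_per_group=1, n_channels=montage.n_channels, duration=40.0,
            n_classes=n_classes, snr=1e9, template_jitter=0.0,
            n_mask_segments=0, seed=seed,
            duration_means={g: tuple([55.0] * n_classes)
                            for g in ("control", "patient")},
            occurrence_weights={g: tuple([1.0] * n_classes)
                                for g in ("control", "patient")})
        templates = md.make_templates(montage, n_classes, seed=seed)
        seq = md.simulate_state_sequence(cfg, "control", seed)
        rec, truth = md.render_eeg(seq, templates, cfg, seed + 1,
                                   montage=montage, subject="NF")
        return rec, truth

    def test_noise_free_four_classes_recovered(self, montage64):
        rec, truth = self._noise_free_subject(montage64, 4)
        model = md.cluster_subject(rec, seed=0, n_restarts=5)
        assert model.k_star == 4
        corr = np.abs(_corr_matrix(normalize_maps(truth.templates),
                                   normalize_maps(model.templates)))
        assert np.allclose(corr.max(axis=1), 1.0, atol=1e-6)

    def test_seed_stability_of_k_star(self, cohort):
        _, recordings, _, _ = cohort
        rec = md.bandpass_and_reref(recordings[0])
        # at the default restart count the selection is seed-stable
        m1 = md.cluster_subject(rec, seed=1)
        m2 = md.cluster_subject(rec, seed=99)
        assert m1.k_star == m2.k_star

    def test_too_few_peaks_reports_minimum(self, montage16):
        rec = md.Recording(subject="s", group="control", sampling_rate=250.0,
                           data=np.random.default_rng(0).standard_normal(
                               (16, 120)),
                           mask=None, montage=montage16)
        rec.data -= rec.data.mean(axis=0)
        with pytest.raises(ValueError, match="at least"):
            md.cluster_subject(rec, min_peaks=10 ** 6)

    def test_w_non_increasing_in_k(self, fitted_cohort):
        *_, result = fitted_cohort
        for model in result.subject_models[:4]:
            ks = sorted(model.W_by_k)
            w = [model.W_by_k[k] for k in ks]
            assert all(w[i + 1] <= w[i] + 1e-9 for i in range(len(w) - 1))


class TestClusterGroup:
    def test_identical_subjects_recover_shared_templates(self, montage16):
        shared = md.make_templates(montage16, 5, seed=31)
        models = [
            md.SubjectClusterModel(subject=f"s{i}", W_by_k={}, KL_by_k={},
                                   k_star=5, templates=shared.copy())
            for i in range(6)
        ]
        gm = md.cluster_group(models, seed=1, n_restarts=5)
        assert gm.k_star == 5
        corr = np.abs(_corr_matrix(normalize_maps(shared),
                                   normalize_maps(gm.templates)))
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-9)

    def test_two_subject_assignment_matches_exhaustive(self, montage16):
        rng = np.random.default_rng(32)
        t1 = normalize_maps(rng.standard_normal((2, 16)))
        t2 = normalize_maps(rng.standard_normal((2, 16)))
        models = [
            md.SubjectClusterModel(subject="a", W_by_k={}, KL_by_k={},
                                   k_star=2, templates=t1),
            md.SubjectClusterModel(subject="b", W_by_k={}, KL_by_k={},
                                   k_star=2, templates=t2),
        ]
        gm = md.cluster_group(models, candidate_range=(2, 2), seed=2,
                              n_restarts=10)
        group_templates = normalize_maps(gm.templates)
        for subj, templates in (("a", t1), ("b", t2)):
            got = gm.assignment[subj]
            corr = np.abs(_corr_matrix(templates, group_templates))
            best = max(
                ((perm, corr[0, perm[0]] + corr[1, perm[1]])
                 for perm in itertools.permutations(range(2))),
                key=lambda x: x[1])
            assert corr[0, got[0]] + corr[1, got[1]] == pytest.approx(
                best[1], abs=1e-12)

    def test_distinctness_constraint_held(self, fitted_cohort):
        *_, result = fitted_cohort
        gm = result.group_model
        for subj, assign in gm.assignment.items():
            ki = len(assign)
            assert len(set(assign.tolist())) == min(ki, gm.k_star)


class TestCanonicalLabeling:
    def test_identity_on_references(self, montage64):
        refs = md.canonical_references(montage64)
        gm = md.GroupMicrostateModel(k_star=5, templates=refs.copy())
        gm = md.canonical_labeling(gm, refs)
        assert gm.canonical_labels == ["A", "B", "C", "D", "E"]

    def test_polarity_ignored(self, montage64):
        refs = md.canonical_references(montage64)
        gm = md.GroupMicrostateModel(k_star=5, templates=-refs.copy())
        gm = md.canonical_labeling(gm, refs)
        assert gm.canonical_labels == ["A", "B", "C", "D", "E"]

    def test_shuffle_matches_permutation_oracle(self, montage64):
        refs = md.canonical_references(montage64)
        rng = np.random.default_rng(33)
        perm = rng.permutation(5)
        templates = refs[perm] + 0.05 * rng.standard_normal(refs.shape)
        gm = md.GroupMicrostateModel(k_star=5, templates=templates)
        gm = md.canonical_labeling(gm, refs)
        corr = np.abs(_corr_matrix(normalize_maps(templates), refs))
        best_perm = max(itertools.permutations(range(5)),
                        key=lambda p: sum(corr[i, p[i]] for i in range(5)))
        expected = [chr(ord("A") + j) for j in best_perm]
        assert gm.canonical_labels == expected

    def test_surplus_labeled_by_explained_variance(self, montage16):
        refs = md.canonical_references(montage16)[:2]
        templates = md.make_templates(montage16, 4, seed=34)
        gm = md.GroupMicrostateModel(k_star=4, templates=templates)
        gm = md.canonical_labeling(gm, refs, reference_labels=["A", "B"],
                                   ev_per_class=np.array([1, 2, 3, 4.0]))
        assert sorted(gm.canonical_labels) == ["A", "B", "C", "D"]


class TestGlobalExplainedVariance:
    def test_exact_template_maps_give_100(self, montage16):
        rec, _ = TestClusterSubject()._noise_free_subject(montage16, 3)
        model = md.GroupMicrostateModel(
            k_star=3, templates=md.make_templates(montage16, 3, seed=21))
        # noise-free rendering: every peak map is proportional to a template
        assert md.global_explained_variance(rec, model) == pytest.approx(
            100.0, abs=1e-6)

    def test_matches_brute_force_formula(self, fitted_cohort):
        _, recordings, _, _, result = fitted_cohort
        rec = md.bandpass_and_reref(recordings[0])
        gm = result.group_model
        gev = md.global_explained_variance(rec, gm)
        gfp_series = md.compute_gfp(rec)
        peaks = md.find_gfp_peaks(gfp_series, rec.mask)
        num = den = 0.0
        templates = normalize_maps(gm.templates)
        for t in peaks:
            v = rec.data[:, t]
            g = gfp_series.gfp[t]
            corr = [float((v - v.mean()) @ tm / (
                np.linalg.norm(v - v.mean()) * np.linalg.norm(tm)))
                for tm in templates]
            c = max(corr, key=abs)
            num += (g * c) ** 2
            den += g ** 2
        assert gev == pytest.approx(100 * num / den, abs=1e-9)
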