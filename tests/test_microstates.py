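"""Microstate clustering, backfitting, and statistics against planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import expon

from restwise.eeg_io import Recording
from restwise.microstates import (
    MicrostateSegmentation,
    ModifiedKMeans,
    TopographySet,
    aggregate_templates,
    align_to,
    backfit,
    gfp,
    gfp_peaks,
    microstate_stats,
    modified_kmeans,
    spatial_correlation,
)
from restwise.synthetic_data import (
    TraitSpec,
    _draw_labels,
    default_montage,
    make_templates,
    simulate_microstate_eeg,
)

from conftest import make_recording


class TestGfp:
    def test_equal_potentials_give_zero(self):
        assert np.allclose(gfp(np.full((4, 10), 3.0)), 0.0)

    def test_two_channel_unit_frame(self):
        assert gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    def test_matches_per_frame_std_loop(self, rng):
        data = rng.normal(size=(8, 40))
        got = gfp(data)
        expected = np.array([data[:, t].std() for t in range(40)])  # oracle
        assert np.allclose(got, expected, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.zeros((1, 10)))


class TestGfpPeaks:
    def test_monotone_has_no_peaks(self):
        assert gfp_peaks(np.arange(10.0)).size == 0

    def test_simple_trace(self):
        assert list(gfp_peaks(np.array([0, 1, 0, 2, 0.0]))) == [1, 3]

    def test_plateau_resolved_to_first_sample(self):
        assert list(gfp_peaks(np.array([0, 2, 2, 2, 0.0]))) == [1]

    def test_rectified_oscillation_peak_count(self):
        t = np.arange(1000) / 1000.0
        trace = np.abs(np.sin(2 * np.pi * 10 * t))  # 20 humps per second
        n = gfp_peaks(trace).size
        assert 18 <= n <= 21


class TestModifiedKMeans:
    def test_sign_flipped_single_topography(self, rng):
        _, pos = default_montage(16)
        base = make_templates(pos, 1)[0]
        signs = rng.choice([-1.0, 1.0], size=50)
        maps = np.outer(signs, base) + 0  # pure sign flips
        model = ModifiedKMeans(k=1, n_restarts=5, seed=0).fit(maps)
        c = abs(spatial_correlation(model.maps_, base[None, :])[0, 0])
        assert c == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_four_class_recovery(self, rng):
        _, pos = default_montage(32)
        truth = make_templates(pos, 4)
        idx = rng.integers(0, 4, size=400)
        amps = rng.uniform(0.5, 2.0, size=400) * rng.choice([-1, 1], size=400)
        maps = truth[idx] * amps[:, None]
        model = ModifiedKMeans(k=4, n_restarts=20, seed=1).fit(maps)
        c = np.abs(spatial_correlation(truth, model.maps_))
        r, col = linear_sum_assignment(-c)
        assert np.all(c[r, col] >= 0.999)

    def test_best_restart_dominates_ensemble(self, rng):
        maps = rng.normal(size=(60, 16))
        model = ModifiedKMeans(k=3, n_restarts=10, seed=2).fit(maps)
        assert model.gev_ >= model.gev_per_restart_.max() - 1e-12

    def test_deterministic_given_seed(self, rng):
        maps = rng.normal(size=(50, 12))
        a = ModifiedKMeans(k=4, n_restarts=5, seed=7).fit(maps)
        b = ModifiedKMeans(k=4, n_restarts=5, seed=7).fit(maps)
        assert np.array_equal(a.maps_, b.maps_)
        assert a.gev_ == b.gev_

    def test_k_exceeding_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="at least k"):
            ModifiedKMeans(k=5).fit(rng.normal(size=(3, 8)))

    def test_zero_map_rejected(self):
        maps = np.zeros((10, 8))
        with pytest.raises(ValueError, match="zero map"):
            ModifiedKMeans(k=2).fit(maps)


class TestAggregation:
    @staticmethod
    def _sets(rng, n_sets=6, noise=0.0):
        labels, pos = default_montage(16)
        truth = make_templates(pos, 4)
        sets = []
        for i in range(n_sets):
            maps = truth + noise * rng.normal(size=truth.shape)
            order = rng.permutation(4)
            signs = rng.choice([-1.0, 1.0], size=4)
            sets.append(TopographySet(maps[order] * signs[:, None], labels))
        return sets, truth

    def test_identical_sets_recovered_up_to_sign_and_order(self, rng):
        sets, truth = self._sets(rng, n_sets=10, noise=0.0)
        agg = aggregate_templates(sets, 4, seed=3)
        c = np.abs(spatial_correlation(truth, agg.maps))
        r, col = linear_sum_assignment(-c)
        assert np.all(c[r, col] >= 1 - 1e-9)

    def test_noisy_sets_average_toward_truth(self, rng):
        sets, truth = self._sets(rng, n_sets=12, noise=0.3)
        agg = aggregate_templates(sets, 4, seed=3)
        c_agg = np.abs(spatial_correlation(truth, agg.maps))
        r, col = linear_sum_assignment(-c_agg)
        agg_match = c_agg[r, col].mean()
        indiv = []
        for s in sets:
            c = np.abs(spatial_correlation(truth, s.maps))
            ri, ci = linear_sum_assignment(-c)
            indiv.append(c[ri, ci].mean())
        assert agg_match >= np.mean(indiv)

    def test_invariant_to_member_row_order(self, rng):
        sets, _ = self._sets(rng, n_sets=4, noise=0.1)
        flipped = [
            TopographySet(s.maps[::-1].copy(), s.channel_labels) for s in sets
        ]
        a = aggregate_templates(sets, 4, seed=5)
        b = aggregate_templates(flipped, 4, seed=5)
        c = np.abs(spatial_correlation(a.maps, b.maps))
        r, col = linear_sum_assignment(-c)
        assert np.all(c[r, col] >= 1 - 1e-9)

    def test_montage_mismatch_rejected(self, rng):
        sets, _ = self._sets(rng, n_sets=2)
        other = TopographySet(sets[0].maps, [f"X{i}" for i in range(16)])
        with pytest.raises(ValueError, match="montage"):
            aggregate_templates([sets[0], other], 4)


class TestBackfit:
    @staticmethod
    def _setup(rng, n=500):
        labels, pos = default_montage(16)
        truth = make_templates(pos, 4)
        topo = TopographySet(truth, labels)
        env = 1.0 + rng.random(n)
        return labels, truth, topo, env

    def test_scaled_template_fully_labeled(self, rng):
        labels, truth, topo, env = self._setup(rng)
        rec = Recording(truth[2][:, None] * env[None, :], 250.0, labels)
        seg = backfit(rec, topo)
        assert np.all(seg.labels == 2)

    def test_polarity_ignored(self, rng):
        labels, truth, topo, env = self._setup(rng)
        rec = Recording(-truth[2][:, None] * env[None, :], 250.0, labels)
        assert np.all(backfit(rec, topo).labels == 2)

    def test_scale_invariance_of_labels(self, rng):
        labels, pos = default_montage(16)
        topo = TopographySet(make_templates(pos, 4), labels)
        data = rng.normal(size=(16, 300))
        rec1 = Recording(data, 250.0, labels)
        rec2 = Recording(3.7 * data, 250.0, labels)
        s1, s2 = backfit(rec1, topo), backfit(rec2, topo)
        assert np.array_equal(s1.labels, s2.labels)
        assert np.allclose(s2.gfp_trace, 3.7 * s1.gfp_trace)

    def test_zero_gfp_frames_carry_previous_label(self, rng):
        labels, truth, topo, env = self._setup(rng, n=10)
        data = truth[1][:, None] * np.ones((1, 10))
        data[:, 4] = 0.0  # flat frame
        seg = backfit(Recording(data, 250.0, labels), topo)
        assert seg.labels[4] == seg.labels[3]
        assert seg.n_zero_gfp == 1

    def test_montage_mismatch_rejected(self, rng):
        labels, truth, topo, env = self._setup(rng)
        other = [f"X{i}" for i in range(16)]
        rec = make_recording(rng.normal(size=(16, 20)), labels=other)
        with pytest.raises(ValueError, match="montage"):
            backfit(rec, topo)


class TestMicrostateStats:
    def test_two_block_labels(self):
        seg = MicrostateSegmentation(
            labels=np.r_[np.zeros(100, int), np.ones(100, int)],
            srate=1000.0,
            gfp_trace=np.ones(200),
            n_classes=2,
        )
        stats = microstate_stats(seg)
        assert list(stats["coverage_pct"]) == [50.0, 50.0]
        assert list(stats["occurrence"]) == [5.0, 5.0]  # 1 run per 0.2 s
        assert stats["duration_ms"].isna().all()  # both runs touch boundaries

    def test_single_class_recording(self):
        seg = MicrostateSegmentation(
            labels=np.zeros(100, int), srate=100.0,
            gfp_trace=np.ones(100), n_classes=3,
        )
        stats = microstate_stats(seg)
        assert stats.loc[0, "coverage_pct"] == 100.0
        assert list(stats.loc[1:, "coverage_pct"]) == [0.0, 0.0]
        assert list(stats.loc[1:, "occurrence"]) == [0.0, 0.0]

    def test_coverage_sums_to_100(self, rng):
        seg = MicrostateSegmentation(
            labels=rng.integers(0, 4, 997), srate=250.0,
            gfp_trace=np.ones(997), n_classes=4,
        )
        assert microstate_stats(seg)["coverage_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_coverage_identity_on_planted_dwell(self):
        traits = TraitSpec()
        rng = np.random.default_rng(5)
        labels = _draw_labels(traits, 45000, 250.0, rng)
        seg = MicrostateSegmentation(labels, 250.0, np.ones(45000), 4)
        stats = microstate_stats(seg)
        # occurrence (1/s) × duration (s) ≈ coverage fraction, up to
        # boundary runs excluded from the duration mean
        for _, r in stats.iterrows():
            lhs = r.occurrence * r.duration_ms / 1000.0
            assert lhs == pytest.approx(r.coverage_pct / 100.0, rel=0.02)

    def test_duration_estimator_unbiased_over_replicates(self):
        """Mean estimated dwell matches the discretized-exponential mean."""
        traits = TraitSpec()
        srate = 250.0
        # oracle: E[samples] for round(max(Exp(80), 10) * srate/1000), ≥ 1
        mean_ms, min_ms = 80.0, 10.0
        upper = 3000  # samples; exponential tail beyond is ~ e^-150
        e_samples = 0.0
        dist = expon(scale=mean_ms)
        for n in range(1, upper):
            lo_ms = max((n - 0.5) * 1000.0 / srate, 0.0)
            hi_ms = (n + 0.5) * 1000.0 / srate
            p = dist.cdf(hi_ms) - dist.cdf(lo_ms)
            if hi_ms <= min_ms:  # clipped to the floor → rounds to floor bin
                p = 0.0
            elif lo_ms < min_ms:
                p = dist.cdf(hi_ms)  # all clipped mass rounds here
            e_samples += n * p
        expected_ms = e_samples * 1000.0 / srate

        est = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            labels = _draw_labels(traits, 7500, srate, rng)  # 30 s
            seg = MicrostateSegmentation(labels, srate, np.ones(7500), 4)
            est.append(microstate_stats(seg)["duration_ms"].mean())
        est = np.asarray(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - expected_ms) < 3 * se + 1.0


class TestPolarityAndScaleInvariance:
    def test_full_polarity_flip_invariance(self):
        rec, truth = simulate_microstate_eeg(duration_s=20.0, srate=250.0,
                                             n_channels=16, seed=9)
        neg = rec.copy_with(-rec.data)
        trace, ntrace = gfp(rec), gfp(neg)
        assert np.allclose(trace, ntrace)
        peaks = gfp_peaks(trace)
        t1, _ = modified_kmeans(rec.data[:, peaks].T, 4, rec.channel_labels, seed=3)
        t2, _ = modified_kmeans(neg.data[:, peaks].T, 4, rec.channel_labels, seed=3)
        c = np.abs(spatial_correlation(t1.maps, t2.maps))
        r, col = linear_sum_assignment(-c)
        assert np.all(c[r, col] >= 1 - 1e-9)
        s1 = backfit(rec, t1)
        s2 = backfit(neg, t1)
        assert np.array_equal(s1.labels, s2.labels)
        pd.testing.assert_frame_equal(microstate_stats(s1), microstate_stats(s2))


def test_align_to_orders_and_signs(rng):
    labels, pos = default_montage(16)
    truth = make_templates(pos, 4)
    ref = TopographySet(truth, labels)
    shuffled = TopographySet(truth[[2, 0, 3, 1]] * np.array([-1, 1, -1, 1])[:, None], labels)
    aligned = align_to(ref, shuffled)
    assert np.allclose(aligned.maps, truth, atol=1e-9)


def test_template_set_roundtrips_json(tmp_path, rng):
    labels, pos = default_montage(16)
    topo = TopographySet(make_templates(pos, 4), labels, source="grand_mean", gev=0.7)
    back = TopographySet.from_json(topo.to_json(tmp_path / "t.json"))
    assert np.allclose(back.maps, topo.maps)
    assert back.channel_labels == labels and back.source == "grand_mean"
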