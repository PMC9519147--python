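"""Functional unit typing: rates, filtering, features, clustering, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cctype import synth, unit_typing as ut
from cctype.core import InvalidConfigError, RateTrace, SpikeTrain, UnitProfile


class TestInstantaneousRate:
    def test_single_spike_peak_matches_gaussian(self):
        rt = ut.instantaneous_rate(SpikeTrain(0, np.array([5.0])), 10.0, kernel_sd=0.010)
        assert abs(rt.rate.max() - 1.0 / (0.010 * np.sqrt(2 * np.pi))) < 0.05
        assert abs(rt.times[np.argmax(rt.rate)] - 5.0) < 1e-9

    def test_empty_train_zero_trace(self):
        rt = ut.instantaneous_rate(SpikeTrain(0, np.empty(0)), 5.0)
        assert np.allclose(rt.rate, 0.0)

    def test_integral_conserves_spike_count(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(1.0, 99.0, 100))
        rt = ut.instantaneous_rate(SpikeTrain(0, times), 100.0)
        integral = rt.rate.sum() / rt.fs
        assert abs(integral - 100) < 0.1

    def test_integral_conservation_across_population(self):
        trials = synth.generate_trial_table(n_per_condition=1, seed=4)
        units, _ = synth.generate_units(trials, mix={1: 2, 3: 2}, rate_distribution_mean=5.0, seed=5)
        for u in units:
            rt = ut.instantaneous_rate(u, trials.end_time())
            assert abs(rt.rate.sum() / rt.fs - u.n_spikes) <= 0.001 * max(u.n_spikes, 1)


class TestFilterUnits:
    def test_planted_artifacts_removed(self, default_session):
        retained, report = ut.filter_units(default_session["units"], default_session["duration"])
        assert len(retained) == 91
        flags = default_session["gt"].artifact_flags
        removed_ids = set(report["unit_id"])
        assert removed_ids == {u for u, f in flags.items() if f != "clean"}
        assert report["reason"].str.contains("outlier").sum() == 3
        assert report["reason"].str.contains("duplicate").sum() == 1

    def test_clean_population_untouched(self, default_session):
        retained, report = ut.filter_units(default_session["clean"], default_session["duration"])
        assert retained == default_session["clean"]
        assert len(report) == 0

    def test_exact_copy_removed(self):
        rng = np.random.default_rng(1)
        trains = [SpikeTrain(i, np.sort(rng.uniform(0, 100, 200))) for i in range(4)]
        trains.append(SpikeTrain(4, trains[0].spike_times.copy()))
        retained, report = ut.filter_units(trains, 100.0)
        assert len(retained) == 4
        assert report["unit_id"].tolist() == [4]  # fewer-or-equal spikes: later unit removed

    def test_too_few_units_rejected(self):
        with pytest.raises(InvalidConfigError):
            ut.filter_units([SpikeTrain(0, np.array([1.0]))] * 2, 10.0)


def _const_rate_trace(values, fs=100.0):
    t = np.arange(values.size) / fs
    return RateTrace(0, t, values, 0.010)


class TestNormalizeRate:
    def _trials(self):
        import pandas as pd

        from cctype.core import TrialTable

        return TrialTable(
            pd.DataFrame(
                {"trial_id": [0, 1], "run_id": [0, 0], "condition": ["search", "add"],
                 "cue_onset": [5.0, 15.0], "task_onset": [6.0, 16.0], "task_offset": [11.0, 21.0]}
            )
        )

    def test_constant_rate_zero_percent(self):
        rt = _const_rate_trace(np.full(3000, 4.0))
        ep = ut.normalize_rate(rt, self._trials())
        assert np.allclose(ep.data, 0.0)
        assert ep.baseline_hz == pytest.approx(4.0)

    def test_doubled_rate_plus_100(self):
        values = np.full(3000, 2.0)
        t = np.arange(3000) / 100.0
        in_trial = ((t >= 5.0) & (t < 11.0)) | ((t >= 15.0) & (t < 21.0))
        values[in_trial] = 4.0
        ep = ut.normalize_rate(_const_rate_trace(values), self._trials())
        task = ep.times >= 0.0
        assert np.allclose(ep.data[:, task], 100.0)

    def test_low_baseline_flagged(self):
        ep = ut.normalize_rate(_const_rate_trace(np.full(3000, 0.01)), self._trials())
        assert ep.low_baseline

    def test_type1_gain3_recovers_200pct(self):
        """Search-selective unit with gain 3: search epochs ~ +200%, others ~ 0%."""
        profile = {1: UnitProfile(1, {"search": 3.0, "add": 1.0, "past": 1.0,
                                      "future": 1.0, "rest": 1.0}, ramp_tau=0.01)}
        trials = synth.generate_trial_table(seed=8)
        units, _ = synth.generate_units(
            trials, mix={1: 1}, rate_distribution_mean=20.0, basal_sigma=0.0,
            profiles=profile, seed=9,
        )
        rt = ut.instantaneous_rate(units[0], trials.end_time())
        ep = ut.normalize_rate(rt, trials, span=(-0.5, 3.0))
        window = (ep.times >= 1.0) & (ep.times < 3.0)
        by_cond = {c: ep.data[ep.conditions == c][:, window].mean() for c in np.unique(ep.conditions)}
        assert by_cond["search"] == pytest.approx(200.0, abs=20.0)
        for c in ("add", "past", "future", "rest"):
            assert by_cond[c] == pytest.approx(0.0, abs=15.0)


class TestFeatureVectors:
    def _epochs(self, n_units=2, fs=100.0, identical=True):
        rng = np.random.default_rng(2)
        from cctype.core import EpochedResponse

        times = -0.5 + np.arange(int(3.5 * fs)) / fs
        conds = np.array(["search", "add", "past", "future", "rest"] * 2)
        out = []
        for u in range(n_units):
            data = rng.random((10, times.size)) if not identical else np.tile(
                np.sin(np.arange(times.size) / 7.0), (10, 1)
            )
            out.append(EpochedResponse(data.copy(), times, conds, np.arange(10), label=u))
        return out

    def test_vector_length(self):
        ids, F = ut.build_feature_vectors(self._epochs(), span=(0.0, 3.0))
        assert F.shape == (2, 5 * 300)

    def test_condition_invariant_unit_tiles(self):
        ids, F = ut.build_feature_vectors(self._epochs(identical=True))
        v = F[0]
        seg = v[: v.size // 5]
        assert np.allclose(v, np.tile(seg, 5))

    def test_identical_epochs_identical_vectors(self):
        ids, F = ut.build_feature_vectors(self._epochs(identical=True))
        assert np.allclose(F[0], F[1])

    def test_missing_condition_excluded(self):
        eps = self._epochs()
        eps[1].conditions = np.array(["search"] * 10)
        with pytest.warns(UserWarning, match="no add trials"):
            ids, F = ut.build_feature_vectors(eps)
        assert ids == [0]


class TestDistanceMatrix:
    def test_identical_anticorrelated_uncorrelated(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(500)
        w = rng.standard_normal(500)
        F = np.vstack([v, v, -v, w])
        d, kept = ut.correlation_distance_matrix(F)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert d[0, 3] == pytest.approx(1.0, abs=0.2)  # independent noise: r ~ 0

    def test_constant_vector_excluded(self):
        F = np.vstack([np.ones(100), np.arange(100.0), np.cos(np.arange(100.0))])
        with pytest.warns(UserWarning, match="constant"):
            d, kept = ut.correlation_distance_matrix(F)
        assert list(kept) == [1, 2]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            np.float64, (5, 40),
            elements=st.floats(-100, 100, allow_nan=False),
        ).filter(lambda a: (a.std(axis=1) > 1e-6).all())
    )
    def test_metric_properties(self, F):
        d, kept = ut.correlation_distance_matrix(F)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 2).all()


class TestClustering:
    def test_two_separated_clouds(self):
        rng = np.random.default_rng(4)
        base1, base2 = rng.standard_normal(300), rng.standard_normal(300)
        F = np.vstack(
            [base1 + 0.1 * rng.standard_normal(300) for _ in range(5)]
            + [base2 + 0.1 * rng.standard_normal(300) for _ in range(5)]
        )
        d, _ = ut.correlation_distance_matrix(F)
        res = ut.cluster_units(d)
        assert res.n_clusters == 2
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_equal_distances_tie_case(self):
        # all merges at height d; the 0.9*d cut lies below every merge, so
        # every unit remains a singleton (hand-trace of the merge tree, n=4)
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        res = ut.cluster_units(d)
        assert res.n_clusters == 4

    def test_merge_heights_nondecreasing_and_labels_by_size(self, default_session):
        retained, _ = ut.filter_units(default_session["units"], default_session["duration"])
        ids, F, _ = ut.unit_feature_matrix(
            retained[:30], default_session["trials"], default_session["duration"]
        )
        d, _ = ut.correlation_distance_matrix(F)
        res = ut.cluster_units(d)
        assert (np.diff(res.merges[:, 2]) >= -1e-12).all()
        sizes = res.sizes
        assert (np.diff(sizes) <= 0).all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        F = np.vstack([rng.standard_normal(200) + 3 * (i // 4) for i in range(12)])
        d, _ = ut.correlation_distance_matrix(F)
        res = ut.cluster_units(d)
        perm = rng.permutation(12)
        res_p = ut.cluster_units(d[np.ix_(perm, perm)])
        _, identical = ut.match_partitions(res_p.labels, res.labels[perm])
        assert identical

    def test_single_unit_rejected(self):
        with pytest.raises(InvalidConfigError):
            ut.cluster_units(np.zeros((1, 1)))


class TestMatchPartitions:
    def test_permuted_ids_identical(self):
        a = np.array([1, 1, 2, 2, 3])
        b = np.array([3, 3, 1, 1, 2])
        mapping, identical = ut.match_partitions(a, b)
        assert identical
        assert mapping == {1: 3, 2: 1, 3: 2}

    def test_one_unit_moved_not_identical(self):
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 2, 2])
        _, identical = ut.match_partitions(a, b)
        assert not identical

    def test_crossed_pairs_brute_force(self):
        # {AB|CD} vs {AC|BD}: both possible matchings overlap exactly 2 units
        a = np.array([1, 1, 2, 2])
        b = np.array([1, 2, 1, 2])
        mapping, identical = ut.match_partitions(a, b)
        overlap = sum(np.sum((a == ka) & (b == kb)) for ka, kb in mapping.items())
        assert overlap == 2 and not identical


class TestLooStability:
    def test_three_unit_hand_trace(self):
        # d(0,1)=0.1, d(*,2)=1.0; full partition {0,1},{2}.
        # leaving out 0 or 1: two distant singletons -> matches restriction;
        # leaving out 2: the 0.9*max cut falls below the only merge, splitting
        # the pair that the full partition kept together -> not identical.
        d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = ut.loo_stability(None, precomputed_distance=d)
        assert res.n_iterations == 3
        assert res.n_identical == 2
        assert res.rate == pytest.approx(2 / 3)

    def test_zero_noise_perfectly_stable(self):
        profiles = {
            i + 1: UnitProfile(i + 1, {c: (5.0 if c == cond else 1.0) for c in
                                       ("search", "add", "past", "future", "rest")})
            for i, cond in enumerate(("search", "add", "past", "future"))
        }
        trials = synth.generate_trial_table(n_per_condition=4, seed=20)
        units, _ = synth.generate_units(
            trials, mix={1: 4, 2: 4, 3: 4, 4: 4}, rate_distribution_mean=20.0,
            basal_sigma=0.3, noise_cv=0.0, profiles=profiles, seed=21,
        )
        ids, F, _ = ut.unit_feature_matrix(units, trials, trials.end_time())
        res = ut.loo_stability(F, unit_ids=ids)
        assert res.rate == 1.0


class TestNoiseKnob:
    @staticmethod
    def _ari(cv, seed=21):
        from sklearn.metrics import adjusted_rand_score

        profiles = {
            i + 1: UnitProfile(i + 1, {c: (5.0 if c == cond else 1.0) for c in
                                       ("search", "add", "past", "future", "rest")})
            for i, cond in enumerate(("search", "add", "past", "future"))
        }
        trials = synth.generate_trial_table(n_per_condition=6, seed=seed)
        units, gt = synth.generate_units(
            trials, mix={1: 6, 2: 6, 3: 6, 4: 6}, rate_distribution_mean=20.0,
            basal_sigma=0.3, noise_cv=cv, profiles=profiles, seed=seed + 1,
        )
        ids, F, _ = ut.unit_feature_matrix(units, trials, trials.end_time())
        d, kept = ut.correlation_distance_matrix(F, ids)
        res = ut.cluster_units(d)
        truth = [gt.unit_types[ids[i]] for i in kept]
        return adjusted_rand_score(truth, res.labels)

    def test_zero_noise_perfect_recovery(self):
        assert self._ari(0.0) == 1.0

    def test_ari_nonincreasing_in_noise(self):
        aris = [self._ari(cv) for cv in (0.0, 1.0, 4.0, 12.0)]
        assert all(a >= b - 1e-12 for a, b in zip(aris, aris[1:]))
        assert aris[-1] < aris[0]  # the knob actually degrades recovery


class TestSampleRateInvariance:
    def test_halved_feature_rate_same_partition(self, default_session):
        retained, _ = ut.filter_units(default_session["units"], default_session["duration"])
        subset = retained[::3]
        trials, dur = default_session["trials"], default_session["duration"]
        results = []
        for fs in (1000.0, 500.0):
            ids, F, _ = ut.unit_feature_matrix(subset, trials, dur, feature_fs=fs)
            d, _ = ut.correlation_distance_matrix(F, ids)
            results.append(ut.cluster_units(d, unit_ids=ids).labels)
        _, identical = ut.match_partitions(results[0], results[1])
        assert identical
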