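import numpy as np
import pytest

from retell import transformation as tr
from retell.io_formats import AnalysisConfig, Label, MicroSegment, \
    MovieSegmentation, ParcelTimeseries, RecallTranscript, Run
from tests.conftest import make_utterance


def _pattern_set(rng, S=4, K=6, F=15, shared_recall=True, shift=None,
                 movie_noise=0.0, noise=0.0, unrecalled=()):
    """Hand-built ScenePatternSet around a shared per-scene pattern.

    movie = shared + idiosyncratic movie noise; recall = shared (+ shift)
    + idiosyncratic recall noise, or fully independent patterns.
    """
    shared = rng.normal(size=(K, F))
    movie = np.repeat(shared[None], S, axis=0)
    if movie_noise:
        movie = movie + movie_noise * rng.normal(size=(S, K, F))
    if shared_recall:
        recall = np.repeat(shared[None], S, axis=0)
    else:
        recall = rng.normal(size=(S, K, F))
    if shift is not None:
        recall = recall + shift[None, :, :]
    if noise:
        recall = recall + noise * rng.normal(size=(S, K, F))
    recalled = np.ones((S, K), dtype=bool)
    for (i, k) in unrecalled:
        recalled[i, k] = False
        recall[i, k] = np.nan
    return tr.ScenePatternSet(
        subject_ids=[f"s{i}" for i in range(S)], scene_ids=list(range(1, K + 1)),
        parcel_ids=[0], movie={0: movie}, recall={0: recall},
        recalled=recalled)


@pytest.fixture
def cfg3():
    return AnalysisConfig(lag_trs=0, n_perm=100, min_recallers=2)


class TestRecallSceneIntervals:
    def test_intervals_from_utterances(self, seg_small):
        t = RecallTranscript("s1", [
            make_utterance(1, Label.PRECISE, 1, 2, onset=0.0),
            make_utterance(2, Label.PRECISE, 3, 3, onset=6.0),
            make_utterance(3, Label.PRECISE, 4, 5, onset=20.0)])
        out = tr.recall_scene_intervals(t, seg_small)
        assert out == [(1, 0.0, 11.0), (2, 20.0, 25.0)]

    def test_majority_scene_assignment(self, seg_small):
        # segments 3 (3 s, scene 1) and 4 (6 s, scene 2): majority scene 2
        t = RecallTranscript("s1", [make_utterance(1, Label.SUMMARY, 3, 4)])
        out = tr.recall_scene_intervals(t, seg_small)
        assert [k for k, _, _ in out] == [2]

    def test_other_utterances_ignored(self, seg_small):
        from retell.io_formats import Utterance
        t = RecallTranscript("s1", [
            Utterance("s1", 1, 0.0, 5.0, "x", None, None, Label.OTHER)])
        assert tr.recall_scene_intervals(t, seg_small) == []


class TestScenePatterns:
    def test_constant_series(self):
        ts = ParcelTimeseries("s1", Run.MOVIE, 1.5,
                              {0: np.tile([[2.0], [3.0]], (1, 10))})
        cfg = AnalysisConfig(lag_trs=0)
        out = tr.scene_patterns(ts, [(1, 0.0, 6.0), (2, 6.0, 15.0)], cfg)
        np.testing.assert_allclose(out[0][1], [2.0, 3.0])
        np.testing.assert_allclose(out[0][2], [2.0, 3.0])

    def test_two_tr_scene_average(self):
        data = np.arange(20, dtype=float).reshape(2, 10)
        ts = ParcelTimeseries("s1", Run.MOVIE, 1.5, {0: data})
        cfg = AnalysisConfig(lag_trs=0)
        out = tr.scene_patterns(ts, [(1, 3.0, 6.0)], cfg)
        np.testing.assert_allclose(out[0][1], data[:, 2:4].mean(axis=1))

    def test_out_of_run_scene_omitted(self):
        ts = ParcelTimeseries("s1", Run.RECALL, 1.5, {0: np.zeros((2, 10))})
        cfg = AnalysisConfig(lag_trs=0)
        out = tr.scene_patterns(ts, [(1, 0.0, 5.0), (2, 100.0, 110.0)], cfg)
        assert 1 in out[0] and 2 not in out[0]


class TestBetweenSubjectSimilarity:
    def test_identical_noiseless_patterns_give_unity(self, cfg3):
        sps = _pattern_set(np.random.default_rng(0))
        mr = tr.between_subject_similarity(sps, "MR", cfg3)
        rr = tr.between_subject_similarity(sps, "RR", cfg3)
        assert mr.parcel_mean[0] == pytest.approx(1.0)
        assert rr.parcel_mean[0] == pytest.approx(1.0)

    def test_independent_recall_near_zero(self, cfg3):
        sps = _pattern_set(np.random.default_rng(1), S=8, K=10, F=400,
                           shared_recall=False)
        mr = tr.between_subject_similarity(sps, "MR", cfg3)
        rr = tr.between_subject_similarity(sps, "RR", cfg3)
        assert abs(mr.parcel_mean[0]) < 0.05
        assert abs(rr.parcel_mean[0]) < 0.05

    def test_unrecalled_cells_excluded(self, cfg3):
        sps = _pattern_set(np.random.default_rng(2), unrecalled=[(0, 0), (1, 0)])
        mr = tr.between_subject_similarity(sps, "MR", cfg3)
        assert np.isnan(mr.cells[0][0, 0]) and np.isnan(mr.cells[0][1, 0])
        assert not np.isnan(mr.cells[0][2, 0])

    def test_subject_order_and_scale_invariance(self, cfg3):
        rng = np.random.default_rng(3)
        sps = _pattern_set(rng, movie_noise=0.5, noise=0.5)
        base = tr.between_subject_similarity(sps, "MR", cfg3).parcel_mean[0]
        perm = [2, 0, 3, 1]
        sps2 = tr.ScenePatternSet(
            subject_ids=[sps.subject_ids[i] for i in perm],
            scene_ids=sps.scene_ids, parcel_ids=[0],
            movie={0: sps.movie[0][perm]}, recall={0: 4.0 * sps.recall[0][perm]},
            recalled=sps.recalled[perm])
        again = tr.between_subject_similarity(sps2, "MR", cfg3).parcel_mean[0]
        assert again == pytest.approx(base, abs=1e-12)

    def test_mode_validation_and_min_recallers(self, cfg3):
        sps = _pattern_set(np.random.default_rng(4))
        with pytest.raises(ValueError, match="MR or RR"):
            tr.between_subject_similarity(sps, "XX", cfg3)
        strict = AnalysisConfig(lag_trs=0, min_recallers=99)
        with pytest.raises(ValueError, match="no scene"):
            tr.between_subject_similarity(sps, "MR", strict)


class TestSceneLabelPermutation:
    def test_extreme_p_values(self, cfg3):
        rng = np.random.default_rng(5)
        strong = _pattern_set(rng, noise=0.1)
        p = tr.scene_label_permutation(strong, "MR", cfg3,
                                       np.random.default_rng(0))[0]
        assert p == 0.0
        smoothed = AnalysisConfig(lag_trs=0, n_perm=100, min_recallers=2,
                                  perm_smoothing=True)
        ps = tr.scene_label_permutation(strong, "MR", smoothed,
                                        np.random.default_rng(0))[0]
        assert ps == pytest.approx(1 / 101)

    def test_anti_signal_gives_p_one(self, cfg3):
        # recall patterns anticorrelated with own scene, uncorrelated otherwise
        rng = np.random.default_rng(6)
        sps = _pattern_set(rng, F=30)
        sps.recall[0] = -sps.recall[0]
        # left = movie, right = average of others' (-movie) -> diagonal is -1
        p = tr.scene_label_permutation(sps, "MR", cfg3,
                                       np.random.default_rng(0))[0]
        assert p == 1.0


class TestReliabilityMaskAndT:
    def _result(self, cfg3, rng, shift=None, noise=1.0):
        sps = _pattern_set(rng, S=6, K=8, F=60, shift=shift,
                           movie_noise=noise, noise=noise)
        return tr.transformation_analysis(sps, cfg3, rng)

    def test_either_rule_for_mask(self, cfg3):
        mr = tr.SimilarityResult("MR", [1], ["a"], np.array([True]),
                                 {0: np.zeros((1, 1)), 1: np.zeros((1, 1))},
                                 {0: 0.5, 1: 0.1})
        rr = tr.SimilarityResult("RR", [1], ["a"], np.array([True]),
                                 {0: np.zeros((1, 1)), 1: np.zeros((1, 1))},
                                 {0: 0.3, 1: 0.1})
        res = tr.reliability_mask_and_T(mr, rr, {0: 0.001, 1: 0.5},
                                        {0: 0.9, 1: 0.6},
                                        AnalysisConfig(lag_trs=0))
        df = res.parcels.set_index("parcel_id")
        assert bool(df.loc[0, "in_reliability_mask"])
        assert not bool(df.loc[1, "in_reliability_mask"])
        # masked parcel with RR < MR: negative T excluded from positives
        assert df.loc[0, "t_score"] == pytest.approx(-0.2)
        assert not bool(df.loc[0, "positive_t"])
        assert res.positive_parcels == []

    def test_shared_shift_yields_positive_t(self, cfg3):
        rng = np.random.default_rng(7)
        shift = 1.5 * rng.normal(size=(8, 60))
        res = self._result(cfg3, rng, shift=shift)
        row = res.parcels.iloc[0]
        assert row.rr > row.mr
        assert row.t_score == pytest.approx(row.rr - row.mr)
        assert row.positive_t

    def test_equal_noise_no_shift_t_near_zero(self, cfg3):
        rng = np.random.default_rng(8)
        ts = [self._result(cfg3, np.random.default_rng(100 + i),
                           noise=1.0).parcels.iloc[0].t_score
              for i in range(10)]
        assert abs(np.mean(ts)) < 3 * np.std(ts, ddof=1) / np.sqrt(len(ts)) + 0.02

    def test_matches_straight_loop_oracle(self, cfg3):
        """Vectorised MR/RR/T equals an explicit per-cell loop to 1e-10."""
        rng = np.random.default_rng(9)
        sps = _pattern_set(rng, S=3, K=4, F=10, movie_noise=0.5, noise=0.8,
                           unrecalled=[(0, 1)])
        mr = tr.between_subject_similarity(sps, "MR", cfg3)
        rr = tr.between_subject_similarity(sps, "RR", cfg3)
        t_vec = rr.parcel_mean[0] - mr.parcel_mean[0]
        t_loop = _oracle_t(sps.movie[0], sps.recall[0], sps.recalled,
                           cfg3.min_recallers)
        assert t_vec == pytest.approx(t_loop, abs=1e-10)


def _oracle_t(movie, recall, recalled, min_recallers):
    """Straight-loop MR/RR/T, independent of the package implementation."""
    S, K, _ = movie.shape
    mr_vals, rr_vals = [], []
    for i in range(S):
        for k in range(K):
            if not recalled[i, k]:
                continue
            if recalled[:, k].sum() < min_recallers:
                continue
            others = [j for j in range(S) if j != i and recalled[j, k]]
            if not others:
                continue
            avg = np.mean([recall[j, k] for j in others], axis=0)
            mr_vals.append(np.corrcoef(movie[i, k], avg)[0, 1])
            rr_vals.append(np.corrcoef(recall[i, k], avg)[0, 1])
    return np.mean(rr_vals) - np.mean(mr_vals)
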