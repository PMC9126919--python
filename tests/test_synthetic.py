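import numpy as np
import pytest

from retell import coding, synthetic as syn
from retell.io_formats import AnalysisConfig, Label


class TestSegmentation:
    def test_forced_counts(self):
        cfg = syn.GeneratorConfig(n_scenes=2, segments_per_scene=3)
        seg = syn.simulate_segmentation(cfg, np.random.default_rng(0))
        assert len(seg.micro_segments) == 6
        assert len(seg.scenes) == 2

    def test_determinism(self):
        cfg = syn.GeneratorConfig(n_scenes=5)
        a = syn.simulate_segmentation(cfg, np.random.default_rng(3))
        b = syn.simulate_segmentation(cfg, np.random.default_rng(3))
        assert a == b

    def test_scene_duration_calibration(self):
        """Monte-Carlo check of the truncated log-normal scene model."""
        cfg = syn.GeneratorConfig()
        durs = syn.draw_scene_durations(cfg, 10_000, np.random.default_rng(11))
        assert durs.min() >= cfg.scene_min_s and durs.max() <= cfg.scene_max_s
        se = durs.std(ddof=1) / np.sqrt(durs.size)
        assert abs(durs.mean() - 57.7) < 3 * se
        assert abs(durs.std(ddof=1) - 41.6) < 41.6 * 0.1

    def test_segment_durations_bounded(self, tiny_dataset):
        _, ds = tiny_dataset
        for s in ds.segmentation.micro_segments:
            assert 1.0 - 1e-9 <= s.duration_s <= 9.5 + 1e-9

    def test_annotations_use_scene_specific_vocabulary(self, tiny_dataset):
        _, ds = tiny_dataset
        segs = ds.segmentation.micro_segments
        within, between = [], []
        for a in segs[:30]:
            for b in segs[:30]:
                if a.segment_id >= b.segment_id:
                    continue
                shared = len(set(a.annotation.split())
                             & set(b.annotation.split()))
                (within if a.scene_id == b.scene_id else between).append(shared)
        assert np.mean(within) > np.mean(between)


class TestTranscripts:
    def test_full_bias_scene_gives_only_summary_spans(self, acfg):
        cfg = syn.GeneratorConfig(n_scenes=1, segments_per_scene=8,
                                  scene_min_s=30, scene_max_s=31,
                                  p_other=0.0, p_describe=1.0, p_recall=1.0,
                                  p_redescribe=0.0,
                                  bias_alpha=1e4, bias_beta=1e-2,
                                  bias_jitter_sd=0.0, n_subjects=4)
        rng = np.random.default_rng(0)
        seg = syn.simulate_segmentation(cfg, rng)
        transcripts, truth = syn.simulate_transcripts(cfg, seg, rng)
        for t in transcripts:
            assert t.utterances
            for u in t.utterances:
                assert u.label is Label.SUMMARY
                assert coding.described_duration(u, seg) > 10.0

    def test_zero_bias_scene_gives_only_precise_spans(self, acfg):
        cfg = syn.GeneratorConfig(n_scenes=2, p_other=0.0, p_recall=1.0,
                                  bias_alpha=1e-2, bias_beta=1e4,
                                  bias_jitter_sd=0.0, n_subjects=4)
        rng = np.random.default_rng(1)
        seg = syn.simulate_segmentation(cfg, rng)
        transcripts, _ = syn.simulate_transcripts(cfg, seg, rng)
        for t in transcripts:
            for u in t.utterances:
                if u.label is not Label.OTHER:
                    assert coding.described_duration(u, seg) <= 10.0

    def test_recorded_bias_recovered_by_coding(self, acfg):
        """Recomputing summary bias from the emitted words recovers the
        generator's per-scene mean targets."""
        meas: dict[tuple[int, int], list] = {}
        true: dict[tuple[int, int], list] = {}
        for rep in range(3):
            cfg = syn.GeneratorConfig(seed=60 + rep)
            rng = np.random.default_rng(cfg.seed)
            seg = syn.simulate_segmentation(cfg, rng)
            transcripts, truth = syn.simulate_transcripts(cfg, seg, rng)
            for t in transcripts:
                df = coding.scene_summary_bias(t, seg, acfg)
                for row in df.itertuples():
                    if row.recalled and not np.isnan(row.summary_bias):
                        key = (rep, row.scene_id)
                        meas.setdefault(key, []).append(row.summary_bias)
                        true.setdefault(key, []).append(
                            truth.true_summary_bias[(row.subject_id,
                                                     row.scene_id)])
        devs = [abs(np.mean(meas[k]) - np.mean(true[k])) for k in meas]
        assert np.mean(devs) < 0.1

    def test_overlap_rate_matches_redescription_probability(self, tiny_dataset):
        _, ds = tiny_dataset
        overlaps = [coding.summary_precise_overlap(t) for t in ds.transcripts]
        assert 0.05 < np.nanmean(overlaps) < 0.6


class TestNeural:
    def test_noiseless_identity(self, acfg):
        from retell import reinstatement as ri
        cfg = syn.GeneratorConfig.model2(
            c=0.0, seed=2, n_scenes=4, n_parcels=1, features_per_parcel=20,
            movie_noise_sd=0.0, recall_noise_sd=0.0, p_other=0.0,
            p_recall=1.0, p_describe=1.0, n_subjects=3)
        ds = syn.simulate_dataset(cfg)
        rows = []
        for (mov, rec), t in zip(ds.neural, ds.transcripts):
            rows.append(ri.segment_reinstatement(mov, rec, t,
                                                 ds.segmentation, acfg))
        import pandas as pd
        allr = pd.concat(rows)
        assert np.allclose(allr.r, 1.0, atol=1e-6)

    def test_unknown_scene_in_truth_rejected(self, tiny_dataset):
        cfg, ds = tiny_dataset
        bad = syn.GroundTruth(
            scene_shift_magnitude={999: 1.0},
            true_summary_bias=ds.truth.true_summary_bias,
            linked_parcels=frozenset(), model="MODEL2")
        with pytest.raises(ValueError, match="absent"):
            syn.simulate_neural(cfg, ds.segmentation, ds.transcripts, bad,
                                np.random.default_rng(0))

    def test_dataset_determinism(self):
        cfg = syn.GeneratorConfig(seed=9, n_scenes=6, n_parcels=1,
                                  features_per_parcel=10)
        a = syn.simulate_dataset(cfg)
        b = syn.simulate_dataset(cfg)
        for (am, ar), (bm, br) in zip(a.neural, b.neural):
            np.testing.assert_array_equal(am.data[0], bm.data[0])
            np.testing.assert_array_equal(ar.data[0], br.data[0])
        assert a.truth.true_summary_bias == b.truth.true_summary_bias

    def test_model1_truth_has_zero_shift(self):
        cfg = syn.GeneratorConfig.model1(seed=1, n_scenes=4, n_parcels=1,
                                         features_per_parcel=5)
        ds = syn.simulate_dataset(cfg)
        assert ds.truth.model == "MODEL1"
        assert all(v == 0.0 for v in ds.truth.scene_shift_magnitude.values())
        ds2 = syn.simulate_dataset(
            syn.GeneratorConfig.model2(c=1.0, seed=1, n_scenes=4, n_parcels=1,
                                       features_per_parcel=5))
        assert ds2.truth.model == "MODEL2"


class TestClosedForms:
    def test_oracle_values(self):
        assert syn.expected_mr(1, 1, 1, 17) == pytest.approx(0.4924, abs=1e-4)
        assert syn.expected_rr(1, 1, 1, 17) == pytest.approx(0.8040, abs=1e-4)
        assert syn.expected_transformation(1, 1, 0, 17) == pytest.approx(0.0)

    def test_transformation_sign_tracks_shift(self):
        # (u - 1)(u + sigma^2 (u + 1)) > 0 for u = 1 + c^2 > 1
        for c in (0.5, 1.0, 2.0):
            assert syn.expected_transformation(1, 1, c, 17) > 0

    def test_reinstatement_oracle_monotone_in_noise(self):
        r1 = syn.expected_reinstatement_r(1, 1, extra_sd=1.0)
        r2 = syn.expected_reinstatement_r(1, 1, extra_sd=2.0)
        assert r1 > r2 > 0
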