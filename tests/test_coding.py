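import numpy as np
import pytest

from retell import coding, synthetic as syn
from retell.io_formats import AnalysisConfig, Label, Utterance
from retell.stats import pearson_r
from tests.conftest import make_utterance


class TestContentWords:
    @pytest.mark.parametrize("text,stop,expected", [
        ("the detective is clever", ("the", "is"), 2),
        ("", (), 0),
        ("Um, the the uh knife", ("the",), 1),
        ("A Knife! a KNIFE?", ("a",), 2),
    ])
    def test_examples(self, text, stop, expected):
        assert coding.count_content_words(text, stop, ("uh", "um")) == expected


class TestDescribedDuration:
    def test_sums_covered_segments(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 1, 2)
        assert coding.described_duration(u, seg_small) == pytest.approx(9.0)

    def test_single_segment(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 3, 3)
        assert coding.described_duration(u, seg_small) == pytest.approx(3.0)

    def test_full_range_is_total_duration(self, seg_small):
        u = make_utterance(1, Label.SUMMARY, 1, 5)
        assert coding.described_duration(u, seg_small) == pytest.approx(25.0)

    def test_unknown_segment_raises(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 5, 9)
        with pytest.raises(Exception, match="unknown segment"):
            coding.described_duration(u, seg_small)


class TestAutoLabel:
    def test_rule(self, seg_small, acfg):
        assert coding.auto_label(
            make_utterance(1, Label.PRECISE, 1, 3), seg_small, acfg) is Label.SUMMARY
        assert coding.auto_label(
            make_utterance(1, Label.SUMMARY, 1, 1), seg_small, acfg) is Label.PRECISE
        other = Utterance("s", 1, 0.0, 3.0, "x", None, None, Label.OTHER)
        assert coding.auto_label(other, seg_small, acfg) is Label.OTHER

    def test_boundary_rule_at_exact_threshold(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 2, 2)  # 5 s segment
        le = AnalysisConfig(threshold_s=5.0, boundary_rule="LE_PRECISE")
        lt = AnalysisConfig(threshold_s=5.0, boundary_rule="LT_PRECISE")
        assert coding.auto_label(u, seg_small, le) is Label.PRECISE
        assert coding.auto_label(u, seg_small, lt) is Label.SUMMARY

    def test_invariant_to_text_and_label(self, seg_small, acfg):
        a = make_utterance(1, Label.PRECISE, 1, 3, text="anything at all")
        b = make_utterance(1, Label.SUMMARY, 1, 3, text="other words")
        assert coding.auto_label(a, seg_small, acfg) == \
            coding.auto_label(b, seg_small, acfg)


class TestTcf:
    def test_formula(self, seg_small):
        u = make_utterance(1, Label.SUMMARY, 1, 3)  # 12 s described
        u.content_word_count = 6
        assert coding.compute_tcf(u, seg_small) == pytest.approx(0.5)

    def test_zero_words_gives_one(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 1, 1)
        u.content_word_count = 0
        assert coding.compute_tcf(u, seg_small) == pytest.approx(1.0)

    def test_can_be_negative(self, seg_small):
        u = make_utterance(1, Label.PRECISE, 1, 1)  # 4 s described
        u.content_word_count = 8
        assert coding.compute_tcf(u, seg_small) == pytest.approx(-1.0)

    def test_other_utterance_is_missing(self, seg_small):
        other = Utterance("s", 1, 0.0, 3.0, "x", None, None, Label.OTHER)
        assert np.isnan(coding.compute_tcf(other, seg_small))


class TestSceneSummaryBias:
    def test_proportion(self, seg_small, acfg):
        t = _transcript([
            (Label.SUMMARY, 1, 3, 30),
            (Label.PRECISE, 1, 2, 70),
        ])
        df = coding.scene_summary_bias(t, seg_small, acfg)
        row = df[df.scene_id == 1].iloc[0]
        assert row.summary_bias == pytest.approx(0.30)
        assert row.recalled

    def test_other_only_scene_missing_and_unrecalled(self, seg_small, acfg):
        t = _transcript([(Label.OTHER, None, None, 10)])
        df = coding.scene_summary_bias(t, seg_small, acfg)
        assert np.isnan(df.summary_bias).all()
        assert not df.recalled.any()

    def test_multi_scene_utterance_credits_both_scenes(self, seg_small, acfg):
        t = _transcript([(Label.SUMMARY, 3, 4, 10)])  # touches scenes 1 and 2
        df = coding.scene_summary_bias(t, seg_small, acfg)
        assert (df.words_summary == [10, 10]).all()

    def test_relabelling_summary_as_precise_zeroes_bias(self, seg_small, acfg):
        t = _transcript([(Label.SUMMARY, 1, 3, 12), (Label.PRECISE, 4, 4, 5)])
        flipped = _transcript([(Label.PRECISE, 1, 3, 12),
                               (Label.PRECISE, 4, 4, 5)])
        df = coding.scene_summary_bias(flipped, seg_small, acfg)
        defined = df.dropna(subset=["summary_bias"])
        assert (defined.summary_bias == 0).all()
        orig = coding.scene_summary_bias(t, seg_small, acfg)
        defined = orig.dropna(subset=["summary_bias"])
        assert ((defined.summary_bias >= 0) & (defined.summary_bias <= 1)).all()


class TestSceneMeanTcf:
    def test_mean_over_touching_utterances(self, seg_small):
        t = _transcript([(Label.PRECISE, 1, 1, None), (Label.PRECISE, 2, 2, None)])
        t.utterances[0].tcf = 0.2
        t.utterances[1].tcf = 0.6
        out = coding.scene_mean_tcf(t, seg_small)
        assert out[1] == pytest.approx(0.4)

    def test_single_utterance_and_missing(self, seg_small):
        t = _transcript([(Label.PRECISE, 4, 4, None)])
        t.utterances[0].tcf = 0.7
        out = coding.scene_mean_tcf(t, seg_small)
        assert out == {2: pytest.approx(0.7)}


class TestOverlapAndAgreement:
    def test_overlap_cases(self):
        full = _transcript([(Label.SUMMARY, 1, 3, 5), (Label.PRECISE, 2, 2, 5)])
        assert coding.summary_precise_overlap(full) == pytest.approx(1.0)
        disjoint = _transcript([(Label.SUMMARY, 1, 2, 5),
                                (Label.PRECISE, 4, 4, 5)])
        assert coding.summary_precise_overlap(disjoint) == 0.0
        half = _transcript([(Label.SUMMARY, 1, 2, 5), (Label.SUMMARY, 4, 5, 5),
                            (Label.PRECISE, 2, 2, 5)])
        assert coding.summary_precise_overlap(half) == pytest.approx(0.5)
        assert np.isnan(coding.summary_precise_overlap(
            _transcript([(Label.PRECISE, 1, 1, 5)])))

    def test_agreement(self):
        a = [Label.PRECISE, Label.SUMMARY, Label.OTHER, Label.PRECISE]
        assert coding.label_agreement(a, a) == 1.0
        b = [Label.SUMMARY, Label.PRECISE, Label.PRECISE, Label.SUMMARY]
        assert coding.label_agreement(a, b) == 0.0
        c = list(a)
        c[0] = Label.OTHER
        assert coding.label_agreement(a, c) == pytest.approx(0.75)
        with pytest.raises(Exception):
            coding.label_agreement(a, a[:2])


class TestAgainstGenerator:
    def test_auto_and_tcf_biases_correlate(self, acfg):
        """Scene bias from duration-rule labels tracks a TCF-based bias."""
        cfg = syn.GeneratorConfig(seed=5)
        rng = np.random.default_rng(cfg.seed)
        seg = syn.simulate_segmentation(cfg, rng)
        transcripts, _ = syn.simulate_transcripts(cfg, seg, rng)
        rs = []
        for t in transcripts[:8]:
            t = coding.annotate_transcript(t, seg, acfg)
            df = coding.scene_summary_bias(t, seg, acfg).dropna(
                subset=["summary_bias", "mean_tcf"])
            if len(df) > 10:
                r = pearson_r(df.summary_bias.to_numpy(), df.mean_tcf.to_numpy())
                if not np.isnan(r):
                    rs.append(r)
        assert np.mean(rs) > 0


def _transcript(rows):
    from retell.io_formats import RecallTranscript
    utts = []
    for i, (label, start, end, words) in enumerate(rows, start=1):
        u = Utterance("sub-01", i, i * 10.0, i * 10.0 + 5, "w " * (words or 0),
                      start, end, label)
        if words is not None:
            u.content_word_count = words
        utts.append(u)
    return RecallTranscript("sub-01", utts)
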