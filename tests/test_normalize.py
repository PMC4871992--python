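"""Two-stage normalization: canonicalization, vocabulary, fallback scan."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdva import (
    AcuityEntry,
    AcuityVocabulary,
    NormalizationStatus,
    VocabularyError,
    canonicalize_text,
    fallback_scan,
    normalize,
    unmapped_report,
)
from bdva.normalize import _scan_tokens

ALL_LABELS = [
    "20/10", "20/20", "20/25", "20/30", "20/40", "20/50", "20/60", "20/70",
    "20/80", "20/100", "20/125", "20/200", "20/400", "CF", "HM", "LP", "NLP",
]


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  20/40 ", "20/40"),
            ("2O/2O", "20/20"),
            ("CF @ 3FT", "cf @ 3ft"),
            ("20/2OO", "20/200"),       # repair iterates to a fixed point
            ("O/20", "0/20"),           # o against a digit-flanked slash
            ("  20   /  40 ", "20 / 40"),
            ("", ""),
            ("   ", ""),
            ("room", "room"),           # plain o untouched away from digits
        ],
    )
    def test_examples(self, raw, expected):
        assert canonicalize_text(raw) == expected

    def test_idempotent(self):
        for raw in ["  2O/2O ", "Counting  Fingers", "20/25+2", "j1"]:
            once = canonicalize_text(raw)
            assert canonicalize_text(once) == once


class TestVocabulary:
    def test_identity_entry(self, vocab):
        res = vocab.lookup("20/40")
        assert res.status is NormalizationStatus.VOCAB_HIT
        assert res.category.label == "20/40"

    def test_jager_is_near(self, vocab):
        assert vocab.lookup("J1").status is NormalizationStatus.NEAR

    def test_spelled_out_qualitative(self, vocab):
        res = vocab.lookup("no light perception")
        assert res.status is NormalizationStatus.VOCAB_HIT
        assert res.category.label == "NLP"

    def test_miss_is_distinct_from_unmapped(self, vocab):
        assert vocab.lookup("20/20 slow") is None
        assert vocab.lookup("not tested").status is NormalizationStatus.UNMAPPED

    def test_lookup_is_canonicalized(self, vocab):
        assert vocab.lookup("  Counting   Fingers ").category.label == "CF"

    def test_duplicate_keys_reported_with_line(self, tmp_path):
        path = tmp_path / "vocab.csv"
        path.write_text("raw_text,target\n20/40,20/40\n 20/40 ,20/50\n")
        with pytest.raises(VocabularyError, match=r":3.*duplicate"):
            AcuityVocabulary.from_csv(path)

    def test_invalid_target_reported_with_line(self, tmp_path):
        path = tmp_path / "vocab.csv"
        path.write_text("raw_text,target\nxx,20/15\n")
        with pytest.raises(VocabularyError, match=r":2.*invalid target"):
            AcuityVocabulary.from_csv(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "vocab.csv"
        path.write_text("raw,target\n")
        with pytest.raises(VocabularyError, match="header"):
            AcuityVocabulary.from_csv(path)


class TestFallbackScan:
    @pytest.mark.parametrize(
        "raw,label,token",
        [
            ("20/20 slow", "20/20", "20/20"),
            ("20/60 w/head tilted down", "20/60", "20/60"),
            ("after waiting 1 min 20/20 in lighted room", "20/20", "20/20"),
            ("20/60 blinking with ointment", "20/60", "20/60"),
            ("20/25+2", "20/25", "20/25+2"),   # line modifier strips to base
            ("20/30-1 with glasses", "20/30", "20/30-1"),
            ("20/15 on ETDRS lane", "20/20", "20/15"),  # off-list snaps, tie to worse
            ("counting fingers at 2 feet", "CF", "counting fingers"),
            ("HM temporally", "HM", "hm"),
            ("vision is no light perception today", "NLP", "no light perception"),
            ("light perception only", "LP", "light perception"),
        ],
    )
    def test_token_recovery(self, scale, raw, label, token):
        res = fallback_scan(raw, scale)
        assert res.status is NormalizationStatus.FALLBACK_HIT
        assert res.category.label == label
        assert res.matched_token == token

    def test_no_token_is_unmapped(self, scale):
        assert fallback_scan("no view", scale).status is NormalizationStatus.UNMAPPED

    def test_blank_is_empty(self, scale):
        assert fallback_scan("   ", scale).status is NormalizationStatus.EMPTY

    def test_unlisted_jager_flagged_near(self, scale):
        res = fallback_scan("J17 with add", scale)
        assert res.status is NormalizationStatus.NEAR
        assert res.category is None

    def test_nlp_not_double_counted_as_lp(self, scale):
        tokens = _scan_tokens("no light perception", scale)
        assert [c.label for c, _, _ in tokens] == ["NLP"]

    def test_multiple_tokens_take_best(self, scale):
        res = fallback_scan("20/70 ph 20/40", scale)
        assert res.category.label == "20/40"

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.sampled_from(ALL_LABELS), min_size=1, max_size=4),
        st.sampled_from(
            ["{}", "{} slow", "pt tired {}", "{} after drops", "? {} ?"]
        ),
    )
    def test_multi_token_result_equals_best_of_all_tokens(self, labels, template):
        """With several tokens in one field the winner is the best-ranked
        token, checked against a brute-force scan of all planted tokens."""
        from bdva import AcuityScale

        scale = AcuityScale.default()
        text = " and ".join(template.format(l) for l in labels)
        res = fallback_scan(text, scale)
        assert res.status is NormalizationStatus.FALLBACK_HIT
        assert res.category == scale.best_of(labels)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sampled_from(ALL_LABELS),
        st.text(
            alphabet="abdegiknorstuwy .,?!",  # no c/f/h/l/m/p: cannot spell a keyword
            max_size=30,
        ),
        st.integers(min_value=0, max_value=1),
    )
    def test_embedded_token_always_recovered(self, label, noise, side):
        """A canonical token embedded anywhere in token-free annotation text
        is found by the fallback scan."""
        from bdva import AcuityScale

        scale = AcuityScale.default()
        text = f"{noise} {label}" if side else f"{label} {noise}"
        res = fallback_scan(text, scale)
        assert res.status is NormalizationStatus.FALLBACK_HIT
        assert res.category.label == label


class TestNormalize:
    def test_annotated_response_falls_through_to_scan(self, vocab):
        res = normalize("20/60 blinking with ointment", vocab)
        assert res.category.label == "20/60"
        assert res.status is NormalizationStatus.FALLBACK_HIT

    def test_blank_is_empty(self, vocab):
        assert normalize("", vocab).status is NormalizationStatus.EMPTY

    def test_vocabulary_wins_over_fallback(self, scale):
        """A curated entry overrides whatever the token scan would say."""
        vocab = AcuityVocabulary(
            {"20/400 historic": "UNMAPPED", "20/40": "20/40"}, scale
        )
        res = normalize("20/400 historic", vocab)
        assert res.status is NormalizationStatus.UNMAPPED
        assert fallback_scan("20/400 historic", scale).category.label == "20/400"

    def test_category_level_idempotence(self, vocab):
        for label in ALL_LABELS:
            first = normalize(label, vocab)
            again = normalize(first.category.label, vocab)
            assert again.category == first.category

    def test_o_transposed_entry_normalizes(self, vocab):
        assert normalize("2O/2O", vocab).category.label == "20/20"


class TestUnmappedReport:
    @staticmethod
    def entry(raw, vocab):
        e = AcuityEntry("n1", "p1", "OD", "corrected", raw)
        e.normalization = normalize(raw, vocab)
        return e

    def test_counts_and_order(self, vocab):
        raws = ["poor view", "poor view", "glare", "glare", "aaa", "20/40"]
        table = unmapped_report([self.entry(r, vocab) for r in raws])
        assert list(table["raw_text"]) == ["glare", "poor view", "aaa"]
        assert list(table["count"]) == [2, 2, 1]

    def test_empty_when_everything_maps(self, vocab):
        table = unmapped_report([self.entry("20/40", vocab)])
        assert len(table) == 0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from(["xx", "yy", "zz", "20/40", "J1"]), max_size=20))
    def test_matches_brute_force_tally(self, raws):
        vocab = AcuityVocabulary.default()
        entries = [self.entry(r, vocab) for r in raws]
        table = unmapped_report(entries)
        expected = {}
        for e in entries:
            if e.normalization.status is NormalizationStatus.UNMAPPED:
                expected[e.raw_text] = expected.get(e.raw_text, 0) + 1
        assert dict(zip(table["raw_text"], table["count"])) == expected
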