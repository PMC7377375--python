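"""Corpus I/O: tokenization, stop-word filtering, inclusion rule, TRC proxy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreamgraph.corpus import (
    CorpusError,
    EmptyReportError,
    ReportMeta,
    TokenizedReport,
    apply_stopword_filter,
    default_fillers,
    default_stopwords,
    effective_trc,
    filter_min_length,
    load_corpus,
    tokenize,
    word_count,
)


class TestTokenize:
    @pytest.mark.parametrize(
        "text, tokens, breaks",
        [
            ("The dog. The dog ran.", ("the", "dog", "the", "dog", "ran"), ()),
            ("a b\n\nc d", ("a", "b", "c", "d"), (1,)),
            ("don't stop-go now", ("don't", "stop-go", "now"), ()),
            ("one\n\n\n\ntwo\n\nthree", ("one", "two", "three"), (0, 1)),
            ("word", ("word",), ()),
        ],
    )
    def test_examples(self, text, tokens, breaks):
        got_tokens, got_breaks = tokenize(text)
        assert got_tokens == tokens
        assert got_breaks == breaks

    def test_pure_punctuation_raises(self):
        with pytest.raises(EmptyReportError):
            tokenize("!!! ...")

    def test_empty_paragraph_between_text_adds_no_break(self):
        tokens, breaks = tokenize("a b\n\n???\n\nc")
        assert tokens == ("a", "b", "c")
        assert breaks == (1,)

    @given(
        st.lists(st.from_regex(r"[a-z]{1,8}", fullmatch=True), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, words):
        """Tokenizing the space-joined tokens reproduces the token list."""
        tokens, _ = tokenize(" ".join(words))
        again, breaks = tokenize(" ".join(tokens))
        assert again == tokens
        assert breaks == ()


class TestStopwordFilter:
    def test_direct_removal(self, make_report):
        rep = make_report(["the", "dog", "ran"])
        out = apply_stopword_filter(rep, {"the"})
        assert out.tokens == ("dog", "ran")

    def test_disjoint_list_is_identity(self, make_report):
        rep = make_report(["dog", "ran"], breaks=(0,))
        out = apply_stopword_filter(rep, {"zebra"})
        assert out.tokens == rep.tokens
        assert out.break_positions == rep.break_positions

    def test_empty_list_is_identity(self, make_report):
        rep = make_report(["the", "dog"])
        assert apply_stopword_filter(rep, ()) is rep

    def test_break_reindexing(self, make_report):
        # 'the dog | the cat' -> removing 'the' keeps boundary between dog/cat
        rep = make_report(["the", "dog", "the", "cat"], breaks=(1,))
        out = apply_stopword_filter(rep, {"the"})
        assert out.tokens == ("dog", "cat")
        assert out.break_positions == (0,)
        assert out.n_paragraphs == 2

    def test_emptied_paragraph_merges(self, make_report):
        rep = make_report(["a", "the", "b"], breaks=(0, 1))
        out = apply_stopword_filter(rep, {"the"})
        assert out.tokens == ("a", "b")
        assert out.n_paragraphs == 2  # 3 paragraphs -> 2, never increases

    def test_filtered_report_can_fall_below_floor(self, make_report, rng):
        toks = ["the"] * 10 + [f"w{i}" for i in range(25)]
        rep = make_report(list(rng.permutation(toks)))
        out = apply_stopword_filter(rep, {"the"})
        assert out.n_tokens == 25
        fr = filter_min_length([out], 30)
        assert fr.kept == [] and len(fr.excluded) == 1

    @given(
        st.lists(st.sampled_from("abcdefgh"), min_size=2, max_size=30),
        st.sets(st.sampled_from("abcdefgh"), max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_increases_counts(self, words, stops):
        meta = ReportMeta("r", "p", "n", "REM", 0.0)
        rep = TokenizedReport(
            meta=meta,
            tokens=tuple(words),
            break_positions=(len(words) // 2 - 1,) if len(words) > 2 else (),
        )
        try:
            out = apply_stopword_filter(rep, stops)
        except EmptyReportError:
            return
        assert out.n_tokens <= rep.n_tokens
        assert out.n_paragraphs <= rep.n_paragraphs

    def test_bundled_lists_load(self):
        assert "the" in default_stopwords()
        assert "um" in default_fillers()


class TestMinLength:
    def test_boundary(self, make_report):
        r29 = make_report([f"w{i}" for i in range(29)], report_id="a")
        r30 = make_report([f"w{i}" for i in range(30)], report_id="b")
        fr = filter_min_length([r29, r30])
        assert [r.meta.report_id for r in fr.kept] == ["b"]
        assert [r.meta.report_id for r in fr.excluded] == ["a"]

    def test_partition_is_exact(self, make_report, rng):
        reports = [
            make_report([f"w{i}" for i in range(int(n))], report_id=f"r{k}")
            for k, n in enumerate(rng.integers(5, 60, 25))
        ]
        fr = filter_min_length(reports)
        assert sorted(r.meta.report_id for r in fr.kept + fr.excluded) == sorted(
            r.meta.report_id for r in reports
        )
        assert not set(r.meta.report_id for r in fr.kept) & set(
            r.meta.report_id for r in fr.excluded
        )

    def test_exclusion_log_counts_by_stage(self, make_report):
        reports = [
            make_report(["w"] * 10, stage="REM", report_id="a"),
            make_report(["w"] * 10, stage="N2", report_id="b"),
            make_report(["w"] * 12, stage="N2", report_id="c"),
            make_report(["w"] * 40, stage="REM", report_id="d"),
        ]
        fr = filter_min_length(reports)
        assert "REM = 1; N2 = 2" in fr.summary()

    def test_all_kept(self, make_report):
        reports = [make_report([f"w{i}" for i in range(35)])]
        fr = filter_min_length(reports)
        assert fr.excluded == [] and len(fr.kept) == 1


class TestWordCount:
    def test_fillers_removed(self, make_report):
        rep = make_report(["i", "was", "um", "flying"])
        assert word_count(rep) == 3

    def test_empty_filler_list_gives_plain_count(self, make_report):
        rep = make_report(["i", "was", "um", "flying"])
        assert word_count(rep, fillers=()) == 4

    def test_supplied_trc_takes_precedence(self, make_report):
        rep = make_report(["a"] * 10, trc=51)
        assert effective_trc(rep) == 51

    def test_proxy_when_trc_missing(self, make_report):
        rep = make_report(["a", "um", "b"])
        assert effective_trc(rep) == 2


class TestLoadCorpus:
    @pytest.fixture
    def corpus_dir(self, tmp_path):
        texts = tmp_path / "texts"
        texts.mkdir()
        rows = ["report_id,participant_id,night_id,stage,minutes_since_lights_off,pirs,trc"]
        for i, stage in enumerate(["REM", "N2", "N2"]):
            rid = f"r{i}"
            rows.append(f"{rid},p1,n1,{stage},{100 + i},{i},")
            (texts / f"{rid}.txt").write_text(f"some words here for report {i}\n\nmore text")
        (tmp_path / "meta.csv").write_text("\n".join(rows) + "\n")
        return tmp_path

    def test_roundtrip(self, corpus_dir):
        reports = load_corpus(corpus_dir / "meta.csv", corpus_dir / "texts")
        assert [r.meta.report_id for r in reports] == ["r0", "r1", "r2"]
        assert reports[0].meta.stage == "REM"
        assert reports[1].meta.pirs == 1
        assert reports[0].meta.trc is None
        assert reports[0].n_paragraphs == 2

    def test_missing_file_lists_report_id(self, corpus_dir):
        (corpus_dir / "texts" / "r1.txt").unlink()
        with pytest.raises(CorpusError, match="r1"):
            load_corpus(corpus_dir / "meta.csv", corpus_dir / "texts")

    def test_invalid_pirs_names_field(self, corpus_dir):
        meta = corpus_dir / "meta.csv"
        meta.write_text(meta.read_text().replace(",1,", ",12,"))
        with pytest.raises(CorpusError, match="pirs"):
            load_corpus(meta, corpus_dir / "texts")

    def test_duplicate_report_id(self, corpus_dir):
        meta = corpus_dir / "meta.csv"
        content = meta.read_text()
        meta.write_text(content + "r0,p1,n1,REM,100,,\n")
        with pytest.raises(CorpusError, match="duplicate"):
            load_corpus(meta, corpus_dir / "texts")

    def test_tab_delimited_autodetect(self, tmp_path):
        texts = tmp_path / "texts"
        texts.mkdir()
        (texts / "x.txt").write_text("hello world again")
        (tmp_path / "meta.tsv").write_text(
            "report_id\tparticipant_id\tnight_id\tstage\tminutes_since_lights_off\tpirs\ttrc\n"
            "x\tp1\tn1\tN2\t55\t\t\n"
        )
        reports = load_corpus(tmp_path / "meta.tsv", texts)
        assert reports[0].tokens == ("hello", "world", "again")


class TestReportMeta:
    def test_stage_validated(self):
        with pytest.raises(CorpusError, match="stage"):
            ReportMeta("r", "p", "n", "REM2", 0.0)

    def test_pirs_range(self):
        with pytest.raises(CorpusError, match="pirs"):
            ReportMeta("r", "p", "n", "REM", 0.0, pirs=10)
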