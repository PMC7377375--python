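"""Transcript corpora: metadata, tokenization, stop-word filtering, inclusion rules.

A corpus is a set of plain-text oral-report transcripts (one report per file,
blank lines marking paragraph/turn boundaries) plus a delimited metadata table
carrying, per report: participant, night, sleep stage (REM/N2/N3), minutes
since lights-off, an optional ordinal complexity rating (PIRS, 0-9), and an
optional human-judged total recall count (TRC).

Tokenization is deliberately simple and configurable: lowercase, split on
whitespace, strip everything non-alphanumeric except intra-word apostrophes
and hyphens.  Paragraph boundaries are remembered as "break positions": a
break at index ``i`` means no word-to-word transition exists between token
``i`` and token ``i+1`` when the report is later turned into a graph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STAGES = ("REM", "N2", "N3")

#: default minimum report length (tokens) for inclusion in analysis
MIN_TOKENS = 30

_TOKEN_RE = re.compile(r"[^\W_]+(?:['’\-][^\W_]+)*", re.UNICODE)


class CorpusError(ValueError):
    """Malformed corpus input (metadata, transcript, or list file)."""


class EmptyReportError(CorpusError):
    """A transcript contains no alphabetic/alphanumeric tokens."""


@dataclass(frozen=True)
class ReportMeta:
    """Per-report metadata.

    ``pirs`` (0-9 ordinal complexity rating) and ``trc`` (human-judged total
    recall count) may be missing (``None``); ``trc`` when present always takes
    precedence over any word-count proxy.
    """

    report_id: str
    participant_id: str
    night_id: str
    stage: str
    minutes_since_lights_off: float
    pirs: int | None = None
    trc: int | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise CorpusError(
                f"report {self.report_id!r}: stage must be one of {STAGES}, got {self.stage!r}"
            )
        if self.minutes_since_lights_off < 0:
            raise CorpusError(
                f"report {self.report_id!r}: minutes_since_lights_off must be >= 0"
            )
        if self.pirs is not None and not 0 <= self.pirs <= 9:
            raise CorpusError(
                f"report {self.report_id!r}: pirs must be in [0, 9], got {self.pirs}"
            )
        if self.trc is not None and self.trc < 0:
            raise CorpusError(f"report {self.report_id!r}: trc must be >= 0")


@dataclass(frozen=True)
class TokenizedReport:
    """An ordered token sequence with paragraph breaks and metadata.

    ``break_positions`` holds indices ``i`` such that no transition exists
    between ``tokens[i]`` and ``tokens[i+1]``; hence
    ``n_paragraphs == len(break_positions) + 1``.
    """

    meta: ReportMeta
    tokens: tuple[str, ...]
    break_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.tokens:
            raise EmptyReportError(f"report {self.meta.report_id!r}: no tokens")
        breaks = tuple(sorted(set(self.break_positions)))
        object.__setattr__(self, "break_positions", breaks)
        n = len(self.tokens)
        if breaks and (breaks[0] < 0 or breaks[-1] > n - 2):
            raise CorpusError(
                f"report {self.meta.report_id!r}: break positions must lie in "
                f"[0, {n - 2}], got {breaks}"
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_paragraphs(self) -> int:
        return len(self.break_positions) + 1


def tokenize(raw_text: str) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Tokenize a transcript into lowercase words and paragraph breaks.

    Paragraphs are separated by one or more blank lines; a paragraph that
    yields no tokens (e.g. pure punctuation) is dropped without introducing a
    break.  Raises :class:`EmptyReportError` if nothing survives.
    """
    tokens: list[str] = []
    breaks: list[int] = []
    for block in re.split(r"\n\s*\n", raw_text):
        words = _TOKEN_RE.findall(block.lower())
        if not words:
            continue
        if tokens:
            breaks.append(len(tokens) - 1)
        tokens.extend(words)
    if not tokens:
        raise EmptyReportError("transcript contains no alphanumeric tokens")
    return tuple(tokens), tuple(breaks)


def _read_word_list(path: str | Path) -> frozenset[str]:
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip().lower()
        if w and not w.startswith("#"):
            words.append(w)
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """Bundled standard English stop-word list (pronouns, articles, etc.)."""
    with resources.as_file(
        resources.files("dreamgraph.data") / "stopwords_en.txt"
    ) as p:
        return _read_word_list(p)


def default_fillers() -> frozenset[str]:
    """Bundled filler list ('um', 'uh', ...) used by the TRC word-count proxy."""
    with resources.as_file(resources.files("dreamgraph.data") / "fillers.txt") as p:
        return _read_word_list(p)


def apply_stopword_filter(
    report: TokenizedReport, stopwords: Iterable[str] | str | Path
) -> TokenizedReport:
    """Remove stop-words from a report, preserving surviving paragraph breaks.

    ``stopwords`` may be a path to a one-word-per-line file or any iterable of
    words.  Paragraphs emptied by the filter merge with their neighbours (the
    paragraph count never increases).  An empty list is an identity transform.
    A report reduced to zero tokens raises :class:`EmptyReportError`.
    """
    if isinstance(stopwords, (str, Path)):
        stopset = _read_word_list(stopwords)
    else:
        stopset = frozenset(w.lower() for w in stopwords)
    if not stopset:
        return report

    # paragraph id per token, then re-derive breaks among survivors
    par = [0] * len(report.tokens)
    p = 0
    breakset = set(report.break_positions)
    for i in range(1, len(report.tokens)):
        if i - 1 in breakset:
            p += 1
        par[i] = p

    kept_tokens: list[str] = []
    kept_par: list[int] = []
    for tok, pid in zip(report.tokens, par):
        if tok not in stopset:
            kept_tokens.append(tok)
            kept_par.append(pid)
    if not kept_tokens:
        raise EmptyReportError(
            f"report {report.meta.report_id!r}: stop-word filter removed every token"
        )
    new_breaks = tuple(
        i for i in range(len(kept_tokens) - 1) if kept_par[i] != kept_par[i + 1]
    )
    return replace(report, tokens=tuple(kept_tokens), break_positions=new_breaks)


@dataclass
class FilterResult:
    """Outcome of the minimum-length inclusion rule."""

    kept: list[TokenizedReport]
    excluded: list[TokenizedReport]
    min_tokens: int

    def excluded_by_stage(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.excluded:
            counts[r.meta.stage] = counts.get(r.meta.stage, 0) + 1
        return counts

    def summary(self) -> str:
        """Human-readable exclusion log, e.g. ``'2 excluded (REM = 1; N2 = 1)'``."""
        by_stage = self.excluded_by_stage()
        detail = "; ".join(
            f"{s} = {by_stage[s]}" for s in STAGES if s in by_stage
        )
        n = len(self.excluded)
        return f"{n} report(s) below {self.min_tokens} tokens excluded" + (
            f" ({detail})" if detail else ""
        )


def filter_min_length(
    corpus: Sequence[TokenizedReport], min_tokens: int = MIN_TOKENS
) -> FilterResult:
    """Partition a corpus into reports meeting the minimum word count and the rest."""
    if min_tokens < 1:
        raise ValueError("min_tokens must be >= 1")
    kept = [r for r in corpus if r.n_tokens >= min_tokens]
    excluded = [r for r in corpus if r.n_tokens < min_tokens]
    return FilterResult(kept=kept, excluded=excluded, min_tokens=min_tokens)


def word_count(
    report: TokenizedReport, fillers: Iterable[str] | None = None
) -> int:
    """Token count after removing fillers ('um', 'uh', ...).

    This is the word-count proxy for TRC; it is used downstream only when the
    metadata carries no human-judged ``trc``.
    """
    fillerset = default_fillers() if fillers is None else frozenset(
        w.lower() for w in fillers
    )
    return sum(1 for t in report.tokens if t not in fillerset)


def effective_trc(
    report: TokenizedReport, fillers: Iterable[str] | None = None
) -> int:
    """Human-rated TRC when present, else the word-count proxy."""
    if report.meta.trc is not None:
        return report.meta.trc
    return word_count(report, fillers)


_META_COLUMNS = (
    "report_id",
    "participant_id",
    "night_id",
    "stage",
    "minutes_since_lights_off",
)


def _parse_optional_int(value, what: str, row: int) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None
    try:
        return int(float(s))
    except ValueError:
        raise CorpusError(f"metadata row {row}: cannot parse {what}={value!r}")


def read_metadata(metadata_path: str | Path) -> list[ReportMeta]:
    """Read a comma- or tab-delimited metadata table into validated records."""
    path = Path(metadata_path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CorpusError(f"cannot parse metadata file {path}: {exc}") from exc
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusError(f"metadata file {path} lacks required columns: {missing}")

    metas: list[ReportMeta] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, accounting for header
        rid = str(row["report_id"]).strip()
        if rid in seen:
            raise CorpusError(f"metadata row {rownum}: duplicate report_id {rid!r}")
        seen.add(rid)
        try:
            minutes = float(row["minutes_since_lights_off"])
        except (TypeError, ValueError):
            raise CorpusError(
                f"metadata row {rownum}: cannot parse minutes_since_lights_off="
                f"{row['minutes_since_lights_off']!r}"
            )
        try:
            metas.append(
                ReportMeta(
                    report_id=rid,
                    participant_id=str(row["participant_id"]).strip(),
                    night_id=str(row["night_id"]).strip(),
                    stage=str(row["stage"]).strip(),
                    minutes_since_lights_off=minutes,
                    pirs=_parse_optional_int(row.get("pirs"), "pirs", rownum),
                    trc=_parse_optional_int(row.get("trc"), "trc", rownum),
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"metadata row {rownum}: {exc}") from exc
    return metas


def load_corpus(
    metadata_path: str | Path, text_dir: str | Path
) -> list[TokenizedReport]:
    """Load and tokenize a transcript corpus.

    One ``<report_id>.txt`` file per metadata row is expected in ``text_dir``;
    the returned list follows metadata order.  Missing transcript files are
    reported collectively in one error.
    """
    metas = read_metadata(metadata_path)
    text_dir = Path(text_dir)
    missing = [m.report_id for m in metas if not (text_dir / f"{m.report_id}.txt").exists()]
    if missing:
        raise CorpusError(
            f"missing transcript file(s) for report_id(s): {', '.join(missing)}"
        )
    reports = []
    for m in metas:
        raw = (text_dir / f"{m.report_id}.txt").read_text(encoding="utf-8")
        try:
            tokens, breaks = tokenize(raw)
        except EmptyReportError as exc:
            raise EmptyReportError(f"report {m.report_id!r}: {exc}") from exc
        reports.append(TokenizedReport(meta=m, tokens=tokens, break_positions=breaks))
    return reports
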