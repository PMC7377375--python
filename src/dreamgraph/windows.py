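"""Sliding-window graph measures: the report-length control.

Connectedness measures grow with word count, so whole-report graphs would
mostly reflect verbosity.  Instead a fixed-length window (default 30 words,
sliding one word at a time, i.e. 29-word overlap) is moved across the full
token sequence; graph measures are computed per window and averaged with
equal weight.  Paragraph breaks inside a window still suppress their
transition, but windows slide across the concatenated sequence regardless of
paragraph boundaries.  Reports shorter than one window must be excluded
upstream (see :func:`dreamgraph.corpus.filter_min_length`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import corpus as _corpus
from ._kernels import window_measures_kernel
from .corpus import TokenizedReport, effective_trc
from .graph import build_graph, graph_measures

WINDOW_LENGTH = 30  #: default window length (words)


class ReportTooShortError(ValueError):
    """Report shorter than one window; it should have been excluded upstream."""


@dataclass(frozen=True)
class WindowedMeasures:
    """Window-averaged connectedness measures for one report."""

    report_id: str
    n_windows: int
    mean_edges: float
    mean_lcc: float
    mean_lsc: float


def window_spans(
    n_tokens: int, window_length: int = WINDOW_LENGTH, step: int = 1
) -> list[range]:
    """Half-open index ranges [i, i+window_length) covering a token sequence."""
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if n_tokens < window_length:
        raise ReportTooShortError(
            f"{n_tokens} tokens < window length {window_length}"
        )
    return [
        range(i, i + window_length)
        for i in range(0, n_tokens - window_length + 1, step)
    ]


def encode_tokens(report: TokenizedReport) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code a report for the fast kernels.

    Returns ``(codes, noedge)`` where ``noedge[i]`` is True when the
    transition i -> i+1 is suppressed by a paragraph break.
    """
    codes_series, _ = pd.factorize(np.asarray(report.tokens, dtype=object))
    codes = codes_series.astype(np.int64)
    noedge = np.zeros(max(len(report.tokens) - 1, 1), dtype=np.bool_)
    for b in report.break_positions:
        noedge[b] = True
    return codes, noedge


def window_measure_array(
    report: TokenizedReport,
    window_length: int = WINDOW_LENGTH,
    step: int = 1,
    engine: str = "fast",
) -> np.ndarray:
    """Per-window (edges, lcc, lsc) as an (n_windows, 3) integer array.

    ``engine='fast'`` uses the numba kernel; ``engine='networkx'`` builds one
    networkx graph per window (reference path used for cross-validation).
    """
    spans = window_spans(report.n_tokens, window_length, step)
    if engine == "fast":
        codes, noedge = encode_tokens(report)
        return window_measures_kernel(codes, noedge, window_length, step)
    if engine == "networkx":
        breakset = set(report.break_positions)
        rows = []
        for span in spans:
            toks = report.tokens[span.start : span.stop]
            local_breaks = [
                b - span.start for b in breakset if span.start <= b < span.stop - 1
            ]
            gm = graph_measures(build_graph(toks, local_breaks))
            rows.append((gm.edges, gm.lcc, gm.lsc))
        return np.asarray(rows, dtype=np.int64)
    raise ValueError(f"unknown engine {engine!r}")


def windowed_measures(
    report: TokenizedReport,
    window_length: int = WINDOW_LENGTH,
    step: int = 1,
    engine: str = "fast",
) -> WindowedMeasures:
    """Window-averaged graph measures for one report (equal window weights)."""
    arr = window_measure_array(report, window_length, step, engine)
    means = arr.mean(axis=0)
    return WindowedMeasures(
        report_id=report.meta.report_id,
        n_windows=arr.shape[0],
        mean_edges=float(means[0]),
        mean_lcc=float(means[1]),
        mean_lsc=float(means[2]),
    )


def measures_table(
    reports: Sequence[TokenizedReport],
    window_length: int = WINDOW_LENGTH,
    step: int = 1,
) -> pd.DataFrame:
    """Per-report measures table joining metadata and windowed graph measures.

    Columns: report_id, participant_id, night_id, stage,
    minutes_since_lights_off, pirs, trc (human TRC or word-count proxy),
    n_tokens, n_paragraphs, n_windows, mean_edges, mean_lcc, mean_lsc.
    """
    rows = []
    for r in reports:
        wm = windowed_measures(r, window_length, step)
        rows.append(
            {
                "report_id": r.meta.report_id,
                "participant_id": r.meta.participant_id,
                "night_id": r.meta.night_id,
                "stage": r.meta.stage,
                "minutes_since_lights_off": r.meta.minutes_since_lights_off,
                "pirs": r.meta.pirs,
                "trc": effective_trc(r),
                "n_tokens": r.n_tokens,
                "n_paragraphs": r.n_paragraphs,
                "n_windows": wm.n_windows,
                "mean_edges": wm.mean_edges,
                "mean_lcc": wm.mean_lcc,
                "mean_lsc": wm.mean_lsc,
            }
        )
    return pd.DataFrame(rows)
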