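"""End-to-end orchestration: corpus -> measures -> nulls -> tests -> ledgers.

A :class:`RunConfig` fully determines a run; with a fixed ``master_seed`` the
emitted artifacts are byte-identical across repeats.  Outputs are delimited
text tables plus a JSON manifest recording the configuration hash, seed and
package version, so the sample-size bookkeeping of a study (reports
collected, excluded, analyzed) stays auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .corpus import (
    TokenizedReport,
    apply_stopword_filter,
    default_stopwords,
    filter_min_length,
    load_corpus,
)
from .nulls import N_SHUFFLES, null_table
from .simulate import SimulationConfig, generate_corpus, preset_dream_study
from .stats import (
    DEFAULT_PREDICTORS,
    build_ledger,
    ledger_to_frame,
    pirs_partialled_rows,
    pirs_rows,
    stage_comparison_table,
    stage_discernment_rows,
    time_of_night_rows,
)
from .windows import WINDOW_LENGTH, measures_table

logger = logging.getLogger("dreamgraph")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``metadata_path``/``text_dir`` point at a real corpus, or
    ``simulate`` carries a :class:`SimulationConfig`.  Defaults reproduce the
    reference analysis settings: 30-word windows sliding one word at a time,
    a 30-token inclusion floor, and 1,000 shuffles per report.
    """

    output_dir: str = "dreamgraph_run"
    metadata_path: str | None = None
    text_dir: str | None = None
    simulate: SimulationConfig | None = None
    window_length: int = WINDOW_LENGTH
    step: int = 1
    min_tokens: int = 30
    n_shuffles: int = N_SHUFFLES
    master_seed: int = 12345
    stopword_file: str | None = None  # None -> bundled list for the rerun
    filler_file: str | None = None
    analyses: dict = field(
        default_factory=lambda: {
            "wilcoxon": True,
            "time_of_night": True,
            "stage_ledger": True,
            "pirs_ledger": True,
            "pirs_partialled": True,
            "interactions": True,
            "paragraph_covariate": False,
            "stopword_rerun": False,
        }
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _analysis_tables(
    analyzed: pd.DataFrame,
    cfg: RunConfig,
    out: Path,
    suffix: str = "",
) -> None:
    """Run the requested comparisons on a merged measures+nulls table."""
    toggles = cfg.analyses
    extra = ("n_paragraphs",) if toggles.get("paragraph_covariate") else ()
    have_z = analyzed["lcc_z"].notna().any()
    predictors = (
        DEFAULT_PREDICTORS
        if have_z
        else tuple(p for p in DEFAULT_PREDICTORS if not p.endswith("_z"))
    )

    if toggles.get("wilcoxon"):
        tab = stage_comparison_table(analyzed, predictors)
        _write(tab, out / f"wilcoxon{suffix}.tsv")
    if toggles.get("time_of_night"):
        rows = build_ledger(
            analyzed,
            "minutes_since_lights_off",
            "gaussian",
            time_of_night_rows(predictors),
            extra_covariates=extra,
        )
        _write(ledger_to_frame(rows), out / f"ledger_time_of_night{suffix}.tsv")
    if toggles.get("stage_ledger"):
        rows = build_ledger(
            analyzed,
            "stage",
            "binomial",
            stage_discernment_rows(predictors),
            extra_covariates=extra,
        )
        _write(ledger_to_frame(rows), out / f"ledger_stage{suffix}.tsv")
    if toggles.get("pirs_ledger") and analyzed["pirs"].notna().any():
        rows = build_ledger(
            analyzed,
            "pirs",
            "ordinal",
            pirs_rows(predictors, interactions=toggles.get("interactions", True)),
            extra_covariates=extra,
        )
        _write(ledger_to_frame(rows), out / f"ledger_pirs{suffix}.tsv")
    if toggles.get("pirs_partialled") and analyzed["pirs"].notna().any():
        rows = build_ledger(
            analyzed,
            "stage",
            "binomial",
            pirs_partialled_rows(),
            extra_covariates=extra,
        )
        _write(ledger_to_frame(rows), out / f"ledger_pirs_partialled{suffix}.tsv")


def _measure_and_merge(
    kept: list[TokenizedReport], cfg: RunConfig, out: Path, suffix: str = ""
) -> pd.DataFrame:
    measures = measures_table(kept, cfg.window_length, cfg.step)
    nulls = null_table(
        kept, cfg.n_shuffles, cfg.window_length, cfg.step, cfg.master_seed
    )
    _write(measures, out / f"measures{suffix}.tsv")
    _write(nulls, out / f"nulls{suffix}.tsv")
    return measures.merge(
        nulls[["report_id", "lcc_z", "lsc_z"]], on="report_id", how="left"
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute a full run; returns the output directory.

    Stages: acquire corpus (load or simulate) -> minimum-length filter ->
    windowed measures -> shuffle nulls -> requested analyses (+ optional
    stop-word-filtered and paragraph-covariate reruns) -> manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        corpus, truth = generate_corpus(sim_cfg)
        (out / "ground_truth.json").write_text(truth.to_json() + "\n")
        logger.info("simulated %d reports", len(corpus))
    elif cfg.metadata_path and cfg.text_dir:
        corpus = load_corpus(cfg.metadata_path, cfg.text_dir)
        logger.info("loaded %d reports", len(corpus))
    else:
        raise ValueError("RunConfig needs either corpus paths or a simulate config")

    fr = filter_min_length(corpus, cfg.min_tokens)
    exclusion_lines = [fr.summary()]
    exclusion_lines += [
        f"excluded: {r.meta.report_id} ({r.meta.stage}, {r.n_tokens} tokens)"
        for r in fr.excluded
    ]
    if not fr.kept:
        raise ValueError("no reports meet the minimum length; nothing to analyze")

    analyzed = _measure_and_merge(fr.kept, cfg, out)
    _analysis_tables(analyzed, cfg, out)

    if cfg.analyses.get("stopword_rerun"):
        stopset = (
            default_stopwords()
            if cfg.stopword_file is None
            else cfg.stopword_file
        )
        filtered = []
        for r in fr.kept:
            try:
                filtered.append(apply_stopword_filter(r, stopset))
            except Exception as exc:
                exclusion_lines.append(
                    f"stopword rerun: {r.meta.report_id} dropped ({exc})"
                )
        fr2 = filter_min_length(filtered, cfg.min_tokens)
        exclusion_lines.append("stopword rerun: " + fr2.summary())
        if fr2.kept:
            analyzed2 = _measure_and_merge(fr2.kept, cfg, out, "_stopword")
            _analysis_tables(analyzed2, cfg, out, "_stopword")

    (out / "exclusions.log").write_text("\n".join(exclusion_lines) + "\n")

    manifest = {
        "package": "dreamgraph",
        "version": __version__,
        "master_seed": cfg.master_seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "n_reports_input": len(corpus),
        "n_reports_analyzed": len(fr.kept),
        "n_reports_excluded": len(fr.excluded),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1, default=str) + "\n"
    )
    return out
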