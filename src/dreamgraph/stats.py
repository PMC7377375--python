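"""Inferential machinery: paired Wilcoxon tests and hierarchical model ledgers.

Two families of analysis are provided.

**Participant-median Wilcoxon signed-rank tests.**  Because reports are
repeated within participants, stage comparisons (REM vs N2) first collapse
each participant to a per-stage median and then apply a signed-rank test to
the participant pairs.  The effect size is reported as ``r = |Z| / sqrt(N)``
where, by the default convention, ``N`` is the number of observations
entering the test (two per pair after zero differences are dropped).

**Bottom-up model-comparison ledgers.**  Outcomes (time of night, sleep
stage, ordinal complexity rating) are modeled by Gaussian mixed models,
random-intercept logistic regression, or cumulative-link ordinal models;
predictors are added one at a time to a stated baseline, and every ledger
row carries Nagelkerke's pseudo-R², its change versus the row's baseline,
and a likelihood-ratio-test p-value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from . import glmm

#: measure column -> display name used in ledger labels
MEASURE_LABELS = {
    "trc": "TRC",
    "mean_edges": "Edges",
    "mean_lcc": "LCC",
    "mean_lsc": "LSC",
    "lcc_z": "LCCz",
    "lsc_z": "LSCz",
    "n_paragraphs": "Paragraphs",
    "pirs": "PIRS",
    "stage": "Sleep Stage",
}

DEFAULT_PREDICTORS = ("trc", "mean_edges", "mean_lcc", "mean_lsc", "lcc_z", "lsc_z")


class NoInformationError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class EmptyPairingError(ValueError):
    """No participant has observations in both stages."""


# ---------------------------------------------------------------------------
# participant medians + Wilcoxon
# ---------------------------------------------------------------------------


@dataclass
class PairedMedians:
    participant_ids: list[str]
    rem_values: np.ndarray
    n2_values: np.ndarray
    excluded_participants: list[str] = field(default_factory=list)


def participant_medians(
    table: pd.DataFrame,
    measure: str,
    stages: tuple[str, str] = ("REM", "N2"),
) -> PairedMedians:
    """Per-participant medians of a measure in each of two stages.

    Participants lacking either stage are excluded (and listed in the result).
    """
    a, b = stages
    sub = table[table["stage"].isin(stages)][["participant_id", "stage", measure]]
    sub = sub.dropna(subset=[measure])
    med = sub.groupby(["participant_id", "stage"], sort=True)[measure].median()
    pids, va, vb, excluded = [], [], [], []
    for pid in sorted(sub["participant_id"].unique()):
        try:
            x, y2 = med[(pid, a)], med[(pid, b)]
        except KeyError:
            excluded.append(pid)
            continue
        pids.append(pid)
        va.append(float(x))
        vb.append(float(y2))
    if not pids:
        raise EmptyPairingError(
            f"no participant has {measure!r} observations in both of {stages}"
        )
    return PairedMedians(
        participant_ids=pids,
        rem_values=np.asarray(va),
        n2_values=np.asarray(vb),
        excluded_participants=excluded,
    )


@dataclass(frozen=True)
class WilcoxonResult:
    z: float
    p: float
    r: float
    n_pairs_used: int
    n_obs: int
    w_plus: float
    method: str


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic under sign flips.

    Mid-ranks may be half-integers, so ranks are doubled to integers and the
    exact distribution of 2*W+ is built by dynamic-programming convolution.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x,
    y=None,
    *,
    n_obs_convention: str = "observations",
    method: str = "auto",
    continuity: bool = False,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test with a normal-approximation Z and effect size.

    ``x`` may be a :class:`PairedMedians` (differences taken as N2 - REM, so a
    REM excess yields a negative Z, the usual reporting convention for this
    comparison) or an array of first-member values with ``y`` the second.

    Zero differences are dropped; ties are mid-ranked and the normal
    approximation uses the tie-corrected variance.  ``method='exact'`` (or
    ``'auto'`` with <= 12 pairs) computes the exact sign-flip permutation p;
    the reported Z is always the normal approximation.  ``n_obs_convention``
    is ``'observations'`` (N = 2 * pairs used, the default) or ``'pairs'``.
    """
    if isinstance(x, PairedMedians):
        d = x.n2_values - x.rem_values
    else:
        x = np.asarray(x, dtype=float)
        d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise NoInformationError("all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise NoInformationError("zero variance in signed ranks")
    dev = w_plus - mu
    if continuity:
        dev -= 0.5 * np.sign(dev)
    z = dev / np.sqrt(var)

    use_exact = method == "exact" or (method == "auto" and n <= 12)
    if use_exact:
        p = _exact_signed_rank_p(ranks, w_plus)
        used = "exact"
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        used = "normal"

    if n_obs_convention == "observations":
        n_obs = 2 * n
    elif n_obs_convention == "pairs":
        n_obs = n
    else:
        raise ValueError(f"unknown n_obs_convention {n_obs_convention!r}")
    return WilcoxonResult(
        z=float(z),
        p=p,
        r=float(abs(z) / np.sqrt(n_obs)),
        n_pairs_used=n,
        n_obs=n_obs,
        w_plus=w_plus,
        method=used,
    )


def stage_comparison_table(
    measures: pd.DataFrame,
    measure_columns: tuple[str, ...] = DEFAULT_PREDICTORS,
    stages: tuple[str, str] = ("REM", "N2"),
    n_obs_convention: str = "observations",
) -> pd.DataFrame:
    """Stage-comparison summary: one row per measure.

    Cells summarize participant medians (median and SD across participants)
    per stage, plus the signed-rank Z, effect size r, and p-value.
    """
    rows = []
    for col in measure_columns:
        pm = participant_medians(measures, col, stages)
        res = wilcoxon_signed_rank(pm, n_obs_convention=n_obs_convention)
        rows.append(
            {
                "measure": MEASURE_LABELS.get(col, col),
                f"{stages[0].lower()}_median": float(np.median(pm.rem_values)),
                f"{stages[0].lower()}_sd": float(np.std(pm.rem_values, ddof=1)),
                f"{stages[1].lower()}_median": float(np.median(pm.n2_values)),
                f"{stages[1].lower()}_sd": float(np.std(pm.n2_values, ddof=1)),
                "z": res.z,
                "r": res.r,
                "p": res.p,
                "n_pairs": res.n_pairs_used,
                "significant": res.p < 0.05,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted model with everything needed for nested comparison."""

    label: str
    family: str
    outcome: str
    terms: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]
    random: tuple[str, ...]
    loglik: float
    n_params: int
    n_obs: int
    coefficients: dict[str, float]
    converged: bool
    notes: list[str] = field(default_factory=list)


def _encode_column(df: pd.DataFrame, col: str) -> np.ndarray:
    if col == "stage":
        vals = df["stage"].to_numpy()
        bad = set(vals) - {"REM", "N2"}
        if bad:
            raise ValueError(f"stage predictor requires REM/N2 only, found {bad}")
        return (vals == "REM").astype(float)
    return df[col].to_numpy(dtype=float)


def _design_matrix(
    df: pd.DataFrame,
    terms: tuple[str, ...],
    interactions: tuple[tuple[str, str], ...],
    intercept: bool,
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for t in terms:
        cols.append(_encode_column(df, t))
        names.append(t)
    for a, b in interactions:
        cols.append(_encode_column(df, a) * _encode_column(df, b))
        names.append(f"{a}:{b}")
    return np.column_stack(cols) if cols else np.empty((len(df), 0)), tuple(names)


def fit_model(
    data: pd.DataFrame,
    outcome: str,
    terms: tuple[str, ...] = (),
    family: str = "gaussian",
    interactions: tuple[tuple[str, str], ...] = (),
    random: tuple[str, ...] = ("participant_id", "night_id"),
    label: str | None = None,
    n_quad: int = 25,
    sigma_fixed: float | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model in a ledger.

    ``family`` is ``'gaussian'`` (mixed linear model via statsmodels MixedLM,
    ML), ``'binomial'`` (random-intercept logistic via quadrature; outcome
    must be binary or the ``stage`` column), or ``'ordinal'``
    (proportional-odds cumulative logit via quadrature).

    ``random`` names grouping factors for random intercepts.  The Gaussian
    family supports participant plus night-within-participant; the quadrature
    families support the participant intercept and drop a requested night
    factor with a note.  Rows with missing values in any used column are
    dropped.
    """
    label = label or " + ".join(MEASURE_LABELS.get(t, t) for t in terms) or "Null"
    terms = tuple(terms)
    interactions = tuple(tuple(i) for i in interactions)
    used_cols = {outcome, *terms, *itertools.chain.from_iterable(interactions)}
    used_cols |= set(random)
    used_cols &= set(data.columns) | {"stage"}
    work = data.dropna(subset=[c for c in used_cols if c in data.columns]).copy()
    notes: list[str] = []
    n_dropped = len(data) - len(work)
    if n_dropped:
        notes.append(f"dropped {n_dropped} row(s) with missing values")

    if family == "gaussian":
        return _fit_gaussian(work, outcome, terms, interactions, random, label, notes)

    groups = None
    if random:
        if "participant_id" in random:
            groups = work["participant_id"].to_numpy()
        extra = [r for r in random if r != "participant_id"]
        if extra:
            notes.append(
                f"random factor(s) {extra} dropped: quadrature families "
                "support a single (participant) intercept"
            )

    if family == "binomial":
        if outcome == "stage":
            yvals = work["stage"].to_numpy()
            y = (yvals == "REM").astype(float)
        else:
            y = work[outcome].to_numpy(dtype=float)
            if not set(np.unique(y)) <= {0.0, 1.0}:
                raise ValueError(f"binomial outcome {outcome!r} must be binary")
        X, names = _design_matrix(work, terms, interactions, intercept=True)
        fit = glmm.fit_binomial(
            y, X, groups=groups, beta_names=names, n_quad=n_quad,
            sigma_fixed=sigma_fixed,
        )
    elif family == "ordinal":
        y = work[outcome].to_numpy()
        if np.any(~np.isfinite(y.astype(float))):
            raise ValueError(f"ordinal outcome {outcome!r} contains non-finite values")
        X, names = _design_matrix(work, terms, interactions, intercept=False)
        fit = glmm.fit_ordinal(
            y.astype(int), X, groups=groups, beta_names=names, n_quad=n_quad,
            sigma_fixed=sigma_fixed,
        )
    else:
        raise ValueError(f"unknown family {family!r}")

    if not fit.converged:
        notes.append(f"optimizer: {fit.message}")
    coeffs = dict(zip(fit.beta_names, (float(b) for b in fit.beta)))
    if fit.sigma is not None:
        coeffs["sigma_participant"] = float(fit.sigma)
    if fit.thresholds is not None:
        for i, c in enumerate(fit.thresholds):
            coeffs[f"cut_{i}"] = float(c)
    return ModelFit(
        label=label,
        family=family,
        outcome=outcome,
        terms=terms,
        interactions=interactions,
        random=tuple(random),
        loglik=fit.loglik,
        n_params=fit.n_params,
        n_obs=fit.n_obs,
        coefficients=coeffs,
        converged=fit.converged,
        notes=notes,
    )


def _fit_gaussian(work, outcome, terms, interactions, random, label, notes):
    import statsmodels.formula.api as smf

    df = work.copy()
    rhs_cols, centers, scales = [], {}, {}
    raw_names = []
    for t in terms:
        cname = f"_t_{t}"
        df[cname] = _encode_column(df, t)
        rhs_cols.append(cname)
        raw_names.append(t)
    for a, b in interactions:
        cname = f"_i_{a}_{b}"
        df[cname] = _encode_column(df, a) * _encode_column(df, b)
        rhs_cols.append(cname)
        raw_names.append(f"{a}:{b}")
    # standardize continuous predictors for optimizer conditioning; this is a
    # pure reparameterization of the fixed effects (ML loglik unchanged)
    for c in rhs_cols:
        col = df[c]
        if col.nunique() > 2 and col.std() > 0:
            centers[c], scales[c] = float(col.mean()), float(col.std())
            df[c] = (col - centers[c]) / scales[c]
    rhs = " + ".join(rhs_cols) if rhs_cols else "1"
    formula = f"{outcome} ~ {rhs}"

    use_participant = "participant_id" in random
    use_night = "night_id" in random
    if use_night and df["night_id"].nunique() < 2:
        use_night = False
        notes.append("night random intercept dropped: fewer than 2 night levels")

    if not use_participant:
        res = smf.ols(formula, data=df).fit()
        loglik = float(res.llf)
        n_params = len(res.params) + 1  # + residual variance
        params = dict(res.params)
        converged = True
    else:
        vcf = {"night": "0 + C(night_id)"} if use_night else None
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for meth in ("lbfgs", "bfgs", "powell", "cg"):
                model = smf.mixedlm(
                    formula,
                    data=df,
                    groups=df["participant_id"],
                    re_formula="1",
                    vc_formula=vcf,
                )
                try:
                    cand = model.fit(reml=False, method=meth, maxiter=500)
                except Exception:
                    continue
                if np.isfinite(cand.llf) and (best is None or cand.llf > best.llf):
                    best = cand
        if best is None:
            raise RuntimeError(f"gaussian mixed model failed to fit: {label}")
        res = best
        loglik = float(res.llf)
        n_var = 1 + (1 if use_night else 0) + 1  # participant, night, residual
        n_params = int(res.k_fe) + n_var
        params = dict(res.fe_params)
        converged = bool(getattr(res, "converged", True))
        if not converged:
            notes.append("MixedLM did not report convergence")

    # map coefficients back to the raw predictor scale
    coeffs = {}
    shift = 0.0
    for c, raw in zip(rhs_cols, raw_names):
        b = float(params.get(c, 0.0))
        if c in scales:
            coeffs[raw] = b / scales[c]
            shift += b * centers[c] / scales[c]
        else:
            coeffs[raw] = b
    coeffs["intercept"] = float(params.get("Intercept", 0.0)) - shift
    return ModelFit(
        label=label,
        family="gaussian",
        outcome=outcome,
        terms=tuple(terms),
        interactions=tuple(interactions),
        random=tuple(random),
        loglik=loglik,
        n_params=n_params,
        n_obs=len(df),
        coefficients=coeffs,
        converged=converged,
        notes=notes,
    )


def lr_test(nested: ModelFit, full: ModelFit, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested pair: returns (chi2, df, p)."""
    if nested.family != full.family:
        raise ValueError(
            f"cannot compare families {nested.family!r} and {full.family!r}"
        )
    if nested.n_obs != full.n_obs:
        raise ValueError(
            f"model data differ: n_obs {nested.n_obs} vs {full.n_obs}"
        )
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError(
            f"{full.label!r} has fewer parameters than {nested.label!r}"
        )
    chi2 = 2.0 * (full.loglik - nested.loglik)
    if chi2 < -max(tol, 1e-6 * abs(full.loglik)):
        raise ValueError(
            f"full model {full.label!r} has lower likelihood than nested "
            f"{nested.label!r} (chi2 = {chi2:.4g}); refit or check nesting"
        )
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(sps.chi2.sf(chi2, df))


def nagelkerke_r2(fit: ModelFit, null_fit: ModelFit) -> float:
    """Nagelkerke's pseudo-R² of ``fit`` against its null model.

    ``R² = [1 - exp((2/n)(LL0 - LL1))] / [1 - exp((2/n) LL0)]``, clipped to
    [0, 1].
    """
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("n_obs mismatch between fit and null model")
    n = fit.n_obs
    ll0, ll1 = null_fit.loglik, fit.loglik
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll0)
    if max_r2 <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_r2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# ledgers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LedgerRowSpec:
    """One planned comparison: a model and the baseline it is tested against."""

    label: str
    terms: tuple[str, ...]
    baseline_terms: tuple[str, ...]
    baseline_label: str
    interactions: tuple[tuple[str, str], ...] = ()
    baseline_interactions: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class LedgerRow:
    label: str
    pseudo_r2: float
    pseudo_r2_change: float
    chi2: float
    df: int
    p: float
    baseline_label: str
    significant: bool
    loglik: float
    n_obs: int


def _ledger_columns(rows: tuple[LedgerRowSpec, ...]) -> set[str]:
    cols = set()
    for r in rows:
        cols |= set(r.terms) | set(r.baseline_terms)
        for a, b in r.interactions + r.baseline_interactions:
            cols |= {a, b}
    return cols


def build_ledger(
    data: pd.DataFrame,
    outcome: str,
    family: str,
    rows: tuple[LedgerRowSpec, ...],
    random: tuple[str, ...] = ("participant_id", "night_id"),
    extra_covariates: tuple[str, ...] = (),
    n_quad: int = 25,
) -> list[LedgerRow]:
    """Fit a bottom-up model-comparison ledger.

    Every model in the ledger is fitted on the complete cases of the union of
    all columns used by any row, so nested pairs always share data.
    ``extra_covariates`` (e.g. ``('n_paragraphs',)`` for the paragraph-count
    confound rerun) are appended to every model including the null.
    """
    used = _ledger_columns(rows) | {outcome} | set(extra_covariates)
    used = {c for c in used if c != "stage" or "stage" in data.columns}
    present = [c for c in used if c in data.columns]
    work = data.dropna(subset=present).reset_index(drop=True)

    cache: dict[tuple, ModelFit] = {}

    def get_fit(terms, inters, label):
        terms = tuple(extra_covariates) + tuple(terms)
        key = (terms, tuple(inters))
        if key not in cache:
            cache[key] = fit_model(
                work, outcome, terms, family, interactions=inters,
                random=random, label=label, n_quad=n_quad,
            )
        return cache[key]

    null_fit = get_fit((), (), "Null")
    out = []
    for spec in rows:
        full = get_fit(spec.terms, spec.interactions, spec.label)
        base = get_fit(spec.baseline_terms, spec.baseline_interactions, spec.baseline_label)
        chi2, dof, p = lr_test(base, full)
        r2 = nagelkerke_r2(full, null_fit)
        r2_base = nagelkerke_r2(base, null_fit)
        out.append(
            LedgerRow(
                label=spec.label,
                pseudo_r2=r2,
                pseudo_r2_change=r2 - r2_base,
                chi2=chi2,
                df=dof,
                p=p,
                baseline_label=spec.baseline_label,
                significant=p < 0.05,
                loglik=full.loglik,
                n_obs=full.n_obs,
            )
        )
    return out


def ledger_to_frame(rows: list[LedgerRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "pseudo_r2": r.pseudo_r2,
                "pseudo_r2_change": r.pseudo_r2_change,
                "p": r.p,
                "significant": r.significant,
                "baseline": r.baseline_label,
                "chi2": r.chi2,
                "df": r.df,
                "loglik": r.loglik,
                "n_obs": r.n_obs,
            }
            for r in rows
        ]
    )


def _lab(col: str) -> str:
    return MEASURE_LABELS.get(col, col)


def time_of_night_rows(
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> tuple[LedgerRowSpec, ...]:
    """Gaussian ledger: minutes since lights-off ~ stage, then stage + X."""
    rows = [
        LedgerRowSpec("Sleep Stage", ("stage",), (), "Null"),
    ]
    for x in predictors:
        rows.append(
            LedgerRowSpec(
                f"Sleep Stage + {_lab(x)}", ("stage", x), ("stage",), "Sleep Stage"
            )
        )
    return tuple(rows)


def stage_discernment_rows(
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    composites: bool = True,
) -> tuple[LedgerRowSpec, ...]:
    """Binomial ledger: stage ~ X (vs null), then TRC+LCC in both orders."""
    rows = [LedgerRowSpec(_lab(x), (x,), (), "Null") for x in predictors]
    if composites and "trc" in predictors and "mean_lcc" in predictors:
        rows.append(
            LedgerRowSpec("TRC + LCC", ("trc", "mean_lcc"), ("trc",), "TRC")
        )
        rows.append(
            LedgerRowSpec("LCC + TRC", ("mean_lcc", "trc"), ("mean_lcc",), "LCC")
        )
    return tuple(rows)


def pirs_rows(
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    interactions: bool = True,
) -> tuple[LedgerRowSpec, ...]:
    """Ordinal ledger: PIRS ~ stage, stage + X, TRC composites, interactions."""
    rows = [LedgerRowSpec("Sleep Stage", ("stage",), (), "Null")]
    for x in predictors:
        rows.append(
            LedgerRowSpec(
                f"Sleep Stage + {_lab(x)}", ("stage", x), ("stage",), "Sleep Stage"
            )
        )
    composite_xs = [x for x in predictors if x not in ("trc",)]
    if "trc" in predictors:
        for x in composite_xs:
            rows.append(
                LedgerRowSpec(
                    f"Sleep Stage + TRC + {_lab(x)}",
                    ("stage", "trc", x),
                    ("stage", "trc"),
                    "Sleep Stage + TRC",
                )
            )
        if {"mean_lcc", "lsc_z"} <= set(predictors):
            rows.append(
                LedgerRowSpec(
                    "Sleep Stage + TRC + LSCz + LCC",
                    ("stage", "trc", "lsc_z", "mean_lcc"),
                    ("stage", "trc", "lsc_z"),
                    "Sleep Stage + TRC + LSCz",
                )
            )
            rows.append(
                LedgerRowSpec(
                    "Sleep Stage + TRC + LCC + LSCz",
                    ("stage", "trc", "mean_lcc", "lsc_z"),
                    ("stage", "trc", "mean_lcc"),
                    "Sleep Stage + TRC + LCC",
                )
            )
    if interactions:
        for x in predictors:
            rows.append(
                LedgerRowSpec(
                    f"Sleep Stage × {_lab(x)}",
                    ("stage", x),
                    ("stage", x),
                    f"Sleep Stage + {_lab(x)}",
                    interactions=(("stage", x),),
                )
            )
    return tuple(rows)


def pirs_partialled_rows() -> tuple[LedgerRowSpec, ...]:
    """Binomial ledger: stage ~ PIRS, then PIRS + LCC / TRC / both."""
    return (
        LedgerRowSpec("PIRS", ("pirs",), (), "Null"),
        LedgerRowSpec("PIRS + LCC", ("pirs", "mean_lcc"), ("pirs",), "PIRS"),
        LedgerRowSpec("PIRS + TRC", ("pirs", "trc"), ("pirs",), "PIRS"),
        LedgerRowSpec(
            "PIRS + LCC + TRC", ("pirs", "mean_lcc", "trc"), ("pirs",), "PIRS"
        ),
    )
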