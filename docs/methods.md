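# Methods

## Word graphs from transcripts

A transcript is tokenized by lowercasing, splitting on whitespace and
stripping every non-alphanumeric character except intra-word apostrophes and
hyphens; blank lines mark paragraph (turn-taking) boundaries. The directed
word graph of a token sequence has one node per distinct word and one edge
per observed transition between consecutive words. Three choices fix the
graph's semantics:

- **Edge multiplicity.** Edges are *distinct* ordered pairs: a transition
  that recurs contributes one edge. Counting transition tokens instead would
  pin the Edges measure of a 30-word window at ≤ 29 with essentially no
  variance, which is inconsistent with the variation the measure is meant to
  capture; distinct-edge counting yields values slightly below 29 that move
  with repetition.
- **Self-loops.** Immediate word repetition creates a self-loop and is kept
  as an edge. A lone node is strongly connected to itself, so LSC ≥ 1
  always.
- **Paragraph breaks.** No transition is created across a paragraph
  boundary. Break positions travel with the token sequence so every
  downstream stage (windows, shuffles) respects them.

Measures per graph: `Edges` = |E|; `LCC` = size of the largest weakly
connected component (direction-blind reachability); `LSC` = size of the
largest strongly connected component (mutual directed reachability).
Components are computed with standard linear-time algorithms (networkx in
the reference path; a numba kernel using union-find and iterative Tarjan in
the sliding-window fast path — the two paths are asserted equal, and equal
to a brute-force reachability-closure oracle, in the test suite).

## Sliding window

Connectedness grows mechanically with word count, and REM reports are
systematically longer than N2 reports, so whole-report graphs mostly measure
verbosity. A fixed window of 30 words (default; step 1, i.e. 29-word
overlap) slides across the concatenated token sequence; per-window measures
are averaged with equal weight. Windows slide across paragraph boundaries,
but a break inside a window still suppresses its transition — paragraph
structure therefore still affects window graphs, which is what makes the
paragraph-count confound analysis meaningful. Reports with fewer than 30
tokens (`min_tokens`, configurable) are excluded and logged by stage. No
partial trailing windows are emitted.

## Shuffle null and z-scores

Each report is its own null ensemble: the token multiset is permuted
uniformly (default 1,000 shuffles) with paragraph-break indices held fixed,
and the windowed pipeline is recomputed per shuffle. Holding breaks fixed
keeps the paragraph-count covariate identical between observed and null.
The observed windowed means are standardized against the ensemble:
`z = (observed − null mean) / null SD`, with the SD in population form
(denominator n). A zero null SD (e.g. a report of one repeated word, or any
token multiset whose permutations all yield identical windowed means) makes
z undefined; this is flagged, never raised.

Randomness is seeded per report from a hash of `(master_seed, report_id)`,
so corpus-level results are independent of report ordering and
bit-reproducible.

Very short reports (30–39 tokens) have almost no permutation variety per
window; their null distributions are coarse and strongly skewed, and a
normal-deviate reading of their z-scores is unreliable. The calibration
study (below) therefore uses reports of ≥ 40 tokens; the pipeline itself
still scores short reports and leaves the interpretation to the analyst.

## Statistical comparison

**Wilcoxon signed-rank on participant medians.** Reports are repeated
within participants, so stage contrasts collapse each participant to a
per-stage median first; participants lacking either stage are excluded and
logged. Zero differences are dropped, ties are mid-ranked, and the reported
Z uses the tie-corrected normal approximation (continuity correction off by
default; a documented switch). For ≤ 12 pairs an exact sign-flip permutation
p is available, computed by dynamic-programming convolution over doubled
mid-ranks. The effect size is r = |Z|/√N with N = 2 × (pairs used) by
default — the convention consistent with published stage-comparison tables
where each pair contributes two observations; N = pairs is available as a
config option. Summary cells report the median and SD of the participant
medians per stage.

**Model ledgers.** Four bottom-up designs are provided:

1. *Time of night* (Gaussian): minutes since lights-off ~ sleep stage, then
   stage + each predictor (TRC, Edges, LCC, LSC, LCCz, LSCz).
2. *Stage discernment* (binomial): stage ~ each predictor vs the null model,
   then the TRC/LCC composites in both orders.
3. *Complexity rating* (ordinal, PIRS 0–9): PIRS ~ stage, stage + each
   predictor, TRC composites, the LCC/LSCz joint composites, and
   stage × predictor interaction rows.
4. *PIRS-partialled stage discernment* (binomial): stage ~ PIRS, then
   PIRS + LCC / TRC / both.

Each row carries Nagelkerke's pseudo-R²
`[1 − exp((2/n)(LL0 − LL1))]/[1 − exp((2/n)LL0)]` (clipped to [0, 1],
computed against the intercept-plus-random-effects null so that it reflects
fixed-effect contribution), the pseudo-R² change against the row's stated
baseline, and a likelihood-ratio χ² p-value. All models of a ledger are
fitted on the complete cases of the union of the ledger's columns, so nested
pairs always share data. An optional covariate (`n_paragraphs`) can be
appended to every model including the null for the paragraph-confound rerun;
a stop-word-filtered rerun repeats the whole measure-and-model pipeline on
filtered tokens (bundled standard English stop-word list, or any
one-word-per-line file).

**Model fitting.** Gaussian mixed models use statsmodels MixedLM (ML, not
REML, so log-likelihoods are comparable across fixed-effect nestings) with a
participant random intercept and a night-within-participant variance
component. Binomial and ordinal families are fitted by direct maximum
likelihood with the participant random intercept integrated out by
Gauss–Hermite quadrature (25 nodes); a requested night factor is dropped
with a log entry for these families — with 2–3 nights per participant the
night variance is weakly identified, and the single-factor quadrature keeps
the likelihood exact and fast. The ordinal family is a proportional-odds
cumulative-logit model with cutpoints parameterized as
(first, log-spacings) to enforce monotonicity. At σ = 0 the quadrature
collapses exactly to the fixed-effects likelihood, which provides the
nesting-limit checks (plain logistic ML, statsmodels OrderedModel) used in
the tests; the random-intercept logistic fit is cross-checked against
lme4::glmer (nAGQ = 25) to ~10⁻³ in log-likelihood.

Numerical choices: continuous predictors are standardized internally for
optimizer conditioning and coefficients mapped back to the raw scale (the
likelihood is invariant); σ is optimized on [0, 20] with L-BFGS-B; logistic
starting values come from ridge-stabilized Newton steps, with |η| > 15
flagged as possible separation; the Gaussian path retries several
optimizers and keeps the best log-likelihood, since MixedLM's default
optimizer occasionally stalls and a full model must never report a lower
likelihood than its nested baseline.

## Synthetic corpus generator

The generator emulates a laboratory awakening protocol: participants ×
nights × awakenings, each awakening assigned a stage (REM/N2) and producing
a report only on successful recall. Reports are emitted by a **two-urn
recency process**: with probability `recurrence_prob` the next token re-uses
one of the last `recurrence_range` *distinct* words (uniformly; the chosen
word becomes most recent), otherwise a previously unused vocabulary word is
introduced. This is deliberately simpler than a Markov chain: the recurrence
range is a single interpretable dial for how far back words recur, which is
exactly the structural property the windowed LCC is sensitive to — a
recurrence whose antecedent precedes the current window contributes a new
distinct word to that window, so longer-range recurrence raises windowed
connectedness.

Stage-dependent parameters and their preset defaults (`preset_dream_study`):

| parameter | REM | N2 | rationale |
|---|---|---|---|
| recall probability | .907 | .724 | published recall prevalences |
| report length (log-normal median, tokens) | 100 | 70 | REM reports longer; raw token counts sit above judged recall counts, and ~95% of reports clear the 30-token floor |
| log-length σ | 0.5 | 0.5 | realistic spread with few floor exclusions |
| recurrence probability | .22 | .22 | gives ~24 distinct words per 30-word window, matching observed windowed Edges/LCC scale |
| recurrence range (distinct words) | 12 | 4 | REM words recur over a longer range |
| paragraphs per report (1 + Poisson) | 2.5 | 3.5 | N2 reports more fragmented |

Stage probabilities (.27 REM / .73 N2) over 20 participants × 2 nights × 5
awakenings yield ~200 awakenings and ~135–150 analyzable reports, matching
the scale of the reference corpus (133 reports). Participant and night
random intercepts act on log-length (SD 0.15 and 0.08). A latent complexity
score — a fixed standardized function of log report length and log
recurrence range plus Gaussian noise (SD 0.5) — is discretized through fixed
equal-width thresholds into the ordinal 0–9 rating, so recovery tests know
the ground truth; the thresholds are fixed rather than estimated precisely
so that truth is known. TRC is the token count (no filler words are
generated; fillers add no structure the pipeline tests).

Two derived configurations support validation: `preset_null_stages`
equalizes every stage parameter (zero-effect corpora for type-I studies)
and `preset_recurrence_contrast` differs *only* in recurrence range (12 vs
4) for power studies.

**What the generator does not emulate.** Token sequences are not language:
there is no syntax, no Zipfian word-frequency skew, and no function-word
backbone. One visible consequence is that generated reports sit *below*
their shuffle null in windowed LCC (negative LCCz, occasionally by many
null SDs), whereas real speech tends to score near or above it; the
generator's z-scores are heavier-tailed than real ones. Passing calibration
and power tests therefore show that the pipeline's statistics behave
correctly for corpora with the assumed structure — not that the generator
reproduces the joint distribution of real dream reports.

## Validation studies

`dreamgraph.studies` packages three simulation experiments (also run by
`scripts/acceptance.py` and the acceptance tests):

- **Null calibration** — 200 reports whose token order is itself a uniform
  permutation are scored against their own 1,000-shuffle nulls; mean LCCz
  should lie near 0 and |z| > 1.96 should fire at ≈ 5%.
- **Type-I calibration** — on 200 zero-effect corpora, each predictor of the
  stage-discernment ledger should reject at ≈ 5%. These runs compute
  z-score predictors with 300 shuffles per report rather than 1,000 — the
  largest ensemble that keeps the study tractable on one CPU. Ensemble size
  matters here: much smaller ensembles (e.g. a few dozen shuffles) add
  t-like tail noise to an already heavy-tailed predictor, and heavy-tailed,
  high-leverage predictors are exactly where the χ²(1) likelihood-ratio
  approximation is weakest at n ≈ 140. Even at the method's own conditions
  the z-predictor rejection rates run slightly above nominal (~0.05–0.08
  across seeds), a finite-sample property of the likelihood-ratio test
  under this generator's heavy-tailed z distribution rather than an
  implementation defect (the p-value distributions are otherwise uniform,
  and the fits match independent implementations).
- **Power/recovery** — on 100 recurrence-contrast corpora, the
  participant-median windowed LCC should be larger in REM nearly always and
  the stage ledger should flag LCC at α = .05 in the large majority.

Problem sizes used by the studies (200/200/100 corpora; 1,000/300 shuffles)
are the package's chosen defaults for these experiments.

## Known limitations

- The quadrature families support one random-intercept factor
  (participant); crossed or nested binomial/ordinal random effects are out
  of scope.
- Nagelkerke's pseudo-R² for the Gaussian family inherits the usual caveat
  that likelihood-based R² for continuous densities is scale-sensitive; it
  is comparable within a ledger (fixed outcome), not across outcomes.
- The exact Wilcoxon mode enumerates the sign-flip distribution and is
  intended for ≤ 12 pairs; larger samples use the tie-corrected normal
  approximation.
- Windowed measures of reports barely longer than one window rest on very
  few windows; their z-scores are reported but poorly calibrated (see
  above).
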