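# Methods

## The scoring system

`vetprio` implements a closed weighted scoring system for prioritising
infectious animal diseases and for locating research gaps in their
control tools. A *model* is an ordered list of criteria; each criterion
groups `I` sub-criteria (levels) scored on an integer scale with
maximum `X`; the per-level weighting coefficient is `W = 100/(X·I)`.
This construction normalises every criterion's maximum weighted total
to exactly 100, which is the sense in which all criteria "carry equal
weight": no criterion can contribute more than any other, regardless of
how many levels it happens to have.

Two concrete models ship with the package:

| model          | criteria (levels)                                              | scale       |
|----------------|----------------------------------------------------------------|-------------|
| prioritisation | disease knowledge (10), animal health & welfare (3), public health (6), wider society (3), trade (4), control tools (3) | 0..4, control tools −2..+2 |
| gap analysis   | diagnostic tools (12), vaccination tools (11), pharmaceutical tools (11) | −2..+2      |

The control-tools sign convention is deliberate: a disease with good
existing diagnostics, vaccines and pharmaceuticals receives negative
control-tool scores, lowering its priority; missing tools add to the
total and push the disease up the list. In the gap model, +2 means an
important gap and −2 means current tools are appropriate, so a
positive weighted area total flags a research gap.

## Rounding conventions

All rounding in the package is **half away from zero** (so 2.5 → 3,
−2.5 → −3), applied uniformly to: displayed coefficients (two
decimals), integer gap-area totals, even-panel medians, and the panel
coverage percentage. Published renderings of the same coefficient are
not internally consistent (100/6 appears as 16.66, and 100/24 as both
4.16 and 4.17 in different tables); we store coefficients at full
precision, display 16.67 and 4.17, and treat the divergent printed
renderings as rounding artefacts rather than attempting to reproduce
two contradictory conventions at once. Prioritisation overall scores
are never rounded by the engine; the published overall scores in the
fixtures are kept as the already-rounded integers they were printed
as.

## Availability override in the gap model

Each gap area's first sub-criterion records product availability. When
a disease has *no* product in an area, not even in development, the
area is assigned a fixed maximum rather than its scored total. The
stated rule caps the raw score of the whole criterion at 20, which
after weighting yields 83 (diagnostics, 12 levels) or 91 (the 11-level
areas); yet published gap tables show an apparent ceiling of 40, which
that rule does not explain. Both readings are implemented as modes of
`gap_totals`:

* `raw_cap` (default) — set the raw score sum to 20, then weight; the
  most literal reading of the rule;
* `display_cap` — set the final integer to a configured ceiling
  (default 40), matching the observed table ceiling.

The mode is a logged configuration option; the per-sub-criterion
scores needed to decide between them empirically were never published.

## Expert-panel aggregation

Each disease is scored by its own panel. The elicitation protocol asks
panels to reach consensus; it does not define a numeric aggregation
rule, so the package must choose one for machine aggregation:

* **Consensus statistic: median** per sub-criterion. It is robust to a
  single outlier expert, reproduces unanimous panels exactly, and is
  always within the range of the expert scores.
* **Even panels**: a half-integer median rounds away from zero, i.e.
  toward the more extreme (higher-priority or deeper-gap) value — the
  conservative direction for a prioritisation exercise. The result is
  clamped to the criterion's scale (a no-op for the contiguous scales
  of the shipped models).
* **Dissent**: a sub-criterion whose expert score range (max − min)
  exceeds `dissent_threshold` produces a `DissentRecord` alongside the
  consensus value. The default threshold of 1 treats adjacent scores
  as agreement and flags a spread of two or more; a failure to agree
  is reported as a knowledge gap, never silently averaged away.
  Because the real protocol does not state what value was recorded
  when consensus failed, we emit both a consensus value and the
  dissent record rather than guessing.
* **Availability flags** (gap panels) aggregate by majority vote, ties
  resolved toward the more pessimistic flag (none > in_development >
  available).
* **Coverage**: a panel meets the composition minimum when at least
  four experts together span the four required roles (diagnostic,
  epidemiology, industry, economics). All experts weigh equally; the
  protocol offers no role weighting.

## Ranking and sensitivity

Rankings use **competition ranking**: tied scores share a rank, the
next rank is skipped (1, 2, 2, 4), and ties are listed alphabetically
by disease name. The published tables do not document a tie rule —
their tied rows are not in alphabetical order, most plausibly because
the printed integers are rounded sums whose unpublished decimals broke
the ties — so a deterministic standard convention is adopted and
documented here. Consequently, reproduction of the published tables is
asserted exactly on scores, ranks and tie-group membership, with
within-tie order being the package's own convention.

Alternative stakeholder weightings are modelled by `WeightScheme`
(criterion → non-negative weight, at least one positive):
`reweight` recomputes each criterion's contribution as raw score sum ×
weight. Agreement between two rankings is measured by **Kendall
tau-b** — chosen over Spearman's rho because sensitivity questions
here are about pairwise order reversals, which tau counts directly —
with the tau-b tie correction; the implementation delegates to
`scipy.stats.kendalltau`, and the test suite checks it against an
exhaustive concordant/discordant pair-count oracle on small instances.

## Synthetic studies

No raw per-expert scores were ever deposited for the real elicitation,
so the generator produces studies with the structure the analysis
assumes, for pipeline testing and parameter-recovery experiments — it
makes no attempt to calibrate latent distributions so as to reproduce
the published scores (their sub-criterion decomposition is not
public). Defaults mirror the real study's shape and are **the** study
conditions, not tuning knobs:

| parameter               | default | rationale |
|-------------------------|---------|-----------|
| `n_diseases`            | 52      | the real disease list |
| `category_proportions`  | (17, 16, 19)/52 | the real epizootic / food-producing / zoonotic split |
| `panel_size_mean`       | 7.0     | the real average panel size (Poisson draw, floored at `panel_size_min`) |
| `panel_size_min`        | 1       | the real study had panels down to ≤3 experts |
| `expert_noise_sd`       | 0.5     | illustrative: disagreement mostly within ±1 scale point, the real level was never reported |
| `category_effects`      | zoonoses +2 on public health | reproduces the observed pattern that zoonoses top the public-health criterion |
| `availability_none_prob`| 0.1     | gaps with no product at all are the exception, not the rule |

Latent scores are integers on the scale (the elicitation instrument is
integer-valued): uniform over the scale, shifted by any category
effect, clamped. Expert sheets are latent + rounded Gaussian noise,
clamped. Panel roles: the first four experts take the four required
roles, extras rotate randomly, so small panels realistically fail the
coverage minimum. Reproducibility: a single integer seed; per-disease
substreams are keyed by (seed, disease index) via
`numpy.random.SeedSequence`, so extending a study never perturbs
earlier diseases. Category allocation uses deterministic
largest-remainder rounding.

What the generator does **not** emulate: correlated scores across
sub-criteria within a disease, systematic per-expert bias (optimists /
pessimists), panel-level discussion dynamics, and any real
disease-specific structure. Passing recovery tests therefore show that
the pipeline is internally consistent and that aggregation behaves as
designed under independent noise — not that the published rankings
could be re-derived from first principles.

## Numerical and degenerate-input choices

* Weighted totals are plain float sums over ≤ 12 terms; oracle
  equivalence is asserted to 1e-9 and the normalisation invariant
  `W·X·I = 100` to 1e-9.
* Model coefficients are recomputed from structure on every load;
  a coefficient smuggled into a model JSON document is ignored.
* Incomplete score sheets fail validation — no imputation; the real
  panels scored every criterion, so a missing score is a data error.
* Empty panels, empty ranking inputs, duplicate disease or expert ids,
  mixed disease ids within a panel, unknown categories, scopes, areas
  and availability flags all raise with messages naming the offender.
* Kendall tau-b is undefined when either ranking is one single tie
  group; a single-entry comparison returns 1.0 by convention.
* File writes go through temp-file + atomic rename; a failed write
  never leaves a partial file.

## Problem sizes used in the checks

The acceptance-style checks run at the study's own scale: 52 diseases,
panels of about seven experts, 1,000 random sheets for the
oracle-equivalence sweep, 20 replicate seeds for the panel-size
recovery comparison, and 300 diseases for the one-off category-effect
sanity check. These sizes make the whole suite complete in well under
two minutes on a single CPU while keeping every check at or above the
scale of the real exercise.

## Known limitations

* The published overall scores cannot be recomputed from first
  principles here because the per-sub-criterion consensus scores live
  only in the online database; the fixtures store the printed integers
  as given, and property-based checks stand in for value-level
  reproduction.
* The median-based aggregation is one defensible reading of "reach a
  consensus"; real panels negotiated, which no statistic reproduces.
* The availability-override ambiguity (20-point raw cap vs the
  observed 40-point ceiling) is surfaced as a mode rather than
  resolved.
* Free-text disease dossiers are carried as opaque notes; nothing is
  parsed from them.
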