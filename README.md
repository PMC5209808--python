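# vetprio

Multi-criteria prioritisation and control-tool gap analysis for
infectious animal diseases.

Research funders in animal health face a recurring question: of the
dozens of epizootic, enzootic and zoonotic diseases competing for a
finite research budget, which ones most urgently need new diagnostics,
vaccines or pharmaceuticals? A widely used answer is a *closed weighted
scoring system* built by expert elicitation: each disease is scored by
an expert panel on a fixed set of criteria, criterion totals are
normalised to a common range, and diseases are ranked by the summed
score. `vetprio` implements such a system end to end — the scoring
models, the expert-panel aggregation, the rankings, a sensitivity
analysis for alternative weightings, and a synthetic-study generator —
for the two published model structures it ships with:

* a **prioritisation model** with six criteria (disease knowledge;
  impact on animal health and welfare; impact on public health; impact
  on wider society; impact on trade; control tools), scored on
  five-tier integer scales; and
* a **gap-analysis model** with three control-tool areas (diagnostic,
  vaccination and pharmaceutical tools), scored on a −2..+2 scale
  where a positive weighted total flags a research gap.

## The model

Each criterion groups `I` scored items (levels); every level receives
an integer score on the criterion's scale with maximum `X`. The
per-level weighting coefficient is

```
W = 100 / (X · I)
```

so that each criterion's maximum weighted total is exactly 100 and all
criteria carry equal weight in the overall score. The first five
prioritisation criteria use the scale 0..4; control tools use
+2..−2 so that an effective existing tool *lowers* a disease's
priority and a missing one raises it. The overall prioritisation score
is the unrounded sum of the six weighted criterion totals and lies in
[−100, 600]. Gap-area totals are rounded to integers (half away from
zero); when an area has no product at all — not even in development —
an availability override assigns the area a fixed maximum instead of
its scored total.

Expert panels (about seven experts per disease, ideally spanning
diagnostic, epidemiological, industry and economic expertise) are
aggregated by the per-sub-criterion median; sub-criteria on which the
panel spread exceeds a threshold are recorded as dissent — itself a
knowledge gap worth reporting, not noise to discard.

## Worked example

```python
import vetprio as vp

model = vp.build_default_prioritisation_model()
gap_model = vp.build_default_gap_model()

# synthetic elicitation: 8 diseases, noisy experts, fixed seed
config = vp.GeneratorConfig(n_diseases=8, expert_noise_sd=0.5, seed=7)
study = vp.generate_study(config, model, gap_model)

consensus, dissent = [], []
for panel in study.prioritisation_panels:
    sheet, records = vp.aggregate_panel(panel, model)
    consensus.append(sheet)
    dissent.extend(records)

totals = [vp.disease_total(s, model) for s in consensus]
table = vp.rank(totals, "overall")
for e in table.entries[:3]:
    print(f"{e.rank}  {e.disease_name}  {e.score:.2f}")
print(f"{len(dissent)} dissent records across {config.n_diseases} panels")

scheme = vp.WeightScheme("trade-focused", {
    c.name: (3.0 if c.name == "Impact on trade" else 1.0) for c in model.criteria
})
alt = vp.rank(vp.reweight(consensus, model, scheme), "overall")
print(f"Kendall tau-b vs baseline: {vp.rank_concordance(table, alt):.3f}")
```

prints

```
1  Synthetic disease 006  371.67
2  Synthetic disease 001  308.33
3  Synthetic disease 007  306.25
58 dissent records across 8 panels
Kendall tau-b vs baseline: 0.764
```

The three top scores are weighted sums on the 0–600-ish scale of the
six-criterion model; the 58 dissent records are sub-criteria where an
expert panel's scores spread by more than one point; the tau-b of
0.764 says that tripling the trade weight reorders the ranking
noticeably but far from completely.

The published reference tables (the 52-disease overall ranking topped
by Nipah virus at 464, the per-category rankings, and the gap scores
of the top-10 diseases per category) ship as checksummed fixtures:

```
vetprio rank --fixture            # the published overall ranking
vetprio fixtures                  # list packaged tables
```

The same pipeline is scriptable from the shell: `vetprio simulate`,
`vetprio aggregate`, `vetprio score`, `vetprio gaps`, `vetprio rank`,
`vetprio sensitivity`, `vetprio validate` (see `vetprio --help`).

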