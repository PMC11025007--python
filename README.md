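# paralogsl

Paralog synthetic-lethality discovery from CRISPR dependency panels.

Gene paralogs often buffer one another: knocking out either gene alone is
tolerated, but cancers that have silenced one paralog become selectively
dependent on the other. `paralogsl` finds such candidate synthetic-lethal
(SL) interactions in panels of cancer cell lines by correlating each gene's
CRISPR gene-effect (Chronos) scores with the expression of its paralog, then
triaging and characterizing the hits:

1. **Screen** — for each two-member paralog family (sequence identity > 50%
   by default) and each direction (dep gene, expr gene), compute the Pearson
   correlation *r* between Chronos scores and paralog expression across the
   shared cell lines, with an analytic two-sided *p* (the *t* tail of
   `t = r·√((n−2)/(1−r²))` on *n−2* df) or a seeded permutation *p*.
   Benjamini–Hochberg adjust, rank by descending *r*, and flag hits at
   q ≤ 0.05 with *r* > 0 — the SL signature, since low paralog expression
   should accompany gene effect near −1.
2. **Essentiality triage** — classify each hit's dependency gene from its
   Chronos distribution: common essential (panel mean ≤ −0.7), selectively
   essential (≥ 10% of lines at Chronos ≤ −0.7), or non-essential. Common
   essential genes make poor targets (narrow therapeutic window); selective
   dependencies are the interesting ones.
3. **Biomarker prevalence** — call a sample "low" for the partner gene when
   its transformed expression falls strictly below a cutoff (e.g.
   log2(FPKM+0.001) < −3), optionally excluding samples at or below a floor
   (> −9 retained) from the denominator, and report the prevalence of the
   low-expression state in cell-line or tumor/normal panels, with pooled
   Student *t* contrasts between groups.
4. **Methylation association** — summarize promoter methylation (mean beta
   over 450k-style probes in the 1 kb upstream of the TSS, or a supplied
   probe set / precomputed per-gene fraction) and correlate it with
   expression; silencing by promoter hypermethylation shows as negative *r*.

A seeded synthetic-panel generator (`paralogsl.simulate`) produces
DepMap-like expression / Chronos / promoter-beta matrices with implanted SL
pairs, silenced biomarkers, and common-essential genes plus a ground-truth
table, so the whole pipeline is testable without downloads.

## Worked example

Generate a default synthetic panel (53 cell lines, 200 paralog families,
3 implanted SL pairs, 20% of lines silenced per biomarker gene) and run the
full pipeline:

```bash
paralogsl simulate --out demo --seed 7
paralogsl run-all \
    --expression demo/expression.csv --chronos demo/chronos.csv \
    --paralogs demo/paralogs.tsv --methylation demo/methylation.csv \
    --out demo_results --min-identity 50
```

The run prints a JSON summary; on this seed it reports
`"n_pairs_screened": 200`, `"n_shared_samples": 53`, `"n_hits": 3`, and the
top hit is

```json
{
  "family_id": "F0155",
  "dep_gene": "F0155B",
  "expr_gene": "F0155A",
  "rank": 1,
  "r": 0.9387559524766326,
  "q": 1.1923543049048566e-22,
  "dep_essentiality": "selectively_essential",
  "expr_low_prevalence": 0.20754716981132076,
  "methylation_r": -0.9462141567602349
}
```

which is exactly one of the implanted pairs: the dependency gene F0155B is
selectively essential (depleted only in the lines where F0155A is
silenced), F0155A is low-expressed in 11/53 = 20.8% of lines (the implanted
silencing fraction), and its promoter beta is strongly anticorrelated with
its expression (r ≈ −0.95), the hypermethylation-silencing signature. The
per-record screen table, essentiality, biomarker and methylation reports
land in `demo_results/` as TSVs whose `#` headers echo the configuration,
seed and input checksums.

The same stages are available as library calls — `ParalogScreen` and
`EssentialityClassifier` are scikit-learn-style estimators
(`fit` + trailing-underscore results, `get_params`/`set_params`), and
`screen_paralog_pairs`, `prevalence`, `two_sample_t`,
`summarize_promoter_methylation`, `methylation_expression_correlation`,
`generate_panel` etc. are plain functions.

## Real panels

The package reads the public resources this analysis is designed for
(DepMap gene-effect and expression exports, Xena TCGA/GTEx expression,
processed 450k promoter betas) as plain wide CSV/TSV matrices; users supply
the files (no download clients). Place them under `data/external/` in the
formats described in the module docstrings to enable the optional
real-data reproduction test in `tests/test_acceptance.py`.
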