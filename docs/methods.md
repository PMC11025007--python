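# Methods

## The screen model

For a two-member paralog family (A, B) across a panel of *n* cell lines,
let *g* be the CRISPR gene-effect (Chronos) vector of one member (the
candidate dependency) and *x* the expression vector of the other (the
candidate biomarker). The screen statistic is the sample Pearson
correlation

    r = Σ (g_i − ḡ)(x_i − x̄) / sqrt( Σ(g_i − ḡ)² · Σ(x_i − x̄)² )

computed over pairwise-complete samples. Under the synthetic-lethality
hypothesis, lines that have lost the biomarker's expression are selectively
depleted on knockout of the partner (Chronos shifted toward −1 while the
rest of the panel sits near 0), so an SL pair appears as a **positive** r:
hits require r > 0 (configurable off) in addition to significance.

Significance is the two-sided analytic tail of t = r·√((n−2)/(1−r²)) on
n−2 degrees of freedom, equivalent to the standard Pearson test. Because
the record contract keeps p in (0, 1], a perfectly correlated pair (|r| = 1,
where t diverges) reports the smallest positive double rather than 0. A
permutation alternative is available (p = (1 + #{|r_perm| ≥ |r|}) /
(1 + B), y permuted under a named seeded generator); it agrees with the
analytic p to Monte-Carlo error at panel sizes of interest and serves as a
cross-check rather than the default.

Both directions of each family are scored and reported as separate records
by default (`directions="both"`); the per-family best can be obtained by
restricting to one direction or post-filtering. Records with a gene absent
from either matrix are emitted with `status=missing_gene`; records with
fewer than `min_samples` (default 10) complete pairs or a constant vector
are `degenerate`. Neither enters the multiple-testing correction or the
ranking.

Scored p values are Benjamini–Hochberg adjusted (step-up; missing entries
pass through and do not count toward m), records are ranked by descending
r with ties broken by smaller p then lexicographically by (dep gene, expr
gene), and hits are flagged at q ≤ 0.05. The FDR level, direction policy,
minimum overlap, and sign requirement are all estimator parameters.

## Essentiality triage

A dependency gene is only therapeutically interesting if it is *not*
essential everywhere. Each gene's Chronos distribution is summarized by
its panel mean and the fraction of lines at or below a dependence cutoff:

- mean ≤ −0.7 → `common_essential`
- else dependent fraction ≥ 0.10 → `selectively_essential`
- else `non_essential`

The −0.7 / 10% defaults are conventional dependency-panel values; the
underlying description of the classes is qualitative (distributions
centered near −1 vs a peak at 0 with a small tail toward −1), so the
thresholds are exposed as parameters and echoed into every report. The
triage deliberately avoids mixture models or dip tests: the mean/tail rule
matches how the distributions are read visually and is directly testable.

## Biomarker prevalence

Low-expression calls are strict: a sample is "low" iff its value on the
declared transformed scale is < cutoff (a value exactly at the cutoff is
not low). The scale is declared metadata, never inferred — a cutoff of −3
is meaningful on log2(FPKM+0.001) (where zero FPKM maps to ≈ −9.97) and
would mean something different on log2(TPM+1). When a floor is given
(e.g. −9), samples at or below it, like missing samples, are removed from
the denominator before the prevalence `n_low / n_total_after_floor` is
computed; this mirrors panel-size filtering in tumor/normal compendia.
Group contrasts use the pooled-variance two-sided Student t on n1+n2−2 df
(Welch behind a flag), erroring on zero pooled variance or groups smaller
than 2. The caliper tumor-volume helper computes L·W²·0.5 and warns (but
computes) when width exceeds length.

## Promoter methylation

The promoter is the 1 kb immediately upstream of the TSS: the half-open
interval [TSS−1000, TSS) on the + strand, mirrored to (TSS, TSS+1000] on
the − strand, with 1-based input coordinates. The per-sample promoter beta
is the mean over in-window probes, skipping missing probes; a sample with
no non-missing in-window probe is missing. An explicit probe set (e.g. a
promoter region taken from an external annotation tool) overrides the
window, and precomputed per-gene promoter fractions can bypass
summarization entirely. The methylation–expression association is the same
Pearson machinery as the screen, on complete cases only (pairs with a
missing member are dropped and the complete-case count is reported);
promoter hypermethylation silencing appears as negative r.

## The synthetic panel generator

`generate_panel` emulates the study conditions of a colorectal dependency
panel: 53 cell lines, 200 two-member families (identity drawn uniformly in
(50, 100]), 3 implanted SL families, 5% of genes common essential. For an
SL family, the biomarker gene A is silenced in exactly
round(0.2 × n_samples) lines (a fixed count, not binomial, so prevalence
assertions are exact): expression N(−5, 0.5) in silenced lines vs
N(5, 1) elsewhere (both on the log2 scale, straddling the −3 cutoff and
above the −9 floor), promoter beta N(0.8, 0.08) vs N(0.1, 0.05) (clipped
to [0, 1]), and the partner B's Chronos N(−1, 0.15) in exactly those lines
vs N(0, 0.15) elsewhere. A's own knockout is tolerated everywhere
(Chronos N(0, 0.15)) — single loss is buffered by the paralog. Common
essential genes draw Chronos N(−1, 0.15) panel-wide.

Randomness: each family uses its own substream
(`SeedSequence(seed, spawn_key=(i,))`), with a reserved substream for
panel-level choices, so a family's data are stable when the panel grows
and the whole panel is byte-reproducible given the seed. The generator
makes no attempt to mimic real CCLE covariance, lineage substructure, or
batch effects — passing tests on synthetic panels demonstrates that the
statistics recover implanted structure under the stated noise model, not
that real panels are this clean (real screens have correlated noise,
partial silencing, and confounded lineages that depress effect sizes).

## Numerical and design choices

- Matrix text IO writes shortest-repr decimals and parses with Python's
  correctly rounded `float()`, so write→read round-trips float64 exactly.
- The correlation denominator is computed as sqrt(Σdx²·Σdy²) (not
  sqrt(Σdx²)·sqrt(Σdy²)) so y = ±x yields exactly r = ±1; r is clipped to
  [−1, 1] against rounding.
- Paralog identity filtering is strict (> threshold), matching a
  "greater than 50%" catalogue definition; raising the threshold is
  monotone in the retained count.
- Missing values are propagated, never imputed: pairwise-complete deletion
  in correlations, exclusion from prevalence denominators, NaN passthrough
  in BH.
- Sample matching across matrices is exact string equality after trimming
  whitespace; identifier reconciliation across heterogeneous sources is
  left to a user-supplied mapping applied before ingestion.
- BH adjustment delegates to `statsmodels.multipletests(method="fdr_bh")`
  and the t test to `scipy.stats.ttest_ind`; both are verified against
  hand oracles in the test suite.
- Reports are deterministic byte-for-byte given config and inputs; the
  output directory is excluded from the echoed config so reruns into
  different directories compare equal.

## Problem sizes

The test suite and acceptance script run the screen at the generator's
native conditions (53 samples × 200 families × 2 directions): 20 seeded
panels for recovery, 50 null panels for false-discovery calibration, 50
seeds for triage accuracy, 20 for methylation sign recovery, 1,000 random
vector pairs and 500 random p-vectors for the oracle comparisons, and
10,000 permutations for the analytic-vs-permutation check. These sizes
give tight Monte-Carlo error on every reported rate while the whole
acceptance run completes in seconds.

## Limitations

- The screen tests marginal correlation only; it will miss SL pairs whose
  dependency is masked by lineage or co-occurring alterations, and it
  cannot distinguish silencing from deletion as the cause of low
  expression.
- The essentiality rule is a thresholded summary, not a model; genes with
  intermediate panel-wide depletion (mean just above −0.7) classify as
  selective when a mixture fit might call them common essential.
- The analytic p assumes bivariate normality; with 53 lines and the
  bimodal expression of silenced biomarkers this is approximate, which is
  why the permutation p exists.
- Real-data headline numbers depend on the exact public release versions
  and identifier reconciliation; the package reproduces them only given
  those inputs, supplied by the user.
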