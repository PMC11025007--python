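"""Promoter methylation summaries and methylation-expression association.

The promoter of a gene is the 1 kb immediately upstream of its
transcription start site (half-open window [TSS-window, TSS) on the +
strand, mirrored to (TSS, TSS+window] on the - strand; input coordinates
are 1-based).  A per-sample promoter beta is the mean beta over the
probes falling in the window, or over an explicit probe set when one is
supplied (e.g. regions taken from an external promoter annotation).
Precomputed per-gene promoter fractions (DepMap style) can bypass
summarization entirely and feed the correlation directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screen import pearson_with_p

logger = logging.getLogger(__name__)


@dataclass
class PromoterDefinition:
    gene: str
    tss_position: int
    strand: str = "+"
    window_bp: int = 1000
    probe_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")
        if self.probe_ids is not None and len(self.probe_ids) == 0:
            raise ValidationError("explicit probe set must be non-empty")

    def contains(self, position: int) -> bool:
        """Window membership for a 1-based probe position."""
        if self.strand == "+":
            return self.tss_position - self.window_bp <= position < self.tss_position
        return self.tss_position < position <= self.tss_position + self.window_bp


class MethylationCorrelation(NamedTuple):
    r: float
    p: float
    n_used: int


def summarize_promoter_methylation(
    probes: pd.DataFrame,
    promoter: PromoterDefinition,
) -> pd.Series:
    """Per-sample mean beta over the probes in a gene's promoter.

    ``probes`` is indexed by probe id with a ``position`` column and one
    column per sample (betas in [0, 1] or missing).  When the promoter
    carries an explicit ``probe_ids`` set it overrides the window.  A
    sample with no non-missing in-window probe gets a missing summary; a
    promoter with no probes at all is an error naming the gene.
    """
    if "position" not in probes.columns:
        raise ValidationError("probe table must have a 'position' column")
    sample_cols = [c for c in probes.columns if c not in ("position", "gene")]
    if promoter.probe_ids is not None:
        wanted = [p for p in promoter.probe_ids if p in probes.index]
        selected = probes.loc[wanted]
    else:
        mask = probes["position"].astype(int).map(promoter.contains)
        selected = probes.loc[mask]
    if selected.shape[0] == 0:
        raise ValidationError(
            f"no probes fall in the promoter of gene {promoter.gene!r}"
        )
    betas = selected[sample_cols].apply(pd.to_numeric, errors="coerce")
    finite = betas.to_numpy(dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValidationError("beta values must lie in [0, 1]")
    summary = betas.mean(axis=0, skipna=True)
    summary.name = promoter.gene
    return summary


def methylation_expression_correlation(
    promoter_beta,
    expression,
    p_method: str = "analytic_t",
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> MethylationCorrelation:
    """Pearson correlation between per-sample promoter beta and expression.

    Vectors must be sample-aligned (shared index when both are Series);
    pairs with a missing member are dropped, and fewer than 3 complete
    cases is an error.  Promoter hypermethylation silencing shows as a
    negative r.
    """
    if isinstance(promoter_beta, pd.Series) and isinstance(expression, pd.Series):
        common = promoter_beta.index.intersection(expression.index)
        if len(common) == 0:
            raise ValidationError("promoter beta and expression share no samples")
        b = promoter_beta.loc[common].to_numpy(dtype=float)
        e = expression.loc[common].to_numpy(dtype=float)
    else:
        b = np.asarray(promoter_beta, dtype=float)
        e = np.asarray(expression, dtype=float)
        if b.shape != e.shape:
            raise ValidationError("vectors must be sample-aligned and equal length")
    complete = np.isfinite(b) & np.isfinite(e)
    n_used = int(complete.sum())
    n_dropped = b.size - n_used
    if n_used < 3:
        raise ValidationError(
            f"only {n_used} complete beta/expression cases; need >= 3"
        )
    logger.info("methylation correlation: %d cases used, %d dropped", n_used, n_dropped)
    res = pearson_with_p(
        b[complete], e[complete],
        p_method=p_method, n_permutations=n_permutations, rng_seed=rng_seed,
    )
    if not np.isfinite(res.r):
        raise ValidationError("degenerate (constant) beta or expression vector")
    return MethylationCorrelation(r=res.r, p=res.p, n_used=n_used)
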