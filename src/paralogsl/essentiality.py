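"""Essentiality triage from the shape of a gene's Chronos distribution.

A gene whose knockout depletes essentially every line in the panel has
Chronos scores centered near -1 (common essential); a gene essential only
in a subset shows a peak near 0 with a tail toward -1 (selectively
essential); a gene with neither signature is non-essential.  The triage
uses the panel mean and the fraction of dependent lines (Chronos at or
below a cutoff) rather than formal bimodality tests, matching how
dependency panels are read in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .matrix import OmicsMatrix

LABELS = ("common_essential", "selectively_essential", "non_essential")


@dataclass
class EssentialityThresholds:
    """Cutoffs for the triage.

    dependent_cutoff : Chronos value at or below which a line counts as
        dependent (default -0.7, the conventional strong-depletion bound).
    common_mean_cutoff : panel-mean Chronos at or below which the gene is
        called common essential (default -0.7).
    selective_min_frac : minimum dependent fraction for a selectively
        essential call (default 0.10).
    """

    dependent_cutoff: float = -0.7
    common_mean_cutoff: float = -0.7
    selective_min_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.dependent_cutoff >= 0:
            raise ValidationError("dependent_cutoff must be negative")
        if not (0.0 < self.selective_min_frac < 1.0):
            raise ValidationError("selective_min_frac must lie in (0, 1)")


class ChronosSummary(NamedTuple):
    n: int
    mean: float
    frac_dependent: float


@dataclass
class EssentialityCall:
    gene: str
    n: int
    mean_chronos: float
    frac_dependent: float
    label: str


def summarize_chronos(values, dependent_cutoff: float = -0.7) -> ChronosSummary:
    """Panel summary of one gene's Chronos scores: count, mean, and the
    fraction of lines at or below ``dependent_cutoff``.  Missing values are
    dropped; an all-missing vector is an error."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no non-missing Chronos values to summarize")
    frac = float(np.mean(v <= dependent_cutoff))
    return ChronosSummary(n=int(v.size), mean=float(v.mean()), frac_dependent=frac)


def classify_essentiality(
    summary: ChronosSummary,
    thresholds: EssentialityThresholds | None = None,
    gene: str = "",
) -> EssentialityCall:
    """Label a summarized gene: common essential if the panel mean is at or
    below the mean cutoff; otherwise selectively essential if the dependent
    fraction reaches the minimum; otherwise non-essential."""
    th = thresholds or EssentialityThresholds()
    if summary.mean <= th.common_mean_cutoff:
        label = "common_essential"
    elif summary.frac_dependent >= th.selective_min_frac:
        label = "selectively_essential"
    else:
        label = "non_essential"
    return EssentialityCall(
        gene=gene,
        n=summary.n,
        mean_chronos=summary.mean,
        frac_dependent=summary.frac_dependent,
        label=label,
    )


class EssentialityClassifier(BaseEstimator):
    """Per-gene essentiality triage over a Chronos gene × sample matrix.

    Attributes (after ``fit``)
    --------------------------
    calls_ : list of EssentialityCall, one per gene.
    labels_ : pandas.Series mapping gene id to label.
    results_ : pandas.DataFrame of the full triage table.
    """

    def __init__(
        self,
        dependent_cutoff: float = -0.7,
        common_mean_cutoff: float = -0.7,
        selective_min_frac: float = 0.10,
    ):
        self.dependent_cutoff = dependent_cutoff
        self.common_mean_cutoff = common_mean_cutoff
        self.selective_min_frac = selective_min_frac

    def _thresholds(self) -> EssentialityThresholds:
        return EssentialityThresholds(
            dependent_cutoff=self.dependent_cutoff,
            common_mean_cutoff=self.common_mean_cutoff,
            selective_min_frac=self.selective_min_frac,
        )

    def fit(self, X: OmicsMatrix | pd.DataFrame, y=None) -> "EssentialityClassifier":
        values = X.values if isinstance(X, OmicsMatrix) else X
        th = self._thresholds()
        calls = []
        for gene in values.index:
            summary = summarize_chronos(
                values.loc[gene].to_numpy(dtype=float), th.dependent_cutoff
            )
            calls.append(classify_essentiality(summary, th, gene=str(gene)))
        self.calls_ = calls
        self.labels_ = pd.Series({c.gene: c.label for c in calls}, name="label")
        self.results_ = pd.DataFrame(
            {
                "gene": [c.gene for c in calls],
                "n": [c.n for c in calls],
                "mean_chronos": [c.mean_chronos for c in calls],
                "frac_dependent": [c.frac_dependent for c in calls],
                "label": [c.label for c in calls],
            }
        )
        return self

    def predict(self, X: OmicsMatrix | pd.DataFrame) -> np.ndarray:
        """Label each gene row of ``X`` without storing state."""
        values = X.values if isinstance(X, OmicsMatrix) else X
        th = self._thresholds()
        return np.array(
            [
                classify_essentiality(
                    summarize_chronos(values.loc[g].to_numpy(dtype=float), th.dependent_cutoff),
                    th,
                    gene=str(g),
                ).label
                for g in values.index
            ]
        )


def classify_matrix(
    chronos: OmicsMatrix,
    thresholds: EssentialityThresholds | None = None,
    genes: Sequence[str] | None = None,
) -> list[EssentialityCall]:
    """Triage selected genes (default: all) of a Chronos matrix."""
    th = thresholds or EssentialityThresholds()
    gene_list = list(genes) if genes is not None else chronos.gene_ids
    calls = []
    for gene in gene_list:
        summary = summarize_chronos(chronos.gene_vector(gene), th.dependent_cutoff)
        calls.append(classify_essentiality(summary, th, gene=gene))
    return calls
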