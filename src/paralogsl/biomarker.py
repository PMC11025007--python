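"""Low-expression biomarker calls, prevalence, and group contrasts.

Expression cutoffs are applied on the declared transformed scale verbatim
(the standard analysis calls a sample "low" when log2(FPKM+0.001) falls
strictly below -3, after excluding samples at or below a -9 floor, which
removes zero-FPKM artifacts near log2(0.001) ~= -9.97).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .matrix import OmicsMatrix


@dataclass
class PrevalenceResult:
    gene: str
    cutoff: float
    floor: float | None
    n_total_after_floor: int
    n_low: int
    prevalence: float


@dataclass
class GroupComparisonResult:
    gene: str
    group_labels: tuple[str, str]
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_statistic: float
    p_value: float


def call_low_expression(values, cutoff: float) -> pd.Series:
    """Boolean low-expression calls: True iff value < cutoff (strict).
    Missing values stay missing (pandas nullable boolean)."""
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    out = pd.Series(pd.array(s < cutoff, dtype="boolean"), index=s.index)
    out[s.isna()] = pd.NA
    return out


def prevalence(
    expr: OmicsMatrix,
    gene: str,
    cutoff: float,
    floor: float | None = None,
) -> PrevalenceResult:
    """Fraction of samples calling a gene low, after the optional floor.

    Samples with missing values, or values at or below ``floor`` when a
    floor is given, are excluded from the denominator; the prevalence is
    ``n_low / n_total_after_floor`` over the survivors.
    """
    row = expr.gene_vector(gene).astype(float)
    keep = row.notna()
    if floor is not None:
        keep &= row > floor
    n_total = int(keep.sum())
    if n_total == 0:
        raise ValidationError(
            f"gene {gene!r}: no samples survive the floor {floor!r}"
        )
    n_low = int((row[keep] < cutoff).sum())
    return PrevalenceResult(
        gene=gene,
        cutoff=cutoff,
        floor=floor,
        n_total_after_floor=n_total,
        n_low=n_low,
        prevalence=n_low / n_total,
    )


def two_sample_t(
    group1,
    group2,
    gene: str = "",
    group_labels: tuple[str, str] = ("group1", "group2"),
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-sided unpaired t test, pooled-variance Student by default
    (Welch behind the ``welch`` flag).  Missing values are dropped; each
    group needs >= 2 values and the pooled variance must be positive."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    if g1.size < 2 or g2.size < 2:
        raise ValidationError("each group needs at least 2 non-missing values")
    if not welch and g1.var(ddof=1) == 0.0 and g2.var(ddof=1) == 0.0:
        raise ValidationError("pooled variance is zero; t statistic undefined")
    res = stats.ttest_ind(g1, g2, equal_var=not welch)
    p = float(min(1.0, max(res.pvalue, np.finfo(float).tiny)))
    return GroupComparisonResult(
        gene=gene,
        group_labels=group_labels,
        n1=int(g1.size),
        n2=int(g2.size),
        mean1=float(g1.mean()),
        mean2=float(g2.mean()),
        t_statistic=float(res.statistic),
        p_value=p,
    )


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume, L x W^2 x 0.5 (mm^3).

    Warns when width exceeds length (the caliper convention takes length
    as the larger axis) but still computes the formula as given."""
    if length_mm < 0 or width_mm < 0:
        raise ValidationError("tumor measurements must be non-negative")
    if width_mm > length_mm:
        warnings.warn(
            "width exceeds length; caliper convention expects L >= W",
            stacklevel=2,
        )
    return length_mm * width_mm * width_mm * 0.5
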