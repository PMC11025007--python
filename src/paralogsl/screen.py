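"""Paralog synthetic-lethality screen.

For each two-member paralog family the screen correlates one gene's CRISPR
gene-effect (Chronos) scores with the other gene's expression across a
cell-line panel.  A synthetic-lethal pair shows a positive correlation:
cell lines with low expression of one paralog are selectively depleted
when the partner is knocked out (Chronos shifted toward -1), while lines
still expressing the paralog tolerate the knockout (Chronos near 0).
Records are Benjamini-Hochberg adjusted, ranked by descending Pearson r,
and flagged as hits at a configurable FDR.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix import OmicsMatrix, ParalogPair, align_panels

logger = logging.getLogger(__name__)

_P_FLOOR = float(np.finfo(float).tiny)


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_with_p(
    x,
    y,
    p_method: str = "analytic_t",
    n_permutations: int = 10_000,
    rng_seed: int = 0,
) -> PearsonResult:
    """Pearson correlation with a two-sided p value.

    Missing entries are removed pairwise.  The analytic p is the two-sided
    tail of ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom
    (floored at the smallest positive float so p stays in (0, 1]).  The
    permutation p is ``(1 + #{|r_perm| >= |r|}) / (1 + n_permutations)``
    with ``y`` permuted under a seeded generator.

    Degenerate inputs (fewer than 3 complete pairs, or a constant vector
    after deletion) return ``(nan, nan, n)`` rather than raising, so the
    screen can flag them per-record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return PearsonResult(np.nan, np.nan, n)
    xv = x[mask]
    yv = y[mask]
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        return PearsonResult(np.nan, np.nan, n)
    # sqrt(sxx*syy) rather than sqrt(sxx)*sqrt(syy): exact r = ±1 for y = ±x
    r = float(np.sum(dx * dy) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))

    if p_method == "analytic_t":
        if abs(r) >= 1.0:
            p = _P_FLOOR
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            p = float(min(1.0, max(p, _P_FLOOR)))
    elif p_method == "permutation":
        rng = np.random.default_rng(rng_seed)
        u = dx / np.sqrt(sxx)
        v = dy / np.sqrt(syy)
        count = 0
        chunk = 2_000
        done = 0
        while done < n_permutations:
            b = min(chunk, n_permutations - done)
            # each row is a random permutation of v
            order = np.argsort(rng.random((b, n)), axis=1)
            r_perm = v[order] @ u
            count += int(np.sum(np.abs(r_perm) >= abs(r)))
            done += b
        p = (1 + count) / (1 + n_permutations)
    else:
        raise ValidationError(f"unknown p_method {p_method!r}")
    return PearsonResult(r, float(p), n)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    Missing (NaN) entries pass through as missing and do not count toward
    the number of tests ``m``.  Values outside (0, 1] raise
    :class:`ValidationError`.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        pv = p[mask]
        if np.any(pv <= 0.0) or np.any(pv > 1.0):
            raise ValidationError("p values must lie in (0, 1]")
        out[mask] = multipletests(pv, method="fdr_bh")[1]
    return out


@dataclass
class ScreenRecord:
    """One (dependency gene, expression gene) direction of a paralog family."""

    family_id: str
    dep_gene: str
    expr_gene: str
    n_samples: int = 0
    pearson_r: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan
    rank: int | None = None
    is_hit: bool = False
    status: str = "scored"  # scored | missing_gene | degenerate


@dataclass
class ScreenConfig:
    """Screen tuning knobs; defaults match the standard analysis."""

    q_threshold: float = 0.05
    directions: str = "both"  # both | a_dep_b_expr | b_dep_a_expr
    min_samples: int = 10
    p_method: str = "analytic_t"
    n_permutations: int = 10_000
    rng_seed: int = 0
    require_positive_r: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0):
            raise ValidationError("q_threshold must lie in (0, 1)")
        if self.min_samples < 3:
            raise ValidationError("min_samples must be >= 3")
        if self.directions not in ("both", "a_dep_b_expr", "b_dep_a_expr"):
            raise ValidationError(f"unknown directions {self.directions!r}")


def rank_and_flag(
    records: list[ScreenRecord],
    q_threshold: float = 0.05,
    require_positive_r: bool = True,
) -> list[ScreenRecord]:
    """Rank scored records by descending Pearson r and flag hits.

    Hits require q <= threshold and (by default) r > 0, the
    synthetic-lethality signature: low paralog expression accompanied by
    gene effect near -1.  Ties in r break by smaller p, then by
    (dep_gene, expr_gene) lexicographically.  Degenerate and missing-gene
    records are unranked and placed after the ranked ones.
    """
    scored = [rec for rec in records if rec.status == "scored"]
    other = [rec for rec in records if rec.status != "scored"]
    scored.sort(key=lambda rec: (-rec.pearson_r, rec.p_value, rec.dep_gene, rec.expr_gene))
    for i, rec in enumerate(scored, start=1):
        rec.rank = i
        rec.is_hit = (
            np.isfinite(rec.q_value)
            and rec.q_value <= q_threshold
            and (rec.pearson_r > 0.0 or not require_positive_r)
        )
    for rec in other:
        rec.rank = None
        rec.is_hit = False
    other.sort(key=lambda rec: (rec.family_id, rec.dep_gene, rec.expr_gene))
    return scored + other


class ParalogScreen(BaseEstimator):
    """Correlation screen over paralog pairs, as an estimator.

    Parameters
    ----------
    q_threshold : float, default 0.05
        Benjamini-Hochberg FDR level for hit flagging.
    directions : {"both", "a_dep_b_expr", "b_dep_a_expr"}, default "both"
        Which (dependency gene, expression gene) directions to score per
        family; "both" emits two records per pair.
    min_samples : int, default 10
        Minimum complete sample pairs for a record to be scored.
    p_method : {"analytic_t", "permutation"}, default "analytic_t"
    n_permutations : int, default 10000
        Permutations when ``p_method="permutation"``.
    random_state : int, default 0
        Seed for the permutation generator.
    require_positive_r : bool, default True
        Restrict hits to positive correlations (the SL signature).

    Attributes
    ----------
    records_ : list of ScreenRecord
        All records, ranked records first.
    results_ : pandas.DataFrame
        Tabular view of ``records_``.
    hits_ : list of ScreenRecord
        Flagged hits in rank order.
    n_shared_samples_ : int
        Size of the sample intersection the screen ran on.
    """

    def __init__(
        self,
        q_threshold: float = 0.05,
        directions: str = "both",
        min_samples: int = 10,
        p_method: str = "analytic_t",
        n_permutations: int = 10_000,
        random_state: int = 0,
        require_positive_r: bool = True,
    ):
        self.q_threshold = q_threshold
        self.directions = directions
        self.min_samples = min_samples
        self.p_method = p_method
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.require_positive_r = require_positive_r

    def fit(
        self,
        dep: OmicsMatrix,
        expr: OmicsMatrix,
        pairs: Sequence[ParalogPair],
    ) -> "ParalogScreen":
        cfg = ScreenConfig(
            q_threshold=self.q_threshold,
            directions=self.directions,
            min_samples=self.min_samples,
            p_method=self.p_method,
            n_permutations=self.n_permutations,
            rng_seed=self.random_state,
            require_positive_r=self.require_positive_r,
        )
        if dep.kind != "gene_effect":
            raise ValidationError(f"dep matrix has kind {dep.kind!r}, expected gene_effect")
        if expr.kind != "expression":
            raise ValidationError(f"expr matrix has kind {expr.kind!r}, expected expression")
        if not pairs:
            logger.warning("empty paralog pair list: screen produces no records")
            self.records_, self.hits_ = [], []
            self.results_ = records_to_frame([])
            self.n_shared_samples_ = 0
            return self

        dep_al, expr_al = align_panels(dep, expr)
        self.n_shared_samples_ = len(dep_al.sample_ids)
        if self.n_shared_samples_ < cfg.min_samples:
            raise ValidationError(
                f"panels share only {self.n_shared_samples_} samples; "
                f"min_samples is {cfg.min_samples}"
            )

        dep_genes = set(dep_al.gene_ids)
        expr_genes = set(expr_al.gene_ids)
        if cfg.directions == "both":
            dirs = (("a", "b"), ("b", "a"))
        elif cfg.directions == "a_dep_b_expr":
            dirs = (("a", "b"),)
        else:
            dirs = (("b", "a"),)

        records: list[ScreenRecord] = []
        for pair in pairs:
            members = {"a": pair.gene_a, "b": pair.gene_b}
            for d, e in dirs:
                dep_gene, expr_gene = members[d], members[e]
                rec = ScreenRecord(pair.family_id, dep_gene, expr_gene)
                if dep_gene not in dep_genes or expr_gene not in expr_genes:
                    rec.status = "missing_gene"
                else:
                    res = pearson_with_p(
                        dep_al.values.loc[dep_gene].to_numpy(dtype=float),
                        expr_al.values.loc[expr_gene].to_numpy(dtype=float),
                        p_method=cfg.p_method,
                        n_permutations=cfg.n_permutations,
                        rng_seed=cfg.rng_seed,
                    )
                    rec.n_samples = res.n
                    if not np.isfinite(res.r) or res.n < cfg.min_samples:
                        rec.status = "degenerate"
                    else:
                        rec.pearson_r, rec.p_value = res.r, res.p
                records.append(rec)

        scored = [rec for rec in records if rec.status == "scored"]
        if not scored:
            raise ValidationError("no scorable records: every pair was missing or degenerate")
        q = adjust_bh([rec.p_value for rec in scored])
        for rec, qv in zip(scored, q):
            rec.q_value = float(qv)
        self.records_ = rank_and_flag(records, cfg.q_threshold, cfg.require_positive_r)
        self.hits_ = [rec for rec in self.records_ if rec.is_hit]
        self.results_ = records_to_frame(self.records_)
        logger.info(
            "screen: %d records (%d scored), %d hits at q <= %g",
            len(records), len(scored), len(self.hits_), cfg.q_threshold,
        )
        return self


def screen_paralog_pairs(
    dep: OmicsMatrix,
    expr: OmicsMatrix,
    pairs: Sequence[ParalogPair],
    cfg: ScreenConfig | None = None,
) -> list[ScreenRecord]:
    """Functional wrapper over :class:`ParalogScreen`."""
    cfg = cfg or ScreenConfig()
    est = ParalogScreen(
        q_threshold=cfg.q_threshold,
        directions=cfg.directions,
        min_samples=cfg.min_samples,
        p_method=cfg.p_method,
        n_permutations=cfg.n_permutations,
        random_state=cfg.rng_seed,
        require_positive_r=cfg.require_positive_r,
    ).fit(dep, expr, pairs)
    return est.records_


_REPORT_COLUMNS = [
    "family_id", "dep_gene", "expr_gene", "n", "r", "p", "q", "rank", "is_hit", "status",
]


def records_to_frame(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    rows = [
        {
            "family_id": rec.family_id,
            "dep_gene": rec.dep_gene,
            "expr_gene": rec.expr_gene,
            "n": rec.n_samples,
            "r": rec.pearson_r,
            "p": rec.p_value,
            "q": rec.q_value,
            "rank": rec.rank,
            "is_hit": rec.is_hit,
            "status": rec.status,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_screen_report(
    records: Sequence[ScreenRecord],
    path: str | Path,
    config: ScreenConfig | None = None,
    checksums: dict[str, str] | None = None,
) -> Path:
    """Write the screen TSV with '#' header lines recording config, seed,
    and input checksums (provenance)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config: {json.dumps(asdict(config), sort_keys=True)}\n")
            fh.write(f"# seed: {config.rng_seed}\n")
        for name, digest in (checksums or {}).items():
            fh.write(f"# checksum {name}: {digest}\n")
        records_to_frame(records).to_csv(fh, sep="\t", index=False, na_rep="NA")
    return path
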