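"""End-to-end orchestration: align -> screen -> essentiality triage of hit
dependency genes -> biomarker prevalence of hit expression genes ->
optional methylation association, with provenance-stamped reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .biomarker import prevalence
from .errors import InputError, ValidationError
from .essentiality import EssentialityThresholds, classify_matrix
from .matrix import align_panels, read_matrix, read_paralog_table, read_sample_annotations
from .methylation import methylation_expression_correlation
from .screen import (
    ParalogScreen,
    ScreenConfig,
    file_checksum,
    records_to_frame,
    write_screen_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression_path: str
    chronos_path: str
    paralogs_path: str
    out_dir: str
    samples_path: str | None = None
    methylation_path: str | None = None
    expression_scale: str = "log2(FPKM+0.001)"
    min_identity_pct: float = 50.0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    thresholds: EssentialityThresholds = field(default_factory=EssentialityThresholds)
    cutoff: float = -3.0
    floor: float | None = None


def _header_lines(cfg: RunConfig, checksums: dict[str, str]) -> list[str]:
    echoed = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    lines = [
        f"# config: {json.dumps(echoed, sort_keys=True)}",
        f"# seed: {cfg.screen.rng_seed}",
    ]
    lines += [f"# checksum {name}: {digest}" for name, digest in checksums.items()]
    return lines


def _write_report(df: pd.DataFrame, path: Path, header: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict, and writes
    screen.tsv, essentiality.tsv, biomarker.tsv, (methylation.tsv) and
    summary.json under ``cfg.out_dir``.  All results are computed before
    any report is written, so a failure leaves no partial outputs."""
    for name in ("expression_path", "chronos_path", "paralogs_path"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise InputError(f"{name.replace('_path', '')} file not found: {p}")

    expr = read_matrix(cfg.expression_path, "expression", cfg.expression_scale)
    dep = read_matrix(cfg.chronos_path, "gene_effect", "Chronos")
    pairs = read_paralog_table(cfg.paralogs_path, min_identity_pct=cfg.min_identity_pct)
    if cfg.samples_path:
        read_sample_annotations(cfg.samples_path)  # validated; grouping is optional
    meth = (
        read_matrix(cfg.methylation_path, "methylation", "beta fraction")
        if cfg.methylation_path
        else None
    )

    checksums = {
        "expression": file_checksum(cfg.expression_path),
        "chronos": file_checksum(cfg.chronos_path),
        "paralogs": file_checksum(cfg.paralogs_path),
    }
    if cfg.methylation_path:
        checksums["methylation"] = file_checksum(cfg.methylation_path)

    sc = cfg.screen
    screen = ParalogScreen(
        q_threshold=sc.q_threshold,
        directions=sc.directions,
        min_samples=sc.min_samples,
        p_method=sc.p_method,
        n_permutations=sc.n_permutations,
        random_state=sc.rng_seed,
        require_positive_r=sc.require_positive_r,
    ).fit(dep, expr, pairs)
    hits = screen.hits_

    hit_dep_genes = sorted({h.dep_gene for h in hits})
    calls = classify_matrix(dep, cfg.thresholds, genes=[g for g in hit_dep_genes if g in dep.gene_ids])
    ess_df = pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "n": [c.n for c in calls],
            "mean_chronos": [c.mean_chronos for c in calls],
            "frac_dependent": [c.frac_dependent for c in calls],
            "label": [c.label for c in calls],
            "dependent_cutoff": cfg.thresholds.dependent_cutoff,
            "common_mean_cutoff": cfg.thresholds.common_mean_cutoff,
            "selective_min_frac": cfg.thresholds.selective_min_frac,
        }
    )
    labels = {c.gene: c.label for c in calls}

    hit_expr_genes = sorted({h.expr_gene for h in hits})
    prev_rows = []
    for gene in hit_expr_genes:
        if gene not in expr.gene_ids:
            continue
        res = prevalence(expr, gene, cutoff=cfg.cutoff, floor=cfg.floor)
        prev_rows.append(
            {
                "gene": gene,
                "panel": "input",
                "cutoff": res.cutoff,
                "floor": res.floor,
                "n_total": res.n_total_after_floor,
                "n_low": res.n_low,
                "prevalence": res.prevalence,
            }
        )
    prev_df = pd.DataFrame(
        prev_rows,
        columns=["gene", "panel", "cutoff", "floor", "n_total", "n_low", "prevalence"],
    )

    meth_rows = []
    if meth is not None:
        expr_al, meth_al = align_panels(expr, meth)
        for gene in hit_expr_genes:
            if gene not in meth_al.gene_ids or gene not in expr_al.gene_ids:
                continue
            try:
                corr = methylation_expression_correlation(
                    meth_al.gene_vector(gene), expr_al.gene_vector(gene)
                )
            except ValidationError as exc:
                logger.warning("methylation correlation skipped for %s: %s", gene, exc)
                continue
            meth_rows.append(
                {"gene": gene, "r": corr.r, "p": corr.p, "n_used": corr.n_used}
            )
    meth_df = pd.DataFrame(meth_rows, columns=["gene", "r", "p", "n_used"])

    summary = {
        "n_pairs_screened": len(pairs),
        "n_shared_samples": screen.n_shared_samples_,
        "n_hits": len(hits),
        "hits": [
            {
                "family_id": h.family_id,
                "dep_gene": h.dep_gene,
                "expr_gene": h.expr_gene,
                "rank": h.rank,
                "r": h.pearson_r,
                "p": h.p_value,
                "q": h.q_value,
                "dep_essentiality": labels.get(h.dep_gene),
                "expr_low_prevalence": next(
                    (row["prevalence"] for row in prev_rows if row["gene"] == h.expr_gene),
                    None,
                ),
                "methylation_r": next(
                    (row["r"] for row in meth_rows if row["gene"] == h.expr_gene), None
                ),
            }
            for h in hits
        ],
        "seed": sc.rng_seed,
        "checksums": checksums,
    }

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header_lines(cfg, checksums)
    write_screen_report(screen.records_, out / "screen.tsv", config=sc, checksums=checksums)
    _write_report(ess_df, out / "essentiality.tsv", header)
    _write_report(prev_df, out / "biomarker.tsv", header)
    if meth is not None:
        _write_report(meth_df, out / "methylation.tsv", header)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d hits, reports in %s", len(hits), out)
    return summary
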