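"""Seeded generator of DepMap-like multi-omic panels with known ground truth.

The generator emulates the structure of a colorectal cell-line dependency
panel: ~53 samples, a few hundred two-member paralog families, bimodal
expression for biomarker genes (silenced vs expressed on a log2 scale),
Chronos gene-effect scores near 0 for tolerated knockouts and near -1 for
common-essential genes, a synthetic-lethal shift of the partner's Chronos
toward -1 in exactly the silenced lines, and promoter beta values
anticorrelated with expression for silenced genes.  Every draw is
deterministic given the seed; each family has its own substream so a
family's data do not change when the panel grows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .matrix import (
    OmicsMatrix,
    ParalogPair,
    SampleAnnotation,
    read_matrix,
    read_paralog_table,
    read_sample_annotations,
    write_matrix,
)

EXPRESSION_SCALE = "log2(FPKM+0.001)"
_PANEL_STREAM = 1 << 20  # spawn key reserved for panel-level draws


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror the real screen's setting: 53 cell lines, 3 implanted
    synthetic-lethal families among 200, a biomarker gene silenced in 20%
    of lines (expression -5 vs +5 on the log2 scale, i.e. well below the
    -3 low-expression cutoff and above the -9 floor), Chronos noise 0.15
    around class centers 0 / -1, and promoter betas 0.8 (hypermethylated,
    silenced lines) vs 0.1 (unmethylated).
    """

    rng_seed: int = 0
    n_samples: int = 53
    n_families: int = 200
    n_sl_families: int = 3
    frac_common_essential: float = 0.05
    silencing_fraction: float = 0.2
    expr_high_mean: float = 5.0
    expr_high_sd: float = 1.0
    expr_silenced_mean: float = -5.0
    expr_silenced_sd: float = 0.5
    chronos_noise_sd: float = 0.15
    sl_effect: float = -1.0
    beta_high_mean: float = 0.8
    beta_high_sd: float = 0.08
    beta_low_mean: float = 0.1
    beta_low_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("n_samples must be >= 3")
        if self.n_families < 1 or self.n_sl_families < 0:
            raise ValidationError("family counts must be positive")
        if self.n_sl_families > self.n_families:
            raise ValidationError("n_sl_families cannot exceed n_families")
        for name in ("frac_common_essential", "silencing_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in (
            "expr_high_sd", "expr_silenced_sd", "chronos_noise_sd",
            "beta_high_sd", "beta_low_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def n_silenced_samples(self) -> int:
        return int(round(self.silencing_fraction * self.n_samples))


@dataclass(frozen=True)
class FamilyTruth:
    family_id: str
    is_sl: bool
    silenced_gene: str | None = None
    partner_gene: str | None = None
    silenced_sample_ids: tuple[str, ...] = ()


@dataclass
class TruthTable:
    """Ground truth of one generated panel: which families carry an
    implanted SL interaction (and in which samples the biomarker gene is
    silenced), plus each gene's essentiality class."""

    families: list[FamilyTruth]
    essentiality: dict[str, str]

    @property
    def sl_families(self) -> list[FamilyTruth]:
        return [f for f in self.families if f.is_sl]


@dataclass
class SyntheticPanel:
    expression: OmicsMatrix
    gene_effect: OmicsMatrix
    methylation: OmicsMatrix
    pairs: list[ParalogPair]
    annotations: list[SampleAnnotation]
    truth: TruthTable
    config: SyntheticConfig


def _family_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def generate_panel(cfg: SyntheticConfig | None = None) -> SyntheticPanel:
    """Generate one panel (expression, Chronos, promoter beta matrices,
    paralog table, annotations, truth), deterministically from the seed."""
    cfg = cfg or SyntheticConfig()
    samples = [f"LINE{j:03d}" for j in range(cfg.n_samples)]
    panel_rng = _family_rng(cfg.rng_seed, _PANEL_STREAM)

    sl_families = set(
        panel_rng.choice(cfg.n_families, size=cfg.n_sl_families, replace=False).tolist()
    )
    n_genes = 2 * cfg.n_families
    non_sl_genes = [
        f"F{i:04d}{m}"
        for i in range(cfg.n_families)
        if i not in sl_families
        for m in ("A", "B")
    ]
    n_common = int(round(cfg.frac_common_essential * n_genes))
    n_common = min(n_common, len(non_sl_genes))
    common_essential = set(
        panel_rng.choice(non_sl_genes, size=n_common, replace=False).tolist()
    )
    msi = panel_rng.choice(["MSI", "MSS"], size=cfg.n_samples, p=[0.15, 0.85])

    expr_rows, chronos_rows, beta_rows = {}, {}, {}
    pairs: list[ParalogPair] = []
    fam_truth: list[FamilyTruth] = []
    essentiality: dict[str, str] = {}
    k = cfg.n_silenced_samples

    for i in range(cfg.n_families):
        rng = _family_rng(cfg.rng_seed, i)
        fam = f"F{i:04d}"
        gene_a, gene_b = fam + "A", fam + "B"
        identity = float(rng.uniform(50.0, 100.0))
        pairs.append(ParalogPair(fam, gene_a, gene_b, identity))

        if i in sl_families:
            silenced_idx = np.sort(rng.choice(cfg.n_samples, size=k, replace=False))
            silenced = np.zeros(cfg.n_samples, dtype=bool)
            silenced[silenced_idx] = True
            # gene A: the silenced biomarker; expression bimodal, promoter
            # hypermethylated exactly in the silenced lines, knockout tolerated.
            expr_a = rng.normal(cfg.expr_high_mean, cfg.expr_high_sd, cfg.n_samples)
            expr_a[silenced] = rng.normal(
                cfg.expr_silenced_mean, cfg.expr_silenced_sd, k
            )
            beta_a = rng.normal(cfg.beta_low_mean, cfg.beta_low_sd, cfg.n_samples)
            beta_a[silenced] = rng.normal(cfg.beta_high_mean, cfg.beta_high_sd, k)
            chronos_a = rng.normal(0.0, cfg.chronos_noise_sd, cfg.n_samples)
            # gene B: the dependency partner; Chronos shifted to sl_effect in
            # exactly the silenced lines.
            expr_b = rng.normal(cfg.expr_high_mean, cfg.expr_high_sd, cfg.n_samples)
            beta_b = rng.normal(cfg.beta_low_mean, cfg.beta_low_sd, cfg.n_samples)
            chronos_b = rng.normal(0.0, cfg.chronos_noise_sd, cfg.n_samples)
            chronos_b[silenced] = rng.normal(cfg.sl_effect, cfg.chronos_noise_sd, k)
            fam_truth.append(
                FamilyTruth(
                    family_id=fam,
                    is_sl=True,
                    silenced_gene=gene_a,
                    partner_gene=gene_b,
                    silenced_sample_ids=tuple(samples[j] for j in silenced_idx),
                )
            )
            essentiality[gene_a] = "non_essential"
            essentiality[gene_b] = "selectively_essential"
        else:
            expr_a = rng.normal(cfg.expr_high_mean, cfg.expr_high_sd, cfg.n_samples)
            expr_b = rng.normal(cfg.expr_high_mean, cfg.expr_high_sd, cfg.n_samples)
            beta_a = rng.normal(cfg.beta_low_mean, cfg.beta_low_sd, cfg.n_samples)
            beta_b = rng.normal(cfg.beta_low_mean, cfg.beta_low_sd, cfg.n_samples)
            chronos_a, chronos_b = (
                rng.normal(
                    -1.0 if g in common_essential else 0.0,
                    cfg.chronos_noise_sd,
                    cfg.n_samples,
                )
                for g in (gene_a, gene_b)
            )
            fam_truth.append(FamilyTruth(family_id=fam, is_sl=False))
            for g in (gene_a, gene_b):
                essentiality[g] = (
                    "common_essential" if g in common_essential else "non_essential"
                )

        expr_rows[gene_a], expr_rows[gene_b] = expr_a, expr_b
        chronos_rows[gene_a], chronos_rows[gene_b] = chronos_a, chronos_b
        beta_rows[gene_a] = np.clip(beta_a, 0.0, 1.0)
        beta_rows[gene_b] = np.clip(beta_b, 0.0, 1.0)

    def as_matrix(rows: dict, kind: str, scale: str) -> OmicsMatrix:
        df = pd.DataFrame(rows, index=samples).T
        return OmicsMatrix(kind=kind, scale=scale, values=df)

    annotations = [
        SampleAnnotation(
            sample_id=s, tissue_class="cell_line", msi_status=str(m), lineage="colorectal"
        )
        for s, m in zip(samples, msi)
    ]
    return SyntheticPanel(
        expression=as_matrix(expr_rows, "expression", EXPRESSION_SCALE),
        gene_effect=as_matrix(chronos_rows, "gene_effect", "Chronos"),
        methylation=as_matrix(beta_rows, "methylation", "beta fraction"),
        pairs=pairs,
        annotations=annotations,
        truth=TruthTable(families=fam_truth, essentiality=essentiality),
        config=cfg,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(panel: SyntheticPanel, directory: str | Path) -> dict[str, Path]:
    """Write the panel as a fixture bundle readable by the IO module:
    expression.csv, chronos.csv, methylation.csv, paralogs.tsv,
    samples.tsv, truth.tsv, plus manifest.json with config and checksums."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create fixture directory {directory}: {exc}") from exc

    paths: dict[str, Path] = {}
    paths["expression"] = write_matrix(panel.expression, directory / "expression.csv")
    paths["chronos"] = write_matrix(panel.gene_effect, directory / "chronos.csv")
    paths["methylation"] = write_matrix(panel.methylation, directory / "methylation.csv")

    pd.DataFrame(
        {
            "family_id": [p.family_id for p in panel.pairs],
            "gene_a": [p.gene_a for p in panel.pairs],
            "gene_b": [p.gene_b for p in panel.pairs],
            "identity_pct": [p.identity_pct for p in panel.pairs],
        }
    ).to_csv(directory / "paralogs.tsv", sep="\t", index=False)
    paths["paralogs"] = directory / "paralogs.tsv"

    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in panel.annotations],
            "tissue_class": [a.tissue_class for a in panel.annotations],
            "msi_status": [a.msi_status for a in panel.annotations],
            "lineage": [a.lineage for a in panel.annotations],
        }
    ).to_csv(directory / "samples.tsv", sep="\t", index=False)
    paths["samples"] = directory / "samples.tsv"

    fam_by_id = {f.family_id: f for f in panel.truth.families}
    truth_rows = []
    for pair in panel.pairs:
        fam = fam_by_id[pair.family_id]
        for gene in (pair.gene_a, pair.gene_b):
            role = "none"
            silenced_samples = ""
            if fam.is_sl:
                if gene == fam.silenced_gene:
                    role = "silenced"
                    silenced_samples = ";".join(fam.silenced_sample_ids)
                elif gene == fam.partner_gene:
                    role = "partner"
            truth_rows.append(
                {
                    "family_id": pair.family_id,
                    "gene": gene,
                    "is_sl": fam.is_sl,
                    "role": role,
                    "essentiality": panel.truth.essentiality[gene],
                    "silenced_samples": silenced_samples,
                }
            )
    pd.DataFrame(truth_rows).to_csv(directory / "truth.tsv", sep="\t", index=False)
    paths["truth"] = directory / "truth.tsv"

    manifest = {
        "format": "paralogsl-fixture-1",
        "seed": panel.config.rng_seed,
        "config": asdict(panel.config),
        "checksums": {name: _sha256(p) for name, p in paths.items()},
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def load_fixture_bundle(directory: str | Path) -> SyntheticPanel:
    """Read a fixture bundle back into memory through the IO module."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    cfg = SyntheticConfig(**manifest["config"])

    expression = read_matrix(directory / "expression.csv", "expression", EXPRESSION_SCALE)
    gene_effect = read_matrix(directory / "chronos.csv", "gene_effect", "Chronos")
    methylation = read_matrix(directory / "methylation.csv", "methylation", "beta fraction")
    pairs = read_paralog_table(directory / "paralogs.tsv", min_identity_pct=0.0)
    annotations = read_sample_annotations(directory / "samples.tsv")

    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t", keep_default_na=False)
    families: list[FamilyTruth] = []
    essentiality: dict[str, str] = {}
    for fam_id, grp in truth_df.groupby("family_id", sort=False):
        is_sl = bool(grp["is_sl"].iloc[0] in (True, "True"))
        silenced_gene = partner_gene = None
        silenced_samples: tuple[str, ...] = ()
        for _, row in grp.iterrows():
            essentiality[row["gene"]] = row["essentiality"]
            if row["role"] == "silenced":
                silenced_gene = row["gene"]
                if row["silenced_samples"]:
                    silenced_samples = tuple(str(row["silenced_samples"]).split(";"))
            elif row["role"] == "partner":
                partner_gene = row["gene"]
        families.append(
            FamilyTruth(
                family_id=str(fam_id),
                is_sl=is_sl,
                silenced_gene=silenced_gene,
                partner_gene=partner_gene,
                silenced_sample_ids=silenced_samples,
            )
        )
    return SyntheticPanel(
        expression=expression,
        gene_effect=gene_effect,
        methylation=methylation,
        pairs=pairs,
        annotations=annotations,
        truth=TruthTable(families=families, essentiality=essentiality),
        config=cfg,
    )
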