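"""Panel input/output: omics matrices, paralog tables, sample annotations.

All downstream stages consume the containers defined here.  Matrices are
wide gene × sample tables (DepMap / UCSC-Xena style): first column holds
gene identifiers, the header row holds sample identifiers, values are
numeric with empty cells or ``NA`` meaning missing.  Comma and tab
delimiters are auto-detected (falling back to comma, the DepMap export
convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("expression", "gene_effect", "methylation")
TISSUE_CLASSES = ("tumor", "normal", "cell_line")
MSI_STATUSES = ("MSI", "MSS", "unknown")


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class OmicsMatrix:
    """A gene × sample numeric matrix with a declared kind and value scale.

    Parameters
    ----------
    kind : {"expression", "gene_effect", "methylation"}
        What the values measure.
    scale : str
        Free-text declaration of the value scale, e.g. ``"log2(TPM+1)"``,
        ``"log2(FPKM+0.001)"``, ``"Chronos"`` or ``"beta fraction"``.
        Cutoffs downstream are applied on this declared scale verbatim;
        the scale is never inferred from the data.
    values : pandas.DataFrame
        Genes on the index, samples on the columns.  NaN means missing.
    """

    kind: str
    scale: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(
                f"unknown matrix kind {self.kind!r}; expected one of {MATRIX_KINDS}"
            )
        idx = self.values.index.astype(str).str.strip()
        cols = self.values.columns.astype(str).str.strip()
        self.values.index = idx
        self.values.columns = cols
        dup = _first_duplicate(idx)
        if dup is not None:
            raise ValidationError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(cols)
        if dup is not None:
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.kind == "methylation":
            arr = self.values.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValidationError(
                    "methylation beta values must lie in [0, 1]; "
                    f"found range [{finite.min():g}, {finite.max():g}]"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Restrict to the given samples, in the given order."""
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return OmicsMatrix(self.kind, self.scale, self.values.loc[:, list(sample_ids)])

    def gene_vector(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise ValidationError(f"gene {gene!r} not present in {self.kind} matrix")
        return self.values.loc[gene]


@dataclass(frozen=True)
class ParalogPair:
    """A two-member gene family with percent sequence identity."""

    family_id: str
    gene_a: str
    gene_b: str
    identity_pct: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(
                f"family {self.family_id}: gene_a == gene_b ({self.gene_a!r})"
            )
        if not (0.0 < self.identity_pct <= 100.0):
            raise ValidationError(
                f"family {self.family_id}: identity_pct {self.identity_pct} "
                "outside (0, 100]"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    tissue_class: str
    msi_status: str = "unknown"
    lineage: str = ""

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id}: tissue class {self.tissue_class!r} "
                f"not in {TISSUE_CLASSES}"
            )
        if self.msi_status not in MSI_STATUSES:
            raise ValidationError(
                f"sample {self.sample_id}: MSI status {self.msi_status!r} "
                f"not in {MSI_STATUSES}"
            )


def _parse_float(token) -> float:
    try:
        return float(token)
    except (TypeError, ValueError):
        return float("nan")


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"input file is empty: {path}")
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or df.shape[0] == 0 and df.shape[1] <= 1:
        raise InputError(f"input file has no parseable table: {path}")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_matrix(
    path: str | Path,
    kind: str,
    scale: str,
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read a wide gene × sample matrix file into an :class:`OmicsMatrix`.

    Non-numeric cells (including ``NA`` and empty cells) become missing.
    Duplicate gene or sample identifiers raise :class:`ValidationError`
    naming the duplicate; an empty file raises :class:`InputError`.
    """
    path = Path(path)
    if path.exists() and path.stat().st_size > 0:
        # pandas mangles duplicate header names, so check the raw header
        sep = _sniff_delimiter(path, delimiter)
        with open(path, "r", encoding="utf-8") as fh:
            header = [tok.strip() for tok in fh.readline().rstrip("\n").split(sep)]
        dup = _first_duplicate(header[1:])
        if dup is not None:
            raise ValidationError(f"duplicate sample id {dup!r} in {path}")
    raw = _read_table(path, delimiter)
    gene_col = raw.columns[0]
    genes = raw[gene_col].astype(str).str.strip()
    dup = _first_duplicate(genes)
    if dup is not None:
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    body = raw.drop(columns=[gene_col])
    # Python's float() is correctly rounded, so decimal text written with
    # shortest-repr round-trips float64 exactly (pandas' fast parser does not)
    values = body.map(_parse_float)
    values.index = genes
    mat = OmicsMatrix(kind=kind, scale=scale, values=values)
    logger.info(
        "read %s matrix %s: %d genes x %d samples", kind, path, *mat.shape
    )
    return mat


def write_matrix(matrix: OmicsMatrix, path: str | Path, delimiter: str = ",") -> Path:
    """Write a matrix in the same wide format :func:`read_matrix` reads.

    Floats are written with Python's shortest round-tripping repr, so a
    read-back reproduces the values bit-for-bit.
    """
    path = Path(path)
    matrix.values.to_csv(path, sep=delimiter, index_label="gene", na_rep="NA")
    return path


def read_paralog_table(
    path: str | Path,
    min_identity_pct: float = 50.0,
    delimiter: str | None = None,
) -> list[ParalogPair]:
    """Read a paralog-family table, keeping rows with identity strictly
    greater than ``min_identity_pct``.

    Expected columns: ``family_id``, ``gene_a``, ``gene_b``, ``identity_pct``.
    """
    df = _read_table(path, delimiter)
    required = ("family_id", "gene_a", "gene_b", "identity_pct")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"paralog table {path} missing columns {missing}")
    pairs: list[ParalogPair] = []
    n_dropped = 0
    for _, row in df.iterrows():
        ident = _parse_float(row["identity_pct"])
        if not np.isfinite(ident):
            raise ValidationError(
                f"family {row['family_id']}: identity {row['identity_pct']!r} "
                "is not a number"
            )
        pair = ParalogPair(
            family_id=str(row["family_id"]).strip(),
            gene_a=str(row["gene_a"]).strip(),
            gene_b=str(row["gene_b"]).strip(),
            identity_pct=float(ident),
        )
        if pair.identity_pct > min_identity_pct:
            pairs.append(pair)
        else:
            n_dropped += 1
    logger.info(
        "paralog table %s: retained %d pairs, dropped %d at identity <= %g%%",
        path, len(pairs), n_dropped, min_identity_pct,
    )
    return pairs


def read_sample_annotations(
    path: str | Path, delimiter: str | None = None
) -> list[SampleAnnotation]:
    """Read sample annotations (sample_id, tissue_class, optional msi_status,
    optional lineage).  A missing MSI column defaults every sample to
    ``unknown``."""
    df = _read_table(path, delimiter)
    required = ("sample_id", "tissue_class")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table {path} missing columns {missing}")
    has_msi = "msi_status" in df.columns
    has_lineage = "lineage" in df.columns
    out: list[SampleAnnotation] = []
    for _, row in df.iterrows():
        msi = str(row["msi_status"]).strip() if has_msi else "unknown"
        if msi in ("", "NA", "nan"):
            msi = "unknown"
        out.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]).strip(),
                tissue_class=str(row["tissue_class"]).strip(),
                msi_status=msi,
                lineage=str(row["lineage"]).strip() if has_lineage else "",
            )
        )
    dup = _first_duplicate(a.sample_id for a in out)
    if dup is not None:
        raise ValidationError(f"duplicate sample id {dup!r} in {path}")
    return out


def align_panels(a: OmicsMatrix, b: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict two matrices to their shared samples, in the first
    matrix's column order.  Idempotent on already-aligned panels."""
    in_b = set(b.sample_ids)
    common = [s for s in a.sample_ids if s in in_b]
    if not common:
        raise ValidationError("panels share no samples")
    logger.info("aligned panels on %d shared samples", len(common))
    if common == a.sample_ids and common == b.sample_ids:
        return a, b
    return a.select_samples(common), b.select_samples(common)
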