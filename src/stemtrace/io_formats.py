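"""Tabular I/O for the stemness pipeline.

Expression matrices are handled as :class:`pandas.DataFrame` objects with
gene identifiers on the index and sample identifiers on the columns, in
TPM-like (non-negative, within-sample normalised) units.  Two on-disk
dialects are supported: plain TSV (first column = gene id, header row =
sample ids) and GCT 1.2 (``#1.2`` version line, dimensions line, then a
body with ``Name``/``Description`` columns).

Sample metadata is a flat table with one row per sample.  Column names in
the source file are mapped onto the canonical fields through a configurable
column map whose defaults follow GTEx attribute names (``SAMPID``,
``SUBJID``, ``SMTS``, ``SMTSD``, ``AGE``, ``SEX``, ``DTHHRDY``).  Ages may
be given either as decade bins (``"20-29"`` … ``"70-79"``), which are
mapped to their midpoints 25 … 75 years, or as literal ages in years.
Death classification (Hardy scale) and sex are carried as opaque
categorical strings; missing optional covariates are recorded as missing,
never imputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneSet",
    "AGE_BIN_MIDPOINTS",
    "DEFAULT_COLUMN_MAP",
    "SAMPLE_TABLE_COLUMNS",
    "age_bin_to_midpoint",
    "validate_expression",
    "read_expression",
    "write_expression",
    "read_sample_table",
    "read_gene_sets",
    "write_gene_sets",
    "filter_tissue_details",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


#: Decade age bins and the midpoint (years) each is approximated to.
AGE_BIN_MIDPOINTS: dict[str, float] = {
    "20-29": 25.0,
    "30-39": 35.0,
    "40-49": 45.0,
    "50-59": 55.0,
    "60-69": 65.0,
    "70-79": 75.0,
}

_BIN_LIKE = re.compile(r"^\s*\d{1,3}\s*-\s*\d{1,3}\s*$")

#: Default source-column names for sample metadata (GTEx conventions).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "sample_id": "SAMPID",
    "subject_id": "SUBJID",
    "tissue": "SMTS",
    "region": "SMTSD",
    "age": "AGE",
    "sex": "SEX",
    "death": "DTHHRDY",
}

#: Canonical columns of a sample table, in output order.
SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "tissue",
    "region",
    "age_bin",
    "age_years",
    "sex",
    "death",
)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (one GMT line)."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def age_bin_to_midpoint(age_bin: str) -> float:
    """Map a decade age bin to its midpoint in years.

    Only the six bins ``20-29`` … ``70-79`` are supported; anything else
    raises :class:`ValueError`.
    """
    try:
        return AGE_BIN_MIDPOINTS[age_bin]
    except KeyError:
        raise ValueError(
            f"unsupported age bin {age_bin!r}; expected one of "
            f"{sorted(AGE_BIN_MIDPOINTS)}"
        ) from None


def validate_expression(df: pd.DataFrame, where: str = "expression matrix") -> pd.DataFrame:
    """Validate an expression matrix and return it as float64.

    Checks: unique gene and sample ids, all values numeric, finite and
    non-negative.
    """
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{where}: duplicate gene ids {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{where}: duplicate sample ids {dup}")
    try:
        values = df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: non-numeric cell ({exc})") from exc
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        gi, sj = np.argwhere(~np.isfinite(arr))[0]
        raise FormatError(
            f"{where}: non-finite value at gene {values.index[gi]!r}, "
            f"sample {values.columns[sj]!r}"
        )
    if (arr < 0).any():
        gi, sj = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{where}: negative value at gene {values.index[gi]!r}, "
            f"sample {values.columns[sj]!r}"
        )
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "gene_id"
    return values


def _check_unique_header(line: str, where: str) -> None:
    # pandas silently mangles duplicate sample ids to "x.1"; catch them first
    names = line.rstrip("\n").split("\t")[1:]
    dup = [n for n in names if names.count(n) > 1]
    if dup:
        raise FormatError(f"{where}: duplicate sample id(s) {sorted(set(dup))}")


def _collapse_duplicate_genes(df: pd.DataFrame, where: str) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    n_dup = int(df.index.duplicated().sum())
    log.warning("%s: collapsing %d duplicate gene row(s) by mean", where, n_dup)
    # groupby(sort=False) keeps first-occurrence order
    return df.groupby(level=0, sort=False).mean()


def read_expression(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read an expression matrix from ``path``.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` (gene id in the first column, sample ids in the header)
        or ``"gct"`` (GCT 1.2).

    Duplicate gene rows are collapsed by their mean with a logged warning;
    duplicate sample ids are an error.
    """
    path = Path(path)
    where = str(path)
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            _check_unique_header(fh.readline(), where)
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise FormatError(f"{where}: cannot parse TSV ({exc})") from exc
    elif format == "gct":
        with open(path, encoding="utf-8") as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{where}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2 or not all(d.isdigit() for d in dims):
                raise FormatError(f"{where}: malformed GCT dimensions line {dims!r}")
            n_rows, n_cols = map(int, dims)
            header_pos = fh.tell()
            _check_unique_header(fh.readline(), where)
            fh.seek(header_pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns="Description")
        if df.shape != (n_rows, n_cols):
            raise FormatError(
                f"{where}: GCT body is {df.shape[0]}x{df.shape[1]}, "
                f"header declares {n_rows}x{n_cols}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    df = _collapse_duplicate_genes(df, where)
    return validate_expression(df, where)


def write_expression(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or GCT 1.2 (UTF-8, '.' decimal)."""
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            body = df.copy()
            body.insert(0, "Description", "na")
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def _parse_age(raw: object, where: str) -> tuple[str | None, float]:
    """Return (age_bin or None, age_years) from a raw AGE cell."""
    text = str(raw).strip()
    if _BIN_LIKE.match(text):
        return text, age_bin_to_midpoint(text)
    try:
        years = float(text)
    except ValueError:
        raise FormatError(f"{where}: cannot interpret age {raw!r}") from None
    if not years > 0:
        raise FormatError(f"{where}: age must be positive, got {raw!r}")
    return None, years


def read_sample_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read per-sample metadata into the canonical sample table.

    ``column_map`` maps canonical field names (``sample_id``,
    ``subject_id``, ``tissue``, ``region``, ``age``, ``sex``, ``death``)
    to source-column names; unspecified entries fall back to
    :data:`DEFAULT_COLUMN_MAP`.  ``sample_id``, ``subject_id``, ``tissue``
    and ``age`` are required, the rest optional.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    where = str(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)

    for required in ("sample_id", "subject_id", "tissue", "age"):
        if cmap[required] not in raw.columns:
            raise FormatError(
                f"{where}: required column {cmap[required]!r} (for {required}) missing"
            )

    out = pd.DataFrame(
        {
            "sample_id": raw[cmap["sample_id"]].str.strip(),
            "subject_id": raw[cmap["subject_id"]].str.strip(),
            "tissue": raw[cmap["tissue"]].str.strip(),
        }
    )
    dup = out["sample_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{where}: duplicate sample_id(s) {sorted(out.loc[dup, 'sample_id'].unique())}"
        )

    parsed = [
        _parse_age(a, f"{where} row {i}") for i, a in enumerate(raw[cmap["age"]])
    ]
    out["age_bin"] = pd.array([b for b, _ in parsed], dtype="string")
    out["age_years"] = [y for _, y in parsed]

    for optional in ("region", "sex", "death"):
        col = cmap[optional]
        if col in raw.columns:
            out[optional] = raw[col].str.strip().astype("string")
        else:
            out[optional] = pd.array([pd.NA] * len(out), dtype="string")

    return out[list(SAMPLE_TABLE_COLUMNS)].reset_index(drop=True)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, then gene ids)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in (g.strip() for g in genes) if g]
            sets.append(GeneSet(name=name, description=description, genes=frozenset(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na", *sorted(gs.genes)]) + "\n")


def filter_tissue_details(
    table: pd.DataFrame, exclude: Sequence[str]
) -> pd.DataFrame:
    """Drop samples whose region (tissue detail) is in ``exclude``.

    Used e.g. to remove cultured cell lines (EBV-transformed lymphocytes,
    fibroblasts) that otherwise dominate the top of the stemness scale.
    """
    exclude = set(exclude)
    if not exclude:
        return table.copy()
    keep = ~table["region"].isin(exclude)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_tissue_details: removed %d sample(s)", n_removed)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        log.warning("filter_tissue_details: exclusion removed every sample")
    return out
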