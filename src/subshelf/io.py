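"""Tab-separated interchange with header comments, plus schema validation.

All tables travel as TSV with optional leading ``# key: value`` comment
lines (value kind, units, provenance). Readers validate the documented
schemas and report violations with file line numbers; a column map lets
DIAMOND-style tabular output feed the hit-table reader directly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd
import yaml

from .containers import AbundanceMatrix
from .errors import SchemaError
from .profiling import HIT_COLUMNS, validate_catalog

__all__ = [
    "DIAMOND_TABULAR_MAP",
    "read_tsv",
    "write_tsv",
    "read_hits",
    "read_catalog",
    "catalog_from_fasta",
    "read_counts",
    "read_coverage",
    "read_taxon_table",
    "read_matrix",
    "write_matrix",
    "write_newick",
    "load_yaml_config",
    "write_provenance",
]

#: Rename map for BLAST/DIAMOND tabular columns (qcovhsp and qlen requested).
DIAMOND_TABULAR_MAP = {
    "qseqid": "read_id",
    "sseqid": "gene_id",
    "pident": "percent_identity",
    "qcovhsp": "query_coverage",
    "bitscore": "bitscore",
    "qlen": "read_length",
}


def write_tsv(df: pd.DataFrame, path, comments: dict | None = None,
              index: bool = True) -> None:
    """Write a TSV with leading ``# key: value`` comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_tsv`; returns (table, comments)."""
    path = Path(path)
    comments = {}
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                comments[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=n_comment, index_col=index_col)
    return df, comments


def _line_numbers(mask: pd.Series, n_comment: int) -> list[int]:
    # +2: one header line plus 1-based numbering
    return [int(i) + n_comment + 2 for i in mask.to_numpy().nonzero()[0][:10]]


def read_hits(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a read→gene alignment hit table.

    ``column_map`` renames input columns to the expected schema (pass
    :data:`DIAMOND_TABULAR_MAP` for DIAMOND tabular output with
    ``qseqid sseqid pident qcovhsp bitscore qlen`` columns).
    """
    df, comments = read_tsv(path, index_col=None)
    n_comment = len(comments)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: hit table missing columns {missing}")
    for col in ("percent_identity", "query_coverage"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals > 100)
        if bad.any():
            raise SchemaError(
                f"{path}: {col} outside [0, 100] at lines {_line_numbers(bad, n_comment)}"
            )
        df[col] = vals
    bit = pd.to_numeric(df["bitscore"], errors="coerce")
    bad = bit.isna() | (bit < 0)
    if bad.any():
        raise SchemaError(
            f"{path}: negative/unparseable bitscore at lines {_line_numbers(bad, n_comment)}"
        )
    rl = pd.to_numeric(df["read_length"], errors="coerce")
    bad = rl.isna() | (rl <= 0)
    if bad.any():
        raise SchemaError(
            f"{path}: non-positive read_length at lines {_line_numbers(bad, n_comment)}"
        )
    return df


def read_catalog(path) -> pd.DataFrame:
    """Read a gene catalog TSV (index gene_id; family, length_bp, ...)."""
    df, _ = read_tsv(path, index_col=0)
    if "is_single_copy_marker" in df.columns:
        df["is_single_copy_marker"] = df["is_single_copy_marker"].astype(bool)
    return validate_catalog(df)


def catalog_from_fasta(fasta_path, attributes: pd.DataFrame) -> pd.DataFrame:
    """Build a catalog from gene sequences plus per-gene attributes.

    Gene lengths come from the FASTA records; ``attributes`` (indexed by
    gene id) supplies at least ``family`` and optionally genome, pathway
    and marker flags.
    """
    from Bio import SeqIO

    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not lengths:
        raise SchemaError(f"{fasta_path}: no FASTA records")
    catalog = attributes.copy()
    missing = [g for g in catalog.index if g not in lengths]
    if missing:
        raise SchemaError(f"genes without sequences: {missing[:10]}")
    catalog["length_bp"] = [lengths[g] for g in catalog.index]
    return validate_catalog(catalog)


def read_counts(path) -> pd.DataFrame:
    """Read an ORF × sample transcript count table."""
    df, _ = read_tsv(path, index_col=0)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise SchemaError(f"{path}: non-numeric counts")
    if (vals < 0).any().any():
        raise SchemaError(f"{path}: negative counts")
    return vals


def read_coverage(path) -> pd.DataFrame:
    """Read a genome × window coverage table."""
    df, _ = read_tsv(path, index_col=0)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if (vals.fillna(0) < 0).any().any():
        raise SchemaError(f"{path}: negative coverage")
    return vals


def read_taxon_table(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a taxon × sample count table.

    A ``taxonomy`` column (semicolon-delimited ranks), if present, is split
    off and returned separately.
    """
    df, _ = read_tsv(path, index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise SchemaError(f"{path}: non-numeric taxon counts")
    return df, taxonomy


def write_matrix(matrix: AbundanceMatrix, path, units: str | None = None) -> None:
    """Write an abundance matrix with its value kind in a header comment."""
    comments = {"value_kind": matrix.value_kind}
    if units:
        comments["units"] = units
    if matrix.total_reads is not None:
        comments["total_reads"] = json.dumps(matrix.total_reads.to_dict())
    write_tsv(matrix.data, path, comments=comments)


def read_matrix(path) -> AbundanceMatrix:
    """Read an abundance matrix written by :func:`write_matrix`."""
    df, comments = read_tsv(path, index_col=0)
    if "value_kind" not in comments:
        raise SchemaError(f"{path}: missing '# value_kind:' header comment")
    total_reads = None
    if "total_reads" in comments:
        total_reads = pd.Series(json.loads(comments["total_reads"]))
    return AbundanceMatrix(
        data=df.apply(pd.to_numeric), value_kind=comments["value_kind"],
        total_reads=total_reads,
    )


def write_newick(dendrogram, path) -> None:
    Path(path).write_text(dendrogram.newick() + "\n")


def load_yaml_config(path) -> dict:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: top-level YAML must be a mapping")
    return data


def write_provenance(path, **entries) -> None:
    """Record the configuration and seeds a run used, as JSON."""
    def _clean(value):
        if is_dataclass(value) and not isinstance(value, type):
            return _clean(asdict(value))
        if isinstance(value, dict):
            return {str(k): _clean(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [_clean(v) for v in value]
        if hasattr(value, "item"):
            return value.item()
        return value

    Path(path).write_text(json.dumps(_clean(entries), indent=2, default=str) + "\n")
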