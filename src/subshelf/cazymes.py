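"""Carbohydrate-active enzyme (CAZyme) summaries per reconstructed genome.

dbCAN-style annotations (gene, CAZyme family such as GH13, class, e-value,
alignment coverage) are filtered at stringent thresholds (e-value < 1e-15
and coverage > 0.35), tallied into per-genome distinct-gene counts per
class, and ranked by glycoside-hydrolase (GH) family diversity to select
the genomes shown in class-level transcription (TPM) summaries. CBM
(carbohydrate-binding module) annotations are reported under the display
label CBD ("genes containing carbohydrate binding domains").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = [
    "CAZYME_CLASSES",
    "DISPLAY_CLASSES",
    "filter_cazyme",
    "class_counts",
    "gh_family_diversity",
    "top_by_gh_diversity",
    "class_tpm",
]

CAZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")
#: Classes shown by default in summaries (CBM displayed as CBD).
DISPLAY_CLASSES = ("GH", "GT", "CBD")

ANNOTATION_COLUMNS = ("gene_id", "cazyme_family", "cazyme_class", "evalue", "coverage")

_CLASS_DISPLAY = {c: c for c in CAZYME_CLASSES} | {"CBM": "CBD"}

EVALUE_MAX = 1e-15
COVERAGE_MIN = 0.35


def _check(annotations: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns: {missing}")


def filter_cazyme(
    annotations: pd.DataFrame,
    evalue_max: float = EVALUE_MAX,
    coverage_min: float = COVERAGE_MIN,
) -> pd.DataFrame:
    """Retain annotations with e-value strictly below ``evalue_max`` and
    coverage strictly above ``coverage_min``. Idempotent.

    Raises
    ------
    SchemaError
        On missing columns or unparseable e-values (reported with row
        numbers).
    """
    _check(annotations)
    evalue = pd.to_numeric(annotations["evalue"], errors="coerce")
    bad = annotations.index[evalue.isna()].tolist()
    if bad:
        raise SchemaError(f"malformed e-values at rows: {bad[:10]}")
    if (evalue < 0).any():
        raise SchemaError("negative e-values")
    coverage = pd.to_numeric(annotations["coverage"], errors="coerce")
    if coverage.isna().any() or (coverage < 0).any() or (coverage > 1).any():
        raise SchemaError("coverage must be a fraction in [0, 1]")
    keep = (evalue < evalue_max) & (coverage > coverage_min)
    return annotations.loc[keep].copy()


def class_counts(
    annotations: pd.DataFrame,
    catalog: pd.DataFrame,
    classes: tuple[str, ...] = CAZYME_CLASSES,
) -> pd.DataFrame:
    """Distinct annotated genes per (genome, CAZyme class).

    A gene annotated in several classes contributes one count to each.
    Genes without a genome assignment are tallied under ``"unbinned"``.
    CBM appears in the output under the display label CBD.
    """
    _check(annotations)
    unknown = set(annotations["cazyme_class"]) - set(CAZYME_CLASSES)
    if unknown:
        raise SchemaError(f"unknown CAZyme classes: {sorted(unknown)}")
    out_cols = [_CLASS_DISPLAY[c] for c in classes]
    if annotations.empty:
        return pd.DataFrame(0, index=pd.Index([], name="genome_id"), columns=out_cols)
    genome = annotations["gene_id"].map(catalog.get("genome_id", pd.Series(dtype=object)))
    genome = genome.fillna("unbinned")
    df = annotations.assign(genome_id=genome.values)
    tally = (
        df.drop_duplicates(["genome_id", "cazyme_class", "gene_id"])
        .groupby(["genome_id", "cazyme_class"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(classes), fill_value=0)
    )
    tally.columns = out_cols
    return tally


def gh_family_diversity(annotations: pd.DataFrame, catalog: pd.DataFrame) -> pd.Series:
    """Number of distinct GH families annotated per genome."""
    _check(annotations)
    gh = annotations.loc[annotations["cazyme_class"] == "GH"]
    genome = gh["gene_id"].map(catalog.get("genome_id", pd.Series(dtype=object))).fillna("unbinned")
    return gh.assign(genome_id=genome.values).groupby("genome_id")["cazyme_family"].nunique()


def top_by_gh_diversity(
    annotations: pd.DataFrame, catalog: pd.DataFrame, n: int = 50
) -> list:
    """Genomes ranked by distinct-GH-family count, descending.

    Ties are broken by genome id ascending; the first ``n`` are returned
    (all genomes if fewer than ``n`` carry GH annotations).
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    diversity = gh_family_diversity(annotations, catalog)
    order = diversity.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:n].tolist()


def class_tpm(
    orf_tpm: pd.DataFrame | pd.Series,
    annotations: pd.DataFrame,
    catalog: pd.DataFrame,
    classes: tuple[str, ...] = CAZYME_CLASSES,
) -> pd.DataFrame:
    """Summed TPM of annotated genes per (genome, class).

    ``orf_tpm`` is the whole-sample TPM table (so class sums are shares of
    the 10⁶ total). Annotated genes missing from the TPM table are skipped
    with a warning. For multi-sample TPM tables a genome × class table is
    returned per sample, concatenated with a sample column level.
    """
    _check(annotations)
    if isinstance(orf_tpm, pd.Series):
        orf_tpm = orf_tpm.to_frame(name="sample")
    missing = set(annotations["gene_id"]) - set(orf_tpm.index)
    if missing:
        warnings.warn(
            f"{len(missing)} annotated genes missing from the TPM table were skipped",
            stacklevel=2,
        )
    ann = annotations.loc[annotations["gene_id"].isin(orf_tpm.index)]
    ann = ann.drop_duplicates(["gene_id", "cazyme_class"])
    genome = ann["gene_id"].map(catalog.get("genome_id", pd.Series(dtype=object))).fillna("unbinned")
    out = {}
    for sample in orf_tpm.columns:
        tpm = ann["gene_id"].map(orf_tpm[sample])
        grouped = (
            pd.DataFrame(
                {"genome_id": genome.values, "cls": ann["cazyme_class"].values, "tpm": tpm.values}
            )
            .groupby(["genome_id", "cls"])["tpm"]
            .sum()
            .unstack(fill_value=0.0)
            .reindex(columns=list(classes), fill_value=0.0)
        )
        grouped.columns = [_CLASS_DISPLAY[c] for c in classes]
        out[sample] = grouped
    result = pd.concat(out, axis=1)
    if len(orf_tpm.columns) == 1:
        result = result.droplevel(0, axis=1)
    return result
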