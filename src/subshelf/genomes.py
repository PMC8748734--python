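"""Genome-resolved abundance and expression metrics.

Abundance of a reconstructed genome in the metagenome is summarized by the
interquartile (Q2Q3) mean of its per-position (or per-window) coverage —
robust to islands of aberrant depth — and normalized across genomes to
counts per million (CPM = B/ΣB × 10⁶). Expression is summarized per ORF as
transcripts per million (TPM = A/ΣA × 10⁶ with A = count/length_kbp), which
makes both metrics within-sample shares summing to 10⁶ and hence directly
comparable. Genome-level activity is the RNA/DNA ratio (summed genome TPM
over genome CPM) and the fraction of the genome's ORFs that are expressed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigError, NormalizationError

__all__ = [
    "compute_tpm",
    "q2q3_mean",
    "genome_coverage_summary",
    "compute_cpm",
    "rna_dna_ratio",
    "genome_tpm",
    "fraction_expressed",
    "combine_replicates",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Transcripts per million from an ORF × sample count table.

    ``A = count / (length_bp / 1000)``; ``TPM = A / ΣA × 10⁶`` per sample,
    so each sample column sums to 10⁶ exactly.

    Parameters
    ----------
    counts:
        Non-negative integer counts, ORFs as index, samples as columns.
    lengths:
        ORF lengths in bp — a Series indexed by ORF id, or a catalog
        DataFrame with a ``length_bp`` column.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths["length_bp"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ConfigError(f"lengths unknown for ORFs: {list(missing[:5])}")
    vals = counts.to_numpy()
    if (vals < 0).any():
        raise ConfigError("counts must be non-negative")
    a = counts.div(lengths.loc[counts.index] / 1000.0, axis=0)
    colsums = a.sum(axis=0)
    zero = colsums.index[colsums == 0].tolist()
    if zero:
        raise NormalizationError(f"all-zero samples, TPM undefined: {zero}")
    return a.div(colsums, axis=1) * 1e6


def q2q3_mean(coverage: np.ndarray | pd.Series | list) -> float:
    """Interquartile (Q2Q3) mean of a coverage vector.

    Values are sorted and positions *i* (0-based) with
    ``ceil(n/4) <= i < floor(3n/4)`` retained; when that slice is empty
    (n ≤ 2) all values are retained. The mean of the retained values is
    returned, so the result always lies within [min, max] and equals the
    plain mean for constant vectors.
    """
    arr = np.sort(np.asarray(coverage, dtype=float))
    n = arr.size
    if n == 0:
        raise ConfigError("coverage vector is empty")
    lo = math.ceil(n / 4)
    hi = math.floor(3 * n / 4)
    if hi <= lo:
        return float(arr.mean())
    return float(arr[lo:hi].mean())


def genome_coverage_summary(coverage: pd.DataFrame) -> pd.Series:
    """Q2Q3 mean coverage per genome from a genome × window coverage table.

    NaN cells (unequal window counts across genomes) are ignored.
    """
    return coverage.apply(lambda row: q2q3_mean(row.dropna().to_numpy()), axis=1)


def compute_cpm(coverages: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Counts per million across genomes: ``CPM = B / ΣB × 10⁶``.

    Accepts a per-genome Series (one sample) or a genome × sample DataFrame;
    each sample sums to 10⁶ exactly.
    """
    if isinstance(coverages, pd.Series):
        total = coverages.sum()
        if total <= 0:
            raise NormalizationError("total coverage is zero; CPM undefined")
        return coverages / total * 1e6
    colsums = coverages.sum(axis=0)
    zero = colsums.index[colsums <= 0].tolist()
    if zero:
        raise NormalizationError(f"zero total coverage, CPM undefined: {zero}")
    return coverages.div(colsums, axis=1) * 1e6


def genome_tpm(tpm: pd.DataFrame, orf_catalog: pd.DataFrame, how: str = "sum") -> pd.DataFrame:
    """Aggregate ORF-level TPM to genome level (sum by default, or mean)."""
    if how not in ("sum", "mean"):
        raise ConfigError("how must be 'sum' or 'mean'")
    genome = tpm.index.map(orf_catalog["genome_id"])
    grouped = tpm.groupby(genome)
    return grouped.sum() if how == "sum" else grouped.mean()


def rna_dna_ratio(genome_tpm_value, genome_cpm_value):
    """Transcriptional activity: genome TPM (summed over ORFs) over genome CPM.

    Dimensionless; >1 means the genome contributes a larger share of the
    transcript pool than of the DNA pool. Accepts scalars or aligned
    Series/DataFrames; zero CPM raises.
    """
    if np.isscalar(genome_cpm_value):
        if genome_cpm_value <= 0:
            raise NormalizationError("genome CPM is zero; RNA/DNA ratio undefined")
        return genome_tpm_value / genome_cpm_value
    cpm = pd.Series(genome_cpm_value) if not isinstance(
        genome_cpm_value, (pd.Series, pd.DataFrame)
    ) else genome_cpm_value
    if (np.asarray(cpm) <= 0).any():
        raise NormalizationError("zero genome CPM entries; RNA/DNA ratio undefined")
    return genome_tpm_value / cpm


def fraction_expressed(
    counts: pd.DataFrame,
    orf_catalog: pd.DataFrame,
    genome_id: str,
    min_count: int = 1,
) -> pd.Series:
    """Percentage of a genome's ORFs with transcript count ≥ ``min_count``.

    Returns one percentage per sample column.
    """
    orfs = orf_catalog.index[orf_catalog["genome_id"] == genome_id]
    if len(orfs) == 0:
        raise KeyError(f"unknown genome {genome_id!r} (no ORFs in catalog)")
    sub = counts.reindex(orfs, fill_value=0)
    return (sub >= min_count).sum(axis=0) / len(orfs) * 100.0


def combine_replicates(
    tables: list[pd.DataFrame], kind: str = "counts"
) -> pd.DataFrame:
    """Merge replicate samples before normalization.

    ``kind="counts"``: element-wise sum (outer-aligned, missing = 0).
    ``kind="coverage"``: coverage vectors are concatenated along windows.
    """
    if not tables:
        raise ConfigError("no tables to combine")
    if kind == "counts":
        out = tables[0]
        for t in tables[1:]:
            out = out.add(t, fill_value=0)
        return out
    if kind == "coverage":
        out = pd.concat(tables, axis=1)
        out.columns = range(out.shape[1])
        return out
    raise ConfigError("kind must be 'counts' or 'coverage'")
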