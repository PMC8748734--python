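"""Assembly-free functional profiling of metagenomic/metatranscriptomic reads.

Reads aligned to curated metabolic-gene databases arrive as a hit table
(read, gene, percent identity, query coverage, bitscore). The pipeline is:

1. :func:`filter_hits` — drop alignments below the per-family identity
   thresholds, the query-coverage cutoff, the minimum read length, and (for
   the universal single-copy marker genes) the bitscore floor; keep one best
   hit per read.
2. :func:`compute_rpkm` — reads per kilobase million,
   ``RPKM = X / total_sample_reads × 10⁶`` with
   ``X = hits_to_gene / gene_length_kbp``, optionally summed over genes of
   a family.
3. :func:`scg_baseline` — the mean RPKM of 14 universal single-copy
   ribosomal marker genes, representing the abundance of "one average
   organism" in the sample.
4. :func:`copies_per_organism` — family RPKM divided by the baseline: the
   average number of gene copies carried per organism, the community-
   fraction scale used for presentation (values near 1 mean essentially
   every organism carries the gene once).
5. :func:`collapse_pathways` / :func:`display_transform` — pathway sums and
   the presentation-only cap-at-1 / log10(x+1) transforms.

Metagenome and metatranscriptome hit tables take the same code path; only
the input differs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix
from .errors import CatalogMismatchError, ConfigError, NormalizationError, SchemaError

__all__ = [
    "MARKER_FAMILIES",
    "HitFilterConfig",
    "validate_catalog",
    "filter_hits",
    "compute_rpkm",
    "scg_baseline",
    "copies_per_organism",
    "collapse_pathways",
    "display_transform",
    "profile_sample",
]

#: The 14 universal single-copy ribosomal marker gene families used as the
#: per-organism abundance baseline, with typical gene lengths (bp). Every
#: prokaryotic genome carries exactly one copy of each.
MARKER_FAMILIES: dict[str, int] = {
    "RplB": 830,
    "RplC": 650,
    "RplD": 620,
    "RplE": 540,
    "RplF": 535,
    "RplN": 370,
    "RplP": 410,
    "RplR": 355,
    "RplV": 330,
    "RpsC": 700,
    "RpsH": 400,
    "RpsJ": 310,
    "RpsQ": 260,
    "RpsS": 280,
}

HIT_COLUMNS = (
    "read_id",
    "gene_id",
    "percent_identity",
    "query_coverage",
    "bitscore",
    "read_length",
)

CATALOG_COLUMNS = ("family", "length_bp")

#: Gene-family-specific percent-identity cutoffs for retaining alignments.
DEFAULT_IDENTITY_THRESHOLDS: dict[str, float] = {
    "RHO": 40.0,
    "AtpA": 60.0,
    "AmoA": 60.0,
    "MmoA": 60.0,
    "CoxL": 60.0,
    "NxrA": 60.0,
    "NuoF": 60.0,
    "RbcL": 60.0,
    "HbsT": 75.0,
    "PsbA": 70.0,
    "YgfK": 70.0,
    "ARO": 70.0,
    "IsoA": 70.0,
    "PsaA": 80.0,
}


@dataclass(frozen=True)
class HitFilterConfig:
    """Alignment retention thresholds.

    Conventions: query coverage must strictly exceed ``query_coverage_min``;
    percent identity must be greater than or equal to the family threshold
    (``default_identity_min`` for unlisted families); marker-gene hits must
    additionally reach ``marker_bitscore_min``; reads shorter than
    ``min_read_length`` are discarded. The family list is user-extensible
    via ``identity_thresholds``.
    """

    query_coverage_min: float = 80.0
    identity_thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_THRESHOLDS)
    )
    default_identity_min: float = 50.0
    marker_bitscore_min: float = 40.0
    min_read_length: int = 124

    def __post_init__(self):
        for name, thr in {
            "query_coverage_min": self.query_coverage_min,
            "default_identity_min": self.default_identity_min,
            **dict(self.identity_thresholds),
        }.items():
            if not 0 <= thr <= 100:
                raise ConfigError(f"identity/coverage threshold {name}={thr} outside [0, 100]")
        if self.marker_bitscore_min < 0:
            raise ConfigError("marker_bitscore_min must be >= 0")
        if self.min_read_length <= 0:
            raise ConfigError("min_read_length must be positive")

    def identity_min(self, family: str) -> float:
        return float(self.identity_thresholds.get(family, self.default_identity_min))


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check a gene catalog: index gene_id, columns family and length_bp.

    Optional columns: ``genome_id``, ``pathway``, ``is_single_copy_marker``
    (added as all-False when absent). Returns the catalog (possibly with the
    marker column filled in).
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise SchemaError(f"catalog missing columns: {missing}")
    if (catalog["length_bp"] <= 0).any():
        bad = catalog.index[catalog["length_bp"] <= 0][:5].tolist()
        raise SchemaError(f"non-positive gene lengths for: {bad}")
    if not catalog.index.is_unique:
        raise SchemaError("duplicate gene ids in catalog")
    if "is_single_copy_marker" not in catalog.columns:
        catalog = catalog.copy()
        catalog["is_single_copy_marker"] = False
    n_marker_families = catalog.loc[catalog["is_single_copy_marker"], "family"].nunique()
    if n_marker_families not in (0, len(MARKER_FAMILIES)):
        raise ConfigError(
            f"catalog has {n_marker_families} single-copy marker families; "
            f"expected {len(MARKER_FAMILIES)} (or none)"
        )
    return catalog


def _check_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise SchemaError(f"hit table missing columns: {missing}")


def filter_hits(
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    cfg: HitFilterConfig | None = None,
) -> pd.DataFrame:
    """Apply the alignment retention thresholds and best-hit selection.

    Retained rows satisfy, in this order of evaluation: read length ≥
    minimum; query coverage strictly above the cutoff; percent identity at
    or above the family-specific threshold; and, for single-copy marker
    families, bitscore at or above the marker floor. Among surviving
    alignments one row is kept per read — highest bitscore, ties broken by
    lexicographically smallest gene id. Idempotent.

    Raises
    ------
    CatalogMismatchError
        If any hit references a gene id absent from the catalog.
    """
    cfg = cfg or HitFilterConfig()
    _check_hits(hits)
    catalog = validate_catalog(catalog)
    if hits.empty:
        return hits.copy()

    unknown = set(hits["gene_id"]) - set(catalog.index)
    if unknown:
        raise CatalogMismatchError(unknown)

    family = hits["gene_id"].map(catalog["family"])
    is_marker = hits["gene_id"].map(catalog["is_single_copy_marker"]).astype(bool)
    identity_min = family.map(cfg.identity_min)

    keep = (
        (hits["read_length"] >= cfg.min_read_length)
        & (hits["query_coverage"] > cfg.query_coverage_min)
        & (hits["percent_identity"] >= identity_min)
        & (~is_marker | (hits["bitscore"] >= cfg.marker_bitscore_min))
    )
    kept = hits.loc[keep]
    if kept.empty:
        return kept.copy()
    # best hit per read: bitscore desc, gene id asc
    kept = kept.sort_values(["read_id", "bitscore", "gene_id"], ascending=[True, False, True])
    best = kept.drop_duplicates("read_id", keep="first")
    return best.sort_index()


def compute_rpkm(
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    total_reads: int,
    collapse: str = "family",
    sample: str = "sample",
) -> AbundanceMatrix:
    """Reads-per-kilobase-million from a filtered hit table.

    Per gene, ``X = hits_to_gene / (length_bp / 1000)`` and
    ``RPKM = X / total_reads × 10⁶``. ``collapse="family"`` sums gene-level
    RPKM within each family; ``collapse="gene"`` keeps genes. Features with
    no hits are present with RPKM 0 so downstream means stay comparable
    across samples.

    Parameters
    ----------
    hits:
        Hit table, already passed through :func:`filter_hits`.
    total_reads:
        Total reads in the sample (the library size before alignment),
        strictly positive.
    """
    if total_reads <= 0:
        raise ConfigError("total_reads must be positive")
    if collapse not in ("family", "gene"):
        raise ConfigError(f"collapse must be 'family' or 'gene', got {collapse!r}")
    catalog = validate_catalog(catalog)
    if not hits.empty:
        _check_hits(hits)
        unknown = set(hits["gene_id"]) - set(catalog.index)
        if unknown:
            raise CatalogMismatchError(unknown)
        counts = hits["gene_id"].value_counts()
    else:
        counts = pd.Series(dtype=float)
    counts = counts.reindex(catalog.index, fill_value=0).astype(float)
    x = counts / (catalog["length_bp"] / 1000.0)
    rpkm = x / total_reads * 1e6
    if collapse == "family":
        rpkm = rpkm.groupby(catalog["family"]).sum().sort_index()
        rpkm.index.name = "family"
    else:
        rpkm.index.name = "gene_id"
    data = rpkm.to_frame(name=sample)
    return AbundanceMatrix(
        data=data, value_kind="RPKM", total_reads=pd.Series({sample: total_reads})
    )


def scg_baseline(
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    cfg: HitFilterConfig | None = None,
    total_reads: int | None = None,
) -> tuple[float, pd.Series]:
    """Mean RPKM of the 14 single-copy ribosomal marker families.

    Hits are filtered with ``cfg`` (filtering is idempotent, so passing an
    already-filtered table is harmless), converted to family RPKM, and the
    14 marker families are averaged arithmetically; families with no
    retained hits contribute 0 to the mean so the baseline stays comparable
    across samples.

    Returns
    -------
    (baseline, per_family)
        The scalar baseline and the 14 per-family RPKM values for
        diagnostics.
    """
    if total_reads is None:
        raise ConfigError("total_reads is required")
    catalog = validate_catalog(catalog)
    marker_families = sorted(catalog.loc[catalog["is_single_copy_marker"], "family"].unique())
    if len(marker_families) != len(MARKER_FAMILIES):
        raise ConfigError(
            f"catalog carries {len(marker_families)} marker families, "
            f"need {len(MARKER_FAMILIES)}"
        )
    kept = filter_hits(hits, catalog, cfg)
    fam_rpkm = compute_rpkm(kept, catalog, total_reads, collapse="family").data.iloc[:, 0]
    per_family = fam_rpkm.reindex(marker_families, fill_value=0.0)
    return float(per_family.mean()), per_family


def copies_per_organism(
    family_rpkm: AbundanceMatrix,
    baseline: float | Mapping | pd.Series,
) -> AbundanceMatrix:
    """Normalize family RPKM by the single-copy-gene baseline.

    The result estimates the average number of copies of the gene family
    carried per organism in the community; a single-copy gene present in a
    fraction *p* of organisms comes out near *p*, and the marker families
    themselves come out near 1.

    Parameters
    ----------
    baseline:
        Scalar (single-sample matrix) or per-sample mapping. A zero
        baseline is an error naming the sample.
    """
    if family_rpkm.value_kind != "RPKM":
        raise ConfigError(f"expected an RPKM matrix, got {family_rpkm.value_kind}")
    if np.isscalar(baseline):
        baseline = pd.Series({s: float(baseline) for s in family_rpkm.samples})
    else:
        baseline = pd.Series(baseline, dtype=float)
    for s in family_rpkm.samples:
        if s not in baseline.index:
            raise ConfigError(f"no baseline for sample {s!r}")
        if baseline[s] <= 0:
            raise NormalizationError(
                f"single-copy-gene baseline is {baseline[s]} for sample {s!r}; "
                "copies per organism undefined"
            )
    data = family_rpkm.data.div(baseline[family_rpkm.samples], axis=1)
    return AbundanceMatrix(
        data=data, value_kind="copies_per_organism", total_reads=family_rpkm.total_reads
    )


def collapse_pathways(
    matrix: AbundanceMatrix, pathway_map: Mapping[str, str]
) -> AbundanceMatrix:
    """Sum family-level values into pathway-level values.

    Families absent from ``pathway_map`` are dropped with a warning; the
    pathway value is the plain sum of its member families (so a disjoint
    partition conserves the grand total).
    """
    mapped = pd.Series(
        {f: pathway_map.get(f) for f in matrix.features}, dtype=object
    )
    unmapped = mapped.index[mapped.isna()].tolist()
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} families without a pathway were dropped: "
            f"{unmapped[:5]}{'...' if len(unmapped) > 5 else ''}",
            stacklevel=2,
        )
    keep = mapped.dropna()
    data = matrix.data.loc[keep.index].groupby(keep).sum()
    data.index.name = "pathway"
    return matrix.with_data(data)


def display_transform(matrix: AbundanceMatrix, mode: str) -> AbundanceMatrix:
    """Presentation-only rescaling: ``cap1`` or ``log10p1``.

    ``cap1`` clips values at 1 (the copies-per-organism heatmap scale);
    ``log10p1`` applies log₁₀(x + 1) (the RPKM/TPM heatmap scale). The
    input matrix is untouched; value_kind is preserved because these are
    display scales, not unit changes.
    """
    values = matrix.data
    if (values.to_numpy() < 0).any():
        raise ConfigError("display transforms require non-negative values")
    if mode == "cap1":
        data = values.clip(upper=1.0)
    elif mode == "log10p1":
        data = np.log10(values + 1.0)
    else:
        raise ConfigError(f"unknown display mode {mode!r}")
    return matrix.with_data(pd.DataFrame(data, index=values.index, columns=values.columns))


def profile_sample(
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    total_reads: int,
    cfg: HitFilterConfig | None = None,
    sample: str = "sample",
) -> dict:
    """Run the full per-sample profiling chain.

    Returns a dict with keys ``filtered_hits``, ``family_rpkm``,
    ``baseline``, ``marker_rpkm`` and ``copies_per_organism``.
    """
    cfg = cfg or HitFilterConfig()
    kept = filter_hits(hits, catalog, cfg)
    fam = compute_rpkm(kept, catalog, total_reads, collapse="family", sample=sample)
    baseline, per_family = scg_baseline(kept, catalog, cfg, total_reads)
    cpo = copies_per_organism(fam, baseline)
    return {
        "filtered_hits": kept,
        "family_rpkm": fam,
        "baseline": baseline,
        "marker_rpkm": per_family,
        "copies_per_organism": cpo,
    }
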