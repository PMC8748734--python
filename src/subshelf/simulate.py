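"""Synthetic multi-omics inputs with known ground truth.

The generator emulates every table the downstream pipeline consumes, for a
community of genomes with log-normal abundances:

* a gene catalog in which every genome carries exactly one copy of each of
  the 14 universal single-copy ribosomal marker families plus
  Bernoulli-carried metabolic gene families with configurable prevalence,
  copy number, length and identity-threshold class;
* read→gene alignment hit tables in which reads land on genes with
  probability proportional to genome abundance × copy number × gene length,
  a configurable fraction of reads stays unmapped, and a configurable
  fraction of emitted hits is planted below the identity / coverage /
  bitscore / read-length filters so that filtering is exercised;
* per-genome coverage tables (multiplicative noise around abundance) and
  per-ORF transcript counts (Poisson around abundance × activity × length),
  mirroring mapping-based quantification output;
* a two-group taxon × sample count table with planted indicator taxa of
  configurable fold change.

One random stream is derived per (table kind, sample) from the master seed,
so adding samples never perturbs earlier ones, and identical configurations
reproduce outputs bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .envdata import table1_fixture  # noqa: F401  (fixture re-exported here)
from .errors import ConfigError
from .profiling import MARKER_FAMILIES, HitFilterConfig

__all__ = [
    "FamilySpec",
    "IndicatorSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_community",
    "build_catalog",
    "sample_gene_hits",
    "orf_catalog",
    "sample_genome_tables",
    "sample_taxon_table",
    "table1_fixture",
    "DEFAULT_FAMILY_SPECS",
    "DEFAULT_PATHWAYS",
]

# stream codes: one independent generator per (table kind, sample)
_STREAM_COMMUNITY = 1
_STREAM_HITS = 2
_STREAM_GENOME = 3
_STREAM_TAXON = 4
_STREAM_ORFS = 5
_STREAM_CAZYME = 6


def _rng(seed: int, stream: int, sample_index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, sample_index]))


@dataclass(frozen=True)
class FamilySpec:
    """A metabolic gene family to plant in the community.

    ``identity_class`` selects which percent-identity threshold applies to
    the family's alignments (defaults to the family's own name, falling
    back to the generic 50% cutoff when unlisted).
    """

    name: str
    prevalence: float
    copies: int = 1
    length_bp: int = 1000
    identity_class: str | None = None


@dataclass(frozen=True)
class IndicatorSpec:
    """A taxon planted as an indicator of one group.

    ``fold`` multiplies the taxon's mean abundance inside ``group``;
    ``math.inf`` removes it entirely from other groups (a perfect
    indicator)."""

    taxon: str
    group: str
    fold: float


#: Gene families emulating curated metabolic databases (nitrification,
#: carbon fixation, oxidative phosphorylation, trace-gas oxidation ...).
DEFAULT_FAMILY_SPECS: tuple[FamilySpec, ...] = (
    FamilySpec("AmoA", prevalence=0.08, copies=1, length_bp=750),
    FamilySpec("NxrA", prevalence=0.05, copies=1, length_bp=1200),
    FamilySpec("RbcL", prevalence=0.10, copies=1, length_bp=1400),
    FamilySpec("CoxL", prevalence=0.15, copies=1, length_bp=2300),
    FamilySpec("NuoF", prevalence=0.50, copies=1, length_bp=1300),
    FamilySpec("AtpA", prevalence=0.95, copies=1, length_bp=1550),
    FamilySpec("RHO", prevalence=0.30, copies=1, length_bp=900),
    FamilySpec("HbsT", prevalence=0.05, copies=1, length_bp=1100),
    FamilySpec("PsbA", prevalence=0.02, copies=1, length_bp=1080),
    FamilySpec("SoxB", prevalence=0.12, copies=1, length_bp=1650),
    FamilySpec("NiFeHyd1", prevalence=0.15, copies=1, length_bp=1700),
    FamilySpec("PmoA", prevalence=0.03, copies=2, length_bp=820),
)

#: Default family → pathway map for pathway collapsing.
DEFAULT_PATHWAYS: dict[str, str] = {
    "AmoA": "ammonia oxidation",
    "PmoA": "methane oxidation",
    "NxrA": "nitrite oxidation",
    "RbcL": "CBB carbon fixation",
    "HbsT": "4-hydroxybutyrate cycle",
    "CoxL": "carbon monoxide oxidation",
    "NiFeHyd1": "hydrogen oxidation",
    "SoxB": "sulfur oxidation",
    "NuoF": "aerobic respiration",
    "AtpA": "aerobic respiration",
    "RHO": "rhodopsin phototrophy",
    "PsbA": "oxygenic photosynthesis",
}


def _default_groups(n_samples: int) -> dict[str, str]:
    """Triplicate basal-layer samples vs the remaining mid-column samples."""
    names = [f"s{i + 1:02d}" for i in range(n_samples)]
    split = min(3, max(1, n_samples // 3))
    return {
        name: ("basal" if i < split else "mid_column") for i, name in enumerate(names)
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community and its sampled tables."""

    n_genomes: int = 200
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    family_specs: Sequence[FamilySpec] = DEFAULT_FAMILY_SPECS
    n_reads_per_sample: int = 100_000
    n_samples: int = 9
    offtarget_fraction: float = 0.05
    unmapped_fraction: float = 0.4
    activity_mu: float = 0.0
    activity_sigma: float = 1.0
    read_length_bp: int = 150
    hit_filter: HitFilterConfig = field(default_factory=HitFilterConfig)
    # genome-resolved tables
    n_orfs_per_genome: int = 20
    rna_reads_per_sample: int = 200_000
    coverage_depth_scale: float = 1000.0
    coverage_noise_sigma: float = 0.15
    n_coverage_windows: int = 40
    # taxon table
    n_taxa: int = 150
    taxon_mu: float = 2.5
    taxon_sigma: float = 1.0
    group_assignment: Mapping[str, str] | None = None
    indicator_specs: Sequence[IndicatorSpec] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes <= 0:
            raise ConfigError("n_genomes must be a positive integer")
        if self.n_reads_per_sample < 0:
            raise ConfigError("n_reads_per_sample must be non-negative")
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if not 0 <= self.offtarget_fraction < 1:
            raise ConfigError("offtarget_fraction must lie in [0, 1)")
        if not 0 <= self.unmapped_fraction < 1:
            raise ConfigError("unmapped_fraction must lie in [0, 1)")
        if self.abundance_sigma < 0 or self.activity_sigma < 0:
            raise ConfigError("abundance_sigma/activity_sigma must be >= 0")
        if self.read_length_bp <= 0:
            raise ConfigError("read_length_bp must be positive")
        if self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        for spec in self.family_specs:
            if not 0 <= spec.prevalence <= 1:
                raise ConfigError(f"family_specs[{spec.name}].prevalence outside [0, 1]")
            if spec.copies < 1:
                raise ConfigError(f"family_specs[{spec.name}].copies must be >= 1")
            if spec.length_bp <= 0:
                raise ConfigError(f"family_specs[{spec.name}].length_bp must be positive")
        if spec_names := [s.name for s in self.family_specs]:
            if len(set(spec_names)) != len(spec_names):
                raise ConfigError("duplicate family names in family_specs")
            clash = set(spec_names) & set(MARKER_FAMILIES)
            if clash:
                raise ConfigError(f"family names collide with marker families: {clash}")

    @property
    def sample_names(self) -> list[str]:
        if self.group_assignment is not None:
            return list(self.group_assignment)
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def groups(self) -> pd.Series:
        mapping = self.group_assignment or _default_groups(self.n_samples)
        return pd.Series(dict(mapping), name="group")


@dataclass
class SyntheticTruth:
    """Ground-truth community underlying every generated table.

    ``gene_copy_table`` holds per-genome copy numbers for all families
    (marker rows are identically 1); ``true_copies_per_organism`` is the
    abundance-weighted mean copy number per family — the quantity that
    single-copy-gene-normalized profiling estimates.
    """

    genome_abundances: pd.Series
    gene_copy_table: pd.DataFrame  # genomes × families
    activity: pd.Series
    config: SimulationConfig

    def __post_init__(self):
        if abs(self.genome_abundances.sum() - 1.0) > 1e-9:
            raise ConfigError("genome abundances must sum to 1")
        markers = [f for f in self.gene_copy_table.columns if f in MARKER_FAMILIES]
        if (self.gene_copy_table[markers] != 1).any().any():
            raise ConfigError("single-copy marker rows must be exactly 1")

    @property
    def true_copies_per_organism(self) -> pd.Series:
        """Σ_g abundance(g) · copies(g, family), per family."""
        return self.gene_copy_table.mul(self.genome_abundances, axis=0).sum(axis=0)


def simulate_community(config: SimulationConfig) -> SyntheticTruth:
    """Draw the ground-truth community for a configuration.

    Abundances are log-normal then normalized to sum to 1; family carriage
    is Bernoulli(prevalence) per genome with the configured copy number;
    every genome carries one copy of each marker family; transcription
    activity multipliers are log-normal. Deterministic given
    ``config.seed``.
    """
    rng = _rng(config.seed, _STREAM_COMMUNITY)
    genomes = [f"g{i + 1:04d}" for i in range(config.n_genomes)]
    raw = rng.lognormal(config.abundance_mu, config.abundance_sigma, config.n_genomes)
    abund = pd.Series(raw / raw.sum(), index=genomes, name="abundance")

    copies = {fam: np.ones(config.n_genomes, dtype=np.int64) for fam in MARKER_FAMILIES}
    for spec in config.family_specs:
        carrier = rng.random(config.n_genomes) < spec.prevalence
        copies[spec.name] = np.where(carrier, spec.copies, 0).astype(np.int64)
    copy_table = pd.DataFrame(copies, index=genomes)

    activity = pd.Series(
        rng.lognormal(config.activity_mu, config.activity_sigma, config.n_genomes),
        index=genomes,
        name="activity",
    )
    return SyntheticTruth(
        genome_abundances=abund,
        gene_copy_table=copy_table,
        activity=activity,
        config=config,
    )


def build_catalog(truth: SyntheticTruth) -> pd.DataFrame:
    """Gene catalog implied by the truth table (deterministic, no RNG).

    Each (genome, family) pair with copy number *c* yields *c* distinct
    gene entries; marker genes carry their conventional lengths.
    """
    config = truth.config
    lengths = dict(MARKER_FAMILIES)
    classes: dict[str, str | None] = {fam: None for fam in MARKER_FAMILIES}
    pathways: dict[str, str | None] = {fam: None for fam in MARKER_FAMILIES}
    for spec in config.family_specs:
        lengths[spec.name] = spec.length_bp
        classes[spec.name] = spec.identity_class
        pathways[spec.name] = DEFAULT_PATHWAYS.get(spec.name)

    records = []
    copy_values = truth.gene_copy_table
    for genome in copy_values.index:
        row = copy_values.loc[genome]
        for family, c in row.items():
            for k in range(int(c)):
                records.append(
                    (
                        f"{genome}_{family}_{k + 1}",
                        family,
                        lengths[family],
                        genome,
                        pathways[family],
                        family in MARKER_FAMILIES,
                        classes[family],
                    )
                )
    catalog = pd.DataFrame.from_records(
        records,
        columns=["gene_id", "family", "length_bp", "genome_id", "pathway",
                 "is_single_copy_marker", "identity_class"],
    ).set_index("gene_id")
    return catalog


def sample_gene_hits(
    truth: SyntheticTruth, config: SimulationConfig, sample_index: int
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Emit one sample's read→gene hit table plus the gene catalog.

    Reads land on genes with probability ∝ abundance × copies × length; a
    configured fraction of the library stays unmapped (emits no hit); of
    the emitted hits, ``offtarget_fraction`` are planted below one of the
    retention thresholds, chosen uniformly among percent identity, query
    coverage, read length and — for marker genes — bitscore, so every
    filter branch is exercised. The boolean ``planted_offtarget`` column
    records the truth for filter-fidelity checks.

    Returns
    -------
    (hits, catalog, total_reads)
        ``total_reads`` is the configured library size (the RPKM
        denominator), not the number of emitted hits.
    """
    if not 0 <= sample_index < config.n_samples:
        raise IndexError(
            f"sample_index {sample_index} out of range [0, {config.n_samples})"
        )
    rng = _rng(config.seed, _STREAM_HITS, sample_index)
    catalog = build_catalog(truth)

    total_reads = config.n_reads_per_sample
    n_mapped = int(round(total_reads * (1.0 - config.unmapped_fraction)))
    if n_mapped == 0:
        hits = pd.DataFrame(
            columns=[
                "read_id", "gene_id", "percent_identity", "query_coverage",
                "bitscore", "read_length", "planted_offtarget",
            ]
        )
        return hits, catalog, total_reads

    weights = (
        catalog["genome_id"].map(truth.genome_abundances).to_numpy()
        * catalog["length_bp"].to_numpy()
    )
    probs = weights / weights.sum()
    gene_counts = rng.multinomial(n_mapped, probs)
    gene_idx = np.repeat(np.arange(len(catalog)), gene_counts)
    rng.shuffle(gene_idx)

    families = catalog["family"].to_numpy()[gene_idx]
    is_marker = catalog["is_single_copy_marker"].to_numpy()[gene_idx]
    # thresholds are what the downstream filter will apply: keyed by family
    thr_by_family = {f: config.hit_filter.identity_min(f) for f in set(families)}
    thr = np.array([thr_by_family[f] for f in families])

    cov_min = config.hit_filter.query_coverage_min
    identity = rng.uniform(thr, 100.0)
    coverage = rng.uniform(cov_min + 0.5, 100.0, len(gene_idx))
    bitscore = rng.uniform(config.hit_filter.marker_bitscore_min + 20.0, 300.0,
                           len(gene_idx))
    read_length = np.full(len(gene_idx), config.read_length_bp, dtype=np.int64)

    offtarget = rng.random(len(gene_idx)) < config.offtarget_fraction
    if offtarget.any():
        viol = rng.integers(0, 3, size=len(gene_idx))
        sel = offtarget & (viol == 0)  # identity below threshold
        identity[sel] = np.maximum(0.0, thr[sel] - 0.5 - rng.uniform(0, 20, sel.sum()))
        sel = offtarget & (viol == 1)  # coverage at/below the cutoff
        coverage[sel] = rng.uniform(max(0.0, cov_min - 40.0), cov_min, sel.sum())
        sel = offtarget & (viol == 2) & is_marker  # bitscore below the marker floor
        bitscore[sel] = rng.uniform(5.0, config.hit_filter.marker_bitscore_min - 0.5,
                                    sel.sum())
        sel = offtarget & (viol == 2) & ~is_marker  # short read
        read_length[sel] = rng.integers(
            max(1, config.hit_filter.min_read_length - 60),
            config.hit_filter.min_read_length,
            sel.sum(),
        )

    hits = pd.DataFrame(
        {
            "read_id": [f"s{sample_index}_r{i:07d}" for i in range(len(gene_idx))],
            "gene_id": catalog.index.to_numpy()[gene_idx],
            "percent_identity": identity,
            "query_coverage": coverage,
            "bitscore": bitscore,
            "read_length": read_length,
            "planted_offtarget": offtarget,
        }
    )
    return hits, catalog, total_reads


def orf_catalog(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-genome ORF catalog (id, genome, length); shared across samples.

    Drawn from its own stream of the master seed so it is identical for
    every sample of a configuration.
    """
    config = truth.config
    rng = _rng(config.seed, _STREAM_ORFS)
    records = []
    for genome in truth.genome_abundances.index:
        lengths = rng.integers(300, 3001, config.n_orfs_per_genome)
        for k, length in enumerate(lengths):
            records.append((f"{genome}_orf{k + 1:03d}", genome, int(length)))
    return pd.DataFrame.from_records(
        records, columns=["orf_id", "genome_id", "length_bp"]
    ).set_index("orf_id")


def sample_genome_tables(
    truth: SyntheticTruth, config: SimulationConfig, sample_index: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One sample's genome coverage table and per-ORF transcript counts.

    Coverage per window is ``abundance × coverage_depth_scale`` with
    multiplicative log-normal noise (σ = ``coverage_noise_sigma``; zero
    gives the exact noiseless limit). Transcript counts are Poisson with
    mean ∝ abundance × activity × ORF length, scaled so means sum to
    ``rna_reads_per_sample``.
    """
    if not 0 <= sample_index < config.n_samples:
        raise IndexError(
            f"sample_index {sample_index} out of range [0, {config.n_samples})"
        )
    rng = _rng(config.seed, _STREAM_GENOME, sample_index)
    sample = config.sample_names[sample_index]

    base = truth.genome_abundances.to_numpy() * config.coverage_depth_scale
    n_win = config.n_coverage_windows
    if config.coverage_noise_sigma > 0:
        noise = rng.lognormal(0.0, config.coverage_noise_sigma,
                              (len(base), n_win))
    else:
        noise = np.ones((len(base), n_win))
    coverage = pd.DataFrame(
        base[:, None] * noise,
        index=truth.genome_abundances.index,
        columns=[f"w{j + 1:03d}" for j in range(n_win)],
    )

    orfs = orf_catalog(truth)
    rate = (
        orfs["genome_id"].map(truth.genome_abundances)
        * orfs["genome_id"].map(truth.activity)
        * (orfs["length_bp"] / 1000.0)
    ).to_numpy()
    mean = rate / rate.sum() * config.rna_reads_per_sample
    counts = pd.DataFrame(
        {sample: rng.poisson(mean)}, index=orfs.index
    )
    return coverage, counts


def sample_cazyme_annotations(
    truth: SyntheticTruth,
    annotated_fraction: float = 0.15,
    fail_fraction: float = 0.3,
) -> pd.DataFrame:
    """dbCAN-style CAZyme annotations over the synthetic ORF catalog.

    A fraction of ORFs receives an annotation (GH families dominate, with
    GT/PL/CE/AA/CBM represented); ``fail_fraction`` of rows is planted with
    an e-value or coverage outside the stringent retention thresholds so
    that :func:`subshelf.cazymes.filter_cazyme` is exercised. Deterministic
    given the configuration seed.
    """
    config = truth.config
    rng = _rng(config.seed, _STREAM_CAZYME)
    orfs = orf_catalog(truth)
    chosen = orfs.index[rng.random(len(orfs)) < annotated_fraction]
    classes = rng.choice(
        ["GH", "GT", "PL", "CE", "AA", "CBM"],
        size=len(chosen),
        p=[0.45, 0.2, 0.08, 0.08, 0.07, 0.12],
    )
    family_num = rng.integers(1, 31, len(chosen))
    fails = rng.random(len(chosen)) < fail_fraction
    # passing rows: e-value well under 1e-15, coverage above 0.35
    log_e = rng.uniform(-60, -16, len(chosen))
    coverage = rng.uniform(0.36, 0.95, len(chosen))
    which = rng.integers(0, 2, len(chosen))
    evalue_fail = fails & (which == 0)
    coverage_fail = fails & (which == 1)
    log_e[evalue_fail] = rng.uniform(-14.8, -3, evalue_fail.sum())
    coverage[coverage_fail] = rng.uniform(0.02, 0.35, coverage_fail.sum())
    return pd.DataFrame(
        {
            "gene_id": chosen,
            "cazyme_family": [f"{c}{n}" for c, n in zip(classes, family_num)],
            "cazyme_class": classes,
            "evalue": 10.0 ** log_e,
            "coverage": coverage,
            "planted_fail": fails,
        }
    ).reset_index(drop=True)


def sample_taxon_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group taxon × sample count table with planted indicators.

    Non-indicator taxa are exchangeable across groups (Poisson around a
    taxon-specific log-normal mean); each :class:`IndicatorSpec` multiplies
    its taxon's mean by ``fold`` inside the named group (``fold = inf``
    keeps the base mean inside the group and zero outside). Bit-exact on
    rerun for a fixed configuration.
    """
    groups = config.groups
    counts_per_group = groups.value_counts()
    if config.indicator_specs and len(counts_per_group) < 2:
        raise ConfigError("indicator planting needs at least two groups")
    if config.indicator_specs and (counts_per_group < 2).any():
        raise ConfigError("each group needs at least two samples")
    rng = _rng(config.seed, _STREAM_TAXON)

    taxa = [f"t{i + 1:04d}" for i in range(config.n_taxa)]
    base_mean = rng.lognormal(config.taxon_mu, config.taxon_sigma, config.n_taxa)
    mean = pd.DataFrame(
        np.tile(base_mean[:, None], (1, len(groups))), index=taxa, columns=groups.index
    )
    for spec in config.indicator_specs:
        if spec.taxon not in mean.index:
            raise ConfigError(f"unknown indicator taxon {spec.taxon!r}")
        if spec.group not in set(groups):
            raise ConfigError(f"unknown indicator group {spec.group!r}")
        in_group = groups.index[groups == spec.group]
        out_group = groups.index[groups != spec.group]
        if math.isinf(spec.fold):
            mean.loc[spec.taxon, out_group] = 0.0
        else:
            if spec.fold <= 0:
                raise ConfigError("indicator fold change must be positive")
            mean.loc[spec.taxon, in_group] *= spec.fold
    table = pd.DataFrame(
        rng.poisson(mean.to_numpy()), index=mean.index, columns=mean.columns
    )
    table.attrs["taxonomy"] = {
        t: f"Bacteria;Phylum{(i % 8) + 1};Class{(i % 8) + 1};Order{(i % 20) + 1};"
           f"Family{(i % 40) + 1};Genus{(i % 60) + 1};Species_{t}"
        for i, t in enumerate(taxa)
    }
    return table, groups
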