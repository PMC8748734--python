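"""End-to-end report over a synthetic community.

Ties the modules into the full downstream workflow: simulate a community,
profile gene families against the single-copy-gene baseline, quantify
genome abundance (CPM) and expression (TPM), summarize CAZymes, run the
community-ecology statistics on the taxon table, and derive the
biogeochemical budget from the bundled environmental profile. Everything
is written as TSV/newick/JSON under one output directory together with a
provenance file sufficient to reproduce the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import biogeochem as bgc
from . import cazymes as cz
from . import ecology as eco
from . import genomes as gq
from . import io as sio
from . import profiling as prof
from . import simulate as sim
from .containers import AbundanceMatrix
from .envdata import table1_fixture

logger = logging.getLogger("subshelf")

__all__ = ["run_report"]


def run_report(
    config: sim.SimulationConfig,
    out_dir,
    params: bgc.BiogeochemParams | None = None,
) -> dict:
    """Run the full synthetic workflow and write a report bundle.

    Returns a dict of section name → output path (or in-memory result);
    failed sections are logged and recorded as incomplete rather than
    aborting the run.
    """
    params = params or bgc.BiogeochemParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    incomplete: list[str] = []

    truth = sim.simulate_community(config)
    sio.write_tsv(
        truth.gene_copy_table.assign(abundance=truth.genome_abundances,
                                     activity=truth.activity),
        out / "truth.tsv",
        comments={"section": "ground truth", "seed": config.seed},
    )

    # --- functional profiling across samples -------------------------------
    try:
        cpo_cols, rpkm_cols, baselines = [], [], {}
        for idx, name in enumerate(config.sample_names):
            hits, catalog, total = sim.sample_gene_hits(truth, config, idx)
            res = prof.profile_sample(
                hits, catalog, total, config.hit_filter, sample=name
            )
            cpo_cols.append(res["copies_per_organism"].data)
            rpkm_cols.append(res["family_rpkm"].data)
            baselines[name] = res["baseline"]
        cpo = AbundanceMatrix(pd.concat(cpo_cols, axis=1), "copies_per_organism")
        rpkm = AbundanceMatrix(pd.concat(rpkm_cols, axis=1), "RPKM")
        metabolic = [f for f in cpo.data.index if f in sim.DEFAULT_PATHWAYS]
        pathways = prof.collapse_pathways(
            cpo.with_data(cpo.data.loc[metabolic]), sim.DEFAULT_PATHWAYS
        )
        sio.write_matrix(rpkm, out / "family_rpkm.tsv")
        sio.write_matrix(cpo, out / "copies_per_organism.tsv")
        sio.write_matrix(
            prof.display_transform(pathways, "cap1"), out / "pathway_cpo_cap1.tsv"
        )
        results["profiling"] = {
            "copies_per_organism": out / "copies_per_organism.tsv",
            "baselines": baselines,
        }
    except Exception:
        logger.exception("functional profiling section failed")
        incomplete.append("profiling")

    # --- genome-resolved quantification -------------------------------------
    try:
        orfs = sim.orf_catalog(truth)
        tpm_cols, cpm_cols = [], []
        counts_by_sample = {}
        for idx, name in enumerate(config.sample_names):
            coverage, counts = sim.sample_genome_tables(truth, config, idx)
            counts.columns = [name]
            counts_by_sample[name] = counts
            tpm_cols.append(gq.compute_tpm(counts, orfs))
            cov_summary = gq.genome_coverage_summary(coverage)
            cpm_cols.append(gq.compute_cpm(cov_summary).rename(name))
        tpm = pd.concat(tpm_cols, axis=1)
        cpm = pd.concat(cpm_cols, axis=1)
        gtpm = gq.genome_tpm(tpm, orfs)
        ratio = gq.rna_dna_ratio(gtpm, cpm)
        sio.write_matrix(AbundanceMatrix(tpm, "TPM"), out / "orf_tpm.tsv")
        sio.write_matrix(AbundanceMatrix(cpm, "CPM"), out / "genome_cpm.tsv")
        sio.write_tsv(ratio, out / "rna_dna_ratio.tsv",
                      comments={"value_kind": "RNA/DNA ratio"})
        results["genome_quant"] = {"tpm": out / "orf_tpm.tsv", "cpm": out / "genome_cpm.tsv"}
    except Exception:
        logger.exception("genome quantification section failed")
        incomplete.append("genome_quant")

    # --- CAZyme summary ------------------------------------------------------
    try:
        ann = sim.sample_cazyme_annotations(truth)
        kept = cz.filter_cazyme(ann)
        counts_matrix = cz.class_counts(kept, orfs)
        top = cz.top_by_gh_diversity(kept, orfs, n=50)
        ctpm = cz.class_tpm(tpm[[config.sample_names[0]]], kept, orfs)
        sio.write_tsv(counts_matrix, out / "cazyme_class_counts.tsv",
                      comments={"value_kind": "distinct gene counts"})
        sio.write_tsv(ctpm, out / "cazyme_class_tpm.tsv",
                      comments={"value_kind": "TPM"})
        (out / "cazyme_top_genomes.txt").write_text("\n".join(top) + "\n")
        results["cazymes"] = {"top": top, "class_counts": out / "cazyme_class_counts.tsv"}
    except Exception:
        logger.exception("CAZyme section failed")
        incomplete.append("cazymes")

    # --- community ecology ---------------------------------------------------
    try:
        table, groups = sim.sample_taxon_table(config)
        rel = table / table.sum(axis=0)
        bc = eco.bray_curtis(table, normalize=True)
        tree = eco.upgma(bc)
        perma = eco.permanova(bc, groups, n_permutations=999, seed=config.seed)
        iv = eco.indval(table, groups, n_permutations=999, seed=config.seed)
        share = eco.signature_share(rel, iv, groups=groups)
        alpha = pd.DataFrame(
            {s: dict(zip(("observed", "chao1"), eco.chao1(table[s]))) for s in table}
        ).T
        sio.write_tsv(table.assign(), out / "taxon_counts.tsv")
        sio.write_tsv(bc, out / "bray_curtis.tsv")
        sio.write_newick(tree, out / "upgma.nwk")
        sio.write_tsv(iv, out / "indval.tsv")
        sio.write_tsv(alpha, out / "alpha_diversity.tsv")
        results["ecology"] = {
            "permanova": perma,
            "signature_mean_share": share.mean,
            "tree": out / "upgma.nwk",
        }
    except Exception:
        logger.exception("ecology section failed")
        incomplete.append("ecology")

    # --- biogeochemical budget ----------------------------------------------
    try:
        env = table1_fixture()
        budget = bgc.derive_budget(env, params)
        sio.write_tsv(budget, out / "budget.tsv",
                      comments={"units": "umol C m-3 (biomass); d (turnover); "
                                         "umol C m-3 d-1 (demand)"})
        results["budget"] = budget
    except Exception:
        logger.exception("budget section failed")
        incomplete.append("budget")

    sio.write_provenance(
        out / "provenance.json",
        config=config,
        biogeochem_params=params,
        incomplete_sections=incomplete,
    )
    results["incomplete"] = incomplete
    return results
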