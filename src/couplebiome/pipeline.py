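"""One-command orchestration: simulate -> QC -> classify -> diversity ->
partner tests -> correlations, with per-stage seeding and a manifest
that reconciles read counts across stages.

Every stage writes its outputs as plain TSV/FASTA/Newick under the
configured output directory; the manifest (JSON) records the config,
per-stage seeds, and input/output counts so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cbio
from .alpha import TreeIndex, alpha_summary, default_rarefaction_depth, group_compare
from .beta import all_pairs_unifrac, anosim, pcoa
from .couples import (
    prevalence_filter,
    spearman_couple_correlations,
    stratified_partner_analysis,
)
from .qc import QcParams, filter_cohort, write_qc_report
from .seeding import derive_rng, derive_seed
from .simulate import GeneratorConfig, simulate_cohort
from .taxonomy import assign_all, map_taxa_to_tips, train_kmer_model
from .types import metadata_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Aggregated thresholds and paths for one end-to-end run."""

    output_dir: str
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: QcParams = field(default_factory=QcParams)
    min_identity: float = 97.0
    min_confidence: float = 0.80
    n_bootstrap: int = 100
    depth_fraction: float = 0.9
    n_subsamples: int = 10
    n_permutations: int = 999
    master_seed: int = 0


@dataclass
class RunManifest:
    config: dict
    stage_seeds: dict[str, int]
    counts: dict[str, int]
    version: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "stage_seeds": self.stage_seeds,
                    "counts": self.counts,
                    "version": self.version,
                },
                fh,
                indent=2,
                default=str,
            )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on a synthetic cohort and write all outputs.

    Raises from the failing stage with its name; identical configs give
    byte-identical outputs.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: derive_seed(config.master_seed, stage)
        for stage in ("simulate", "classify", "alpha", "beta", "anosim")
    }
    counts: dict[str, int] = {}

    logger.info("stage=simulate seed=%d", seeds["simulate"])
    gen = GeneratorConfig(**{**asdict(config.generator), "seed": seeds["simulate"]})
    specimens, truth = simulate_cohort(gen)
    counts["specimens"] = len(specimens)
    counts["reads_simulated"] = sum(len(s.reads) for s in specimens)
    cbio.write_metadata(specimens, out / "metadata.tsv")
    truth.reference.write(out / "reference.fasta", out / "reference_taxonomy.tsv")
    cbio.write_newick(truth.tree, out / "tree.nwk")

    logger.info("stage=qc")
    filtered, report = filter_cohort(specimens, config.qc)
    write_qc_report(report, out / "qc_report.tsv")
    totals = report.totals()
    counts["reads_kept"] = totals.reads_kept
    counts["reads_rejected"] = totals.reads_in - totals.reads_kept
    if totals.reads_in != counts["reads_simulated"]:
        raise RuntimeError("stage=qc: accounting failure")

    logger.info("stage=classify seed=%d", seeds["classify"])
    model = train_kmer_model(truth.reference)
    rng = derive_rng(config.master_seed, "classify")
    assignments, table, excluded = assign_all(
        filtered,
        truth.reference,
        model,
        rng,
        min_identity=config.min_identity,
        min_confidence=config.min_confidence,
        n_bootstrap=config.n_bootstrap,
    )
    counts["reads_classified"] = int(table.depths().sum())
    counts["reads_excluded"] = sum(excluded.values())
    if counts["reads_classified"] + counts["reads_excluded"] != counts["reads_kept"]:
        raise RuntimeError("stage=classify: accounting failure")
    cbio.write_otu_table(table, out / "otu_table.tsv")
    rows = [
        {"specimen_id": sid, "read_id": a.read_id, "tier": a.tier,
         "label": a.label or "", "score": a.score}
        for sid, specimen_assignments in assignments.items()
        for a in specimen_assignments
    ]
    pd.DataFrame(rows).to_csv(out / "assignments.tsv", sep="\t", index=False)

    tip_table = map_taxa_to_tips(table, truth.reference)
    index = TreeIndex(truth.tree)
    meta = metadata_frame(filtered)

    logger.info("stage=alpha seed=%d", seeds["alpha"])
    depth = default_rarefaction_depth(tip_table, config.depth_fraction)
    alpha = alpha_summary(
        tip_table, index, depth, config.n_subsamples,
        derive_rng(config.master_seed, "alpha"),
    )
    adf = pd.DataFrame([a.__dict__ for a in alpha])
    adf.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    tests = []
    vag = meta[meta["site"] == "vagina"]
    group_ids = {
        g: set(vag.loc[vag["group"] == g, "specimen_id"]) for g in ("BV", "normal")
    }
    for metric in ("chao1", "observed_species", "pd_whole_tree"):
        mdf = adf[adf["metric"] == metric]
        values = {
            g: mdf.loc[mdf["specimen_id"].isin(ids), "value"].to_numpy()
            for g, ids in group_ids.items()
        }
        if min(len(v) for v in values.values()) >= 2:
            t, p = group_compare(
                values["BV"], values["normal"], "permutation",
                config.n_permutations, derive_rng(config.master_seed, f"alpha-{metric}"),
            )
            tests.append({"site": "vagina", "metric": metric, "t": t, "p": p})
    pd.DataFrame(tests).to_csv(out / "alpha_tests.tsv", sep="\t", index=False)

    logger.info("stage=beta seed=%d", seeds["beta"])
    dm = all_pairs_unifrac(
        tip_table, index, depth, derive_rng(config.master_seed, "beta")
    )
    cbio.write_distance_matrix(dm, out / "unifrac.tsv")
    ord_res = pcoa(dm)
    pd.DataFrame(
        ord_res.coordinates,
        index=ord_res.ids,
        columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    ).to_csv(out / "pcoa.tsv", sep="\t")

    logger.info("stage=anosim seed=%d", seeds["anosim"])
    anosim_rows = []
    for group in ("BV", "normal"):
        ps = meta[(meta["site"] == "penile_skin") & (meta["group"] == group)]
        labels = ps["circumcised"].map({True: "circumcised", False: "uncircumcised"})
        if labels.nunique() == 2 and labels.value_counts().min() >= 2:
            sub = dm.filter(list(ps["specimen_id"]))
            res = anosim(
                sub, labels.to_numpy(), config.n_permutations,
                derive_rng(config.master_seed, f"anosim-{group}"),
            )
            anosim_rows.append(
                {"group": group, "R": res.r, "p": res.p, "n": len(labels)}
            )
    pd.DataFrame(anosim_rows).to_csv(out / "anosim.tsv", sep="\t", index=False)

    logger.info("stage=partner-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        results = stratified_partner_analysis(dm, meta)
    pd.DataFrame([r.__dict__ for r in results]).to_csv(
        out / "partner_tests.tsv", sep="\t", index=False
    )

    logger.info("stage=otu-correlations")
    corr_rows = []
    for group in ("BV", "normal"):
        women = sorted(group_ids[group] & set(table.specimen_ids))
        if not women:
            continue
        taxa = prevalence_filter(table, women)
        for c in spearman_couple_correlations(table, meta, taxa, group):
            corr_rows.append(
                {"group": group, "taxon": c.taxon, "site_pair": c.site_pair,
                 "rho": np.nan if c.rho is None else c.rho, "n_couples": c.n_couples}
            )
    pd.DataFrame(corr_rows).to_csv(out / "otu_correlations.tsv", sep="\t", index=False)

    manifest = RunManifest(
        config={**asdict(config), "generator": asdict(config.generator)},
        stage_seeds=seeds,
        counts=counts,
        version=__version__,
    )
    manifest.write(out / "manifest.json")
    return manifest
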