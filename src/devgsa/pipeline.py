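"""End-to-end orchestration.

Runs the full analysis sequence from a config mapping: per-gene association
statistics -> set filtering -> competitive set tests with FDR -> stepwise
independent-set selection -> per-stage interaction scan with Bonferroni ->
child-vs-parent conditional tests -> trajectory clustering with cluster
enrichment -> beta contrasts.  Stage outputs are written as TSVs as they
are produced, together with a YAML run manifest sufficient to re-run
identically.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .compare import contrast_sets
from .devexpr import brain_expression_covariate, compute_rpkm, expression_scores, stage_means
from .gene_assoc import gene_analysis
from .geneset_assoc import (
    bh_fdr,
    bonferroni,
    competitive_test,
    conditional_subset_test,
    interaction_test,
    results_to_frame,
    stepwise_selection,
)
from .io import DevgsaError, filter_sets, write_manifest
from .synthetic_data import SimulationConfig, generate_dataset, paper_like_config, write_dataset
from .trajectory import cluster_enrichment, kmeans_trajectories, scale_trajectories, scree

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "maf_threshold": 0.01,
    "upstream_kb": 35.0,
    "downstream_kb": 10.0,
    "min_set_size": 100,
    "fdr_alpha": 0.05,
    "drop_alpha": 0.05,
    "kmeans_k": 4,
    "kmeans_starts": 20,
    "kmeans_max_iter": 20,
    "transform": "log2p0.5",
    "cluster_parent": None,
    "children": [],
    "forced_interaction_sets": [],
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the whole pipeline from a config mapping; return a summary dict.

    The config must contain ``seed`` and a ``simulate`` section (preset name
    plus overrides); analysis parameters default to :data:`DEFAULTS`.
    Outputs are flushed stage by stage, and the manifest is written even if
    a later stage fails.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(DEFAULTS)
    params.update({k: v for k, v in config.items() if k not in {"simulate", "seed"}})
    seed = int(config["seed"])

    sim_cfg = dict(config.get("simulate", {}))
    preset = sim_cfg.pop("preset", "paper_like")
    if preset == "paper_like":
        cfg = paper_like_config(seed, **sim_cfg)
    else:
        cfg = SimulationConfig(seed=seed, **sim_cfg)
    ds = generate_dataset(cfg)
    input_paths = write_dataset(ds, out / "inputs")

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "inputs": {k: {"path": v, "sha256": _checksum(Path(v))} for k, v in input_paths.items()},
        "counts": {},
        "notes": [],
    }
    summary: dict[str, Any] = {"outdir": str(out)}

    try:
        # -- gene-level association -----------------------------------------
        gene_results = gene_analysis(
            ds.snps, ds.panel.loci, ds.panel.ld_blocks(),
            maf_threshold=params["maf_threshold"],
            upstream_kb=params["upstream_kb"], downstream_kb=params["downstream_kb"],
        )
        genes_df = pd.DataFrame(
            [
                {"gene_id": r.gene_id, "n_snps": r.n_snps, "stat": r.stat,
                 "p": r.pvalue, "z": r.z, "method": r.method}
                for r in gene_results
            ]
        )
        genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
        gene_z = genes_df.set_index("gene_id")["z"]
        manifest["counts"]["genes_tested"] = int(len(genes_df))

        # -- covariates: brain expression from the expression data ----------
        rpkm = compute_rpkm(ds.expression_counts, ds.gene_lengths)
        covariates = brain_expression_covariate(rpkm).to_frame()
        universe = gene_z.index.intersection(covariates.index)
        manifest["counts"]["universe"] = int(len(universe))

        # -- main competitive scan + FDR ------------------------------------
        filtered = filter_sets(ds.sets, universe, min_size=params["min_set_size"])
        main_results = [
            competitive_test(gene_z, genes, covariates=covariates, set_name=name)
            for name, genes in filtered.sets.items()
        ]
        main_df = results_to_frame(main_results)
        if not main_df.empty:
            main_df["fdr"] = bh_fdr(main_df["p"])
        main_df.to_csv(out / "set_main.tsv", sep="\t", index=False)
        significant = (
            list(main_df.loc[main_df["fdr"] < params["fdr_alpha"], "set"])
            if not main_df.empty else []
        )
        manifest["counts"]["fdr_significant_sets"] = len(significant)

        # -- stepwise independent-set selection ------------------------------
        if significant:
            selected = stepwise_selection(
                {name: filtered.sets[name] for name in significant},
                gene_z, covariates=covariates, drop_alpha=params["drop_alpha"],
            )
            results_to_frame(selected).to_csv(out / "stepwise.tsv", sep="\t", index=False)
            selected_names = [r.set_name for r in selected]
        else:
            selected_names = []
            results_to_frame([]).to_csv(out / "stepwise.tsv", sep="\t", index=False)
            manifest["notes"].append("no FDR-significant sets; stepwise selection skipped")

        # -- expression scores ------------------------------------------------
        score_matrix = expression_scores(rpkm, ds.samples, transform=params["transform"])
        score_matrix.scores.rename_axis("gene_id").to_csv(out / "scores.tsv", sep="\t")
        manifest["counts"]["stages_retained"] = len(score_matrix.stages)

        # -- per-stage interaction scan --------------------------------------
        scan_sets = list(selected_names)
        family_stages_only = False
        if not scan_sets and params["forced_interaction_sets"]:
            scan_sets = [s for s in params["forced_interaction_sets"] if s in ds.sets.sets]
            family_stages_only = True
            manifest["notes"].append(
                "interaction scan forced on user-named sets; Bonferroni over stages only"
            )
        inter_rows = []
        if scan_sets:
            n_stages = len(score_matrix.stages)
            m = n_stages if family_stages_only else len(scan_sets) * n_stages
            for name in scan_sets:
                genes = ds.sets.sets[name]
                for stage in score_matrix.stages:
                    res = interaction_test(
                        gene_z, genes, score_matrix.stage_column(stage),
                        covariates=covariates, set_name=name,
                    )
                    inter_rows.append(
                        {"set": name, "stage": stage, "beta": res.beta, "se": res.se,
                         "p": res.pvalue, "degenerate": res.degenerate}
                    )
            inter_df = pd.DataFrame(inter_rows)
            inter_df["p_adj"] = bonferroni(inter_df["p"], m)
            inter_df["bonferroni_m"] = m
        else:
            inter_df = pd.DataFrame(
                columns=["set", "stage", "beta", "se", "p", "degenerate", "p_adj", "bonferroni_m"]
            )
            manifest["notes"].append("interaction scan skipped: no sets to scan")
        inter_df.to_csv(out / "interaction.tsv", sep="\t", index=False)

        # -- child-vs-parent conditional tests -------------------------------
        child_rows = []
        child_results = {}
        for spec in params["children"]:
            child, parent = spec["child"], spec["parent"]
            res = conditional_subset_test(
                ds.sets.sets[child], ds.sets.sets[parent], gene_z,
                covariates=covariates, child_name=child, parent_name=parent,
            )
            plain = competitive_test(gene_z, ds.sets.sets[child], covariates=covariates, set_name=child)
            child_results[child] = plain
            child_rows.append(
                {"child": child, "parent": parent, "n": res.n_genes_in_universe,
                 "beta": plain.beta, "p": plain.pvalue,
                 "beta_conditional": res.beta, "p_conditional": res.pvalue,
                 "degenerate": res.degenerate}
            )
        pd.DataFrame(child_rows).to_csv(out / "children_conditional.tsv", sep="\t", index=False)

        # -- trajectory clustering + cluster enrichment ----------------------
        parent_name = params["cluster_parent"]
        if parent_name:
            parent_genes = ds.sets.sets[parent_name]
            sm = stage_means(rpkm, ds.samples).loc[lambda d: d.index.isin(parent_genes)]
            tm = scale_trajectories(sm)
            scree_df = scree(tm, seed=seed, n_starts=params["kmeans_starts"],
                             max_iter=params["kmeans_max_iter"])
            scree_df.to_csv(out / "scree.tsv", sep="\t", index=False)
            assignment = kmeans_trajectories(
                tm, k=params["kmeans_k"], n_starts=params["kmeans_starts"],
                max_iter=params["kmeans_max_iter"], seed=seed,
            )
            assignment.labels.rename_axis("gene_id").to_frame().to_csv(
                out / "clusters.tsv", sep="\t"
            )
            enr = cluster_enrichment(
                assignment, parent_genes, gene_z, covariates=covariates,
                parent_name=parent_name,
            )
            enr.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
            summary["cluster_enrichment"] = enr
            summary["scree_suggestion"] = int(scree_df["suggested_k"].iloc[0])

        # -- contrasts between disjoint children ------------------------------
        contrast_rows = []
        names = [s["child"] for s in params["children"]]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                if set(ds.sets.sets[a]) & set(ds.sets.sets[b]):
                    continue
                c = contrast_sets(child_results[a], child_results[b],
                                  ds.sets.sets[a], ds.sets.sets[b], action="warn")
                contrast_rows.append(
                    {"a": a, "b": b, "beta_a": c.beta_a, "beta_b": c.beta_b,
                     "z": c.z, "p": c.pvalue}
                )
        pd.DataFrame(contrast_rows).to_csv(out / "contrasts.tsv", sep="\t", index=False)

        summary.update(
            {
                "gene_results": genes_df,
                "set_main": main_df,
                "selected_sets": selected_names,
                "interaction": inter_df,
                "children": pd.DataFrame(child_rows),
            }
        )
        manifest["counts"]["selected_sets"] = len(selected_names)
    finally:
        write_manifest(out / "run_manifest.yaml", manifest)
    return summary
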