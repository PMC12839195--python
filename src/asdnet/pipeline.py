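"""End-to-end orchestration of the analysis on synthetic or user data.

Stages run in the method's order: network construction, topology and hub
classification, dynamic perturbation propagation, hypergraph assembly and
communities, embedding/clustering with hub-independent validation,
enrichment, and target prioritization.  A single global seed fans out to
per-stage seeds through fixed offsets so stages can be rerun in isolation;
identical configuration and seed give identical output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import embed as emb
from . import hypergraph as hgm
from . import mldpp as mp
from . import network_io as nio
from . import prioritize as pri
from . import stats as st
from . import synthetic as syn
from . import topology as topo

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PRESETS"]

_STAGE_OFFSETS = {
    "synthetic": 0, "topology": 101, "mldpp": 202, "hypergraph": 303,
    "embed": 404, "enrich": 505, "prioritize": 606,
}


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    edges_path: str | None = None
    genes_path: str | None = None
    expression_path: str | None = None
    gene_sets_path: str | None = None
    confidence_threshold: float = 0.7
    hub_percentile: float = 80.0
    coexpression_r: float = 0.7
    mldpp: mp.MLDPPConfig = field(default_factory=mp.MLDPPConfig)
    train: emb.TrainConfig = field(default_factory=emb.TrainConfig)
    contrastive: emb.ContrastiveConfig = field(default_factory=emb.ContrastiveConfig)
    k_clusters: int = 5
    priority_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)
    n_expression_samples: int = 60
    robustness_n_iter: int = 20
    n_random_graphs: int = 5
    n_perm: int = 500
    top_n: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["frac_category"] = dict(d["synthetic"]["frac_category"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            s = dict(d["synthetic"])
            for key in ("conf_range", "module_size_range", "pathway_size_range"):
                if key in s:
                    s[key] = tuple(s[key])
            d["synthetic"] = syn.SyntheticConfig(**s)
        if "mldpp" in d and isinstance(d["mldpp"], dict):
            d["mldpp"] = mp.MLDPPConfig(**d["mldpp"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = emb.TrainConfig(**d["train"])
        if "contrastive" in d and isinstance(d["contrastive"], dict):
            d["contrastive"] = emb.ContrastiveConfig(**d["contrastive"])
        if "priority_weights" in d:
            d["priority_weights"] = tuple(d["priority_weights"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _STAGE_OFFSETS[stage]) % (2**31 - 1)


PRESETS = {
    "desk": lambda seed: PipelineConfig(
        synthetic=syn.SyntheticConfig(n_genes=300, n_pathways=30, seed=seed),
        train=emb.TrainConfig(max_epochs=60, seed=seed),
        robustness_n_iter=10,
        seed=seed,
    ),
    "full-scale": lambda seed: PipelineConfig(
        synthetic=syn.SyntheticConfig(seed=seed),
        train=emb.TrainConfig(seed=seed),
        seed=seed,
    ),
}


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages and write artifacts plus a summary JSON.

    Returns the summary dictionary.  A stage failure raises RuntimeError
    naming the stage; artifacts written by earlier stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
    }
    stage = "inputs"
    try:
        # ------------------------------------------------------------------
        stage = "network"
        syn_cfg = dataclasses.replace(
            config.synthetic, seed=config.stage_seed("synthetic")
        )
        if config.edges_path:
            network = nio.read_edge_table(
                config.edges_path, config.confidence_threshold
            )
            truth = None
            gene_table = nio.read_gene_table(config.genes_path)
            expression = (
                nio.read_expression(config.expression_path)
                if config.expression_path else None
            )
            gene_sets = (
                nio.read_gene_sets(config.gene_sets_path)
                if config.gene_sets_path else None
            )
        else:
            network, truth = syn.generate_ppi_network(syn_cfg)
            gene_table = syn.generate_gene_table(network, truth, syn_cfg)
            expression = syn.generate_expression(
                truth, config.n_expression_samples, syn_cfg
            )
            gene_sets = syn.generate_pathway_sets(truth, syn_cfg)
            nio.write_edge_table(network, outdir / "edges.tsv")
            gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
            expression.to_csv(outdir / "expression.tsv", sep="\t")
            nio.write_gene_sets(gene_sets, outdir / "pathways.gmt")
        giant, comp_report = nio.giant_component(network)
        summary["network"] = {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "mean_degree": 2 * network.number_of_edges() / network.number_of_nodes(),
            "giant_fraction": comp_report.giant_fraction,
            "n_components": comp_report.n_components,
        }

        # ------------------------------------------------------------------
        stage = "topology"
        centralities = topo.centrality_profile(network)
        scores = topo.perturbation_scores(network)
        hubs = topo.classify_hubs(scores, config.hub_percentile)
        degrees = centralities["degree"].to_numpy()
        fit = topo.fit_power_law(degrees, discrete=True)
        sw = topo.small_world_stats(
            giant, n_random=config.n_random_graphs,
            seed=config.stage_seed("topology"),
        )
        robustness = topo.edge_removal_robustness(
            network, (0.1, 0.2, 0.3), n_iter=config.robustness_n_iter,
            seed=config.stage_seed("topology"), percentile=config.hub_percentile,
        )
        cv = topo.edge_cv_stability(
            network, k=5, sample_frac=0.8,
            seed=config.stage_seed("topology"), percentile=config.hub_percentile,
        )
        _write(centralities, outdir / "centralities.tsv")
        _write(robustness, outdir / "robustness.tsv")
        hub_deg = degrees[hubs.is_hub.to_numpy()]
        non_deg = degrees[~hubs.is_hub.to_numpy()]
        summary["topology"] = {
            "n_hubs": hubs.n_hubs,
            "hub_threshold": hubs.threshold_value,
            "power_law_alpha": fit.alpha,
            "power_law_r_squared": fit.r_squared,
            "clustering_coefficient": sw["C"],
            "clustering_ratio_vs_random": sw["C_ratio"],
            "path_length": sw["L"],
            "path_length_random": sw["L_random"],
            "assortativity": sw["assortativity"],
            "degree_fold_change": st.fold_change(hub_deg.mean(), non_deg.mean()),
            "robustness_mean_consistency": robustness["mean_consistency"].tolist(),
            "cv_mean_consistency": cv.attrs["mean_consistency"],
        }

        # ------------------------------------------------------------------
        stage = "mldpp"
        p0 = mp.initialize_perturbation(gene_table, hubs, network)
        traj = mp.run_mldpp(network, p0, config.mldpp)
        metrics = mp.mldpp_metrics(traj, scores)
        mdf = metrics.to_frame()
        _write(mdf, outdir / "mldpp.tsv")
        hub_mask = hubs.is_hub.reindex(mdf.index).to_numpy()
        u, pval, r_eff = st.mann_whitney(
            mdf.loc[hub_mask, "mldpp_final"], mdf.loc[~hub_mask, "mldpp_final"]
        )
        summary["mldpp"] = {
            "converged_at": traj.converged_at,
            "hub_final_mean": float(mdf.loc[hub_mask, "mldpp_final"].mean()),
            "nonhub_final_mean": float(mdf.loc[~hub_mask, "mldpp_final"].mean()),
            "final_relative_increase": st.relative_increase(
                float(mdf.loc[hub_mask, "mldpp_final"].mean()),
                float(mdf.loc[~hub_mask, "mldpp_final"].mean()),
            ),
            "hub_gain_mean": float(mdf.loc[hub_mask, "gain"].mean()),
            "nonhub_gain_mean": float(mdf.loc[~hub_mask, "gain"].mean()),
            "mannwhitney_p": pval,
            "effect_r": r_eff,
        }

        # ------------------------------------------------------------------
        stage = "hypergraph"
        sources = [hgm.clique_hyperedges(network)]
        if expression is not None:
            sources.append(
                hgm.coexpression_hyperedges(expression, config.coexpression_r)
            )
        else:
            logger.info("no expression input: co-expression hyperedges skipped")
        if gene_sets is not None:
            universe = set(network.nodes())
            curated = {
                n: s for n, s in gene_sets.sets.items()
                if gene_sets.descriptions.get(n) == "hub_enriched"
            }
            broad = {
                n: s for n, s in gene_sets.sets.items() if n not in curated
            }
            if curated:
                sources.append(
                    hgm.pathway_hyperedges(curated, universe, "autism_pathway")
                )
            if broad:
                sources.append(
                    hgm.pathway_hyperedges(broad, universe, "reactome_pathway")
                )
        hg = hgm.assemble_hypergraph(sources, network.nodes())
        communities = hgm.spectral_communities(
            hg, config.k_clusters, seed=config.stage_seed("hypergraph")
        )
        modularity = hgm.hypergraph_modularity(hg, communities)
        cohesion = hgm.module_cohesion(hg, metrics.final, hubs, network)
        counting = hgm.multiway_statistics(hg, network)
        _write(cohesion, outdir / "cohesion.tsv")
        summary["hypergraph"] = {
            "n_hyperedges": len(hg.hyperedges),
            "hyperedge_sizes_mean": float(np.mean(hg.De)),
            "modularity": modularity,
            "cohesion_max": float(cohesion["cohesion"].max()),
            "cohesion_mean": float(cohesion["cohesion"].mean()),
            **counting,
        }

        # ------------------------------------------------------------------
        stage = "embed"
        fm = emb.build_feature_matrix(
            centralities, mdf, gene_table, "topology7", static_scores=scores
        )
        hub_labels = hubs.is_hub.reindex(fm.genes).to_numpy()
        train_cfg = dataclasses.replace(
            config.train, seed=config.stage_seed("embed")
        )
        params, history = emb.train_hgnn(
            hg, fm.X, hub_labels, train_cfg, config.contrastive
        )
        embeddings = emb.hgnn_forward(hg, fm.X, params, training=False)
        assignment = pd.Series(
            emb.kmeans_clusters(
                embeddings, config.k_clusters, seed=config.stage_seed("embed")
            ),
            index=pd.Index(fm.genes, name="gene"), name="cluster",
        )
        quality = emb.cluster_quality(embeddings, assignment.to_numpy())
        coords, evr = emb.project_2d(embeddings, "pca")
        # hub-independent validation clustering on raw standardized features
        fm_val = emb.build_feature_matrix(
            centralities, None, gene_table, "hub_independent5"
        )
        val_assignment = pd.Series(
            emb.kmeans_clusters(
                fm_val.X, config.k_clusters, seed=config.stage_seed("embed") + 1
            ),
            index=pd.Index(fm_val.genes, name="gene"), name="cluster",
        )
        focus = set(metrics.final.nlargest(config.top_n).index)
        comparison = emb.compare_clusterings(
            assignment, val_assignment, focus,
            n_perm=config.n_perm, seed=config.stage_seed("embed") + 2,
        )
        pd.DataFrame(embeddings, index=fm.genes).to_csv(
            outdir / "embeddings.tsv", sep="\t"
        )
        assignment.to_csv(outdir / "clusters.tsv", sep="\t")
        summary["embed"] = {
            "best_epoch": int(history.attrs["best_epoch"]),
            "initial_train_loss": float(history["train_loss"].iloc[0]),
            "best_train_loss": float(history["train_loss"].min()),
            "loss_reduction": st.relative_increase(
                float(history["train_loss"].iloc[0]),
                float(history["train_loss"].min()),
            ) if history["train_loss"].min() > 0 else float("inf"),
            "initial_intergroup_distance": float(
                history["intergroup_distance"].iloc[0]
            ),
            "final_intergroup_distance": float(
                history["intergroup_distance"].iloc[
                    int(history.attrs["best_epoch"]) - 1
                ]
            ),
            "pca_variance_2d": float(evr.sum()),
            **quality,
            "validation_jaccard": comparison["jaccard"],
            "validation_ari": comparison["adjusted_rand"],
            "validation_perm_p": comparison["perm_p"],
        }

        # ------------------------------------------------------------------
        stage = "enrich"
        if gene_sets is not None:
            universe = set(network.nodes())
            enrichment = st.hypergeom_enrichment(
                hubs.hubs & universe, gene_sets.sets, universe
            )
            _write(enrichment, outdir / "enrichment.tsv")
            sig = enrichment[enrichment["q"] < 0.05]
            summary["enrich"] = {
                "n_sets_tested": len(enrichment),
                "n_significant_q05": int(len(sig)),
                "max_ratio": float(enrichment["ratio"].max()),
            }

        # ------------------------------------------------------------------
        stage = "prioritize"
        priority = pri.priority_scores(
            hubs, metrics, gene_table, config.priority_weights
        )
        ranked = pri.rank_targets(priority, config.top_n)
        _write(priority, outdir / "priority.tsv")
        summary["prioritize"] = {
            "n_ranked": len(priority),
            "n_excluded_missing_druggability": priority.attrs["n_excluded"],
            "top_priority": float(priority["priority"].iloc[0]),
            "top_vs_rest_p": ranked["p"],
            "top_vs_rest_effect_r": ranked["effect_r"],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
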