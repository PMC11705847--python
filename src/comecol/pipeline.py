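"""End-to-end orchestration: filter -> normalize -> diversity -> network ->
neutral model -> assembly, driven by a single serializable configuration."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assembly as asm
from . import core_io, diversity, network, neutral_model, synthetic_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    output_dir: str
    seed: int = 0
    # either real inputs ...
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    # ... or a simulation spec
    simulation: dict | None = None
    # preprocessing
    min_rel_abund: float = 5e-5
    drop_singletons: bool = True
    normalization: str = "rarefy"  # rarefy | tss | none
    rarefy_depth: int | None = None  # default: minimum sample total
    # grouping column used for group-wise statistics
    group_column: str = "group"
    # network
    rho_min: float = 0.6
    p_max: float = 0.01
    min_prevalence: float = 0.0
    # null models
    n_null: int = 999
    bootstrap_reps: int = 1000
    fast: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "rarefy", "permanova", "network", "ncm", "assembly"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


def _load_inputs(cfg: RunConfig, seeds: dict[str, int], outdir: Path):
    if cfg.simulation is not None:
        spec = dict(cfg.simulation)
        scenario = spec.pop("scenario")
        spec.setdefault("seed", seeds["simulate"])
        tree = None
        meta = None
        if scenario == "neutral":
            table, p = synthetic_data.simulate_neutral(**spec)
            n_taxa = table.n_taxa
            tree = synthetic_data.simulate_tree(len(p), seed=spec["seed"] + 1)
            half = table.n_samples // 2
            meta = core_io.SampleMetadata(
                pd.DataFrame(
                    {
                        "sample_id": table.sample_ids,
                        "group": ["g1"] * half + ["g2"] * (table.n_samples - half),
                    }
                )
            )
        elif scenario == "selection":
            n_taxa = spec.pop("n_taxa")
            tree = synthetic_data.simulate_tree(n_taxa, seed=spec["seed"] + 1)
            table, meta = synthetic_data.simulate_selection(tree, **spec)
        elif scenario == "dispersal_limited":
            table, meta = synthetic_data.simulate_dispersal_limited(**spec)
        elif scenario == "modular_network":
            table = synthetic_data.simulate_modular_network_data(**spec)
            meta = core_io.SampleMetadata(
                pd.DataFrame(
                    {
                        "sample_id": table.sample_ids,
                        "group": ["all"] * table.n_samples,
                    }
                )
            )
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
        core_io.write_otu_table(table, outdir / "simulated_table.tsv")
        if meta is not None:
            core_io.write_metadata(meta, outdir / "simulated_metadata.tsv")
        if tree is not None:
            tree.write(outdir / "simulated_tree.nwk")
        sidecar = {"scenario": scenario, **spec}
        (outdir / "simulation_params.json").write_text(json.dumps(sidecar, indent=2))
        return table, tree, meta
    if cfg.table_path is None:
        raise ValueError("config needs either input paths or a simulation spec")
    table = core_io.read_otu_table(cfg.table_path)
    tree = core_io.read_tree(cfg.tree_path) if cfg.tree_path else None
    meta = core_io.read_metadata(cfg.metadata_path) if cfg.metadata_path else None
    return table, tree, meta


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain; returns (and writes) the summary report.

    Stages degrade gracefully: without a tree the assembly stage is skipped
    with a notice; without metadata the group-wise statistics are skipped.
    Any stage failure aborts with the stage name; partial outputs stay on
    disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    n_null = 199 if config.fast else config.n_null
    reps = 200 if config.fast else config.bootstrap_reps
    log_lines = [
        f"comecol {__version__} on python {platform.python_version()}",
        f"seed={config.seed} stage_seeds={seeds}",
        f"config={json.dumps(config.to_dict())}",
    ]
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    stage = "load"
    try:
        table, tree, meta = _load_inputs(config, seeds, outdir)
        log_lines.append(f"loaded table {table.shape}")

        stage = "filter"
        table = core_io.filter_otus(
            table, min_rel_abund=config.min_rel_abund, drop_singletons=config.drop_singletons
        )
        summary["stages"]["filter"] = {"n_taxa": table.n_taxa, "n_samples": table.n_samples}

        stage = "normalize"
        if config.normalization == "rarefy":
            depth = config.rarefy_depth or int(table.sample_totals().min())
            table = core_io.rarefy(table, depth, seed=seeds["rarefy"], drop_shallow=True)
            summary["stages"]["normalize"] = {"method": "rarefy", "depth": depth}
        elif config.normalization in {"tss", "none"}:
            summary["stages"]["normalize"] = {"method": config.normalization}
        else:
            raise ValueError(f"unknown normalization {config.normalization!r}")

        groups = None
        if meta is not None and config.group_column in meta.frame.columns:
            groups = meta.groups(table, config.group_column)

        stage = "diversity"
        alpha = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "shannon": [diversity.shannon(table.counts[:, j]) for j in range(table.n_samples)],
            }
        )
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", index=False)
        dist = diversity.rclr_aitchison_dist(table)
        ord_res = diversity.pcoa(dist, k=2)
        pd.DataFrame(
            ord_res.coordinates,
            index=ord_res.sample_ids,
            columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])],
        ).to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
        div_summary = {
            "mean_shannon": float(alpha["shannon"].mean()),
            "pcoa_prop_explained": [float(x) for x in ord_res.proportion_explained],
        }
        if groups is not None and len(np.unique(groups)) >= 2:
            perm = diversity.permanova(dist, groups, n_perm=999, seed=seeds["permanova"])
            div_summary["permanova"] = {
                "pseudo_F": perm.pseudo_f,
                "R2": perm.r2,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
            }
            if len(np.unique(groups)) == 2:
                simper_df = diversity.simper(table, groups)
                simper_df.to_csv(outdir / "simper.tsv", sep="\t", index=False)
        breadth = diversity.levins_breadth(table)
        breadth.to_csv(outdir / "levins_breadth.tsv", sep="\t", index=False)
        summary["stages"]["diversity"] = div_summary

        stage = "network"
        try:
            cg = network.correlation_graph(
                table, rho_min=config.rho_min, p_max=config.p_max,
                min_prevalence=config.min_prevalence,
            )
            if cg.n_edges > 0:
                cg = network.detect_modules(cg, seed=seeds["network"])
                net_metrics, node_df = network.topology(cg)
                zipi = network.classify_roles(network.zi_pi(cg))
                node_df = node_df.merge(zipi, on="taxon")
                node_df.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
                network.write_edge_list(cg, outdir / "network_edges.tsv")
                network.write_graphml(cg, outdir / "network.graphml")
                keystones = node_df[node_df["role"] != "peripheral"]["taxon"].tolist()
                summary["stages"]["network"] = {**net_metrics, "keystones": keystones}
            else:
                summary["stages"]["network"] = {"n_nodes": cg.n_nodes, "n_edges": 0}
        except ValueError as exc:
            summary["stages"]["network"] = {"skipped": str(exc)}

        stage = "ncm"
        try:
            fit = neutral_model.fit_ncm(table)
            fit = neutral_model.ncm_bootstrap(fit=fit, table=table, reps=reps, seed=seeds["ncm"])
            partition = neutral_model.ncm_partition(fit)
            fit.to_frame().to_csv(outdir / "ncm_per_otu.tsv", sep="\t", index=False)
            summary["stages"]["ncm"] = {
                "m": fit.m,
                "N": fit.N,
                "Nm": fit.Nm,
                "R2": fit.r2,
                "ci": fit.ci,
                "partition": partition,
            }
        except ValueError as exc:
            summary["stages"]["ncm"] = {"skipped": str(exc)}

        stage = "assembly"
        if tree is None:
            summary["stages"]["assembly"] = {"skipped": "no tree provided"}
            log_lines.append("assembly skipped: no tree")
        else:
            phylo_dist = tree.cophenetic(table.taxon_ids)
            bnti_mat = asm.bnti(
                table, tree, n_null=n_null, seed=seeds["assembly"], phylo_dist=phylo_dist
            )
            rc_mat = asm.raup_crick_bray(table, n_null=n_null, seed=seeds["assembly"] + 1)
            result = asm.classify_processes(bnti_mat, rc_mat)
            result.pairs.to_csv(outdir / "assembly_pairs.tsv", sep="\t", index=False)
            asm_summary = {
                "fractions": result.fractions,
                "counts": result.counts,
                "n_excluded": result.n_excluded,
                "metadata": result.metadata,
            }
            if groups is not None:
                lookup = dict(zip(table.sample_ids, (str(g) for g in groups)))
                asm_summary["fractions_by_group"] = result.fractions_by_group(lookup)
                uniq, cnts = np.unique(groups, return_counts=True)
                if (cnts >= 3).all():
                    nst = asm.pnst(
                        table, tree, groups, n_null=n_null,
                        seed=seeds["assembly"] + 2, phylo_dist=phylo_dist,
                    )
                    asm_summary["pnst"] = nst.group_pnst
                    asm_summary["pnst_metadata"] = nst.metadata
                    if nst.comparison:
                        asm_summary["pnst_comparison"] = {
                            k: v for k, v in nst.comparison.items() if k != "posthoc"
                        }
            summary["stages"]["assembly"] = asm_summary
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log_lines.append("pipeline complete")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
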