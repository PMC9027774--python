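"""End-to-end orchestration: one config in, one run directory out.

The pipeline executes, in order: input loading (or simulation) →
normalization → β/M conversion → DMP screening → region summary → DMR
screening → soft-threshold scan → adjacency/TOM → module detection and
merging → eigengenes → GS/MM → hub selection → edge export → gene-set
over-representation. Every intermediate lands as a TSV under the run
directory together with a JSON manifest, a parameter echo, and a
deterministic log, so a fixed seed reproduces the directory bit for bit
(stage timings go to stderr only).
"""

from __future__ import annotations

import copy
import sys
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import conetwork, core_io, differential, enrichment, methylation_values, synthetic_data

__all__ = ["DEFAULT_CONFIG", "PipelineError", "load_config", "run_pipeline"]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "output_dir": "comethyl_run",
    "inputs": None,  # {sample_sheet, matrix, matrix_kind, annotation, gene_sets?}
    "simulate": None,  # SimulationConfig kwargs (seed injected from top level)
    "normalize": {"epsilon": 1e-6, "max_missing": 0.05, "skip_quantile": False},
    "differential": {"welch": False},
    "region": {"kind": "promoter"},
    "network": {
        "power": None,
        "fit_target": 0.8,
        "n_bins": 10,
        "cut_height": 0.97,
        "min_module_size": 30,
        "merge_cut": 0.15,
    },
    "hubs": {"top_n": 20, "gs_alpha": 0.05},
    "edges": {"threshold": 0.22, "weight": "tom", "modules": None},  # None → largest
    "enrichment": {"top_k": 10, "simulate_gene_sets": True},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


def load_config(source: str | Path | dict) -> dict[str, Any]:
    """Merge a user config (YAML path or dict) over the defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    config = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _stage(log: list[str], name: str):
    class _StageContext:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.append(f"stage {name}: ok")
            print(f"[comethyl] stage {name}: {elapsed:.2f}s", file=sys.stderr)
            return False

    return _StageContext()


def _validate_inputs(config: dict[str, Any]) -> None:
    inputs = config.get("inputs")
    simulate = config.get("simulate")
    if (inputs is None) == (simulate is None):
        raise PipelineError("config must provide exactly one of 'inputs' or 'simulate'")
    if inputs is not None:
        for key in ("sample_sheet", "matrix", "annotation"):
            if key not in inputs:
                raise PipelineError(f"inputs missing {key!r}")
            if not Path(inputs[key]).exists():
                raise PipelineError(f"input file not found: {inputs[key]}")
        if inputs.get("gene_sets") and not Path(inputs["gene_sets"]).exists():
            raise PipelineError(f"input file not found: {inputs['gene_sets']}")


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Run the full analysis; returns the run directory."""
    config = load_config(config)
    _validate_inputs(config)
    seed = int(config["seed"])
    run_dir = Path(out_dir if out_dir is not None else config["output_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)

    log: list[str] = [f"comethyl run, seed {seed}"]
    tables: dict[str, pd.DataFrame] = {}
    index_labels: dict[str, str] = {}
    truth = None
    gene_sets = None

    with _stage(log, "load"):
        if config["simulate"] is not None:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs["seed"] = seed
            sim_config = synthetic_data.SimulationConfig(**sim_kwargs)
            sheet, data, annotation, truth = synthetic_data.simulate_dataset(sim_config)
            log.append(
                f"simulated {len(data.probe_ids)} positions x {len(sheet.sample_ids)} samples"
            )
        else:
            inputs = config["inputs"]
            sheet, data, annotation = core_io.read_dataset(
                inputs["sample_sheet"],
                inputs["matrix"],
                inputs["annotation"],
                matrix_kind=inputs.get("matrix_kind", "beta"),
            )
            if inputs.get("gene_sets"):
                gene_sets = core_io.read_gene_sets_gmt(inputs["gene_sets"])
            log.append(
                f"loaded {len(data.probe_ids)} probes x {len(sheet.sample_ids)} samples"
            )

    norm = config["normalize"]
    with _stage(log, "normalize"):
        if isinstance(data, core_io.SignalIntensities):
            if not norm["skip_quantile"]:
                data = methylation_values.quantile_normalize_intensities(data)
                log.append("quantile-normalized intensities (both channels jointly)")
            beta = methylation_values.compute_beta(data)
        else:
            beta = data
            if not norm["skip_quantile"]:
                beta = methylation_values.quantile_normalize(beta)
                log.append("quantile-normalized beta matrix")
        beta, qc = methylation_values.qc_filter(beta, norm["max_missing"])
        log.append(f"QC dropped {qc.n_dropped} probes, imputed {len(qc.imputed)}")
        annotation = annotation.restrict(beta.probe_ids)
        m_matrix = methylation_values.beta_to_m(beta, norm["epsilon"])
        tables["beta_values"] = beta.values
        tables["m_values"] = m_matrix.values

    with _stage(log, "dmp"):
        dmp = differential.test_features(m_matrix, sheet, welch=config["differential"]["welch"])
        dmp = differential.combined_rank(dmp)
        dmp = dmp.join(differential.volcano_table(dmp)["neg_log10_p"])
        tables["dmp_stats"] = dmp
        index_labels["dmp_stats"] = "feature_id"
        log.append(f"DMP screen over {len(dmp)} positions")

    kind = config["region"]["kind"]
    with _stage(log, "regions"):
        regions = differential.summarize_regions(m_matrix, annotation, kind)
        tables[f"{kind}_m_values"] = regions.values
        index_labels[f"{kind}_m_values"] = f"{kind}_id"
        log.append(f"{len(regions.values)} {kind} regions summarized")

    with _stage(log, "dmr"):
        dmr = differential.test_features(
            regions.as_methylation_matrix(), sheet, welch=config["differential"]["welch"]
        )
        dmr = differential.combined_rank(dmr)
        dmr = dmr.join(differential.volcano_table(dmr)["neg_log10_p"])
        tables["dmr_stats"] = dmr
        index_labels["dmr_stats"] = f"{kind}_id"

    net_cfg = config["network"]
    with _stage(log, "network"):
        net = conetwork.CoMethylationNetwork(
            power=net_cfg["power"],
            fit_target=net_cfg["fit_target"],
            n_bins=net_cfg["n_bins"],
            cut_height=net_cfg["cut_height"],
            min_module_size=net_cfg["min_module_size"],
            merge_cut=net_cfg["merge_cut"],
        ).fit(regions.values.T)
        assignment = net.assignment_
        tables["soft_threshold"] = net.soft_threshold_table_
        index_labels["soft_threshold"] = "power"
        tables["module_assignment"] = assignment.labels.to_frame()
        index_labels["module_assignment"] = f"{kind}_id"
        tables["eigengenes"] = net.eigengenes_
        index_labels["eigengenes"] = "sample_id"
        log.append(f"soft power {net.power_}")
        log.append(
            "modules: "
            + ", ".join(f"{m}={s}" for m, s in assignment.sizes().items())
        )

    with _stage(log, "gs_mm"):
        gs = pd.Series(
            conetwork.gene_significance(dmr["p_value"].reindex(regions.values.index)),
            index=regions.values.index,
            name="GS",
        )
        mm_gs = net.module_membership_.copy()
        mm_gs["GS"] = gs
        mm_gs["module"] = assignment.labels
        mm_gs["k_within"] = net.k_within_
        tables["mm_gs"] = mm_gs
        index_labels["mm_gs"] = f"{kind}_id"
        tables["module_gs_summary"] = conetwork.module_gs_summary(assignment, gs)
        index_labels["module_gs_summary"] = "module"

    hub_cfg = config["hubs"]
    with _stage(log, "hubs"):
        hub_frames = [
            conetwork.select_hubs(
                net.module_membership_, gs, assignment, module,
                top_n=hub_cfg["top_n"], gs_alpha=hub_cfg["gs_alpha"],
            )
            for module in assignment.module_names
        ]
        tables["hubs"] = (
            pd.concat(hub_frames) if hub_frames else pd.DataFrame(
                columns=["module", "MM", "GS", "gs_significant", "hub_rank"]
            )
        )
        index_labels["hubs"] = f"{kind}_id"

    edge_cfg = config["edges"]
    with _stage(log, "edges"):
        weight_matrix = net.tom_ if edge_cfg["weight"] == "tom" else (
            net.adjacency_ ** (1.0 / net.power_)
        )
        edge_modules = edge_cfg["modules"] or assignment.module_names[:1]
        for module in edge_modules:
            edges = conetwork.export_edges(
                weight_matrix, assignment, module, edge_cfg["threshold"]
            )
            tables[f"edges_{module}"] = edges.set_index("feature_a")
            index_labels[f"edges_{module}"] = "feature_a"
            log.append(f"{len(edges)} edges in {module} at threshold {edge_cfg['threshold']}")

    enr_cfg = config["enrichment"]
    with _stage(log, "enrichment"):
        if gene_sets is None and truth is not None and enr_cfg.get("simulate_gene_sets"):
            gene_sets = synthetic_data.simulate_gene_sets(truth, annotation, seed=seed)
        if gene_sets is not None and assignment.module_names:
            gene_map = annotation.promoter_gene_map()
            enr = enrichment.enrich_modules(
                assignment, gene_sets, gene_map, top_k=enr_cfg["top_k"]
            )
            tables["enrichment"] = enr.set_index("module")
            index_labels["enrichment"] = "module"
            log.append(f"enrichment over {len(gene_sets)} gene sets")
        else:
            log.append("enrichment skipped: no gene sets or no modules")

    with _stage(log, "write"):
        if truth is not None:
            tables["truth_promoters"] = pd.DataFrame(
                {
                    "module": truth.promoter_module,
                    "loading": truth.loadings,
                    "delta": truth.differential,
                }
            )
            index_labels["truth_promoters"] = "promoter_id"
            tables["truth_factors"] = truth.factors
            index_labels["truth_factors"] = "sample_id"
        tables["sample_sheet"] = sheet.data
        index_labels["sample_sheet"] = "sample_id"
        core_io.write_tables(tables, run_dir, index_labels=index_labels)
        with open(run_dir / "params.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        (run_dir / "log.txt").write_text("\n".join(log) + "\n")

    return run_dir
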