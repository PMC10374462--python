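"""End-to-end pipeline orchestration on synthetic data.

Runs simulate → score → signatures → enrich → varpart → ephys-assoc in
order, writing per-stage plain-text outputs and a JSON run report. All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, enrichment, ephys, io, normalize, scoring, signatures
from . import simulate as sim
from . import varpart
from .errors import MicrocontamError

log = logging.getLogger(__name__)

STAGES = ("simulate", "score", "signatures", "enrich", "varpart", "ephys_assoc")


@dataclass
class PipelineConfig:
    """Pipeline-level settings; thresholds default to the analysis' own
    conventions (quartile groups, |log2FC| > 2.5, p < 0.01, 50 markers,
    pseudocount 1)."""

    outdir: str = "pipeline_out"
    seed: int = 0
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    marker_n: int = 50
    pseudocount: float = 1.0
    group_scheme: str = "quartile"
    fc_threshold: float = 2.5
    p_threshold: float = 0.01
    min_cells_per_type: int = 20

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": {}, "warnings": []}
    state: dict = {}

    def run_stage(name, fn):
        if not config.stages.get(name, True):
            report["stages"][name] = {"status": "skipped"}
            log.info("stage %s skipped", name)
            return
        t0 = time.perf_counter()
        try:
            summary = fn()
        except MicrocontamError as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_report(report, out)
            raise MicrocontamError(f"stage {name!r} failed: {exc}") from exc
        summary["status"] = "ok"
        summary["seconds"] = round(time.perf_counter() - t0, 2)
        report["stages"][name] = summary

    def stage_simulate():
        catalog = sim.build_gene_catalog(config.sim)
        reference = sim.simulate_reference(catalog, config.sim, config.seed)
        patchseq, truth = sim.simulate_patchseq(catalog, config.sim,
                                                config.seed + 1)
        ephys_tab = sim.simulate_ephys(truth, patchseq.obs, config.sim,
                                       config.seed + 2)
        state.update(catalog=catalog, reference=reference, patchseq=patchseq,
                     truth=truth, ephys=ephys_tab)
        io.write_counts(reference, out / "reference")
        io.write_counts(patchseq, out / "patchseq")
        io.write_ground_truth(truth, out / "ground_truth.json")
        io.write_table(ephys_tab, out / "ephys_features.tsv", seed=config.seed)
        io.write_sim_config(config.sim, out / "sim_config.yaml")
        return {"n_reference_cells": reference.n_obs,
                "n_patchseq_cells": patchseq.n_obs,
                "n_genes": patchseq.n_vars}

    def stage_score():
        reference = state["reference"]
        patchseq = normalize.filter_genes(state["patchseq"], {"mito"})
        reference_f = normalize.filter_genes(reference, {"mito"})
        panel = normalize.select_markers(reference_f, sim.MICROGLIA,
                                         n=config.marker_n, mode="off",
                                         pseudocount=config.pseudocount)
        table = scoring.score_dataset(patchseq, reference_f, panel,
                                      pseudocount=config.pseudocount)
        state.update(panel=panel, scores=table, patchseq_f=patchseq,
                     reference_f=reference_f)
        io.write_marker_panel(panel, out / "marker_panel.json")
        io.write_table(table, out / "scores.tsv", seed=config.seed)
        return {"mean_score": round(float(table["score"].mean()), 4),
                "sd_score": round(float(table["score"].std()), 4)}

    def stage_signatures():
        normed = normalize.cpm_log2(state["patchseq_f"], config.pseudocount)
        groups = signatures.define_contamination_groups(
            state["scores"]["score"], config.group_scheme)
        de = signatures.differential_expression(
            normed, groups, config.fc_threshold, config.p_threshold)
        general = signatures.general_microglia_signature(
            state["reference_f"], sim.MICROGLIA, config.sim.neuron_types,
            config.fc_threshold, config.p_threshold, config.pseudocount)
        sig = signatures.derive_signatures(de, general)
        assoc = signatures.cluster_contamination_association(
            normed, state["scores"]["score"],
            n_hvg=min(2000, normed.values.shape[0]), seed=config.seed)
        state.update(de=de, sig=sig, normed=normed)
        io.write_table(de, out / "de_table.tsv", seed=config.seed)
        io.write_signatures(sig, out / "signatures.json")
        return {"n_patchseq_signature": len(sig.patchseq_contamination),
                "n_general": len(sig.general_microglia),
                "n_distinct": len(sig.patchseq_distinct),
                "cluster_score_r2": round(assoc["r2"], 4)}

    def stage_enrich():
        universe = set(state["normed"].genes)
        gene_meta = state["patchseq_f"].var
        collection = {
            f"class:{c}": set(gene_meta.index[gene_meta["gene_class"] == c])
            for c in gene_meta["gene_class"].unique()}
        result = enrichment.hypergeometric_enrichment(
            state["sig"].patchseq_distinct, collection, universe)
        io.write_table(result.drop(columns="overlap_genes"),
                       out / "enrichment.tsv", seed=config.seed, index=False)
        top = result.iloc[0] if len(result) else None
        return {"top_set": None if top is None else str(top["set_name"]),
                "top_q": None if top is None else float(top["q"])}

    def stage_varpart():
        meta = state["patchseq"].obs.join(state["scores"]["score"])
        frame = varpart.prepare_covariates(
            meta, response="score",
            min_cells_per_type=config.min_cells_per_type)
        spec = varpart.LmmSpec(
            response="score",
            fixed=[*frame.categorical, *frame.continuous],
            random=[frame.group])
        part = varpart.partition_variance(spec, frame)
        state["varpart"] = part
        io.write_table(part.to_frame(), out / "variance_partition.tsv",
                       seed=config.seed, index=False)
        return {"r2_marginal": round(part.r2_marginal, 4),
                "r2_conditional": round(part.r2_conditional, 4),
                "donor_share": round(part.donor_share, 4)}

    def stage_ephys_assoc():
        transforms = sim.ephys_transforms(config.sim)
        std = ephys.prepare_ephys(state["ephys"], transforms)
        effects = ephys.ephys_contamination_model(
            std, state["scores"]["score"], state["patchseq"].obs)
        io.write_table(effects, out / "ephys_effects.tsv", seed=config.seed)
        return {"n_features": len(effects),
                "n_significant": int((effects["p"] < 0.05).sum())}

    run_stage("simulate", stage_simulate)
    run_stage("score", stage_score)
    run_stage("signatures", stage_signatures)
    run_stage("enrich", stage_enrich)
    run_stage("varpart", stage_varpart)
    run_stage("ephys_assoc", stage_ephys_assoc)
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
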