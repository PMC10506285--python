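"""End-to-end orchestration: simulate → preprocess → DE → GSEA → regulons →
signaling → scoring, with a reproducibility manifest.

Each stage receives a seed derived from the root seed by a fixed labeling
scheme, writes its outputs under the run directory, and registers every
file with a content hash in the manifest; re-running with the same inputs
and seed reproduces identical hashes for deterministic stages.
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

from . import __version__
from .config import PipelineConfig, stage_seed
from .dataset import GeneSetCollection, SpotDataset
from .diffexp import classify_de, nb_wald_test, pseudobulk
from .errors import SpotlinkError
from .gsea import preranked_gsea
from .io import (write_10x_triplet, write_gmt, write_lr_reference,
                 write_network, write_run_metadata)
from .preprocess import (attach_clusters, compartment_proportions,
                         filter_low_quality_spots, filter_rare_genes,
                         merge_compartments, normalize_logcpm)
from .regulon import aucell_scores, build_modules, coexpression_importance
from .scoring import compare_regions, module_score
from .signaling import run_interaction_analysis, score_network_recovery
from .synthetic import (DOMAIN_TO_COMPARTMENT, SimulationParams,
                        generate_tissue, lr_reference_from_truth,
                        truth_to_annotations)

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    config: dict
    version: str = __version__
    stages: dict[str, str] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def register(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.files[str(Path(path).relative_to(root))] = digest

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def run_pipeline(out_dir, config: PipelineConfig | None = None,
                 sim_params: SimulationParams | None = None,
                 seed: int | None = None) -> RunManifest:
    """One-command simulated end-to-end run; returns the manifest.

    Stages run in dependency order; a stage failure aborts with the stage
    named and a ``.failed`` marker next to the partial outputs.
    """
    config = config or PipelineConfig()
    config.validate()
    seed = config.rng_seed if seed is None else int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=config.to_dict())
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("de", _stage_de),
        ("gsea", _stage_gsea),
        ("regulons", _stage_regulons),
        ("signaling", _stage_signaling),
        ("score", _stage_score),
    ]
    for name, fn in stages:
        try:
            fn(out, config, sim_params, seed, state, manifest)
            manifest.stages[name] = "ok"
        except Exception:
            manifest.stages[name] = "failed"
            (out / f"{name}.failed").write_text("stage failed\n")
            manifest.write(out / "manifest.json")
            log.exception("stage %s failed", name)
            raise SpotlinkError(f"stage {name!r} failed; see logs")
    write_run_metadata(out / "run_metadata.json", config, seed)
    manifest.register(out / "run_metadata.json", out)
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(out, config, sim_params, seed, state, manifest):
    params = sim_params or SimulationParams()
    ds, truth = generate_tissue(params, seed=stage_seed(seed, "simulate"))
    state["ds_raw"], state["truth"] = ds, truth
    tissue_dir = out / "tissue"
    write_10x_triplet(ds, tissue_dir)
    ann = truth_to_annotations(truth)
    ann.to_csv(out / "annotations.tsv", sep="\t",
               index_label="barcode")
    lr = lr_reference_from_truth(truth)
    state["lr"] = lr
    write_lr_reference(lr, out / "lr_reference.tsv")
    truth_json = {
        "planted_links": [dataclasses.asdict(l) for l in truth.planted_links],
        "planted_de": truth.planted_de,
        "planted_regulons": [{"tf": r.tf, "targets": r.targets,
                              "receiver_domain": r.receiver_domain}
                             for r in truth.planted_regulons],
        "planted_signatures": {n: {"genes": g, "domain": d}
                               for n, (g, d) in
                               truth.planted_signatures.items()},
        "generator_params": truth.generator_params,
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2,
                                               sort_keys=True))
    for f in ["annotations.tsv", "lr_reference.tsv", "truth.json"]:
        manifest.register(out / f, out)
    for f in tissue_dir.iterdir():
        manifest.register(f, out)


def _stage_preprocess(out, config, sim_params, seed, state, manifest):
    ds, truth = state["ds_raw"], state["truth"]
    ds = filter_low_quality_spots(ds, config.min_counts)
    ann = truth_to_annotations(truth).loc[ds.obs.index]
    ds = attach_clusters(ds, ann)
    ds = merge_compartments(ds, DOMAIN_TO_COMPARTMENT)
    if config.gene_filter_scope == "global":
        ds = filter_rare_genes(ds, config.min_spot_fraction)
    state["ds"] = ds
    props = compartment_proportions(ds)
    props.to_csv(out / "compartment_proportions.tsv", sep="\t")
    manifest.register(out / "compartment_proportions.tsv", out)
    state["norm"] = normalize_logcpm(ds)


def _stage_de(out, config, sim_params, seed, state, manifest):
    ds = state["ds"]
    table = pseudobulk(ds, "tumor")
    res = nb_wald_test(table, config=config)
    flags, summary = classify_de(res, config)
    res.table.to_csv(out / "de_results.tsv", sep="\t")
    (out / "de_summary.json").write_text(json.dumps(summary, indent=2))
    state["de"] = res
    manifest.register(out / "de_results.tsv", out)
    manifest.register(out / "de_summary.json", out)


def _stage_gsea(out, config, sim_params, seed, state, manifest):
    truth, res = state["truth"], state["de"]
    sets = {}
    for name, (genes, _domain) in truth.planted_signatures.items():
        sets[name] = list(genes)
    up_a = [g for g, l in truth.planted_de.items() if l > 0]
    up_b = [g for g, l in truth.planted_de.items() if l < 0]
    if up_a:
        sets["PLANTED_UP_A"] = up_a
    if up_b:
        sets["PLANTED_UP_B"] = up_b
    sets = {n: g for n, g in sets.items() if g}
    if not sets:
        state["gsea"] = None
        return
    coll = GeneSetCollection(sets).restrict(list(res.table.index))
    ranking = res.table["log2fc"]
    if config.gsea_rank_metric == "signed_logp":
        ranking = np.sign(res.table["log2fc"]) * (
            -np.log10(np.maximum(res.table["pvalue"], 1e-300)))
    enr = preranked_gsea(ranking, coll, n_perm=config.gsea_permutations,
                         seed=stage_seed(seed, "gsea"))
    enr.table.to_csv(out / "gsea_results.tsv", sep="\t")
    state["gsea"] = enr
    manifest.register(out / "gsea_results.tsv", out)
    write_gmt(coll, out / "gene_sets.gmt")
    manifest.register(out / "gene_sets.gmt", out)


def _stage_regulons(out, config, sim_params, seed, state, manifest):
    ds, truth = state["ds"], state["truth"]
    norm = state["norm"]
    if not truth.tf_list:
        state["regulons"], state["activity"] = [], None
        return
    imp = coexpression_importance(norm, ds.gene_ids, truth.tf_list,
                                  seed=stage_seed(seed, "regulons"),
                                  method=config.importance_method)
    prior = {r.tf: r.targets for r in truth.planted_regulons}
    regs = build_modules(imp, config.importance_percentile,
                         config.min_module_genes, prior=prior or None,
                         percentile_scope=config.percentile_scope)
    state["regulons"] = regs
    (out / "regulons.json").write_text(json.dumps(
        [{"tf": r.tf, "targets": r.targets, "provenance": r.provenance}
         for r in regs], indent=2))
    manifest.register(out / "regulons.json", out)
    if regs:
        act = aucell_scores(norm, ds.gene_ids, regs, list(ds.obs.index),
                            config.aucell_top_fraction,
                            seed=stage_seed(seed, "aucell"))
        act.scores.to_csv(out / "activity.tsv", sep="\t")
        manifest.register(out / "activity.tsv", out)
        state["activity"] = act
    else:
        state["activity"] = None


def _stage_signaling(out, config, sim_params, seed, state, manifest):
    ds, truth = state["ds"], state["truth"]
    act, regs = state.get("activity"), state.get("regulons", [])
    if act is None or not regs:
        (out / "network_recovery.json").write_text(json.dumps(
            {"precision": None, "recall": None, "n_edges": 0}))
        manifest.register(out / "network_recovery.json", out)
        state["networks"] = {}
        return
    nets = run_interaction_analysis(ds, act, regs, state["lr"], config)
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for (sample, snd, rcv), net in nets.items():
        path = net_dir / f"{sample}__{snd}__{rcv}.tsv"
        write_network(net, path)
        manifest.register(path, out)
    precision, recall = score_network_recovery(nets, truth)
    n_edges = sum(len(n.edges) for n in nets.values())
    payload = {"precision": None if np.isnan(precision) else precision,
               "recall": None if np.isnan(recall) else recall,
               "n_edges": n_edges}
    (out / "network_recovery.json").write_text(json.dumps(payload, indent=2))
    manifest.register(out / "network_recovery.json", out)
    state["networks"] = nets


def _stage_score(out, config, sim_params, seed, state, manifest):
    ds, truth = state["ds"], state["truth"]
    norm = state["norm"]
    sigs = {n: list(g) for n, (g, _d) in truth.planted_signatures.items()
            if g}
    if not sigs:
        state["scores"] = None
        return
    coll = GeneSetCollection(sigs).restrict(list(ds.gene_ids))
    scores = module_score(norm, ds.gene_ids, coll, list(ds.obs.index))
    scores.to_csv(out / "signature_scores.tsv", sep="\t")
    manifest.register(out / "signature_scores.tsv", out)
    domains = truth.domain_map.loc[ds.obs.index]
    a = list(domains.index[domains == "tumor_B"])
    b = list(domains.index[domains == "tumor_A"])
    if len(a) >= 10 and len(b) >= 10:
        contrast = compare_regions(scores, a, b)
        contrast.to_csv(out / "region_contrast.tsv", sep="\t")
        manifest.register(out / "region_contrast.tsv", out)
        state["region_contrast"] = contrast
    state["scores"] = scores
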