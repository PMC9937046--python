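"""End-to-end orchestration: simulate/load -> filter -> ASE -> call -> estimate.

Driven by a YAML config with three sections (``seed``, ``simulate``,
``thresholds``); every stage writes its table under the output directory
and appends a structured JSON-lines entry to ``run_log.jsonl`` echoing the
thresholds in force, so a run is auditable.  Data outputs are deterministic
for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import ase as ase_mod
from . import caller as caller_mod
from . import estimate as estimate_mod
from . import io
from . import snps as snps_mod
from .simulate import SimulationConfig, simulate_cross_dataset

DEFAULT_THRESHOLDS = dict(
    min_pooled_depth=40,
    min_sample_depth=8,
    min_f1_covered=3,
    upper=0.65,
    lower=0.35,
    fpkm_min=1.0,
    xci_maternal_min=0.99,
    boundary_distance=5,
)

_TOP_KEYS = {"seed", "simulate", "thresholds"}


def load_config(source) -> dict:
    """Load and validate a pipeline config (YAML path or dict)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = cfg.get("simulate") or {}
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
    thr = dict(DEFAULT_THRESHOLDS)
    user_thr = cfg.get("thresholds") or {}
    unknown = set(user_thr) - set(thr)
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    thr.update(user_thr)
    return dict(seed=int(cfg.get("seed", 0)), simulate=sim, thresholds=thr)


def run_pipeline(config, outdir) -> dict:
    """Run the full imprinting-discovery pipeline on a simulated dataset.

    Returns a summary dict (also written to ``summary.json``) with
    per-tissue call counts, the coverage fraction and the genome-wide
    extrapolation.
    """
    cfg = load_config(config)
    thr = cfg["thresholds"]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **info):
        log_fh.write(json.dumps({"stage": stage, **info}, default=str) + "\n")

    log("config", seed=cfg["seed"], thresholds=thr, simulate=cfg["simulate"])

    # simulate ------------------------------------------------------------
    sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
    data = simulate_cross_dataset(sim_cfg)
    io.write_counts_tsv(data.counts, out / "counts.tsv")
    data.meta.to_csv(out / "samples.tsv", sep="\t", index=False)
    io.write_gff3(data.genes, data.exons, out / "genes.gff3")
    data.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    data.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    log("simulate", n_genes=sim_cfg.n_genes, n_snps=len(data.counts))

    # filter --------------------------------------------------------------
    candidates = snps_mod.discover_candidate_snps(data.counts, thr["min_pooled_depth"])
    log("discover", retained=len(candidates), removed=len(data.counts) - len(candidates))
    genotypes = snps_mod.genotype_stocks(candidates, data.meta,
                                         min_depth=thr["min_sample_depth"])
    masks = snps_mod.MaskSet.from_inputs(exons=data.exons,
                                         boundary_distance=thr["boundary_distance"])

    calls_frames, ratio_frames, covered_genes = [], [], set()
    for tissue in sim_cfg.tissues:
        tissue_meta = data.meta[data.meta["tissue"] == tissue]
        informative = snps_mod.assess_informativeness(
            genotypes, candidates, tissue_meta,
            min_f1_covered=thr["min_f1_covered"], min_depth=thr["min_sample_depth"])
        informative, mask_log = snps_mod.apply_masks(informative, masks)
        log("informative", tissue=tissue, n_informative=len(informative), **mask_log)

        ratios = ase_mod.snp_allelic_ratios(candidates, tissue_meta, informative,
                                            min_depth=thr["min_sample_depth"])
        ratios["gene_id"] = ase_mod.assign_genes(ratios, data.genes).to_numpy()
        ratio_frames.append(ratios)
        gene_ase = ase_mod.aggregate_genes(ratios, data.genes)
        covered_genes.update(gene_ase["gene_id"])
        gene_ase = ase_mod.expression_gate(gene_ase, data.expression, thr["fpkm_min"])

        caller_cfg = caller_mod.CallerConfig(upper=thr["upper"], lower=thr["lower"],
                                             xci_maternal_min=thr["xci_maternal_min"])
        calls = caller_mod.call_genes(gene_ase, caller_cfg)
        per_sample = ase_mod.per_sample_gene_fractions(ratios, data.genes)
        calls = caller_mod.flag_xci_candidates(calls, data.genes, caller_cfg,
                                               per_sample_maternal=per_sample)
        calls_frames.append(calls)
        log("call", tissue=tissue,
            **{s: int((calls["status"] == s).sum()) for s in caller_mod.STATUSES})

    all_ratios = pd.concat(ratio_frames, ignore_index=True)
    all_ratios.to_csv(out / "snp_ratios.tsv", sep="\t", index=False)
    all_calls = pd.concat(calls_frames, ignore_index=True)
    all_calls.to_csv(out / "calls.tsv", sep="\t", index=False)

    # estimate ------------------------------------------------------------
    summary = caller_mod.summarize_calls(all_calls)
    expressed = set(data.expression.loc[data.expression["fpkm"] >= thr["fpkm_min"],
                                        "gene_id"])
    covered = covered_genes & expressed
    autosomal = set(data.genes.loc[~data.genes["chrom"].isin(["chrUn", "chrX"]),
                                   "gene_id"])
    detected = set(all_calls.loc[all_calls["status"].isin(["MEG", "PEG"]),
                                 "gene_id"]) & autosomal
    if expressed and covered:
        cov = estimate_mod.coverage_fraction(covered, expressed)
        genome = estimate_mod.extrapolate_total(len(detected), cov, n_covered=len(covered))
        summary["estimate"] = dict(
            n_detected=genome.n_detected, coverage_fraction=genome.coverage_fraction,
            extrapolated_total=genome.extrapolated_total, interval=list(genome.interval))
        log("estimate", **summary["estimate"])
    else:
        summary["estimate"] = None
        log("estimate", skipped="no covered expressed genes")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log_fh.close()
    return summary
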