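"""End-to-end orchestration: simulate (or load) methylomes, bin, call
valleys, classify, annotate, quantify the KO-WT change and the TF-site
enrichment, and write a traceable report bundle.

The run is a pure function of (inputs, config, seed): the summary JSON
echoes every threshold, and re-running with the same config reproduces it
byte for byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate_enrich as ae
from . import classifier as cl
from .binning import bin_methylation
from .dmv_caller import call_dmvs, dmv_summary, dmvs_to_intervalset, write_dmvs
from .genomic_io import IntervalSet, jaccard, merge, write_bed, write_methyl_calls
from .synthetic import SimulationConfig, simulate_all

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Parameters of one pipeline run; serialized verbatim into the output
    directory so every reported number is traceable."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bin_width: int = 1000
    min_bin_coverage: int = 5
    window: int = 5000
    step: int = 1000
    max_meth: float = 0.15
    min_covered_bins_per_window: int = 3
    min_tsdmr_len: int = 2000
    min_tsdmr_cover: float = 0.5
    hyper_threshold: float = 0.1
    n_enrichment_controls: int = 200
    outdir: str = "dmvscan_run"
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", {})
        sim = {k: (tuple(v) if isinstance(v, list) else v) for k, v in sim.items()}
        return cls(simulation=SimulationConfig(**sim), **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, call, classify, annotate and report; returns the summary
    dict (also written as summary.json in the output directory)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    sim = simulate_all(config.simulation)
    truth = sim["truth"]
    calls_by_lineage = sim["calls_by_lineage"]
    features = sim["features"]
    layout = truth.layout
    lineages = list(config.simulation.lineages)
    log.info("simulated %d-bp genome with %d planted valleys", layout.total_bp, len(truth.valleys))

    from .synthetic import write_truth

    write_truth(truth, outdir / "truth")
    sim["expression"].write(outdir / "expression.fpkm.tsv", outdir / "sample_lineages.tsv")
    for lin, calls in calls_by_lineage.items():
        write_methyl_calls(calls, outdir / f"calls.{lin}.bedgraph")

    # bin and call per lineage, then merge valleys across lineages
    per_lineage_dmvs = {}
    for lin in lineages:
        track = bin_methylation(calls_by_lineage[lin], layout,
                                width=config.bin_width, min_total_coverage=config.min_bin_coverage)
        per_lineage_dmvs[lin] = call_dmvs(
            track,
            window=config.window,
            step=config.step,
            max_meth=config.max_meth,
            min_covered_bins_per_window=config.min_covered_bins_per_window,
        )
        log.info("%s: %d DMVs", lin, len(per_lineage_dmvs[lin]))
    union = merge(
        IntervalSet.from_records(
            [(d.chrom, d.start, d.end) for lin in lineages for d in per_lineage_dmvs[lin]],
            layout=layout,
        )
    )
    dmv_set = IntervalSet.from_records(
        [(rec.chrom, rec.start, rec.end, f"DMV{i + 1:05d}") for i, rec in enumerate(union)],
        layout=layout,
    )
    write_bed(dmv_set, outdir / "dmvs.bed")
    write_dmvs(per_lineage_dmvs[lineages[0]], outdir / f"dmvs.{lineages[0]}.bed",
               outdir / f"dmvs.{lineages[0]}.tsv")
    summary_lengths = dmv_summary(per_lineage_dmvs[lineages[0]])

    # classification on the union set
    meth_by_lineage = cl.lineage_methylation(list(dmv_set), calls_by_lineage, lineages)
    gene_map = cl.associate_genes(list(dmv_set), truth.tss)
    classification = cl.classify_dmvs(
        list(dmv_set),
        truth.tsdmrs,
        meth_by_lineage,
        sim["expression"],
        gene_map,
        min_tsdmr_len=config.min_tsdmr_len,
        min_cover=config.min_tsdmr_cover,
    )
    classification.write(outdir / "classification.tsv")
    group_counts = classification.counts()

    # chromatin state + super-enhancer overlap per group
    states = ae.chromatin_state(dmv_set, features["k4_peaks"], features["k27_peaks"],
                                features["eed_peaks"])
    states.to_csv(outdir / "chromatin_state.tsv", sep="\t")
    group_sets = {
        g: IntervalSet(
            dmv_set.df[dmv_set.df["name"].isin(classification.ids_in_group(g))].reset_index(drop=True),
            layout=layout,
        )
        for g in ("I", "II", "III", cl.UNASSIGNED)
    }
    se_overlap = ae.overlap_percentage(group_sets, features["super_enhancers"])
    se_overlap.to_csv(outdir / "se_overlap.tsv", sep="\t")

    # KO - WT methylation change on Polycomb (EED-overlapping) DMVs
    polycomb_ids = list(states.index[states["polycomb"]])
    polycomb_set = IntervalSet(
        dmv_set.df[dmv_set.df["name"].isin(polycomb_ids)].reset_index(drop=True), layout=layout
    )
    delta = ae.methylation_change(sim["wt"], sim["ko"], polycomb_set, truth.cgis,
                                  hyper_threshold=config.hyper_threshold)
    delta.to_csv(outdir / "delta_methylation.tsv", sep="\t")
    hyper_by_group = {}
    for g in ("I", "II", "III", cl.UNASSIGNED):
        ids = [i for i in classification.ids_in_group(g) if i in delta.index]
        hyper_by_group[g] = (
            100.0 * float(delta.loc[ids, "hypermethylated"].mean()) if ids else None
        )

    # TF-site density profile and enrichment against length-matched controls
    if len(dmv_set):
        profile = ae.site_density_profile(features["tf_sites"], dmv_set)
        profile.to_frame().to_csv(outdir / "tf_profile.tsv", sep="\t", index=False)
        observed = ae.region_site_density(features["tf_sites"], dmv_set)
        controls = ae.control_densities(
            features["tf_sites"], dmv_set, layout, config.n_enrichment_controls,
            seed=config.simulation.seed + 1,
        )
        enrich = ae.enrichment_test(observed, controls)
    else:
        pd.DataFrame(columns=["bin", "segment", "density_per_kb"]).to_csv(
            outdir / "tf_profile.tsv", sep="\t", index=False
        )
        enrich = {"p": None, "fold": None, "observed": None, "control_mean": None,
                  "n_controls": 0}

    truth_vs_called = jaccard(truth.valleys, dmv_set)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "parameters": {
            "seed": config.simulation.seed,
            "bin_width": config.bin_width,
            "min_bin_coverage": config.min_bin_coverage,
            "window": config.window,
            "step": config.step,
            "max_meth": config.max_meth,
            "min_covered_bins_per_window": config.min_covered_bins_per_window,
            "min_tsdmr_len": config.min_tsdmr_len,
            "min_tsdmr_cover": config.min_tsdmr_cover,
            "hyper_threshold": config.hyper_threshold,
            "n_enrichment_controls": config.n_enrichment_controls,
        },
        "n_planted_valleys": int(len(truth.valleys)),
        "n_called_dmvs": int(len(dmv_set)),
        "dmvs_per_lineage": {lin: len(per_lineage_dmvs[lin]) for lin in lineages},
        "dmv_length_summary": {k: (None if pd.isna(v) else float(v))
                               for k, v in summary_lengths.items()},
        "group_counts": {k: int(v) for k, v in group_counts.items()},
        "percent_hypermethylated_by_group": hyper_by_group,
        "se_overlap_percent_by_group": {
            g: (None if pd.isna(v) else float(v)) for g, v in se_overlap["percent"].items()
        },
        "tf_enrichment": {k: (float(v) if np.isfinite(v) else None) if isinstance(v, float) else v
                          for k, v in enrich.items()},
        "truth_vs_called_jaccard": float(truth_vs_called),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline finished: %d DMVs, groups %s", len(dmv_set), dict(group_counts))
    return summary
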