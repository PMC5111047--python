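"""Configuration-driven pipeline chaining the analysis stages.

A run takes a config (YAML path or dict) naming either a synthetic-data
design or real input files, plus the sample design and stage thresholds,
and writes one TSV per stage output under ``outdir`` together with a
machine-readable run log recording the thresholds and seed.  Re-running
the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, diffmeth, expression, landscape, motifs, permnull, simulate
from .calling import ConversionControl
from .design import SampleInfo, StudyDesign
from .io import (
    combine_sample_counts,
    read_annotation,
    read_cytosine_report,
    read_genome,
    write_annotation,
    write_bed,
    write_cytosine_report,
    write_genome,
    write_table,
)

ALL_STAGES = ("simulate", "call", "landscape", "diffmeth", "permtest",
              "expression", "motifs")


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


def _require_seed(cfg: dict, stage: str) -> int:
    seed = cfg.get("seed")
    if seed is None:
        raise ValueError(f"stage {stage!r} is stochastic and requires a seed")
    return int(seed)


def _design_from_config(cfg: dict) -> StudyDesign:
    entries = cfg.get("design")
    if entries is None:
        return simulate.SimulationDesign(
            seed=cfg.get("seed", 0), **cfg.get("simulate", {})
        ).methylome_design()
    samples = [
        SampleInfo(name, spec[0], spec[1], int(spec[2]))
        for name, spec in sorted(entries.items())
    ]
    return StudyDesign(samples)


def _load_inputs(cfg: dict, outdir: Path):
    """Either simulate the study or load the files the config names."""
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        design = _design_from_config(cfg)
        reports = inputs.get("reports", {})
        missing = [s for s in reports if s not in {x.name for x in design.samples}]
        if missing:
            raise ValueError(
                f"samples {missing} have report files but no design entry"
            )
        missing = [s.name for s in design.samples if s.name not in reports]
        if missing:
            raise ValueError(f"design samples {missing} lack report files")
        genome = read_genome(inputs["genome"])
        annotation = read_annotation(
            inputs["annotation"],
            promoter_len=cfg.get("promoter_len", 1000),
            genome=genome,
        )
        counts = {s: read_cytosine_report(p) for s, p in reports.items()}
        ctrl = inputs.get("control", {"unconverted": 50, "total": 10_000})
        controls = {
            s: ConversionControl(int(ctrl["unconverted"]), int(ctrl["total"]))
            for s in counts
        }
        truth = None
        sim_design = None
    else:
        seed = _require_seed(cfg, "simulate")
        sim_design = simulate.SimulationDesign(seed=seed, **cfg.get("simulate", {}))
        genome, annotation, truth = simulate.simulate_genome(sim_design)
        plant = cfg.get("motifs", {}).get("plant", [])
        if plant and len(truth["dmrs"]):
            plants = []
            for consensus in plant:
                for r in truth["dmrs"].itertuples():
                    mid = (r.start + r.end) // 2
                    plants.append((r.scaffold, mid + 10, consensus))
            genome, motif_truth = simulate.plant_motifs(genome, plants)
            truth["motifs"] = motif_truth
        counts, controls = simulate.simulate_methylomes(
            genome, annotation, truth, sim_design
        )
        design = sim_design.methylome_design()
    return genome, annotation, design, counts, controls, truth, sim_design


def run_pipeline(config, outdir=None, stages=None) -> dict:
    """Run the configured stages; returns the in-memory stage results."""
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "termeth_results"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages or cfg.get("stages", ALL_STAGES))

    genome, annotation, design, counts, controls, truth, sim_design = _load_inputs(
        cfg, outdir
    )
    results: dict = {"design": design, "truth": truth}

    if "simulate" in stages and truth is not None:
        write_genome(genome, outdir / "genome.fasta")
        write_annotation(annotation, outdir / "annotation.gff3")
        for s, df in counts.items():
            write_cytosine_report(df, outdir / f"{s}.cytosine_report.tsv")
        write_table(truth["genes"], outdir / "truth_genes.tsv")
        write_table(truth["dmrs"], outdir / "truth_dmrs.tsv")

    wide = combine_sample_counts(counts)
    call_cfg = cfg.get("call", {})
    err = calling.estimate_conversion_error(
        ConversionControl(
            sum(c.unconverted_reads for c in controls.values()),
            sum(c.total_read_cytosines for c in controls.values()),
        )
    )
    results["conversion_error"] = err
    samples = design.names
    calls = calling.call_all_samples(
        wide, samples, err,
        alpha=call_cfg.get("alpha", 0.01), min_cov=call_cfg.get("min_cov", 3),
    )
    pooled = calling.call_sites(
        calling.pool_counts(wide, samples), err,
        alpha=call_cfg.get("alpha", 0.01), min_cov=call_cfg.get("min_cov", 3),
    )
    results["calls"] = calls
    results["pooled_calls"] = pooled
    if "call" in stages:
        per_sample = pd.concat(calls.values(), ignore_index=True)
        write_table(per_sample, outdir / "calls_per_sample.tsv")
        write_table(pooled, outdir / "calls_pooled.tsv")

    if "landscape" in stages:
        profile = landscape.metagene_profile(pooled, annotation.genes)
        write_table(profile, outdir / "metagene_profile.tsv")
        feats = [(g.id, g.scaffold, g.exons) for g in annotation.genes]
        gene_meth = calling.feature_methylation(
            calling.pool_counts(wide, samples), feats
        )
        write_table(gene_meth, outdir / "gene_methylation.tsv")
        dist = landscape.nearest_gene_distance(annotation.genes)
        write_table(dist.rename_axis("gene").reset_index(),
                    outdir / "nearest_gene_distance.tsv")
        results["gene_methylation"] = gene_meth

    dm_cfg = cfg.get("diffmeth", {})
    width = dm_cfg.get("width", 200)
    wcounts = diffmeth.window_counts(wide, samples, width=width)
    dm_results = {}
    for comparison in ("caste", "sex"):
        side_a, side_b = design.sides(comparison)
        testable = diffmeth.filter_testable(
            wcounts, calls, side_a, side_b,
            min_reads=dm_cfg.get("min_reads", 5), width=width,
        )
        res = diffmeth.test_windows(
            testable, side_a, side_b,
            q_thresh=dm_cfg.get("q_thresh", 0.05),
            diff_thresh=dm_cfg.get("diff_thresh", 0.15),
            label_a="alate" if comparison == "caste" else "male",
            label_b="worker" if comparison == "caste" else "female",
            width=width,
        )
        dmrs, dmgs = diffmeth.merge_and_assign(res, annotation)
        dm_results[comparison] = {
            "windows": res, "dmrs": dmrs, "dmgs": dmgs, "testable": testable,
        }
        if "diffmeth" in stages:
            write_table(res, outdir / f"dm_windows_{comparison}.tsv")
            write_table(dmrs, outdir / f"dmrs_{comparison}.tsv")
            write_table(dmgs, outdir / f"dmgs_{comparison}.tsv")
            write_bed(
                dmrs[["scaffold", "start", "end", "direction"]].itertuples(index=False),
                outdir / f"dmrs_{comparison}.bed",
            )
    results["diffmeth"] = dm_results

    if "permtest" in stages:
        seed = _require_seed(cfg, "permtest")
        pt_cfg = cfg.get("permtest", {})
        n_perms = pt_cfg.get("n_perms", 100)
        test = pt_cfg.get("test", "ttest")
        perm_out = {}
        for comparison in ("caste", "sex"):
            side_a, side_b = design.sides(comparison)
            testable = dm_results[comparison]["testable"]
            schemes = permnull.shuffle_replicates(
                samples, side_a, n_perms, seed + (0 if comparison == "caste" else 1),
                with_replacement=(test == "ttest"),
            )
            if test == "ttest":
                observed = permnull.ttest_window_significance(testable, side_a, side_b)
            else:
                observed = int(dm_results[comparison]["windows"]["significant"].sum())
            null = permnull.permuted_dmr_counts(testable, schemes, samples, test=test)
            summary = permnull.empirical_excess(observed, null)
            perm_out[comparison] = summary
            write_table(
                pd.DataFrame({"scheme": range(len(null)), "n_significant": null}),
                outdir / f"permnull_{comparison}.tsv",
            )
        write_table(
            pd.DataFrame(perm_out).T.rename_axis("comparison").reset_index(),
            outdir / "permnull_summary.tsv",
        )
        results["permtest"] = perm_out

    if "expression" in stages and sim_design is not None:
        expr = simulate.simulate_expression(truth, sim_design)
        tdesign = sim_design.transcriptome_design()
        mat = expression.fpkm(expr["sense"], expr["lengths"])
        summaries = expression.expression_summaries(mat, tdesign)
        anti = expression.antisense_flags(expr["sense"], expr["antisense"], tdesign)
        write_table(summaries.rename_axis("gene").reset_index(),
                    outdir / "expression_summaries.tsv")
        write_table(anti.reset_index(), outdir / "antisense.tsv")
        results["expression"] = {"fpkm": mat, "summaries": summaries,
                                 "antisense": anti}

    if "motifs" in stages:
        mo_cfg = cfg.get("motifs", {})
        # single-CpG (DMC) mode: every dyad is its own window
        site_counts = wide.copy()
        site_counts["start"] = site_counts["pos"]
        site_counts["end"] = site_counts["pos"] + 1
        site_counts["n_cpg"] = 1
        side_a, side_b = design.sides("caste")
        testable_sites = diffmeth.filter_testable(
            site_counts, calls, side_a, side_b, width=1
        )
        res = diffmeth.test_windows(
            testable_sites, side_a, side_b, label_a="alate", label_b="worker",
            width=mo_cfg.get("disp_width", 200),
        )
        dmcs = diffmeth.confident_dmcs(res)
        frac = pooled.set_index(["scaffold", "pos"])["fraction"]
        non = res[~((res["q"] < 0.01) & (res["diff"].abs() > 0.20))].copy()
        key = pd.MultiIndex.from_frame(non[["scaffold", "start"]].rename(
            columns={"start": "pos"}))
        non["fraction"] = frac.reindex(key).to_numpy()
        non_dmcs = non[non["fraction"] > mo_cfg.get("min_control_meth", 0.30)]
        test_set, control_set = motifs.build_sequence_sets(
            dmcs.rename(columns={"start": "pos"}),
            non_dmcs.rename(columns={"start": "pos"}),
            genome,
            width=mo_cfg.get("width", 150),
            max_dist=mo_cfg.get("max_dist", 1500),
        )
        motif_models = [
            motifs.pwm_from_consensus(c) for c in mo_cfg.get("plant", [])
        ]
        enr = pd.DataFrame()
        if motif_models and len(test_set) and len(control_set):
            enr = motifs.enrich_motifs(
                dict(zip(test_set.index.astype(str), test_set["seq"])),
                dict(zip(control_set.index.astype(str), control_set["seq"])),
                motif_models,
            )
        write_table(test_set.drop(columns="seq"), outdir / "dmc_test_set.tsv")
        write_table(control_set.drop(columns="seq"), outdir / "dmc_control_set.tsv")
        write_table(enr, outdir / "motif_enrichment.tsv")
        results["motifs"] = {"test_set": test_set, "control_set": control_set,
                             "enrichment": enr, "dmcs": dmcs}

    log = {
        "seed": cfg.get("seed"),
        "stages": list(stages),
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "n_samples": len(design.samples),
        "conversion_error": float(err),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    results["outdir"] = outdir
    return results
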