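"""Pipeline orchestration: run the analysis stages under a single YAML
config and write TSV report artifacts plus a run manifest.

Stages (each toggleable): synth (generate all inputs with known ground
truth), physiology, fluxes, metabolome, fpkm, reporter, tf_venn.  Reports
mirror the study's tables: a physiology summary per profile, a flux table
(reaction, net flux), metabolome significance counts and pathway tables,
log2 FPKM per condition, a reporter feature matrix and TF-family Venn
counts.  Re-running with the same config and seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import synth
from .fluxfit import FitConfig, MeasurementSet, fit_fluxes
from .network import network_from_json, network_to_json
from .omics import (MetaboliteAbundanceTable, compute_fpkm,
                    differential_metabolome, log2_expression_compare,
                    summarize_significance)
from .orthotf import TFCatalog, parse_groups, tf_family_venn
from .physiology import FermentationProfile, physio_summary
from .reporter import REPORTER_CUTOFFS, ReporterGraph, directional_scores, reporter_scores

__all__ = ["default_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def default_config() -> dict:
    """Bundled synthetic demo configuration (all stages on)."""
    return {
        "output_dir": "crabtree_out",
        "seed": 17,
        "stages": {"synth": True, "physiology": True, "fluxes": True,
                   "metabolome": True, "fpkm": True, "reporter": True,
                   "tf_venn": True},
        "thresholds": {"reporter_go": REPORTER_CUTOFFS["go_term"],
                       "reporter_metabolite": REPORTER_CUTOFFS["metabolite"],
                       "significance": [0.05, 0.1]},
        "synth": {
            "batch": {"mu": 0.47, "X0": 0.05, "S0": 20.0,
                      "yields": {"Ysx": 0.55, "YsEtOH": 0.003,
                                 "YsAc": 0.001, "YsPyr": 0.004}},
            "chemostat": {"D": 0.1, "S_in": 10.0, "yields": {"Ysx": 0.55}},
            "flux_scenario": "positive_chemostat",
            "sfl_noise_sd": 0.0,
            "metabolome": {"n_per_group": 6, "cv": 0.3},
            "counts": {"n_genes": 120, "dispersion": 0.05},
            "reporter": {"n_genes": 150, "n_features": 25, "n_hot": 2},
        },
        "fluxes": {"multistart": 2, "max_nfev": 150, "n_polish": 1,
                   "polish_nfev": 60},
        "inputs": {},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _input_path(cfg: dict, outdir: Path, key: str, default_name: str) -> Path:
    explicit = cfg.get("inputs", {}).get(key)
    return Path(explicit) if explicit else outdir / "inputs" / default_name

REQUIRED_INPUTS = {
    "physiology": ["batch_profile", "chemostat_profile"],
    "fluxes": ["network", "sfl", "rates"],
    "metabolome": ["metabolome"],
    "fpkm": ["counts"],
    "reporter": ["reporter_edges", "reporter_kinds", "gene_pvalues"],
    "tf_venn": ["groups", "tf_list_a", "tf_list_b"],
}

DEFAULT_NAMES = {
    "batch_profile": "batch_profile.csv",
    "chemostat_profile": "chemostat_profile.csv",
    "network": "network.json",
    "sfl": "sfl.tsv",
    "rates": "rates.tsv",
    "metabolome": "metabolome.tsv",
    "metabolome_groups": "metabolome_groups.tsv",
    "counts": "counts.tsv",
    "reporter_edges": "reporter_edges.tsv",
    "reporter_kinds": "reporter_kinds.tsv",
    "gene_pvalues": "gene_pvalues.tsv",
    "groups": "groups.txt",
    "tf_list_a": "tf_sc.txt",
    "tf_list_b": "tf_ps.txt",
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (also written to the output directory).
    Missing inputs are reported before any stage runs; a stage failure
    keeps earlier outputs and raises.
    """
    if not isinstance(config, dict):
        config_text = Path(config).read_text()
        config = yaml.safe_load(config_text)
    else:
        config_text = yaml.safe_dump(config, sort_keys=True)
    stages = config.get("stages", {})
    outdir = Path(config.get("output_dir", "crabtree_out"))
    seed = int(config.get("seed", 17))
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    (outdir / "reports").mkdir(parents=True, exist_ok=True)

    # pre-flight: every enabled stage must find its inputs (from an earlier
    # synth stage or from explicit paths) before anything runs
    if not stages.get("synth"):
        missing = []
        for stage, keys in REQUIRED_INPUTS.items():
            if not stages.get(stage):
                continue
            for key in keys:
                p = _input_path(config, outdir, key, DEFAULT_NAMES[key])
                if not p.exists():
                    missing.append(f"{stage}: {p}")
        if missing:
            raise PipelineError("missing inputs:\n  " + "\n  ".join(missing))

    manifest: dict[str, Any] = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "stages": {},
        "inputs": {},
        "versions": {"crabtree": __import__("crabtree").__version__,
                     "pandas": pd.__version__},
    }

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        }

    if stages.get("synth"):
        t0 = time.time()
        scfg = config.get("synth", {})
        bp = synth.make_batch_profile(seed=seed, **{k: v for k, v in
                                                    scfg.get("batch", {}).items()})
        bp.to_csv(outdir / "inputs" / DEFAULT_NAMES["batch_profile"])
        cp = synth.make_chemostat_profile(seed=seed, **{k: v for k, v in
                                                        scfg.get("chemostat", {}).items()})
        cp.to_csv(outdir / "inputs" / DEFAULT_NAMES["chemostat_profile"])
        net, truth = synth.reference_flux_scenario(scfg.get("flux_scenario",
                                                            "positive_chemostat"))
        network_to_json(net, outdir / "inputs" / DEFAULT_NAMES["network"])
        meas = synth.make_sfl_dataset(net, truth,
                                      noise_sd=scfg.get("sfl_noise_sd", 0.0),
                                      seed=seed)
        meas.sfl.to_csv(outdir / "inputs" / DEFAULT_NAMES["sfl"], sep="\t", index=False)
        meas.rates.to_csv(outdir / "inputs" / DEFAULT_NAMES["rates"], sep="\t", index=False)
        pd.DataFrame({"reaction": list(truth.net),
                      "net_flux": [truth.net[r] for r in truth.net]}).to_csv(
            outdir / "inputs" / "planted_fluxes.tsv", sep="\t", index=False)
        table = synth.make_metabolome(seed=seed, **scfg.get("metabolome", {}))
        table.frame.to_csv(outdir / "inputs" / DEFAULT_NAMES["metabolome"], sep="\t")
        pd.DataFrame(sorted(table.groups.items()),
                     columns=["sample", "group"]).to_csv(
            outdir / "inputs" / DEFAULT_NAMES["metabolome_groups"], sep="\t", index=False)
        counts = synth.make_counts(seed=seed, **scfg.get("counts", {}))
        counts.to_csv(outdir / "inputs" / DEFAULT_NAMES["counts"], sep="\t", index=False)
        graph, gene_table = synth.make_reporter_graph(seed=seed,
                                                      **scfg.get("reporter", {}))
        pd.DataFrame(graph.edges, columns=["gene_id", "feature_id"]).to_csv(
            outdir / "inputs" / DEFAULT_NAMES["reporter_edges"], sep="\t", index=False)
        pd.DataFrame(sorted(graph.feature_kinds.items()),
                     columns=["feature_id", "kind"]).to_csv(
            outdir / "inputs" / DEFAULT_NAMES["reporter_kinds"], sep="\t", index=False)
        gene_table.to_csv(outdir / "inputs" / DEFAULT_NAMES["gene_pvalues"], sep="\t")
        _write_demo_orthologs(outdir / "inputs")
        record("synth", t0, sorted((outdir / "inputs").glob("*")))

    for key in DEFAULT_NAMES:
        p = _input_path(config, outdir, key, DEFAULT_NAMES[key])
        if p.exists():
            manifest["inputs"][key] = _sha256(p)

    if stages.get("physiology"):
        t0 = time.time()
        outputs = []
        for key, label in (("batch_profile", "batch"), ("chemostat_profile", "chemostat")):
            p = _input_path(config, outdir, key, DEFAULT_NAMES[key])
            prof = FermentationProfile.from_csv(p)
            summ = physio_summary(prof)
            out = outdir / "reports" / f"physiology_{label}.tsv"
            summ.to_frame().to_csv(out, sep="\t", index=False)
            outputs.append(out)
        record("physiology", t0, outputs)

    if stages.get("fluxes"):
        t0 = time.time()
        net = network_from_json(_input_path(config, outdir, "network",
                                            DEFAULT_NAMES["network"]))
        sfl = pd.read_csv(_input_path(config, outdir, "sfl", DEFAULT_NAMES["sfl"]), sep="\t")
        rates = pd.read_csv(_input_path(config, outdir, "rates", DEFAULT_NAMES["rates"]), sep="\t")
        fcfg = config.get("fluxes", {})
        fit = fit_fluxes(net, MeasurementSet(sfl, rates),
                         FitConfig(seed=seed, **{k: v for k, v in fcfg.items()
                                                 if k in ("multistart", "max_nfev",
                                                          "n_polish", "polish_nfev")}))
        out = outdir / "reports" / "fluxes.tsv"
        pd.DataFrame({"reaction": list(fit.fluxes.net),
                      "net_flux": [round(v, 6) for v in fit.fluxes.net.values()]}
                     ).to_csv(out, sep="\t", index=False)
        record("fluxes", t0, [out])
        manifest["stages"]["fluxes"]["converged"] = fit.converged
        manifest["stages"]["fluxes"]["ssr"] = round(fit.ssr, 6)

    if stages.get("metabolome"):
        t0 = time.time()
        frame = pd.read_csv(_input_path(config, outdir, "metabolome",
                                        DEFAULT_NAMES["metabolome"]),
                            sep="\t", index_col=0)
        gmap = pd.read_csv(_input_path(config, outdir, "metabolome_groups",
                                       DEFAULT_NAMES["metabolome_groups"]), sep="\t")
        groups = dict(zip(gmap["sample"], gmap["group"]))
        table = MetaboliteAbundanceTable(frame, groups)
        g1, g2 = sorted(set(groups.values()), reverse=True)
        res = differential_metabolome(table, g1, g2)
        lo, hi = config.get("thresholds", {}).get("significance", [0.05, 0.1])
        summary = summarize_significance(res, (lo, hi))
        out1 = outdir / "reports" / "metabolome_results.tsv"
        res.to_csv(out1, sep="\t")
        out2 = outdir / "reports" / "metabolome_counts.tsv"
        pd.DataFrame([summary["counts"]]).to_csv(out2, sep="\t", index=False)
        out3 = outdir / "reports" / "metabolome_by_pathway.tsv"
        summary["by_pathway"].to_csv(out3, sep="\t", index=False)
        record("metabolome", t0, [out1, out2, out3])

    if stages.get("fpkm"):
        t0 = time.time()
        counts = pd.read_csv(_input_path(config, outdir, "counts",
                                         DEFAULT_NAMES["counts"]), sep="\t")
        fpkm = compute_fpkm(counts)
        log2 = log2_expression_compare(fpkm)
        out1 = outdir / "reports" / "fpkm.tsv"
        fpkm.to_csv(out1, sep="\t", index=False)
        out2 = outdir / "reports" / "log2_fpkm.tsv"
        log2.to_csv(out2, sep="\t", index=False)
        record("fpkm", t0, [out1, out2])

    if stages.get("reporter"):
        t0 = time.time()
        graph = ReporterGraph.from_tsv(
            _input_path(config, outdir, "reporter_edges", DEFAULT_NAMES["reporter_edges"]),
            _input_path(config, outdir, "reporter_kinds", DEFAULT_NAMES["reporter_kinds"]))
        gp = pd.read_csv(_input_path(config, outdir, "gene_pvalues",
                                     DEFAULT_NAMES["gene_pvalues"]),
                         sep="\t", index_col=0)
        res = reporter_scores(graph, gp["p"], seed=seed)
        cutoffs = config.get("thresholds", {})
        res["significant"] = [
            p <= cutoffs.get("reporter_metabolite" if kind == "metabolite"
                             else "reporter_go", REPORTER_CUTOFFS.get(kind, 0.05))
            for p, kind in zip(res["p"], res["kind"])]
        if {"p_up_a", "p_up_b"}.issubset(gp.columns):
            dres = directional_scores(graph, gp["p_up_a"], gp["p_up_b"], seed=seed)
            res = res.join(dres[["signed_score"]])
        out = outdir / "reports" / "reporter_features.tsv"
        res.to_csv(out, sep="\t")
        record("reporter", t0, [out])

    if stages.get("tf_venn"):
        t0 = time.time()
        catalog = TFCatalog.from_lists({
            "sc": _input_path(config, outdir, "tf_list_a", DEFAULT_NAMES["tf_list_a"]),
            "ps": _input_path(config, outdir, "tf_list_b", DEFAULT_NAMES["tf_list_b"]),
        })
        families = parse_groups(Path(_input_path(config, outdir, "groups",
                                                 DEFAULT_NAMES["groups"])),
                                catalog=catalog)
        venn, table = tf_family_venn(families, catalog)
        sp_a, sp_b = catalog.species
        out1 = outdir / "reports" / "tf_venn.tsv"
        pd.DataFrame([{"shared": venn.shared, f"unique_{sp_a}": venn.unique_a,
                       f"unique_{sp_b}": venn.unique_b}]).to_csv(out1, sep="\t", index=False)
        out2 = outdir / "reports" / "tf_families.tsv"
        table.to_csv(out2, sep="\t")
        record("tf_venn", t0, [out1, out2])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_demo_orthologs(indir: Path) -> None:
    """Small hand-built ortholog/TF fixture for the demo pipeline."""
    groups = [
        "FAM1: sc|RGT1 ps|PICST_0001",
        "FAM2: sc|HAP2 ps|HAP2",
        "FAM3: sc|MIG1 ps|MIG1 sc|MIG2",
        "FAM4: sc|INO2",
        "FAM5: ps|FRC1",
        "FAM6: sc|CDC19 ps|CDC19",
    ]
    (indir / DEFAULT_NAMES["groups"]).write_text("\n".join(groups) + "\n")
    (indir / DEFAULT_NAMES["tf_list_a"]).write_text(
        "\n".join(["RGT1", "HAP2", "MIG1", "MIG2", "INO2", "INO4"]) + "\n")
    (indir / DEFAULT_NAMES["tf_list_b"]).write_text(
        "\n".join(["HAP2", "MIG1", "FRC1"]) + "\n")
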