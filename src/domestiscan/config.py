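"""Run configuration: YAML parsing, defaults, validation, and orchestration.

A single ``RunConfig`` bundles every stage's parameters with the defaults of
the analysis protocol (MAF 0.05, per-population call rate 0.95, HWE 0.01 in
half the populations, 10 kb / r2 0.2 clumping, Hmin 0.1, q 0.05, 5K SNPs for
Ne, 500 kb / 100 bins / 30 samples for LD decay, ROH 200 kb / 50 kb / 1000 kb
with 1 het and 5 missing per window, enrichment FDR 0.1). ``run_all`` chains
simulate -> qc -> stats -> ne -> lddecay -> roh -> scan -> panel -> report
with per-stage sub-seeds derived by stable hashing so toggling one stage
never shifts another's random stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import gio, lddecay, ne_ld, panelrf, popstats, qcfilter, roh as roh_mod
from .genoscan import ScanConfig, make_clumped_neutral, scan as run_scan
from .panelrf import RfConfig
from .qcfilter import FilterConfig
from .roh import RohParams
from .simpop import SimConfig, StrainSpec, default_demo_config, subseed

log = logging.getLogger("domestiscan")

ALL_STAGES = ["simulate", "qc", "stats", "ne", "lddecay", "roh", "scan", "panel", "report"]


@dataclass
class NeOptions:
    n_snps: int = 5000
    maf_min: float = 0.05
    min_samples: int = 10
    compute_ci: bool = True


@dataclass
class DecayOptions:
    max_dist: int = 500_000
    n_bins: int = 100
    subsample: int = 30


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    vcf: str | None = None          # input data when not simulating
    popmap: str | None = None
    regions: str | None = None
    enrichment_fdr: float = 0.1
    sim: SimConfig = field(default_factory=lambda: default_demo_config())
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    roh: RohParams = field(default_factory=RohParams)
    ne: NeOptions = field(default_factory=NeOptions)
    lddecay: DecayOptions = field(default_factory=DecayOptions)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(self)


def _build(dc_type, data: dict, where: str):
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key {where}.{key}")
        kwargs[key] = val
    return dc_type(**kwargs)


def validate_config(path_or_dict) -> RunConfig:
    """Load + validate a YAML run configuration; defaults fill every gap."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config key {key}")
    sub = {}
    if "sim" in raw:
        sim_raw = dict(raw["sim"])
        specs = sim_raw.pop("strain_specs", None)
        anchor = sim_raw.pop("anchor_freq", None)
        sim = _build(SimConfig, sim_raw, "sim")
        if specs is not None:
            sim.strain_specs = [
                _build(StrainSpec, {**s, "selected_loci": [tuple(x) for x in s.get("selected_loci", [])],
                                    "admix_from": tuple(s["admix_from"]) if s.get("admix_from") else None},
                       "sim.strain_specs") for s in specs]
        if anchor is not None:
            sim.anchor_freq = {int(k): float(v) for k, v in anchor.items()}
        sub["sim"] = sim
    for key, typ in (("filter", FilterConfig), ("scan", ScanConfig), ("rf", RfConfig),
                     ("roh", RohParams), ("ne", NeOptions), ("lddecay", DecayOptions)):
        if key in raw:
            sub[key] = _build(typ, dict(raw[key]), key)
    top = {k: v for k, v in raw.items() if k in known - set(sub) and k not in
           ("sim", "filter", "scan", "rf", "roh", "ne", "lddecay")}
    cfg = RunConfig(**top, **sub)
    for st in cfg.stages:
        if st not in ALL_STAGES:
            raise ValueError(f"unknown stage {st!r}")
    return cfg


class StageError(RuntimeError):
    pass


def run_all(cfg: RunConfig, out_dir: str | None = None) -> dict:
    """Execute the configured stages in dependency order; returns artifacts.

    Every artifact is also written under ``out_dir``. A stage whose inputs
    were not produced (stage toggled off, no input files given) raises
    :class:`StageError` naming the missing stage.
    """
    from .integrate import report as write_report

    out_dir = out_dir or cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    art: dict = {"out_dir": out_dir}
    stages = set(cfg.stages)

    def need(name, key):
        if key not in art:
            raise StageError(f"stage {name!r} requires output of a stage that did not run")

    if "simulate" in stages:
        log.info("stage simulate")
        cfg.sim.seed = subseed(cfg.seed, "simulate")
        ds, truth = __import__("domestiscan.simpop", fromlist=["assemble_panel"]).assemble_panel(
            cfg.sim, out_dir=os.path.join(out_dir, "sim"))
        art["dataset"], art["truth"] = ds, truth
    elif cfg.vcf and cfg.popmap:
        art["dataset"] = gio.read_vcf(cfg.vcf, cfg.popmap)

    if "qc" in stages:
        need("qc", "dataset")
        log.info("stage qc")
        regions = gio.read_regions(cfg.regions) if cfg.regions else None
        full, rep = qcfilter.apply_filters(art["dataset"], cfg.filter, regions)
        clumped = qcfilter.ld_clump(full, cfg.filter)
        rep.to_csv(os.path.join(out_dir, "filter_report.tsv"), sep="\t", index=False)
        gio.write_vcf(full, os.path.join(out_dir, "full_snps.vcf"))
        art["full"], art["clumped"], art["filter_report"] = full, clumped, rep

    if "scan" in stages:
        need("scan", "full")
        log.info("stage scan")
        table, counts = run_scan(art["full"], art["clumped"], cfg.scan)
        art["scan_table"], art["scan_counts"] = table, counts
        union = table.loc[table["outlier_union"], "marker_id"].tolist()
        art["union_ids"] = union
        art["clumped_neutral"] = (make_clumped_neutral(art["full"], union, cfg.filter)
                                  if len(union) < art["full"].n_markers else art["clumped"])

    analysis_ds = art.get("clumped_neutral", art.get("clumped"))

    if "stats" in stages:
        need("stats", "full")
        log.info("stage stats")
        div = popstats.diversity(analysis_ds)
        fst = popstats.wc_fst(art["full"])
        art["diversity"], art["fst_matrix"] = div, fst
        if "union_ids" in art and art["union_ids"]:
            keep = np.isin(art["full"].markers.ids, art["union_ids"])
            art["fst_matrix_outliers"] = popstats.wc_fst(
                art["full"].subset_markers(np.flatnonzero(keep)))

    if "ne" in stages:
        need("ne", "full")
        log.info("stage ne")
        art["ne_table"] = ne_ld.estimate_ne_all(
            analysis_ds, cfg.ne.maf_min, cfg.ne.n_snps, subseed(cfg.seed, "ne"),
            cfg.ne.min_samples, cfg.ne.compute_ci)
        art["ne_table"].to_csv(os.path.join(out_dir, "ne.tsv"), sep="\t", index=False)

    if "lddecay" in stages:
        need("lddecay", "full")
        log.info("stage lddecay")
        art["decay"] = lddecay.decay_curves(
            art["full"], cfg.lddecay.max_dist, cfg.lddecay.n_bins,
            cfg.lddecay.subsample, subseed(cfg.seed, "lddecay"))
        art["decay"].to_csv(os.path.join(out_dir, "lddecay.tsv"), sep="\t", index=False)
        if len(art["decay"]) and art["decay"]["class"].nunique() > 1 \
                and art["decay"]["chrom"].nunique() > 1:
            try:
                art["decay_anova"] = lddecay.decay_anova(art["decay"])
            except ValueError as exc:
                log.warning("lddecay ANOVA skipped: %s", exc)

    if "roh" in stages:
        need("roh", "full")
        log.info("stage roh")
        segments, meta = roh_mod.call_roh(art["full"], cfg.roh)
        art["roh_segments"], art["roh_meta"] = segments, meta
        art["froh"] = roh_mod.froh_all(segments, meta, art["full"])
        segments.to_csv(os.path.join(out_dir, "roh_segments.tsv"), sep="\t", index=False)
        art["froh"].to_csv(os.path.join(out_dir, "froh.tsv"), sep="\t", index=False)

    if "panel" in stages:
        need("panel", "scan_table")
        log.info("stage panel")
        union = art["union_ids"]
        if len(union) < 3:
            log.warning("panel stage skipped: only %d union outliers", len(union))
        else:
            full = art["full"]
            keep = np.flatnonzero(np.isin(full.markers.ids, union))
            x = full.genotypes[:, keep]
            y = full.class_labels()
            cfg.rf.seed = subseed(cfg.seed, "panel")
            result = panelrf.backward_purge(x, y, cfg.rf)
            panel_ids = full.markers.ids[keep][result.final_idx]
            conf, acc = panelrf.dapc_confusion(x[:, result.final_idx], y)
            art["panel"] = {"result": result, "panel_ids": list(panel_ids),
                            "confusion": conf, "accuracy": acc}
            result.trace.to_csv(os.path.join(out_dir, "purge_trace.tsv"), sep="\t", index=False)
            conf.to_csv(os.path.join(out_dir, "dapc_confusion.tsv"), sep="\t")
            with open(os.path.join(out_dir, "panel_markers.txt"), "w") as fh:
                fh.write("\n".join(map(str, panel_ids)) + "\n")

    if "report" in stages:
        need("report", "full")
        log.info("stage report")
        manifest = {"config": cfg.to_dict(), "seed": cfg.seed,
                    "stages": sorted(stages)}
        art["summary"] = write_report(
            os.path.join(out_dir, "report"),
            diversity_table=art.get("diversity"),
            ne_table=art.get("ne_table"),
            fst_matrix=art.get("fst_matrix"),
            fst_matrix_outliers=art.get("fst_matrix_outliers"),
            pop_class=art["full"].pop_class,
            froh_table=art.get("froh"),
            scan_table=art.get("scan_table"),
            manifest=manifest)
        if "panel" in art:
            art["summary"]["dapc_accuracy"] = art["panel"]["accuracy"]
            art["summary"]["panel_size"] = len(art["panel"]["panel_ids"])
        with open(os.path.join(out_dir, "report", "summary.json"), "w") as fh:
            json.dump(art["summary"], fh, indent=1, default=str)
    return art
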