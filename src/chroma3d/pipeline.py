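"""Pipeline configuration, stage orchestration, and the run report.

A run consumes a directory of canonical input files (the layout written
by :func:`chroma3d.synthetic_data.write_dataset` — contacts.<chrom>.coo,
chrom.sizes, genes.gff3, peak BEDs, depth/methylation bedGraphs,
expression.tsv, snps.tsv) plus a YAML config of thresholds, and writes
per-stage outputs and a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from . import contacts as con
from . import domains as dom
from . import elements as ele
from . import io as cio
from . import loops as loo
from . import variants as var
from .synthetic_data import DEPTH_STEP, METH_STEP

__version__ = "0.1.0"

log = logging.getLogger("chroma3d")


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_dir: str = "."
    bin_size: int = 25_000
    tad_window_bins: int = 5
    tad_delta: float = 0.1
    min_tad_bins: int = 3
    tad_resolutions: list = field(default_factory=list)  # extra, multiples of bin_size
    loop_q: float = 0.05
    loop_min_distance_bins: int = 2
    loop_max_distance_bp: int = 2_000_000
    loop_enrichment_donut: float = 1.75
    loop_enrichment_lowerleft: float = 1.5
    promoter_upstream: int = 3000
    diff_lfc: float = 1.0
    diff_alpha: float = 0.05
    ice_tol: float = 1e-5
    ice_max_iter: int = 200
    ice_mask_quantile: float = 0.02
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        checks = [
            (0 < self.loop_q <= 1, "loop_q must be in (0, 1]"),
            (self.tad_delta >= 0, "tad_delta must be >= 0"),
            (self.tad_window_bins >= 1, "tad_window_bins must be >= 1"),
            (self.min_tad_bins >= 1, "min_tad_bins must be >= 1"),
            (self.bin_size > 0, "bin_size must be positive"),
            (self.promoter_upstream > 0, "promoter_upstream must be positive"),
            (self.loop_enrichment_donut >= 1, "loop_enrichment_donut must be >= 1"),
            (self.loop_enrichment_lowerleft >= 1,
             "loop_enrichment_lowerleft must be >= 1"),
            (0 < self.diff_alpha < 1, "diff_alpha must be in (0, 1)"),
            (0 <= self.ice_mask_quantile < 1, "ice_mask_quantile in [0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PipelineConfigError(msg)
        for r in self.tad_resolutions:
            if r % self.bin_size:
                raise PipelineConfigError(
                    f"tad resolution {r} is not a multiple of bin_size")
        return self


def validate_config(path) -> PipelineConfig:
    """Load and range-check a YAML config; unknown keys are rejected."""
    p = Path(path)
    if not p.exists():
        raise PipelineConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineConfigError("config must be a YAML mapping")
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw).validate()


# ----------------------------------------------------------------- loading

@dataclass
class Inputs:
    chrom_sizes: dict
    matrices: dict
    genes: pd.DataFrame
    atac_s1: pd.DataFrame
    atac_s2: pd.DataFrame
    h3k27ac: pd.DataFrame
    atac_depth_s1: cio.StepTrack
    atac_depth_s2: cio.StepTrack
    h3k27ac_depth: cio.StepTrack
    methylation: dict
    expression: pd.DataFrame
    snps: pd.DataFrame
    gene_density: cio.StepTrack | None = None


def load_inputs(cfg: PipelineConfig) -> Inputs:
    d = Path(cfg.input_dir)

    def need(name):
        p = d / name
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        return p

    sizes = cio.read_chrom_sizes(need("chrom.sizes"))
    mats = {}
    for chrom in sizes:
        mats[chrom] = con.read_contacts(need(f"contacts.{chrom}.coo"),
                                        d / "chrom.sizes", chrom, cfg.bin_size)
    genes = cio.read_gff3_genes(need("genes.gff3"))
    meth = {ctx: cio.read_bedgraph(need(f"meth_{ctx}.bedGraph"), sizes, METH_STEP)
            for ctx in ("CG", "CHG", "CHH")}
    gd_path = d / "gene_density.bedGraph"
    gd = (cio.read_bedgraph(gd_path, sizes, cfg.bin_size)
          if gd_path.exists() else None)
    return Inputs(
        chrom_sizes=sizes, matrices=mats, genes=genes,
        atac_s1=cio.read_bed(need("atac_sample1.bed")),
        atac_s2=cio.read_bed(need("atac_sample2.bed")),
        h3k27ac=cio.read_bed(need("h3k27ac.bed")),
        atac_depth_s1=cio.read_bedgraph(need("atac_depth_sample1.bedGraph"),
                                        sizes, DEPTH_STEP),
        atac_depth_s2=cio.read_bedgraph(need("atac_depth_sample2.bedGraph"),
                                        sizes, DEPTH_STEP),
        h3k27ac_depth=cio.read_bedgraph(need("h3k27ac_depth.bedGraph"),
                                        sizes, DEPTH_STEP),
        methylation=meth,
        expression=cio.read_expression(need("expression.tsv")),
        snps=cio.read_snps(need("snps.tsv")),
        gene_density=gd,
    )


def _gene_density_per_bin(genes: pd.DataFrame, chrom: str, bin_size: int,
                          n_bins: int) -> np.ndarray:
    sub = genes[genes["chrom"] == chrom]
    mids = (((sub["start"] + sub["end"]) // 2) // bin_size).astype(int)
    return np.bincount(mids.clip(0, n_bins - 1), minlength=n_bins).astype(float)


def _bin_tracks(inputs: Inputs, cfg: PipelineConfig, chrom: str,
                n_bins: int) -> dict[str, np.ndarray]:
    """Per-bin marker tracks for compartment summaries and TAD profiling."""
    nb = {c: -(-L // cfg.bin_size) for c, L in inputs.chrom_sizes.items()}
    tracks = {
        "gene_density": _gene_density_per_bin(inputs.genes, chrom,
                                              cfg.bin_size, n_bins),
        "atac": inputs.atac_depth_s1.aggregate(cfg.bin_size, nb).values[chrom],
        "h3k27ac": inputs.h3k27ac_depth.aggregate(cfg.bin_size, nb).values[chrom],
    }
    for ctx, tr in inputs.methylation.items():
        tracks[ctx.lower()] = tr.aggregate(cfg.bin_size, nb).values[chrom]
    expr = inputs.genes.merge(inputs.expression, on="gene_id", how="left")
    sub = expr[expr["chrom"] == chrom]
    mids = (((sub["start"] + sub["end"]) // 2) // cfg.bin_size).astype(int)
    per_bin = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    np.add.at(per_bin, mids.clip(0, n_bins - 1),
              sub["expression"].fillna(0).to_numpy())
    np.add.at(cnt, mids.clip(0, n_bins - 1), 1)
    with np.errstate(invalid="ignore"):
        tracks["expression"] = np.where(cnt > 0, per_bin / np.maximum(cnt, 1), 0.0)
    return tracks


# ------------------------------------------------------------------ stages

def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages in dependency order; returns the RunReport."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": asdict(cfg)}

    def stage(name, fn, *args, **kw):
        log.info("[%s] start", name)
        try:
            res = fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise StageError(name, exc) from exc
        log.info("[%s] done", name)
        return res

    inputs = stage("load", load_inputs, cfg)
    balanced = stage("balance", _stage_balance, inputs, cfg)
    report["compartments"] = stage("compartments", _stage_compartments,
                                   inputs, balanced, cfg, out)
    report["tads"] = stage("tads", _stage_tads, inputs, balanced, cfg, out)
    report["loops"] = stage("loops", _stage_loops, inputs, balanced, cfg, out)
    loops_df = report["loops"].pop("_loops_df")
    report["elements"] = stage("elements", _stage_elements, inputs, loops_df,
                               cfg, out)
    report["variants"] = stage("variants", _stage_variants, inputs, cfg, out)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _stage_balance(inputs: Inputs, cfg: PipelineConfig) -> dict:
    out = {}
    for chrom, m in inputs.matrices.items():
        out[chrom] = con.ice_balance(m, max_iter=cfg.ice_max_iter,
                                     tol=cfg.ice_tol,
                                     mask_quantile=cfg.ice_mask_quantile)
    return out


def _stage_compartments(inputs: Inputs, balanced: dict, cfg: PipelineConfig,
                        out: Path) -> dict:
    seg_rows, pc_rows, summary = [], [], {}
    n_a = n_b = a_bins = b_bins = genes_a = genes_b = 0
    for chrom, m in balanced.items():
        profile = con.expected_by_distance(m)
        oe = con.oe_transform(m, profile)
        gd = _gene_density_per_bin(inputs.genes, chrom, cfg.bin_size, m.n_bins)
        tracks = _bin_tracks(inputs, cfg, chrom, m.n_bins)
        caller = comp.CompartmentCaller(chrom, cfg.bin_size).fit(
            oe, gene_density=gd, genes=inputs.genes, tracks=tracks)
        call = caller.call_
        n_a += call.stats["n_A_segments"]
        n_b += call.stats["n_B_segments"]
        a_bins += int((caller.labels_ == "A").sum())
        b_bins += int((caller.labels_ == "B").sum())
        genes_a += call.stats.get("genes_in_A", 0)
        genes_b += call.stats.get("genes_in_B", 0)
        summary[chrom] = call.stats
        for r in call.segments.itertuples(index=False):
            seg_rows.append((chrom, r.start_bin * cfg.bin_size,
                             min(r.end_bin * cfg.bin_size,
                                 inputs.chrom_sizes[chrom]),
                             r.label,
                             float(np.nanmean(
                                 caller.pc1_[r.start_bin:r.end_bin]))))
        for b, v in enumerate(caller.pc1_):
            if not np.isnan(v):
                pc_rows.append((chrom, b * cfg.bin_size,
                                min((b + 1) * cfg.bin_size,
                                    inputs.chrom_sizes[chrom]), v))
    pd.DataFrame(seg_rows).to_csv(out / "compartments.bed", sep="\t",
                                  header=False, index=False)
    pd.DataFrame(pc_rows).to_csv(out / "pc1.bedGraph", sep="\t",
                                 header=False, index=False)
    tot = a_bins + b_bins
    stats = {
        "per_chrom": summary,
        "n_A_segments": n_a, "n_B_segments": n_b,
        "pct_genome_A": 100.0 * a_bins / tot if tot else float("nan"),
        "pct_genome_B": 100.0 * b_bins / tot if tot else float("nan"),
        "genes_in_A": genes_a, "genes_in_B": genes_b,
    }
    (out / "stats.json").write_text(json.dumps(stats, indent=1))
    return stats


def _stage_tads(inputs: Inputs, balanced: dict, cfg: PipelineConfig,
                out: Path) -> dict:
    all_tads, ins_rows = [], []
    for chrom, m in balanced.items():
        est = dom.InsulationTADCaller(cfg.tad_window_bins, cfg.tad_delta,
                                      cfg.min_tad_bins).fit(m)
        tads = est.tads_.copy()
        tads.insert(0, "chrom", chrom)
        tads["resolution_bp"] = cfg.bin_size
        all_tads.append(tads)
        for b, v in enumerate(est.insulation_):
            if not np.isnan(v):
                ins_rows.append((chrom, b * cfg.bin_size,
                                 (b + 1) * cfg.bin_size, v))
    tads = pd.concat(all_tads, ignore_index=True)
    counts = {int(cfg.bin_size): len(tads)}
    for res in cfg.tad_resolutions:
        n_res = 0
        for chrom, m in inputs.matrices.items():
            res_tads = dom.multi_resolution(
                m, [res], window_bins=cfg.tad_window_bins,
                delta_threshold=cfg.tad_delta,
                min_tad_bins=cfg.min_tad_bins)[res]
            n_res += len(res_tads)
        counts[int(res)] = n_res
    pd.DataFrame(ins_rows).to_csv(out / "insulation.bedGraph", sep="\t",
                                  header=False, index=False)
    bed = tads.assign(start=tads["start_bin"] * cfg.bin_size,
                      end=tads["end_bin"] * cfg.bin_size)
    bed[["chrom", "start", "end"]].to_csv(out / f"tads_{cfg.bin_size}.bed",
                                          sep="\t", header=False, index=False)

    # epigenetic clustering of TADs
    marker_tracks = {}
    cluster_info: dict = {}
    try:
        per_chrom = {c: _bin_tracks(inputs, cfg, c, balanced[c].n_bins)
                     for c in balanced}
        names = next(iter(per_chrom.values())).keys()
        rows = []
        for r in tads.itertuples(index=False):
            tr = per_chrom[r.chrom]
            rows.append({k: np.nanmean(tr[k][r.start_bin:r.end_bin])
                         for k in names})
        raw = pd.DataFrame(rows)
        z = (raw - raw.mean()) / raw.std(ddof=0).replace(0, np.nan)
        clu = dom.TadClusterer(3).fit(z)
        tads_out = tads.assign(cluster=clu.labels_, role=clu.role_per_tad_)
        tads_out = pd.concat([tads_out, raw.add_prefix("mean_")], axis=1)
        tads_out.to_csv(out / "tad_clusters.tsv", sep="\t", index=False)
        sizes_ = pd.Series(clu.role_per_tad_).value_counts().to_dict()
        cluster_info = {"roles": {str(k): int(v) for k, v in sizes_.items()}}
    except ValueError as exc:
        cluster_info = {"skipped": str(exc)}
    return {"counts_by_resolution": counts, "n_tads": len(tads),
            "clusters": cluster_info}


def _stage_loops(inputs: Inputs, balanced: dict, cfg: PipelineConfig,
                 out: Path) -> dict:
    frames = []
    for chrom, m in balanced.items():
        decay = con.expected_by_distance(m)
        caller = loo.DonutLoopCaller(
            min_distance_bins=cfg.loop_min_distance_bins,
            max_distance_bp=cfg.loop_max_distance_bp,
            q_threshold=cfg.loop_q,
            min_enrichment_donut=cfg.loop_enrichment_donut,
            min_enrichment_lowerleft=cfg.loop_enrichment_lowerleft,
        ).fit(m, decay=decay)
        frames.append(caller.loops_)
    loops = pd.concat(frames, ignore_index=True)
    loops = loo.classify_loops(loops, inputs.genes)
    cat = loops["category"].value_counts().to_dict()
    profiles = loo.loops_per_gene(loops, inputs.genes)
    profiles = profiles.merge(inputs.expression, on="gene_id", how="left")
    trend = loo.expression_by_loopcount(profiles[profiles["n_loops"] >= 1])
    dist = loo.loop_distance_stats(loops, cfg.bin_size)

    bedpe = loops.assign(name=".", score=loops["enrichment_donut"],
                         strand1=".", strand2=".")
    bedpe[["chrom", "anchor1_start", "anchor1_end", "chrom", "anchor2_start",
           "anchor2_end", "name", "score", "strand1", "strand2", "observed",
           "expected_local", "q", "category"]].to_csv(
        out / "loops.bedpe", sep="\t", header=False, index=False)
    profiles.to_csv(out / "gene_loops.tsv", sep="\t", index=False)
    return {"n_loops": len(loops), "categories": {k: int(v) for k, v in cat.items()},
            "n_multi_loop_genes": len(loo.select_multi_loop_genes(profiles)),
            "expression_trend": {k: (v if not isinstance(v, dict) else v)
                                 for k, v in trend.items()},
            "fraction_within_400kb": dist["fraction_within"],
            "_loops_df": loops}


def _stage_elements(inputs: Inputs, loops: pd.DataFrame, cfg: PipelineConfig,
                    out: Path) -> dict:
    sizes = inputs.chrom_sizes
    acrs = ele.classify_acrs(inputs.atac_s1, inputs.genes,
                             cfg.promoter_upstream, sizes)
    enh = ele.define_enhancers(inputs.h3k27ac, inputs.genes,
                               cfg.promoter_upstream, sizes)
    enh = ele.mark_active(enh, inputs.atac_s1)
    links = ele.link_enhancer_genes(enh, loops, inputs.genes,
                                    cfg.promoter_upstream, sizes)
    prom = acrs[acrs["element_class"] == "promoter_ACR"]
    pexpr = ele.promoter_acr_expression(inputs.genes, prom, inputs.expression,
                                        cfg.promoter_upstream, sizes)
    diff = ele.differential_accessibility(inputs.atac_depth_s1,
                                          inputs.atac_depth_s2, inputs.atac_s1,
                                          lfc_threshold=cfg.diff_lfc,
                                          alpha=cfg.diff_alpha)
    acrs.to_csv(out / "acr_classes.tsv", sep="\t", index=False)
    enh.to_csv(out / "enhancers.tsv", sep="\t", index=False)
    diff.to_csv(out / "differential_accessibility.tsv", sep="\t", index=False)
    class_counts = acrs["element_class"].value_counts().to_dict()
    return {
        "acr_classes": {k: int(v) for k, v in class_counts.items()},
        "n_atac_peaks": len(acrs),
        "n_enhancers": len(enh),
        "n_active_enhancers": int(enh["active"].sum()),
        "active_fraction": ele.active_fraction(enh),
        "n_enhancer_anchors": links["n_enhancer_anchors"],
        "n_genes_linked": links["n_genes_linked"],
        "promoter_expression": pexpr,
        "n_differential_peaks": int(diff["differential"].sum()),
    }


def _stage_variants(inputs: Inputs, cfg: PipelineConfig, out: Path) -> dict:
    sizes = inputs.chrom_sizes
    acrs = ele.classify_acrs(inputs.atac_s1, inputs.genes,
                             cfg.promoter_upstream, sizes)
    enh = ele.define_enhancers(inputs.h3k27ac, inputs.genes,
                               cfg.promoter_upstream, sizes)
    genome_len = int(sum(sizes.values()))
    whole = pd.DataFrame({"chrom": list(sizes), "start": 0,
                          "end": [sizes[c] for c in sizes]})
    classes = {
        "promoter_ACR": acrs[acrs["element_class"] == "promoter_ACR"],
        "enhancer": enh,
        "whole_genome": whole,
    }
    rep = var.density_report(inputs.snps, classes, genome_len, sizes)
    rep.to_csv(out / "snp_density.tsv", sep="\t", index=False)
    return {r["class_name"]: {k: (None if isinstance(v, float) and np.isnan(v)
                                  else v)
                              for k, v in r.items() if k != "class_name"}
            for r in rep.to_dict("records")}
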