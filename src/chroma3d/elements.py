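"""Regulatory-element annotation and accessibility statistics.

ATAC peaks (accessible chromatin regions, ACRs) are partitioned into
promoter / other / distal classes against strand-aware 3-kb upstream
promoter windows.  H3K27ac peaks in distal intergenic space are
enhancers; enhancers overlapping an ATAC peak are active.  Enhancers
are linked to genes through loop anchors: an enhancer on one anchor
regulates the genes whose body or promoter window touches the other
anchor.

Also here: TSS / peak meta-profiles, the promoter-ACR expression
contrast, and two-sample differential accessibility on read-depth
tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu

from . import intervals as iv
from .io import StepTrack

PROMOTER_UPSTREAM = 3000


def classify_acrs(atac_peaks: pd.DataFrame, genes: pd.DataFrame,
                  upstream: int = PROMOTER_UPSTREAM,
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Assign each ATAC peak exactly one ACR class.

    Precedence: promoter-window overlap -> promoter_ACR; else gene-body
    overlap -> other_ACR; else distal_ACR.
    """
    peaks = atac_peaks.copy()
    windows = iv.promoter_windows(genes, upstream, chrom_sizes)
    in_prom = iv.flag_overlaps(peaks, windows)
    in_body = iv.flag_overlaps(peaks, genes)
    peaks["element_class"] = np.select(
        [in_prom, in_body], ["promoter_ACR", "other_ACR"], default="distal_ACR")
    return peaks


def define_enhancers(h3k27ac_peaks: pd.DataFrame, genes: pd.DataFrame,
                     upstream: int = PROMOTER_UPSTREAM,
                     chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """H3K27ac peaks in distal intergenic space (no gene-body and no
    promoter-window overlap) are enhancers."""
    classified = classify_acrs(h3k27ac_peaks, genes, upstream, chrom_sizes)
    enh = classified[classified["element_class"] == "distal_ACR"].copy()
    enh["element_class"] = "enhancer"
    return enh.reset_index(drop=True)


def mark_active(enhancers: pd.DataFrame, atac_peaks: pd.DataFrame
                ) -> pd.DataFrame:
    """Flag enhancers overlapping >= 1 bp of any ATAC peak as active."""
    enh = enhancers.copy()
    enh["active"] = iv.flag_overlaps(enh, atac_peaks)
    return enh


def active_fraction(enhancers: pd.DataFrame) -> float:
    if len(enhancers) == 0:
        return float("nan")
    return float(enhancers["active"].mean())


def link_enhancer_genes(enhancers: pd.DataFrame, loops: pd.DataFrame,
                        genes: pd.DataFrame,
                        upstream: int = PROMOTER_UPSTREAM,
                        chrom_sizes: dict[str, int] | None = None) -> dict:
    """Loop-mediated enhancer->gene links.

    For each loop, enhancers overlapping one anchor are linked to the
    genes whose body or promoter window overlaps the *other* anchor
    (both orientations considered; same-anchor colocation never links).
    Returns the link table plus distinct enhancer-anchor and gene counts.
    """
    enh_trees = iv.build_trees(enhancers)
    windows = iv.promoter_windows(genes, upstream, chrom_sizes)
    gene_regions = pd.concat([
        genes[["chrom", "start", "end"]].assign(gene_id=genes["gene_id"].to_numpy()),
        windows[["chrom", "start", "end", "gene_id"]]], ignore_index=True)
    gene_trees = iv.build_trees(gene_regions)

    links = []
    enh_anchors = set()
    for lid, row in enumerate(loops.itertuples(index=False)):
        anchors = ((row.anchor1_start, row.anchor1_end),
                   (row.anchor2_start, row.anchor2_end))
        for side, other in ((0, 1), (1, 0)):
            a_s, a_e = anchors[side]
            hits = iv.overlapping_indices(enh_trees, row.chrom, a_s, a_e)
            if not hits:
                continue
            enh_anchors.add((row.chrom, a_s, a_e))
            o_s, o_e = anchors[other]
            gidx = iv.overlapping_indices(gene_trees, row.chrom, o_s, o_e)
            gids = {gene_regions.loc[g, "gene_id"] for g in gidx}
            for e_idx in hits:
                for gid in sorted(gids):
                    links.append((lid, e_idx, gid))
    link_df = pd.DataFrame(links, columns=["loop_id", "enhancer_idx", "gene_id"])
    return {
        "links": link_df,
        "n_enhancer_anchors": len(enh_anchors),
        "n_genes_linked": int(link_df["gene_id"].nunique()) if len(link_df) else 0,
    }


def tss_metaprofile(depth: StepTrack, genes: pd.DataFrame,
                    flank: int = 2000) -> dict:
    """Strand-oriented mean read depth around TSSs.

    Offsets run -flank..+flank at track resolution; genes whose window
    leaves the chromosome contribute NaN at the missing positions.
    """
    step = depth.step
    half = flank // step
    mats = []
    for row in genes.itertuples(index=False):
        vals = depth.values.get(row.chrom)
        if vals is None:
            continue
        tss = row.start if getattr(row, "strand", "+") != "-" else row.end - 1
        c = tss // step
        lo, hi = c - half, c + half + 1
        window = np.full(2 * half + 1, np.nan)
        s, e = max(0, lo), min(len(vals), hi)
        window[s - lo: s - lo + (e - s)] = vals[s:e]
        if getattr(row, "strand", "+") == "-":
            window = window[::-1]
        mats.append(window)
    if not mats:
        raise ValueError("no genes to profile")
    profile = np.nanmean(np.vstack(mats), axis=0)
    offsets = (np.arange(-half, half + 1)) * step
    return {"offsets": offsets, "profile": profile,
            "peak_offset": int(offsets[np.nanargmax(profile)]),
            "n_features": len(mats)}


def peak_metaprofile(track: StepTrack, peaks: pd.DataFrame,
                     flank: int = 2000, body_positions: int = 100) -> dict:
    """Mean signal over scaled peak bodies with unscaled flanks.

    Bodies are linearly rescaled to ``body_positions`` points; flanks
    keep track resolution.  Reports body and flank means (used for the
    methylation-dip contrast around active peaks).
    """
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    step = track.step
    half = flank // step
    up, body, down = [], [], []
    for row in peaks.itertuples(index=False):
        vals = track.values.get(row.chrom)
        if vals is None:
            continue
        s_bin, e_bin = row.start // step, -(-row.end // step)
        e_bin = max(e_bin, s_bin + 1)  # sub-bin peak uses its covering bin
        bvals = vals[max(0, s_bin):min(len(vals), e_bin)].astype(float)
        if bvals.size == 0:
            continue
        xp = np.linspace(0, 1, bvals.size) if bvals.size > 1 else np.array([0.5])
        body.append(np.interp(np.linspace(0, 1, body_positions), xp, bvals))
        uw = np.full(half, np.nan)
        lo = s_bin - half
        s = max(0, lo)
        uw[s - lo: s - lo + (min(s_bin, len(vals)) - s)] = vals[s:min(s_bin, len(vals))]
        up.append(uw)
        dw = np.full(half, np.nan)
        e = min(len(vals), e_bin + half)
        dw[: e - min(e_bin, len(vals))] = vals[min(e_bin, len(vals)):e]
        down.append(dw)
    up_m = np.nanmean(np.vstack(up), axis=0)
    body_m = np.nanmean(np.vstack(body), axis=0)
    down_m = np.nanmean(np.vstack(down), axis=0)
    return {"upstream": up_m, "body": body_m, "downstream": down_m,
            "body_mean": float(np.nanmean(body_m)),
            "upstream_mean": float(np.nanmean(up_m)),
            "downstream_mean": float(np.nanmean(down_m)),
            "n_features": len(body)}


def peak_methylation_profile(meth_tracks: dict[str, StepTrack],
                             peaks: pd.DataFrame, flank: int = 2000) -> dict:
    """Per-context (CG/CHG/CHH) meta-profile around peak bodies."""
    return {ctx: peak_metaprofile(tr, peaks, flank)
            for ctx, tr in meth_tracks.items()}


def promoter_acr_expression(genes: pd.DataFrame, promoter_acrs: pd.DataFrame,
                            expression: pd.DataFrame,
                            upstream: int = PROMOTER_UPSTREAM,
                            chrom_sizes: dict[str, int] | None = None) -> dict:
    """Expression contrast between genes with and without a promoter ACR.

    A gene "has" a promoter ACR when its promoter window overlaps >= 1 bp
    of a promoter-classified ATAC peak.  Two-sided Wilcoxon rank-sum.
    """
    windows = iv.promoter_windows(genes, upstream, chrom_sizes)
    has = iv.flag_overlaps(windows, promoter_acrs)
    expr = genes[["gene_id"]].merge(expression, on="gene_id", how="left")
    x = expr.loc[has, "expression"].dropna()
    y = expr.loc[~has, "expression"].dropna()
    if len(x) == 0 or len(y) == 0:
        return {"median_with": np.nan, "median_without": np.nan,
                "p_value": np.nan, "defined": False}
    stat = mannwhitneyu(x, y, alternative="two-sided")
    return {"median_with": float(x.median()), "median_without": float(y.median()),
            "n_with": len(x), "n_without": len(y),
            "p_value": float(stat.pvalue), "defined": True}


def differential_accessibility(depth1: StepTrack, depth2: StepTrack,
                               peaks: pd.DataFrame, pseudocount: float = 0.5,
                               lfc_threshold: float = 1.0,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample differential accessibility over a fixed peak set.

    Per-peak read totals are scaled to counts-per-million; peaks with
    |log2 CPM ratio| >= ``lfc_threshold`` and a significant two-sided
    rate test (binomial conditional on the summed count, success
    probability = library-size share) are flagged differential.
    """
    lib1, lib2 = depth1.total(), depth2.total()
    if lib1 <= 0 or lib2 <= 0:
        raise ValueError("zero library size")
    rows = []
    p0 = lib1 / (lib1 + lib2)
    for row in peaks.itertuples(index=False):
        c1 = _peak_count(depth1, row)
        c2 = _peak_count(depth2, row)
        cpm1 = c1 / lib1 * 1e6
        cpm2 = c2 / lib2 * 1e6
        lfc = np.log2((cpm1 + pseudocount) / (cpm2 + pseudocount))
        n = int(round(c1 + c2))
        pval = binomtest(int(round(c1)), n, p0).pvalue if n > 0 else 1.0
        rows.append((row.chrom, row.start, row.end, c1, c2, lfc, pval))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count1",
                                     "count2", "log2_ratio", "p_value"])
    df["differential"] = (df["log2_ratio"].abs() >= lfc_threshold) & \
                         (df["p_value"] < alpha)
    return df


def _peak_count(depth: StepTrack, row) -> float:
    vals = depth.values.get(row.chrom)
    if vals is None:
        return 0.0
    s, e = row.start // depth.step, -(-row.end // depth.step)
    return float(vals[max(0, s):min(len(vals), e)].sum())
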