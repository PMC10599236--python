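"""Synthetic genome generator with planted 3D-chromatin ground truth.

Generates a small multi-chromosome genome together with every input the
pipeline consumes — binned Hi-C contacts, gene models, ATAC / H3K27ac
peaks and read-depth tracks, per-context methylation, expression, SNPs —
with the statistical structure the analysis assumes planted by
construction:

* telomeric A compartments / pericentromeric B compartments expressed as
  a contact plaid and as coordinated track contrasts (genes, CHH, ATAC,
  H3K27ac high in A; GC, LTR, CG, CHG high in B);
* TAD blocks with elevated within-domain contact;
* focal loop pixels (3x3 neighborhoods) at hub genes and isolated sites,
  giving a planted loops-per-gene gradient that drives expression;
* promoter ACRs on a configurable fraction of genes (with an expression
  bonus), distal enhancers with a fixed planted active fraction, and a
  designated gene carrying two sample-specific differential ATAC peaks;
* SNPs enriched inside promoter/enhancer elements by a planted factor.

Every output layer draws from its own RNG stream (seed + layer index),
so adding a layer never perturbs the others, and a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .contacts import ContactMatrix
from .io import StepTrack

DEPTH_STEP = 100
METH_STEP = 200
GENE_LENGTH = 2000
ACTIVE_ENHANCER_PERIOD = 4  # every 4th enhancer gets an ATAC peak => 25% active


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 5_000_000
    bin_size_bp: int = 25_000
    decay_exponent: float = 0.7
    plaid_amplitude: float = 0.3
    tad_contrast: float = 1.5
    loop_strength: float = 3.0
    coverage_scale: float = 50.0
    n_genes: int = 400
    promoter_acr_fraction: float = 0.5
    snp_enrichment_factor: float = 20.0
    rng_seed: int = 0
    # secondary knobs (defaults are the study conditions; see docs/methods.md)
    n_snps: int = 2500
    n_enhancers_per_chrom: int = 40
    gene_weight_a: float = 5.0
    gene_weight_b: float = 1.0
    loop_count_classes: tuple = (6, 4, 3)  # loops per hub gene, per chromosome
    expression_loop_beta: float = 1.2
    expression_promoter_beta: float = 0.7
    expression_noise_sd: float = 0.3

    def __post_init__(self):
        if self.chrom_length_bp % self.bin_size_bp:
            raise ConfigError("chrom_length_bp must be divisible by bin_size_bp")
        if not (0 <= self.plaid_amplitude < 1):
            raise ConfigError("plaid_amplitude must be in [0, 1)")
        if self.tad_contrast < 1:
            raise ConfigError("tad_contrast must be >= 1")
        if self.loop_strength < 1:
            raise ConfigError("loop_strength must be >= 1")
        if self.coverage_scale <= 0:
            raise ConfigError("coverage_scale must be positive")
        if not (0 <= self.promoter_acr_fraction <= 1):
            raise ConfigError("promoter_acr_fraction must be in [0, 1]")
        if self.snp_enrichment_factor < 1:
            raise ConfigError("snp_enrichment_factor must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.chrom_length_bp // self.bin_size_bp

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


@dataclass
class SyntheticTruth:
    """Planted ground truth, the oracle for recovery tests."""

    compartment_labels: dict[str, np.ndarray]
    tad_boundaries: dict[str, list[int]]
    loop_pixels: dict[str, list[tuple[int, int]]]
    hub_genes: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    differential_gene: str | None = None
    differential_peaks: list[tuple[str, int, int]] = field(default_factory=list)
    enhancer_gene_links: list[tuple[int, str]] = field(default_factory=list)
    snp_in_element_flags: np.ndarray | None = None
    loops_per_gene: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=conv, indent=1)


# ------------------------------------------------------------ structural truth

def _compartment_layout(n_bins: int) -> np.ndarray:
    """Deterministic telomeric-A / pericentromeric-B layout."""
    labels = np.full(n_bins, "B", dtype=object)
    arm = max(1, int(round(0.2 * n_bins)))
    labels[:arm] = "A"
    labels[n_bins - arm:] = "A"
    return labels


def _tad_layout(n_bins: int, rng: np.random.Generator,
                forbidden: set[int] = frozenset()) -> list[int]:
    """Boundary positions every ~20 bins with jitter; bins whose
    insulation diamond would intersect a planted loop block are skipped
    so every planted structure stays recoverable."""
    margin = 8 if n_bins >= 40 else max(2, n_bins // 5)
    bounds = []
    b = margin + int(rng.integers(0, 4))
    while b < n_bins - margin:
        bb = b
        while bb in forbidden and bb < n_bins - margin:
            bb += 1
        if bb < n_bins - margin and (not bounds or bb - bounds[-1] >= 10):
            bounds.append(bb)
        b += 18 + int(rng.integers(0, 5))
    return bounds


def _boundary_exclusion(pixels: list[tuple[int, int]],
                        window: int = 5) -> set[int]:
    """Bins whose w-bin insulation diamond overlaps a 3x3 loop block."""
    forbidden: set[int] = set()
    for i, j in pixels:
        if j - i <= 2 * (window + 1):
            forbidden.update(range(max(i, j - window - 1), min(i + window + 1, j) + 1))
    return forbidden


def _loop_layout(n_bins: int, classes: tuple) -> tuple[list[tuple[int, int]],
                                                       list[int],
                                                       list[tuple[int, int]]]:
    """Planted loop pixels: hub fans plus isolated singles.

    Returns (pixels, hub_bins, single_pixels).  All pixels are pairwise
    >= 4 apart in Chebyshev distance so their 3x3 neighborhoods stay
    separable, and >= 6 bins from the matrix edge.
    """
    if n_bins < 100:
        return [], [], []
    pixels: list[tuple[int, int]] = []
    hub_bins: list[int] = []
    # hubs sit so each fan (up to +/-24 bins) stays inside one compartment
    # block; a fan crossing the A/B transition would put loop pixels in
    # mixed donut backgrounds and make them unrecoverable by design
    hub_positions = [int(0.35 * n_bins), int(0.5 * n_bins), int(0.88 * n_bins)]
    # hub fans alternate row/column sides with 8-bin within-side spacing so
    # no planted 3x3 block falls inside another pixel's donut stripes
    fan = [("row", 4), ("col", 8), ("row", 12), ("col", 16), ("row", 20),
           ("col", 24)]
    for h, n_loops in zip(hub_positions, classes):
        hub_bins.append(h)
        got = 0
        for side, d in fan:
            if got >= n_loops:
                break
            if side == "row" and h + d <= n_bins - 7:
                pixels.append((h, h + d))
                got += 1
            elif side == "col" and h - d >= 6:
                pixels.append((h - d, h))
                got += 1
    single_layout = [(0.05, 9), (0.25, 4), (0.28, 8), (0.37, 12), (0.40, 16),
                     (0.475, 11), (0.55, 7), (0.60, 6), (0.63, 9), (0.66, 10),
                     (0.72, 14), (0.82, 6)]
    singles = []
    for f, d in single_layout:
        i = int(f * n_bins)
        j = i + d
        if not (6 <= i and j <= n_bins - 7):
            continue
        cand = (i, j)
        if all(max(abs(i - pi), abs(j - pj)) >= 4 for pi, pj in pixels):
            pixels.append(cand)
            singles.append(cand)
    return pixels, hub_bins, singles


def plant_truth(config: SyntheticConfig) -> SyntheticTruth:
    labels = {}
    bounds = {}
    loops = {}
    hubs = {}
    rng = np.random.default_rng(config.rng_seed + 1)
    for chrom in config.chrom_names:
        n = config.n_bins
        labels[chrom] = _compartment_layout(n)
        px, hb, _ = _loop_layout(n, config.loop_count_classes)
        bounds[chrom] = _tad_layout(n, rng, _boundary_exclusion(px))
        loops[chrom] = px
        hubs[chrom] = [(h, cnt) for h, cnt in zip(hb, config.loop_count_classes)]
    return SyntheticTruth(labels, bounds, loops, hub_genes=hubs)


# ------------------------------------------------------------------- contacts

def simulate_contacts(truth: SyntheticTruth, config: SyntheticConfig
                      ) -> dict[str, ContactMatrix]:
    """Poisson contact matrices with decay x plaid x TAD x loop structure.

    E[i,j] = coverage * (1+|i-j|)^-alpha * c_plaid * t_tad * l_loop with
    c = 1 +/- plaid_amplitude by compartment agreement, t = tad_contrast
    within a planted TAD, and l = loop_strength on the 3x3 neighborhood
    of each planted pixel.  Drawn independently on the upper triangle
    and mirrored, so the result is exactly symmetric.
    """
    if config.coverage_scale <= 0:
        raise ConfigError("coverage_scale must be positive")
    rng = np.random.default_rng(config.rng_seed + 2)
    out = {}
    n = config.n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    decay = (1.0 + d) ** (-config.decay_exponent)
    for chrom in config.chrom_names:
        labs = truth.compartment_labels[chrom]
        if labs.shape[0] != n:
            raise ConfigError("truth dimensions inconsistent with config")
        same = np.equal.outer(labs, labs)
        plaid = np.where(same, 1 + config.plaid_amplitude,
                         1 - config.plaid_amplitude)
        tad_id = np.zeros(n, dtype=int)
        for k, b in enumerate(truth.tad_boundaries[chrom]):
            tad_id[b:] = k + 1
        tad = np.where(np.equal.outer(tad_id, tad_id) & (d > 0),
                       config.tad_contrast, 1.0)
        np.fill_diagonal(tad, 1.0)
        loop = np.ones((n, n))
        for (i, j) in truth.loop_pixels[chrom]:
            loop[max(0, i - 1):i + 2, max(0, j - 1):j + 2] = config.loop_strength
            loop[max(0, j - 1):j + 2, max(0, i - 1):i + 2] = config.loop_strength
        e = config.coverage_scale * decay * plaid * tad * loop
        upper = np.triu(rng.poisson(e))
        counts = upper + np.triu(upper, 1).T
        out[chrom] = ContactMatrix(chrom, config.bin_size_bp,
                                   counts.astype(float))
    return out


# --------------------------------------------------------------------- genome

@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame
    gene_density: dict[str, np.ndarray]
    gc: dict[str, np.ndarray]
    ltr: dict[str, np.ndarray]


def _quota_allocation(weights: np.ndarray, total: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items over weights.

    Ties among equal remainders are broken by a seeded shuffle so that
    leftover items spread evenly instead of piling onto low-index bins.
    """
    if total == 0 or weights.sum() == 0:
        return np.zeros(weights.size, dtype=int)
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    perm = (rng.permutation(weights.size) if rng is not None
            else np.arange(weights.size))
    order = perm[np.argsort(-(exact - base)[perm], kind="stable")]
    base[order[:rem]] += 1
    return base


def make_genome(config: SyntheticConfig, truth: SyntheticTruth | None = None
                ) -> tuple[Genome, SyntheticTruth]:
    """Gene models and per-bin annotation tracks with compartment
    contrasts planted by construction (genes rich in A, GC/LTR rich
    in B)."""
    if truth is None:
        truth = plant_truth(config)
    rng = np.random.default_rng(config.rng_seed + 0)
    n = config.n_bins
    bs = config.bin_size_bp
    rows = []
    gid = 0

    # background genes: deterministic per-bin quota by compartment weight
    weights = np.concatenate([
        np.where(truth.compartment_labels[c] == "A",
                 config.gene_weight_a, config.gene_weight_b)
        for c in config.chrom_names])
    # keep the differential gene's neighborhood free of background genes:
    # a bystander promoter peak or TSS signal there would dilute the
    # planted accessibility ratio
    if n >= 100:
        b_diff = int(0.93 * n)
        weights[max(0, b_diff - 1): b_diff + 2] = 0.0
    quota = _quota_allocation(weights, config.n_genes, rng)
    max_slots = max(1, bs // (GENE_LENGTH + 1000))
    for ci, chrom in enumerate(config.chrom_names):
        for b in range(n):
            k = min(int(quota[ci * n + b]), max_slots)
            if k == 0:
                continue
            slots = rng.permutation(max_slots)[:k]
            for s in sorted(slots):
                start = b * bs + 500 + int(s) * (GENE_LENGTH + 1000)
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"gene{gid:05d}", chrom, start,
                             start + GENE_LENGTH, strand, "background"))
                gid += 1

    # hub genes at planted loop anchor bins (multi-loop gene classes);
    # two satellite genes share each hub bin so every loop-count class
    # holds several genes and its expression median is stable
    for chrom in config.chrom_names:
        for h, cnt in truth.hub_genes.get(chrom, []):
            start = h * bs + (bs - GENE_LENGTH) // 2
            rows.append((f"hub_{chrom}_{h}", chrom, start,
                         start + GENE_LENGTH, "+", "hub"))
            for k, off in enumerate((1500, bs - GENE_LENGTH - 1500)):
                rows.append((f"hubsat{k}_{chrom}_{h}", chrom, h * bs + off,
                             h * bs + off + GENE_LENGTH, "+", "hub"))

    # designated differential-accessibility gene (telomeric A arm, chr1)
    diff_id = None
    if n >= 100:
        chrom = config.chrom_names[0]
        b_diff = int(0.93 * n)
        start = b_diff * bs + 8000
        diff_id = "gene_diff"
        rows.append((diff_id, chrom, start, start + GENE_LENGTH, "+",
                     "differential"))

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand", "origin"])
    genes = genes.sort_values(["chrom", "start"], ignore_index=True)
    truth.differential_gene = diff_id

    density, gc, ltr = {}, {}, {}
    for chrom in config.chrom_names:
        sub = genes[genes["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2) // bs
        density[chrom] = np.bincount(mids.astype(int), minlength=n).astype(float)
        a_mask = truth.compartment_labels[chrom] == "A"
        gc[chrom] = np.where(a_mask, 0.38, 0.45) + rng.normal(0, 0.005, n)
        ltr[chrom] = np.clip(np.where(a_mask, 0.2, 0.7)
                             + rng.normal(0, 0.05, n), 0, 1)
    genome = Genome(config.chrom_sizes, genes, density, gc, ltr)
    return genome, truth


# ---------------------------------------------------------- functional layers

@dataclass
class FunctionalLayers:
    atac_peaks_s1: pd.DataFrame
    atac_peaks_s2: pd.DataFrame
    h3k27ac_peaks: pd.DataFrame
    atac_depth_s1: StepTrack
    atac_depth_s2: StepTrack
    h3k27ac_depth: StepTrack
    methylation: dict[str, StepTrack]
    expression: pd.DataFrame
    snps: pd.DataFrame


def _intergenic_gaps(genes: pd.DataFrame, chrom: str, length: int,
                     upstream: int = 3000, min_gap: int = 4000) -> list[tuple[int, int]]:
    """Gaps free of gene bodies and promoter windows."""
    from . import intervals as iv
    occ = [(max(0, s - upstream), min(length, e + upstream))
           for s, e in zip(genes.loc[genes["chrom"] == chrom, "start"],
                           genes.loc[genes["chrom"] == chrom, "end"])]
    occ.sort()
    gaps, cur = [], 0
    for s, e in occ:
        if s - cur >= min_gap:
            gaps.append((cur, s))
        cur = max(cur, e)
    if length - cur >= min_gap:
        gaps.append((cur, length))
    return gaps


def _add_rect(track: StepTrack, chrom: str, start: int, end: int,
              height: float) -> None:
    v = track.values[chrom]
    v[start // track.step: -(-end // track.step)] += height


def _add_bump(track: StepTrack, chrom: str, center: int, height: float,
              sigma: float) -> None:
    v = track.values[chrom]
    c = center / track.step
    lo = max(0, int(c - 4 * sigma / track.step))
    hi = min(len(v), int(c + 4 * sigma / track.step) + 1)
    x = np.arange(lo, hi)
    v[lo:hi] += height * np.exp(-0.5 * ((x - c) * track.step / sigma) ** 2)


def _planted_loops_frame(truth: SyntheticTruth, config: SyntheticConfig
                         ) -> pd.DataFrame:
    rows = []
    bs = config.bin_size_bp
    for chrom, pxs in truth.loop_pixels.items():
        for i, j in pxs:
            rows.append((chrom, i, j, i * bs, (i + 1) * bs, j * bs, (j + 1) * bs))
    return pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j",
                                       "anchor1_start", "anchor1_end",
                                       "anchor2_start", "anchor2_end"])


def simulate_functional_layers(truth: SyntheticTruth, genome: Genome,
                               config: SyntheticConfig) -> FunctionalLayers:
    """Peaks, depth and methylation tracks, expression and SNPs.

    Raises ConfigError when more enhancers are requested than the
    intergenic space can hold.
    """
    from . import intervals as iv
    from .loops import loops_per_gene

    genes = genome.genes
    sizes = config.chrom_sizes
    rng_peaks = np.random.default_rng(config.rng_seed + 3)
    rng_meth = np.random.default_rng(config.rng_seed + 4)
    rng_depth = np.random.default_rng(config.rng_seed + 5)
    rng_expr = np.random.default_rng(config.rng_seed + 6)
    rng_snp = np.random.default_rng(config.rng_seed + 7)

    # ---- ATAC peaks -------------------------------------------------------
    atac_rows = []  # (chrom, start, end, name, height_s1, height_s2)
    prom_flags = rng_peaks.random(len(genes)) < config.promoter_acr_fraction
    for has_prom, row in zip(prom_flags, genes.itertuples(index=False)):
        if not has_prom:
            continue
        if row.strand == "-":
            s, e = row.end + 300, row.end + 900
        else:
            s, e = row.start - 900, row.start - 300
        if s < 0 or e > sizes[row.chrom]:
            continue
        atac_rows.append((row.chrom, s, e, f"prom_{row.gene_id}", 15.0, 15.0))

    # gene-body ACRs on a subset of genes without promoter peaks
    body_genes = genes[~prom_flags]
    body_pick = rng_peaks.random(len(body_genes)) < 0.25
    for row in body_genes[body_pick].itertuples(index=False):
        mid = (row.start + row.end) // 2
        atac_rows.append((row.chrom, mid - 300, mid + 300,
                          f"body_{row.gene_id}", 12.0, 12.0))

    # ---- enhancers (H3K27ac distal) and distal ATAC -----------------------
    h3k_rows = []
    enhancer_regions = []
    for chrom in config.chrom_names:
        gaps = _intergenic_gaps(genes, chrom, sizes[chrom])
        if len(gaps) < 1:
            raise ConfigError(f"no intergenic space on {chrom}")
        want = config.n_enhancers_per_chrom
        placed = 0
        gi = 0
        positions = []
        while placed < want and gi < 10 * want:
            gap = gaps[gi % len(gaps)]
            gi += 1
            width = int(rng_peaks.integers(1200, 2400))
            span = gap[1] - gap[0]
            if span < width + 400:
                continue
            # pack several enhancers into long gaps, left to right
            off = (gi // len(gaps)) * (width + 2500)
            s = gap[0] + 200 + off
            e = s + width
            if e + 200 > gap[1]:
                continue
            if positions and any(c == chrom and s < pe + 500 and e > ps - 500
                                 for c, ps, pe in positions):
                continue
            positions.append((chrom, s, e))
            h3k_rows.append((chrom, s, e, f"enh_{chrom}_{placed}"))
            enhancer_regions.append((chrom, s, e))
            if placed % ACTIVE_ENHANCER_PERIOD == 0:
                mid = (s + e) // 2
                atac_rows.append((chrom, mid - 250, mid + 250,
                                  f"distal_{chrom}_{placed}", 14.0, 14.0))
            placed += 1
        if placed < want:
            raise ConfigError(
                f"cannot place {want} enhancers on {chrom}: intergenic space"
                " exhausted")

    # H3K27ac promoter peaks on a subset of genes
    h3k_prom = rng_peaks.random(len(genes)) < 0.3
    for row in genes[h3k_prom].itertuples(index=False):
        tss = row.start if row.strand != "-" else row.end - 1
        s = max(0, tss - 500)
        e = min(sizes[row.chrom], tss + 700)
        h3k_rows.append((row.chrom, s, e, f"k27prom_{row.gene_id}"))

    # ---- differential peaks at the designated gene ------------------------
    diff_peaks = []
    if truth.differential_gene is not None:
        g = genes[genes["gene_id"] == truth.differential_gene].iloc[0]
        # body peak sits in the 3' half of the gene, clear of the TSS
        # accessibility bump shared by both samples
        body = (g["chrom"], int(g["start"]) + 1200, int(g["start"]) + 1800)
        up = (g["chrom"], int(g["start"]) - 1500, int(g["start"]) - 900)
        for k, (chrom, s, e) in enumerate((body, up)):
            atac_rows.append((chrom, s, e, f"diff_{k}", 20.0, 5.0))
            diff_peaks.append((chrom, s, e))
    truth.differential_peaks = diff_peaks

    atac = pd.DataFrame(atac_rows, columns=["chrom", "start", "end", "name",
                                            "h1", "h2"])
    atac = atac.sort_values(["chrom", "start"], ignore_index=True)
    atac_s1 = atac[["chrom", "start", "end", "name"]].copy()
    atac_s1["score"] = atac["h1"]
    atac_s1["strand"] = "."
    keep2 = ~atac["name"].str.startswith("diff_")
    atac_s2 = atac_s1[keep2].reset_index(drop=True)
    h3k = pd.DataFrame(h3k_rows, columns=["chrom", "start", "end", "name"])
    h3k = h3k.sort_values(["chrom", "start"], ignore_index=True)
    h3k["score"] = 10.0
    h3k["strand"] = "."

    # ---- depth tracks -----------------------------------------------------
    def blank(step):
        return StepTrack(step, {c: np.zeros(sizes[c] // step)
                                for c in config.chrom_names})

    atac_d1, atac_d2, h3k_d = blank(DEPTH_STEP), blank(DEPTH_STEP), blank(DEPTH_STEP)
    for row in atac.itertuples(index=False):
        _add_rect(atac_d1, row.chrom, row.start, row.end, row.h1)
        _add_rect(atac_d2, row.chrom, row.start, row.end, row.h2)
    for row in h3k.itertuples(index=False):
        _add_rect(h3k_d, row.chrom, row.start, row.end, 10.0)
    for row in genes.itertuples(index=False):
        tss = row.start if row.strand != "-" else row.end - 1
        _add_bump(atac_d1, row.chrom, tss, 8.0, 300.0)
        _add_bump(atac_d2, row.chrom, tss, 8.0, 300.0)
        _add_bump(h3k_d, row.chrom, tss, 5.0, 300.0)
    scale = config.coverage_scale / 50.0
    for tr, lam in ((atac_d1, 2.0), (atac_d2, 2.0), (h3k_d, 1.5)):
        for c in tr.values:
            tr.values[c] = rng_depth.poisson((tr.values[c] + lam) * scale
                                             ).astype(float)

    # ---- methylation ------------------------------------------------------
    meth_mu = {"CG": {"A": 0.55, "B": 0.80},
               "CHG": {"A": 0.35, "B": 0.65},
               "CHH": {"A": 0.22, "B": 0.08}}
    all_peaks = pd.concat([atac_s1[["chrom", "start", "end"]],
                           h3k[["chrom", "start", "end"]]], ignore_index=True)
    peak_trees = iv.build_trees(all_peaks)
    nu = 30.0
    meth = {}
    for ctx, mus in meth_mu.items():
        tr = blank(METH_STEP)
        for chrom in config.chrom_names:
            npos = sizes[chrom] // METH_STEP
            pos_bin = (np.arange(npos) * METH_STEP) // config.bin_size_bp
            labs = truth.compartment_labels[chrom][pos_bin]
            mu = np.where(labs == "A", mus["A"], mus["B"])
            in_peak = np.zeros(npos, dtype=bool)
            t = peak_trees.get(chrom)
            if t is not None:
                for ivl in t:
                    in_peak[ivl.begin // METH_STEP: -(-ivl.end // METH_STEP)] = True
            mu = np.where(in_peak, mu * 0.3, mu)
            tr.values[chrom] = rng_meth.beta(mu * nu, (1 - mu) * nu)
        meth[ctx] = tr

    # ---- expression -------------------------------------------------------
    planted_loops = _planted_loops_frame(truth, config)
    lpg = loops_per_gene(planted_loops, genes)
    n_loops = lpg["n_loops"].to_numpy()
    log_tpm = (1.0 + config.expression_loop_beta * np.log1p(n_loops)
               + config.expression_promoter_beta * prom_flags.astype(float)
               + rng_expr.normal(0, config.expression_noise_sd, len(genes)))
    expression = pd.DataFrame({"gene_id": genes["gene_id"],
                               "expression": np.exp(log_tpm)})
    truth.loops_per_gene = dict(zip(lpg["gene_id"], (int(x) for x in n_loops)))

    # ---- enhancer-gene link truth ----------------------------------------
    from .elements import link_enhancer_genes
    enh_df = pd.DataFrame(enhancer_regions, columns=["chrom", "start", "end"])
    res = link_enhancer_genes(enh_df, planted_loops, genes,
                              chrom_sizes=sizes)
    truth.enhancer_gene_links = [(int(r.enhancer_idx), r.gene_id)
                                 for r in res["links"].itertuples(index=False)]

    # ---- SNPs: planted in-element rate enrichment -------------------------
    prom_elements = atac_s1[atac_s1["name"].str.startswith("prom_")]
    elements = pd.concat([prom_elements[["chrom", "start", "end"]], enh_df],
                         ignore_index=True)
    merged = iv.merge_intervals(elements)
    L = float((merged["end"] - merged["start"]).sum())
    G = float(sum(sizes.values()))
    p_in = config.snp_enrichment_factor * L / G
    if p_in >= 1:
        raise ConfigError("snp_enrichment_factor x element fraction >= 1")
    seg_len = (merged["end"] - merged["start"]).to_numpy()
    seg_cum = np.concatenate([[0], np.cumsum(seg_len)])
    chrom_names = list(sizes)
    chrom_offsets = np.concatenate([[0], np.cumsum([sizes[c] for c in chrom_names])])
    snp_rows = []
    flags = np.zeros(config.n_snps, dtype=bool)
    merged_trees = iv.build_trees(merged)
    for k in range(config.n_snps):
        if rng_snp.random() < p_in:
            u = rng_snp.random() * seg_cum[-1]
            si = int(np.searchsorted(seg_cum, u, side="right")) - 1
            off = int(u - seg_cum[si])
            chrom = merged.loc[si, "chrom"]
            pos0 = int(merged.loc[si, "start"]) + off
            flags[k] = True
        else:
            while True:
                u = rng_snp.random() * G
                ci = int(np.searchsorted(chrom_offsets, u, side="right")) - 1
                chrom = chrom_names[ci]
                pos0 = int(u - chrom_offsets[ci])
                if not iv.overlaps_any(merged_trees, chrom, pos0, pos0 + 1):
                    break
        snp_rows.append((chrom, pos0 + 1, f"snp{k:05d}", "metabolite"))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos_1based", "id", "tag"])
    truth.snp_in_element_flags = flags

    return FunctionalLayers(atac_s1, atac_s2, h3k, atac_d1, atac_d2, h3k_d,
                            meth, expression, snps)


# ------------------------------------------------------------------- dataset

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    genome: Genome
    contacts: dict[str, ContactMatrix]
    layers: FunctionalLayers


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator layers in order."""
    truth = plant_truth(config)
    genome, truth = make_genome(config, truth)
    mats = simulate_contacts(truth, config)
    layers = simulate_functional_layers(truth, genome, config)
    return SyntheticDataset(config, truth, genome, mats, layers)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write every input file the pipeline consumes, plus truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = ds.config.chrom_sizes
    cio.write_chrom_sizes(sizes, out / "chrom.sizes")
    cio.write_gff3_genes(ds.genome.genes, out / "genes.gff3")
    cio.write_bed(ds.layers.atac_peaks_s1, out / "atac_sample1.bed")
    cio.write_bed(ds.layers.atac_peaks_s2, out / "atac_sample2.bed")
    cio.write_bed(ds.layers.h3k27ac_peaks, out / "h3k27ac.bed")
    for chrom, m in ds.contacts.items():
        cio.write_coo(m.counts, out / f"contacts.{chrom}.coo")
    for ctx, tr in ds.layers.methylation.items():
        cio.write_bedgraph(tr, sizes, out / f"meth_{ctx}.bedGraph")
    cio.write_bedgraph(ds.layers.atac_depth_s1, sizes, out / "atac_depth_sample1.bedGraph")
    cio.write_bedgraph(ds.layers.atac_depth_s2, sizes, out / "atac_depth_sample2.bedGraph")
    cio.write_bedgraph(ds.layers.h3k27ac_depth, sizes, out / "h3k27ac_depth.bedGraph")
    bin_tracks = StepTrack(ds.config.bin_size_bp, ds.genome.gene_density)
    cio.write_bedgraph(bin_tracks, sizes, out / "gene_density.bedGraph")
    cio.write_bedgraph(StepTrack(ds.config.bin_size_bp, ds.genome.gc), sizes,
                       out / "gc.bedGraph")
    cio.write_bedgraph(StepTrack(ds.config.bin_size_bp, ds.genome.ltr), sizes,
                       out / "ltr.bedGraph")
    ds.layers.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    ds.layers.snps.to_csv(out / "snps.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(ds.truth.to_json())
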