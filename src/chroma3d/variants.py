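"""SNP-to-element intersection and per-class SNP density.

SNP positions are 1-based; elements are 0-based half-open, so a SNP at
position ``p`` lies inside ``[s, e)`` iff ``s <= p-1 < e``.  Class
density is SNPs per kb of *merged* element length (overlapping elements
collapse before length summation), and enrichment is the ratio to the
genome-wide density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv


def intersect_snps(snps: pd.DataFrame, elements: pd.DataFrame,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-SNP element assignments (one row per SNP-element hit; SNPs in
    no element are absent from the result)."""
    if chrom_sizes is not None:
        for row in snps.itertuples(index=False):
            L = chrom_sizes.get(row.chrom)
            if L is not None and not (1 <= row.pos_1based <= L):
                raise ValueError(
                    f"SNP {row.id} at {row.chrom}:{row.pos_1based} outside "
                    f"chromosome of length {L}")
    trees = iv.build_trees(elements)
    rows = []
    for row in snps.itertuples(index=False):
        p0 = row.pos_1based - 1
        for e_idx in iv.overlapping_indices(trees, row.chrom, p0, p0 + 1):
            rows.append((row.id, row.chrom, row.pos_1based, e_idx))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_1based",
                                       "element_idx"])


@dataclass
class SnpDensityReport:
    class_name: str
    n_snps: int
    n_elements_hit: int
    total_element_kb: float
    density_snps_per_kb: float
    genomewide_density: float
    enrichment: float


def snp_density(assignments: pd.DataFrame, elements: pd.DataFrame,
                class_name: str, genome_length_bp: int,
                n_total_snps: int) -> SnpDensityReport:
    """Density and genome-wide enrichment for one element class.

    ``assignments`` is the output of :func:`intersect_snps` against the
    same ``elements`` table.  A SNP hitting two overlapping elements is
    still one SNP; merged length prevents double-counted kilobases.
    """
    merged_kb = iv.total_length(elements) / 1000.0
    genomewide = n_total_snps / (genome_length_bp / 1000.0)
    if merged_kb == 0:
        return SnpDensityReport(class_name, 0, 0, 0.0, float("nan"),
                                genomewide, float("nan"))
    n_snps = int(assignments["snp_id"].nunique()) if len(assignments) else 0
    n_hit = int(assignments["element_idx"].nunique()) if len(assignments) else 0
    dens = n_snps / merged_kb
    return SnpDensityReport(class_name, n_snps, n_hit, merged_kb, dens,
                            genomewide, dens / genomewide)


def density_report(snps: pd.DataFrame, element_classes: dict[str, pd.DataFrame],
                   genome_length_bp: int,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """SnpDensityReport rows for several element classes at once."""
    out = []
    for name, els in element_classes.items():
        asg = intersect_snps(snps, els.reset_index(drop=True), chrom_sizes)
        rep = snp_density(asg, els, name, genome_length_bp, len(snps))
        out.append(rep.__dict__)
    return pd.DataFrame(out)
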