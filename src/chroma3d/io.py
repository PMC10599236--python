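"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: chrom.sizes, upper-triangle COO contact text, GFF3 gene models,
BED6 peak files, fixed-step bedGraph tracks, and simple TSV tables
(expression, SNPs).  Coordinates follow the usual conventions: BED and
bedGraph are 0-based half-open, GFF3 is 1-based inclusive, SNP tables
carry 1-based positions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- chrom.sizes

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'name<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ------------------------------------------------------------------ COO text

def read_coo(path, n_bins: int) -> np.ndarray:
    """Read an upper-triangle (i <= j) COO text file into a dense
    symmetric matrix.  Duplicate pixels are summed; absent pixels are 0.
    """
    m = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 'i j count'")
            i, j = int(parts[0]), int(parts[1])
            c = float(parts[2])
            if i > j:
                raise FormatError(f"{path}:{ln}: lower-triangle entry i={i} > j={j}")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise FormatError(
                    f"{path}:{ln}: bin index out of range for {n_bins} bins: {line.strip()!r}")
            if c < 0:
                raise FormatError(f"{path}:{ln}: negative count {c}")
            m[i, j] += c
            if i != j:
                m[j, i] += c
    return m


def write_coo(matrix: np.ndarray, path) -> None:
    iu, ju = np.triu_indices_from(matrix)
    vals = matrix[iu, ju]
    keep = vals != 0
    with open(path, "w") as fh:
        for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
            fh.write(f"{i}\t{j}\t{v:.0f}\n" if float(v).is_integer()
                     else f"{i}\t{j}\t{v}\n")


# --------------------------------------------------------------------- GFF3

def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records from a GFF3 file as a 0-based half-open table."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        rows.append((gid, g.seqid, g.start - 1, g.end, g.strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\tchroma3d\tgene\t{row.start + 1}\t{row.end}\t.\t"
                     f"{row.strand}\t.\tID={row.gene_id}\n")


# ---------------------------------------------------------------------- BED

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


# ----------------------------------------------------------------- bedGraph

@dataclass
class StepTrack:
    """A fixed-step numeric track, one value per ``step``-bp window.

    The in-memory carrier for read-depth and methylation signal; also
    used for per-bin annotation tracks (gene density, GC, LTR) where
    step equals the Hi-C bin size.
    """

    step: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def aggregate(self, bin_size: int, n_bins: dict[str, int]) -> "StepTrack":
        """Mean-pool to a coarser step (bin_size must be a multiple)."""
        if bin_size % self.step:
            raise ValueError("bin_size must be a multiple of track step")
        k = bin_size // self.step
        out: dict[str, np.ndarray] = {}
        for chrom, v in self.values.items():
            nb = n_bins[chrom]
            pad = nb * k - len(v)
            vv = np.pad(v.astype(float), (0, max(0, pad)), constant_values=np.nan)
            out[chrom] = np.nanmean(vv[: nb * k].reshape(nb, k), axis=1)
        return StepTrack(bin_size, out)


def read_bedgraph(path, chrom_sizes: dict[str, int], step: int) -> StepTrack:
    tr = StepTrack(step, {c: np.zeros(-(-L // step)) for c, L in chrom_sizes.items()})
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    for row in df.itertuples(index=False):
        v = tr.values.get(row.chrom)
        if v is None:
            raise FormatError(f"{path}: unknown chromosome {row.chrom!r}")
        v[row.start // step: -(-row.end // step)] = row.value
    return tr


def write_bedgraph(track: StepTrack, chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            L = chrom_sizes[chrom]
            for k, v in enumerate(vals):
                s = k * track.step
                if s >= L:
                    break
                fh.write(f"{chrom}\t{s}\t{min(s + track.step, L)}\t{v:.6g}\n")


# --------------------------------------------------------------------- TSVs

def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos_1based", "id"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: SNP table needs columns {sorted(required)}")
    return df
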