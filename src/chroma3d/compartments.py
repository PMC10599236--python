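"""PCA-based A/B compartment calling.

The first principal component of the Pearson-correlation matrix of the
O/E map partitions bins into two interaction communities.  The sign of
the eigenvector is arbitrary, so it is oriented against a gene-density
track: A compartments are gene-rich, so PC1 is flipped when it
anticorrelates with gene density.  A bins are pc1 > 0 after orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin


class DegenerateInputError(ValueError):
    pass


def correlation_pc1(oe: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the centered O/E correlation matrix.

    Returns a unit-norm vector over all bins with NaN at masked bins.
    Requires >= 3 valid bins with nonzero variance.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    valid = ~np.all(np.isnan(oe), axis=0)
    sub = oe[np.ix_(valid, valid)]
    if sub.shape[0] < 3:
        raise DegenerateInputError("need >= 3 valid bins for PCA")
    if np.nanstd(sub) == 0:
        raise DegenerateInputError("O/E matrix is constant; no compartment signal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    centered = corr - corr.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    vals, vecs = np.linalg.eigh(cov)
    pc1_sub = vecs[:, -1]
    pc1_sub = pc1_sub / np.linalg.norm(pc1_sub)
    pc1 = np.full(n, np.nan)
    pc1[valid] = pc1_sub
    return pc1


def orient_and_label(pc1: np.ndarray, gene_density: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Orient PC1 by gene density and call A/B labels.

    Returns ``(oriented_pc1, labels)`` where labels is an object array of
    'A'/'B' (NaN bins stay None).  pc1 == 0 bins inherit the previous
    bin's label; a leading zero run inherits the first labelled bin.
    """
    pc1 = np.asarray(pc1, dtype=float).copy()
    gd = np.asarray(gene_density, dtype=float)
    if pc1.shape != gd.shape:
        raise ValueError("pc1 and gene density must have equal length")
    ok = ~np.isnan(pc1) & ~np.isnan(gd)
    if ok.sum() >= 2 and np.std(gd[ok]) > 0 and np.std(pc1[ok]) > 0:
        r = np.corrcoef(pc1[ok], gd[ok])[0, 1]
        if r < 0:
            pc1 = -pc1
    else:
        warnings.warn("gene density has zero variance; PC1 orientation "
                      "undetermined, keeping computed sign", stacklevel=2)

    labels = np.empty(pc1.shape[0], dtype=object)
    labels[:] = None
    prev = None
    pending: list[int] = []
    for i, v in enumerate(pc1):
        if np.isnan(v):
            continue
        if v > 0:
            lab = "A"
        elif v < 0:
            lab = "B"
        else:
            lab = prev
        if lab is None:
            pending.append(i)
        else:
            labels[i] = lab
            if pending:
                for j in pending:
                    labels[j] = lab
                pending = []
        prev = labels[i] if labels[i] is not None else prev
    return pc1, labels


@dataclass
class CompartmentCall:
    chrom: str
    bin_size: int
    pc1: np.ndarray
    labels: np.ndarray
    segments: pd.DataFrame
    stats: dict = field(default_factory=dict)
    track_means: pd.DataFrame | None = None


def _segments_from_labels(labels: np.ndarray) -> pd.DataFrame:
    """Maximal same-label runs over valid bins; masked bins break runs."""
    rows = []
    start = None
    cur = None
    for i, lab in enumerate(labels):
        if lab is None:
            if cur is not None:
                rows.append((start, i, cur))
            start, cur = None, None
        elif lab != cur:
            if cur is not None:
                rows.append((start, i, cur))
            start, cur = i, lab
    if cur is not None:
        rows.append((start, len(labels), cur))
    return pd.DataFrame(rows, columns=["start_bin", "end_bin", "label"])


def segment_and_summarize(labels: np.ndarray, chrom: str, bin_size: int,
                          pc1: np.ndarray | None = None,
                          genes: pd.DataFrame | None = None,
                          tracks: dict[str, np.ndarray] | None = None
                          ) -> CompartmentCall:
    """Run-length segmentation plus per-class summaries.

    Genes are assigned to the compartment of their midpoint bin
    (half-open: a midpoint on a bin edge belongs to the right bin).
    ``tracks`` are per-bin vectors summarised as per-class means.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label vector")
    segs = _segments_from_labels(labels)
    n_valid = int((labels != None).sum())  # noqa: E711
    n_a = int((labels == "A").sum())
    n_b = int((labels == "B").sum())
    stats = {
        "n_A_segments": int((segs["label"] == "A").sum()),
        "n_B_segments": int((segs["label"] == "B").sum()),
        "pct_genome_A": 100.0 * n_a / n_valid if n_valid else float("nan"),
        "pct_genome_B": 100.0 * n_b / n_valid if n_valid else float("nan"),
    }
    if genes is not None:
        sub = genes[genes["chrom"] == chrom]
        mid_bins = ((sub["start"] + sub["end"]) // 2) // bin_size
        mid_bins = mid_bins.astype(int).clip(0, labels.size - 1)
        glabs = labels[mid_bins.to_numpy()]
        stats["genes_in_A"] = int((glabs == "A").sum())
        stats["genes_in_B"] = int((glabs == "B").sum())
    tm = None
    if tracks:
        rows = {}
        for name, vec in tracks.items():
            vec = np.asarray(vec, dtype=float)
            rows[name] = {
                "A": float(np.nanmean(vec[labels == "A"])) if n_a else np.nan,
                "B": float(np.nanmean(vec[labels == "B"])) if n_b else np.nan,
            }
        tm = pd.DataFrame(rows).T
    return CompartmentCall(chrom, bin_size,
                           pc1 if pc1 is not None else np.full(labels.size, np.nan),
                           labels, segs, stats, tm)


class CompartmentCaller(ClusterMixin, BaseEstimator):
    """A/B compartment caller as a scikit-learn style estimator.

    ``fit(X)`` takes an O/E matrix (NaN on masked bins); the oriented
    eigenvector, per-bin labels and segments become fitted attributes.
    Gene density for sign orientation is passed as a fit parameter.
    """

    def __init__(self, chrom: str = "chr", bin_size: int = 100_000):
        self.chrom = chrom
        self.bin_size = bin_size

    def fit(self, X: np.ndarray, y=None, gene_density: np.ndarray | None = None,
            genes: pd.DataFrame | None = None,
            tracks: dict[str, np.ndarray] | None = None) -> "CompartmentCaller":
        pc1 = correlation_pc1(X)
        if gene_density is None:
            gene_density = np.zeros_like(pc1)
        pc1, labels = orient_and_label(pc1, gene_density)
        call = segment_and_summarize(labels, self.chrom, self.bin_size,
                                     pc1=pc1, genes=genes, tracks=tracks)
        self.pc1_ = pc1
        self.labels_ = labels
        self.segments_ = call.segments
        self.stats_ = call.stats
        self.call_ = call
        return self
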