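"""Insulation-score TAD calling and epigenetic TAD clustering.

The insulation score at bin ``i`` is the log2 ratio of the mean balanced
contact in the ``w x w`` diamond crossing ``i`` (rows ``i-w..i-1``,
columns ``i+1..i+w``) to the chromosome-wide mean diamond.  Local minima
with sufficient prominence are domain boundaries; consecutive boundaries
(chromosome ends included) delimit TADs.

TADs are then profiled over epigenomic tracks, z-scored, and clustered
into three groups (Ward agglomerative clustering) labelled repressive /
intermediate / active from their mean marker z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering

from .contacts import ContactMatrix, coarsen, ice_balance

ACTIVE_MARKERS = ("h3k27ac", "atac", "expression", "gene_density")
REPRESSIVE_MARKERS = ("cg", "chg", "chh")


def insulation_score(m: ContactMatrix, window_bins: int = 5) -> np.ndarray:
    """Per-bin insulation score (NaN within ``window_bins`` of the ends
    and where the diamond has no valid pixel)."""
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = m.n_bins
    if window_bins > n // 2:
        raise ValueError("window larger than half the chromosome")
    b = m.balanced()
    diamond = np.full(n, np.nan)
    for i in range(window_bins, n - window_bins):
        block = b[i - window_bins:i, i + 1:i + 1 + window_bins]
        ok = ~np.isnan(block)
        if ok.any():
            diamond[i] = block[ok].mean()
    mean_diamond = np.nanmean(diamond)
    if not np.isfinite(mean_diamond) or mean_diamond <= 0:
        return diamond
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(diamond / mean_diamond)


def call_boundaries(score: np.ndarray, delta_threshold: float = 0.1
                    ) -> pd.DataFrame:
    """Local insulation minima with prominence >= ``delta_threshold``.

    Equal-valued adjacent minima (plateaus) resolve to the left edge.
    Returns columns ``bin`` and ``strength`` (the prominence).
    """
    score = np.asarray(score, dtype=float)
    valid = np.where(~np.isnan(score))[0]
    if valid.size == 0:
        return pd.DataFrame(columns=["bin", "strength"])
    lo, hi = valid[0], valid[-1] + 1
    seg = score[lo:hi]
    if np.isnan(seg).any():  # interior gaps: fill with +inf so they never win
        seg = np.where(np.isnan(seg), np.inf, seg)
    peaks, props = find_peaks(-seg, prominence=delta_threshold,
                              plateau_size=(1, None))
    bins = props["left_edges"]
    return pd.DataFrame({"bin": bins + lo,
                         "strength": props["prominences"]})


def assemble_tads(boundaries, n_bins: int, min_tad_bins: int = 3
                  ) -> pd.DataFrame:
    """Tile the chromosome into TADs between consecutive boundaries.

    Chromosome ends count as boundaries; intervals shorter than
    ``min_tad_bins`` are discarded.
    """
    if isinstance(boundaries, pd.DataFrame):
        boundaries = boundaries["bin"].tolist()
    cuts = sorted({0, n_bins, *(int(b) for b in boundaries)})
    rows = [(s, e) for s, e in zip(cuts[:-1], cuts[1:]) if e - s >= min_tad_bins]
    return pd.DataFrame(rows, columns=["start_bin", "end_bin"])


@dataclass
class InsulationProfile:
    chrom: str
    window_bins: int
    score: np.ndarray
    boundaries: pd.DataFrame


class InsulationTADCaller(BaseEstimator):
    """Insulation-score TAD caller (scikit-learn estimator style).

    ``fit(X)`` accepts a balanced matrix as ndarray (NaN-masked) or a
    balanced :class:`ContactMatrix`; fitted attributes are
    ``insulation_``, ``boundaries_`` and ``tads_``.
    """

    def __init__(self, window_bins: int = 5, delta_threshold: float = 0.1,
                 min_tad_bins: int = 3):
        self.window_bins = window_bins
        self.delta_threshold = delta_threshold
        self.min_tad_bins = min_tad_bins

    def fit(self, X, y=None) -> "InsulationTADCaller":
        if isinstance(X, ContactMatrix):
            m = X
        else:
            X = np.asarray(X, dtype=float)
            mask = ~np.all(np.isnan(X), axis=0)
            w = np.where(mask, 1.0, np.nan)
            m = ContactMatrix("chr", 1, np.nan_to_num(X),
                              valid_mask=mask, weights=np.nan_to_num(w))
        self.insulation_ = insulation_score(m, self.window_bins)
        self.boundaries_ = call_boundaries(self.insulation_, self.delta_threshold)
        self.tads_ = assemble_tads(self.boundaries_, m.n_bins, self.min_tad_bins)
        return self


def call_tads(m: ContactMatrix, window_bins: int = 5,
              delta_threshold: float = 0.1, min_tad_bins: int = 3
              ) -> pd.DataFrame:
    est = InsulationTADCaller(window_bins, delta_threshold, min_tad_bins).fit(m)
    tads = est.tads_.copy()
    tads.insert(0, "chrom", m.chrom)
    tads["resolution_bp"] = m.bin_size
    return tads


def multi_resolution(m: ContactMatrix, resolutions: list[int],
                     **caller_kwargs) -> dict[int, pd.DataFrame]:
    """Call TADs at several bin sizes by sum-pooling the raw matrix.

    Each resolution must be a multiple of the base bin size.  The raw
    matrix is coarsened, re-balanced and called independently.
    """
    out: dict[int, pd.DataFrame] = {}
    for res in resolutions:
        if res % m.bin_size:
            raise ValueError(f"resolution {res} not a multiple of bin size")
        mm = coarsen(m, res // m.bin_size)
        out[res] = call_tads(ice_balance(mm), **caller_kwargs)
    return out


def tad_marker_matrix(tads: pd.DataFrame, tracks: dict[str, np.ndarray]
                      ) -> pd.DataFrame:
    """Per-TAD track means, column z-scored.  Zero-variance tracks come
    out as NaN columns (flagged by being all-NaN)."""
    if len(tads) < 2:
        raise ValueError("need >= 2 TADs to z-score marker means")
    if len(tracks) < 2:
        raise ValueError("need >= 2 tracks")
    raw = {}
    for name, vec in tracks.items():
        vec = np.asarray(vec, dtype=float)
        raw[name] = [np.nanmean(vec[s:e]) for s, e in
                     zip(tads["start_bin"], tads["end_bin"])]
    df = pd.DataFrame(raw, index=tads.index)
    mu, sd = df.mean(), df.std(ddof=0)
    z = (df - mu) / sd.replace(0, np.nan)
    return z


def marker_correlation(marker_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of marker z-scores over TADs."""
    return marker_matrix.corr(method="pearson")


class TadClusterer(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering of TAD marker profiles into k groups
    with repressive / intermediate / active role assignment.

    Roles come from mean marker z-scores: the cluster with the highest
    mean active score (H3K27ac, ATAC, expression, gene density) is
    active; of the rest, the highest mean repressive score (CG, CHG,
    CHH methylation) is repressive; remaining clusters are intermediate.
    Role assignment therefore never depends on cluster id numbering.
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame, y=None) -> "TadClusterer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if self.n_clusters > len(X):
            raise ValueError("more clusters than TADs")
        Xv = X.dropna(axis=1, how="all").fillna(0.0)
        if np.allclose(Xv.to_numpy().std(axis=0), 0):
            raise ValueError("marker matrix has no variance; cannot cluster")
        model = AgglomerativeClustering(n_clusters=self.n_clusters,
                                        linkage="ward")
        labels = model.fit_predict(Xv.to_numpy())

        cols = {c.lower(): c for c in X.columns}
        act = [cols[m] for m in ACTIVE_MARKERS if m in cols]
        rep = [cols[m] for m in REPRESSIVE_MARKERS if m in cols]
        means = X.groupby(labels).mean()
        roles = {int(c): "intermediate" for c in means.index}
        if act:
            active_c = int(means[act].mean(axis=1).idxmax())
            roles[active_c] = "active"
        else:
            active_c = None
        if rep:
            rep_scores = means[rep].mean(axis=1).drop(index=[active_c],
                                                      errors="ignore")
            if len(rep_scores):
                roles[int(rep_scores.idxmax())] = "repressive"
        self.labels_ = labels
        self.roles_ = roles
        self.role_per_tad_ = np.array([roles[int(l)] for l in labels])
        self.cluster_means_ = means
        return self


def cluster_tads(marker_matrix: pd.DataFrame, k: int = 3
                 ) -> tuple[np.ndarray, np.ndarray]:
    est = TadClusterer(n_clusters=k).fit(marker_matrix)
    return est.labels_, est.role_per_tad_


def locate_gene_tad(gene_start: int, gene_end: int, tads: pd.DataFrame,
                    bin_size: int) -> int | None:
    """Index of the TAD fully containing [gene_start, gene_end) in bp,
    or None.  Containment is strict: straddling genes match nothing."""
    for idx, s, e in zip(tads.index, tads["start_bin"], tads["end_bin"]):
        if s * bin_size <= gene_start and gene_end <= e * bin_size:
            return idx
    return None
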