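"""Contact-matrix model, I/O, ICE balancing, and observed/expected.

A :class:`ContactMatrix` holds one chromosome's dense symmetric raw count
matrix at a fixed bin size.  Balancing follows iterative correction
(ICE): low-coverage bins are masked, then multiplicative per-bin weights
are iterated until the balanced marginals are uniform to a coefficient
of variation below ``tol``.  The balanced value is
``counts[i, j] * w[i] * w[j]``.

Distance-decay expectation and the O/E transform operate on the balanced
matrix; masked rows/columns propagate as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import io as cio

EXPECTED_FLOOR = 1e-10


class BalanceError(RuntimeError):
    """Degenerate matrix: nothing left to balance."""


class StateError(RuntimeError):
    """Operation called on a matrix in the wrong state (e.g. unbalanced)."""


@dataclass
class ContactMatrix:
    """Symmetric intra-chromosomal raw contact counts at one resolution."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    valid_mask: np.ndarray | None = None
    weights: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def balanced(self) -> np.ndarray:
        """Balanced matrix with NaN on masked rows/columns."""
        if self.weights is None:
            raise StateError("matrix is not balanced; run ice_balance first")
        w = np.where(self.valid_mask, self.weights, np.nan)
        return self.counts * np.outer(w, w)


def read_contacts(coo_path, chrom_sizes_path, chrom: str,
                  bin_size: int) -> ContactMatrix:
    """Load one chromosome's COO text into a dense ContactMatrix."""
    sizes = cio.read_chrom_sizes(chrom_sizes_path)
    if chrom not in sizes:
        raise cio.FormatError(f"chromosome {chrom!r} not in chrom.sizes")
    n_bins = -(-sizes[chrom] // bin_size)
    counts = cio.read_coo(coo_path, n_bins)
    return ContactMatrix(chrom, bin_size, counts)


def write_contacts(m: ContactMatrix, path) -> None:
    cio.write_coo(m.counts, path)


class IceBalancer(TransformerMixin, BaseEstimator):
    """Iterative-correction balancing as a scikit-learn transformer.

    ``fit`` learns the valid-bin mask and per-bin weights from a square
    symmetric count matrix; ``transform`` returns the balanced matrix
    with NaN at masked bins.

    Parameters
    ----------
    max_iter : stop after this many correction sweeps.
    tol : convergence threshold on the coefficient of variation of the
        balanced marginals.
    mask_quantile : bins whose marginal falls below this quantile of the
        *nonzero* marginals are masked before iterating.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-5,
                 mask_quantile: float = 0.02):
        self.max_iter = max_iter
        self.tol = tol
        self.mask_quantile = mask_quantile

    def fit(self, X: np.ndarray, y=None) -> "IceBalancer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("expected a square matrix")
        if not np.allclose(X, X.T):
            raise ValueError("expected a symmetric matrix")
        marg = X.sum(axis=1)
        nz = marg[marg > 0]
        if nz.size == 0:
            raise BalanceError("matrix has no contacts on any bin")
        cutoff = np.quantile(nz, self.mask_quantile, method="lower")
        mask = marg >= cutoff
        if not mask.any():
            raise BalanceError("all bins masked at the requested quantile")

        sub = X[np.ix_(mask, mask)]
        w = np.ones(sub.shape[0])
        n_iter = 0
        cv = np.inf
        for n_iter in range(1, self.max_iter + 1):
            b = sub * np.outer(w, w)
            s = b.sum(axis=1)
            if (s <= 0).any():
                raise BalanceError("zero balanced marginal inside valid set")
            cv = s.std() / s.mean()
            if cv < self.tol:
                break
            w = w / np.sqrt(s / s.mean())
        # normalize so the balanced matrix keeps the raw total scale
        b = sub * np.outer(w, w)
        scale = np.sqrt(sub.sum() / b.sum()) if b.sum() > 0 else 1.0
        w = w * scale

        self.mask_ = mask
        self.weights_ = np.zeros(X.shape[0])
        self.weights_[mask] = w
        self.n_iter_ = n_iter
        self.cv_ = float(cv)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        w = np.where(self.mask_, self.weights_, np.nan)
        return np.asarray(X, dtype=float) * np.outer(w, w)


def ice_balance(m: ContactMatrix, max_iter: int = 200, tol: float = 1e-5,
                mask_quantile: float = 0.02) -> ContactMatrix:
    """Balance a ContactMatrix in place-style (returns a new object)."""
    est = IceBalancer(max_iter=max_iter, tol=tol,
                      mask_quantile=mask_quantile).fit(m.counts)
    return ContactMatrix(m.chrom, m.bin_size, m.counts,
                         valid_mask=est.mask_, weights=est.weights_)


@dataclass
class DecayProfile:
    """Mean balanced count per bin-separation; NaN where no valid pair."""

    expected_by_distance: np.ndarray

    def expected_matrix(self, n_bins: int) -> np.ndarray:
        d = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        return self.expected_by_distance[d]


def expected_by_distance(m: ContactMatrix) -> DecayProfile:
    """Distance-decay expectation from a balanced matrix."""
    b = m.balanced()
    n = m.n_bins
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(b, offset=d)
        ok = ~np.isnan(diag)
        if ok.any():
            exp[d] = diag[ok].mean()
    return DecayProfile(exp)


def oe_transform(m: ContactMatrix, profile: DecayProfile,
                 floor: float = EXPECTED_FLOOR) -> np.ndarray:
    """Observed/expected matrix; masked bins propagate as NaN.

    Expected values below ``floor`` are floored, which keeps the ratio
    finite; such pixels are large and should be excluded from loop
    statistics by the caller.
    """
    b = m.balanced()
    n = m.n_bins
    if profile.expected_by_distance.shape[0] != n:
        raise ValueError("profile dimension does not match matrix")
    e = profile.expected_matrix(n)
    return b / np.maximum(e, floor)


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum-pool raw counts into bins ``factor`` times larger."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return ContactMatrix(m.chrom, m.bin_size, m.counts.copy())
    n = m.n_bins
    nb = -(-n // factor)
    padded = np.zeros((nb * factor, nb * factor))
    padded[:n, :n] = m.counts
    pooled = padded.reshape(nb, factor, nb, factor).sum(axis=(1, 3))
    return ContactMatrix(m.chrom, m.bin_size * factor, pooled)
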