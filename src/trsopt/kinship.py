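"""Genomic relationship matrix construction.

The relationship matrix follows the marker-based estimator G = WW'/f, where
W holds mean-centered minor-allele counts, W_ik = X_ik - 2 p_k, p_k is the
minor-allele frequency of marker k, and f = 2 * sum_k p_k (1 - p_k) is the
normalization constant (VanRaden 2008; Endelman & Jannink 2012).  With
in-sample frequencies every column of W sums to zero, so G has zero row sums
and, under Hardy-Weinberg equilibrium with no inbreeding, a mean diagonal
close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geno_io import MarkerMatrix

#: smallest eigenvalue below which a ridge is added to make G invertible
_SINGULAR_TOL = 1e-8
#: default ridge added to the diagonal when G is (numerically) singular
_DEFAULT_RIDGE = 1e-6


@dataclass
class CenteredMarkers:
    """Mean-centered minor-allele counts with centering metadata.

    ``W`` is n x m with column k equal to X_k - 2 p_k; ``p`` are minor-allele
    frequencies in (0, 0.5] (when estimated in-sample); ``f`` is the
    normalization constant 2 * sum p_k (1 - p_k).
    """

    W: np.ndarray
    p: np.ndarray
    f: float
    kept_markers: tuple[str, ...]
    individual_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.W.shape != (len(self.individual_ids), len(self.kept_markers)):
            raise ValueError("W shape does not match id lists")
        if self.p.shape != (self.W.shape[1],):
            raise ValueError("p length does not match marker count")
        if not self.f > 0:
            raise ValueError(f"normalization constant f must be > 0, got {self.f}")


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with the ridge actually applied."""

    matrix: np.ndarray
    individual_ids: tuple[str, ...]
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.individual_ids = tuple(str(i) for i in self.individual_ids)
        n = len(self.individual_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("G must be square and aligned with individual_ids")
        asym = np.abs(self.matrix - self.matrix.T).max() if n else 0.0
        if asym > 1e-10:
            raise ValueError(f"G asymmetric (max asymmetry {asym:.2e})")
        if self.epsilon < 0:
            raise ValueError("ridge epsilon must be >= 0")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.individual_ids)}
        try:
            return np.array([pos[str(g)] for g in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not present in kinship matrix") from None

    def submatrix(self, ids) -> "KinshipMatrix":
        idx = self.index_of(ids)
        return KinshipMatrix(self.matrix[np.ix_(idx, idx)], tuple(str(g) for g in ids), self.epsilon)


def recode_and_filter(markers: MarkerMatrix, maf_min: float = 0.0) -> MarkerMatrix:
    """Orient columns to minor-allele counts, drop rare/monomorphic markers, impute.

    Columns whose in-sample allele-1 frequency exceeds 0.5 are flipped
    (x -> 2 - x) so that calls count minor alleles.  Monomorphic columns and
    columns with minor-allele frequency below ``maf_min`` are dropped.
    Missing calls are imputed with the column mean of the non-missing calls,
    so downstream matrices are real-valued and complete.
    """
    calls = markers.calls.copy()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    all_missing = np.isnan(freq)
    flip = ~all_missing & (freq > 0.5)
    calls[:, flip] = 2.0 - calls[:, flip]
    freq = np.where(flip, 1.0 - freq, freq)

    keep = ~all_missing & (freq > 0.0) & (freq <= 0.5) & (freq >= maf_min)
    if not keep.any():
        raise ValueError("no polymorphic markers left after recoding/filtering")
    calls = calls[:, keep]
    col_mean = np.nanmean(calls, axis=0)
    nan_at = np.isnan(calls)
    calls[nan_at] = np.broadcast_to(col_mean, calls.shape)[nan_at]
    kept_ids = tuple(m for m, k in zip(markers.marker_ids, keep) if k)
    return MarkerMatrix(markers.individual_ids, kept_ids, calls,
                        minor_allele_coded=True, imputed=True)


def center_markers(markers: MarkerMatrix, p: np.ndarray | None = None) -> CenteredMarkers:
    """Center recoded marker calls: W = X - 2p, f = 2 * sum p(1-p).

    ``p`` defaults to the in-sample frequency (column mean / 2); an external
    frequency vector may be supplied, e.g. when a fixed reference panel
    defines the centering.
    """
    if markers.n_markers == 0:
        raise ValueError("cannot center a matrix with zero markers")
    X = markers.calls
    if np.isnan(X).any():
        raise ValueError("markers must be imputed before centering")
    if p is None:
        p = X.mean(axis=0) / 2.0
    else:
        p = np.asarray(p, dtype=float)
        if p.shape != (markers.n_markers,):
            raise ValueError("external frequency vector has wrong length")
    f = 2.0 * float(np.sum(p * (1.0 - p)))
    if not f > 0:
        raise ValueError("normalization constant f is zero (all markers monomorphic)")
    W = X - 2.0 * p
    return CenteredMarkers(W, p, f, markers.marker_ids, markers.individual_ids)


def compute_G(cm: CenteredMarkers, epsilon: float | None = None) -> KinshipMatrix:
    """G = WW'/f, optionally ridged to guarantee invertibility.

    With ``epsilon=None`` a ridge of 1e-6 is added only when the smallest
    eigenvalue falls below 1e-8 (duplicated inbred lines and in-sample
    centering both make WW' singular); pass an explicit value (possibly 0) to
    override.  The ridge actually applied is recorded on the result.
    """
    G = cm.W @ cm.W.T / cm.f
    G = (G + G.T) / 2.0  # enforce exact symmetry
    if epsilon is None:
        w_min = float(np.linalg.eigvalsh(G).min())
        epsilon = _DEFAULT_RIDGE if w_min < _SINGULAR_TOL else 0.0
    if epsilon:
        G = G + epsilon * np.eye(G.shape[0])
    return KinshipMatrix(G, cm.individual_ids, float(epsilon))
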