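"""GBLUP mixed-model machinery: Henderson equations, PEV/CD of contrasts, REML.

The model is y = X beta + Z u + e with var(u) = G sigma_g^2 and
var(e) = I sigma_e^2 (fixed effects default to an intercept, i.e. the
population mean).  Writing lambda = sigma_e^2 / sigma_g^2, the inverse of the
Henderson coefficient matrix

    [ X'X      X'Z            ]
    [ Z'X      Z'Z + lambda G^-1 ]

has lower-right block C22 = theta = (Z'MZ + lambda G^-1)^-1 where
M = I - X (X'X)^- X' projects out the fixed effects.  For a contrast c of
genetic values (sum of elements zero):

    PEV(c) = c' theta c / c'c * sigma_e^2
    CD(c)  = c'(G - lambda theta) c / c' G c  =  1 - lambda c' theta c / c' G c

CD is the squared correlation between the true and predicted contrast
(Laloe 1993; Rincent et al. 2012) and lies in [0, 1].  CDmean / PEVmean
criteria average these over the contrasts between each unphenotyped
candidate and the panel mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

from .kinship import KinshipMatrix

_SYM_TOL = 1e-10
#: floor for lambda so that h2 = 1 (noise-free) stays numerically solvable
_LAMBDA_FLOOR = 1e-6


def lambda_from_h2(h2: float, floor: float = _LAMBDA_FLOOR) -> float:
    """Variance ratio lambda = (1 - h2) / h2 for a single record per genotype."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must be in (0, 1], got {h2}")
    return max((1.0 - h2) / h2, floor)


def inv_spd(A: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Invert a symmetric positive definite matrix via Cholesky.

    Falls back to an eigendecomposition when the Cholesky factorization fails
    marginally; raises ``numpy.linalg.LinAlgError`` naming ``name`` when the
    matrix is genuinely singular.
    """
    A = np.asarray(A, dtype=float)
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve((c, low), np.eye(A.shape[0]), check_finite=False)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        w, V = np.linalg.eigh(A)
        if w.min() <= 1e-12 * max(1.0, abs(w.max())):
            raise np.linalg.LinAlgError(f"singular or indefinite block: {name}")
        return (V / w) @ V.T


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MMESolution:
    """Solved Henderson system for one training set.

    ``u_hat`` is indexed by *all* genotypes of the kinship matrix passed to
    :func:`solve_mme` (training-set members and unphenotyped candidates
    alike); ``theta`` is the C22 block of the inverse coefficient matrix,
    ``M`` the fixed-effect projector over training-set observations.
    """

    ids: tuple[str, ...]
    trs_ids: tuple[str, ...]
    trs_indices: np.ndarray
    lam: float
    theta: np.ndarray
    M: np.ndarray
    beta_hat: np.ndarray | None
    u_hat: np.ndarray | None
    C11: np.ndarray
    C12: np.ndarray
    C22: np.ndarray

    @property
    def C21(self) -> np.ndarray:
        return self.C12.T

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class VarianceComponents:
    """Variance components (trait units squared) and derived heritability."""

    sigma_g2: float
    sigma_e2: float
    sigma_ge2: float = 0.0
    e: int = 1
    r: int = 1
    boundary: bool = False
    h2: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.sigma_g2, self.sigma_e2, self.sigma_ge2) < 0:
            raise ValueError("variance components must be >= 0")
        if self.e < 1 or self.r < 1:
            raise ValueError("environments and replicates must be >= 1")
        self.h2 = heritability(self)


@dataclass
class ReliabilityScores:
    """PEV and/or CD per contrast, plus their means over the contrast set."""

    contrasts: np.ndarray
    pev: np.ndarray | None = None
    cd: np.ndarray | None = None

    @property
    def pevmean(self) -> float:
        if self.pev is None:
            raise ValueError("PEV part not computed")
        return float(np.mean(self.pev))

    @property
    def cdmean(self) -> float:
        if self.cd is None:
            raise ValueError("CD part not computed")
        return float(np.mean(self.cd))


# ---------------------------------------------------------------------------
# Henderson system
# ---------------------------------------------------------------------------


def solve_mme(
    G: KinshipMatrix,
    trs_ids,
    y: np.ndarray | None = None,
    lam: float = 1.0,
    X: np.ndarray | None = None,
) -> MMESolution:
    """Solve the GBLUP mixed-model equations for one training set.

    ``G`` covers every genotype in the random-effect vector (training-set
    members plus any candidates to be predicted); ``Z`` is built internally
    as the incidence of training-set observations onto those genotypes (one
    record per genotype).  ``X`` defaults to an intercept, i.e. the fixed
    effect is the population mean.  When ``y`` is None only the inverse
    blocks are computed, which is all the reliability criteria need.
    """
    trs_ids = tuple(str(t) for t in trs_ids)
    if not trs_ids:
        raise ValueError("training set is empty")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    tidx = G.index_of(trs_ids)
    N = G.n
    n = len(trs_ids)

    if X is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != n:
            raise ValueError("X must have one row per training-set observation")
    XtX = X.T @ X
    XtX_pinv = np.linalg.pinv(XtX)  # Moore-Penrose generalized inverse
    M = np.eye(n) - X @ XtX_pinv @ X.T
    M = (M + M.T) / 2.0

    Ginv = inv_spd(G.matrix, name="G (ridge it before solving)")
    A = lam * Ginv
    A[np.ix_(tidx, tidx)] += M  # Z'MZ scattered onto the genotype index
    theta = inv_spd(A, name="Z'MZ + lambda*G^-1")
    theta = (theta + theta.T) / 2.0

    beta_hat = None
    u_hat = None
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.shape != (n,):
            raise ValueError("y must have one value per training-set member")
        ZtMy = np.zeros(N)
        ZtMy[tidx] = M @ y
        u_hat = theta @ ZtMy
        beta_hat = XtX_pinv @ X.T @ (y - u_hat[tidx])

    XtZ = np.zeros((X.shape[1], N))
    XtZ[:, tidx] = X.T
    C12 = -XtX_pinv @ XtZ @ theta
    C11 = XtX_pinv + XtX_pinv @ XtZ @ theta @ XtZ.T @ XtX_pinv

    return MMESolution(
        ids=G.individual_ids,
        trs_ids=trs_ids,
        trs_indices=tidx,
        lam=float(lam),
        theta=theta,
        M=M,
        beta_hat=beta_hat,
        u_hat=u_hat,
        C11=C11,
        C12=C12,
        C22=theta,
    )


def _check_contrasts(C: np.ndarray, n: int) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError(f"contrasts must have {n} rows, got {C.shape[0]}")
    sums = C.sum(axis=0)
    if np.abs(sums).max() > 1e-9:
        j = int(np.abs(sums).argmax())
        raise ValueError(f"contrast {j} does not sum to 0 (sum = {sums[j]:.3e})")
    return C


def pev_of_contrasts(sol: MMESolution, C: np.ndarray, sigma_e2: float = 1.0) -> ReliabilityScores:
    """Prediction error variance of each contrast: c' theta c / c'c * sigma_e^2."""
    C = _check_contrasts(C, sol.n)
    ThC = sol.theta @ C
    num = np.einsum("ij,ij->j", C, ThC)
    den = np.einsum("ij,ij->j", C, C)
    pev = num / den * sigma_e2
    return ReliabilityScores(contrasts=C, pev=pev)


def cd_of_contrasts(
    sol: MMESolution,
    G: KinshipMatrix,
    C: np.ndarray,
    lam: float | None = None,
    form: str = "difference",
) -> ReliabilityScores:
    """Coefficient of determination of each contrast.

    ``form='difference'`` evaluates c'(G - lambda theta)c / c'Gc;
    ``form='one_minus'`` evaluates the algebraically identical
    1 - lambda c' theta c / c' G c.  Both are exposed so the identity can be
    verified numerically.
    """
    C = _check_contrasts(C, sol.n)
    lam = sol.lam if lam is None else float(lam)
    cGc = np.einsum("ij,ij->j", C, G.matrix @ C)
    if cGc.min() <= 1e-12:
        j = int(cGc.argmin())
        raise ValueError(f"contrast {j} lies in the null space of G (c'Gc = {cGc[j]:.3e})")
    cThc = np.einsum("ij,ij->j", C, sol.theta @ C)
    if form == "difference":
        cd = (cGc - lam * cThc) / cGc
    elif form == "one_minus":
        cd = 1.0 - lam * cThc / cGc
    else:
        raise ValueError(f"unknown CD form {form!r}")
    return ReliabilityScores(contrasts=C, cd=cd)


def predict_gebv(sol: MMESolution, target_ids) -> np.ndarray:
    """Genomic estimated breeding values for target genotypes.

    Targets must be part of the random-effect vector of the solved system
    (i.e. present in the kinship matrix handed to :func:`solve_mme`); the
    prediction for a training-set member is its own u_hat.
    """
    if sol.u_hat is None:
        raise ValueError("system was solved without phenotypes; no GEBVs available")
    pos = {g: i for i, g in enumerate(sol.ids)}
    missing = [str(t) for t in target_ids if str(t) not in pos]
    if missing:
        raise KeyError(f"target id(s) absent from the solved system: {missing}")
    idx = np.array([pos[str(t)] for t in target_ids], dtype=int)
    return sol.u_hat[idx]


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------


def reml_estimate(
    y: np.ndarray,
    G: KinshipMatrix,
    log_lambda_bounds: tuple[float, float] = (-10.0, 10.0),
) -> VarianceComponents:
    """Single-kernel spectral REML for y = 1 beta + g + e, g ~ N(0, sigma_g^2 G).

    The restricted likelihood is profiled over the variance ratio
    delta = sigma_e^2 / sigma_g^2 by a 1-D search on log delta within
    ``log_lambda_bounds`` (natural log), using the eigendecomposition of the
    intercept-projected kinship matrix, as in EMMA-style solvers.  Returns
    the components and h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2); a fit on the
    search boundary (e.g. a constant phenotype driving sigma_g^2 to zero) is
    flagged via ``boundary``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("REML needs at least 10 observations")
    if G.n != n:
        raise ValueError("G must cover exactly the phenotyped individuals")

    # project out the intercept and rotate to the eigenbasis of S G S
    S = np.eye(n) - np.ones((n, n)) / n
    SGS = S @ G.matrix @ S
    w, U = np.linalg.eigh((SGS + SGS.T) / 2.0)
    d = w[1:]  # drop the null direction spanned by the intercept
    Ur = U[:, 1:]
    d = np.clip(d, 0.0, None)
    eta2 = (Ur.T @ y) ** 2
    nr = n - 1

    def negloglik(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = d + delta
        if denom.min() <= 0:
            return np.inf
        sg2 = float(np.sum(eta2 / denom)) / nr
        if sg2 <= 0:
            return np.inf
        return 0.5 * (nr * np.log(sg2) + float(np.sum(np.log(denom))))

    lo, hi = log_lambda_bounds
    grid = np.linspace(lo, hi, 81)
    vals = np.array([negloglik(g) for g in grid])
    if not np.isfinite(vals).any():
        raise ValueError(f"restricted likelihood non-finite over log lambda in [{lo}, {hi}]")
    k = int(vals.argmin())
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(negloglik, bounds=(a, b), method="bounded")
    log_delta = float(res.x) if np.isfinite(res.fun) and res.fun <= vals[k] else float(grid[k])
    delta = float(np.exp(log_delta))

    sigma_g2 = float(np.sum(eta2 / (d + delta))) / nr
    sigma_e2 = delta * sigma_g2
    span = hi - lo
    on_boundary = (log_delta <= lo + 0.01 * span) or (log_delta >= hi - 0.01 * span)
    tiny_genetic = sigma_g2 <= 1e-10 * max(np.var(y), 1e-30)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        boundary=bool(on_boundary or tiny_genetic),
    )


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability across environments and replicates.

    h2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2 / e + sigma_e^2 / (e r)), the
    entry-mean heritability for a trial with e environments and r replicates
    per environment.
    """
    denom = vc.sigma_g2 + vc.sigma_ge2 / vc.e + vc.sigma_e2 / (vc.e * vc.r)
    if denom == 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return float(vc.sigma_g2 / denom)
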