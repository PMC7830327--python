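"""Penalized non-negative MCR-ALS (multivariate curve resolution).

Factorizes a non-negative hyperspectral matrix A (m wavenumbers x n
spectra) as A ~ W H with W >= 0 (pure-component spectra, m x k) and
H >= 0 (abundances, k x n), minimizing the Frobenius norm ||A - WH||_F.

The alternating updates solve regularized normal equations:

    (W'W + a2 * E) H = W'A        E = k x k all-ones  (L1-type coupling)
    (H H' + b2 * I) W' = H A'     I = k x k identity  (ridge)

followed by projection of negative entries to zero ("clip" mode); an
exact per-column NNLS mode is available for comparison.  Iteration starts
from a sign-corrected truncated SVD and stops on relative objective
change.  The scale ambiguity of WH is resolved by unit-norm W columns
(the inverse scale is folded into H), which makes abundance magnitudes
comparable across components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _nnls

from .errors import DegenerateInputError, ParameterError
from .io import HyperspectralDataset

__all__ = [
    "MCRConfig",
    "MCRResult",
    "RankReport",
    "estimate_rank",
    "initialize_from_svd",
    "update_H",
    "update_W",
    "fit_mcr_als",
    "relative_abundance",
    "match_components",
]


@dataclass
class MCRConfig:
    """Solver parameters.  ``k`` components; ``alpha2``/``beta2`` are the
    L1/L2 penalty weights entering the normal equations; ``nonneg`` is
    "clip" (projected ALS, default) or "nnls" (exact per-column NNLS)."""

    k: int = 7
    alpha2: float = 0.005
    beta2: float = 0.005
    tol: float = 1e-8
    max_iter: int = 1000
    seed: int = 0
    nonneg: str = "clip"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.alpha2 < 0 or self.beta2 < 0:
            raise ParameterError("penalty weights must be >= 0")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if self.nonneg not in ("clip", "nnls"):
            raise ParameterError("nonneg must be 'clip' or 'nnls'")


@dataclass
class MCRResult:
    """Fitted factors.  W columns are unit Euclidean norm; scaling is
    carried by H.  ``objective_trace[t]`` is ||A - WH||_F after sweep t
    (index 0 = at initialization)."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return int(self.W.shape[1])


@dataclass
class RankReport:
    singular_values: np.ndarray
    noise_floor: float
    suggested_k: int

    def __str__(self) -> str:  # printable report for manual rank choice
        lines = [f"suggested k = {self.suggested_k} (noise floor {self.noise_floor:.4g})"]
        for i, s in enumerate(self.singular_values[:20], start=1):
            marker = "*" if s > self.noise_floor else " "
            lines.append(f"  {marker} s[{i:2d}] = {s:.6g}")
        return "\n".join(lines)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, HyperspectralDataset):
        return data.A
    return np.asarray(data, dtype=float)


def estimate_rank(data, noise_factor: float = 5.0) -> RankReport:
    """Suggest a component count from the singular-value spectrum.

    The noise floor is ``noise_factor`` x the median of the trailing half
    of the singular values; the suggestion is the count above the floor.
    The suggestion is advisory — the pipeline default keeps k = 7.
    """
    A = _as_matrix(data)
    s = np.linalg.svd(A, compute_uv=False)
    if not np.any(s > 0):
        warnings.warn("rank estimation on an all-zero matrix", stacklevel=2)
        return RankReport(s, 0.0, 0)
    floor = noise_factor * float(np.median(s[s.size // 2 :]))
    # never drop below the numerical-rank tolerance (noiseless matrices
    # have a trailing tail of pure round-off singular values)
    floor = max(floor, float(s[0]) * max(A.shape) * np.finfo(float).eps)
    return RankReport(s, floor, int(np.sum(s > floor)))


def initialize_from_svd(data, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative starting factors from the truncated SVD.

    Each singular vector is sign-flipped so its largest-magnitude entry is
    positive, then negatives are clipped; left vectors are scaled by their
    singular values.  An all-zero clipped column of W0 falls back to the
    uniform vector 1/m.
    """
    A = _as_matrix(data)
    m, n = A.shape
    if k > min(m, n):
        raise ParameterError(f"k = {k} exceeds min(m, n) = {min(m, n)}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    W0 = U[:, :k] * s[:k]
    H0 = Vt[:k, :].copy()
    for j in range(k):
        if W0[np.argmax(np.abs(W0[:, j])), j] < 0:
            W0[:, j] = -W0[:, j]
        if H0[j, np.argmax(np.abs(H0[j, :]))] < 0:
            H0[j, :] = -H0[j, :]
    W0 = np.maximum(W0, 0.0)
    H0 = np.maximum(H0, 0.0)
    dead = ~np.any(W0 > 0, axis=0)
    W0[:, dead] = 1.0 / m
    dead_h = ~np.any(H0 > 0, axis=1)
    H0[dead_h, :] = 1.0 / n
    return W0, H0


def _solve_or_lstsq(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(G, B)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(G, B, rcond=None)[0]


def update_H(A: np.ndarray, W: np.ndarray, alpha2: float, nonneg: str = "clip") -> np.ndarray:
    """One abundance half-update: solve (W'W + a2 E) H = W'A, then project."""
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    if A.shape[0] != W.shape[0]:
        raise ParameterError("A and W row counts differ")
    k = W.shape[1]
    if nonneg == "nnls":
        # (W'W + a2 E) is the normal matrix of W augmented with sqrt(a2)*1'
        W_aug = np.vstack([W, np.sqrt(alpha2) * np.ones((1, k))])
        H = np.empty((k, A.shape[1]))
        rhs = np.zeros(W_aug.shape[0])
        for j in range(A.shape[1]):
            rhs[:-1] = A[:, j]
            H[:, j] = _nnls(W_aug, rhs)[0]
        return H
    G = W.T @ W + alpha2 * np.ones((k, k))
    H = _solve_or_lstsq(G, W.T @ A)
    return np.maximum(H, 0.0)


def update_W(A: np.ndarray, H: np.ndarray, beta2: float, nonneg: str = "clip") -> np.ndarray:
    """One spectral half-update: solve (H H' + b2 I) W' = H A', then project."""
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if A.shape[1] != H.shape[1]:
        raise ParameterError("A and H column counts differ")
    k = H.shape[0]
    if nonneg == "nnls":
        H_aug = np.vstack([H.T, np.sqrt(beta2) * np.eye(k)])
        W = np.empty((A.shape[0], k))
        rhs = np.zeros(H_aug.shape[0])
        for i in range(A.shape[0]):
            rhs[: A.shape[1]] = A[i, :]
            W[i, :] = _nnls(H_aug, rhs)[0]
        return W
    G = H @ H.T + beta2 * np.eye(k)
    Wt = _solve_or_lstsq(G, H @ A.T)
    return np.maximum(Wt.T, 0.0)


def _normalize_W(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm W columns; inverse scale folded into H (WH invariant)."""
    norms = np.linalg.norm(W, axis=0)
    safe = norms.copy()
    safe[safe == 0] = 1.0
    return W / safe, H * norms[:, None]


def fit_mcr_als(data, config: MCRConfig | None = None) -> MCRResult:
    """Alternating least squares from the SVD start until the relative
    change of ||A - WH||_F drops below ``tol`` or ``max_iter`` is hit.

    Negative entries in the input (noise undershoot) are floored at zero
    with a warning; an all-zero matrix is rejected.
    """
    cfg = config or MCRConfig()
    A = _as_matrix(data)
    if np.any(A < 0):
        warnings.warn("input contains negative values; flooring at 0", stacklevel=2)
        A = np.maximum(A, 0.0)
    if not np.any(A > 0):
        raise DegenerateInputError("cannot factorize an all-zero matrix")

    W, H = initialize_from_svd(A, cfg.k)
    W, H = _normalize_W(W, H)
    norm_A = np.linalg.norm(A)
    trace = [float(np.linalg.norm(A - W @ H))]
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        H = update_H(A, W, cfg.alpha2, cfg.nonneg)
        W = update_W(A, H, cfg.beta2, cfg.nonneg)
        W, H = _normalize_W(W, H)
        # re-seed any component that died during the sweep
        dead = ~np.any(W > 0, axis=0)
        if np.any(dead):
            rng = np.random.default_rng(cfg.seed + it)
            W[:, dead] = rng.uniform(0.0, 1.0 / A.shape[0], size=(A.shape[0], int(dead.sum())))
            W, H = _normalize_W(W, H)
        obj = float(np.linalg.norm(A - W @ H))
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / max(prev, 1e-300) < cfg.tol:
            converged = True
            break
    return MCRResult(W, H, np.asarray(trace), it, converged)


@dataclass
class RelativeAbundance:
    """Per-spectrum ratio H[i,:]/H[j,:]; columns with a zero denominator
    are flagged and excluded (ratio NaN)."""

    ratios: np.ndarray
    excluded: np.ndarray  # boolean mask of zero-denominator columns

    @property
    def mean(self) -> float:
        vals = self.ratios[~self.excluded]
        return float(np.mean(vals)) if vals.size else float("nan")


def relative_abundance(result: MCRResult, component_i: int, component_j: int) -> RelativeAbundance:
    H = result.H
    k = H.shape[0]
    for idx in (component_i, component_j):
        if not 0 <= idx < k:
            raise ParameterError(f"component index {idx} out of range 0..{k - 1}")
    denom = H[component_j, :]
    excluded = denom == 0.0
    ratios = np.full(H.shape[1], np.nan)
    ratios[~excluded] = H[component_i, ~excluded] / denom[~excluded]
    return RelativeAbundance(ratios, excluded)


def abundance_per_cell(H: np.ndarray, cell_ids) -> tuple[np.ndarray, np.ndarray]:
    """Average point-spectrum abundances into one column per cell.

    Returns ``(H_cells, cells)`` with cells in order of first appearance,
    matching :func:`ramanmcr.preprocess.average_per_cell`.
    """
    import pandas as pd

    cell_ids = np.asarray(cell_ids)
    order = pd.unique(cell_ids)
    H = np.asarray(H, dtype=float)
    out = np.column_stack([H[:, cell_ids == c].mean(axis=1) for c in order])
    return out, order


def match_components(W_est: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one assignment of estimated to true components by
    cosine similarity (Hungarian algorithm); returns (permutation,
    cosines) where ``permutation[t]`` is the estimated column matched to
    true column t."""
    from scipy.optimize import linear_sum_assignment

    def _unit(M):
        n = np.linalg.norm(M, axis=0)
        n[n == 0] = 1.0
        return M / n

    C = _unit(W_est).T @ _unit(W_true)  # cosine matrix, est x true
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(W_true.shape[1], dtype=int)
    cosines = np.empty(W_true.shape[1])
    for r, c in zip(rows, cols):
        perm[c] = r
        cosines[c] = C[r, c]
    return perm, cosines
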