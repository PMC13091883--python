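"""Robust PCA: low-rank + sparse decomposition of stacked FC matrices.

Each scene's subjects-by-edges matrix Z_t is split as Z_t = L_t + S_t, where
the low-rank L_t captures the stimulus-induced connectivity pattern shared
across subjects and the sparse S_t the idiosyncratic, subject-specific
deviations.  The solver is the inexact augmented Lagrange multiplier (IALM)
iteration for principal component pursuit,

    min ||L||_* + lambda * ||S||_1   s.t.   Z = L + S,

alternating the nuclear-norm proximal step (singular value thresholding) for L
with the l1 proximal step (soft thresholding) for S, with the standard
lambda = 1 / sqrt(max(M, r)) scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SolverConfig",
    "DecompositionResult",
    "soft_threshold",
    "singular_value_threshold",
    "RobustPCA",
    "rpca_decompose",
    "decompose_all_scenes",
]


def soft_threshold(x: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Elementwise shrinkage sign(x) * max(|x| - tau, 0) (the l1 prox)."""
    if tau < 0:
        raise ValueError(f"threshold must be non-negative, got {tau}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)
    return out if out.ndim else float(out)


def _fix_svd_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign convention: largest-|.| entry of each left vector positive
    if u.shape[1] == 0:
        return u, vt
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs, vt * signs[:, None]


def singular_value_threshold(z: np.ndarray, tau: float) -> np.ndarray:
    """Nuclear-norm proximal operator: shrink the singular values by tau."""
    if tau < 0:
        raise ValueError(f"threshold must be non-negative, got {tau}")
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite input to singular value thresholding")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    u, vt = _fix_svd_signs(u, vt)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


@dataclass(frozen=True)
class SolverConfig:
    """IALM solver knobs.

    lam : l1 weight; ``None`` means the default 1/sqrt(max(M, r)).
    tol : relative Frobenius residual ||Z - L - S||_F / ||Z||_F at which to stop.
    mu / rho : initial penalty (``None`` -> 1.25/||Z||_2) and its growth factor.
    """

    lam: float | None = None
    tol: float = 1e-7
    max_iter: int = 500
    mu: float | None = None
    rho: float = 1.2

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")


@dataclass
class DecompositionResult:
    """Z = L + S split for one scene, with solver diagnostics."""

    scene_index: int
    low_rank: np.ndarray
    sparse: np.ndarray
    lam: float
    iterations: int
    residual: float
    converged: bool
    residual_trace: list[float] = field(default_factory=list)

    @property
    def rank(self) -> int:
        s = np.linalg.svd(self.low_rank, compute_uv=False)
        if s.size == 0 or s[0] == 0:
            return 0
        return int(np.sum(s > 1e-6 * s[0]))


class RobustPCA(TransformerMixin, BaseEstimator):
    """Sklearn-style robust PCA via inexact augmented Lagrange multipliers.

    Parameters
    ----------
    lam : float or None
        Sparsity weight; ``None`` uses 1/sqrt(max(n_samples, n_features)).
    tol : float
        Relative Frobenius reconstruction residual for convergence.
    max_iter : int
        Iteration cap; non-convergence warns and sets ``converged_ = False``.
    mu, rho : float
        Initial augmented-Lagrangian penalty (``None`` -> 1.25 / ||Z||_2) and
        its per-iteration growth factor.

    Attributes
    ----------
    low_rank_, sparse_ : ndarray
        The fitted components, ``Z ≈ low_rank_ + sparse_``.
    lam_ : float
        The sparsity weight actually used.
    n_iter_, residual_, converged_ : solver diagnostics.
    rank_ : numerical rank of ``low_rank_``.
    """

    def __init__(
        self,
        lam: float | None = None,
        tol: float = 1e-7,
        max_iter: int = 500,
        mu: float | None = None,
        rho: float = 1.2,
    ) -> None:
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter
        self.mu = mu
        self.rho = rho

    def fit(self, X: np.ndarray, y=None) -> "RobustPCA":
        z = np.asarray(X, dtype=float)
        if z.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.isfinite(z).all():
            raise ValueError("X contains non-finite values")
        m, n = z.shape
        if min(m, n) < 2:
            raise ValueError("X must be at least 2 x 2")
        cfg = SolverConfig(self.lam, self.tol, self.max_iter, self.mu, self.rho)

        lam = cfg.lam if cfg.lam is not None else 1.0 / np.sqrt(max(m, n))
        z_norm = np.linalg.norm(z)
        if z_norm == 0.0:
            self.low_rank_ = np.zeros_like(z)
            self.sparse_ = np.zeros_like(z)
            self.lam_, self.n_iter_, self.residual_ = lam, 0, 0.0
            self.converged_, self.residual_trace_ = True, []
            self.rank_ = 0
            return self

        spec = np.linalg.norm(z, 2)
        mu = cfg.mu if cfg.mu is not None else 1.25 / spec
        mu_bar = mu * 1e7
        # dual ascent init of Lin et al.'s IALM
        y_dual = z / max(spec, np.abs(z).max() / lam)
        s = np.zeros_like(z)
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            low = singular_value_threshold(z - s + y_dual / mu, 1.0 / mu)
            s = soft_threshold(z - low + y_dual / mu, lam / mu)
            resid_mat = z - low - s
            y_dual = y_dual + mu * resid_mat
            mu = min(mu * cfg.rho, mu_bar)
            resid = np.linalg.norm(resid_mat) / z_norm
            trace.append(resid)
            if resid < cfg.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"robust PCA did not converge in {cfg.max_iter} iterations "
                f"(residual {trace[-1]:.2e})",
                stacklevel=2,
            )
        self.low_rank_ = low
        self.sparse_ = s
        self.lam_ = lam
        self.n_iter_ = it
        self.residual_ = trace[-1]
        self.converged_ = converged
        self.residual_trace_ = trace
        sv = np.linalg.svd(low, compute_uv=False)
        self.rank_ = 0 if sv.size == 0 or sv[0] == 0 else int(np.sum(sv > 1e-6 * sv[0]))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Return the low-rank component fitted on this matrix."""
        check_is_fitted(self, "low_rank_")
        return self.low_rank_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def rpca_decompose(
    z: np.ndarray, cfg: SolverConfig = SolverConfig(), scene_index: int = 0
) -> DecompositionResult:
    """Decompose one subjects-by-edges matrix Z into Z = L + S."""
    est = RobustPCA(cfg.lam, cfg.tol, cfg.max_iter, cfg.mu, cfg.rho).fit(z)
    return DecompositionResult(
        scene_index=scene_index,
        low_rank=est.low_rank_,
        sparse=est.sparse_,
        lam=est.lam_,
        iterations=est.n_iter_,
        residual=est.residual_,
        converged=est.converged_,
        residual_trace=est.residual_trace_,
    )


def decompose_all_scenes(
    tensor, cfg: SolverConfig = SolverConfig(), layout: str = "subjects_by_edges"
):
    """Independently decompose every scene slice of a (W, M, r) tensor.

    ``layout='subjects_by_edges'`` (default) solves on the M x r matrix whose
    low rank captures across-subject shared structure.  ``layout='stacked_
    blocks'`` solves on the (M*R) x R vertical stack of the square FC
    matrices — the alternative reading of "concatenated" — and maps L/S back
    to M x r edge rows, so downstream classification is layout-agnostic.
    """
    if layout not in ("subjects_by_edges", "stacked_blocks"):
        raise ValueError(f"unknown layout {layout!r}")
    results = []
    for t in range(tensor.data.shape[0]):
        try:
            if layout == "subjects_by_edges":
                results.append(
                    rpca_decompose(
                        tensor.data[t], cfg, scene_index=tensor.scene_indices[t]
                    )
                )
            else:
                from .connectivity import devectorize_lower_triangle

                blocks = [devectorize_lower_triangle(row) for row in tensor.data[t]]
                res = rpca_decompose(
                    np.vstack(blocks), cfg, scene_index=tensor.scene_indices[t]
                )
                n = blocks[0].shape[0]
                rows, cols = np.tril_indices(n, k=-1)
                res.low_rank = np.stack(
                    [res.low_rank[m * n : (m + 1) * n][rows, cols] for m in range(len(blocks))]
                )
                res.sparse = np.stack(
                    [res.sparse[m * n : (m + 1) * n][rows, cols] for m in range(len(blocks))]
                )
                results.append(res)
        except Exception as exc:  # annotate with scene index
            raise RuntimeError(
                f"decomposition failed for scene {tensor.scene_indices[t]}: {exc}"
            ) from exc
    return results
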