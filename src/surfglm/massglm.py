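"""Chunked mass-univariate ordinary least squares over vertices.

One design matrix X (n subjects × p predictors) is shared by every vertex;
the stack Y (n × V) holds the per-vertex outcome.  The coefficients for all
vertices solve the same normal equations, B = (XᵀX)⁻¹XᵀY, but we factor X
once by Householder QR and recover (XᵀX)⁻¹ = R⁻¹R⁻ᵀ — numerically safer
than forming and inverting XᵀX, and mathematically identical.

Vertices are processed in chunks so that peak additional memory scales with
n × chunk_size rather than with V.  Chunks are independent work units with
no shared mutable state; the per-vertex arithmetic is written with
fixed-order reductions so the result is bitwise identical for any chunk
size and any execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .design import CollinearityError, DesignMatrix
from .fsio import VertexMapStack

__all__ = ["MassGLMResult", "make_mask", "fit_chunk", "run_massglm", "residuals"]

DEFAULT_CHUNK_SIZE = 1000

#: p-value reported for a perfect fit (residual sum of squares exactly 0).
MIN_PVAL = np.nextafter(0.0, 1.0)

#: RSS below this fraction of the outcome's sum of squares is rounded to an
#: exact 0 (perfect fit): pure floating-point residue sits around eps² ≈
#: 5e-32 relative, while any genuine residual variance is many orders above.
PERFECT_RSS_RTOL = 1e-24


@dataclass
class MassGLMResult:
    """Per-stack vertex maps from the mass-univariate fit.

    All four maps are exact zeros at masked-out vertices (the FreeSurfer
    display convention for excluded vertices).
    """

    coef: np.ndarray  # (p, V)
    se: np.ndarray  # (p, V)
    tval: np.ndarray  # (p, V)
    pval: np.ndarray  # (p, V)
    df_resid: int
    mask: np.ndarray  # (V,) bool
    stack_names: list[str]

    @property
    def p(self) -> int:
        return self.coef.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.coef.shape[1]


def make_mask(stack: VertexMapStack, cortex_only: np.ndarray | None = None) -> np.ndarray:
    """Select analyzable vertices.

    A vertex is kept iff no subject has an exactly-zero value there (zero is
    FreeSurfer's sentinel for off-cortex / failed vertices), the values vary
    across subjects, and — when given — it lies in ``cortex_only``.
    """
    data = stack.data
    nonzero = ~np.any(data == 0.0, axis=0)
    varying = np.var(data, axis=0) > 0.0
    mask = nonzero & varying
    if cortex_only is not None:
        keep = np.zeros(stack.n_vertices, dtype=bool)
        keep[np.asarray(cortex_only, dtype=np.int64)] = True
        mask &= keep
    if not mask.any():
        raise ValueError("empty vertex mask: nothing to analyze")
    return mask


class _QRFit:
    """Shared factorization of X used by every chunk."""

    def __init__(self, x: np.ndarray, colnames: list[str]):
        n, p = x.shape
        if n <= p:
            raise ValueError(f"need more subjects than predictors (n={n}, p={p})")
        q, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        if diag.min() <= diag.max() * max(n, p) * np.finfo(np.float64).eps:
            raise CollinearityError("design matrix is rank deficient")
        self.x = x
        self.q = q
        self.r_inv = solve_triangular(r, np.eye(p))
        self.xtx_inv_diag = np.einsum("ij,ij->i", self.r_inv, self.r_inv)
        self.n = n
        self.p = p
        self.df = n - p
        self.colnames = list(colnames)

    def solve(self, y_chunk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients and residual sums of squares for an n × c chunk.

        Each vertex column goes through the same fixed-shape operations
        (matrix-vector products only), so the arithmetic — and hence the
        result, bitwise — does not depend on how vertices are grouped
        into chunks or in which order chunks run.
        """
        c = y_chunk.shape[1]
        beta = np.empty((self.p, c))
        rss = np.empty(c)
        for j in range(c):
            y = np.ascontiguousarray(y_chunk[:, j])
            b = self.r_inv @ (self.q.T @ y)
            resid = y - self.x @ b
            beta[:, j] = b
            r2 = resid @ resid
            rss[j] = 0.0 if r2 <= PERFECT_RSS_RTOL * (y @ y) else r2
        return beta, rss


def _chunk_stats(fit: _QRFit, beta: np.ndarray, rss: np.ndarray):
    sigma2 = rss / fit.df
    se = np.sqrt(np.outer(fit.xtx_inv_diag, sigma2))
    safe_se = np.where(se > 0, se, 1.0)
    tval = np.where(se > 0, beta / safe_se, np.sign(beta) * np.inf)
    tval = np.where((se == 0.0) & (beta == 0.0), 0.0, tval)
    pval = 2.0 * stats.t.sf(np.abs(tval), fit.df)
    pval = np.where(pval <= 0, MIN_PVAL, pval)
    return se, tval, pval


def fit_chunk(x: DesignMatrix, y_chunk: np.ndarray) -> MassGLMResult:
    """Fit the shared design to an n × c block of vertex outcomes.

    Returns a :class:`MassGLMResult` whose mask covers all c columns.
    Perfect-fit columns (RSS = 0) get SE 0, t = ±∞ and the smallest
    representable p-value rather than an error.
    """
    y_chunk = np.asarray(y_chunk, dtype=np.float64)
    if y_chunk.ndim == 1:
        y_chunk = y_chunk[:, None]
    fit = _QRFit(x.matrix, x.colnames)
    if y_chunk.shape[0] != fit.n:
        raise ValueError("chunk rows must match design rows")
    beta, rss = fit.solve(y_chunk)
    se, tval, pval = _chunk_stats(fit, beta, rss)
    mask = np.ones(y_chunk.shape[1], dtype=bool)
    return MassGLMResult(beta, se, tval, pval, fit.df, mask, fit.colnames)


def run_massglm(
    x: DesignMatrix,
    stack: VertexMapStack,
    mask: np.ndarray,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> MassGLMResult:
    """Fit every masked vertex, iterating in chunks of ``chunk_size``.

    Output maps have V columns with exact zeros at masked-out vertices.
    Any chunk size yields bitwise-identical coefficients.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != stack.n_vertices:
        raise ValueError("mask length must equal the stack's vertex count")
    fit = _QRFit(x.matrix, x.colnames)
    if stack.n_subjects != fit.n:
        raise ValueError("stack subject count must match design rows")
    v = stack.n_vertices
    coef = np.zeros((fit.p, v))
    se = np.zeros((fit.p, v))
    tval = np.zeros((fit.p, v))
    pval = np.zeros((fit.p, v))
    cols = np.flatnonzero(mask)
    for start in range(0, len(cols), chunk_size):
        idx = cols[start : start + chunk_size]
        beta, rss = fit.solve(stack.chunk(idx))
        c_se, c_t, c_p = _chunk_stats(fit, beta, rss)
        coef[:, idx] = beta
        se[:, idx] = c_se
        tval[:, idx] = c_t
        pval[:, idx] = c_p
    return MassGLMResult(coef, se, tval, pval, fit.df, mask, fit.colnames)


def residuals(x: DesignMatrix, stack: VertexMapStack, result: MassGLMResult) -> np.ndarray:
    """n × V residual maps (zeros at masked-out vertices)."""
    res = np.zeros((stack.n_subjects, stack.n_vertices))
    cols = np.flatnonzero(result.mask)
    y = stack.chunk(cols)
    res[:, cols] = y - x.matrix @ result.coef[:, cols]
    return res
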