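"""Rubin's-rules pooling across multiply-imputed phenotype datasets.

Given M complete-data fits of the same model, the pooled estimate of each
coefficient is the mean of the per-imputation estimates,

    q̄ = (1/M) Σ q_i ,

with total variance splitting into within- and between-imputation parts,

    W = (1/M) Σ SE_i²,   B = (1/(M−1)) Σ (q_i − q̄)²,   T = W + (1 + 1/M)·B .

Inference uses t = q̄/√T on the Barnard–Rubin small-sample degrees of
freedom, which combines the classical ν_old = (M−1)/λ² (λ the fraction of
variance due to missingness) with an observed-data correction; the
classical ν_old alone is available via ``df_method="old"``.  When the
between-imputation variance is exactly zero (λ = 0) the degrees of freedom
fall back to the complete-data value n − p.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .massglm import MIN_PVAL, MassGLMResult

__all__ = ["ImputedPhenotypes", "PooledResult", "normalize_phenotypes", "pool_rubin", "read_phenotypes"]


@dataclass
class ImputedPhenotypes:
    """An ordered list of M complete phenotype tables with shared schema."""

    tables: list[pd.DataFrame]
    id_column: str

    @property
    def m(self) -> int:
        return len(self.tables)

    @property
    def ids(self) -> list:
        return list(self.tables[0][self.id_column])


@dataclass
class PooledResult:
    """Pooled per-vertex maps; satisfies T = W + (1 + 1/M)·B elementwise."""

    qbar: np.ndarray  # (p, V) pooled coefficients
    within: np.ndarray  # (p, V) mean squared SE
    between: np.ndarray  # (p, V) sample variance of coefficients
    total: np.ndarray  # (p, V)
    df_pool: np.ndarray  # (p, V)
    tval: np.ndarray
    pval: np.ndarray
    m: int
    df_resid: int
    mask: np.ndarray
    stack_names: list[str]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.total)

    @property
    def p(self) -> int:
        return self.qbar.shape[0]


def read_phenotypes(
    source,
    id_column: str,
    sep: str = ",",
    imputation_column: str | None = None,
) -> ImputedPhenotypes:
    """Load phenotypes from flexible sources into an :class:`ImputedPhenotypes`.

    ``source`` may be a DataFrame, a list of DataFrames, a delimited-text
    path, a glob pattern matching one file per imputation, or a single file
    carrying an imputation-index column (named via ``imputation_column``).
    """
    if isinstance(source, pd.DataFrame):
        return normalize_phenotypes(source, id_column)
    if isinstance(source, (list, tuple)) and source and isinstance(source[0], pd.DataFrame):
        return normalize_phenotypes(list(source), id_column)
    pattern = str(source)
    paths = sorted(globmod.glob(pattern)) if any(c in pattern for c in "*?[") else [pattern]
    if not paths:
        raise FileNotFoundError(f"no phenotype files match {pattern!r}")
    frames = [pd.read_csv(p, sep=sep) for p in paths]
    if len(frames) == 1 and imputation_column is not None:
        df = frames[0]
        if imputation_column not in df.columns:
            raise ValueError(f"imputation column {imputation_column!r} not found")
        frames = [
            g.drop(columns=[imputation_column]).reset_index(drop=True)
            for _, g in df.groupby(imputation_column, sort=True)
        ]
    return normalize_phenotypes(frames if len(frames) > 1 else frames[0], id_column)


def normalize_phenotypes(obj, id_column: str) -> ImputedPhenotypes:
    """Normalize a table or list of tables into M validated complete tables.

    All tables must share columns; rows are reordered to the first table's
    identifier order.  Any residual missing value is an error (imputation
    happens upstream).
    """
    tables = [obj] if isinstance(obj, pd.DataFrame) else list(obj)
    if not tables:
        raise ValueError("need at least one phenotype table")
    ref_cols = list(tables[0].columns)
    if id_column not in ref_cols:
        raise ValueError(f"identifier column {id_column!r} not in the phenotype table")
    ref_ids = tables[0][id_column].tolist()
    if len(set(ref_ids)) != len(ref_ids):
        dupes = tables[0][id_column][tables[0][id_column].duplicated()].tolist()
        raise ValueError(f"duplicate subject identifiers: {sorted(set(map(str, dupes)))}")
    out = []
    for i, t in enumerate(tables):
        cols = list(t.columns)
        if set(cols) != set(ref_cols):
            extra = sorted(set(cols) ^ set(ref_cols))
            raise ValueError(f"imputation {i + 1}: column mismatch on {extra}")
        t = t[ref_cols]
        if sorted(map(str, t[id_column])) != sorted(map(str, ref_ids)):
            raise ValueError(f"imputation {i + 1}: identifier set differs from imputation 1")
        t = t.set_index(id_column).loc[ref_ids].reset_index()
        na = t.isna().sum()
        bad = na[na > 0]
        if len(bad):
            detail = ", ".join(f"{int(v)} missing in {k}" for k, v in bad.items())
            raise ValueError(f"imputation {i + 1}: {detail}")
        out.append(t)
    return ImputedPhenotypes(tables=out, id_column=id_column)


def pool_rubin(
    per_imputation: Sequence[MassGLMResult],
    n: int,
    p: int,
    df_method: str = "barnard-rubin",
) -> PooledResult:
    """Pool M mass-GLM results by Rubin's rules.

    With M = 1 the output is numerically identical to the single fit.
    """
    results = list(per_imputation)
    if not results:
        raise ValueError("need at least one result to pool")
    m = len(results)
    ref = results[0]
    for r in results[1:]:
        if r.coef.shape != ref.coef.shape or not np.array_equal(r.mask, ref.mask):
            raise ValueError("per-imputation results differ in shape or mask")
        if r.stack_names != ref.stack_names:
            raise ValueError("per-imputation results differ in stack names")
    df_com = n - p
    if m == 1:
        r = results[0]
        return PooledResult(
            qbar=r.coef.copy(),
            within=r.se**2,
            between=np.zeros_like(r.coef),
            total=r.se**2,
            df_pool=np.full_like(r.coef, float(df_com)),
            tval=r.tval.copy(),
            pval=r.pval.copy(),
            m=1,
            df_resid=df_com,
            mask=r.mask.copy(),
            stack_names=list(r.stack_names),
        )
    coefs = np.stack([r.coef for r in results])  # (M, p, V)
    ses = np.stack([r.se for r in results])
    qbar = coefs.mean(axis=0)
    within = (ses**2).mean(axis=0)
    between = coefs.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    lam = np.zeros_like(total)
    pos = total > 0
    lam[pos] = (1.0 + 1.0 / m) * between[pos] / total[pos]
    df_pool = np.full_like(total, float(df_com))
    nz = lam > 0
    with np.errstate(divide="ignore"):
        nu_old = (m - 1) / lam[nz] ** 2
    if df_method == "old":
        df_pool[nz] = nu_old
    elif df_method == "barnard-rubin":
        nu_obs = ((df_com + 1) / (df_com + 3)) * df_com * (1.0 - lam[nz])
        df_pool[nz] = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    safe_t = np.where(total > 0, np.sqrt(np.where(total > 0, total, 1.0)), 1.0)
    tval = np.where(total > 0, qbar / safe_t, np.where(qbar == 0, 0.0, np.sign(qbar) * np.inf))
    pval = 2.0 * stats.t.sf(np.abs(tval), df_pool)
    pval = np.where(pval <= 0, MIN_PVAL, pval)
    off = ~ref.mask
    for arr in (qbar, within, between, total, tval, pval):
        arr[:, off] = 0.0
    df_pool[:, off] = 0.0
    return PooledResult(
        qbar=qbar,
        within=within,
        between=between,
        total=total,
        df_pool=df_pool,
        tval=tval,
        pval=pval,
        m=m,
        df_resid=df_com,
        mask=ref.mask.copy(),
        stack_names=list(ref.stack_names),
    )
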