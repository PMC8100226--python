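"""Formula parsing and design-matrix construction.

A model is written the way statisticians write it::

    qdecr_thickness ~ age + sex + poly(bmi, 2)

The left-hand side names the per-vertex surface measure (always prefixed
``qdecr_``); the right-hand side lists predictors drawn from the phenotype
table.  Supported syntax:

* ``a + b`` — main effects;
* ``a * b`` — main effects plus interaction (expands to ``a, b, a:b``);
* ``a:b`` — the interaction alone, as products of the coded columns;
* ``poly(x, k)`` — orthogonal polynomial basis of degree ``k``;
* ``pow(x, k)`` — raw powers ``x, x², …, x^k``;
* ``ns(x, k)`` — natural cubic spline basis with ``k`` columns;
* ``scale(x)`` — standardize to mean 0, sample SD 1 (n−1 denominator);
* ``cut(x, k)`` — ``k`` equal-width right-closed bins, treatment-coded.

Categorical variables (string or boolean columns) are treatment-coded with
the lexicographically first level as reference — a deterministic convention,
unlike data-dependent factor-level order.  The intercept is mandatory;
intercept-removal syntax is rejected.  The hyphen/minus sign is reserved and
rejected on the right-hand side (measure names use underscores instead, e.g.
``qdecr_w_g.pct`` for the ``w-g.pct`` measure).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormulaError",
    "CollinearityError",
    "Factor",
    "Term",
    "FormulaSpec",
    "DesignMatrix",
    "parse_formula",
    "build_design",
    "natural_spline_basis",
    "orthogonal_poly",
    "KNOWN_MEASURES",
]


class FormulaError(ValueError):
    """Raised for unsupported or malformed formula syntax."""


class CollinearityError(ValueError):
    """Raised when the built design matrix is rank-deficient."""


#: Standard FreeSurfer surface measures and the formula token each maps to.
KNOWN_MEASURES = {
    "area": "area",
    "area.pial": "area.pial",
    "curv": "curv",
    "jacobian_white": "jacobian_white",
    "sulc": "sulc",
    "thickness": "thickness",
    "volume": "volume",
    "w_g.pct": "w-g.pct",
    "white.H": "white.H",
    "white.K": "white.K",
}

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")
_FUNC_RE = re.compile(r"^(poly|pow|ns|scale|cut)\s*\(\s*([A-Za-z_][A-Za-z0-9_.]*)\s*(?:,\s*(\d+)\s*)?\)$")
_FUNCS_WITH_K = {"poly", "pow", "ns", "cut"}


@dataclass(frozen=True)
class Factor:
    """One multiplicand of a term: a bare variable or a function term."""

    raw: str  # e.g. "age", "poly(age,2)", "sex"
    kind: str  # "var" | "poly" | "pow" | "ns" | "scale" | "cut"
    var: str
    k: int | None = None


@dataclass(frozen=True)
class Term:
    """A model term: a single factor, or an interaction of several."""

    factors: tuple[Factor, ...]

    @property
    def label(self) -> str:
        return ":".join(f.raw for f in self.factors)


@dataclass
class FormulaSpec:
    """Parsed formula: the response measure plus an ordered list of terms."""

    response: str  # measure token, qdecr_ prefix stripped and decoded
    response_raw: str  # the token as written (after qdecr_)
    terms: list[Term] = field(default_factory=list)

    @property
    def variables(self) -> list[str]:
        """Phenotype columns referenced by the right-hand side, in order."""
        seen: dict[str, None] = {}
        for t in self.terms:
            for f in t.factors:
                seen.setdefault(f.var, None)
        return list(seen)


@dataclass
class DesignMatrix:
    """A named N × p design matrix; column 0 is always the intercept."""

    matrix: np.ndarray
    colnames: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


def _parse_factor(text: str) -> Factor:
    text = text.strip()
    m = _FUNC_RE.match(text)
    if m:
        func, var, k = m.group(1), m.group(2), m.group(3)
        if func in _FUNCS_WITH_K:
            if k is None:
                raise FormulaError(f"{func}() requires an integer second argument: {text!r}")
            k_int = int(k)
            if k_int < 1:
                raise FormulaError(f"{func}() argument must be >= 1: {text!r}")
        else:
            if k is not None:
                raise FormulaError(f"scale() takes a single argument: {text!r}")
            k_int = None
        canon = f"{func}({var},{k_int})" if k_int is not None else f"{func}({var})"
        return Factor(raw=canon, kind=func, var=var, k=k_int)
    if _NAME_RE.match(text):
        return Factor(raw=text, kind="var", var=text)
    if re.match(r"^[A-Za-z_.][A-Za-z0-9_.]*\s*\(", text):
        raise FormulaError(f"unknown function in term {text!r}")
    raise FormulaError(f"cannot parse term {text!r}")


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormulaError(f"unbalanced parentheses in {text!r}")
        if ch == sep and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise FormulaError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(cur))
    return parts


def parse_formula(text: str) -> FormulaSpec:
    """Parse a formula string into a :class:`FormulaSpec`.

    ``a*b`` expands to main effects plus all interactions (ordered by
    interaction order, then appearance); duplicate terms arising from the
    expansion are dropped, keeping the first occurrence.
    """
    sides = text.split("~")
    if len(sides) != 2:
        raise FormulaError("formula must contain exactly one '~'")
    lhs, rhs = sides[0].strip(), sides[1].strip()
    if not lhs.startswith("qdecr_"):
        raise FormulaError(
            f"response {lhs!r} must be a surface measure prefixed with 'qdecr_'"
        )
    response_raw = lhs[len("qdecr_"):]
    if not response_raw or not _NAME_RE.match(response_raw):
        raise FormulaError(f"invalid response token {lhs!r}")
    response = KNOWN_MEASURES.get(response_raw, response_raw)
    if "-" in rhs:
        raise FormulaError(
            "'-' is not supported on the right-hand side (the minus sign is "
            "reserved; intercept removal is not allowed and measure names "
            "spell hyphens as underscores)"
        )
    terms: list[Term] = []
    labels: set[str] = set()
    for chunk in _split_top(rhs, "+"):
        chunk = chunk.strip()
        if not chunk:
            raise FormulaError("empty term on the right-hand side")
        if chunk in {"0", "1"}:
            if chunk == "0":
                raise FormulaError("intercept removal ('+ 0') is not supported")
            continue  # '+ 1' is the implicit intercept
        star_parts = [p.strip() for p in _split_top(chunk, "*")]
        expanded: list[tuple[str, ...]] = []
        if len(star_parts) > 1:
            # a*b*c -> all non-empty subsets, by order then position
            for order in range(1, len(star_parts) + 1):
                for combo in itertools.combinations(range(len(star_parts)), order):
                    expanded.append(tuple(star_parts[i] for i in combo))
        else:
            expanded.append((chunk,))
        for group in expanded:
            factors: list[Factor] = []
            for part in group:
                for colon_part in _split_top(part, ":"):
                    factors.append(_parse_factor(colon_part))
            term = Term(factors=tuple(factors))
            if term.label not in labels:
                labels.add(term.label)
                terms.append(term)
    if not terms:
        raise FormulaError("right-hand side has no terms")
    return FormulaSpec(response=response, response_raw=response_raw, terms=terms)


# ---------------------------------------------------------------------------
# Basis constructions


def orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of the given degree, orthogonal to 1.

    Built by QR-decomposing the Vandermonde matrix of the centered data and
    dropping the constant column; each column is normalized to unit length
    with the sign fixed so it correlates positively with the matching raw
    power.
    """
    x = np.asarray(x, dtype=np.float64)
    if degree >= len(np.unique(x)):
        raise FormulaError(f"poly degree {degree} requires > {degree} distinct values")
    xc = x - x.mean()
    vander = np.vander(xc, degree + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    basis = q[:, 1:]
    for j in range(degree):
        sign = np.sign(basis[:, j] @ xc ** (j + 1))
        if sign < 0:
            basis[:, j] = -basis[:, j]
    return basis


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns.

    Boundary knots sit at min(x) and max(x) and ``df − 1`` interior knots at
    equally spaced quantiles.  The basis is linear beyond the boundary knots
    (vanishing second derivative), the defining property of a *natural*
    spline; with ``df = 1`` it degenerates to the identity map of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    if df < 1:
        raise FormulaError("spline df must be >= 1")
    if len(np.unique(x)) <= df:
        raise FormulaError(f"ns df={df} requires more than {df} distinct values")
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, probs)  # df+1 knots incl. boundaries
    if len(np.unique(knots)) != len(knots):
        raise FormulaError("degenerate spline knots (too many ties in x)")
    n_knots = len(knots)
    if n_knots == 2:
        return x.reshape(-1, 1)

    def d(k: int, t: np.ndarray) -> np.ndarray:
        num = np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    d_last = d(n_knots - 2, x)
    for k in range(n_knots - 2):
        cols.append(d(k, x) - d_last)
    return np.column_stack(cols)


def _cut_dummies(x: np.ndarray, k: int, raw: str) -> tuple[np.ndarray, list[str]]:
    cats = pd.cut(pd.Series(np.asarray(x, dtype=np.float64)), bins=k, right=True)
    if cats.isna().any():
        raise FormulaError(f"{raw}: binning produced missing categories")
    levels = list(cats.cat.categories)
    cols = np.column_stack([(cats == lvl).to_numpy(dtype=np.float64) for lvl in levels[1:]])
    names = [f"{raw}{lvl}" for lvl in levels[1:]]
    return cols, names


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or series.dtype == bool
        or isinstance(series.dtype, pd.CategoricalDtype)
        or pd.api.types.is_string_dtype(series)
    )


def _eval_factor(f: Factor, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Evaluate a factor to its coded columns and their labels."""
    if f.var not in table.columns:
        raise FormulaError(f"variable {f.var!r} not found in the phenotype table")
    series = table[f.var]
    if series.isna().any():
        raise FormulaError(
            f"variable {f.var!r} has {int(series.isna().sum())} missing values; "
            "impute upstream before building the design"
        )
    if f.kind == "var":
        if _is_categorical(series):
            levels = sorted(str(v) for v in series.unique())
            if len(levels) < 2:
                raise FormulaError(f"categorical {f.var!r} has a single level {levels!r}")
            vals = series.astype(str).to_numpy()
            cols = np.column_stack([(vals == lvl).astype(np.float64) for lvl in levels[1:]])
            return cols, [f"{f.var}_{lvl}" for lvl in levels[1:]]
        x = series.to_numpy(dtype=np.float64)
        return x.reshape(-1, 1), [f.var]
    x = series.to_numpy(dtype=np.float64)
    if f.kind == "scale":
        sd = x.std(ddof=1)
        if sd == 0:
            raise FormulaError(f"scale({f.var}): zero variance")
        return ((x - x.mean()) / sd).reshape(-1, 1), [f.raw]
    if f.kind == "poly":
        basis = orthogonal_poly(x, f.k)
        return basis, [f"{f.raw}{j + 1}" for j in range(f.k)]
    if f.kind == "pow":
        basis = np.column_stack([x ** (j + 1) for j in range(f.k)])
        return basis, [f"{f.raw}{j + 1}" for j in range(f.k)]
    if f.kind == "ns":
        basis = natural_spline_basis(x, f.k)
        return basis, [f"{f.raw}{j + 1}" for j in range(basis.shape[1])]
    if f.kind == "cut":
        return _cut_dummies(x, f.k, f.raw)
    raise FormulaError(f"unknown factor kind {f.kind!r}")  # pragma: no cover


def build_design(spec: FormulaSpec, table: pd.DataFrame) -> DesignMatrix:
    """Build the numeric design matrix for a complete phenotype table.

    Interaction columns are element-wise products of their parents' coded
    columns.  The result is checked for full column rank; a rank-deficient
    matrix raises :class:`CollinearityError` naming the dependent columns.
    """
    missing = [v for v in spec.variables if v not in table.columns]
    if missing:
        raise FormulaError(f"variables missing from the phenotype table: {', '.join(missing)}")
    n = len(table)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["(Intercept)"]
    cache: dict[str, tuple[np.ndarray, list[str]]] = {}
    for term in spec.terms:
        coded = []
        for f in term.factors:
            if f.raw not in cache:
                cache[f.raw] = _eval_factor(f, table)
            coded.append(cache[f.raw])
        if len(coded) == 1:
            cols, labels = coded[0]
        else:
            col_sets = [list(range(c.shape[1])) for c, _ in coded]
            prod_cols, labels = [], []
            for combo in itertools.product(*col_sets):
                col = np.ones(n)
                parts = []
                for (cmat, lnames), j in zip(coded, combo):
                    col = col * cmat[:, j]
                    parts.append(lnames[j])
                prod_cols.append(col)
                labels.append(":".join(parts))
            cols = np.column_stack(prod_cols)
        blocks.append(np.atleast_2d(cols.T).T if cols.ndim == 1 else cols)
        names.extend(labels)
    matrix = np.column_stack(blocks)
    dupes = [nm for nm in names if names.count(nm) > 1]
    if dupes:
        raise FormulaError(f"duplicate design columns after expansion: {sorted(set(dupes))}")
    _check_rank(matrix, names)
    return DesignMatrix(matrix=matrix, colnames=names)


def _check_rank(matrix: np.ndarray, names: list[str]) -> None:
    n, p = matrix.shape
    if n <= p:
        raise CollinearityError(f"n = {n} subjects is not greater than p = {p} predictors")
    # Pivoted QR flags the columns that add no independent information.
    from scipy.linalg import qr

    _, r, piv = qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, p) * np.finfo(np.float64).eps
    rank = int((diag > tol).sum())
    if rank < p:
        bad = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < p {p}); "
            f"linearly dependent column(s): {', '.join(bad)}"
        )
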