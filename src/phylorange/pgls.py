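"""Phylogenetic generalized least squares (PGLS) with ML Pagel's lambda.

The model is ``y = X beta + e`` with ``e ~ N(0, sigma^2 * C(lambda))``,
where ``C`` is the Brownian-motion VCV implied by the phylogeny and
``C(lambda)`` multiplies its off-diagonal entries by Pagel's lambda.
Lambda is estimated by maximising the profile log-likelihood on [0, 1]
(0.01-grid pre-scan followed by bounded local refinement), after which
``beta`` is the GLS estimate at ``lambda_hat``.  Standard errors use the
conventional residual variance RSS/(n - k) in the whitened space, so the
reported t statistics match ordinary regression conventions; R^2 compares
the model against an intercept-only GLS null evaluated at the same
``lambda_hat``.

Directional hypotheses are handled by per-coefficient one-tailed p-values:
declaring a predicted sign on a predictor halves the two-tailed p when the
estimate falls on the predicted side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import PhyloTree, canonical_label, prune_to_taxa, to_vcv

__all__ = [
    "Term",
    "ModelSpec",
    "PGLSFit",
    "MinimumNError",
    "fit_pgls",
    "profile_loglik",
    "r_squared",
    "partial_r2",
    "one_tailed_p",
    "residual_diagnostics",
    "DiagnosticsReport",
]

MIN_SPECIES = 5  # models are only run with five or more species
MIN_PER_CATEGORY = 5  # and five or more species per category of a binary predictor

Transform = Literal["none", "log", "log1p", "sqrt"]


class MinimumNError(ValueError):
    """Raised when a model would be fitted on too few species."""


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when the design matrix is singular (collinear columns)."""


@dataclass(frozen=True)
class Term:
    """One model variable: a trait-table column, a transform, and optionally
    a predicted sign ('+' or '-') that requests a one-tailed test."""

    column: str
    transform: Transform = "none"
    sign: Optional[str] = None

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log", "log1p", "sqrt"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.sign not in (None, "+", "-"):
            raise ValueError(f"predicted sign must be '+', '-' or None, got {self.sign!r}")

    @property
    def label(self) -> str:
        return self.column if self.transform == "none" else f"{self.transform}({self.column})"


@dataclass(frozen=True)
class ModelSpec:
    """A PGLS model: outcome, ordered predictors, and how lambda is handled.

    ``lambda_mode`` is either the string "ML" (profile-likelihood
    estimation on [0, 1]) or a fixed value in [0, 1].
    """

    outcome: Term
    predictors: tuple[Term, ...] = ()
    lambda_mode: "str | float" = "ML"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if isinstance(self.lambda_mode, str):
            if self.lambda_mode != "ML":
                raise ValueError("lambda_mode must be 'ML' or a fixed value in [0, 1]")
        elif not 0.0 <= float(self.lambda_mode) <= 1.0:
            raise ValueError("fixed lambda must lie in [0, 1]")

    def drop(self, column: str) -> "ModelSpec":
        """Spec with one predictor removed (for nested-model comparisons)."""
        kept = tuple(t for t in self.predictors if t.column != column)
        if len(kept) == len(self.predictors):
            raise KeyError(f"no predictor named {column!r} in model")
        return ModelSpec(self.outcome, kept, self.lambda_mode, self.name)


def _apply_transform(values: pd.Series, term: Term) -> np.ndarray:
    x = values.astype(float).to_numpy()
    if term.transform == "none":
        return x
    if term.transform == "log":
        bad = values.index[x <= 0]
        if len(bad):
            raise ValueError(
                f"log transform of {term.column!r} undefined for species with "
                f"non-positive values: {list(bad)}"
            )
        return np.log(x)
    if term.transform == "log1p":
        bad = values.index[x <= -1]
        if len(bad):
            raise ValueError(
                f"log1p transform of {term.column!r} undefined for species: {list(bad)}"
            )
        warnings.warn(
            f"log1p applied to {term.column!r}: a +1 offset precedes the log "
            "because the column contains zeros",
            stacklevel=3,
        )
        return np.log1p(x)
    bad = values.index[x < 0]
    if len(bad):
        raise ValueError(
            f"sqrt transform of {term.column!r} undefined for species with "
            f"negative values: {list(bad)}"
        )
    return np.sqrt(x)


@dataclass
class PGLSFit:
    """A fitted PGLS model and its full statistic suite."""

    spec: ModelSpec
    species: tuple[str, ...]
    terms: tuple[str, ...]  # coefficient labels, intercept first
    n: int
    k: int
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_two: np.ndarray
    p_one: np.ndarray  # NaN where no sign was predicted
    F: float
    df: tuple[int, int]
    p_model: float
    lambda_hat: float
    loglik: float
    rss: float
    rss_null: float
    R2: float
    R2_adj: float
    residuals_raw: np.ndarray
    residuals_whitened: np.ndarray
    fitted: np.ndarray
    y_whitened: np.ndarray = field(repr=False, default=None)
    fitted_whitened: np.ndarray = field(repr=False, default=None)
    _table: pd.DataFrame = field(repr=False, default=None)
    _tree: PhyloTree = field(repr=False, default=None)

    def p_value(self, column: str) -> float:
        """One-tailed p for ``column`` if a sign was predicted, else two-tailed."""
        i = self._coef_index(column)
        return float(self.p_one[i]) if np.isfinite(self.p_one[i]) else float(self.p_two[i])

    def coef(self, column: str) -> float:
        return float(self.beta[self._coef_index(column)])

    def t_stat(self, column: str) -> float:
        return float(self.t[self._coef_index(column)])

    def _coef_index(self, column: str) -> int:
        for i, term in enumerate(("(intercept)",) + tuple(p.column for p in self.spec.predictors)):
            if term == column:
                return i
        raise KeyError(f"no coefficient for {column!r}")

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient t confidence intervals, shape (k, 2)."""
        crit = stats.t.ppf(0.5 + level / 2.0, self.df[1])
        return np.column_stack([self.beta - crit * self.se, self.beta + crit * self.se])

    def term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p_two": self.p_two,
                "p_one": self.p_one,
            }
        )

    def summary(self) -> str:
        lines = [
            f"PGLS fit{': ' + self.spec.name if self.spec.name else ''}",
            f"  N = {self.n}, lambda = {self.lambda_hat:.2f}, "
            f"F{self.df[0]},{self.df[1]} = {self.F:.2f}, p = {self.p_model:.3g}",
            f"  R2 = {self.R2:.2f}, adj. R2 = {self.R2_adj:.2f}",
        ]
        for row in self.term_table().itertuples(index=False):
            p = row.p_one if np.isfinite(row.p_one) else row.p_two
            tail = "one-tailed" if np.isfinite(row.p_one) else "two-tailed"
            lines.append(
                f"  {row.term}: beta = {row.beta:.3f} (se {row.se:.3f}), "
                f"t = {row.t:.2f}, p = {p:.3g} ({tail})"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# core numerics


def _whitened_gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS via Cholesky whitening; returns (beta, rss, Xw, yw, logdetV)."""
    from scipy.linalg import solve_triangular

    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "lambda-scaled VCV numerically singular; consider adding a small "
            "diagonal jitter to the branch-length matrix"
        ) from exc
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficientError(
            "design matrix is rank deficient (collinear predictor columns)"
        )
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, Xw, yw, logdet


def profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    """ML profile log-likelihood of the GLS model at a given lambda.

    beta is profiled out by GLS and sigma^2 by its ML estimate RSS/n, so the
    returned value is a function of lambda alone.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    C = np.asarray(C, float)
    n = y.shape[0]
    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    _, rss, _, _, logdet = _whitened_gls(y, X, V)
    sigma2 = max(rss / n, np.finfo(float).tiny)
    return -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n + logdet)


def _ml_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray, grid_step: float = 0.01) -> float:
    """Grid pre-scan on [0, 1] then bounded refinement of the profile likelihood."""
    grid = np.arange(0.0, 1.0 + 1e-12, grid_step)
    lls = np.array([profile_loglik(l, y, X, C) for l in grid])
    i = int(np.argmax(lls))
    lo = max(0.0, grid[i] - grid_step)
    hi = min(1.0, grid[i] + grid_step)
    res = optimize.minimize_scalar(
        lambda l: -profile_loglik(float(np.clip(l, 0.0, 1.0)), y, X, C),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.clip(res.x, 0.0, 1.0))
    if -res.fun < lls[i]:  # refinement never allowed to do worse than the grid
        lam = float(grid[i])
    return lam


# ---------------------------------------------------------------------------
# model assembly and fitting


def _build_design(spec: ModelSpec, table: pd.DataFrame, tree: PhyloTree):
    cols = [spec.outcome.column] + [p.column for p in spec.predictors]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"model columns not found in trait table: {missing_cols}")

    data = table[cols].dropna()  # listwise deletion per model
    tree_canon = {canonical_label(t) for t in tree.tip_names}
    not_in_tree = [s for s in data.index if canonical_label(str(s)) not in tree_canon]
    if not_in_tree:
        raise KeyError(f"species absent from the tree: {not_in_tree}")

    n = len(data)
    if n < MIN_SPECIES:
        raise MinimumNError(
            f"model requires at least {MIN_SPECIES} species with complete data; got {n}"
        )
    for p in spec.predictors:
        vals = data[p.column]
        uniq = vals.unique()
        if len(uniq) == 2:  # binary/categorical predictor: 0/1 dummy coding
            counts = vals.value_counts()
            if counts.min() < MIN_PER_CATEGORY:
                raise MinimumNError(
                    f"binary predictor {p.column!r} needs at least "
                    f"{MIN_PER_CATEGORY} species per category; got {dict(counts)}"
                )
    if data[spec.outcome.column].nunique() <= 1:
        raise ValueError(f"outcome {spec.outcome.column!r} has zero variance")

    pruned = prune_to_taxa(tree, [str(s) for s in data.index])
    vcv = to_vcv(pruned)
    order = {canonical_label(t): i for i, t in enumerate(vcv.taxa)}
    data = data.iloc[np.argsort([order[canonical_label(str(s))] for s in data.index])]

    y = _apply_transform(data[spec.outcome.column], spec.outcome)
    Xcols = [np.ones(n)] + [_apply_transform(data[p.column], p) for p in spec.predictors]
    X = np.column_stack(Xcols)
    labels = ("(intercept)",) + tuple(p.label for p in spec.predictors)
    return y, X, labels, tuple(str(s) for s in data.index), vcv.matrix


def fit_pgls(spec: ModelSpec, table: pd.DataFrame, tree: PhyloTree) -> PGLSFit:
    """Fit a PGLS model on the species with complete data for all model columns.

    The tree is pruned to those species, lambda is estimated (or fixed per
    ``spec.lambda_mode``), and the full statistic suite is computed.
    """
    y, X, labels, species, C = _build_design(spec, table, tree)
    n, k = X.shape
    if n <= k:
        raise MinimumNError(f"model with {k} coefficients needs more than {k} species; got {n}")

    if spec.lambda_mode == "ML":
        lam = _ml_lambda(y, X, C)
    else:
        lam = float(spec.lambda_mode)

    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    beta, rss, Xw, yw, _ = _whitened_gls(y, X, V)

    dof = n - k
    sigma2 = rss / dof
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    p_two = 2.0 * stats.t.sf(np.abs(tvals), dof)

    signs = [None] + [p.sign for p in spec.predictors]
    p_one = np.full(k, np.nan)
    for i, s in enumerate(signs):
        if s is not None:
            p_one[i] = one_tailed_p(float(tvals[i]), dof, s)

    # intercept-only null at the focal model's lambda
    ones = np.ones((n, 1))
    _, rss_null, _, _, _ = _whitened_gls(y, ones, V)
    if k > 1:
        R2 = 1.0 - rss / rss_null if rss_null > 0 else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_null - rss) / (k - 1)) / (rss / dof) if rss > 0 else np.inf
        p_model = float(stats.f.sf(F, k - 1, dof))
    else:
        R2, F, p_model = 0.0, math.nan, math.nan
    R2_adj = 1.0 - (1.0 - R2) * (n - 1) / dof

    fitted_w = Xw @ beta
    fit = PGLSFit(
        spec=spec,
        species=species,
        terms=labels,
        n=n,
        k=k,
        beta=beta,
        se=se,
        t=tvals,
        p_two=p_two,
        p_one=p_one,
        F=float(F),
        df=(k - 1, dof),
        p_model=p_model,
        lambda_hat=lam,
        loglik=profile_loglik(lam, y, X, C),
        rss=rss,
        rss_null=float(rss_null),
        R2=float(R2),
        R2_adj=float(R2_adj),
        residuals_raw=y - X @ beta,
        residuals_whitened=yw - fitted_w,
        fitted=X @ beta,
        y_whitened=yw,
        fitted_whitened=fitted_w,
        _table=table,
        _tree=tree,
    )
    return fit


def r_squared(fit: PGLSFit, null_fit: PGLSFit) -> tuple[float, float]:
    """(R2, adjusted R2) of ``fit`` against an intercept-only null.

    Both models must be fitted on the same species; RSS are compared in the
    phylogenetically whitened space.
    """
    if set(fit.species) != set(null_fit.species):
        raise ValueError("fit and null_fit use different species sets")
    if null_fit.k != 1:
        raise ValueError("null_fit must be intercept-only")
    R2 = 1.0 - fit.rss / null_fit.rss
    R2_adj = 1.0 - (1.0 - R2) * (fit.n - 1) / (fit.n - fit.k)
    return float(R2), float(R2_adj)


def partial_r2(full: PGLSFit, reduced: PGLSFit) -> float:
    """Partial R^2 of the predictor dropped between ``full`` and ``reduced``.

    1 - RSS_full / RSS_reduced in the whitened space; each model keeps its
    own lambda_hat.
    """
    if set(full.species) != set(reduced.species):
        raise ValueError("full and reduced models use different species sets")
    if full.k != reduced.k + 1:
        raise ValueError("reduced model must drop exactly one predictor")
    if reduced.rss <= 0:
        return 0.0
    return float(1.0 - full.rss / reduced.rss)


def one_tailed_p(t: float, df: int, predicted_sign: str) -> float:
    """Directional p-value: P(T >= t) for a predicted '+', P(T <= t) for '-'."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if predicted_sign == "+":
        return float(stats.t.sf(t, df))
    if predicted_sign == "-":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"predicted sign must be '+' or '-', got {predicted_sign!r}")


# ---------------------------------------------------------------------------
# residual diagnostics


@dataclass
class DiagnosticsReport:
    shapiro_w: float
    shapiro_p: float
    passed: bool
    recommendation: Optional[str]
    notes: list[str]


_TRANSFORM_ORDER = ("none", "log", "sqrt")


def residual_diagnostics(fit: PGLSFit) -> DiagnosticsReport:
    """Shapiro-Wilk normality check of the whitened residuals, plus a
    transform recommendation for the outcome.

    Transforms are tried in the order none -> log -> sqrt and the first
    whose refit yields Shapiro p > 0.05 is recommended (log falls back to a
    +1 offset, loudly, when the outcome contains zeros).  With fewer than 8
    species the test is skipped with a notice.
    """
    notes: list[str] = []
    if fit.n < 8:
        return DiagnosticsReport(math.nan, math.nan, True, None,
                                 ["n < 8: normality test skipped"])
    w, p = stats.shapiro(fit.residuals_whitened)
    if p > 0.05:
        return DiagnosticsReport(float(w), float(p), True, "none", notes)

    recommendation = None
    outcome_vals = fit._table.loc[list(fit.species), fit.spec.outcome.column].astype(float)
    for tr in _TRANSFORM_ORDER[1:]:
        actual = tr
        if tr == "log" and (outcome_vals <= 0).any():
            if (outcome_vals < 0).any():
                notes.append("log transform unavailable: negative outcome values")
                continue
            actual = "log1p"
        try:
            respec = ModelSpec(
                Term(fit.spec.outcome.column, actual, fit.spec.outcome.sign),
                fit.spec.predictors,
                fit.spec.lambda_mode,
                fit.spec.name,
            )
            refit = fit_pgls(respec, fit._table, fit._tree)
            _, p_alt = stats.shapiro(refit.residuals_whitened)
        except (ValueError, np.linalg.LinAlgError) as exc:
            notes.append(f"{tr} refit failed: {exc}")
            continue
        if p_alt > 0.05:
            recommendation = actual
            break
    if recommendation is None:
        notes.append("no transform in (log, sqrt) normalised the residuals")
    return DiagnosticsReport(float(w), float(p), False, recommendation, notes)
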