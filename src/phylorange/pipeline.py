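"""The stepwise hypothesis-testing pipeline.

Given a trait table and a phylogeny, the pipeline reproduces the manual,
stepwise comparative procedure this package implements:

1. *Assumption checks* — the outcome of interest must still show an annual
   home range (AHR) association, and (when the column is available) captive
   juvenile mortality must reflect infant mortality.
2. *Screening* — each candidate correlate of AHR is tested for covariation
   with log-AHR by PGLS (two-tailed by default); candidates failing the
   minimum-N rule are marked skipped, never silently dropped.
3. *Collinearity* — confirmed correlates are pairwise-tested; significant
   pairs are flagged.
4. *Univariate welfare models* — each confirmed correlate is regressed
   against the welfare outcome, one-tailed where a direction is predicted.
5. *Mediation (covariate elimination)* — each univariately significant
   correlate is refitted alongside AHR.  A correlate that stays significant
   is an independent predictor; one that loses significance while AHR was
   its only claim is a by-product of AHR.
6. *Combined collinear model* — collinear surviving correlates are placed
   in one model (with AHR) to identify the truly predictive term.
7. *Mortality models* — candidates are tested against juvenile mortality
   with an altriciality control, reporting the candidate's partial R^2.

Model selection is deliberately manual (no AIC): sample sizes and
transformations vary per model, so each step is an explicit hypothesis
test at a configured alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pgls import (
    MinimumNError,
    ModelSpec,
    PGLSFit,
    Term,
    fit_pgls,
    partial_r2,
)
from .trees import PhyloTree

__all__ = [
    "ScreeningResult",
    "MediationResult",
    "MortalityResult",
    "PipelineConfig",
    "PipelineReport",
    "screen_correlates",
    "collinearity_check",
    "univariate_outcome_models",
    "mediation_step",
    "combined_collinear_model",
    "mortality_models",
    "assumption_checks",
    "run_pipeline",
]

ALPHA = 0.05
TREND = 0.1  # p <= 0.1 reported as a trend


@dataclass
class ScreeningResult:
    correlate: str
    n: Optional[int]
    fit: Optional[PGLSFit]
    status: str  # confirmed | rejected | skipped
    p: float = math.nan
    reason: str = ""


@dataclass
class MediationResult:
    correlate: str
    univariate: PGLSFit
    joint: Optional[PGLSFit]
    classification: str  # byproduct_of_AHR | independent_predictor | shared
    reason: str = ""

    @property
    def t_change(self) -> float:
        """Descriptive shift in the correlate's t from univariate to joint."""
        if self.joint is None:
            return math.nan
        return self.joint.t_stat(self.correlate) - self.univariate.t_stat(self.correlate)


@dataclass
class MortalityResult:
    correlate: str
    univariate: Optional[PGLSFit]
    controlled: Optional[PGLSFit]
    partial_r2: float = math.nan
    reason: str = ""


@dataclass
class AssumptionReport:
    ahr_welfare_fit: Optional[PGLSFit]
    ahr_welfare_pass: Optional[bool]
    mortality_infant_fit: Optional[PGLSFit]
    mortality_infant_pass: Optional[bool]
    notes: list[str] = field(default_factory=list)

    @property
    def all_pass(self) -> bool:
        return all(p is not False for p in (self.ahr_welfare_pass, self.mortality_infant_pass))


@dataclass(frozen=True)
class PipelineConfig:
    """Column roles, transforms, predicted signs and thresholds for one run.

    ``candidates`` are the potential correlates of AHR to screen; each
    Term's ``sign`` is the direction predicted for its effect on the
    *welfare outcome* (used one-tailed in steps 4-7), while screening and
    collinearity are two-tailed.  AHR is always log-transformed.
    """

    ahr_col: str = "ahr_km2"
    outcome: Term = Term("route_tracing", sign=None)
    mortality: Term = Term("juvenile_mortality", sign=None)
    altriciality: Term = Term("age_eyes_open")
    infant_mortality_col: Optional[str] = None
    candidates: tuple[Term, ...] = ()
    ahr_outcome_sign: Optional[str] = "+"  # wider-ranging species fare worse
    alpha: float = ALPHA
    screening_tails: str = "two"  # one | two

    @property
    def ahr_term(self) -> Term:
        return Term(self.ahr_col, "log", self.ahr_outcome_sign)


@dataclass
class PipelineReport:
    """Everything the pipeline computed, with provenance and a decision log."""

    config: PipelineConfig
    assumptions: Optional[AssumptionReport]
    screening: list[ScreeningResult]
    collinearity: Optional[pd.DataFrame]
    collinear_pairs: list[tuple[str, str]]
    univariate: dict[str, "PGLSFit | str"]
    mediation: dict[str, MediationResult]
    combined: Optional[PGLSFit]
    final_predictors: list[str]
    mortality: dict[str, MortalityResult]
    log: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # -- serialisation -------------------------------------------------

    def screening_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"correlate": r.correlate, "n": r.n, "p": r.p, "status": r.status,
                 "reason": r.reason}
                for r in self.screening
            ]
        )

    def univariate_table(self) -> pd.DataFrame:
        """Table-1 analogue: one row per univariate welfare model."""
        rows = []
        for name, fit in self.univariate.items():
            if isinstance(fit, str):
                rows.append({"correlate": name, "note": fit})
                continue
            rows.append(
                {
                    "correlate": name,
                    "t": fit.t_stat(name),
                    "F": fit.F,
                    "df1": fit.df[0],
                    "df2": fit.df[1],
                    "N": fit.n,
                    "R2_adj": fit.R2_adj,
                    "lambda": fit.lambda_hat,
                    "p": fit.p_value(name),
                }
            )
        return pd.DataFrame(rows)

    def mediation_table(self) -> pd.DataFrame:
        """Table-2 analogue: correlate and AHR terms in the joint models."""
        rows = []
        for name, m in self.mediation.items():
            row = {"correlate": name, "classification": m.classification,
                   "t_univariate": m.univariate.t_stat(name),
                   "p_univariate": m.univariate.p_value(name)}
            if m.joint is not None:
                row.update(
                    t_joint=m.joint.t_stat(name),
                    p_joint=m.joint.p_value(name),
                    t_ahr=m.joint.t_stat(self.config.ahr_col),
                    p_ahr=m.joint.p_value(self.config.ahr_col),
                    N=m.joint.n,
                    R2_adj=m.joint.R2_adj,
                    **{"lambda": m.joint.lambda_hat},
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def mortality_table(self) -> pd.DataFrame:
        rows = []
        for name, m in self.mortality.items():
            row = {"correlate": name, "partial_R2": m.partial_r2, "note": m.reason}
            if m.univariate is not None:
                row.update(t_univariate=m.univariate.t_stat(name),
                           p_univariate=m.univariate.p_value(name),
                           N_univariate=m.univariate.n)
            if m.controlled is not None:
                row.update(t_controlled=m.controlled.t_stat(name),
                           p_controlled=m.controlled.p_value(name),
                           N_controlled=m.controlled.n,
                           R2_adj_controlled=m.controlled.R2_adj)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "final_predictors": self.final_predictors,
            "screening": self.screening_table().to_dict(orient="records"),
            "univariate": self.univariate_table().to_dict(orient="records"),
            "mediation": self.mediation_table().to_dict(orient="records"),
            "mortality": self.mortality_table().to_dict(orient="records"),
            "collinear_pairs": self.collinear_pairs,
            "log": self.log,
        }

    def save(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.screening_table().to_csv(outdir / "screening.tsv", sep="\t", index=False)
        self.univariate_table().to_csv(outdir / "univariate.tsv", sep="\t", index=False)
        self.mediation_table().to_csv(outdir / "mediation.tsv", sep="\t", index=False)
        self.mortality_table().to_csv(outdir / "mortality.tsv", sep="\t", index=False)
        if self.collinearity is not None:
            self.collinearity.to_csv(outdir / "collinearity.tsv", sep="\t")
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=float) + "\n"
        )
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")


# ---------------------------------------------------------------------------
# pipeline steps


def _screen_p(fit: PGLSFit, column: str, tails: str) -> float:
    if tails == "two":
        return float(fit.p_two[fit._coef_index(column)])
    return fit.p_value(column)


def screen_correlates(
    table: pd.DataFrame,
    tree: PhyloTree,
    ahr_col: str,
    candidates: Sequence[Term],
    alpha: float = ALPHA,
    tails: str = "two",
) -> list[ScreeningResult]:
    """Test which candidates covary with log-AHR (candidate ~ log AHR)."""
    out = []
    ahr = Term(ahr_col, "log")
    for cand in candidates:
        spec = ModelSpec(Term(cand.column, cand.transform), (ahr,),
                         name=f"{cand.column} ~ log({ahr_col})")
        try:
            fit = fit_pgls(spec, table, tree)
        except MinimumNError as exc:
            out.append(ScreeningResult(cand.column, None, None, "skipped", reason=str(exc)))
            continue
        except (ValueError, np.linalg.LinAlgError) as exc:
            out.append(ScreeningResult(cand.column, None, None, "skipped", reason=str(exc)))
            continue
        p = _screen_p(fit, ahr_col, tails)
        status = "confirmed" if p < alpha else "rejected"
        out.append(ScreeningResult(cand.column, fit.n, fit, status, p=p))
    return out


def collinearity_check(
    table: pd.DataFrame,
    tree: PhyloTree,
    variables: Sequence[Term],
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise PGLS association p-values among ``variables``.

    Returns a symmetric DataFrame of two-tailed p-values (diagonal 0, i.e.
    a variable is trivially collinear with itself; untestable pairs NaN)
    and the list of flagged off-diagonal pairs with p < alpha.
    """
    if len(variables) < 2:
        raise ValueError("collinearity check needs at least 2 variables")
    names = [v.column for v in variables]
    P = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    flagged: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(len(variables)), 2):
        vi, vj = variables[i], variables[j]
        spec = ModelSpec(Term(vi.column, vi.transform),
                         (Term(vj.column, vj.transform),),
                         name=f"{vi.column} ~ {vj.column}")
        try:
            fit = fit_pgls(spec, table, tree)
            p = float(fit.p_two[fit._coef_index(vj.column)])
        except (MinimumNError, ValueError, np.linalg.LinAlgError):
            continue  # untestable pair stays NaN
        P.iloc[i, j] = P.iloc[j, i] = p
        if p < alpha:
            flagged.append((vi.column, vj.column))
    np.fill_diagonal(P.values, 0.0)
    return P, flagged


def univariate_outcome_models(
    table: pd.DataFrame,
    tree: PhyloTree,
    outcome: Term,
    predictors: Sequence[Term],
) -> dict[str, "PGLSFit | str"]:
    """One univariate PGLS per predictor; one-tailed where a sign is given.

    Untestable predictors map to a string explaining the skip.
    """
    out: dict[str, "PGLSFit | str"] = {}
    for pred in predictors:
        spec = ModelSpec(outcome, (pred,), name=f"{outcome.column} ~ {pred.column}")
        try:
            out[pred.column] = fit_pgls(spec, table, tree)
        except (MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
            out[pred.column] = f"untestable: {exc}"
    return out


def mediation_step(
    table: pd.DataFrame,
    tree: PhyloTree,
    outcome: Term,
    correlate: Term,
    ahr: Term,
    alpha: float = ALPHA,
) -> MediationResult:
    """Covariate-elimination test of one correlate against AHR.

    The correlate is *independent* if it stays significant with AHR in the
    model; a *byproduct of AHR* if it was significant alone but loses
    significance next to AHR; *shared* if it had no univariate effect to
    begin with (nothing for AHR to eliminate).
    """
    uni = fit_pgls(ModelSpec(outcome, (correlate,),
                             name=f"{outcome.column} ~ {correlate.column}"),
                   table, tree)
    joint = fit_pgls(ModelSpec(outcome, (correlate, ahr),
                               name=f"{outcome.column} ~ {correlate.column} + {ahr.column}"),
                     table, tree)
    p_joint = joint.p_value(correlate.column)
    p_uni = uni.p_value(correlate.column)
    if p_joint < alpha:
        cls = "independent_predictor"
    elif p_uni < alpha:
        cls = "byproduct_of_AHR"
    else:
        cls = "shared"
    return MediationResult(correlate.column, uni, joint, cls)


def combined_collinear_model(
    table: pd.DataFrame,
    tree: PhyloTree,
    outcome: Term,
    predictors: Sequence[Term],
) -> PGLSFit:
    """Joint model over collinear surviving predictors (plus AHR)."""
    if len(predictors) < 2:
        raise ValueError("combined model needs at least 2 predictors")
    name = f"{outcome.column} ~ " + " + ".join(p.column for p in predictors)
    return fit_pgls(ModelSpec(outcome, tuple(predictors), name=name), table, tree)


def mortality_models(
    table: pd.DataFrame,
    tree: PhyloTree,
    mortality: Term,
    altriciality: Term,
    candidates: Sequence[Term],
) -> dict[str, MortalityResult]:
    """Univariate and altriciality-controlled mortality models per candidate.

    The candidate's partial R^2 in the controlled model is computed against
    a reduced (altriciality-only) fit on the same species.
    """
    out: dict[str, MortalityResult] = {}
    for cand in candidates:
        uni = controlled = None
        pr2 = math.nan
        reason = ""
        try:
            uni = fit_pgls(ModelSpec(mortality, (cand,),
                                     name=f"{mortality.column} ~ {cand.column}"),
                           table, tree)
            controlled = fit_pgls(
                ModelSpec(mortality, (cand, Term(altriciality.column, altriciality.transform)),
                          name=f"{mortality.column} ~ {cand.column} + {altriciality.column}"),
                table, tree,
            )
            reduced = fit_pgls(
                ModelSpec(mortality, (Term(altriciality.column, altriciality.transform),)),
                table.loc[list(controlled.species)], tree,
            )
            pr2 = partial_r2(controlled, reduced)
        except (MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
            reason = str(exc)
        out[cand.column] = MortalityResult(cand.column, uni, controlled, pr2, reason)
    return out


def assumption_checks(
    table: pd.DataFrame,
    tree: PhyloTree,
    config: PipelineConfig,
) -> AssumptionReport:
    """Preconditions of the whole analysis.

    (i) AHR predicts the welfare outcome (one-tailed, wider-ranging worse);
    (ii) juvenile mortality reflects infant mortality, when an infant
    mortality column is configured.  Missing columns yield notices, not
    failures.
    """
    notes: list[str] = []
    ahr_fit = ahr_pass = None
    try:
        ahr_fit = fit_pgls(
            ModelSpec(config.outcome, (config.ahr_term,),
                      name=f"{config.outcome.column} ~ log({config.ahr_col})"),
            table, tree,
        )
        ahr_pass = ahr_fit.p_value(config.ahr_col) < config.alpha
    except (KeyError, MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
        notes.append(f"AHR-welfare check unavailable: {exc}")

    mi_fit = mi_pass = None
    if config.infant_mortality_col is None:
        notes.append("no infant-mortality column configured; check (ii) not run")
    else:
        try:
            mi_fit = fit_pgls(
                ModelSpec(config.mortality, (Term(config.infant_mortality_col),),
                          name=f"{config.mortality.column} ~ {config.infant_mortality_col}"),
                table, tree,
            )
            mi_pass = mi_fit.p_value(config.infant_mortality_col) < config.alpha
        except (KeyError, MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
            notes.append(f"mortality-infant check unavailable: {exc}")
    return AssumptionReport(ahr_fit, ahr_pass, mi_fit, mi_pass, notes)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    table: pd.DataFrame,
    tree: PhyloTree,
    config: PipelineConfig,
    provenance: Optional[dict] = None,
) -> PipelineReport:
    """Run the full stepwise procedure and return a structured report."""
    log: list[str] = []
    alpha = config.alpha

    assumptions = assumption_checks(table, tree, config)
    for note in assumptions.notes:
        log.append(f"assumptions: {note}")

    screening = screen_correlates(
        table, tree, config.ahr_col, config.candidates, alpha, config.screening_tails
    )
    confirmed = [r.correlate for r in screening if r.status == "confirmed"]
    for r in screening:
        log.append(f"screening: {r.correlate} -> {r.status}"
                   + (f" ({r.reason})" if r.reason else f" (p={r.p:.3g})"))
    cand_by_name = {c.column: c for c in config.candidates}

    collinearity = None
    collinear_pairs: list[tuple[str, str]] = []
    if len(confirmed) >= 2:
        collinearity, collinear_pairs = collinearity_check(
            table, tree, [cand_by_name[c] for c in confirmed], alpha
        )
        for a, b in collinear_pairs:
            log.append(f"collinearity: {a} x {b} flagged")

    univariate = univariate_outcome_models(
        table, tree, config.outcome, [cand_by_name[c] for c in confirmed]
    )
    uni_significant = [
        name for name, fit in univariate.items()
        if isinstance(fit, PGLSFit) and fit.p_value(name) < alpha
    ]
    for name, fit in univariate.items():
        if isinstance(fit, str):
            log.append(f"univariate: {name} {fit}")
        else:
            log.append(f"univariate: {name} p={fit.p_value(name):.3g} N={fit.n}")

    mediation: dict[str, MediationResult] = {}
    for name in uni_significant:
        try:
            mediation[name] = mediation_step(
                table, tree, config.outcome, cand_by_name[name], config.ahr_term, alpha
            )
            log.append(f"mediation: {name} -> {mediation[name].classification}")
        except (MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
            log.append(f"mediation: {name} untestable ({exc})")

    survivors = [n for n, m in mediation.items()
                 if m.classification == "independent_predictor"]
    flagged = {frozenset(p) for p in collinear_pairs}
    combined = None
    final = list(survivors)
    if len(survivors) >= 2:
        collinear_survivors = sorted(
            {n for a in survivors for b in survivors
             if a != b and frozenset((a, b)) in flagged for n in (a, b)}
        )
        if len(collinear_survivors) >= 2:
            preds = [cand_by_name[n] for n in collinear_survivors] + [config.ahr_term]
            try:
                combined = combined_collinear_model(table, tree, config.outcome, preds)
                final = [n for n in collinear_survivors
                         if combined.p_value(n) < alpha]
                final += [n for n in survivors if n not in collinear_survivors]
                log.append("combined model over collinear survivors: "
                           + ", ".join(f"{n} p={combined.p_value(n):.3g}"
                                       for n in collinear_survivors))
            except (MinimumNError, ValueError, np.linalg.LinAlgError) as exc:
                log.append(f"combined model untestable ({exc})")

    mortality = mortality_models(
        table, tree, config.mortality, config.altriciality, config.candidates
    )
    for name, m in mortality.items():
        if m.reason:
            log.append(f"mortality: {name} untestable ({m.reason})")
        else:
            log.append(f"mortality: {name} p={m.controlled.p_value(name):.3g} "
                       f"partialR2={m.partial_r2:.3g}")

    return PipelineReport(
        config=config,
        assumptions=assumptions,
        screening=screening,
        collinearity=collinearity,
        collinear_pairs=collinear_pairs,
        univariate=univariate,
        mediation=mediation,
        combined=combined,
        final_predictors=sorted(final),
        mortality=mortality,
        log=log,
        provenance=provenance or {},
    )
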