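"""Robustness checks: leave-one-out species influence and treeblock refits.

Comparative datasets are small (often 15-40 species), so a single extreme
species can drive a regression result.  ``loo_influence`` refits a model
with each species removed in turn and standardises the shift in every
slope estimate by the spread of the leave-one-out estimates; a species
whose removal shifts any slope by more than 2 such units is flagged
influential, and the model without it is reported with recomputed slope
and p-value.  ``treeblock_refit`` repeats a fit over a set of alternative
phylogenies and summarises the spread of estimates, quantifying robustness
to phylogenetic uncertainty.  Lambda is re-estimated in every refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pgls import MinimumNError, ModelSpec, PGLSFit, fit_pgls
from .trees import PhyloTree, canonical_label

__all__ = [
    "InfluenceRecord",
    "TreeblockSummary",
    "loo_influence",
    "refit_without",
    "treeblock_refit",
]

INFLUENCE_THRESHOLD = 2.0
_DEGENERATE_SD = 1e-12


@dataclass
class InfluenceRecord:
    species: str
    terms: tuple[str, ...]  # slope terms only (intercept excluded)
    beta_full: np.ndarray
    beta_without: np.ndarray
    standardized_difference: np.ndarray
    influential: bool
    degenerate: bool = False
    refit_without: Optional[PGLSFit] = None


@dataclass
class TreeblockSummary:
    terms: tuple[str, ...]
    n_trees: int
    n_skipped: int
    stats: pd.DataFrame  # per term x statistic: median/min/max over trees
    lambda_summary: dict[str, float]
    fraction_significant: dict[str, float]
    stable: dict[str, bool]
    fits: list[PGLSFit] = field(default_factory=list, repr=False)
    skipped: list[str] = field(default_factory=list)


def _slope_terms(fit: PGLSFit) -> tuple[str, ...]:
    return tuple(p.column for p in fit.spec.predictors)


def refit_without(
    spec: ModelSpec,
    table: pd.DataFrame,
    tree: PhyloTree,
    drop: Sequence[str],
) -> PGLSFit:
    """Refit the model with the listed species removed (canonical matching).

    Multiple species may be dropped simultaneously, e.g. to reproduce
    "with both influential species excluded" analyses.
    """
    drop_canon = {canonical_label(str(s)) for s in drop}
    keep = [s for s in table.index if canonical_label(str(s)) not in drop_canon]
    if len(keep) == len(table):
        unknown = sorted(drop_canon - {canonical_label(str(s)) for s in table.index})
        if unknown and drop:
            raise KeyError(f"species not present in table: {unknown}")
    return fit_pgls(spec, table.loc[keep], tree)


def loo_influence(
    spec: ModelSpec,
    table: pd.DataFrame,
    tree: PhyloTree,
    threshold: float = INFLUENCE_THRESHOLD,
    denominator: str = "loo_sd",
) -> list[InfluenceRecord]:
    """Leave-one-out influence diagnostics for every species in the model.

    For species *i* and slope term *m*, the standardized difference is
    ``(beta_m(-i) - beta_m(full)) / denom_m`` where ``denom_m`` is the
    standard deviation of the leave-one-out estimates of term *m*
    (``denominator='loo_sd'``, the default) or the full-model standard
    error (``denominator='se'``).  Species with |difference| > ``threshold``
    on any term are flagged, and the model without each flagged species is
    attached, refitted with its own lambda.

    Deletions that would push the model below the minimum-N rule are
    skipped with a log entry in the record list (the species simply does
    not appear).
    """
    if denominator not in ("loo_sd", "se"):
        raise ValueError("denominator must be 'loo_sd' or 'se'")
    full = fit_pgls(spec, table, tree)
    terms = _slope_terms(full)
    if not terms:
        raise ValueError("influence analysis needs at least one slope term")
    beta_full = np.array([full.coef(t) for t in terms])

    loo_species: list[str] = []
    loo_beta: list[np.ndarray] = []
    loo_fits: dict[str, PGLSFit] = {}
    for sp in full.species:
        try:
            f = refit_without(spec, table, tree, [sp])
        except MinimumNError:
            continue
        loo_species.append(sp)
        loo_beta.append(np.array([f.coef(t) for t in terms]))
        loo_fits[sp] = f
    B = np.vstack(loo_beta)

    sd = B.std(axis=0, ddof=1) if len(B) > 1 else np.zeros(len(terms))
    if denominator == "se":
        denom = np.array([full.se[full._coef_index(t)] for t in terms])
    else:
        denom = sd
    degenerate = denom <= _DEGENERATE_SD * np.maximum(1.0, np.abs(beta_full))

    records: list[InfluenceRecord] = []
    for sp, b in zip(loo_species, B):
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(degenerate, np.nan, (b - beta_full) / np.where(degenerate, 1.0, denom))
        flagged = bool(np.any(np.abs(z[~degenerate]) > threshold)) if (~degenerate).any() else False
        records.append(
            InfluenceRecord(
                species=sp,
                terms=terms,
                beta_full=beta_full,
                beta_without=b,
                standardized_difference=z,
                influential=flagged,
                degenerate=bool(degenerate.all()),
                refit_without=loo_fits[sp] if flagged else None,
            )
        )
    return records


def influence_table(records: Sequence[InfluenceRecord]) -> pd.DataFrame:
    """Flat TSV-ready view of a list of InfluenceRecords."""
    rows = []
    for r in records:
        for i, term in enumerate(r.terms):
            rows.append(
                {
                    "species": r.species,
                    "term": term,
                    "beta_full": r.beta_full[i],
                    "beta_without": r.beta_without[i],
                    "standardized_difference": r.standardized_difference[i],
                    "influential": r.influential,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)


def treeblock_refit(
    spec: ModelSpec,
    table: pd.DataFrame,
    trees: Sequence[PhyloTree],
    alpha: float = 0.05,
    stability: float = 0.95,
) -> TreeblockSummary:
    """Refit one model over a block of alternative phylogenies.

    Trees missing any of the model's species are skipped with a notice.
    Per slope term the summary reports median/min/max of (beta, t, p) over
    trees, the lambda-hat distribution, the fraction of trees on which the
    term is significant at ``alpha``, and a stability verdict (significant
    on at least ``stability`` of the usable trees).
    """
    if not trees:
        raise ValueError("treeblock must contain at least one tree")
    fits: list[PGLSFit] = []
    skipped: list[str] = []
    for i, tr in enumerate(trees):
        try:
            fits.append(fit_pgls(spec, table, tr))
        except KeyError as exc:
            skipped.append(f"tree {i}: {exc}")
    if not fits:
        raise ValueError("no tree in the block contains the model's species: "
                         + "; ".join(skipped))
    terms = _slope_terms(fits[0])

    rows = []
    frac_sig: dict[str, float] = {}
    stable: dict[str, bool] = {}
    for term in terms:
        beta = np.array([f.coef(term) for f in fits])
        t = np.array([f.t_stat(term) for f in fits])
        p = np.array([f.p_value(term) for f in fits])
        for stat, vals in (("beta", beta), ("t", t), ("p", p)):
            rows.append({"term": term, "stat": stat,
                         "median": float(np.median(vals)),
                         "min": float(vals.min()), "max": float(vals.max())})
        frac_sig[term] = float(np.mean(p < alpha))
        stable[term] = frac_sig[term] >= stability
    lam = np.array([f.lambda_hat for f in fits])
    lambda_summary = {"median": float(np.median(lam)),
                      "min": float(lam.min()), "max": float(lam.max())}
    return TreeblockSummary(
        terms=terms,
        n_trees=len(fits),
        n_skipped=len(skipped),
        stats=pd.DataFrame(rows),
        lambda_summary=lambda_summary,
        fraction_significant=frac_sig,
        stable=stable,
        fits=fits,
        skipped=skipped,
    )
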