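"""Collinearity screening and exhaustive AIC model selection.

Screening runs in two passes. First, variance inflation factors: covariate j
is regressed on all the others, VIF_j = 1/(1 - R²_j), and the worst offender
above the threshold (default 10) is removed until none remains. Second,
pairwise correlation: for every surviving pair whose squared Pearson
correlation exceeds the threshold (default 0.7), the member lower in a
user-supplied priority ordering is dropped. The priority encodes which
covariate is hypothesised to matter more for bears or conflict — a judgment
call, so it is required input, never inferred.

Model search then fits every subset of the screened covariates (the
categorical land-cover term is atomic: all its dummies enter or leave
together), ranks by AIC, and applies the parsimony rule: among candidates
within ΔAIC ≤ 2.0 of the best, the one with the fewest terms is selected
(ties: lowest AIC, then lexicographic term order). The bootstrap is skipped
during the search — AIC needs only the maximised likelihood — and applied
only to the selected model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .rspf import (ConvergenceError, DesignMatrix, RSPFFit, SeparationError,
                   fit_rspf)

logger = logging.getLogger(__name__)

__all__ = ["ScreeningReport", "ModelRanking", "compute_vif",
           "screen_covariates", "enumerate_subsets", "rank_and_select",
           "apply_parsimony_rule", "refit_selected"]

MAX_SUBSET_COVARIATES = 20


@dataclass
class ScreeningReport:
    """Collinearity screen outcome: statistics, removals and survivors."""

    vif: dict[str, float]
    r2_matrix: pd.DataFrame
    removed: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)


@dataclass
class ModelRanking:
    """All-subsets search result: one row per candidate, best-AIC first.

    ``rows`` columns: terms (tuple), n_terms, k, aic, delta_aic.
    ``selected`` indexes the chosen row after the parsimony rule.
    """

    rows: pd.DataFrame
    selected: int

    @property
    def selected_terms(self) -> tuple[str, ...]:
        return tuple(self.rows.iloc[self.selected]["terms"])

    def table(self) -> pd.DataFrame:
        """Human-readable ranking (formula string, df, AIC, ΔAIC)."""
        out = self.rows.copy()
        out["model"] = [" + ".join(t) if t else "(intercept only)"
                        for t in out["terms"]]
        return out[["model", "k", "aic", "delta_aic"]].rename(columns={"k": "df"})


def compute_vif(table: pd.DataFrame | np.ndarray,
                names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors of a set of continuous covariates.

    VIF_j = 1/(1 - R²_j) with R²_j from the least-squares regression of
    covariate j on all the others (with intercept). Linearly dependent
    columns report ``inf``.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        names = names or [f"x{j}" for j in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        Z = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_tot = ((y - y.mean()) ** 2).sum()
        ss_res = (resid ** 2).sum()
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _pairwise_r2(df: pd.DataFrame) -> pd.DataFrame:
    r = df.corr(method="pearson")
    return r ** 2


def screen_covariates(table: pd.DataFrame, priority: list[str],
                      vif_threshold: float = 10.0,
                      r2_threshold: float = 0.7,
                      use_abs_r: bool = False) -> ScreeningReport:
    """Two-stage collinearity screen (VIF, then pairwise correlation).

    ``priority`` must list every covariate, most important first; it breaks
    correlated pairs. With ``use_abs_r`` the pair rule triggers on
    |r| > threshold instead of r² > threshold.
    """
    cols = list(table.columns)
    missing = [c for c in cols if c not in priority]
    if missing:
        raise ValueError(f"priority ordering does not cover: {missing}")
    rank = {c: priority.index(c) for c in cols}
    removed: list[dict] = []
    current = cols.copy()

    # stage 1: iteratively drop the worst VIF offender
    while len(current) >= 2:
        vifs = compute_vif(table[current])
        worst = max(current, key=lambda c: vifs[c])
        if vifs[worst] <= vif_threshold:
            break
        current.remove(worst)
        removed.append({"covariate": worst, "reason": "vif",
                        "statistic": vifs[worst]})
        logger.info("screen: removed %s (VIF = %.2f)", worst, vifs[worst])

    # stage 2: correlated pairs, lower priority loses
    r2 = _pairwise_r2(table[current])
    stat = r2 ** 0.5 if use_abs_r else r2
    changed = True
    while changed:
        changed = False
        for a, b in combinations(sorted(current, key=rank.get), 2):
            if a in current and b in current and stat.loc[a, b] > r2_threshold:
                loser = a if rank[a] > rank[b] else b
                current.remove(loser)
                removed.append({"covariate": loser,
                                "reason": "abs_r" if use_abs_r else "r2",
                                "statistic": float(stat.loc[a, b]),
                                "paired_with": a if loser == b else b})
                logger.info("screen: removed %s (pair statistic %.3f with %s)",
                            loser, stat.loc[a, b], a if loser == b else b)
                changed = True
                break

    final_vif = compute_vif(table[current]) if len(current) >= 2 else {
        c: 1.0 for c in current}
    return ScreeningReport(vif=final_vif, r2_matrix=_pairwise_r2(table[cols]),
                           removed=removed, retained=current)


def enumerate_subsets(covariates: list[str]) -> list[tuple[str, ...]]:
    """All 2**n candidate term-sets (including the intercept-only model).

    Refuses more than 20 covariates — the search is exhaustive by design and
    past that point it is a blow-up, not an analysis.
    """
    n = len(covariates)
    if n < 1:
        raise ValueError("need at least one covariate")
    if n > MAX_SUBSET_COVARIATES:
        raise ValueError(
            f"{n} covariates would mean {2 ** n} models; refusing above "
            f"{MAX_SUBSET_COVARIATES}")
    out: list[tuple[str, ...]] = []
    for mask in range(2 ** n):
        out.append(tuple(covariates[j] for j in range(n) if mask >> j & 1))
    return out


def rank_and_select(data: DesignMatrix, subsets: list[tuple[str, ...]],
                    delta_threshold: float = 2.0,
                    seed: int | None = None) -> ModelRanking:
    """Fit every candidate subset, rank by AIC and apply the parsimony rule.

    Subsets whose fit fails to converge (or separates) are excluded and
    logged. Selection: among rows with ΔAIC ≤ ``delta_threshold``, the fewest
    terms; ties broken by lower AIC, then lexicographic term order.
    """
    recs = []
    for terms in subsets:
        sub = data.subset(list(terms))
        try:
            fit = fit_rspf(sub, B=0, seed=seed)
        except (ConvergenceError, SeparationError) as err:
            logger.warning("subset %s excluded: %s", terms, err)
            continue
        recs.append({"terms": tuple(terms), "n_terms": len(terms),
                     "k": fit.k, "aic": fit.aic, "loglik": fit.loglik})
    if not recs:
        raise RuntimeError("no candidate model converged")
    rows = pd.DataFrame(recs).sort_values("aic", kind="mergesort").reset_index(drop=True)
    rows["delta_aic"] = rows["aic"] - rows["aic"].iloc[0]
    return ModelRanking(rows=rows,
                        selected=apply_parsimony_rule(rows, delta_threshold))


def apply_parsimony_rule(rows: pd.DataFrame, delta_threshold: float = 2.0) -> int:
    """Index of the chosen row: among candidates with ΔAIC ≤ threshold, the
    fewest terms; ties broken by lower AIC, then lexicographic term order."""
    window = rows[rows["delta_aic"] <= delta_threshold]
    return int(window.sort_values(["n_terms", "aic", "terms"],
                                  kind="mergesort").index[0])


def refit_selected(data: DesignMatrix, ranking: ModelRanking,
                   B: int = 1000, seed: int | None = None) -> RSPFFit:
    """Refit the selected model with the bootstrap enabled."""
    return fit_rspf(data.subset(list(ranking.selected_terms)), B=B, seed=seed)
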