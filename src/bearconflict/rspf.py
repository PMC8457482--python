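"""Logistic resource-selection probability functions under a use-availability design.

The model is

    w(x) = exp(b0 + b1*x1 + ... + bn*xn) / (1 + exp(b0 + b1*x1 + ... + bn*xn)),

read as the absolute probability that a location with covariates x experiences
a conflict. Estimation follows the weighted-distributions use-availability
likelihood: with used points i and an availability sample j of size n_avail,

    l(beta) = sum_i [ log w(x_i) - log( (1/n_avail) * sum_j w(x_j) ) ].

The availability mean in the denominator makes l invariant to duplicating the
availability sample, and l == 0 identically when w is constant (e.g. beta = 0,
or an intercept-only model). Maximisation is quasi-Newton (L-BFGS with the
analytic gradient) from an ordinary logistic-regression warm start. Standard
errors come from a nonparametric bootstrap that resamples the used and
available strata independently, with replacement, preserving stratum sizes
(the unmatched design, m = 0); p-values are two-sided normal Wald tests on the
bootstrap SEs. The intercept of a logistic RSPF is only weakly identified;
fits where the likelihood's curvature is near-singular along the intercept
direction are flagged (``intercept_weak``), not silently accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, log_expit
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix", "RSPFFit", "SeparationError", "ConvergenceError",
    "eval_w", "neg_log_likelihood", "fit_rspf", "count_df", "aic_of",
    "build_design",
]

MAX_ITER = 500
GRAD_TOL = 1e-6  # convergence: gradient infinity-norm
REL_TOL = 1e-10  # or relative change in l


class SeparationError(RuntimeError):
    """The likelihood diverges along one covariate (quasi-complete separation)."""


class ConvergenceError(RuntimeError):
    """The optimiser failed to converge within the iteration budget."""


@dataclass
class DesignMatrix:
    """Model matrix for a use-availability fit.

    ``X`` carries an explicit leading intercept column, then continuous
    covariates on their raw (possibly log-transformed) scales, then 0/1
    indicator columns for each non-reference land-cover class. ``labels`` is
    1 for used (conflict) rows and 0 for available rows.
    """

    X: np.ndarray
    labels: np.ndarray
    column_names: list[str]
    reference_class: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels are inconsistent")
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains missing or non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if len(self.column_names) != self.X.shape[1]:
            raise ValueError("column_names length mismatch")

    @property
    def n_used(self) -> int:
        return int(self.labels.sum())

    @property
    def n_avail(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def used_rows(self) -> np.ndarray:
        return self.X[self.labels == 1]

    def avail_rows(self) -> np.ndarray:
        return self.X[self.labels == 0]

    def subset(self, terms: list[str]) -> "DesignMatrix":
        """Design restricted to the intercept plus the named columns."""
        keep = ["intercept"] + [c for c in self.column_names[1:] if _owner(c) in terms]
        idx = [self.column_names.index(c) for c in keep]
        return DesignMatrix(self.X[:, idx], self.labels, keep, self.reference_class)


def _owner(column: str) -> str:
    # dummy columns "cover=3" belong to the atomic term "cover"
    return column.split("=", 1)[0]


def build_design(points: pd.DataFrame, continuous: list[str],
                 cover: str | None = None,
                 reference_class: int | None = None) -> DesignMatrix:
    """Assemble a :class:`DesignMatrix` from an extracted point table.

    The land-cover covariate (if any) enters as dummy indicators for every
    class except the reference, which defaults to the most frequent class in
    the availability sample (coefficients are contrasts against it, so the
    choice is recorded on the design).
    """
    df = points.dropna(subset=[c for c in continuous] + ([cover] if cover else []))
    labels = df["label"].to_numpy(dtype=int)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in continuous:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    ref = reference_class
    if cover is not None:
        codes = df[cover].to_numpy(dtype=int)
        avail_codes = codes[labels == 0]
        if ref is None:
            uniq, cnt = np.unique(avail_codes if avail_codes.size else codes,
                                  return_counts=True)
            ref = int(uniq[np.argmax(cnt)])
        for code in sorted(set(codes.tolist())):
            if code == ref:
                continue
            cols.append((codes == code).astype(float))
            names.append(f"{cover}={code}")
    return DesignMatrix(np.column_stack(cols), labels, names, ref)


def eval_w(beta, x):
    """Evaluate w(x) = expit(beta . x) for one covariate row or a matrix of rows.

    Numerically stable for arbitrarily large |linear predictor|; the result is
    strictly inside (0, 1) up to double precision.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(x).all()):
        raise ValueError("non-finite input")
    if x.ndim == 1:
        if x.shape[0] != beta.shape[0]:
            raise ValueError(f"dimension mismatch: beta has {beta.shape[0]}, x has {x.shape[0]}")
        return float(expit(x @ beta))
    if x.shape[1] != beta.shape[0]:
        raise ValueError(f"dimension mismatch: beta has {beta.shape[0]}, x has {x.shape[1]} columns")
    return expit(x @ beta)


def _loglik_and_grad(beta: np.ndarray, X_used: np.ndarray,
                     X_avail: np.ndarray) -> tuple[float, np.ndarray]:
    eta_u = X_used @ beta
    eta_a = X_avail @ beta
    w_a = expit(eta_a)
    mean_w = w_a.mean()
    n_used = X_used.shape[0]
    ll = log_expit(eta_u).sum() - n_used * np.log(mean_w)
    w_u = expit(eta_u)
    grad = X_used.T @ (1.0 - w_u)
    grad -= (n_used / (mean_w * X_avail.shape[0])) * (X_avail.T @ (w_a * (1.0 - w_a)))
    return ll, grad


def neg_log_likelihood(beta, used_rows, avail_rows) -> float:
    """Negative use-availability log-likelihood -l(beta)."""
    used_rows = np.atleast_2d(np.asarray(used_rows, dtype=float))
    avail_rows = np.atleast_2d(np.asarray(avail_rows, dtype=float))
    if used_rows.shape[0] == 0 or avail_rows.shape[0] == 0:
        raise ValueError("both the used and available strata must be nonempty")
    ll, _ = _loglik_and_grad(np.asarray(beta, dtype=float), used_rows, avail_rows)
    return -ll


# optimisation runs on internally standardised columns; the bounds below live
# on that scale, where a slope of 60 means the odds change by e^60 per sd —
# far past anything estimable, so hitting a bound signals separation, and an
# intercept pinned at the bound signals the flat-ridge (weak-identifiability)
# regime of the logistic RSPF rather than a finite interior maximum.
SLOPE_BOUND = 60.0
INTERCEPT_BOUND = 100.0
# a standardised slope past this is never estimable signal (odds ratio > e^15
# per sd); fits that stall beyond it are on the separating ridge, not at an
# interior maximum
SEPARATION_LIMIT = 15.0


class _Standardizer:
    """Affine reparameterisation (x - mu)/sd per non-intercept column."""

    def __init__(self, X: np.ndarray):
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.mu[0] = 0.0
        self.sd[0] = 1.0
        self.sd[self.sd == 0] = 1.0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd

    def to_raw(self, gamma: np.ndarray) -> np.ndarray:
        beta = gamma / self.sd
        beta[0] = gamma[0] - np.sum(gamma[1:] * self.mu[1:] / self.sd[1:])
        return beta

    def to_std(self, beta: np.ndarray) -> np.ndarray:
        gamma = beta * self.sd
        gamma[0] = beta[0] + np.sum(beta[1:] * self.mu[1:])
        return gamma


def _maximize(X_used: np.ndarray, X_avail: np.ndarray,
              gamma0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Maximise l over standardised coefficients within the drift bounds."""
    def negobj(b):
        ll, g = _loglik_and_grad(b, X_used, X_avail)
        return -ll, -g

    k = gamma0.size
    bounds = [(-INTERCEPT_BOUND, INTERCEPT_BOUND)] + [(-SLOPE_BOUND, SLOPE_BOUND)] * (k - 1)
    start = np.clip(gamma0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(negobj, start, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": MAX_ITER, "gtol": GRAD_TOL,
                                     "ftol": REL_TOL})
    converged = bool(res.success)
    return res.x, -res.fun, converged


def _warm_start(Z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Plain used-vs-available logistic regression (standardised scale)."""
    if Z.shape[1] == 1:
        p = labels.mean()
        return np.array([np.log(p / (1 - p))]) if 0 < p < 1 else np.zeros(1)
    try:
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000, tol=1e-8)
        lr.fit(Z[:, 1:], labels)
        start = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        # keep the start interior: if plain logistic itself separated, starting
        # on the boundary would pin the quasi-Newton there from step one
        return np.clip(start, -10.0, 10.0)
    except Exception:  # pragma: no cover - warm start is best-effort
        return np.zeros(Z.shape[1])


def _boundary_columns(gamma: np.ndarray, column_names: list[str]) -> list[str]:
    slopes = np.abs(gamma[1:])
    return [column_names[1 + j] for j in range(slopes.size)
            if slopes[j] >= SEPARATION_LIMIT]


@dataclass
class RSPFFit:
    """A fitted RSPF: coefficients, bootstrap SEs, Wald p-values and AIC."""

    beta: np.ndarray
    se: np.ndarray | None
    p: np.ndarray | None
    loglik: float
    k: int
    n_used: int
    n_avail: int
    column_names: list[str]
    B: int = 0
    m: int = 0
    converged: bool = True
    seed: int | None = None
    reference_class: int | None = None
    n_boot_dropped: int = 0
    intercept_weak: bool = False
    boundary_columns: tuple[str, ...] = ()
    terms: tuple[str, ...] = field(default_factory=tuple)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficient / SE / p-value table, one row per model column."""
        return pd.DataFrame({
            "covariate": self.column_names,
            "estimate": self.beta,
            "se": self.se if self.se is not None else np.full(self.k, np.nan),
            "p_value": self.p if self.p is not None else np.full(self.k, np.nan),
        })

    def metadata(self) -> dict:
        return {
            "loglik": self.loglik, "aic": self.aic, "k": self.k,
            "n_used": self.n_used, "n_avail": self.n_avail,
            "B": self.B, "m": self.m, "seed": self.seed,
            "converged": self.converged, "reference_class": self.reference_class,
            "n_boot_dropped": self.n_boot_dropped,
            "intercept_weak": self.intercept_weak,
            "boundary_columns": list(self.boundary_columns),
            "terms": list(self.terms),
        }


def _hessian_intercept_flag(beta, X_used, X_avail) -> bool:
    # finite-difference Hessian of l from the analytic gradient; flag if the
    # softest eigen-direction is intercept-dominated and nearly flat
    k = beta.size
    H = np.empty((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(beta))
    for j in range(k):
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h[j]
        bm[j] -= h[j]
        _, gp = _loglik_and_grad(bp, X_used, X_avail)
        _, gm = _loglik_and_grad(bm, X_used, X_avail)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = 0.5 * (H + H.T)
    vals, vecs = np.linalg.eigh(H)
    soft = int(np.argmin(np.abs(vals)))
    scale = np.max(np.abs(vals))
    return bool(scale > 0 and abs(vals[soft]) < 1e-6 * scale
                and np.argmax(np.abs(vecs[:, soft])) == 0)


def fit_rspf(data: DesignMatrix, B: int = 1000, m: int = 0,
             seed: int | None = None, check_hessian: bool = False,
             on_separation: str = "raise") -> RSPFFit:
    """Fit the use-availability RSPF by maximum likelihood.

    Parameters
    ----------
    data
        Design matrix with both used and available rows.
    B
        Bootstrap iterations for the standard errors (0 disables the
        bootstrap — used during exhaustive model search where only the MLE
        and AIC are needed).
    m
        Matching parameter; only the unmatched design ``m = 0`` is supported.
    seed
        Seed for the bootstrap resampling.
    check_hessian
        Also probe the likelihood curvature and set ``intercept_weak``.
    on_separation
        ``"raise"`` (default) errors when a slope diverges to the search
        boundary; ``"flag"`` keeps the boundary fit and records the offending
        columns (useful for validation refits, where only the ranking of the
        scores matters).

    Raises
    ------
    SeparationError
        If a coefficient diverges (the data separate on that column).
    ConvergenceError
        If the optimiser fails; bootstrap refits that fail are dropped and
        counted instead, with an error only if more than 5% drop.
    """
    if m != 0:
        raise NotImplementedError("only the unmatched design (m = 0) is supported")
    if data.n_used == 0 or data.n_avail == 0:
        raise ValueError("both labels must be present")
    sd = data.X.std(axis=0)
    dead = [data.column_names[j] for j in range(1, data.k)
            if sd[j] == 0 and not data.X[:, j].any()]
    if dead:
        raise ValueError(f"all-zero columns in the design: {dead}")

    std = _Standardizer(data.X)
    Z = std.transform(data.X)
    Z_used, Z_avail = Z[data.labels == 1], Z[data.labels == 0]
    gamma0 = _warm_start(Z, data.labels)
    gamma, loglik, ok = _maximize(Z_used, Z_avail, gamma0)
    boundary = _boundary_columns(gamma, data.column_names)
    if boundary and on_separation == "raise":
        raise SeparationError(
            f"coefficient for {boundary[0]!r} is diverging (standardised "
            f"magnitude >= {SEPARATION_LIMIT:g}); the data separate on this column")
    if not ok:
        raise ConvergenceError("RSPF fit did not converge")
    beta = std.to_raw(gamma)
    weak_ridge = bool(abs(gamma[0]) >= INTERCEPT_BOUND - 1.0)

    se = p = None
    n_dropped = 0
    if B > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty((B, data.k))
        good = np.zeros(B, dtype=bool)
        # refits warm-start at the MLE, pulled inside the search box so a
        # boundary (ridge) fit cannot pin every resample to the same edge
        start = np.clip(gamma, -10.0, 10.0)
        for b in range(B):
            iu = rng.integers(0, data.n_used, size=data.n_used)
            ia = rng.integers(0, data.n_avail, size=data.n_avail)
            gb, _, okb = _maximize(Z_used[iu], Z_avail[ia], start)
            boots[b] = std.to_raw(gb)
            good[b] = okb
        n_dropped = int((~good).sum())
        if n_dropped > 0.05 * B:
            raise ConvergenceError(
                f"{n_dropped}/{B} bootstrap refits failed to converge")
        se = boots[good].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * norm.sf(np.abs(z))

    weak = weak_ridge or (
        _hessian_intercept_flag(gamma, Z_used, Z_avail) if check_hessian else False)
    terms = tuple(dict.fromkeys(_owner(c) for c in data.column_names[1:]))
    return RSPFFit(beta=beta, se=se, p=p, loglik=float(loglik), k=data.k,
                   n_used=data.n_used, n_avail=data.n_avail,
                   column_names=list(data.column_names), B=B, m=m,
                   converged=True, seed=seed, reference_class=data.reference_class,
                   n_boot_dropped=n_dropped, intercept_weak=weak,
                   boundary_columns=tuple(boundary), terms=terms)


def count_df(model_terms: list[str], n_cover_classes: int,
             cover_term: str = "cover",
             known_terms: set[str] | None = None) -> int:
    """Estimated-parameter count of a candidate model.

    One intercept, one slope per continuous term, and ``n_cover_classes - 1``
    dummy contrasts if the (atomic) land-cover term is included.
    """
    if known_terms is not None:
        unknown = [t for t in model_terms if t not in known_terms]
        if unknown:
            raise KeyError(f"unknown model terms: {unknown}")
    k = 1
    for t in model_terms:
        k += (n_cover_classes - 1) if t == cover_term else 1
    return k


def aic_of(fit: RSPFFit) -> float:
    """Akaike information criterion, -2*loglik + 2*k, of a converged fit."""
    if not fit.converged:
        raise ValueError("AIC is undefined for an unconverged fit")
    return fit.aic
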