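"""Mixture cure models fitted to grouped relative survival.

Step two of the method.  Within a stratum (stage), relative survival is
modelled as

    RS(t) = c + (1 − c) · S_u(t)

with cure fraction c and non-cured survival S_u, Weibull
S_u(t) = exp(−(λt)^γ) or log-logistic S_u(t) = 1/(1 + (λt)^γ).  Categorical
covariates (age group, period of diagnosis) enter the cure fraction through
a logit link and the scale λ through a log link; the shape γ is shared
across covariate patterns within a stratum.

Fitting maximises a grouped binomial likelihood on interval deaths
(life-table resolution): the modelled conditional observed survival in
interval i is p*_i · RS(t_i)/RS(t_{i−1}) where p*_i is the Ederer II
expected interval survival, and d_i ~ Binomial(n'_i, 1 − that) with the
actuarial effective denominator n'_i.  Cure models are multimodal, so the
optimiser restarts from a small Latin grid of initial values on the
unconstrained scale (logit c, log median, log γ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .relative_survival import GroupedLifeTable

logger = logging.getLogger("mrisk")

FAMILIES = ("weibull", "loglogistic")
_BOUNDARY_LOGIT = 6.0
_CLIP = 1e-12


def su(family: str, t, lam: float, gamma: float) -> np.ndarray:
    """Survival of the non-cured: S_u(t)."""
    t = np.asarray(t, dtype=float)
    x = np.where(t > 0, (lam * t) ** gamma, 0.0)
    if family == "weibull":
        return np.exp(-x)
    if family == "loglogistic":
        return 1.0 / (1.0 + x)
    raise ValueError(f"unknown family {family!r}")


def _lam_from_median(family: str, median: float, gamma: float) -> float:
    if family == "weibull":
        return np.log(2.0) ** (1.0 / gamma) / median
    return 1.0 / median  # loglogistic: S(median) = 1/2 at λ·median = 1


@dataclass
class CureModelSpec:
    """What to fit: family, covariates, and factor levels.

    ``covariates`` maps factor name → ordered levels; the first level is the
    reference.  Patterns without covariates are the intercept-only model.
    """

    family: str = "weibull"
    covariates: dict[str, list[str]] = field(default_factory=dict)
    n_starts: int = 10
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class PatternFit:
    """Fitted quantities for one covariate pattern."""

    pattern: dict[str, str]
    c: float
    lam: float
    gamma: float
    boundary: bool


@dataclass
class CureModelFit:
    """A fitted mixture cure model for one stratum.

    Coefficients are on the unconstrained scale: ``beta_c`` (logit cure),
    ``beta_lam`` (log scale), ``log_gamma``.  ``patterns`` unpacks them per
    covariate pattern.
    """

    stratum: str
    family: str
    spec: CureModelSpec
    beta_c: np.ndarray
    beta_lam: np.ndarray
    log_gamma: float
    se: np.ndarray | None
    loglik: float
    converged: bool
    n_params: int
    patterns: list[PatternFit]
    tables: list[tuple[dict[str, str], GroupedLifeTable]]

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def pattern_fit(self, pattern: dict[str, str] | None) -> PatternFit:
        pattern = pattern or {}
        for pf in self.patterns:
            if pf.pattern == pattern:
                return pf
        raise KeyError(f"unknown covariate pattern {pattern!r} for stratum "
                       f"{self.stratum!r}")


def _design_row(pattern: dict[str, str], covariates: dict[str, list[str]]
                ) -> np.ndarray:
    row = [1.0]
    for name, levels in covariates.items():
        if name not in pattern:
            raise ValueError(f"pattern lacks factor {name!r}")
        if pattern[name] not in levels:
            raise ValueError(f"unknown level {pattern[name]!r} of {name!r}")
        row.extend(1.0 if pattern[name] == lev else 0.0
                   for lev in levels[1:])
    return np.array(row)


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, float]:
    return theta[:p], theta[p:2 * p], theta[2 * p]


def _neg_loglik(theta: np.ndarray, family: str, X: np.ndarray,
                data: list[dict]) -> float:
    p = X.shape[1]
    beta_c, beta_lam, log_gamma = _unpack(theta, p)
    gamma = np.exp(log_gamma)
    nll = 0.0
    for j, tab in enumerate(data):
        eta_c = X[j] @ beta_c
        c = expit(eta_c)
        lam = np.exp(X[j] @ beta_lam)
        rs = c + (1.0 - c) * su(family, tab["t_bounds"], lam, gamma)
        cond = tab["p_exp"] * rs[1:] / rs[:-1]
        cond = np.clip(cond, _CLIP, 1.0 - _CLIP)
        pi = 1.0 - cond
        nll -= np.sum(tab["d"] * np.log(pi)
                      + (tab["n_eff"] - tab["d"]) * np.log(1.0 - pi))
    if not np.isfinite(nll):
        return 1e12
    return nll


def _latin_starts(n_starts: int, rng: np.random.Generator
                  ) -> list[tuple[float, float, float]]:
    """Stratified starts over (logit c, log median T*, shape γ)."""
    lc = np.linspace(-2.0, 3.0, n_starts)
    lm = np.linspace(np.log(6.0), np.log(120.0), n_starts)
    gm = np.linspace(0.5, 2.0, n_starts)
    rng.shuffle(lm)
    rng.shuffle(gm)
    return list(zip(lc, lm, gm))


def _numerical_hessian(fun, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4.0 * eps * eps)
    return H


def fit_mixture_cure(lifetables, spec: CureModelSpec,
                     stratum: str = "all") -> CureModelFit:
    """Fit one stratum's mixture cure model to its grouped life table(s).

    ``lifetables`` is either a single :class:`GroupedLifeTable` (no
    covariates) or a list of ``(pattern, GroupedLifeTable)`` pairs, one per
    covariate pattern.  Requires at least 8 intervals per table.
    """
    if isinstance(lifetables, GroupedLifeTable):
        lifetables = [({}, lifetables)]
    for pattern, lt in lifetables:
        if len(lt.table) < 8:
            raise ValueError(
                f"stratum {stratum!r} pattern {pattern!r}: need >= 8 "
                f"life-table intervals, got {len(lt.table)}")

    X = np.vstack([_design_row(pat, spec.covariates)
                   for pat, _ in lifetables])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design matrix is rank deficient")
    p = X.shape[1]
    data = [{
        "t_bounds": lt.t_bounds,
        "p_exp": lt.table["p_exp"].to_numpy(float),
        "d": lt.table["d"].to_numpy(float),
        "n_eff": lt.table["n_eff"].to_numpy(float),
    } for _, lt in lifetables]

    fun = lambda th: _neg_loglik(th, spec.family, X, data)
    rng = np.random.default_rng(0)  # starts are deterministic by design
    best, best_val = None, np.inf
    for lc, lm, gm in _latin_starts(spec.n_starts, rng):
        theta0 = np.zeros(2 * p + 1)
        theta0[0] = lc
        theta0[p] = np.log(_lam_from_median(spec.family, np.exp(lm), gm))
        theta0[-1] = np.log(gm)
        res = minimize(fun, theta0, method="Nelder-Mead",
                       options={"maxiter": 4000, "fatol": spec.tol,
                                "xatol": 1e-8})
        res = minimize(fun, res.x, method="BFGS",
                       options={"gtol": 1e-8, "maxiter": 1000})
        if res.fun < best_val - 1e-12:
            best, best_val = res, res.fun
    if best is None:
        raise RuntimeError(f"stratum {stratum!r}: all optimizer starts failed")
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.inf
    converged = np.isfinite(best_val) and (
        best.success or grad_norm < 1e-3 * (1.0 + abs(best_val)))
    theta = best.x
    beta_c, beta_lam, log_gamma = _unpack(theta, p)

    se = None
    if converged:
        try:
            H = _numerical_hessian(fun, theta)
            cov = np.linalg.pinv(H)
            diag = np.diag(cov)
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
        except Exception:  # pragma: no cover - numerical corner
            se = None

    patterns = []
    gamma = float(np.exp(log_gamma))
    for j, (pat, _) in enumerate(lifetables):
        eta_c = float(X[j] @ beta_c)
        patterns.append(PatternFit(
            pattern=pat,
            c=float(expit(eta_c)),
            lam=float(np.exp(X[j] @ beta_lam)),
            gamma=gamma,
            boundary=abs(eta_c) > _BOUNDARY_LOGIT,
        ))
    if any(pf.boundary for pf in patterns):
        logger.warning("stratum %s: cure fraction at boundary", stratum)

    return CureModelFit(
        stratum=stratum, family=spec.family, spec=spec,
        beta_c=beta_c, beta_lam=beta_lam, log_gamma=float(log_gamma),
        se=se, loglik=-best_val, converged=converged,
        n_params=2 * p + 1, patterns=patterns, tables=list(lifetables),
    )


def predict_rs(fit: CureModelFit, t, pattern: dict[str, str] | None = None
               ) -> np.ndarray:
    """Model relative survival c + (1 − c)·S_u(t) for a covariate pattern."""
    pf = fit.pattern_fit(pattern)
    return pf.c + (1.0 - pf.c) * su(fit.family, t, pf.lam, pf.gamma)


@dataclass
class FamilySelection:
    family: str
    report: pd.DataFrame
    triggering_strata: list[str]


def select_family(fits_by_family: dict[str, dict[str, CureModelFit]]
                  ) -> FamilySelection:
    """Choose the cure-model family for a whole table of strata.

    Log-logistic is preferred when it converges in every stratum; a single
    non-convergent log-logistic stratum triggers a table-wide fall-back to
    Weibull.  Exact likelihood ties break toward Weibull, which has fewer
    convergence pathologies in practice.  Strata where both families fail
    are reported so callers can leave an explicit gap.
    """
    ll = fits_by_family.get("loglogistic", {})
    wb = fits_by_family.get("weibull", {})
    strata = sorted(set(ll) | set(wb))
    rows, triggering = [], []
    for s in strata:
        for fam, fits in (("weibull", wb), ("loglogistic", ll)):
            if s in fits:
                f = fits[s]
                rows.append({"stratum": s, "family": fam, "aic": f.aic,
                             "converged": f.converged})
                if fam == "loglogistic" and not f.converged:
                    triggering.append(s)
    report = pd.DataFrame(rows)
    ll_ok = bool(ll) and all(f.converged for f in ll.values())
    if ll_ok:
        tie = bool(wb) and all(
            s in wb and abs(ll[s].loglik - wb[s].loglik) < 1e-9
            and wb[s].converged for s in ll)
        family = "weibull" if tie else "loglogistic"
    else:
        family = "weibull"
    return FamilySelection(family=family, report=report,
                           triggering_strata=triggering)


def fit_summary_frame(fits: dict[str, CureModelFit]) -> pd.DataFrame:
    """One row per stratum × covariate pattern for the fit-summary CSV."""
    rows = []
    for stratum, fit in fits.items():
        for pf in fit.patterns:
            pat = ";".join(f"{k}={v}" for k, v in pf.pattern.items()) or "-"
            rows.append({
                "stratum": stratum, "pattern": pat, "family": fit.family,
                "c": pf.c, "lam": pf.lam, "gamma": pf.gamma,
                "loglik": fit.loglik, "converged": fit.converged,
                "boundary": pf.boundary,
            })
    return pd.DataFrame(rows)
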