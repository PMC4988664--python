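"""Cox proportional-hazards regression.

Fits h(t, X) = h0(t) exp(sum_i beta_i X_i) by maximising the partial
likelihood with Newton-Raphson from beta = 0 (relative log-likelihood
tolerance 1e-9, at most 25 iterations, step halving).  Tied event times are
handled by the Breslow or Efron approximations or by the exact discrete
(conditional-logistic) likelihood, whose denominator — the elementary
symmetric function of the risk weights — is evaluated by dynamic
programming together with its first two derivatives.

Also provided: AIC-guided stepwise covariate selection (backward / forward /
both), per-coefficient Wald tests, the likelihood-ratio chi-square
goodness-of-fit test against the null model, and the Grambsch-Therneau
proportional-hazards assumption test on scaled Schoenfeld residuals with a
Kaplan-Meier time transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import ConfigurationError, NumericalError, ValidationError
from .io_model import SurvivalDataset

__all__ = [
    "CoxFit",
    "fit_cox",
    "partial_loglik",
    "stepwise_select",
    "ph_assumption_test",
]

TIES_METHODS = ("breslow", "efron", "exact")
_BETA_CAP = 20.0


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design(ds: SurvivalDataset, covariates, strata=None):
    """Expand covariates to a numeric design matrix.

    Categorical covariates are reference-coded against their first level in
    sorted order; indicator columns are named ``col[level]``.
    """
    frame = ds.frame
    cols = []
    names = []
    for cov in covariates:
        if cov not in frame.columns:
            raise ConfigurationError(f"covariate {cov!r} not present")
        series = frame[cov]
        if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == object:
            if isinstance(series.dtype, pd.CategoricalDtype):
                levels = [lv for lv in series.cat.categories if (series == lv).any()]
            else:
                levels = sorted(series.dropna().unique())
            for level in levels[1:]:
                cols.append((series == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((ds.n, 0))
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"covariate {name!r} is constant")
    if strata is None:
        codes = np.zeros(ds.n, dtype=int)
    else:
        strata = [strata] if isinstance(strata, str) else list(strata)
        for s in strata:
            if s not in frame.columns:
                raise ConfigurationError(f"stratum column {s!r} not present")
        codes = pd.MultiIndex.from_frame(frame[strata]).factorize()[0]
    return X, names, codes


# ---------------------------------------------------------------------------
# partial likelihood, gradient, Hessian
# ---------------------------------------------------------------------------

def _stratum_blocks(time, status, codes):
    for code in np.unique(codes):
        mask = codes == code
        order = np.argsort(time[mask], kind="stable")
        yield np.nonzero(mask)[0][order]


def _esym_derivs(w, X, d):
    """E, F, G for the elementary symmetric function of degree d.

    E = sum over size-d subsets S of prod_{i in S} w_i;
    F = sum_S w_S (sum_{i in S} x_i);  G = sum_S w_S (sum x)(sum x)^T.
    """
    p = X.shape[1]
    E = np.zeros(d + 1)
    E[0] = 1.0
    F = np.zeros((d + 1, p))
    G = np.zeros((d + 1, p, p))
    for wi, xi in zip(w, X):
        for k in range(min(d, len(w)), 0, -1):
            G[k] += wi * (G[k - 1] + np.outer(xi, F[k - 1])
                          + np.outer(F[k - 1], xi)
                          + np.outer(xi, xi) * E[k - 1])
            F[k] += wi * (F[k - 1] + xi * E[k - 1])
            E[k] += wi * E[k - 1]
    return E[d], F[d], G[d]


def _loglik_terms(X, time, status, codes, beta, ties, want_derivs=True):
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for idx in _stratum_blocks(time, status, codes):
        t, s = time[idx], status[idx]
        Xs, ws = X[idx], w[idx]
        # suffix sums over the ascending-time order
        S0 = np.cumsum(ws[::-1])[::-1]
        S1 = np.cumsum((ws[:, None] * Xs)[::-1], axis=0)[::-1] if p else None
        S2 = (np.cumsum((ws[:, None, None] * Xs[:, :, None] * Xs[:, None, :])[::-1],
                        axis=0)[::-1] if (p and want_derivs) else None)
        event_times = np.unique(t[s == 1])
        for tj in event_times:
            start = np.searchsorted(t, tj, side="left")
            dead = np.nonzero((t == tj) & (s == 1))[0]
            d = len(dead)
            s_j = Xs[dead].sum(axis=0) if p else np.zeros(0)
            ll += float(eta[idx][dead].sum())
            if ties == "breslow" or (ties == "exact" and d == 1):
                denom = S0[start]
                ll -= d * np.log(denom)
                if want_derivs and p:
                    m1 = S1[start] / denom
                    grad += s_j - d * m1
                    hess -= d * (S2[start] / denom - np.outer(m1, m1))
            elif ties == "efron":
                wd0 = ws[dead].sum()
                phi = np.arange(d) / d
                denom = S0[start] - phi * wd0
                ll -= float(np.sum(np.log(denom)))
                if want_derivs and p:
                    wd1 = (ws[dead, None] * Xs[dead]).sum(axis=0)
                    wd2 = (ws[dead, None, None]
                           * Xs[dead][:, :, None] * Xs[dead][:, None, :]).sum(axis=0)
                    A = S1[start][None, :] - phi[:, None] * wd1[None, :]
                    B = S2[start][None] - phi[:, None, None] * wd2[None]
                    m1 = A / denom[:, None]
                    grad += s_j - m1.sum(axis=0)
                    hess -= (B / denom[:, None, None]).sum(axis=0)
                    hess += np.einsum("lg,lh->gh", m1, m1)
            elif ties == "exact":
                risk = slice(start, len(t))
                E, F, G = _esym_derivs(ws[risk], Xs[risk] if p else
                                       np.empty((len(t) - start, 0)), d)
                ll -= float(np.log(E))
                if want_derivs and p:
                    m1 = F / E
                    grad += s_j - m1
                    hess -= G / E - np.outer(m1, m1)
            else:
                raise ConfigurationError(f"ties must be one of {TIES_METHODS}")
    return ll, grad, hess


def partial_loglik(ds: SurvivalDataset, covariates, beta, ties: str = "efron",
                   strata=None) -> float:
    """Exact partial log-likelihood at an arbitrary coefficient vector."""
    if ties not in TIES_METHODS:
        raise ConfigurationError(f"ties must be one of {TIES_METHODS}")
    X, names, codes = _design(ds, covariates, strata)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ConfigurationError(
            f"beta must have length {X.shape[1]} (expanded design), got {beta.shape}"
        )
    ll, _, _ = _loglik_terms(X, ds.time, ds.status, codes, beta, ties,
                             want_derivs=False)
    return float(ll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik_null: float
    loglik_fit: float
    ties_method: str
    n: int
    n_events: int
    selected: tuple = ()
    trace: tuple = ()
    _X: np.ndarray | None = field(default=None, repr=False)
    _time: np.ndarray | None = field(default=None, repr=False)
    _status: np.ndarray | None = field(default=None, repr=False)
    _strata: np.ndarray | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.covariance)),
                         index=self.coefficients.index)

    @property
    def ci(self) -> pd.DataFrame:
        z = norm.ppf(0.975)
        return pd.DataFrame({
            "low": self.coefficients - z * self.se,
            "high": self.coefficients + z * self.se,
        })

    @property
    def wald_p(self) -> pd.Series:
        z = self.coefficients / self.se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.coefficients.index)

    @property
    def lrt(self) -> tuple[float, int, float]:
        """Likelihood-ratio chi-square goodness-of-fit test vs the null model."""
        stat = 2.0 * (self.loglik_fit - self.loglik_null)
        df = len(self.coefficients)
        return float(stat), df, float(chi2.sf(stat, df))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik_fit + 2.0 * len(self.coefficients)

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame({
            "coef": self.coefficients,
            "ci_low": ci["low"],
            "ci_high": ci["high"],
            "exp(coef)": self.hazard_ratios,
            "se": self.se,
            "wald_p": self.wald_p,
        })


def fit_cox(ds: SurvivalDataset, covariates, ties: str = "efron",
            strata=None) -> CoxFit:
    """Maximise the partial likelihood under the chosen tie correction."""
    if ties not in TIES_METHODS:
        raise ConfigurationError(f"ties must be one of {TIES_METHODS}")
    if ds.status.sum() < 1:
        raise ValidationError("at least one event is required")
    X, names, codes = _design(ds, covariates, strata)
    time, status = ds.time, ds.status
    p = X.shape[1]

    beta = np.zeros(p)
    ll, grad, hess = _loglik_terms(X, time, status, codes, beta, ties)
    ll_null = ll
    trace = [ll]
    converged = p == 0
    for _ in range(25):
        if converged:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_terms(X, time, status, codes,
                                                   new_beta, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_terms(X, time, status, codes,
                                                       new_beta, ties)
            halvings += 1
        if np.max(np.abs(new_beta)) > _BETA_CAP:
            warnings.warn(
                "monotone partial likelihood: a coefficient diverges; "
                f"estimate capped at +-{_BETA_CAP}"
            )
            new_beta = np.clip(new_beta, -_BETA_CAP, _BETA_CAP)
            new_ll, new_grad, new_hess = _loglik_terms(X, time, status, codes,
                                                       new_beta, ties)
            beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
            trace.append(ll)
            converged = True
            break
        if abs(new_ll - ll) < 1e-9 * (abs(ll) + 1e-9):
            converged = True
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        trace.append(ll)
    if not converged:
        raise NumericalError(
            f"Newton-Raphson did not converge in 25 iterations; "
            f"log-likelihood trace: {[round(v, 6) for v in trace]}"
        )

    cov = np.linalg.pinv(-hess) if p else np.zeros((0, 0))
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik_null=float(ll_null),
        loglik_fit=float(ll),
        ties_method=ties,
        n=ds.n,
        n_events=int(status.sum()),
        selected=tuple(covariates),
        _X=X, _time=time, _status=status, _strata=codes,
    )


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(ds: SurvivalDataset, covariates, direction: str = "backward",
                    ties: str = "efron", strata=None) -> CoxFit:
    """AIC-guided stepwise covariate search.

    ``backward`` starts from the full model and drops terms, ``forward``
    starts empty and adds terms, ``both`` allows adds and drops from the
    empty model.  The search stops at a fixed point: no single move lowers
    the AIC.  Terms are whole covariates (a categorical enters or leaves
    with all its indicator columns).
    """
    if direction not in ("backward", "forward", "both"):
        raise ConfigurationError("direction must be backward, forward or both")
    candidates = list(covariates)
    if len(candidates) < 2:
        raise ConfigurationError("stepwise search needs at least two candidates")

    def aic_of(subset):
        fit = fit_cox(ds, list(subset), ties=ties, strata=strata)
        return fit.aic, fit

    current = list(candidates) if direction == "backward" else []
    if current:
        current_aic, current_fit = aic_of(current)
    else:
        current_fit = fit_cox(ds, [], ties=ties, strata=strata)
        current_aic = current_fit.aic
    search_trace = [(tuple(current), current_aic)]

    while True:
        moves = []
        if direction in ("backward", "both"):
            for cov in current:
                moves.append([c for c in current if c != cov])
        if direction in ("forward", "both"):
            for cov in candidates:
                if cov not in current:
                    moves.append(current + [cov])
        best = None
        for subset in moves:
            a, f = aic_of(subset)
            if best is None or a < best[0]:
                best = (a, f, subset)
        if best is None or best[0] >= current_aic - 1e-10:
            break
        current_aic, current_fit, current = best[0], best[1], best[2]
        search_trace.append((tuple(current), current_aic))

    return CoxFit(
        coefficients=current_fit.coefficients,
        covariance=current_fit.covariance,
        loglik_null=current_fit.loglik_null,
        loglik_fit=current_fit.loglik_fit,
        ties_method=ties,
        n=current_fit.n,
        n_events=current_fit.n_events,
        selected=tuple(current),
        trace=tuple(search_trace),
        _X=current_fit._X, _time=current_fit._time,
        _status=current_fit._status, _strata=current_fit._strata,
    )


# ---------------------------------------------------------------------------
# proportional-hazards assumption test
# ---------------------------------------------------------------------------

def ph_assumption_test(fit: CoxFit) -> pd.DataFrame:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Correlates the Schoenfeld residuals with a Kaplan-Meier transform of
    the event times, g(t) = 1 - S_KM(t-).  Returns one row per covariate
    plus a GLOBAL row, each with the chi-square statistic, df and p value.
    """
    if fit._X is None or len(fit.coefficients) == 0:
        raise ValidationError("a fitted model with at least one covariate is needed")
    X, time, status, codes = fit._X, fit._time, fit._status, fit._strata
    if status.sum() < 2:
        raise ValidationError("at least two events are required")
    beta = fit.coefficients.to_numpy()
    p = X.shape[1]
    w = np.exp(np.clip(X @ beta, -500, 500))

    resid = []      # one Schoenfeld residual per death
    death_times = []
    info = np.zeros((p, p))
    for idx in _stratum_blocks(time, status, codes):
        t, s = time[idx], status[idx]
        Xs, ws = X[idx], w[idx]
        S0 = np.cumsum(ws[::-1])[::-1]
        S1 = np.cumsum((ws[:, None] * Xs)[::-1], axis=0)[::-1]
        S2 = np.cumsum((ws[:, None, None] * Xs[:, :, None] * Xs[:, None, :])[::-1],
                       axis=0)[::-1]
        for tj in np.unique(t[s == 1]):
            start = np.searchsorted(t, tj, side="left")
            dead = np.nonzero((t == tj) & (s == 1))[0]
            xbar = S1[start] / S0[start]
            V = S2[start] / S0[start] - np.outer(xbar, xbar)
            for k in dead:
                resid.append(Xs[k] - xbar)
                death_times.append(tj)
                info += V
    resid = np.asarray(resid)
    death_times = np.asarray(death_times)
    d = len(resid)

    # KM transform of time, evaluated left-continuously at the death times
    from .km import fit_km
    ds_like = SurvivalDataset(
        frame=pd.DataFrame({"time": time, "status": status}),
        time_col="time", status_col="status")
    curve = fit_km(ds_like)[None]
    s_all = np.concatenate([[1.0], curve.survival])
    pos = np.searchsorted(curve.event_times, death_times, side="left")
    g = 1.0 - s_all[pos]
    g_c = g - g.mean()
    ssg = float(np.sum(g_c ** 2))

    U = resid.T @ g_c
    info_inv = np.linalg.pinv(info)
    rows = []
    for j, name in enumerate(fit.coefficients.index):
        stat = d * (info_inv[j] @ U) ** 2 / (info_inv[j, j] * ssg)
        rows.append((name, float(stat), 1, float(chi2.sf(stat, 1))))
    stat_g = float(d * (U @ info_inv @ U) / ssg)
    rows.append(("GLOBAL", stat_g, p, float(chi2.sf(stat_g, p))))
    return pd.DataFrame(rows, columns=["variable", "chisq", "df", "p"]
                        ).set_index("variable")
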