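"""Survival analysis under dependent censoring.

The observed record per subject is Y = min(T, U) with event indicator
delta = 1(T <= U), where the death time T and the censoring time U are
joined by a Clayton copula with dependence alpha (Kendall tau =
alpha / (alpha + 2)). The pieces implemented here:

* ``fit_dependent_cox`` — semiparametric maximum likelihood for a
  univariate Cox-margin model of T (and of U) linked by the copula.
  Both baseline cumulative hazards are left unspecified (step functions
  with jumps at the observed event / censoring times) and maximized
  jointly with the regression coefficients. At alpha = 0 the likelihood
  factorizes and the estimate coincides with the standard Cox
  partial-likelihood estimate.
* ``select_alpha`` — cross-validated concordance of the prognostic index
  over a grid of alpha values.
* ``copula_feature_selection`` — F1 pre-screen (balanced-CV single-feature
  classifier on the death label) followed by per-feature dependent-Cox
  fits, keeping p < 0.05 ordered by p.
* ``cg_estimator`` — the copula-graphic marginal survival estimator,
  which reduces exactly to Kaplan-Meier at alpha = 0.
* prognostic index, median split into good/bad groups, average vertical
  distance D between group curves, and its permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .copula import ClaytonCopula

log = logging.getLogger(__name__)

__all__ = [
    "DependentCoxFit",
    "SurvivalCurve",
    "PrognosticResult",
    "fit_dependent_cox",
    "select_alpha",
    "copula_feature_selection",
    "prognostic_index",
    "split_by_pi",
    "cg_estimator",
    "vertical_distance",
    "permutation_test",
    "binary_survival_predict",
    "rep_group_crosstab",
    "standardize",
]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score columns (population sd); constant columns map to zero."""
    mu = table.mean()
    sd = table.std(ddof=0).replace(0.0, 1.0)
    return (table - mu) / sd


# ----------------------------------------------------------------------
# dependent-censoring Cox fit
# ----------------------------------------------------------------------

@dataclass
class DependentCoxFit:
    """A univariate Cox coefficient estimated under an assumed copula."""

    feature: str
    alpha: float
    beta: float
    se: float
    p_value: float
    converged: bool
    gamma: float = 0.0          # censoring-margin coefficient
    log_likelihood: float = float("nan")


def _log_s_clayton(alpha: float, a: np.ndarray, b: np.ndarray) -> tuple:
    """log(u^-a + v^-a - 1) and the two weights w_u, w_v, stably.

    ``a = -alpha*log u`` and ``b = -alpha*log v`` are >= 0; the weights are
    u^-alpha / S and v^-alpha / S.
    """
    m = np.maximum(a, b)
    s = np.exp(a - m) + np.exp(b - m) - np.exp(-m)
    log_s = m + np.log(s)
    w_u = np.exp(a - log_s)
    w_v = np.exp(b - log_s)
    return log_s, w_u, w_v


class _JointLikelihood:
    """Negative log-likelihood (and gradient) of the joint copula model.

    Parameters are theta = [beta, gamma, log dLambda_T (events),
    log dLambda_U (censorings)], with baseline jumps placed at the
    distinct subject times of each type.
    """

    def __init__(self, x: np.ndarray, time: np.ndarray, event: np.ndarray, alpha: float):
        order = np.argsort(time, kind="stable")
        self.x = np.asarray(x, float)[order]
        self.time = np.asarray(time, float)[order]
        self.delta = np.asarray(event, int)[order]
        self.alpha = float(alpha)
        self.n = len(self.time)
        self.ev_idx = np.flatnonzero(self.delta == 1)
        self.ce_idx = np.flatnonzero(self.delta == 0)
        self.n_e = len(self.ev_idx)
        self.n_c = len(self.ce_idx)
        # risk-set bookkeeping: times are sorted, jump j sits at subject
        # position ev_idx[j]; subjects at risk for it are positions >= the
        # first index with the same time
        t = self.time
        self.ev_first = np.searchsorted(t, t[self.ev_idx], side="left")
        self.ce_first = np.searchsorted(t, t[self.ce_idx], side="left")
        # cumulated-jump bookkeeping: subject i accumulates jumps at
        # positions <= i with matching type (ties included: jump at equal
        # time is experienced by the subject)
        self.ev_count_le = np.searchsorted(t[self.ev_idx], t, side="right")
        self.ce_count_le = np.searchsorted(t[self.ce_idx], t, side="right")

    def initial(self) -> np.ndarray:
        # Nelson-Aalen-style starting jumps at beta = gamma = 0
        risk_e = self.n - self.ev_first
        risk_c = self.n - self.ce_first
        return np.concatenate([[0.0, 0.0], -np.log(risk_e), -np.log(risk_c)])

    def unpack(self, theta):
        return theta[0], theta[1], theta[2:2 + self.n_e], theta[2 + self.n_e:]

    def value_and_grad(self, theta):
        # extreme line-search excursions may overflow transiently; the
        # optimizer backtracks from non-finite objective values
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._value_and_grad(theta)

    def _value_and_grad(self, theta):
        beta, gamma, la, lb = self.unpack(theta)
        dL = np.exp(la)   # event-baseline jumps
        dG = np.exp(lb)   # censoring-baseline jumps
        eb = np.exp(np.clip(beta * self.x, -500, 500))
        eg = np.exp(np.clip(gamma * self.x, -500, 500))
        cumL = np.concatenate([[0.0], np.cumsum(dL)])[self.ev_count_le]
        cumG = np.concatenate([[0.0], np.cumsum(dG)])[self.ce_count_le]
        A = cumL * eb            # -log u_i
        B = cumG * eg            # -log v_i
        alpha = self.alpha
        d = self.delta

        if alpha == 0.0:
            ll = (np.sum(la) + beta * self.x[self.ev_idx].sum()
                  + np.sum(lb) + gamma * self.x[self.ce_idx].sum()
                  - A.sum() - B.sum())
            cT = -np.ones(self.n)
            cU = -np.ones(self.n)
        else:
            log_s, w_u, w_v = _log_s_clayton(alpha, alpha * A, alpha * B)
            ll = (np.sum(la) + beta * self.x[self.ev_idx].sum()
                  + np.sum(lb) + gamma * self.x[self.ce_idx].sum()
                  + alpha * (A[d == 1].sum() + B[d == 0].sum())
                  - (1.0 + alpha) / alpha * log_s.sum())
            # dl_i / dA_i and dl_i / dB_i (A = -log u, B = -log v)
            cT = alpha * (d == 1) - (1.0 + alpha) * w_u
            cU = alpha * (d == 0) - (1.0 + alpha) * w_v

        # gradients
        g_beta = self.x[self.ev_idx].sum() + np.sum(cT * A * self.x)
        g_gamma = self.x[self.ce_idx].sum() + np.sum(cU * B * self.x)
        # jump j (event type): d ll / d la_j = 1 + dL_j * sum_{i at risk} cT_i eb_i
        sT = np.concatenate([np.cumsum((cT * eb)[::-1])[::-1], [0.0]])
        sU = np.concatenate([np.cumsum((cU * eg)[::-1])[::-1], [0.0]])
        g_la = 1.0 + dL * sT[self.ev_first]
        g_lb = 1.0 + dG * sU[self.ce_first]
        grad = np.concatenate([[g_beta, g_gamma], g_la, g_lb])
        return -ll, -grad

    def optimize(self, theta0=None, fix_beta: float | None = None):
        theta0 = self.initial() if theta0 is None else np.asarray(theta0, float).copy()
        if fix_beta is not None:
            theta0[0] = fix_beta

            def fun(t_red):
                th = np.concatenate([[fix_beta], t_red])
                f, g = self.value_and_grad(th)
                return f, g[1:]

            res = optimize.minimize(fun, theta0[1:], jac=True, method="L-BFGS-B",
                                    options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
            theta = np.concatenate([[fix_beta], res.x])
            return theta, -res.fun, res.success
        res = optimize.minimize(self.value_and_grad, theta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        return res.x, -res.fun, res.success


def fit_dependent_cox(x, time, event, copula: ClaytonCopula,
                      feature: str = "x", se_step: float | None = None) -> DependentCoxFit:
    """Semiparametric Cox fit for one covariate under dependent censoring.

    Maximizes the joint likelihood of (Y, delta) with Cox margins for the
    death and censoring times and the given Clayton copula, over the
    regression coefficients and both baseline hazard step functions. The
    standard error comes from the curvature of the profile log-likelihood
    in beta; the p-value is a two-sided Wald test.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.nanstd(x) == 0:
        log.warning("fit_dependent_cox: constant covariate %r; beta = 0, p = 1", feature)
        return DependentCoxFit(feature=feature, alpha=copula.alpha, beta=0.0,
                               se=float("inf"), p_value=1.0, converged=True)
    if event.sum() == 0:
        log.warning("fit_dependent_cox: no events; beta = 0, p = 1")
        return DependentCoxFit(feature=feature, alpha=copula.alpha, beta=0.0,
                               se=float("inf"), p_value=1.0, converged=False)

    lik = _JointLikelihood(x, time, event, copula.alpha)
    theta, ll, ok = lik.optimize()
    beta = float(theta[0])
    gamma = float(theta[1])
    if not ok:
        log.warning("fit_dependent_cox: optimizer did not converge for %r", feature)
        return DependentCoxFit(feature=feature, alpha=copula.alpha, beta=beta,
                               se=float("inf"), p_value=1.0, converged=False,
                               gamma=gamma, log_likelihood=ll)

    h = se_step if se_step is not None else max(1e-3, 0.25 / np.sqrt(max(event.sum(), 1)))
    _, ll_hi, _ = lik.optimize(theta0=theta, fix_beta=beta + h)
    _, ll_lo, _ = lik.optimize(theta0=theta, fix_beta=beta - h)
    info = -(ll_hi + ll_lo - 2.0 * ll) / h ** 2
    if info <= 0 or not np.isfinite(info):
        log.warning("fit_dependent_cox: non-positive profile curvature for %r", feature)
        return DependentCoxFit(feature=feature, alpha=copula.alpha, beta=beta,
                               se=float("inf"), p_value=1.0, converged=False,
                               gamma=gamma, log_likelihood=ll)
    se = float(1.0 / np.sqrt(info))
    p = float(2.0 * sps.norm.sf(abs(beta) / se))
    return DependentCoxFit(feature=feature, alpha=copula.alpha, beta=beta, se=se,
                           p_value=max(p, np.finfo(float).tiny), converged=True,
                           gamma=gamma, log_likelihood=ll)


# ----------------------------------------------------------------------
# alpha selection by cross-validated concordance
# ----------------------------------------------------------------------

def select_alpha(time, event, table: pd.DataFrame,
                 alpha_grid=(0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30),
                 folds: int = 5, seed: int = 0) -> tuple[float, pd.DataFrame]:
    """Choose the copula dependence by cross-validated c-index of the PI.

    For each grid alpha, univariate dependent-Cox coefficients are fit on
    the training folds, the prognostic index beta(alpha)'x is scored on
    the held-out folds by Harrell's concordance against (Y, delta), and
    the alpha with the best mean c-index wins (ties go to the smaller
    alpha). Returns (alpha, per-alpha table).
    """
    from lifelines.utils import concordance_index

    alpha_grid = sorted(float(a) for a in alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must be non-empty")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(time)
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(np.arange(n) % folds)

    records = []
    for alpha in alpha_grid:
        cop = ClaytonCopula(alpha)
        scores = []
        for k in range(folds):
            te = fold_of == k
            tr = ~te
            x_tr = standardize(table.loc[tr])
            x_te = (table.loc[te] - table.loc[tr].mean()) / table.loc[tr].std(ddof=0).replace(0.0, 1.0)
            betas = {}
            n_fail = 0
            for col in table.columns:
                fit = fit_dependent_cox(x_tr[col].to_numpy(), time[tr], event[tr],
                                        cop, feature=col)
                if fit.converged:
                    betas[col] = fit.beta
                else:
                    n_fail += 1
            if not betas:
                log.warning("select_alpha: all fits failed at alpha=%s fold %d", alpha, k)
                continue
            pi = sum(b * x_te[c].to_numpy() for c, b in betas.items())
            if event[te].sum() == 0:
                continue
            # high PI = high risk = short survival
            scores.append(concordance_index(time[te], -pi, event[te]))
        if scores:
            records.append({"alpha": alpha, "c_index": float(np.mean(scores)),
                            "n_folds": len(scores)})
        else:
            log.warning("select_alpha: alpha=%s dropped (no scorable folds)", alpha)
    if not records:
        raise RuntimeError("no alpha on the grid could be scored")
    res = pd.DataFrame(records)
    best = res.loc[res["c_index"].idxmax()]  # idxmax -> first (smallest alpha) on ties
    return float(best["alpha"]), res


# ----------------------------------------------------------------------
# two-step survival feature selection
# ----------------------------------------------------------------------

def copula_feature_selection(table: pd.DataFrame, time, event,
                             copula: ClaytonCopula, f1_threshold: float = 0.7,
                             p_threshold: float = 0.05, seed: int = 0,
                             f1_iterations: int = 10,
                             f1_scores: pd.Series | None = None) -> list[DependentCoxFit]:
    """F1 pre-screen then per-feature dependent-Cox fits, ordered by p.

    Step 1 scores every feature with a balanced-CV single-feature
    classifier of the death label and keeps F1 > ``f1_threshold``;
    step 2 fits the dependent-censoring Cox model per surviving feature
    and keeps p < ``p_threshold``, ascending p. Precomputed ``f1_scores``
    (e.g. when scanning several copulas) skip step 1's classifier runs.
    """
    from .classify import per_feature_f1

    event = np.asarray(event, int)
    f1 = f1_scores if f1_scores is not None else per_feature_f1(
        table, event, n_iterations=f1_iterations, seed=seed)
    survivors = list(f1.index[f1 > f1_threshold])
    if not survivors:
        log.warning("copula_feature_selection: no feature passes F1 > %.2f", f1_threshold)
        return []
    z = standardize(table[survivors])
    fits = [fit_dependent_cox(z[c].to_numpy(), time, event, copula, feature=c)
            for c in survivors]
    kept = [f for f in fits if f.converged and f.p_value < p_threshold]
    return sorted(kept, key=lambda f: f.p_value)


# ----------------------------------------------------------------------
# prognostic index and grouping
# ----------------------------------------------------------------------

def prognostic_index(coefficients: dict | pd.Series, x: pd.DataFrame | pd.Series):
    """PI = beta(alpha)' x — the linear risk score of a feature vector."""
    coef = pd.Series(coefficients, dtype=float)
    if isinstance(x, pd.Series):
        missing = [c for c in coef.index if c not in x.index]
        if missing:
            raise KeyError(f"feature(s) {missing} absent from the input vector")
        return float(sum(coef[c] * x[c] for c in coef.index))
    missing = [c for c in coef.index if c not in x.columns]
    if missing:
        raise KeyError(f"feature(s) {missing} absent from the input table")
    return x[list(coef.index)].to_numpy(dtype=float) @ coef.to_numpy()


def split_by_pi(pis) -> np.ndarray:
    """Median split of prognostic indices into 'good' (low) / 'bad' (high).

    Group sizes differ by at most one; with odd n the extra subject goes
    to the bad group. Ties are broken by stable subject order (logged).
    """
    pis = np.asarray(pis, float)
    n = len(pis)
    if n < 4:
        raise ValueError("need at least 4 subjects to form prognostic groups")
    if np.all(pis == pis[0]):
        raise ValueError("all prognostic indices identical; no grouping possible")
    if len(np.unique(pis)) < n:
        log.info("split_by_pi: tied PIs broken by stable subject order")
    order = np.argsort(pis, kind="stable")
    n_good = n // 2
    groups = np.empty(n, dtype=object)
    groups[order[:n_good]] = "good"
    groups[order[n_good:]] = "bad"
    return groups


# ----------------------------------------------------------------------
# copula-graphic estimator
# ----------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Right-continuous step survival function S(t), S(0) = 1."""

    times: np.ndarray           # event times, ascending
    surv: np.ndarray            # S just after each event time
    group: str = ""
    max_time: float = float("nan")   # largest observed time (any status)
    min_time: float = 0.0            # smallest observed time (any status)

    def evaluate(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.surv])
        return s[idx]


def cg_estimator(times, deltas, copula: ClaytonCopula, group: str = "") -> SurvivalCurve:
    """Copula-graphic estimator of the marginal survival of T.

    With pi(t) the at-risk proportion and phi the copula generator,

        S(t) = phi^{-1}[ -sum_{event u_i <= t} phi(pi(u_i)) - phi(pi(u_i) - 1/n) ]

    processed sequentially through tied events. At alpha = 0 (phi = -log)
    this is exactly the Kaplan-Meier estimator. With no events the curve
    is constant at 1 (logged).
    """
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, int)
    n = len(times)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if deltas.sum() == 0:
        log.warning("cg_estimator: no events; survival constant at 1")
        return SurvivalCurve(times=np.array([]), surv=np.array([]), group=group,
                             max_time=float(times.max()), min_time=float(times.min()))
    # sort by time; events before censorings at tied times so tied
    # censored subjects stay in the risk set of the tied events
    order = np.lexsort((1 - deltas, times))
    t_sorted = times[order]
    d_sorted = deltas[order]
    pos = np.arange(n)
    ev = d_sorted == 1
    risk = (n - pos[ev]).astype(float)          # sequential at-risk counts
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = copula.generator(risk / n) - copula.generator((risk - 1.0) / n)
        s = copula.inverse_generator(-np.cumsum(terms))
    s = np.minimum.accumulate(np.clip(np.nan_to_num(s, nan=0.0), 0.0, 1.0))
    ev_times = t_sorted[ev]
    # collapse tied event times to the last (smallest S) value
    keep = np.r_[ev_times[1:] != ev_times[:-1], True]
    return SurvivalCurve(times=ev_times[keep], surv=s[keep], group=group,
                         max_time=float(times.max()), min_time=float(times.min()))


def vertical_distance(curve_a: SurvivalCurve, curve_b: SurvivalCurve) -> float:
    """Average |S_a - S_b| over the union of event times restricted to the
    overlap of the two curves' observed time ranges."""
    lo = max(curve_a.min_time, curve_b.min_time)
    hi = min(curve_a.max_time, curve_b.max_time)
    grid = np.union1d(curve_a.times, curve_b.times)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise ValueError("curves have no event times in a common observed range")
    return float(np.mean(np.abs(curve_a.evaluate(grid) - curve_b.evaluate(grid))))


def permutation_test(times, deltas, groups, copula: ClaytonCopula,
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Permutation test of the vertical distance between two group curves.

    Group labels are permuted preserving group sizes; the p-value uses the
    add-one convention p = (1 + #{D_perm >= D_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    times = np.asarray(times, float)
    deltas = np.asarray(deltas, int)
    groups = np.asarray(groups)
    labs = np.unique(groups)
    if len(labs) != 2:
        raise ValueError("exactly two non-empty groups are required")

    def dist(g):
        a = g == labs[0]
        ca = cg_estimator(times[a], deltas[a], copula, group=str(labs[0]))
        cb = cg_estimator(times[~a], deltas[~a], copula, group=str(labs[1]))
        return vertical_distance(ca, cb)

    d_obs = dist(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if dist(rng.permutation(groups)) >= d_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return {"D": d_obs, "p_value": p, "n_perm": n_perm}


# ----------------------------------------------------------------------
# binary survival prediction and REP association
# ----------------------------------------------------------------------

def binary_survival_predict(table: pd.DataFrame, event, fits: list[DependentCoxFit],
                            top_k: int, sampling: dict | None = None,
                            iterations: int = 1000, folds: int = 5, seed: int = 0,
                            learner_params: dict | None = None):
    """Balanced-CV classification of the death label on top-k copula features.

    ``fits`` is the p-ordered output of :func:`copula_feature_selection`;
    ``sampling`` gives per-class subsample counts (e.g. 25 dead / 13
    alive per iteration). Classes smaller than the requested count are
    used whole (logged inside the sampler).
    """
    from .classify import balanced_cv_evaluate

    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if top_k > len(fits):
        raise ValueError(f"top_k={top_k} exceeds the {len(fits)} selected features")
    names = [f.feature for f in fits[:top_k]]
    return balanced_cv_evaluate(table[names], np.asarray(event, int),
                                iterations=iterations, folds=folds, seed=seed,
                                sampling=sampling, learner_params=learner_params)


def rep_group_crosstab(groups, rep_labels) -> dict:
    """2x2 REP-status x prognostic-group counts and row percentages."""
    groups = np.asarray(groups)
    rep = np.asarray(rep_labels).astype(int)
    if len(groups) != len(rep):
        raise ValueError("group and REP label vectors must align")
    counts = pd.crosstab(pd.Series(rep, name="rep"), pd.Series(groups, name="group"))
    for col in ("good", "bad"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["bad", "good"]]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return {"counts": counts, "row_percent": pct,
            "rep_in_bad_percent": float(pct.loc[1, "bad"]) if 1 in pct.index else float("nan")}


@dataclass
class PrognosticResult:
    """Bundle of the prognostic-grouping analysis outputs."""

    pi: np.ndarray
    groups: np.ndarray
    D: float
    p_value: float
    crosstab: dict | None = None
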