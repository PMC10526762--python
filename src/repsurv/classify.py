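"""Two-step feature selection and balanced-resampling ensemble classification.

The cohort is heavily imbalanced (13 REP vs 57 non-REP), so every
iteration draws a class-balanced subsample — all minority cases plus an
equal-size random majority subset — and runs stratified k-fold
cross-validation of a gradient-boosted decision-tree ensemble on it.
Metrics (AUC, accuracy, PPV, FPR) are collected per (iteration, fold) and
reported as full distributions, mean +/- sd.

Feature selection is two-step: a univariate screen (Shapiro-Wilk gated
ANOVA / Wilcoxon-Mann-Whitney) inside the balanced resampling loop ranks
features by how often they reach p < 0.05, then the top-ranked features
that remain significant on the full cohort are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

__all__ = [
    "CvMetricDistribution",
    "SelectedFeatureSet",
    "univariate_screen",
    "two_step_select",
    "balanced_cv_evaluate",
    "per_feature_f1",
    "compare_model_configs",
    "DEFAULT_LEARNER_PARAMS",
]

METRICS = ("AUC", "accuracy", "PPV", "FPR")

# pinned ensemble hyperparameters (gradient-boosted decision trees);
# shallow trees and a moderate learning rate suit the tiny balanced
# subsamples (~26 cases) the resampling scheme produces
DEFAULT_LEARNER_PARAMS = dict(
    n_estimators=100,
    max_depth=2,
    learning_rate=0.1,
    subsample=1.0,
    random_state=0,
)


@dataclass
class CvMetricDistribution:
    """One metric's values over every (iteration, fold) cell."""

    metric: str
    values: np.ndarray
    iterations: int
    folds: int

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))

    def summary(self) -> str:
        return f"{self.metric}: {self.mean:.3f} +/- {self.sd:.3f} (n={self.values.size})"


@dataclass
class SelectedFeatureSet:
    """Ordered selected features with p-values and selection frequencies."""

    names: list[str]
    p_values: pd.Series = field(default_factory=pd.Series)
    frequency: pd.Series = field(default_factory=pd.Series)


# ----------------------------------------------------------------------
# univariate screening
# ----------------------------------------------------------------------

def _two_sample_p(a: np.ndarray, b: np.ndarray) -> float:
    """Normality-gated two-sample test: ANOVA if both arms pass
    Shapiro-Wilk at 0.05, otherwise Wilcoxon-Mann-Whitney (two-sided)."""
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return 1.0
    try:
        normal = (stats.shapiro(a).pvalue > 0.05) and (stats.shapiro(b).pvalue > 0.05)
    except ValueError:
        normal = False
    if normal:
        return float(stats.f_oneway(a, b).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def univariate_screen(table: pd.DataFrame, labels) -> pd.Series:
    """Per-feature two-sided p-values for a binary group difference.

    Complete columns are tested in two vectorized batches (ANOVA for the
    Shapiro-normal ones, Wilcoxon-Mann-Whitney for the rest); columns with
    missing values fall back to a per-column path.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be non-empty")
    pos = labels == 1
    out = pd.Series(np.ones(table.shape[1]), index=table.columns)
    x = table.to_numpy(dtype=float)
    complete = np.isfinite(x).all(axis=0)

    normal = np.zeros(table.shape[1], dtype=bool)
    testable = complete.copy()
    for j in np.flatnonzero(complete):
        a, b = x[pos, j], x[~pos, j]
        if len(a) < 3 or len(b) < 3 or np.var(x[:, j]) == 0:
            if np.var(x[:, j]) == 0:
                log.warning("univariate_screen: feature %r constant; p = 1",
                            table.columns[j])
            testable[j] = False
            continue
        if np.var(a) == 0 or np.var(b) == 0:
            normal[j] = False  # Shapiro undefined on a constant arm
            continue
        try:
            normal[j] = (stats.shapiro(a).pvalue > 0.05) and (stats.shapiro(b).pvalue > 0.05)
        except ValueError:
            normal[j] = False
    anova_cols = np.flatnonzero(testable & normal)
    mw_cols = np.flatnonzero(testable & ~normal)
    if anova_cols.size:
        res = stats.f_oneway(x[pos][:, anova_cols], x[~pos][:, anova_cols], axis=0)
        out.iloc[anova_cols] = np.nan_to_num(res.pvalue, nan=1.0)
    if mw_cols.size:
        res = stats.mannwhitneyu(x[pos][:, mw_cols], x[~pos][:, mw_cols],
                                 alternative="two-sided", axis=0)
        out.iloc[mw_cols] = res.pvalue

    for j in np.flatnonzero(~complete):
        v = x[:, j]
        ok = np.isfinite(v)
        a, b = v[ok & pos], v[ok & ~pos]
        if len(a) < 3 or len(b) < 3 or np.var(v[ok]) == 0:
            continue
        out.iloc[j] = _two_sample_p(a, b)
    return out


# ----------------------------------------------------------------------
# balanced subsampling
# ----------------------------------------------------------------------

def _balanced_indices(labels: np.ndarray, rng: np.random.Generator,
                      sampling: dict | None = None) -> np.ndarray:
    """All-minority + sampled-majority (or explicit per-class counts)."""
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if sampling is None:
        if len(idx1) <= len(idx0):
            minority, majority, m_lab = idx1, idx0, 0
        else:
            minority, majority, m_lab = idx0, idx1, 1
        take = rng.choice(majority, size=len(minority), replace=False)
        return np.sort(np.concatenate([minority, take]))
    parts = []
    for lab, want in sampling.items():
        pool = idx1 if int(lab) == 1 else idx0
        if want > len(pool):
            log.warning("class %s has %d cases < requested %d; using all", lab, len(pool), want)
            want = len(pool)
        parts.append(rng.choice(pool, size=want, replace=False))
    return np.sort(np.concatenate(parts))


def _median_impute(train: np.ndarray, test: np.ndarray):
    """Impute NaNs with the training-fold median only (no leakage)."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    tr = np.where(np.isfinite(train), train, med)
    te = np.where(np.isfinite(test), test, med)
    return tr, te


# ----------------------------------------------------------------------
# two-step selection
# ----------------------------------------------------------------------

def two_step_select(table: pd.DataFrame, labels, k_final: int = 3,
                    n_iterations: int = 100, p_threshold: float = 0.05,
                    seed: int = 0, ranking: str = "frequency",
                    learner_params: dict | None = None) -> SelectedFeatureSet:
    """Resampled univariate screen, then a full-cohort significance check.

    Step 1 ranks features by how often they reach ``p_threshold`` under
    the univariate screen across balanced resampled iterations (or, with
    ``ranking='f1'``, by single-feature classifier F1). Step 2 keeps the
    top-ranked features that remain significant on the full cohort and
    returns the best ``k_final`` of them. If fewer than ``k_final``
    survive, all survivors are returned with a log entry.
    """
    labels = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    if k_final == 0:
        return SelectedFeatureSet(names=[])

    if ranking == "frequency":
        hits = pd.Series(0.0, index=table.columns)
        for _ in range(n_iterations):
            idx = _balanced_indices(labels, rng)
            p = univariate_screen(table.iloc[idx], labels[idx])
            hits[p.index[p < p_threshold]] += 1.0
        score = hits / n_iterations
    elif ranking == "f1":
        score = per_feature_f1(table, labels, seed=seed, learner_params=learner_params)
    else:
        raise ValueError(f"unknown ranking {ranking!r}")

    full_p = univariate_screen(table, labels)
    significant = full_p[full_p < p_threshold]
    ordered = score.loc[significant.index].sort_values(ascending=False, kind="stable")
    # tie-break within equal scores by full-cohort p-value
    ordered = (pd.DataFrame({"score": ordered, "p": full_p.loc[ordered.index]})
               .sort_values(["score", "p"], ascending=[False, True], kind="stable"))
    names = list(ordered.index[:k_final])
    if len(names) < k_final:
        log.warning("two_step_select: only %d of %d requested features significant",
                    len(names), k_final)
    return SelectedFeatureSet(
        names=names,
        p_values=full_p.loc[names],
        frequency=score.loc[names],
    )


def per_feature_f1(table: pd.DataFrame, labels, n_iterations: int = 10,
                   folds: int = 3, seed: int = 0,
                   learner_params: dict | None = None) -> pd.Series:
    """Mean cross-validated F1 of a single-feature classifier per feature."""
    labels = np.asarray(labels).astype(int)
    params = dict(DEFAULT_LEARNER_PARAMS, n_estimators=30)
    if learner_params:
        params.update(learner_params)
    rng = np.random.default_rng(seed)
    scores = {c: [] for c in table.columns}
    x_all = table.to_numpy(dtype=float)
    for _ in range(n_iterations):
        idx = _balanced_indices(labels, rng)
        y = labels[idx]
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr, te in skf.split(idx, y):
            for j, col in enumerate(table.columns):
                xtr, xte = _median_impute(x_all[idx[tr], j:j + 1], x_all[idx[te], j:j + 1])
                clf = GradientBoostingClassifier(**params)
                clf.fit(xtr, y[tr])
                pred = clf.predict(xte)
                scores[col].append(f1_score(y[te], pred, zero_division=0))
    return pd.Series({c: float(np.mean(v)) for c, v in scores.items()})


# ----------------------------------------------------------------------
# balanced CV evaluation
# ----------------------------------------------------------------------

def balanced_cv_evaluate(table: pd.DataFrame, labels, features=None,
                         iterations: int = 1000, folds: int = 5, seed: int = 0,
                         sampling: dict | None = None,
                         learner_params: dict | None = None,
                         ) -> dict[str, CvMetricDistribution]:
    """Balanced random-sampling k-fold evaluation of the tree ensemble.

    Per iteration: draw the balanced subsample, stratified k-fold it, fit
    the gradient-boosted ensemble on each training fold (median-imputed),
    and record AUC / accuracy(%) / PPV / FPR on the held-out fold. Folds
    that end up single-class are skipped and logged; PPV is NaN (and
    logged) when no positive prediction occurs.
    """
    labels = np.asarray(labels).astype(int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if features is not None:
        names = features.names if isinstance(features, SelectedFeatureSet) else list(features)
        table = table[names]
    x_all = table.to_numpy(dtype=float)

    params = dict(DEFAULT_LEARNER_PARAMS)
    if learner_params:
        params.update(learner_params)
    rng = np.random.default_rng(seed)
    rows = {m: [] for m in METRICS}
    n_ppv_undefined = 0
    for it in range(iterations):
        idx = _balanced_indices(labels, rng, sampling=sampling)
        y = labels[idx]
        if min(np.bincount(y, minlength=2)) < folds:
            raise ValueError("each class must have at least `folds` members after sampling")
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for tr, te in skf.split(idx, y):
            y_tr, y_te = y[tr], y[te]
            if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
                log.warning("fold with a single class skipped (iteration %d)", it)
                continue
            xtr, xte = _median_impute(x_all[idx[tr]], x_all[idx[te]])
            clf = GradientBoostingClassifier(**params)
            clf.fit(xtr, y_tr)
            prob = clf.predict_proba(xte)[:, 1]
            pred = (prob >= 0.5).astype(int)
            tp = int(((pred == 1) & (y_te == 1)).sum())
            fp = int(((pred == 1) & (y_te == 0)).sum())
            tn = int(((pred == 0) & (y_te == 0)).sum())
            rows["AUC"].append(roc_auc_score(y_te, prob))
            rows["accuracy"].append(100.0 * float((pred == y_te).mean()))
            if tp + fp > 0:
                rows["PPV"].append(tp / (tp + fp))
            else:
                n_ppv_undefined += 1
                rows["PPV"].append(np.nan)
            rows["FPR"].append(fp / (fp + tn) if fp + tn > 0 else np.nan)
    if n_ppv_undefined:
        log.warning("PPV undefined (no positive predictions) on %d folds", n_ppv_undefined)
    return {m: CvMetricDistribution(metric=m, values=np.asarray(rows[m], float),
                                    iterations=iterations, folds=folds)
            for m in METRICS}


def metrics_to_frame(dists: dict[str, CvMetricDistribution]) -> pd.DataFrame:
    """Long-form (iteration, fold, metric, value) table of CV metrics."""
    frames = []
    for m, d in dists.items():
        k = d.folds
        n = d.values.size
        frames.append(pd.DataFrame({
            "iteration": np.arange(n) // k,
            "fold": np.arange(n) % k,
            "metric": m,
            "value": d.values,
        }))
    return pd.concat(frames, ignore_index=True)


def compare_model_configs(dist_a: CvMetricDistribution,
                          dist_b: CvMetricDistribution) -> dict:
    """One-way ANOVA between two models' metric distributions."""
    if dist_a.metric != dist_b.metric:
        raise ValueError(f"metric mismatch: {dist_a.metric} vs {dist_b.metric}")
    if dist_a.values.size != dist_b.values.size:
        raise ValueError("distributions must share the fold structure")
    a = dist_a.values[np.isfinite(dist_a.values)]
    b = dist_b.values[np.isfinite(dist_b.values)]
    if np.array_equal(a, b):
        return {"metric": dist_a.metric, "F": 0.0, "p": 1.0}
    res = stats.f_oneway(a, b)
    return {"metric": dist_a.metric, "F": float(res.statistic), "p": float(res.pvalue)}
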