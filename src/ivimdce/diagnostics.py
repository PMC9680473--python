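"""Diagnostic model building and comparison.

Implements the Tables-4/5 machinery of the workflow: binary logistic
regression with forward likelihood-ratio (Forward: LR) variable selection,
empirical ROC analysis with DeLong standard errors and confidence intervals,
Youden-index operating points, pairwise DeLong tests between correlated
ROC curves, and leave-one-out cross-validated accuracy.

Five candidate-variable families define the five diagnostic models:
model_ADC, model_IVIM, model_DCE, model_DCE+ADC and model_DCE+IVIM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

__all__ = [
    "MODEL_FAMILIES",
    "LogisticFit",
    "FittedModel",
    "ROCReport",
    "DelongReport",
    "fit_logistic",
    "forward_lr_select",
    "roc_report",
    "delong_test",
    "loocv_accuracy",
    "model_candidates",
    "evaluate_models",
]

#: Parameter families (by column-name prefix) making up each diagnostic model.
FAMILY_PREFIXES: dict[str, tuple[str, ...]] = {
    "ADC": ("ADC_",),
    "IVIM": ("D_", "Dstar_", "f_"),
    "DCE": ("Ktrans_", "Kep_", "Ve_"),
}

MODEL_FAMILIES: dict[str, tuple[str, ...]] = {
    "model_ADC": ("ADC",),
    "model_IVIM": ("IVIM",),
    "model_DCE": ("DCE",),
    "model_DCE+ADC": ("DCE", "ADC"),
    "model_DCE+IVIM": ("DCE", "IVIM"),
}

_COEF_CAP = 30.0


@dataclass(frozen=True)
class LogisticFit:
    params: np.ndarray          # intercept first
    llf: float
    converged: bool
    separation: bool


@dataclass
class FittedModel:
    name: str
    selected: list[str]
    coefficients: pd.Series     # index: ["const", *selected]
    llf: float
    selection_trace: list[dict] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.coefficients["const"], dtype=float)
        for v in self.selected:
            eta += self.coefficients[v] * X[v].to_numpy(dtype=float)
        return special.expit(eta)


@dataclass(frozen=True)
class ROCReport:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    sensitivity: float   # percent, at the Youden point
    specificity: float   # percent
    threshold: float     # score cut at the Youden point


@dataclass(frozen=True)
class DelongReport:
    auc_a: float
    auc_b: float
    auc_difference: float
    se: float
    z: float
    p: float
    degenerate: bool = False


def _design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def fit_logistic(X, y) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    Complete or quasi-complete separation is detected and flagged; the
    affected coefficients are capped at +/-30 on the log-odds scale rather
    than diverging.  A singular design raises.
    """
    X = _design(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            res = model.fit(disp=0, maxiter=100)
            params = np.asarray(res.params, dtype=float)
            llf = float(res.llf)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            # Newton failed (typically perfect separation); fall back to a
            # quasi-Newton path that returns large-but-finite coefficients.
            res = model.fit(method="lbfgs", disp=0, maxiter=500)
            params = np.asarray(res.params, dtype=float)
            llf = float(res.llf)
            converged = False
            separation = True

    if np.any(np.abs(params) > _COEF_CAP):
        separation = True
        params = np.clip(params, -_COEF_CAP, _COEF_CAP)
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            llf = float(model.loglike(params))
    return LogisticFit(params=params, llf=llf, converged=converged,
                       separation=separation)


def _null_llf(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        return 0.0
    n1 = float(np.sum(y))
    n0 = y.size - n1
    return n1 * np.log(p) + n0 * np.log(1 - p)


def forward_lr_select(X: pd.DataFrame, y, candidates: list[str],
                      p_enter: float = 0.05, p_remove: float = 0.10,
                      name: str = "model") -> FittedModel:
    """Forward stepwise selection by likelihood-ratio chi-square.

    At each step the candidate with the smallest LR-test p-value against the
    current model enters if p < p_enter; included variables are then retested
    and removed if their LR p-value rises to >= p_remove.  Deterministic
    given the data.  Returns the intercept-only model if nothing enters.
    """
    y = np.asarray(y, dtype=float)
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValueError(f"candidates not in design table: {missing}")

    def ll(cols: list[str]) -> float:
        if not cols:
            return _null_llf(y)
        return fit_logistic(X[cols].to_numpy(), y).llf

    selected: list[str] = []
    trace: list[dict] = []
    visited: set[frozenset] = {frozenset()}
    while True:
        changed = False
        ll_cur = ll(selected)
        # entry step
        remaining = [c for c in candidates if c not in selected]
        best = None
        for c in remaining:
            try:
                ll_new = ll(selected + [c])
            except ValueError:
                continue  # singular with this candidate added
            lr = max(2.0 * (ll_new - ll_cur), 0.0)
            p = float(stats.chi2.sf(lr, df=1))
            if best is None or p < best[1]:
                best = (c, p, ll_new)
        if best is not None and best[1] < p_enter:
            candidate_set = frozenset(selected + [best[0]])
            if candidate_set not in visited:
                selected.append(best[0])
                visited.add(candidate_set)
                trace.append({"step": "enter", "variable": best[0], "p": best[1]})
                changed = True
                ll_cur = best[2]
        # removal step
        if len(selected) > 1:
            worst = None
            for c in selected:
                reduced = [v for v in selected if v != c]
                lr = max(2.0 * (ll_cur - ll(reduced)), 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                if worst is None or p > worst[1]:
                    worst = (c, p)
            if worst is not None and worst[1] >= p_remove:
                reduced_set = frozenset(v for v in selected if v != worst[0])
                if reduced_set not in visited:
                    selected.remove(worst[0])
                    visited.add(reduced_set)
                    trace.append({"step": "remove", "variable": worst[0], "p": worst[1]})
                    changed = True
        if not changed:
            break

    if selected:
        final = fit_logistic(X[selected].to_numpy(), y)
        coefs = pd.Series(final.params, index=["const", *selected])
        llf = final.llf
    else:
        p = float(np.mean(y))
        intercept = np.log(p / (1 - p)) if 0 < p < 1 else 0.0
        coefs = pd.Series({"const": intercept})
        llf = _null_llf(y)
    return FittedModel(name=name, selected=selected, coefficients=coefs,
                       llf=llf, selection_trace=trace)


# ---------------------------------------------------------------------------
# ROC / DeLong


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values (V10 for positives, V01 for negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(cmp.mean()), v10, v01


def roc_report(scores, labels, alpha: float = 0.05) -> ROCReport:
    """Empirical ROC summary: rank-estimator AUC, DeLong SE and normal CI,
    and the Youden-optimal operating point (ties broken toward higher
    specificity, i.e. the higher threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _placements(scores, labels)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = float(max(auc - z * se, 0.0))
    ci_high = float(min(auc + z * se, 1.0))

    # Youden scan over all achievable cuts (predict positive when score >= t).
    thresholds = np.unique(scores)
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)  # "predict none"
    best = None
    for t in thresholds[::-1]:  # descending: high specificity first
        pred = scores >= t
        sens = float(np.mean(pred[labels == 1]))
        spec = float(np.mean(~pred[labels == 0]))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, spec, float(t))
    _, sens, spec, threshold = best
    return ROCReport(auc=float(auc), se=se, ci_low=ci_low, ci_high=ci_high,
                     sensitivity=100.0 * sens, specificity=100.0 * spec,
                     threshold=threshold)


def delong_test(scores_a, scores_b, labels) -> DelongReport:
    """DeLong test for two correlated (paired) ROC curves.

    The covariance of the two AUCs is estimated from the placement values;
    the two-sided p comes from the normal distribution of the AUC
    difference.  A zero-variance difference (e.g. a model against itself)
    is degenerate and reported as p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have identical shape")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        return DelongReport(auc_a=auc_a, auc_b=auc_b, auc_difference=diff,
                            se=0.0, z=0.0, p=1.0, degenerate=True)
    se = float(np.sqrt(var_diff))
    z = diff / se
    p = float(2 * stats.norm.sf(abs(z)))
    return DelongReport(auc_a=auc_a, auc_b=auc_b, auc_difference=diff,
                        se=se, z=float(z), p=p)


def loocv_accuracy(X: pd.DataFrame, y, selected: list[str],
                   cutoff: float = 0.5) -> float:
    """Leave-one-out cross-validated accuracy.

    Variable selection is frozen (the full-data selection); only the
    coefficients are refitted on each fold of n-1 lesions, and the held-out
    lesion is classified at the probability cutoff.  A fold whose fit fails
    counts as misclassified.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("LOOCV needs at least 10 lesions")
    if not selected:
        # Intercept-only: predict the training majority class everywhere.
        correct = 0
        for i in range(n):
            p_train = (y.sum() - y[i]) / (n - 1)
            pred = 1.0 if p_train >= cutoff else 0.0
            correct += int(pred == y[i])
        return correct / n
    Xm = X[selected].to_numpy(dtype=float)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fit = fit_logistic(Xm[mask], y[mask])
        except Exception:
            continue  # fold counted as misclassified
        eta = fit.params[0] + Xm[i] @ fit.params[1:]
        prob = float(special.expit(eta))
        correct += int((prob >= cutoff) == bool(y[i]))
    return correct / n


# ---------------------------------------------------------------------------
# Model families and end-to-end evaluation


def model_candidates(screened: list[str]) -> dict[str, list[str]]:
    """Map each diagnostic model to its screened candidate variables."""
    out: dict[str, list[str]] = {}
    for model, families in MODEL_FAMILIES.items():
        prefixes = tuple(p for fam in families for p in FAMILY_PREFIXES[fam])
        cols = [c for c in screened if c.startswith(prefixes)]
        out[model] = cols
    return out


def evaluate_models(df: pd.DataFrame, screened: list[str],
                    label_col: str = "group",
                    p_enter: float = 0.05, p_remove: float = 0.10
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, FittedModel]]:
    """Fit and compare the five diagnostic models on an analysis table.

    Returns (performance table, pairwise DeLong table, fitted models).  The
    performance table carries AUC, DeLong SE, 95% CI, apparent and LOOCV
    accuracy, and Youden sensitivity/specificity per model; the DeLong table
    compares every model pair on the same lesions.
    """
    y = (df[label_col] == "malignant").to_numpy().astype(int)
    candidates = model_candidates(screened)
    fitted: dict[str, FittedModel] = {}
    scores: dict[str, np.ndarray] = {}
    perf_rows = []
    for model_name, cols in candidates.items():
        if not cols:
            raise ValueError(f"{model_name} has no screened candidate variables")
        fm = forward_lr_select(df, y, cols, p_enter=p_enter,
                               p_remove=p_remove, name=model_name)
        fitted[model_name] = fm
        s = fm.predict(df)
        scores[model_name] = s
        roc = roc_report(s, y)
        apparent = float(np.mean((s >= 0.5) == (y == 1)))
        loocv = loocv_accuracy(df, y, fm.selected)
        perf_rows.append({
            "model": model_name,
            "variables": ", ".join(fm.selected) if fm.selected else "(intercept only)",
            "auc": roc.auc, "se": roc.se,
            "ci_low": roc.ci_low, "ci_high": roc.ci_high,
            "loocv_accuracy": loocv, "apparent_accuracy": apparent,
            "sensitivity_pct": roc.sensitivity, "specificity_pct": roc.specificity,
        })
    perf = pd.DataFrame(perf_rows)

    delong_rows = []
    names = list(candidates)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rep = delong_test(scores[names[i]], scores[names[j]], y)
            delong_rows.append({
                "model_a": names[i], "model_b": names[j],
                "auc_a": rep.auc_a, "auc_b": rep.auc_b,
                "auc_difference": rep.auc_difference,
                "se": rep.se, "z": rep.z, "p_value": rep.p,
            })
    return perf, pd.DataFrame(delong_rows), fitted
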