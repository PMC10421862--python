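"""LASSO-Cox feature selection, radiomic risk score and survival evaluation.

The radiomic risk score (RRS) is the linear combination of the
LASSO-selected delta features weighted by their Cox coefficients,
``RRS_i = sum_j beta_j x_ij``.  The penalty is chosen on a 100-point
log-spaced grid spanning [lambda_max, 0.001*lambda_max] by k-fold
cross-validation (k = min(n_folds, n); leave-one-out when the cohort is
smaller than the requested fold count), minimizing the held-out Cox
partial-likelihood deviance (Verweij-van Houwelingen); a mean-squared
martingale-residual criterion is available as ``cv_criterion =
"mse_linear_predictor"``.  Patients are stratified at the training-median
RRS (ties to low risk) and evaluated with Kaplan-Meier curves, the
log-rank test, hazard ratios from (uni/multivariable) Cox fits with Efron
tie handling and Wald intervals, and Harrell's concordance index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import contextlib

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning, StatisticalWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv


# ---------------------------------------------------------------------------
# partial likelihood helpers (Breslow ties; used only for CV scoring)


def cox_partial_loglik(lp: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    order = np.argsort(-time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    log_cumsum = np.logaddexp.accumulate(lp)
    # risk set of subject i = all subjects with time >= t_i; ties extend the
    # denominator to the last subject sharing t_i
    ev = np.nonzero(event)[0]
    j = np.searchsorted(-time, -time[ev], side="right") - 1
    return float((lp[ev] - log_cumsum[j]).sum())


def _martingale_residuals(lp_train, t_train, e_train, lp_test, t_test, e_test):
    """Held-out martingale residuals with a Breslow baseline from the train set."""
    order = np.argsort(t_train)
    ts, es, lps = t_train[order], e_train[order], lp_train[order]
    risk = np.exp(lps)
    # cumulative baseline hazard at the training event times
    event_times = ts[es == 1]
    uniq = np.unique(event_times)
    H0, h = {}, 0.0
    for t in uniq:
        denom = risk[ts >= t].sum()
        h += (event_times == t).sum() / denom
        H0[t] = h
    times_arr = np.array(sorted(H0))
    vals = np.array([H0[t] for t in times_arr])

    def H(t):
        idx = np.searchsorted(times_arr, t, side="right") - 1
        return 0.0 if idx < 0 else vals[idx]

    Ht = np.array([H(t) for t in t_test])
    return e_test - Ht * np.exp(lp_test)


# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """A fitted LASSO-Cox radiomic risk model."""

    features: list
    coefficients: np.ndarray
    lambda_: float
    lambda_grid: np.ndarray
    cv_criterion: np.ndarray          # mean criterion per grid lambda
    cv_criterion_name: str
    rrs_cutoff: float
    normalization_provenance: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "features": list(self.features),
                "coefficients": [float(c) for c in self.coefficients],
                "lambda": float(self.lambda_),
                "lambda_grid": [float(x) for x in self.lambda_grid],
                "cv_criterion": [float(x) for x in self.cv_criterion],
                "cv_criterion_name": self.cv_criterion_name,
                "rrs_cutoff": float(self.rrs_cutoff),
                "normalization_provenance": self.normalization_provenance,
            }, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["features"], np.asarray(d["coefficients"]), d["lambda"],
                   np.asarray(d["lambda_grid"]), np.asarray(d["cv_criterion"]),
                   d["cv_criterion_name"], d["rrs_cutoff"],
                   d.get("normalization_provenance", ""))


@contextlib.contextmanager
def quiet_lifelines():
    """Silence small-sample convergence chatter from lifelines/scipy."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", StatisticalWarning)
        try:
            from scipy.linalg import LinAlgWarning
            warnings.simplefilter("ignore", LinAlgWarning)
        except ImportError:
            pass
        yield


def _surv_arrays(clinical: pd.DataFrame):
    return (clinical["os_months"].to_numpy(dtype=float),
            clinical["event"].to_numpy(dtype=int))


def fit_lasso_cox(deltas: pd.DataFrame, clinical: pd.DataFrame,
                  lambda_grid=None, n_folds: int = 100, seed: int = 0,
                  cv_criterion: str = "deviance", tol: float = 1e-5) -> RiskModel:
    """Select prognostic delta features by L1-penalized Cox regression.

    ``deltas`` rows align with ``clinical`` rows (os_months, event).  The
    coordinate-descent elastic-net path (pure LASSO, l1_ratio = 1) is fit
    per CV fold on a shared lambda grid; the grid value minimizing the
    summed held-out criterion is refit on the full cohort.  The RRS cutoff
    is the training-cohort median RRS.  Deterministic under ``seed``.
    """
    if len(deltas) < 10:
        raise ValueError("need >= 10 patients")
    time, event = _surv_arrays(clinical)
    if event.sum() < 1:
        raise ValueError("no events in cohort")
    X = deltas.to_numpy(dtype=float)
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features constant")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    n = len(X)

    if lambda_grid is None:
        probe = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=100,
                                       alpha_min_ratio=0.001, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(X, y)
        lambda_grid = np.asarray(probe.alphas_)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    k = min(n_folds, n)
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    crit = np.zeros(len(lambda_grid))
    for tr, te in folds.split(X):
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambda_grid,
                                          fit_baseline_model=False, tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_fit.fit(X[tr], y[tr])
        coefs = _coef_path(fold_fit, lambda_grid, X.shape[1])
        for m, beta in enumerate(coefs):
            lp = X @ beta
            if cv_criterion == "deviance":
                # V&VH: deviance of the held-out contribution
                crit[m] += -2.0 * (
                    cox_partial_loglik(lp, time, event)
                    - cox_partial_loglik(lp[tr], time[tr], event[tr])
                )
            elif cv_criterion == "mse_linear_predictor":
                resid = _martingale_residuals(lp[tr], time[tr], event[tr],
                                              lp[te], time[te], event[te])
                crit[m] += float((resid ** 2).mean())
            else:
                raise ValueError(f"unknown cv_criterion {cv_criterion!r}")

    best = int(np.argmin(crit))
    lambda_min = float(lambda_grid[best])
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambda_grid,
                                   fit_baseline_model=False, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    beta = _coef_path(final, lambda_grid, X.shape[1])[best]
    sel = np.nonzero(beta)[0]
    features = [deltas.columns[j] for j in sel]
    coefficients = beta[sel]
    rrs = X[:, sel] @ coefficients if len(sel) else np.zeros(n)
    return RiskModel(features=features, coefficients=coefficients,
                     lambda_=lambda_min, lambda_grid=lambda_grid,
                     cv_criterion=crit / k, cv_criterion_name=cv_criterion,
                     rrs_cutoff=float(np.median(rrs)))


def _coef_path(model, lambda_grid, p):
    """Coefficients at each grid lambda (zeros outside the fitted path)."""
    fitted = np.asarray(model.alphas_)
    out = np.zeros((len(lambda_grid), p))
    for m, lam in enumerate(lambda_grid):
        idx = np.argmin(np.abs(fitted - lam))
        if np.isclose(fitted[idx], lam, rtol=1e-6):
            out[m] = model.coef_[:, idx]
        # else: lambda not reached by this fold's path -> keep zeros
    return out


def compute_rrs(model: RiskModel, deltas: pd.DataFrame) -> pd.Series:
    """RRS_i = sum_j beta_j x_ij over the model's selected features."""
    missing = [f for f in model.features if f not in deltas.columns]
    if missing:
        raise ValueError(f"missing selected features: {missing}")
    if not model.features:
        return pd.Series(np.zeros(len(deltas)), index=deltas.index, name="rrs")
    vals = deltas[model.features].to_numpy(dtype=float) @ model.coefficients
    return pd.Series(vals, index=deltas.index, name="rrs")


def stratify_by_cutoff(scores, cutoff: float) -> np.ndarray:
    """'high' iff score > cutoff (ties go to low risk)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores > cutoff, "high", "low")


@dataclass
class KMResult:
    curves: dict                  # group -> DataFrame(time, survival)
    median_survival: dict         # group -> float (NaN if curve never < 0.5)
    logrank_statistic: float
    logrank_p: float


def km_logrank(groups, clinical: pd.DataFrame) -> KMResult:
    """Kaplan-Meier curves per group plus the two-sample log-rank test."""
    time, event = _surv_arrays(clinical)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if any((groups == g).sum() == 0 for g in labels) or len(labels) == 0:
        raise ValueError("each group needs >= 1 subject")
    curves, medians = {}, {}
    for g in labels:
        sel = groups == g
        km = KaplanMeierFitter()
        km.fit(time[sel], event[sel], label=str(g))
        sf = km.survival_function_
        curves[g] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        })
        med = km.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
    res = multivariate_logrank_test(time, groups, event)
    return KMResult(curves=curves, median_survival=medians,
                    logrank_statistic=float(res.test_statistic),
                    logrank_p=float(res.p_value))


@dataclass
class SurvivalFit:
    summary: pd.DataFrame         # covariate, hr, ci_lower, ci_upper, p
    c_index: float
    model_type: str


def cox_fit(covariates: pd.DataFrame, clinical: pd.DataFrame,
            multivariable: bool = False) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Wald intervals).

    ``multivariable=False`` with several columns fits each covariate in its
    own univariable model; the reported C-index is then that of the first
    covariate's model.
    """
    time, event = _surv_arrays(clinical)
    if multivariable and event.sum() < covariates.shape[1] + 1:
        raise ValueError("too few events for multivariable fit")
    df = covariates.copy().reset_index(drop=True)
    df["os_months"] = time
    df["event"] = event

    def _one(cols):
        cph = CoxPHFitter()
        with quiet_lifelines():
            cph.fit(df[cols + ["os_months", "event"]],
                    duration_col="os_months", event_col="event")
        s = cph.summary
        tab = pd.DataFrame({
            "covariate": s.index,
            "hr": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        })
        return cph, tab

    cols = list(covariates.columns)
    if multivariable:
        cph, tab = _one(cols)
        lp = cph.predict_partial_hazard(df[cols])
        c = concordance_index(np.log(lp.to_numpy()), clinical)
        return SurvivalFit(tab, c, "multivariable")
    tabs, c = [], None
    for col in cols:
        cph, tab = _one([col])
        tabs.append(tab)
        if c is None:
            c = concordance_index(df[col].to_numpy() * cph.params_.iloc[0],
                                  clinical)
    return SurvivalFit(pd.concat(tabs, ignore_index=True), c, "univariable")


def plot_km(result: KMResult, path) -> None:
    """Export Kaplan-Meier step curves (one line per risk group) as an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in result.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(group))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {result.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def concordance_index(scores, clinical: pd.DataFrame) -> float:
    """Harrell's C of a risk score (higher score -> earlier failure);
    tied scores credit 0.5."""
    time, event = _surv_arrays(clinical)
    scores = np.asarray(scores, dtype=float)
    return float(_lifelines_cindex(time, -scores, event))
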