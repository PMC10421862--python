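"""Clinical+radiomic nomogram, calibration, decision curves, cohort tests.

The nomogram is a points representation of a multivariable Cox model over
the radiomic risk score and clinical covariates: each covariate's points
are proportional to its coefficient times its value range (the widest-
swing covariate spans 100 points), and total points map monotonically to
the predicted probability of surviving the horizon (3 years by default).
Calibration compares decile-grouped predicted event probabilities with
censoring-aware Kaplan-Meier observed proportions (Hosmer-Lemeshow chi^2,
groups-2 df) and quantifies overfitting with bootstrap-resample optimism.
Decision-curve analysis reports net benefit
``NB(t) = TP/n - FP/n * t/(1-t)`` against treat-all / treat-none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .survival import concordance_index, quiet_lifelines

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 36.0


@dataclass
class NomogramModel:
    cph: CoxPHFitter
    covariates: list
    horizon: float
    points_scale: float               # points per unit of linear predictor
    reference: pd.Series              # covariate values worth 0 points
    penalizer: float = 0.0

    @staticmethod
    def encode(data: pd.DataFrame) -> pd.DataFrame:
        """Binary-encode categorical race (white = 0, other = 1)."""
        out = data.copy()
        if "race" in out.columns and out["race"].dtype == object:
            out["race"] = (out["race"] != "white").astype(float)
        return out

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        data = self.encode(data)
        lp = np.zeros(len(data))
        for c in self.covariates:
            lp += self.cph.params_[c] * data[c].to_numpy(dtype=float)
        return lp

    def total_points(self, data: pd.DataFrame) -> np.ndarray:
        ref_lp = float(sum(self.cph.params_[c] * self.reference[c]
                           for c in self.covariates))
        return (self.linear_predictor(data) - ref_lp) * self.points_scale

    def predict_survival(self, data: pd.DataFrame, horizon: float = None) -> np.ndarray:
        """P(survive past horizon | covariates), in (0, 1)."""
        t = self.horizon if horizon is None else horizon
        data = self.encode(data)
        sf = self.cph.predict_survival_function(data[self.covariates], times=[t])
        return np.clip(sf.iloc[0].to_numpy(), 1e-12, 1 - 1e-12)

    def points_table(self) -> pd.DataFrame:
        rows = []
        for c in self.covariates:
            beta = float(self.cph.params_[c])
            rows.append({
                "covariate": c,
                "coefficient": beta,
                "reference_value": float(self.reference[c]),
                "points_per_unit": beta * self.points_scale,
            })
        return pd.DataFrame(rows)

    def c_index(self, data: pd.DataFrame, clinical: pd.DataFrame) -> float:
        return concordance_index(self.linear_predictor(data), clinical)


def build_nomogram(clinical: pd.DataFrame, rrs: pd.Series,
                   covariates=None,
                   horizon: float = DEFAULT_HORIZON_MONTHS,
                   penalizer: float = 0.0) -> NomogramModel:
    """Fit the combined Cox model and lay out its point scales.

    ``clinical`` must hold os_months and event plus the clinical
    covariates; ``rrs`` is added as the radiomic covariate.  Categorical
    race is binary-encoded.  Default covariates: rrs, age, race,
    baseline_tumor_volume_ml (whichever are present).
    """
    df = clinical.reset_index(drop=True).copy()
    df["rrs"] = np.asarray(rrs, dtype=float)
    if "race" in df.columns and df["race"].dtype == object:
        df["race"] = (df["race"] != "white").astype(float)
    if covariates is None:
        covariates = [c for c in
                      ["rrs", "age", "race", "baseline_tumor_volume_ml"]
                      if c in df.columns]
    cph = CoxPHFitter(penalizer=penalizer)
    with quiet_lifelines():
        cph.fit(df[covariates + ["os_months", "event"]],
                duration_col="os_months", event_col="event")

    # reference = per-covariate value with the lowest risk contribution
    ref, swings = {}, {}
    for c in covariates:
        beta = float(cph.params_[c])
        lo, hi = df[c].min(), df[c].max()
        ref[c] = lo if beta >= 0 else hi
        swings[c] = abs(beta) * (hi - lo)
    max_swing = max(swings.values()) if swings else 1.0
    scale = 100.0 / max_swing if max_swing > 0 else 1.0
    return NomogramModel(cph=cph, covariates=list(covariates), horizon=horizon,
                         points_scale=scale, reference=pd.Series(ref),
                         penalizer=penalizer)


@dataclass
class CalibrationResult:
    curve: pd.DataFrame               # group, n, predicted, observed_km
    hl_statistic: float
    hl_p: float
    c_index_apparent: float
    c_index_corrected: float
    optimism: float
    bootstrap_trace: list             # one C-optimism record per resample


def _km_event_prob(time, event, horizon) -> float:
    km = KaplanMeierFitter().fit(time, event)
    return float(1.0 - km.predict(horizon))


def hosmer_lemeshow(predictions, time, event, horizon, groups: int = 10):
    """Censoring-aware Hosmer-Lemeshow goodness of fit.

    Predicted horizon event probabilities are quantile-binned; the observed
    proportion per bin is the KM event probability at the horizon.
    chi^2 = sum n_g (obs_g - pred_g)^2 / (pred_g (1 - pred_g)), groups-2 df.
    Returns (statistic, p, curve DataFrame).
    """
    pred = np.asarray(predictions, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    try:
        bins = pd.qcut(pred, groups, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(pred), dtype=int)
    n_bins = int(np.max(bins)) + 1
    if n_bins < groups:
        logger.warning("merged empty calibration bins: %d used", n_bins)
    rows, hl = [], 0.0
    for g in range(n_bins):
        sel = bins == g
        p_bar = float(pred[sel].mean())
        obs = _km_event_prob(time[sel], event[sel], horizon)
        n_g = int(sel.sum())
        rows.append({"group": g, "n": n_g, "predicted": p_bar,
                     "observed_km": obs})
        denom = p_bar * (1 - p_bar)
        if denom > 0:
            hl += n_g * (obs - p_bar) ** 2 / denom
    dof = max(n_bins - 2, 1)
    return float(hl), float(stats.chi2.sf(hl, dof)), pd.DataFrame(rows)


def assess_calibration(model: NomogramModel, data: pd.DataFrame,
                       n_boot: int = 500, groups: int = 10,
                       seed: int = 0) -> CalibrationResult:
    """Decile calibration + Hosmer-Lemeshow + bootstrap optimism.

    ``data`` carries the model covariates plus os_months/event.  Predicted
    horizon event probabilities are grouped into ``groups`` quantile bins
    (empty bins merge into their neighbour, logged); observed proportions
    are KM-based within bins.  ``n_boot`` resample refits estimate the
    optimism of the apparent C-index.
    """
    if len(data) < 2 * groups:
        raise ValueError("need >= 2 subjects per calibration group")
    df = data.reset_index(drop=True).copy()
    if "race" in df.columns and df["race"].dtype == object:
        df["race"] = (df["race"] != "white").astype(float)
    pred = 1.0 - model.predict_survival(df)
    hl, hl_p, curve = hosmer_lemeshow(pred, df["os_months"], df["event"],
                                      model.horizon, groups)
    c_app = model.c_index(df, df)
    rng = np.random.default_rng(seed)
    trace = []
    for b in range(n_boot):
        idx = rng.integers(0, len(df), len(df))
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            bm = build_nomogram(boot, boot["rrs"],
                                covariates=model.covariates,
                                horizon=model.horizon,
                                penalizer=model.penalizer)
            c_boot = bm.c_index(boot, boot)
            c_orig = bm.c_index(df, df)
            trace.append(c_boot - c_orig)
        except Exception:
            trace.append(float("nan"))
    optimism = float(np.nanmean(trace)) if trace else 0.0
    return CalibrationResult(
        curve=curve, hl_statistic=float(hl), hl_p=hl_p,
        c_index_apparent=c_app, c_index_corrected=c_app - optimism,
        optimism=optimism, bootstrap_trace=trace,
    )


@dataclass
class DCACurve:
    curve: pd.DataFrame               # threshold, nb_model, nb_all, nb_none
    prevalence: float


def decision_curve(predictions, outcomes, thresholds=None) -> DCACurve:
    """Net benefit of acting on predicted event probabilities.

    ``predictions`` are horizon event probabilities; ``outcomes`` are
    binary horizon events.  Treat-none is identically 0; treat-all is
    pi - (1 - pi) t / (1 - t) at prevalence pi.
    """
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n = len(y)
    pi = y.mean()
    rows = []
    for t in thresholds:
        treat = p >= t
        tp = float((treat & (y == 1)).sum()) / n
        fp = float((treat & (y == 0)).sum()) / n
        rows.append({
            "threshold": t,
            "nb_model": tp - fp * t / (1 - t),
            "nb_all": pi - (1 - pi) * t / (1 - t),
            "nb_none": 0.0,
        })
    return DCACurve(pd.DataFrame(rows), float(pi))


def plot_decision_curve(dca: DCACurve, path) -> None:
    """Export the net-benefit curves (model vs treat-all vs treat-none)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    c = dca.curve
    ax.plot(c["threshold"], c["nb_model"], label="model")
    ax.plot(c["threshold"], c["nb_all"], "--", label="treat all")
    ax.plot(c["threshold"], c["nb_none"], ":", label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(-0.1, max(0.05, dca.prevalence + 0.05))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def horizon_outcomes(clinical: pd.DataFrame, horizon: float):
    """Binary event-by-horizon outcomes; censored-before-horizon excluded.

    Returns (outcomes, evaluable_mask).
    """
    time = clinical["os_months"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    evaluable = (time >= horizon) | (event == 1)
    outcomes = ((time < horizon) & (event == 1)).astype(int)
    return outcomes[evaluable], evaluable


def compare_clinical_groups(table, variable: str = None,
                            grouping: str = None) -> dict:
    """Fisher's exact test (categorical) or Welch two-sided t (continuous).

    ``table`` is either a DataFrame with ``variable``/``grouping`` columns,
    or a ready 2x2 contingency array.  Returns {"test", "statistic", "p"}.
    """
    if not isinstance(table, pd.DataFrame):
        ct = np.asarray(table)
        if ct.shape != (2, 2):
            raise ValueError("contingency input must be 2x2")
        if (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any():
            raise ValueError("contingency table has a zero margin")
        odds, p = stats.fisher_exact(ct, alternative="two-sided")
        return {"test": "fisher_exact", "statistic": float(odds), "p": float(p)}
    var, grp = table[variable], table[grouping]
    levels = grp.unique()
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    if pd.api.types.is_numeric_dtype(var) and var.nunique() > 2:
        a = var[grp == levels[0]].to_numpy(dtype=float)
        b = var[grp == levels[1]].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return {"test": "welch_t", "statistic": float(t), "p": float(p)}
    ct = pd.crosstab(var, grp)
    if ct.shape != (2, 2):
        raise ValueError("categorical comparison requires a 2x2 table")
    if (ct.sum(axis=0) == 0).any() or (ct.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    odds, p = stats.fisher_exact(ct.to_numpy(), alternative="two-sided")
    return {"test": "fisher_exact", "statistic": float(odds), "p": float(p)}
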