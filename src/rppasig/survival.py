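"""Distant recurrence-free survival: Kaplan-Meier curves and Cox models.

Per signaling cluster, a Cox proportional-hazards model (Efron tie handling)
estimates the DRFS hazard ratio for pCR; within each cluster's non-responders
a per-analyte Cox screen, adjusted for HR and HER2 status, tests individual
protein/phosphoprotein levels against DRFS with Benjamini-Hochberg control
per cluster family.  Times are in years; administrative censoring is the
caller's (or the generator's) responsibility.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .associate import bh_adjust
from .core import ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "SurvivalFit",
    "KMCurve",
    "km_estimate",
    "cox_fit",
    "drfs_by_cluster",
    "analyte_survival_screen",
]


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclasses.dataclass
class SurvivalFit:
    """One Cox fit of an exposure on DRFS."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    lr_p: float
    coef: float
    se: float
    n: int
    n_events: int
    stratum: str = "population"
    flagged: bool = False


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if len(t) == 0:
        raise ValidationError("empty survival sample")
    if (t <= 0).any():
        raise ValidationError("times must be > 0")
    kmf = KaplanMeierFitter().fit(t, e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def _flagged(n, n_events, stratum) -> SurvivalFit:
    return SurvivalFit(np.nan, 0.0, np.inf, np.nan, np.nan, np.nan, np.nan,
                       n, n_events, stratum, flagged=True)


def cox_fit(times, events, exposure, covariates: pd.DataFrame = None,
            stratum: str = "population") -> SurvivalFit:
    """Cox partial-likelihood fit of one exposure (Efron ties, Wald CI, LR p).

    A monotone partial likelihood (e.g. no events in one exposure group) is
    returned as a flagged fit with an infinite confidence bound rather than
    raising.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(exposure, dtype=float)
    if e.sum() < 1:
        raise ValidationError("need at least one event")
    if x[e == 1].min() == x[e == 1].max() and x.min() == x.max():
        raise ValidationError("exposure is constant")
    df = pd.DataFrame({"time": t, "event": e, "exposure": x})
    cov_cols = []
    if covariates is not None and covariates.shape[1] > 0:
        dummies = pd.get_dummies(covariates.astype(str).reset_index(drop=True),
                                 drop_first=True, dtype=float)
        for c in dummies.columns:
            if dummies[c].min() != dummies[c].max():
                df[c] = dummies[c].to_numpy()
                cov_cols.append(c)
    opts = {"fit_options": {"precision": 1e-9}}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = CoxPHFitter().fit(df, "time", "event", **opts)
            if cov_cols:
                red = CoxPHFitter().fit(df[["time", "event"] + cov_cols],
                                        "time", "event", **opts)
                lr = 2.0 * (full.log_likelihood_ - red.log_likelihood_)
            else:
                lr = full.log_likelihood_ratio_test().test_statistic
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        logger.warning("stratum %s: non-identifiable Cox fit flagged", stratum)
        return _flagged(len(t), int(e.sum()), stratum)
    coef = float(full.params_["exposure"])
    se = float(full.standard_errors_["exposure"])
    # |coef| > 10 means a hazard ratio beyond e^10 on this package's scales
    # (binary pCR or z-scored analytes): a monotone partial likelihood.
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 10 or se > 100:
        logger.warning("stratum %s: monotone likelihood flagged", stratum)
        return _flagged(len(t), int(e.sum()), stratum)
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        return SurvivalFit(
            hazard_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - z * se)),
            ci_high=float(np.exp(coef + z * se)),
            wald_p=float(2 * stats.norm.sf(abs(coef) / se)),
            lr_p=float(stats.chi2.sf(max(lr, 0.0), 1)),
            coef=coef, se=se, n=len(t), n_events=int(e.sum()),
            stratum=stratum,
        )


def drfs_by_cluster(clinical: pd.DataFrame, labels) -> pd.DataFrame:
    """Forest table of per-cluster DRFS hazard ratios for pCR (plus population).

    Clusters where the fit is non-identifiable (e.g. no events in one pCR
    group) appear flagged with missing estimates.
    """
    clin = clinical.set_index("patient_id")
    g = pd.Series(np.asarray(labels, dtype=object),
                  index=clinical["patient_id"].to_numpy())
    if clin["drfs_time"].isna().any():
        raise ValidationError("DRFS columns required for survival analysis")

    def one(members, name):
        sub = clin.loc[members]
        if sub["drfs_event"].sum() < 1 or sub["pcr"].nunique() < 2:
            return _flagged(len(sub), int(sub["drfs_event"].sum()), name)
        return cox_fit(sub["drfs_time"], sub["drfs_event"], sub["pcr"], stratum=name)

    fits = [one(clin.index, "population")]
    for level in pd.unique(g.dropna()):
        fits.append(one(g.index[g == level], str(level)))
    return pd.DataFrame([dataclasses.asdict(f) for f in fits])


def analyte_survival_screen(harmonized: pd.DataFrame, clinical: pd.DataFrame,
                            labels, responders: bool = False,
                            bh_alpha: float = 0.05, min_n: int = 10,
                            min_events: int = 3, p_kind: str = "lr") -> pd.DataFrame:
    """Per-analyte Cox screen of DRFS within each cluster's non-responders.

    Models adjust for HR and HER2 status (levels present in the subset);
    p values (``p_kind``: "lr" or "wald") are BH-adjusted within each
    cluster's analyte family; flagged fits never enter a family.  Clusters
    with fewer than ``min_n`` patients or ``min_events`` events in the
    selected response group are skipped with a warning.
    """
    if p_kind not in ("lr", "wald"):
        raise ValidationError("p_kind must be 'lr' or 'wald'")
    logger.info("analyte DRFS screen using %s p values", p_kind)
    clin = clinical.set_index("patient_id").loc[harmonized.index]
    g = pd.Series(np.asarray(labels, dtype=object), index=harmonized.index)
    records = []
    for level in pd.unique(g.dropna()):
        members = g.index[(g == level) & (clin["pcr"] == int(responders))]
        sub = clin.loc[members]
        if len(sub) < min_n or sub["drfs_event"].sum() < min_events:
            logger.warning("cluster %s skipped (n=%d, events=%d)", level,
                           len(sub), int(sub["drfs_event"].sum()))
            continue
        for analyte in harmonized.columns:
            values = harmonized.loc[members, analyte]
            obs = values.notna()
            if obs.sum() < min_n or values[obs].nunique() < 2:
                continue
            fit = cox_fit(sub.loc[obs, "drfs_time"], sub.loc[obs, "drfs_event"],
                          values[obs], sub.loc[obs, ["hr", "her2"]],
                          stratum=str(level))
            records.append({
                "cluster": level, "analyte": analyte, "n": fit.n,
                "n_events": fit.n_events, "hazard_ratio": fit.hazard_ratio,
                "p": fit.lr_p if p_kind == "lr" else fit.wald_p,
                "flagged": fit.flagged,
            })
    out = pd.DataFrame(records, columns=["cluster", "analyte", "n", "n_events",
                                         "hazard_ratio", "p", "flagged"])
    if len(out):
        out["bh_p"] = np.nan
        for level in out["cluster"].unique():
            fam = (out["cluster"] == level) & ~out["flagged"]
            out.loc[fam, "bh_p"] = bh_adjust(out.loc[fam, "p"])
    else:
        out["bh_p"] = []
    out["significant"] = out["bh_p"] < bh_alpha
    out["nominal"] = out["p"] < 0.05
    return out
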