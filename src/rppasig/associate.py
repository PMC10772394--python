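"""Per-analyte association screens with pCR and between-group differential tests.

Continuous biomarkers are tested one at a time with an adjusted logistic
model (``pCR ~ biomarker + HR + HER2 + Tx`` in whole-population analyses;
HR/HER2 within arms where both levels are present; arm within subtypes), with
a likelihood-ratio test of the biomarker term against the covariate-only
model.  p values are controlled per screen family with Benjamini-Hochberg;
``significant`` means BH p below the family alpha, ``nominal`` means raw
LR p < 0.05.  Between-group differential expression uses the analogous
Gaussian linear-model likelihood-ratio test of the group term.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core import ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "LogisticLR",
    "fit_logistic_lr",
    "bh_adjust",
    "association_screen",
    "differential_screen",
    "count_significant",
    "group_response_rates",
]

RECORD_COLUMNS = ["analyte", "scope", "n", "direction", "lr_p", "bh_p",
                  "significant", "nominal"]


@dataclasses.dataclass
class LogisticLR:
    """One biomarker's adjusted logistic likelihood-ratio test."""

    coef: float
    lr_stat: float
    lr_p: float
    converged: bool
    n: int


def _dummy_design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept + dummy-coded covariates, dropping levels constant in the data."""
    cols = [np.ones(n)]
    if covariates is not None and covariates.shape[1] > 0:
        dummies = pd.get_dummies(covariates.astype(str), drop_first=True, dtype=float)
        for c in dummies.columns:
            v = dummies[c].to_numpy()
            if v.min() != v.max():
                cols.append(v)
    return np.column_stack(cols)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    # IRLS with a deviance-based stopping rule: under quasi-separation in a
    # nuisance dummy the log-likelihood plateaus at its finite limit and the
    # biomarker LR statistic stays well-defined, so only a diverging
    # *biomarker* coefficient flags a record (checked by the caller).
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        llf = res.llf  # force (and cache) inside the suppression context
    converged = bool(getattr(res, "converged", True)) and np.isfinite(llf)
    return res, converged


def fit_logistic_lr(response, biomarker, covariates: pd.DataFrame = None) -> LogisticLR:
    """LR test of one continuous biomarker in an adjusted logistic model.

    Fits the full model (biomarker + covariates) and the covariate-only
    reduced model by maximum likelihood; ``lr_stat = 2(l_full - l_reduced)``
    with a chi-squared(1) upper-tail p value.  Non-convergence or complete
    separation yields ``converged=False`` with missing p (the record is then
    excluded from BH families).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(biomarker, dtype=float)
    if y.min() == y.max():
        raise ValidationError("response has a single class")
    if x.min() == x.max():
        raise ValidationError("biomarker is constant")
    Xr = _dummy_design(covariates, len(y))
    Xf = np.column_stack([Xr[:, :1], x, Xr[:, 1:]])
    try:
        full, conv_f = _fit_logit(y, Xf)
        red, conv_r = _fit_logit(y, Xr)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticLR(np.nan, np.nan, np.nan, False, len(y))
    if not (conv_f and conv_r) or abs(full.params[1]) > 30:
        return LogisticLR(np.nan, np.nan, np.nan, False, len(y))
    lr = max(0.0, 2.0 * (full.llf - red.llf))
    return LogisticLR(float(full.params[1]), float(lr),
                      float(stats.chi2.sf(lr, 1)), True, len(y))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved.

    Missing entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValidationError("p values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _scope_subset(clinical: pd.DataFrame, scope: str):
    """Patient mask and covariate columns implied by a scope string."""
    if scope == "population":
        return np.ones(len(clinical), bool), ["hr", "her2", "arm"]
    kind, _, value = scope.partition(":")
    if kind == "arm":
        return (clinical["arm"] == value).to_numpy(), ["hr", "her2"]
    if kind == "subtype":
        return (clinical["subtype"] == value).to_numpy(), ["arm"]
    raise ValidationError(f"unknown scope {scope!r}")


def association_screen(harmonized: pd.DataFrame, clinical: pd.DataFrame,
                       scope: str = "population", bh_alpha: float = 0.05,
                       min_patients: int = 10, min_coverage: float = 0.8) -> pd.DataFrame:
    """Adjusted logistic LR screen of every analyte against pCR in one scope.

    One record per analyte with at least ``min_coverage`` unmasked values in
    the scope; the BH family is all convergent analytes in the scope.
    Scopes with fewer than ``min_patients`` patients or a single-class
    response are skipped with a warning (empty result).
    """
    clin = clinical.set_index("patient_id").loc[harmonized.index]
    mask, covariate_cols = _scope_subset(clin.reset_index(), scope)
    sub = harmonized.loc[mask]
    csub = clin.loc[mask]
    if len(sub) < min_patients or csub["pcr"].nunique() < 2:
        logger.warning("scope %s skipped (n=%d, classes=%d)", scope, len(sub),
                       csub["pcr"].nunique())
        return pd.DataFrame(columns=RECORD_COLUMNS)

    records = []
    for analyte in sub.columns:
        values = sub[analyte]
        obs = values.notna()
        if obs.mean() < min_coverage:
            continue
        y = csub.loc[obs, "pcr"].to_numpy()
        x = values[obs].to_numpy()
        if y.min() == y.max() or x.min() == x.max():
            continue
        fit = fit_logistic_lr(y, x, csub.loc[obs, covariate_cols])
        records.append({
            "analyte": analyte, "scope": scope, "n": fit.n,
            "direction": int(np.sign(fit.coef)) if fit.converged else 0,
            "lr_p": fit.lr_p,
        })
        if not fit.converged:
            logger.warning("scope %s analyte %s: flagged (non-convergence/separation)",
                           scope, analyte)
    out = pd.DataFrame(records, columns=RECORD_COLUMNS[:5])
    out["bh_p"] = bh_adjust(out["lr_p"]) if len(out) else []
    out["significant"] = out["bh_p"] < bh_alpha
    out["nominal"] = out["lr_p"] < 0.05
    return out


def differential_screen(harmonized: pd.DataFrame, group_labels,
                        covariates: pd.DataFrame = None,
                        bh_alpha: float = 0.05) -> pd.DataFrame:
    """Per-analyte Gaussian linear-model LR test of a grouping factor.

    The full model contains the group dummies (plus covariates); the reduced
    model drops the group term; ``lr = n * log(RSS_reduced / RSS_full)`` with
    chi-squared df equal to the number of group dummies.  BH within the screen.
    """
    g = pd.Series(np.asarray(group_labels, dtype=object), index=harmonized.index)
    levels = g.dropna().unique()
    if len(levels) < 2:
        raise ValidationError("differential screen requires >= 2 group levels")

    records = []
    for analyte in harmonized.columns:
        values = harmonized[analyte]
        obs = values.notna() & g.notna()
        y = values[obs].to_numpy()
        if len(y) < 3 or y.min() == y.max():
            continue
        gd = pd.get_dummies(g[obs].astype(str), drop_first=True, dtype=float).to_numpy()
        Xr = _dummy_design(covariates.loc[obs.to_numpy()] if covariates is not None else None,
                           len(y))
        Xf = np.column_stack([Xr, gd])
        rss_f = np.sum(sm.OLS(y, Xf).fit().resid ** 2)
        rss_r = np.sum(sm.OLS(y, Xr).fit().resid ** 2)
        df = gd.shape[1]
        lr = len(y) * np.log(max(rss_r, 1e-300) / max(rss_f, 1e-300))
        lr = max(0.0, lr)
        mean_by = values[obs].groupby(g[obs]).mean()
        direction = int(np.sign(mean_by.iloc[-1] - mean_by.iloc[0])) if len(mean_by) == 2 else 0
        records.append({
            "analyte": analyte, "scope": "differential", "n": len(y),
            "direction": direction, "lr_p": float(stats.chi2.sf(lr, df)),
        })
    out = pd.DataFrame(records, columns=RECORD_COLUMNS[:5])
    out["bh_p"] = bh_adjust(out["lr_p"]) if len(out) else []
    out["significant"] = out["bh_p"] < bh_alpha
    out["nominal"] = out["lr_p"] < 0.05
    return out


def count_significant(records: pd.DataFrame) -> int:
    """Number of records passing the BH threshold."""
    if len(records) == 0:
        return 0
    return int(records["significant"].sum())


def group_response_rates(labels, clinical: pd.DataFrame) -> pd.DataFrame:
    """pCR rate table per group: (group, n, n_pcr, rate)."""
    g = pd.Series(np.asarray(labels, dtype=object),
                  index=clinical["patient_id"].to_numpy())
    pcr = clinical.set_index("patient_id")["pcr"]
    rows = []
    for level in pd.unique(g.dropna()):
        members = g.index[g == level]
        if len(members) == 0:
            logger.warning("group %r is empty; excluded", level)
            continue
        sub = pcr.loc[members]
        rows.append({"group": level, "n": len(sub), "n_pcr": int(sub.sum()),
                     "rate": float(sub.mean())})
    return pd.DataFrame(rows, columns=["group", "n", "n_pcr", "rate"])
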