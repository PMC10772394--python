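"""HARPS: the HER2-activation response-predictive signature.

Two phosphoprotein cut points — EGFR Y1173 and ERBB2 Y1248 — are derived
independently by Youden-index ROC analysis against pCR in a derivation
cohort (triple-negative patients treated with neratinib), on the harmonized
(z-scored) scale.  A patient is HARPS+ iff *both* markers are at or above
their cuts (co-activation of HER2/EGFR); the cuts are then extrapolated to
the full normalized triple-negative population to tabulate response by
signature status and arm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "HarpsModel",
    "HarpsClassifier",
    "youden_cutpoint",
    "derive_harps",
    "harps_classify",
    "harps_response_table",
    "harps_by_label",
]

MARKER_EGFR = "EGFR Y1173"
MARKER_ERBB2 = "ERBB2 Y1248"


def youden_cutpoint(values, labels) -> tuple:
    """Cut maximizing the Youden index J = sensitivity + specificity - 1.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values plus the two infinities; positivity is ``value >= cut``;
    ties in J break toward the lowest cut.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    if y.min() == y.max():
        raise ValidationError("both label classes required for a ROC cut")
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    # sens(c) = P(v >= c | y=1), spec(c) = P(v < c | y=0)
    pos_sorted = np.sort(v[y == 1])
    neg_sorted = np.sort(v[y == 0])
    sens = 1.0 - np.searchsorted(pos_sorted, candidates, side="left") / n_pos
    spec = np.searchsorted(neg_sorted, candidates, side="left") / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest-cut) maximum
    return float(candidates[best]), float(j[best])


@dataclasses.dataclass
class HarpsModel:
    """Derived two-marker cut points plus derivation-cohort metadata."""

    cut_egfr_y1173: float
    cut_erbb2_y1248: float
    j_egfr: float
    j_erbb2: float
    derivation: dict
    rule: str = "and"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_json(cls, path) -> "HarpsModel":
        return cls(**json.loads(Path(path).read_text()))


class HarpsClassifier(ClassifierMixin, BaseEstimator):
    """Two-marker dichotomous response classifier (Youden cuts, AND rule).

    ``fit(X, y)`` derives independent Youden cut points for the two marker
    columns of ``X`` against the binary response ``y``; ``predict(X)``
    returns 1 (HARPS+) iff both markers are at or above their cuts, and NaN
    where a marker is masked.

    Attributes
    ----------
    cuts_ : dict marker -> cut point (harmonized units)
    j_ : dict marker -> Youden index at the cut
    model_ : HarpsModel
    """

    def __init__(self, marker_egfr: str = MARKER_EGFR,
                 marker_erbb2: str = MARKER_ERBB2, rule: str = "and"):
        self.marker_egfr = marker_egfr
        self.marker_erbb2 = marker_erbb2
        self.rule = rule

    def _columns(self, X: pd.DataFrame):
        for m in (self.marker_egfr, self.marker_erbb2):
            if m not in X.columns:
                raise ValidationError(f"marker column {m!r} missing")
        return X[[self.marker_egfr, self.marker_erbb2]]

    def fit(self, X: pd.DataFrame, y, derivation: dict = None) -> "HarpsClassifier":
        if self.rule != "and":
            raise ValidationError(f"unknown combination rule {self.rule!r}")
        M = self._columns(X)
        y = np.asarray(y, dtype=int)
        if len(y) < 10:
            raise ValidationError(f"derivation cohort too small (n={len(y)})")
        if M.isna().any().any():
            raise ValidationError("derivation cohort has masked marker values")
        self.cuts_, self.j_ = {}, {}
        for m in M.columns:
            cut, j = youden_cutpoint(M[m].to_numpy(), y)
            self.cuts_[m], self.j_[m] = cut, j
        self.classes_ = np.array([0, 1])
        meta = dict(derivation or {})
        meta.update({"n": int(len(y)), "n_pcr": int(y.sum())})
        self.model_ = HarpsModel(
            cut_egfr_y1173=self.cuts_[self.marker_egfr],
            cut_erbb2_y1248=self.cuts_[self.marker_erbb2],
            j_egfr=self.j_[self.marker_egfr],
            j_erbb2=self.j_[self.marker_erbb2],
            derivation=meta, rule=self.rule,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """1 = HARPS+, 0 = HARPS-, NaN where a marker is masked."""
        if not hasattr(self, "cuts_"):
            raise ValidationError("HarpsClassifier is not fitted")
        M = self._columns(X)
        pos = ((M[self.marker_egfr] >= self.cuts_[self.marker_egfr]) &
               (M[self.marker_erbb2] >= self.cuts_[self.marker_erbb2]))
        out = pos.astype(float).to_numpy()
        masked = M.isna().any(axis=1).to_numpy()
        if masked.any():
            logger.warning("%d patient(s) with masked marker(s): status missing",
                           int(masked.sum()))
            out[masked] = np.nan
        return out


def derive_harps(harmonized: pd.DataFrame, clinical: pd.DataFrame,
                 derivation_filter: dict = None) -> HarpsModel:
    """Derive HARPS cut points in a filtered derivation cohort.

    Default filter: triple-negative patients in the neratinib arm; both pCR
    classes must be present.
    """
    derivation_filter = derivation_filter or {"subtype": "TN", "arm": "N"}
    clin = clinical.set_index("patient_id").loc[harmonized.index]
    mask = np.ones(len(clin), dtype=bool)
    for col, val in derivation_filter.items():
        mask &= (clin[col] == val).to_numpy()
    sub = harmonized.loc[mask]
    y = clin.loc[mask, "pcr"].to_numpy()
    est = HarpsClassifier().fit(sub, y, derivation=dict(derivation_filter))
    return est.model_


def harps_classify(matrix: pd.DataFrame, model: HarpsModel) -> pd.Series:
    """Per-patient HARPS status labels from a derived model."""
    est = HarpsClassifier(rule=model.rule)
    est.cuts_ = {MARKER_EGFR: model.cut_egfr_y1173,
                 MARKER_ERBB2: model.cut_erbb2_y1248}
    est.j_ = {MARKER_EGFR: model.j_egfr, MARKER_ERBB2: model.j_erbb2}
    pred = est.predict(matrix)
    status = pd.Series(
        np.where(np.isnan(pred), None,
                 np.where(pred == 1, "HARPS+", "HARPS-")),
        index=matrix.index, name="harps", dtype=object)
    return status


def harps_response_table(status: pd.Series, clinical: pd.DataFrame,
                         population_filter: dict = None) -> pd.DataFrame:
    """pCR rates by arm x HARPS status within a population (default: TN)."""
    population_filter = population_filter or {"subtype": "TN"}
    clin = clinical.set_index("patient_id")
    mask = np.ones(len(clin), dtype=bool)
    for col, val in population_filter.items():
        mask &= (clin[col] == val).to_numpy()
    clin = clin.loc[mask]
    st = status.reindex(clin.index)
    rows = []
    for arm in pd.unique(clin["arm"]):
        for label in ("HARPS+", "HARPS-"):
            members = clin.index[(clin["arm"] == arm) & (st == label).to_numpy()]
            if len(members) == 0:
                continue
            sub = clin.loc[members, "pcr"]
            rows.append({"arm": arm, "harps": label, "n": len(sub),
                         "n_pcr": int(sub.sum()), "rate": float(sub.mean())})
    return pd.DataFrame(rows, columns=["arm", "harps", "n", "n_pcr", "rate"])


def harps_by_label(status: pd.Series, labels) -> pd.DataFrame:
    """Cross-tabulation of HARPS status against an external label set."""
    lab = pd.Series(np.asarray(labels, dtype=object), index=status.index)
    return pd.crosstab(status.fillna("missing"), lab.fillna("missing"),
                       dropna=False)
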