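"""Array batch harmonization by balanced-subsampling standardization.

Each array is standardized before combining: (1) draw B stratified
subsamples of the array's patients, maintaining a fixed receptor-subtype
balance; (2) compute the mean-of-subsample-means and mean-of-subsample-SDs
per endpoint; (3) z-score each endpoint with that (mu, sigma).  Because the
subsamples share one subtype balance across arrays, arrays with different
subtype mixes are standardized against a common reference population, which
removes per-(array, analyte) additive and multiplicative batch effects up to
Monte-Carlo error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .core import SUBTYPES, PipelineConfig, ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "HarmonizationError",
    "HarmonizationModel",
    "BatchHarmonizer",
    "stratified_subsample",
    "resample_moments",
    "zscore_array",
    "combine_arrays",
    "harmonize",
]


class HarmonizationError(ValidationError):
    """Harmonization preconditions violated (e.g., an empty required stratum)."""


@dataclasses.dataclass
class HarmonizationModel:
    """Per-(array, analyte) standardization moments plus provenance.

    ``mu``/``sigma`` are arrays x analytes DataFrames; NaN marks analytes
    absent on an array.
    """

    mu: pd.DataFrame
    sigma: pd.DataFrame
    metadata: dict

    def to_json(self, path) -> None:
        payload = {
            "mu": self.mu.to_dict(orient="split"),
            "sigma": self.sigma.to_dict(orient="split"),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "HarmonizationModel":
        raw = json.loads(Path(path).read_text())

        def frame(key):
            d = raw[key]
            return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

        return cls(mu=frame("mu"), sigma=frame("sigma"), metadata=raw["metadata"])


def _largest_remainder(m: int, proportions) -> np.ndarray:
    quotas = m * np.asarray(proportions, dtype=float)
    base = np.floor(quotas + 1e-9).astype(int)
    short = m - base.sum()
    if short > 0:
        remainders = quotas - base
        # break remainder ties by stratum order
        order = np.lexsort((np.arange(len(quotas)), -remainders))
        base[order[:short]] += 1
    return base


def stratified_subsample(clinical_subset: pd.DataFrame, proportions, m: int,
                         rng) -> np.ndarray:
    """Positional indices of a subtype-balanced subsample of one array.

    Stratum sizes follow largest-remainder rounding of ``m * proportions``
    (capped at the stratum population); sampling is without replacement
    within strata.
    """
    subtype = clinical_subset["subtype"].to_numpy()
    targets = _largest_remainder(m, proportions)
    chosen = []
    for s, want in zip(SUBTYPES, targets):
        members = np.flatnonzero(subtype == s)
        if want > 0 and len(members) == 0:
            raise HarmonizationError(f"subtype {s!r} has no patients in this array")
        take = min(want, len(members))
        if take:
            chosen.append(rng.choice(members, size=take, replace=False))
    if not chosen:
        raise HarmonizationError("empty subsample (all stratum targets are 0)")
    return np.concatenate(chosen)


def resample_moments(matrix: pd.DataFrame, clinical: pd.DataFrame,
                     config: PipelineConfig, rng=None) -> tuple:
    """Balanced-resampling (mu, sigma) per analyte for one array.

    Returns two pandas Series over the matrix's analytes:
    mean-of-subsample-means and mean-of-subsample-SDs (n-1 denominator),
    the SD floored at ``config.sd_floor`` with a logged warning.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clin = clinical.set_index("patient_id").loc[matrix.index]
    n = len(matrix)
    m = max(1, int(round(config.subsample_fraction * n)))
    X = matrix.to_numpy(dtype=float)
    has_nan = np.isnan(X).any()

    mean_acc = np.zeros(X.shape[1])
    sd_acc = np.zeros(X.shape[1])
    B = config.n_subsamples
    for _ in range(B):
        idx = stratified_subsample(clin, config.subtype_proportions, m, rng)
        sub = X[idx]
        if has_nan:
            with np.errstate(invalid="ignore"):
                mean_acc += np.nanmean(sub, axis=0)
                sd_acc += np.nanstd(sub, axis=0, ddof=1)
        else:
            mean_acc += sub.mean(axis=0)
            sd_acc += sub.std(axis=0, ddof=1)
    mu = pd.Series(mean_acc / B, index=matrix.columns)
    sigma = pd.Series(sd_acc / B, index=matrix.columns)
    degenerate = sigma < config.sd_floor
    if degenerate.any():
        logger.warning("sd floor applied to degenerate analyte(s): %s",
                       list(sigma.index[degenerate]))
        sigma[degenerate] = config.sd_floor
    return mu, sigma


def zscore_array(matrix: pd.DataFrame, mu: pd.Series, sigma: pd.Series) -> pd.DataFrame:
    """Z-score one array's endpoints with the resampled moments; masks propagate."""
    missing = [c for c in matrix.columns if c not in mu.index or pd.isna(mu[c])]
    if missing:
        raise HarmonizationError(f"no harmonization moments for analyte(s): {missing[:5]}")
    return (matrix - mu[matrix.columns]) / sigma[matrix.columns]


def combine_arrays(matrices) -> pd.DataFrame:
    """Row-concatenate per-array matrices; the analyte set is the union,
    with masks where an analyte is absent from an array."""
    matrices = list(matrices)
    if len(matrices) == 1:
        return matrices[0].copy()
    all_patients = pd.concat([m.index.to_series() for m in matrices])
    if all_patients.duplicated().any():
        dup = all_patients[all_patients.duplicated()].iloc[0]
        raise ValidationError(f"patient {dup!r} appears on multiple arrays")
    combined = pd.concat(matrices, axis=0, join="outer")
    # keep first-seen analyte order
    order = []
    for m in matrices:
        order.extend(c for c in m.columns if c not in order)
    return combined[order]


class BatchHarmonizer(TransformerMixin, BaseEstimator):
    """Balanced-subsampling batch standardizer for multi-array RPPA data.

    Parameters
    ----------
    n_subsamples : int
        Number of stratified subsamples per array (B).
    subsample_fraction : float
        Fraction of array patients per subsample, drawn without replacement.
    subtype_proportions : tuple of 4 floats
        Target receptor-subtype balance of every subsample.
    sd_floor : float
        Lower guard for the resampled SD of degenerate analytes.
    seed : int
        Seed of the per-array sampling streams.

    Attributes
    ----------
    model_ : HarmonizationModel
        Fitted per-(array, analyte) moments.
    array_of_ : pandas.Series
        patient_id -> array_id mapping seen at fit time.
    """

    def __init__(self, n_subsamples: int = 5000, subsample_fraction: float = 0.8,
                 subtype_proportions: tuple = (0.384, 0.368, 0.158, 0.09),
                 sd_floor: float = 1e-8, seed: int = 0):
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.subtype_proportions = subtype_proportions
        self.sd_floor = sd_floor
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            n_subsamples=self.n_subsamples,
            subsample_fraction=self.subsample_fraction,
            subtype_proportions=tuple(self.subtype_proportions),
            sd_floor=self.sd_floor, seed=self.seed,
        ).validate()

    def fit(self, X: pd.DataFrame, clinical: pd.DataFrame) -> "BatchHarmonizer":
        """Learn (mu, sigma) per (array, analyte) from a combined endpoint matrix.

        ``X`` is patients x analytes (NaN = masked); ``clinical`` supplies
        ``array_id`` and ``subtype`` per patient.
        """
        config = self._config()
        clin = clinical.set_index("patient_id")
        missing = X.index.difference(clin.index)
        if len(missing):
            raise ValidationError(f"patients missing from clinical table: {list(missing)[:5]}")
        arrays = sorted(clin.loc[X.index, "array_id"].unique())
        streams = np.random.SeedSequence(self.seed).spawn(len(arrays))
        mu_rows, sigma_rows = {}, {}
        for arr, ss in zip(arrays, streams):
            rows = clin.loc[X.index, "array_id"] == arr
            sub = X.loc[rows.to_numpy()]
            present = sub.columns[sub.notna().any(axis=0)]
            mu, sigma = resample_moments(
                sub[present], clinical[clinical["patient_id"].isin(sub.index)],
                config, rng=np.random.default_rng(ss))
            mu_rows[arr] = mu
            sigma_rows[arr] = sigma
        self.model_ = HarmonizationModel(
            mu=pd.DataFrame(mu_rows).T.reindex(columns=X.columns),
            sigma=pd.DataFrame(sigma_rows).T.reindex(columns=X.columns),
            metadata={
                "n_subsamples": self.n_subsamples,
                "subsample_fraction": self.subsample_fraction,
                "subtype_proportions": list(self.subtype_proportions),
                "seed": self.seed,
                "arrays": arrays,
            },
        )
        self.array_of_ = clin.loc[X.index, "array_id"]
        return self

    def transform(self, X: pd.DataFrame, clinical: pd.DataFrame = None) -> pd.DataFrame:
        """Z-score per array with the fitted moments (masks propagate)."""
        if not hasattr(self, "model_"):
            raise ValidationError("BatchHarmonizer is not fitted")
        if clinical is not None:
            array_of = clinical.set_index("patient_id").loc[X.index, "array_id"]
        else:
            array_of = self.array_of_.reindex(X.index)
            if array_of.isna().any():
                raise ValidationError("unseen patients; pass their clinical table")
        out = []
        for arr in sorted(array_of.unique()):
            sub = X.loc[(array_of == arr).to_numpy()]
            present = [c for c in sub.columns
                       if arr in self.model_.mu.index and pd.notna(self.model_.mu.loc[arr, c])]
            z = zscore_array(sub[present], self.model_.mu.loc[arr],
                             self.model_.sigma.loc[arr])
            out.append(z.reindex(columns=X.columns))
        combined = pd.concat(out, axis=0).loc[X.index]
        return combined

    def fit_transform(self, X: pd.DataFrame, clinical: pd.DataFrame = None,
                      **fit_params) -> pd.DataFrame:
        return self.fit(X, clinical).transform(X)


def harmonize(matrices: dict, clinical: pd.DataFrame,
              config: PipelineConfig = None):
    """Standardize each array and combine: ``(harmonized matrix, model)``.

    ``matrices`` maps array_id -> per-array endpoint matrix, as produced by
    :func:`rppasig.quantify.quantify`.
    """
    config = (config or PipelineConfig()).validate()
    combined = combine_arrays([matrices[a] for a in sorted(matrices)])
    est = BatchHarmonizer(
        n_subsamples=config.n_subsamples,
        subsample_fraction=config.subsample_fraction,
        subtype_proportions=tuple(config.subtype_proportions),
        sd_floor=config.sd_floor, seed=config.seed,
    )
    z = est.fit_transform(combined, clinical)
    return z, est.model_
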