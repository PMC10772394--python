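"""Shared domain types, validation, and file I/O for the RPPA analysis pipeline.

The pipeline's tabular currency is plain pandas objects with fixed schemas:

* **clinical table** -- one row per patient: hormone-receptor (``hr``) and HER2
  status (``pos``/``neg``), the derived receptor ``subtype``, treatment ``arm``,
  binary pathologic complete response (``pcr``), optional distant
  recurrence-free survival columns (``drfs_time`` in years, ``drfs_event``),
  the RPPA ``array_id`` batch label and optional external labels (``mp``,
  ``rps5``).
* **spot table** -- long-format triplicate spot intensities per
  (patient, array, analyte), with spot types ``primary``,
  ``negative_control`` and ``total_protein``.
* **endpoint matrix** -- patients x analytes of quantified (and later
  harmonized) values; ``NaN`` marks cells masked because an analyte was not
  measured on a patient's array.  Masked cells are never imputed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rppasig")

__all__ = [
    "SUBTYPES",
    "DEFAULT_ARMS",
    "PipelineConfig",
    "SchemaError",
    "ValidationError",
    "derive_subtype",
    "normalize_analyte_name",
    "read_clinical",
    "write_clinical",
    "read_spots",
    "write_spots",
    "read_matrix",
    "write_matrix",
]

#: Receptor subtypes in the order used for stratification proportions.
SUBTYPES = ("HR+HER2-", "TN", "HR+HER2+", "HR-HER2+")

#: Treatment arms with their HER2 eligibility: experimental HER2-targeted
#: arms take HER2+ patients only, PARP/immune arms take HER2- only, the rest
#: take both.
DEFAULT_ARMS = {
    "Ctr": "both",
    "N": "both",
    "VC": "her2_neg_only",
    "AMG386": "both",
    "MK2206": "both",
    "P": "her2_pos_only",
    "TDM1/P": "her2_pos_only",
    "PD1-inh": "her2_neg_only",
}

SPOT_TYPES = ("primary", "negative_control", "total_protein")

CLINICAL_COLUMNS = (
    "patient_id", "hr", "her2", "subtype", "arm", "pcr",
    "drfs_time", "drfs_event", "array_id", "mp", "rps5",
)
SPOT_COLUMNS = (
    "patient_id", "array_id", "analyte", "spot_type", "replicate_index",
    "intensity",
)

# Dash glyphs that appear interchangeably in phospho-site names across
# exports (unicode minus, en dash, em dash) -> ASCII hyphen.
_DASH_TRANSLATION = str.maketrans({"−": "-", "–": "-", "—": "-"})


class SchemaError(ValueError):
    """A required column is missing or has the wrong name."""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


def normalize_analyte_name(name: str) -> str:
    """Normalize dash glyphs in an analyte name to the ASCII hyphen."""
    return str(name).translate(_DASH_TRANSLATION).strip()


def derive_subtype(hr: str, her2: str) -> str:
    """Map the (HR, HER2) 2x2 onto the four receptor subtypes (TN = HR-HER2-)."""
    key = (hr, her2)
    table = {
        ("pos", "neg"): "HR+HER2-",
        ("neg", "neg"): "TN",
        ("pos", "pos"): "HR+HER2+",
        ("neg", "pos"): "HR-HER2+",
    }
    if key not in table:
        raise ValidationError(f"hr/her2 must be 'pos' or 'neg', got {key!r}")
    return table[key]


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters shared across pipeline stages.

    Parameters
    ----------
    n_subsamples:
        Number of stratified subsamples drawn per array during batch
        harmonization (B).
    subsample_fraction:
        Fraction of an array's patients drawn (without replacement) per
        subsample.
    subtype_proportions:
        Target receptor-subtype balance of each subsample, in the order of
        :data:`SUBTYPES`.
    cut_height:
        Dendrogram cut height on the ``1 - r`` Pearson-distance scale.
    bh_alpha:
        Benjamini-Hochberg significance threshold.
    sd_floor:
        Lower guard on resampled standard deviations of degenerate analytes.
    """

    n_subsamples: int = 5000
    subsample_fraction: float = 0.8
    subtype_proportions: tuple = (0.384, 0.368, 0.158, 0.09)
    cut_height: float = 1.54
    bh_alpha: float = 0.05
    seed: int = 0
    sd_floor: float = 1e-8

    def validate(self) -> "PipelineConfig":
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "subtype_proportions must be 4 nonnegative values summing to 1"
            )
        if self.n_subsamples < 1:
            raise ValidationError("n_subsamples must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValidationError("subsample_fraction must be in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "subtype_proportions" in raw:
            raw["subtype_proportions"] = tuple(raw["subtype_proportions"])
        return cls(**raw).validate()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["subtype_proportions"] = list(d["subtype_proportions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {missing}")


def validate_clinical(df: pd.DataFrame, arms=None) -> pd.DataFrame:
    """Validate and canonicalize a clinical table.

    Derives ``subtype`` from (hr, her2), enforces patient uniqueness, the
    paired presence of the DRFS columns, and membership of ``arm`` in the
    declared arm list.
    """
    arms = DEFAULT_ARMS if arms is None else arms
    df = df.copy()
    _require_columns(df, ["patient_id", "hr", "her2", "arm", "pcr", "array_id"],
                     "clinical table")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")
    has_time = "drfs_time" in df.columns and df["drfs_time"].notna().any()
    has_event = "drfs_event" in df.columns and df["drfs_event"].notna().any()
    if has_time != has_event:
        raise ValidationError("drfs_time and drfs_event must be present together")
    if has_time:
        paired = df["drfs_time"].notna() == df["drfs_event"].notna()
        if not paired.all():
            raise ValidationError("drfs_time/drfs_event must be jointly present per patient")
        if (df["drfs_time"].dropna() <= 0).any():
            raise ValidationError("drfs_time must be > 0")
    bad_arm = sorted(set(df["arm"].astype(str)) - set(arms))
    if bad_arm:
        raise ValidationError(f"unknown treatment arm(s): {bad_arm}")
    if not df["pcr"].isin([0, 1]).all():
        raise ValidationError("pcr must be binary 0/1")
    df["subtype"] = [derive_subtype(h, e) for h, e in zip(df["hr"], df["her2"])]
    order = [c for c in CLINICAL_COLUMNS if c in df.columns]
    return df[order + [c for c in df.columns if c not in order]]


def read_clinical(path, schema=None, arms=None) -> pd.DataFrame:
    """Read a clinical CSV/TSV and return a validated table.

    ``schema`` maps canonical column names to the file's column names, to
    absorb external export vocabularies (e.g. ``{"pcr": "pCR"}``).
    """
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        missing = [v for v in schema.values() if v not in df.columns]
        if missing:
            raise SchemaError(f"clinical file is missing mapped column(s): {missing}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_clinical(df, arms=arms)


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_spots(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format spot table (triplicate structure, finiteness)."""
    _require_columns(df, SPOT_COLUMNS, "spot table")
    df = df.copy()
    df["analyte"] = df["analyte"].map(normalize_analyte_name)
    bad_type = sorted(set(df["spot_type"]) - set(SPOT_TYPES))
    if bad_type:
        raise ValidationError(f"unknown spot_type value(s): {bad_type}")
    inten = df["intensity"].to_numpy(dtype=float)
    if not np.isfinite(inten).all():
        raise ValidationError("spot intensities must be finite")
    if (inten < 0).any():
        raise ValidationError("spot intensities must be nonnegative")
    primary = df[df["spot_type"] == "primary"]
    counts = primary.groupby(["patient_id", "array_id", "analyte"]).size()
    bad = counts[counts != 3]
    if len(bad):
        offenders = [(p, a) for (p, _arr, a) in bad.index[:5]]
        raise ValidationError(
            f"expected exactly 3 primary replicates; offending (patient, analyte): {offenders}"
        )
    tp = df[df["spot_type"] == "total_protein"]
    tp_counts = tp.groupby(["patient_id", "array_id"]).size()
    patients = set(map(tuple, primary[["patient_id", "array_id"]].drop_duplicates().to_numpy()))
    missing_tp = sorted(patients - set(tp_counts.index))
    if missing_tp:
        raise ValidationError(f"total_protein spots missing for: {missing_tp[:5]}")
    return df


def read_spots(path) -> pd.DataFrame:
    """Read a long-format spot TSV and validate its triplicate structure."""
    return validate_spots(pd.read_csv(path, sep="\t"))


def write_spots(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a wide patient x analyte matrix TSV ("NA" = masked cell)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     index_col="patient_id")
    df.index = df.index.astype(str)
    df.columns = [normalize_analyte_name(c) for c in df.columns]
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a patient x analyte matrix losslessly (full float precision)."""
    out = matrix.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format=None)


def config_hash(config) -> str:
    """Stable short hash of a dataclass config, for run manifests."""
    import hashlib
    import json

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
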