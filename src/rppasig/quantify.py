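"""Spot-level intensities -> per-array patient x analyte endpoint values.

For each sample/endpoint the final signal is computed by (1) subtracting the
negative-control spot intensity from the primary-antibody spot intensity,
pairing spots by replicate index, (2) averaging the three net replicate
intensities, and (3) dividing by the sample's total-protein (Sypro) value,
itself the average of the three total-protein replicate spots.  Negative net
signals are retained: downstream standardization is location-scale based and
flooring would bias low-expressing samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ValidationError

logger = logging.getLogger("rppasig")

__all__ = [
    "DegenerateSampleError",
    "total_protein",
    "endpoint_signal",
    "quantify_array",
    "quantify",
]


class DegenerateSampleError(ValidationError):
    """A sample's total-protein value is non-positive."""


def total_protein(sypro_replicates) -> float:
    """Average the three replicate Sypro (total protein) spot intensities."""
    reps = np.asarray(sypro_replicates, dtype=float)
    if reps.shape != (3,) or not np.isfinite(reps).all():
        raise ValidationError("total_protein expects exactly 3 finite replicates")
    return float(reps.mean())


def endpoint_signal(primary, negative, total: float) -> float:
    """Net, averaged, total-protein-normalized signal for one endpoint.

    ``mean_i(primary_i - negative_i) / total`` with replicate-index pairing.
    """
    p = np.asarray(primary, dtype=float)
    n = np.asarray(negative, dtype=float)
    if p.shape != (3,) or n.shape != (3,):
        raise ValidationError("endpoint_signal expects 3 primary and 3 negative replicates")
    if not (total > 0):
        raise DegenerateSampleError(f"total protein must be > 0, got {total}")
    return float((p - n).mean() / total)


def _replicate_pivot(df: pd.DataFrame) -> pd.DataFrame:
    """(patient, analyte) x replicate_index intensity table."""
    return df.pivot_table(index=["patient_id", "analyte"],
                          columns="replicate_index", values="intensity",
                          aggfunc="first")


def quantify_array(spots: pd.DataFrame, array_id) -> pd.DataFrame:
    """Quantify one array's spots into a patient x analyte endpoint matrix.

    Analytes absent for a patient are masked (NaN); inconsistent analyte
    sets across patients on the array are reported as a warning.  Negative
    controls are paired per (patient, analyte, replicate); if an analyte has
    no dedicated negative-control spots, the patient's negative-control
    replicates averaged over analytes are used.
    """
    sub = spots[spots["array_id"] == array_id]
    if sub.empty:
        raise ValidationError(f"no spots for array {array_id!r}")
    primary = _replicate_pivot(sub[sub["spot_type"] == "primary"])
    negative = _replicate_pivot(sub[sub["spot_type"] == "negative_control"])

    neg_aligned = negative.reindex(primary.index)
    if neg_aligned.isna().any().any():
        # per-patient fallback background, by replicate index
        fallback = (sub[sub["spot_type"] == "negative_control"]
                    .pivot_table(index="patient_id", columns="replicate_index",
                                 values="intensity", aggfunc="mean"))
        patients = primary.index.get_level_values("patient_id")
        fb = fallback.reindex(patients)
        fb.index = primary.index
        neg_aligned = neg_aligned.fillna(fb)
    if neg_aligned.isna().any().any():
        raise ValidationError(f"negative-control spots missing on array {array_id!r}")

    net = (primary.to_numpy() - neg_aligned.to_numpy()).mean(axis=1)
    net = pd.Series(net, index=primary.index)

    tp = (sub[sub["spot_type"] == "total_protein"]
          .groupby("patient_id")["intensity"].mean())
    bad_tp = tp[~(tp > 0)]
    if len(bad_tp):
        raise DegenerateSampleError(
            f"non-positive total protein for patient(s) {list(bad_tp.index)[:5]} "
            f"on array {array_id!r}")

    patients = net.index.get_level_values("patient_id")
    values = net / tp.reindex(patients).to_numpy()
    matrix = values.unstack("analyte")
    matrix.index.name = "patient_id"

    n_missing = int(matrix.isna().to_numpy().sum())
    if n_missing:
        logger.warning("array %s: %d patient x analyte cells masked "
                       "(inconsistent analyte sets)", array_id, n_missing)
    return matrix


def quantify(spots: pd.DataFrame) -> dict:
    """Quantify every array in a spot table: ``{array_id: endpoint matrix}``."""
    return {a: quantify_array(spots, a)
            for a in sorted(spots["array_id"].unique())}
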