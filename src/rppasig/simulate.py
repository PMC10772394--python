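"""Synthetic cohort and spot-level RPPA data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage has a parameter-recovery test surface:

* a neoadjuvant cohort with the trial's receptor-subtype balance, treatment
  arms gated on HER2 eligibility, and three sequential array batches;
* a latent standardized signaling value ``z`` per patient x analyte, with
  pathway-block correlation and subtype-specific mean offsets;
* pathologic complete response drawn from a logistic model with planted
  per-analyte coefficients on the pCR logit;
* exponential distant-recurrence-free survival whose hazard depends on pCR,
  administratively censored at a follow-up horizon;
* triplicate primary / negative-control / total-protein spot intensities with
  multiplicative replicate noise and per-(array, analyte) additive and
  multiplicative batch effects on the intensity scale.

Ground truth (latent z, batch effects, planted coefficients, true pCR
probabilities and hazards) is returned as a :class:`SimTruth` for recovery
checks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import DEFAULT_ARMS, SUBTYPES, ValidationError

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "default_analyte_names",
    "simulate_cohort",
    "simulate_spots",
    "simulate_harps_cohort",
]

#: The two phosphoproteins used by the HARPS signature; kept as the first two
#: analyte names so the end-to-end pipeline exercises signature derivation.
HARPS_MARKERS = ("EGFR Y1173", "ERBB2 Y1248")

#: Static allocation weights loosely following the trial's arm sizes
#: (the adaptive randomization engine is out of scope; weights are fixed).
DEFAULT_ARM_WEIGHTS = {
    "Ctr": 0.24, "N": 0.13, "VC": 0.10, "AMG386": 0.13,
    "MK2206": 0.12, "P": 0.06, "TDM1/P": 0.07, "PD1-inh": 0.15,
}

#: Baseline pCR rates by receptor subtype (logit scale is derived from these).
DEFAULT_PCR_RATES = {
    "HR+HER2-": 0.18, "TN": 0.40, "HR+HER2+": 0.38, "HR-HER2+": 0.62,
}


def default_analyte_names(n: int) -> list:
    """Analyte name list: the two HARPS phospho-markers, then generic ids."""
    names = list(HARPS_MARKERS)[: min(n, 2)]
    names += [f"P{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def _auto_effect_table(analytes, block_size: int) -> dict:
    """Up to five planted analytes, |beta| = 0.6 on the pCR logit.

    The two HARPS markers (pathway block 0) carry positive effects so the
    downstream signature derivation has signal to find; the remaining
    effects sit at the starts of *distinct later blocks* so that within-block
    correlation cannot cancel a planted marginal effect against an
    oppositely-signed block-mate.
    """
    n = len(analytes)
    table = {a: 0.6 for a in analytes[: min(2, n)]}
    bs = max(block_size, 1)
    for pos, b in zip((bs, 2 * bs, 3 * bs), (-0.6, 0.6, -0.6)):
        if pos < n and analytes[pos] not in table:
            table[analytes[pos]] = b
    return table


def _default_subtype_shifts():
    # HER2+ tumors express markedly higher HER-family phosphoproteins.
    return {
        "HR+HER2+": {"EGFR Y1173": 1.0, "ERBB2 Y1248": 1.2},
        "HR-HER2+": {"EGFR Y1173": 1.0, "ERBB2 Y1248": 1.2},
    }


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort and spot generator.

    Scales and sizes default to the trial-like conditions: 736 patients,
    139 analytes on 3 sequential array batches, subtype balance
    0.384/0.368/0.158/0.09, additive batch-offset SD 0.5 and multiplicative
    batch-scale SD 0.2 (log scale) per (array, analyte), 3% replicate CV,
    pCR hazard ratio 0.25 on an exponential DRFS baseline of 0.06/year
    censored at 5 years.
    """

    n_patients: int = 736
    subtype_proportions: tuple = (0.384, 0.368, 0.158, 0.09)
    arms: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_ARMS))
    arm_weights: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_ARM_WEIGHTS))
    n_analytes: int = 139
    n_arrays: int = 3
    batch_shift_sd: float = 0.5
    batch_shift_mean: float = 1.0
    batch_scale_sd: float = 0.2
    block_size: int = 10
    block_rho: float = 0.5
    effect_table: dict = None  # None -> _auto_effect_table over the analyte panel
    subtype_mean_shifts: dict = dataclasses.field(default_factory=_default_subtype_shifts)
    pcr_rates: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_PCR_RATES))
    replicate_cv: float = 0.03
    neg_control_level: float = 150.0
    intensity_scale: float = 500.0
    intensity_log_sd: float = 0.35
    total_protein_base: float = 1000.0
    total_protein_lognormal_sd: float = 0.3
    baseline_hazard: float = 0.06
    pcr_hazard_ratio: float = 0.25
    censor_horizon: float = 5.0
    seed: int = 0

    def analyte_names(self) -> list:
        return default_analyte_names(self.n_analytes)

    def resolved_effect_table(self) -> dict:
        if self.effect_table is None:
            return _auto_effect_table(self.analyte_names(), self.block_size)
        return dict(self.effect_table)

    def validate(self) -> "SimulationConfig":
        p = np.asarray(self.subtype_proportions, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("subtype_proportions must be 4 values summing to 1")
        for name, val in [("batch_shift_sd", self.batch_shift_sd),
                          ("batch_scale_sd", self.batch_scale_sd),
                          ("replicate_cv", self.replicate_cv),
                          ("total_protein_lognormal_sd", self.total_protein_lognormal_sd)]:
            if val < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValidationError("block_rho must be in [0, 1)")
        unknown = set(self.resolved_effect_table()) - set(self.analyte_names())
        if unknown:
            raise ValidationError(f"effect_table names unknown analytes: {sorted(unknown)}")
        eligible_any = {"pos": False, "neg": False}
        for arm, rule in self.arms.items():
            if self.arm_weights.get(arm, 0) <= 0:
                continue
            if rule in ("both", "her2_pos_only"):
                eligible_any["pos"] = True
            if rule in ("both", "her2_neg_only"):
                eligible_any["neg"] = True
        if not all(eligible_any.values()):
            raise ValidationError("some HER2 status has no eligible arm with positive weight")
        return self


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    z: pd.DataFrame                 # latent standardized values, patients x analytes
    batch_shift: pd.DataFrame       # arrays x analytes additive offsets
    batch_scale: pd.DataFrame       # arrays x analytes multiplicative factors
    beta: pd.Series                 # planted pCR-logit coefficients per analyte
    pcr_prob: pd.Series             # true pCR probability per patient
    hazard: pd.Series               # true DRFS hazard per patient
    total_protein_factor: pd.Series  # per-patient loading factor

    def to_json(self, path) -> None:
        payload = {
            "z": self.z.to_dict(orient="split"),
            "batch_shift": self.batch_shift.to_dict(orient="split"),
            "batch_scale": self.batch_scale.to_dict(orient="split"),
            "beta": self.beta.to_dict(),
            "pcr_prob": self.pcr_prob.to_dict(),
            "hazard": self.hazard.to_dict(),
            "total_protein_factor": self.total_protein_factor.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        raw = json.loads(Path(path).read_text())

        def frame(key):
            d = raw[key]
            return pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])

        return cls(
            z=frame("z"), batch_shift=frame("batch_shift"),
            batch_scale=frame("batch_scale"),
            beta=pd.Series(raw["beta"]), pcr_prob=pd.Series(raw["pcr_prob"]),
            hazard=pd.Series(raw["hazard"]),
            total_protein_factor=pd.Series(raw["total_protein_factor"]),
        )


def _stage_rngs(seed: int):
    """Two deterministic sub-streams (cohort, spots) from one run seed."""
    children = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def simulate_cohort(config: SimulationConfig, rng=None):
    """Draw a clinical cohort plus its latent signaling truth.

    Subtypes are multinomial at the configured proportions; arms are drawn
    from the allocation weights restricted to each patient's HER2-eligible
    set; arrays are contiguous thirds in accrual order.  pCR follows
    ``Bernoulli(expit(baseline(subtype) + sum_k beta_k z_k))`` and DRFS is
    exponential with hazard ``lambda0 * HR_pcr^pcr`` censored at the horizon.

    Returns
    -------
    (clinical, truth) : (pandas.DataFrame, SimTruth)
    """
    config.validate()
    if rng is None:
        rng, _ = _stage_rngs(config.seed)
    n = config.n_patients
    analytes = config.analyte_names()
    patients = [f"PT{i:04d}" for i in range(1, n + 1)]

    props = np.asarray(config.subtype_proportions, dtype=float)
    subtype = rng.choice(len(SUBTYPES), size=n, p=props)
    subtype_labels = np.asarray(SUBTYPES)[subtype]
    her2 = np.where(np.isin(subtype_labels, ["HR+HER2+", "HR-HER2+"]), "pos", "neg")
    hr = np.where(np.isin(subtype_labels, ["HR+HER2-", "HR+HER2+"]), "pos", "neg")

    arm = np.empty(n, dtype=object)
    arm_names = list(config.arms)
    weights = np.array([config.arm_weights.get(a, 0.0) for a in arm_names], float)
    for status in ("pos", "neg"):
        ok = np.array([
            config.arms[a] in ("both", f"her2_{status}_only") for a in arm_names
        ])
        mask = her2 == status
        w = weights * ok
        if w.sum() <= 0:
            raise ValidationError(f"no eligible arm for HER2 {status} patients")
        arm[mask] = rng.choice(np.asarray(arm_names, dtype=object),
                               size=int(mask.sum()), p=w / w.sum())

    array_labels = np.concatenate([
        np.repeat(f"array{i + 1}", len(chunk))
        for i, chunk in enumerate(np.array_split(np.arange(n), config.n_arrays))
    ])

    # Latent standardized values: block-shared factor + idiosyncratic noise,
    # unit marginal variance, then subtype offsets.
    k = config.n_analytes
    block_of = np.arange(k) // max(config.block_size, 1)
    n_blocks = int(block_of.max()) + 1
    shared = rng.standard_normal((n, n_blocks))
    idio = rng.standard_normal((n, k))
    rho = config.block_rho
    z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * idio
    for st, shifts in config.subtype_mean_shifts.items():
        rows = subtype_labels == st
        for analyte, delta in shifts.items():
            z[rows, analytes.index(analyte)] += delta

    beta = pd.Series(0.0, index=analytes)
    for analyte, b in config.resolved_effect_table().items():
        beta[analyte] = b
    baseline = np.array([logit(config.pcr_rates[s]) for s in subtype_labels])
    eta = baseline + z @ beta.to_numpy()
    pcr_prob = expit(eta)
    pcr = (rng.random(n) < pcr_prob).astype(int)

    hazard = config.baseline_hazard * config.pcr_hazard_ratio ** pcr
    raw_t = rng.exponential(1.0 / hazard)
    drfs_event = (raw_t <= config.censor_horizon).astype(int)
    drfs_time = np.minimum(raw_t, config.censor_horizon)

    tp_factor = np.exp(rng.normal(0.0, config.total_protein_lognormal_sd, size=n))

    clinical = pd.DataFrame({
        "patient_id": patients, "hr": hr, "her2": her2,
        "subtype": subtype_labels, "arm": arm, "pcr": pcr,
        "drfs_time": drfs_time, "drfs_event": drfs_event,
        "array_id": array_labels,
    })

    arrays = [f"array{i + 1}" for i in range(config.n_arrays)]
    shift = rng.normal(config.batch_shift_mean, config.batch_shift_sd,
                       size=(config.n_arrays, k))
    scale = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(config.n_arrays, k)))

    truth = SimTruth(
        z=pd.DataFrame(z, index=patients, columns=analytes),
        batch_shift=pd.DataFrame(shift, index=arrays, columns=analytes),
        batch_scale=pd.DataFrame(scale, index=arrays, columns=analytes),
        beta=beta,
        pcr_prob=pd.Series(pcr_prob, index=patients),
        hazard=pd.Series(hazard, index=patients),
        total_protein_factor=pd.Series(tp_factor, index=patients),
    )
    return clinical, truth


def simulate_spots(config: SimulationConfig, clinical: pd.DataFrame,
                   truth: SimTruth, rng=None) -> pd.DataFrame:
    """Emit triplicate spot intensities for a simulated cohort.

    Per (patient, analyte) the noiseless primary-spot level is::

        I = scale_au * (exp(s * z) * batch_scale + batch_shift) * tp + bg

    where ``tp`` is the patient's total-protein loading factor and ``bg`` the
    negative-control background; the three replicates carry multiplicative
    noise with the configured CV.  Negative-control and total-protein
    (Sypro) spot triplicates are emitted alongside.
    """
    if rng is None:
        _, rng = _stage_rngs(config.seed)
    analytes = config.analyte_names()
    patients = clinical["patient_id"].to_numpy()
    arrays = clinical["array_id"].to_numpy()
    n, k = len(patients), len(analytes)

    z = truth.z.loc[patients, analytes].to_numpy()
    scale = truth.batch_scale.loc[arrays, analytes].to_numpy()
    shift = truth.batch_shift.loc[arrays, analytes].to_numpy()
    tp = truth.total_protein_factor.loc[patients].to_numpy()[:, None]

    base = np.exp(config.intensity_log_sd * z)
    signal = config.intensity_scale * (base * scale + shift) * tp

    def with_noise(mean, shape):
        if config.replicate_cv == 0:
            return np.broadcast_to(mean, shape).copy()
        return mean * (1.0 + config.replicate_cv * rng.standard_normal(shape))

    primary = with_noise((signal + config.neg_control_level)[..., None], (n, k, 3))
    negative = with_noise(
        np.full((n, k, 1), config.neg_control_level), (n, k, 3))
    tp_mean = (config.total_protein_base * tp)[..., None]
    total = with_noise(tp_mean, (n, 1, 3))

    # Replicate noise at 3 sigma cannot reach zero for the defaults; clip
    # guards the nonnegativity invariant for extreme configurations.
    primary = np.maximum(primary, 0.0)
    negative = np.maximum(negative, 0.0)
    total = np.maximum(total, 0.0)

    rep = np.array([1, 2, 3])
    frames = []
    for spot_type, values, names in (
        ("primary", primary, analytes),
        ("negative_control", negative, analytes),
        ("total_protein", total, ["Sypro total protein"]),
    ):
        m = len(names)
        frames.append(pd.DataFrame({
            "patient_id": np.repeat(patients, m * 3),
            "array_id": np.repeat(arrays, m * 3),
            "analyte": np.tile(np.repeat(np.asarray(names, dtype=object), 3), n),
            "spot_type": spot_type,
            "replicate_index": np.tile(rep, n * m),
            "intensity": values.reshape(-1),
        }))
    spots = pd.concat(frames, ignore_index=True)
    return spots


def simulate_harps_cohort(n: int = 150, cut: float = 0.7, arm: str = "N",
                          flip_prob: float = 0.0, seed: int = 0):
    """Triple-negative derivation cohort with a planted two-marker step rule.

    Both phospho-markers are marginally standard normal on the harmonized
    scale and *concordant*: their positivity indicators at ``cut`` agree for
    every patient, emulating co-activation of the two phospho-sites.  A
    patient responds iff the (shared) indicator is positive, optionally with
    label-flip noise.  Each marker therefore carries a clean response step
    at ``cut``.  Returns ``(markers, clinical)`` where ``markers`` is a
    patients x 2 DataFrame of the HARPS analytes.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    patients = [f"TN{i:04d}" for i in range(1, n + 1)]
    m1 = rng.standard_normal(n)
    status = m1 >= cut
    # second marker: truncated normal on the same side of the cut
    p_cut = norm.cdf(cut)
    u = rng.random(n)
    u = np.where(status, p_cut + u * (1.0 - p_cut), u * p_cut)
    m2 = norm.ppf(u)
    values = np.column_stack([m1, m2])
    pcr = status.astype(int)
    if flip_prob > 0:
        flips = rng.random(n) < flip_prob
        pcr = np.where(flips, 1 - pcr, pcr)
    if pcr.min() == pcr.max():
        raise ValidationError("degenerate derivation cohort: single pCR class")
    markers = pd.DataFrame(values, index=patients, columns=list(HARPS_MARKERS))
    clinical = pd.DataFrame({
        "patient_id": patients, "hr": "neg", "her2": "neg",
        "subtype": "TN", "arm": arm, "pcr": pcr, "array_id": "array1",
    })
    return markers, clinical
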