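"""Synthetic paired LEM/mMKM rectum cohort generator.

Builds cohorts with the statistical structure the downstream analysis
assumes: three treatment groups (22 prostate at 66.4, 28 L_SAC at 70.4 and
13 H_SAC at 73.6 Gy(RBE), all in 16 fractions), rectum volumes drawn from
truncated normals (prostate 59 +/- 15 cc, sacrum 91 +/- 39 cc), and for
each patient a parametric LEM rectum DVH whose mMKM counterpart is the
image of the LEM curve under a known quadratic ground-truth dose map plus
a per-patient random offset and smooth heteroscedastic noise. Everything
is driven by a single seeded generator, so cohorts are bit-reproducible.

The default ground-truth map is the least-squares quadratic through the
four published (D_LEM|v, D_MKM|v) translation anchor pairs, frozen here
as constants and re-derived by an independent normal-equations oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DVH, VolumeSpec, dose_at_volume

__all__ = [
    "DVHShape",
    "CohortConfig",
    "Patient",
    "Cohort",
    "default_truth_relation",
    "generate_patient",
    "generate_cohort",
    "extract_pairs",
    "DEFAULT_V_LEVELS",
    "GROUPS",
]

GROUPS = ("prostate", "l_sac", "h_sac")

DEFAULT_V_LEVELS = (
    VolumeSpec("percent", 1),
    VolumeSpec("percent", 5),
    VolumeSpec("percent", 10),
    VolumeSpec("percent", 20),
)

# OLS quadratic through the translation anchor pairs
# (42.9, 28.8), (57.7, 46.4), (68.2, 60.0), (72.0, 66.0).
_TRUTH_A = 0.006511883796877242
_TRUTH_B = 0.5217302696304832
_TRUTH_C = -5.5357686465338904


def default_truth_relation() -> tuple[float, float, float]:
    """Frozen (a, b, c) of the generator's ground-truth LEM -> mMKM map."""
    return (_TRUTH_A, _TRUTH_B, _TRUTH_C)


@dataclass(frozen=True)
class DVHShape:
    """Parametric cumulative-DVH family: exponential low-dose tail plus a
    logistic hot-spot shoulder, truncated just above the shoulder.

    All dose scales are fractions of the prescription; per-patient values
    are jittered around the means with the given SDs.
    """

    hot_fraction: float = 0.16  # volume fraction in the hot shoulder
    hot_fraction_sd: float = 0.03
    hot_center_frac: float = 0.96  # shoulder center / prescription
    hot_center_sd: float = 0.025
    hot_width_frac: float = 0.025  # logistic width / prescription
    hot_width_sd: float = 0.007
    tail_scale_frac: float = 0.15  # exponential tail scale / prescription
    tail_scale_sd: float = 0.04
    top_sigmas: float = 4.0  # truncation: center + top_sigmas * width


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict = field(
        default_factory=lambda: {"prostate": 22, "l_sac": 28, "h_sac": 13}
    )
    volume_mean_cc: dict = field(
        default_factory=lambda: {"prostate": 59.0, "l_sac": 91.0, "h_sac": 91.0}
    )
    volume_sd_cc: dict = field(
        default_factory=lambda: {"prostate": 15.0, "l_sac": 39.0, "h_sac": 39.0}
    )
    min_volume_cc: float = 10.0
    prescriptions: dict = field(
        default_factory=lambda: {"prostate": 66.4, "l_sac": 70.4, "h_sac": 73.6}
    )
    n_fractions: int = 16
    dvh_shape: dict = field(
        default_factory=lambda: {
            "prostate": DVHShape(),
            # sacral rectums sit further from the high-dose region and vary more
            "l_sac": DVHShape(
                hot_center_frac=0.62, hot_center_sd=0.055, hot_fraction=0.10, hot_width_frac=0.06
            ),
            "h_sac": DVHShape(
                hot_center_frac=0.62, hot_center_sd=0.08, hot_fraction=0.10, hot_width_frac=0.06
            ),
        }
    )
    truth_relation: tuple[float, float, float] = (_TRUTH_A, _TRUTH_B, _TRUTH_C)
    noise_slope: float = 0.03  # residual SD = noise_slope * dose (heteroscedastic)
    noise_knot_spacing: float = 5.0  # Gy(RBE); correlation length of the noise field
    patient_effect_sd: float = 0.3  # per-patient dose offset shared across the curve
    bin_width: float = 0.1
    seed: int = 12345

    def __post_init__(self) -> None:
        for group, size in self.group_sizes.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
            if size < 1:
                raise ValueError("group sizes must be >= 1")
        if self.noise_slope < 0 or self.patient_effect_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for group in self.group_sizes:
            if self.prescriptions[group] <= 0:
                raise ValueError("prescriptions must be positive")

    @property
    def n_patients(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class Patient:
    patient_id: str
    group: str
    prescription: float
    n_fractions: int
    rectum_volume_cc: float
    dvh_lem: DVH
    dvh_mkm: DVH


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    patients: tuple[Patient, ...]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "group": [p.group for p in self.patients],
                "prescription_gy_rbe": [p.prescription for p in self.patients],
                "n_fractions": [p.n_fractions for p in self.patients],
                "rectum_volume_cc": [p.rectum_volume_cc for p in self.patients],
            }
        )


def _draw_volume(config: CohortConfig, group: str, rng: np.random.Generator) -> float:
    mean = config.volume_mean_cc[group]
    sd = config.volume_sd_cc[group]
    a = (config.min_volume_cc - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _lem_curve(
    shape: DVHShape, prescription: float, bin_width: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a per-patient LEM cumulative curve on a regular dose grid."""
    w_hot = float(np.clip(rng.normal(shape.hot_fraction, shape.hot_fraction_sd), 0.02, 0.5))
    mu = prescription * float(
        np.clip(rng.normal(shape.hot_center_frac, shape.hot_center_sd), 0.3, 0.98)
    )
    s = prescription * float(
        np.clip(rng.normal(shape.hot_width_frac, shape.hot_width_sd), 0.02, 0.2)
    )
    # keep the tail shallow enough that D_20% stays above the positive root
    # of the truth map (~9.5 Gy), where the LEM->MKM relation is meaningful
    lam = prescription * float(
        np.clip(rng.normal(shape.tail_scale_frac, shape.tail_scale_sd), 0.12, 0.5)
    )
    # truncate below the prescription so the hot spot (D_1%) stays under it
    top = min(mu + shape.top_sigmas * s, 0.995 * prescription)
    edges = np.arange(0.0, top + bin_width, bin_width)
    w_tail = 1.0 - w_hot
    raw = w_tail * np.exp(-edges / lam) + w_hot / (1.0 + np.exp((edges - mu) / s))
    # rescale so the curve is exactly 1 at zero dose and 0 at the top edge
    frac = (raw - raw[-1]) / (raw[0] - raw[-1])
    frac = np.clip(frac, 0.0, 1.0)
    frac = np.minimum.accumulate(frac)
    frac[0], frac[-1] = 1.0, 0.0
    return edges, frac


def _smooth_noise(
    edges: np.ndarray,
    slope: float,
    knot_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Heteroscedastic noise field, smooth on the ``knot_spacing`` scale."""
    if slope == 0:
        return np.zeros_like(edges)
    knots = np.arange(0.0, edges[-1] + knot_spacing, knot_spacing)
    values = rng.standard_normal(knots.size)
    return slope * edges * np.interp(edges, knots, values)


def generate_patient(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    patient_id: str = "P000",
) -> Patient:
    """Draw one patient: rectum volume, LEM DVH and its mapped mMKM DVH.

    The mMKM curve is obtained by pushing the LEM dose axis through the
    ground-truth quadratic plus a patient offset and smooth noise, then
    enforcing monotonicity, so at zero noise extracted (D_LEM|v, D_MKM|v)
    pairs lie on the truth relation up to interpolation error.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    volume = _draw_volume(config, group, rng)
    prescription = config.prescriptions[group]
    edges, frac = _lem_curve(config.dvh_shape[group], prescription, config.bin_width, rng)
    dvh_lem = DVH(
        dose_edges=edges,
        cum_volume_fraction=frac,
        total_volume_cc=volume,
        rbe_model="LEM",
        structure="rectum",
        patient_id=patient_id,
    )
    a, b, c = config.truth_relation
    offset = rng.normal(0.0, config.patient_effect_sd) if config.patient_effect_sd else 0.0
    mapped = (
        a * edges**2
        + b * edges
        + c
        + offset
        + _smooth_noise(edges, config.noise_slope, config.noise_knot_spacing, rng)
    )
    mapped = np.maximum.accumulate(mapped)
    keep = mapped > 0
    m, f = mapped[keep], frac[keep]
    # collapse rectification plateaus: keep the last (lowest-fraction) point of a run
    last_of_run = np.append(np.diff(m) > 1e-12, True)
    m, f = m[last_of_run], f[last_of_run]
    dvh_mkm = DVH(
        dose_edges=np.concatenate([[0.0], m]),
        cum_volume_fraction=np.concatenate([[1.0], np.minimum(f, 1.0)]),
        total_volume_cc=volume,
        rbe_model="MKM",
        structure="rectum",
        patient_id=patient_id,
    )
    return Patient(
        patient_id=patient_id,
        group=group,
        prescription=prescription,
        n_fractions=config.n_fractions,
        rectum_volume_cc=volume,
        dvh_lem=dvh_lem,
        dvh_mkm=dvh_mkm,
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the full cohort from a single seeded random stream."""
    if config is None:
        config = CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    patients = []
    counter = 1
    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        for _ in range(size):
            patients.append(
                generate_patient(config, group, rng, patient_id=f"P{counter:03d}")
            )
            counter += 1
    return Cohort(config=config, patients=tuple(patients))


def extract_pairs(
    cohort: Cohort,
    v_levels: tuple[VolumeSpec, ...] = DEFAULT_V_LEVELS,
) -> pd.DataFrame:
    """Long-format (patient, v-level) paired dose-volume points."""
    rows = []
    for patient in cohort.patients:
        for spec in v_levels:
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "group": patient.group,
                    "v_kind": spec.kind,
                    "v_amount": spec.amount,
                    "d_lem": dose_at_volume(patient.dvh_lem, spec),
                    "d_mkm": dose_at_volume(patient.dvh_mkm, spec),
                }
            )
    return pd.DataFrame(rows)
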