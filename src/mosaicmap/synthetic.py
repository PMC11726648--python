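"""Synthetic normative and patient cohorts with planted, ROI-confined atrophy.

The generator emulates the statistical structure the thin-patch-fraction
analysis assumes:

* a large healthy reference cohort whose patch-wise cortical thickness
  depends linearly on age and sex on top of subject- and patch-level
  Gaussian noise;
* an early-disease patient cohort (~135 subjects) carrying a nonnegative
  latent severity; atrophy of ``atrophy_scale * severity`` mm is subtracted
  on a designated "extremity" patch set only;
* clinical scores: an extremity motor subscore driven by severity, a total
  motor score that adds an independent non-extremity component, and a
  cognitive score independent of severity;
* longitudinal follow-ups at 1 and 3 years whose motor drift increases with
  severity, so baseline atrophy is predictive of progression while both
  progressors and non-progressors occur.

Everything is reproducible byte-for-byte from ``(GeneratorConfig, seed)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .roi import PatchSet

logger = logging.getLogger(__name__)

#: minimum admissible thickness after atrophy, in mm; keeps z-scores finite
THICKNESS_FLOOR_MM = 0.1

#: maximum extremity motor subscore: 14 lateralized sub-items x 4 points
EXTREMITY_MAX = 56
#: maximum total motor (MDS-UPDRS III) score
TOTAL_MOTOR_MAX = 132
#: maximum cognitive (MoCA) score
MOCA_MAX = 30

VISITS = ("BL", "Y1", "Y3")
VISIT_YEARS = {"BL": 0.0, "Y1": 1.0, "Y3": 3.0}
MEASURES = ("extremity", "total_motor", "cognitive")

HANDEDNESS_LEVELS = ("R", "L", "A")
# observed right/left/ambidextrous frequencies in an early-PD cohort
HANDEDNESS_PROBS = (119 / 135, 12 / 135, 4 / 135)


def patch_labels(n_patches: int) -> list[str]:
    """1-based, zero-padded patch column labels (``patch_0001`` ...)."""
    width = max(4, len(str(n_patches)))
    return [f"patch_{i + 1:0{width}d}" for i in range(n_patches)]


def default_extremity_patches(n_patches: int = 1000, n_roi: int = 79) -> PatchSet:
    """Evenly spaced stand-in for the extremity-motor patch set.

    Patches are exchangeable in the generator, so only the set's size
    matters; 79 matches the size of an extremity-motor restriction on a
    1000-patch parcellation.
    """
    idx = np.unique(np.round(np.linspace(0, n_patches - 1, n_roi)).astype(int))
    return PatchSet(name="extremity", indices=tuple(int(i) for i in idx),
                    provenance="synthetic evenly-spaced stand-in")


class ConfigError(ValueError):
    """Raised for non-finite or inconsistent generator parameters."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the cohort the analysis was designed for: a normative
    cohort of 650 healthy adults and 135 early-PD patients on a 1000-patch
    parcellation with a 79-patch extremity ROI.
    """

    n_normative: int = 650
    n_patients: int = 135
    n_patches: int = 1000
    age_range: tuple[float, float] = (40.0, 80.0)
    sex_ratio: float = 0.5                     # fraction female, normative
    patient_sex_ratio: float = 53 / 135        # fraction female, patients
    patient_age_mean: float = 63.46            # years
    patient_age_sd: float = 6.76               # years
    baseline_mean_thickness: float | np.ndarray = 2.5   # mm
    age_slope: float = -0.005                  # mm / year
    sex_offset: float = 0.02                   # mm added for female
    subject_sd: float = 0.08                   # mm, shared across patches
    patch_noise_sd: float = 0.12               # mm, independent per patch
    roi_patches: PatchSet | None = None        # default: 79-patch stand-in
    atrophy_scale: float = 0.15                # mm per unit severity
    severity_scale: float = 1.0                # half-normal scale of severity
    score_intercept: float = 6.0               # extremity score at severity 0
    score_gain: float = 12.0                   # extremity score per unit severity
    score_noise_sd: float = 3.0                # score units
    nonextremity_mean: float = 7.0             # non-extremity motor component
    nonextremity_sd: float = 3.0
    cognitive_mean: float = 27.5               # MoCA-like
    cognitive_sd: float = 2.0
    progression_drift: float = -1.0            # nonspecific motor drift / year
    severity_drift_coupling: float = 2.5       # extra drift / year / unit severity
    nonextremity_drift: float = 0.5            # non-extremity motor drift / year
    followup_noise_sd: float = 3.0             # motor follow-up noise
    cognitive_drift: float = -0.3              # MoCA units / year
    cognitive_followup_noise_sd: float = 1.5
    seed: int = 0

    def resolved_roi(self) -> PatchSet:
        if self.roi_patches is not None:
            return self.roi_patches
        return default_extremity_patches(self.n_patches, min(79, self.n_patches))

    def validate(self) -> None:
        scalars = {
            "sex_ratio": self.sex_ratio,
            "patient_sex_ratio": self.patient_sex_ratio,
            "age_slope": self.age_slope,
            "sex_offset": self.sex_offset,
            "subject_sd": self.subject_sd,
            "patch_noise_sd": self.patch_noise_sd,
            "atrophy_scale": self.atrophy_scale,
            "severity_scale": self.severity_scale,
            "score_noise_sd": self.score_noise_sd,
            "progression_drift": self.progression_drift,
            "severity_drift_coupling": self.severity_drift_coupling,
            "followup_noise_sd": self.followup_noise_sd,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ConfigError(f"{name} is not finite: {value}")
        base = np.asarray(self.baseline_mean_thickness, dtype=float)
        if not np.all(np.isfinite(base)):
            raise ConfigError("baseline_mean_thickness contains non-finite values")
        if base.ndim not in (0, 1) or (base.ndim == 1 and base.size != self.n_patches):
            raise ConfigError("baseline_mean_thickness must be scalar or length n_patches")
        if self.n_patches < 1:
            raise ConfigError("n_patches must be >= 1")
        for name in ("subject_sd", "patch_noise_sd", "score_noise_sd",
                     "followup_noise_sd", "cognitive_followup_noise_sd",
                     "severity_scale", "patient_age_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError(f"age_range must satisfy lo < hi, got {self.age_range}")
        if not 0 <= self.sex_ratio <= 1 or not 0 <= self.patient_sex_ratio <= 1:
            raise ConfigError("sex ratios must be in [0, 1]")
        roi = self.resolved_roi()
        roi.validate_range(self.n_patches)


@dataclass
class NormativeCohort:
    """Healthy reference cohort: thickness (subjects x patches) + demographics."""

    thickness: pd.DataFrame
    demographics: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.thickness)


@dataclass
class SyntheticStudy:
    """A complete synthetic study: normative cohort, patients, and ground truth."""

    config: GeneratorConfig
    normative: NormativeCohort
    patient_thickness: pd.DataFrame
    patient_demographics: pd.DataFrame
    clinical: pd.DataFrame            # long: subject_id, visit, measure, value
    truth: dict                       # latent severity + planted atrophy record


def _baseline_vector(config: GeneratorConfig) -> np.ndarray:
    base = np.asarray(config.baseline_mean_thickness, dtype=float)
    if base.ndim == 0:
        base = np.full(config.n_patches, float(base))
    return base


def _thickness_frame(values: np.ndarray, ids: Sequence[str], n_patches: int) -> pd.DataFrame:
    frame = pd.DataFrame(values, columns=patch_labels(n_patches))
    frame.insert(0, "subject_id", list(ids))
    return frame


def _clip_floor(values: np.ndarray, what: str) -> np.ndarray:
    n_clipped = int((values < THICKNESS_FLOOR_MM).sum())
    if n_clipped:
        logger.warning("%s: clipped %d thickness values at the %.1f mm floor",
                       what, n_clipped, THICKNESS_FLOOR_MM)
    return np.maximum(values, THICKNESS_FLOOR_MM)


def _simulate_thickness(config: GeneratorConfig, ages: np.ndarray,
                        female: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = ages.size
    base = _baseline_vector(config)
    mid_age = 0.5 * (config.age_range[0] + config.age_range[1])
    subject_effect = rng.normal(0.0, config.subject_sd, size=n)
    noise = rng.normal(0.0, config.patch_noise_sd, size=(n, config.n_patches))
    thick = (base[None, :]
             + config.age_slope * (ages - mid_age)[:, None]
             + config.sex_offset * female.astype(float)[:, None]
             + subject_effect[:, None]
             + noise)
    return thick


def generate_normative(config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> NormativeCohort:
    """Simulate the healthy reference cohort.

    Thickness follows ``base_j + age_slope*(age - mid_age) + sex_offset*female
    + subject_effect + patch_noise`` with ages uniform over ``age_range``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_normative
    ages = rng.uniform(*config.age_range, size=n)
    female = rng.random(n) < config.sex_ratio
    handedness = rng.choice(HANDEDNESS_LEVELS, size=n, p=HANDEDNESS_PROBS)
    thick = _clip_floor(_simulate_thickness(config, ages, female, rng), "normative cohort")
    ids = [f"hc-{i + 1:04d}" for i in range(n)]
    demographics = pd.DataFrame({
        "subject_id": ids,
        "age": ages,
        "sex": np.where(female, "F", "M"),
        "handedness": handedness,
        "symptom_duration": 0.0,
    })
    return NormativeCohort(thickness=_thickness_frame(thick, ids, config.n_patches),
                           demographics=demographics)


def _round_clip(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.round(values), lo, hi).astype(int)


def generate_patients(config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> SyntheticStudy:
    """Simulate the patient cohort, clinical visits, and ground truth.

    Atrophy ``atrophy_scale * severity`` (mm) is subtracted on the ROI
    patches only; the extremity score tracks severity, the cognitive score
    does not, and follow-up motor drift increases with severity.

    The returned :class:`SyntheticStudy` also carries a freshly generated
    normative cohort (from a sub-stream of the same seed) so a single call
    yields a complete, self-consistent study.
    """
    config.validate()
    roi = config.resolved_roi()
    if rng is None:
        seq = np.random.SeedSequence(config.seed)
        rng_norm, rng = (np.random.default_rng(s) for s in seq.spawn(2))
        normative = generate_normative(config, rng_norm)
    else:
        normative = generate_normative(config, rng)

    n = config.n_patients
    lo, hi = config.age_range
    # keep the +/-2-year matching window inside the normative age support
    ages = np.clip(rng.normal(config.patient_age_mean, config.patient_age_sd, size=n),
                   lo + 4.0, hi - 2.0)
    female = rng.random(n) < config.patient_sex_ratio
    handedness = rng.choice(HANDEDNESS_LEVELS, size=n, p=HANDEDNESS_PROBS)
    symptom_duration = rng.exponential(17.0 / np.log(2.0), size=n)  # median 17 months

    severity = np.abs(rng.normal(0.0, config.severity_scale, size=n))
    thick = _simulate_thickness(config, ages, female, rng)
    roi_idx = roi.as_array()
    thick[:, roi_idx] -= config.atrophy_scale * severity[:, None]
    thick = _clip_floor(thick, "patient cohort")

    ids = [f"pd-{i + 1:04d}" for i in range(n)]
    demographics = pd.DataFrame({
        "subject_id": ids,
        "age": ages,
        "sex": np.where(female, "F", "M"),
        "handedness": handedness,
        "symptom_duration": symptom_duration,
    })

    # continuous latent scores; recorded values are rounded and clamped
    ext_cont = (config.score_intercept + config.score_gain * severity
                + rng.normal(0.0, config.score_noise_sd, size=n))
    nonext_cont = np.abs(rng.normal(config.nonextremity_mean, config.nonextremity_sd, size=n))
    cog_cont = rng.normal(config.cognitive_mean, config.cognitive_sd, size=n)

    rows: list[tuple[str, str, str, int]] = []
    motor_rate = config.progression_drift + config.severity_drift_coupling * severity
    for visit in VISITS:
        h = VISIT_YEARS[visit]
        if h == 0.0:
            ext_v, nonext_v, cog_v = ext_cont, nonext_cont, cog_cont
        else:
            ext_v = (ext_cont + motor_rate * h
                     + rng.normal(0.0, config.followup_noise_sd, size=n))
            nonext_v = (nonext_cont + config.nonextremity_drift * h
                        + rng.normal(0.0, config.followup_noise_sd, size=n))
            cog_v = (cog_cont + config.cognitive_drift * h
                     + rng.normal(0.0, config.cognitive_followup_noise_sd, size=n))
        ext = _round_clip(ext_v, 0, EXTREMITY_MAX)
        nonext = _round_clip(nonext_v, 0, TOTAL_MOTOR_MAX - EXTREMITY_MAX)
        total = ext + nonext
        cog = _round_clip(cog_v, 0, MOCA_MAX)
        for i, sid in enumerate(ids):
            rows.append((sid, visit, "extremity", int(ext[i])))
            rows.append((sid, visit, "total_motor", int(total[i])))
            rows.append((sid, visit, "cognitive", int(cog[i])))
    clinical = pd.DataFrame(rows, columns=["subject_id", "visit", "measure", "value"])

    truth = {
        "severity": dict(zip(ids, severity.tolist())),
        "roi_patches": [int(i) for i in roi.indices],
        "atrophy_scale": config.atrophy_scale,
        "atrophy_mm": dict(zip(ids, (config.atrophy_scale * severity).tolist())),
    }
    return SyntheticStudy(config=config, normative=normative,
                          patient_thickness=_thickness_frame(thick, ids, config.n_patches),
                          patient_demographics=demographics,
                          clinical=clinical, truth=truth)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate a full study (normative cohort + patients) from one seed."""
    return generate_patients(config)
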