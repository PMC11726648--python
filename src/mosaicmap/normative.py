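"""Normative patch scoring: matched references, z-scores, exact rank p-values,
thin-patch calls, and the thin-patch fraction (TPF).

Each patient is compared with an individually matched subgroup of the
normative cohort (same sex, age within +/-2 years).  Per patch, the patient's
thickness is standardized against the matched reference (z-score) and
converted to a left-tail p-value by exact permutation: for one patient
against ``n_ref`` exchangeable reference values the exhaustive, replacement-
free permutation distribution of the patient's position is the discrete
uniform rank distribution, so

    p_j = (1 + #{reference values <= patient value}) / (n_ref + 1).

A patch with ``p < alpha`` (default 0.05, strict) is called "significantly
thin"; thickness above the norm is never flagged.  The TPF over a patch set
is the fraction of its patches called thin.  No multiple-comparison
correction is applied across patches by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .roi import PatchSet

logger = logging.getLogger(__name__)

DEFAULT_AGE_WINDOW = 2.0
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_REF = 10

#: below this reference size no patch can reach p < 0.05 (1/(n+1) >= 1/21)
MIN_REF_FOR_THIN_CALLS = 20


class MatchingError(ValueError):
    """Raised when a patient's matched reference subgroup is too small."""


class ValidationError(ValueError):
    """Raised for non-finite or structurally invalid inputs."""


@dataclass(frozen=True)
class ReferenceSubset:
    """The matched normative subgroup for one patient."""

    patient_id: str
    member_ids: tuple[str, ...]
    age_window: float

    @property
    def n_ref(self) -> int:
        return len(self.member_ids)


@dataclass
class PatchStats:
    """Per-patch z, p, and thin calls for one patient vs. their reference."""

    patient_id: str
    z: np.ndarray
    p: np.ndarray
    thin: np.ndarray
    alpha: float
    n_ref: int
    degenerate_patches: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_frame(self, patch_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Tidy per-patch table: patient, patch, z, p, thin."""
        n = self.z.size
        patches = list(patch_ids) if patch_ids is not None else list(range(n))
        return pd.DataFrame({
            "patient_id": self.patient_id,
            "patch": patches,
            "z": self.z,
            "p": self.p,
            "thin": self.thin,
        })


@dataclass(frozen=True)
class TPFResult:
    """Thin-patch fraction of one patient over one patch set."""

    patient_id: str
    patch_set_name: str
    n_patches_considered: int
    n_thin: int
    tpf: float


def match_reference(
    patient: Mapping,
    demographics: pd.DataFrame,
    age_window: float = DEFAULT_AGE_WINDOW,
    min_ref: int = DEFAULT_MIN_REF,
) -> ReferenceSubset:
    """Select all same-sex cohort members within ``age_window`` years (inclusive).

    ``patient`` needs keys ``subject_id``, ``age``, and ``sex``; the cohort
    ``demographics`` table needs columns of the same names.  Ordering follows
    the cohort table.
    """
    sex = patient["sex"]
    age = float(patient["age"])
    mask = (demographics["sex"].to_numpy() == sex) & (
        np.abs(demographics["age"].to_numpy() - age) <= age_window
    )
    members = tuple(demographics.loc[mask, "subject_id"].tolist())
    if len(members) < min_ref:
        raise MatchingError(
            f"patient {patient['subject_id']!r}: only {len(members)} matched reference "
            f"subjects (sex={sex}, age {age:.1f} +/- {age_window}); minimum is {min_ref}"
        )
    if len(members) < MIN_REF_FOR_THIN_CALLS:
        logger.warning(
            "patient %r: n_ref=%d < %d, so no patch can reach p < 0.05",
            patient["subject_id"], len(members), MIN_REF_FOR_THIN_CALLS,
        )
    return ReferenceSubset(patient_id=str(patient["subject_id"]),
                           member_ids=members, age_window=age_window)


def patch_z(patient_values: np.ndarray, reference_values: np.ndarray) -> np.ndarray:
    """Per-patch z-score against the matched reference (sample SD, ddof=1).

    Patches with zero reference SD get ``z = nan``; callers exclude them
    from thin calling (a count is logged).
    """
    x = np.asarray(patient_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != x.size:
        raise ValidationError("reference must be (n_ref, n_patches) matching the patient row")
    if ref.shape[0] < 2:
        raise ValidationError("need at least 2 reference subjects for a sample SD")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(ref))):
        raise ValidationError("non-finite thickness values")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d patches have zero reference SD; z undefined there",
                       int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[degenerate] = np.nan
    return z


def patch_p_exhaustive(patient_values: np.ndarray, reference_values: np.ndarray) -> np.ndarray:
    """Exact left-tail rank p-value of the patient among the reference values.

    ``p_j = (1 + #{ref_j <= x_j}) / (n_ref + 1)``; ties count toward the
    ``<=`` set (conservative: fewer thin calls).  Smaller patient thickness
    gives smaller p.
    """
    x = np.asarray(patient_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != x.size:
        raise ValidationError("reference must be (n_ref, n_patches) matching the patient row")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(ref))):
        raise ValidationError("non-finite thickness values")
    n_ref = ref.shape[0]
    k = (ref <= x[None, :]).sum(axis=0)
    return (1.0 + k) / (n_ref + 1.0)


def call_thin(p: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Thin call per patch: ``p < alpha``, strict inequality, no correction."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return p < alpha


def tpf(thin: np.ndarray, patch_set: PatchSet | None = None,
        patient_id: str = "", set_name: str | None = None) -> TPFResult:
    """Thin-patch fraction over ``patch_set`` (or all patches when None)."""
    thin = np.asarray(thin, dtype=bool)
    if patch_set is None:
        considered = thin
        name = set_name or "wholebrain"
    else:
        patch_set.validate_range(thin.size)
        considered = thin[patch_set.as_array()]
        name = set_name or patch_set.name
    n = considered.size
    if n == 0:
        raise ValidationError("empty patch set")
    n_thin = int(considered.sum())
    return TPFResult(patient_id=patient_id, patch_set_name=name,
                     n_patches_considered=n, n_thin=n_thin, tpf=n_thin / n)


def null_thin_probability(n_ref: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Exact null probability that one patch is called thin at level ``alpha``.

    Under exchangeability p is uniform on {k/(n_ref+1)}, so
    ``P(p < alpha) = #{k in 1..n_ref+1 : k < alpha*(n_ref+1)} / (n_ref+1)``.
    """
    ks = np.arange(1, n_ref + 2)
    return float((ks < alpha * (n_ref + 1)).sum() / (n_ref + 1))


def score_patient(
    patient_values: np.ndarray,
    reference_values: np.ndarray,
    patient_id: str = "",
    alpha: float = DEFAULT_ALPHA,
) -> PatchStats:
    """Full per-patch scoring of one patient against a matched reference."""
    z = patch_z(patient_values, reference_values)
    p = patch_p_exhaustive(patient_values, reference_values)
    thin = call_thin(p, alpha=alpha)
    degenerate = np.flatnonzero(np.isnan(z))
    if degenerate.size:
        thin = thin.copy()
        thin[degenerate] = False  # zero-SD patches excluded from thin calling
        logger.warning("patient %r: %d degenerate patches excluded from thin calls",
                       patient_id, degenerate.size)
    return PatchStats(patient_id=patient_id, z=z, p=p, thin=thin,
                      alpha=alpha, n_ref=reference_values.shape[0],
                      degenerate_patches=degenerate)


def _split_thickness(thickness: pd.DataFrame) -> tuple[list[str], list[str], np.ndarray]:
    ids = thickness["subject_id"].astype(str).tolist()
    patch_cols = [c for c in thickness.columns if c != "subject_id"]
    values = thickness[patch_cols].to_numpy(dtype=float)
    return ids, patch_cols, values


class MosaicNormativeScorer(TransformerMixin, BaseEstimator):
    """Normative patch scorer with matched-reference standardization.

    Fit on the normative cohort (thickness table + demographics), then
    transform patients to per-patch z-scores or score them fully (z, exact
    rank p, thin calls).

    Parameters
    ----------
    age_window : float
        Half-width of the age matching window in years (inclusive bounds).
    alpha : float
        Significance level for thin calls (strict ``p < alpha``).
    min_ref : int
        Minimum admissible matched-reference size; smaller matches raise
        :class:`MatchingError`.
    """

    def __init__(self, age_window: float = DEFAULT_AGE_WINDOW,
                 alpha: float = DEFAULT_ALPHA, min_ref: int = DEFAULT_MIN_REF):
        self.age_window = age_window
        self.alpha = alpha
        self.min_ref = min_ref

    def fit(self, thickness: pd.DataFrame, demographics: pd.DataFrame):
        """Store the normative cohort (thickness + demographics)."""
        ids, patch_cols, values = _split_thickness(thickness)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in normative thickness table")
        demo = demographics.set_index("subject_id", drop=False).loc[ids]
        self.reference_ids_ = np.asarray(ids)
        self.patch_ids_ = patch_cols
        self.n_patches_ = len(patch_cols)
        self.reference_values_ = values
        self.reference_demographics_ = demo.reset_index(drop=True)
        self._row_of_ = {sid: i for i, sid in enumerate(ids)}
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_values_"):
            raise RuntimeError("scorer is not fitted; call fit() first")

    def match(self, patient: Mapping) -> ReferenceSubset:
        self._check_fitted()
        return match_reference(patient, self.reference_demographics_,
                               age_window=self.age_window, min_ref=self.min_ref)

    def _reference_matrix(self, subset: ReferenceSubset) -> np.ndarray:
        rows = [self._row_of_[sid] for sid in subset.member_ids]
        return self.reference_values_[rows]

    def score_patients(self, thickness: pd.DataFrame,
                       demographics: pd.DataFrame) -> list[PatchStats]:
        """Score every patient: z, exact rank p, and thin calls per patch."""
        self._check_fitted()
        ids, patch_cols, values = _split_thickness(thickness)
        if patch_cols != self.patch_ids_:
            raise ValidationError("patient patch columns differ from the normative table")
        demo = demographics.set_index("subject_id").loc[ids]
        stats = []
        for i, sid in enumerate(ids):
            patient = {"subject_id": sid, "age": demo["age"].iloc[i], "sex": demo["sex"].iloc[i]}
            subset = self.match(patient)
            ref = self._reference_matrix(subset)
            stats.append(score_patient(values[i], ref, patient_id=sid, alpha=self.alpha))
        return stats

    def transform(self, thickness: pd.DataFrame,
                  demographics: pd.DataFrame) -> pd.DataFrame:
        """Per-patch z-score matrix (patients x patches) for downstream models."""
        stats = self.score_patients(thickness, demographics)
        z = np.vstack([s.z for s in stats])
        frame = pd.DataFrame(z, columns=self.patch_ids_)
        frame.insert(0, "subject_id", [s.patient_id for s in stats])
        return frame

    def tpf_table(self, stats: Sequence[PatchStats],
                  patch_sets: Mapping[str, PatchSet | None]) -> pd.DataFrame:
        """TPF of every patient over every named patch set (None = whole brain)."""
        rows = []
        for s in stats:
            for name, ps in patch_sets.items():
                r = tpf(s.thin, ps, patient_id=s.patient_id, set_name=name)
                rows.append((r.patient_id, r.patch_set_name, r.n_patches_considered,
                             r.n_thin, r.tpf))
        return pd.DataFrame(rows, columns=["patient_id", "patch_set", "n_patches",
                                           "n_thin", "tpf"])


def stats_to_frame(stats: Sequence[PatchStats],
                   patch_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Concatenate per-patient tidy PatchStats tables."""
    return pd.concat([s.to_frame(patch_ids) for s in stats], ignore_index=True)
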