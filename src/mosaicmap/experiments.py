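"""Reusable calibration and validation experiments on synthetic studies.

These functions run the package end to end under controlled, planted-truth
conditions: null calibration of the rank p-value and the TPF, recovery of
ROI-confined structure by the restricted-vs-unrestricted model comparison,
and progression-classification under planted and zero signal.  They are the
computations behind the package's reported operating characteristics.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .association import compare_by_adjusted_r2, fit_tpf_model
from .classify import ClassifierConfig, run_experiment_cell, run_full_experiment
from .normative import MosaicNormativeScorer, null_thin_probability
from .progression import label_progressors
from .synthetic import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)


def _dense_null_config(seed: int, n_patients: int) -> GeneratorConfig:
    """Null patients drawn from the normative model, with dense age coverage
    so every matched reference subgroup is large (n_ref >= 40)."""
    return GeneratorConfig(
        n_normative=650, n_patients=n_patients, n_patches=1000,
        age_range=(55.0, 65.0), patient_age_mean=60.0, patient_age_sd=1.5,
        atrophy_scale=0.0, seed=seed,
    )


def null_tpf_calibration(seed: int = 0, n_patients: int = 200) -> dict:
    """Mean whole-brain TPF of null patients vs. its exact discrete expectation.

    Each null patient's thin-call probability per patch is
    ``#{k : k < alpha (n_ref + 1)} / (n_ref + 1)``; the expected mean TPF
    averages this over the patients' matched-reference sizes.
    """
    config = _dense_null_config(seed, n_patients)
    study = generate_study(config)
    scorer = MosaicNormativeScorer().fit(study.normative.thickness,
                                         study.normative.demographics)
    stats = scorer.score_patients(study.patient_thickness,
                                  study.patient_demographics)
    tpfs = np.array([s.thin.mean() for s in stats])
    n_refs = np.array([s.n_ref for s in stats])
    expected = float(np.mean([null_thin_probability(n) for n in n_refs]))
    return {
        "mean_tpf": float(tpfs.mean()),
        "expected_tpf": expected,
        "min_n_ref": int(n_refs.min()),
        "n_patients": n_patients,
    }


def model_comparison_replicates(n_replicates: int = 100, base_seed: int = 0) -> dict:
    """Restricted vs. whole-brain TPF models on studies with ROI-planted atrophy.

    Per replicate (default generator settings), fits the extremity outcome on
    the restricted and the whole-brain TPF and records which wins by adjusted
    R²; also records the TPF term's p-values for the severity-independent
    cognitive outcome (both fits), whose rejection rate at 0.05 estimates the
    type-I error.
    """
    wins = 0
    cognitive_p: list[float] = []
    for rep in range(n_replicates):
        config = GeneratorConfig(seed=base_seed + rep)
        study = generate_study(config)
        scorer = MosaicNormativeScorer().fit(study.normative.thickness,
                                             study.normative.demographics)
        stats = scorer.score_patients(study.patient_thickness,
                                      study.patient_demographics)
        tpf_frame = scorer.tpf_table(stats, {"restricted": config.resolved_roi(),
                                             "wholebrain": None})
        order = [s.patient_id for s in stats]
        tpf_wide = tpf_frame.pivot_table(index="patient_id", columns="patch_set",
                                         values="tpf").loc[order]
        bl = study.clinical[study.clinical["visit"] == "BL"].pivot_table(
            index="subject_id", columns="measure", values="value").loc[order]
        demo = study.patient_demographics

        fits = {}
        for outcome in ("extremity", "cognitive"):
            for set_name in ("restricted", "wholebrain"):
                fits[(outcome, set_name)] = fit_tpf_model(
                    bl[outcome].to_numpy(), tpf_wide[set_name].to_numpy(),
                    demo, outcome_name=outcome)
        comparison = compare_by_adjusted_r2(fits[("extremity", "restricted")],
                                            fits[("extremity", "wholebrain")])
        wins += comparison.winner == "restricted"
        cognitive_p += [fits[("cognitive", "restricted")].tpf_p_value,
                        fits[("cognitive", "wholebrain")].tpf_p_value]
    cognitive_p_arr = np.asarray(cognitive_p)
    return {
        "restricted_win_rate": wins / n_replicates,
        "cognitive_type1_rate": float((cognitive_p_arr < 0.05).mean()),
        "n_replicates": n_replicates,
        "n_cognitive_fits": cognitive_p_arr.size,
    }


def _study_features_and_labels(config: GeneratorConfig, measure: str, horizon: str):
    study = generate_study(config)
    scorer = MosaicNormativeScorer().fit(study.normative.thickness,
                                         study.normative.demographics)
    z = scorer.transform(study.patient_thickness, study.patient_demographics)
    labels = label_progressors(study.clinical, measure, horizon)
    return study, z, labels


def planted_classifier_accuracy(n_seeds: int = 20, base_seed: int = 0,
                                horizon: str = "Y3") -> dict:
    """Pooled held-out accuracy of the restricted-ROI extremity classifier
    across seeds, on studies where ROI atrophy drives motor progression."""
    correct = total = 0
    per_seed = []
    for rep in range(n_seeds):
        config = GeneratorConfig(seed=base_seed + rep)
        _, z, labels = _study_features_and_labels(config, "extremity", horizon)
        clf_config = ClassifierConfig(seed=base_seed + rep,
                                      n_features=len(config.resolved_roi()))
        report = run_experiment_cell(z, labels, "restricted_roi",
                                     config.resolved_roi(), clf_config)
        hits = sum(p["predicted"] == p["observed"] for p in report.predictions)
        correct += hits
        total += len(report.predictions)
        per_seed.append(report.test_accuracy)
    acc = correct / total
    half_width = 1.96 * np.sqrt(acc * (1 - acc) / total)
    return {
        "pooled_accuracy": acc,
        "ci95_low": acc - half_width,
        "ci95_high": acc + half_width,
        "n_predictions": total,
        "per_seed_accuracy": per_seed,
        "horizon": horizon,
    }


def null_classifier_accuracies(seed: int = 0) -> list[dict]:
    """All 12 experiment cells on a zero-signal study (no atrophy, no
    severity-coupled drift); accuracies should sit at the majority rate."""
    config = dataclasses.replace(GeneratorConfig(seed=seed),
                                 atrophy_scale=0.0, severity_drift_coupling=0.0)
    study = generate_study(config)
    scorer = MosaicNormativeScorer().fit(study.normative.thickness,
                                         study.normative.demographics)
    z = scorer.transform(study.patient_thickness, study.patient_demographics)
    clf_config = ClassifierConfig(seed=seed, n_features=len(config.resolved_roi()))
    reports = run_full_experiment(z, study.clinical, config.resolved_roi(), clf_config)
    cells = []
    for report in reports:
        observed = np.array([p["observed"] for p in report.predictions])
        base = max(observed.mean(), 1 - observed.mean())
        cells.append({
            "outcome": report.outcome,
            "horizon": report.horizon,
            "feature_mode": report.feature_mode,
            "test_accuracy": report.test_accuracy,
            "majority_rate": float(base),
            "n_test": observed.size,
        })
    return cells
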