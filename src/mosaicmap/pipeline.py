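"""End-to-end orchestration: simulate -> score -> TPF -> associate -> label ->
test -> classify, with a deterministic provenance manifest.

Every output artifact is a plain CSV/JSON file; the manifest records the
configuration hash, all stage seeds, and the SHA-256 of every written file,
so two runs with identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .association import compare_by_adjusted_r2, fit_tpf_model
from .classify import ClassifierConfig, run_full_experiment, summary_table
from .normative import MosaicNormativeScorer, stats_to_frame
from .progression import HORIZONS, MEASURES, label_progressors, wilcoxon_table
from .roi import PatchSet
from .synthetic import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha: float = 0.05
    age_window: float = 2.0
    min_ref: int = 10
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    wilcoxon_visits: tuple[str, str] = ("BL", "Y3")

    def to_dict(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        roi = self.generator.roi_patches
        gen["roi_patches"] = list(roi.indices) if roi is not None else None
        gen["baseline_mean_thickness"] = np.asarray(
            self.generator.baseline_mean_thickness).tolist()
        raw = {
            "generator": gen,
            "alpha": self.alpha,
            "age_window": self.age_window,
            "min_ref": self.min_ref,
            "classifier": dataclasses.asdict(self.classifier),
            "wilcoxon_visits": list(self.wilcoxon_visits),
        }
        # canonical JSON types (tuples -> lists) so the in-memory manifest
        # equals its serialized form
        return json.loads(json.dumps(raw, sort_keys=True))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the complete analysis on a synthetic study and write all artifacts.

    Returns the manifest (also written to ``manifest.json``): configuration
    hash, seeds, and SHA-256 hashes of every output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_csv(frame: pd.DataFrame, name: str) -> Path:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)
        return path

    def save_json(obj, name: str) -> Path:
        path = out / name
        _write_json(obj, path)
        written.append(path)
        return path

    stage = "simulate"
    try:
        study = generate_study(config.generator)
        roi = config.generator.resolved_roi()
        save_csv(study.normative.thickness, "normative_thickness.csv")
        save_csv(study.normative.demographics, "normative_demographics.csv")
        save_csv(study.patient_thickness, "patient_thickness.csv")
        save_csv(study.patient_demographics, "patient_demographics.csv")
        save_csv(study.clinical, "clinical.csv")
        save_json(study.truth, "truth.json")

        stage = "map"
        scorer = MosaicNormativeScorer(age_window=config.age_window,
                                       alpha=config.alpha, min_ref=config.min_ref)
        scorer.fit(study.normative.thickness, study.normative.demographics)
        stats = scorer.score_patients(study.patient_thickness,
                                      study.patient_demographics)
        save_csv(stats_to_frame(stats, scorer.patch_ids_), "patch_stats.csv")
        z = np.vstack([s.z for s in stats])
        z_frame = pd.DataFrame(z, columns=scorer.patch_ids_)
        z_frame.insert(0, "subject_id", [s.patient_id for s in stats])
        save_csv(z_frame, "z_scores.csv")

        stage = "tpf"
        tpf_frame = scorer.tpf_table(stats, {"restricted": roi, "wholebrain": None})
        save_csv(tpf_frame, "tpf.csv")

        stage = "associate"
        bl = study.clinical[study.clinical["visit"] == "BL"].pivot_table(
            index="subject_id", columns="measure", values="value", aggfunc="first")
        tpf_wide = tpf_frame.pivot_table(index="patient_id", columns="patch_set",
                                         values="tpf")
        demo = study.patient_demographics.set_index("subject_id")
        order = [s.patient_id for s in stats]
        bl, tpf_wide, demo = bl.loc[order], tpf_wide.loc[order], demo.loc[order]
        fits, comparisons = {}, []
        for measure in MEASURES:
            pair = {}
            for set_name in ("restricted", "wholebrain"):
                fit = fit_tpf_model(bl[measure].to_numpy(),
                                    tpf_wide[set_name].to_numpy(),
                                    demo.reset_index(), outcome_name=measure)
                fits[f"{measure}_{set_name}"] = fit.to_dict()
                pair[set_name] = fit
            comparisons.append(
                compare_by_adjusted_r2(pair["restricted"], pair["wholebrain"]).to_dict())
        save_json(fits, "glm_fits.json")
        save_csv(pd.DataFrame(comparisons), "glm_comparisons.csv")

        stage = "label"
        labels = pd.concat(
            [label_progressors(study.clinical, m, h) for m in MEASURES for h in HORIZONS],
            ignore_index=True)
        save_csv(labels, "progression_labels.csv")

        stage = "wilcoxon"
        save_csv(wilcoxon_table(study.clinical, visits=config.wilcoxon_visits),
                 "wilcoxon.csv")

        stage = "classify"
        reports = run_full_experiment(z_frame, study.clinical, roi, config.classifier)
        save_json([r.to_dict() for r in reports], "classifier_reports.json")
        save_csv(summary_table(reports), "classifier_summary.csv")
    except Exception as exc:  # noqa: BLE001 - stage name matters for users
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seeds": {"generator": config.generator.seed,
                  "classifier": config.classifier.seed},
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
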