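"""End-to-end in-silico study orchestration.

Simulates a training and a disjoint external-validation pericardioversion
cohort, assesses signal quality, extracts RR features, internally validates
the main (binary AF) classifier with leave-one-subject-out cross-validation,
trains the final AF and AFL classifiers on the full training cohort, applies
them to the validation cohort, and evaluates diagnostic performance under
both positive-class definitions, with a pre/post user-feedback-revision
subgroup comparison when the validation cohort mixes artifact regimes.

Every source of randomness derives from one master seed via a documented
fan-out (numpy SeedSequence), so any stage can be reproduced in isolation
and two runs with the same config are byte-identical in the summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, viz
from .beats_features import (
    FEATURE_NAMES,
    UndiagnosableRecording,
    detect_pulses,
    extract_features,
)
from .classifier import (
    AF_BINARY,
    AFL_3CLASS,
    ClassifierConfig,
    TrainedModel,
    loso_cross_validate,
    predict_batch,
    train_classifier,
)
from .ppg_sim import CohortSpec, RhythmLabel, simulate_cohort
from .signal_quality import QualityConfig, assess_quality


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"study stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    training: CohortSpec
    validation: CohortSpec
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    gate: float = 0.9
    outdir: str = "study_out"
    master_seed: int = 20240901
    validation_changepoint: int | None = None  # first subject index on the
    # post-revision feedback; None = single-regime validation cohort
    run_loso: bool = True
    run_viz: bool = True
    tsne: viz.TsneConfig = field(default_factory=viz.TsneConfig)

    def __post_init__(self) -> None:
        if self.training.subject_prefix == self.validation.subject_prefix:
            raise ValueError(
                "training and validation cohorts must use distinct subject "
                "prefixes so their subject ids are disjoint"
            )
        if self.validation_changepoint is not None and not (
            0 < self.validation_changepoint < self.validation.n_subjects
        ):
            raise ValueError(
                "validation_changepoint must lie strictly inside the "
                "validation cohort's subject range"
            )

    @classmethod
    def scaled_default(
        cls, master_seed: int = 20240901, outdir: str = "study_out"
    ) -> "StudyConfig":
        """Desk-scale study: 30 training / 40 validation subjects, all on the
        post-revision (artifact-free) feedback regime, ~2.11 recordings/day."""
        s0, s1 = _derive_seeds(master_seed, 2)
        return cls(
            training=CohortSpec(
                n_subjects=30, recs_per_day=2.11, adherence="poisson",
                artifact_regime="post_revision", seed=s0, subject_prefix="T",
            ),
            validation=CohortSpec(
                n_subjects=40, recs_per_day=2.11, adherence="poisson",
                artifact_regime="post_revision", seed=s1, subject_prefix="V",
            ),
            master_seed=master_seed,
            outdir=outdir,
        )

    @classmethod
    def full_default(
        cls, master_seed: int = 20240901, outdir: str = "study_out"
    ) -> "StudyConfig":
        """Full-size study: 180 training / 280 validation subjects; the final
        84 validation subjects (#197 onward) record under the revised
        (artifact-free) feedback, the first 196 under the pre-revision one."""
        s0, s1 = _derive_seeds(master_seed, 2)
        return cls(
            training=CohortSpec(
                n_subjects=180, recs_per_day=2.11, adherence="poisson",
                artifact_regime="post_revision", seed=s0, subject_prefix="T",
            ),
            validation=CohortSpec(
                n_subjects=280, recs_per_day=2.11, adherence="poisson",
                artifact_regime="pre_revision", seed=s1, subject_prefix="V",
            ),
            validation_changepoint=196,
            master_seed=master_seed,
            outdir=outdir,
        )


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic seed fan-out from the master seed (below 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Per-cohort processing
# ---------------------------------------------------------------------------


def process_cohort(
    spec: CohortSpec, qcfg: QualityConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, quality-assess and feature-extract one cohort.

    Returns (manifest, features): the manifest gains ``usable_seconds``,
    ``ppg_sufficient`` and ``diagnosable`` columns; the feature table holds
    one row per diagnosable recording with the reference (``label``) rhythm
    at reporting level plus the 13 RR features.
    """
    recordings, manifest = simulate_cohort(spec)
    usable, sufficient, diagnosable = [], [], []
    feat_rows = []
    for (_, row), rec in zip(manifest.iterrows(), recordings):
        qa = assess_quality(rec, qcfg)
        usable.append(qa.usable_seconds)
        sufficient.append(qa.sufficient)
        ok = False
        if qa.sufficient:
            try:
                fv = extract_features(detect_pulses(rec, qa))
                ok = True
                feat_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "day": row["day"],
                        "rec_idx": row["rec_idx"],
                        "truth": RhythmLabel(row["truth"]).reporting(),
                        "label": RhythmLabel(row["ecg_label"]).reporting(),
                        **fv.values,
                    }
                )
            except UndiagnosableRecording:
                ok = False
        diagnosable.append(ok)
    manifest = manifest.copy()
    manifest["usable_seconds"] = usable
    manifest["ppg_sufficient"] = sufficient
    manifest["diagnosable"] = diagnosable
    manifest["ecg_label"] = [RhythmLabel(v).reporting() for v in manifest["ecg_label"]]
    features = pd.DataFrame(feat_rows)
    return manifest, features


def _evaluation_records(
    manifest: pd.DataFrame, predictions: pd.DataFrame
) -> pd.DataFrame:
    """One row per recording: reference label, quality, classification."""
    keys = ["subject_id", "day", "rec_idx"]
    pred_cols = [
        c for c in predictions.columns
        if c.startswith("p_") or c in ("pred_label", "certainty")
    ]
    merged = manifest.merge(
        predictions[keys + pred_cols], on=keys, how="left", validate="1:1"
    )
    return merged


# ---------------------------------------------------------------------------
# The study
# ---------------------------------------------------------------------------


def run_study(cfg: StudyConfig) -> dict:
    """Execute the full study; returns (and writes) the summary bundle."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (clf_seed, loso_seed, tsne_seed) = _derive_seeds(cfg.master_seed + 1, 3)

    summary: dict = {
        "master_seed": cfg.master_seed,
        "config": {
            "training": _jsonable(dataclasses.asdict(cfg.training)),
            "validation": _jsonable(dataclasses.asdict(cfg.validation)),
            "gate": cfg.gate,
            "validation_changepoint": cfg.validation_changepoint,
        },
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - stage-named rethrow
                raise StageError(name, e) from e
        return deco

    # -- simulate + quality + features ------------------------------------
    @stage("simulate_training")
    def train_data():
        return process_cohort(cfg.training, cfg.quality)

    train_manifest, train_features = train_data

    @stage("simulate_validation")
    def val_data():
        if cfg.validation_changepoint is None:
            return process_cohort(cfg.validation, cfg.quality)
        # mixed regimes: first subjects pre-revision, rest post-revision
        pre_spec = dataclasses.replace(
            cfg.validation,
            n_subjects=cfg.validation_changepoint,
            artifact_regime="pre_revision",
        )
        post_spec = dataclasses.replace(
            cfg.validation,
            n_subjects=cfg.validation.n_subjects - cfg.validation_changepoint,
            artifact_regime="post_revision",
            seed=cfg.validation.seed + 1,
            subject_offset=cfg.validation_changepoint,
        )
        m1, f1 = process_cohort(pre_spec, cfg.quality)
        m2, f2 = process_cohort(post_spec, cfg.quality)
        return (
            pd.concat([m1, m2], ignore_index=True),
            pd.concat([f1, f2], ignore_index=True),
        )

    val_manifest, val_features = val_data

    assert not set(train_manifest["subject_id"]) & set(val_manifest["subject_id"])

    train_manifest.to_csv(out / "training_manifest.csv", index=False)
    val_manifest.to_csv(out / "validation_manifest.csv", index=False)
    train_features.to_csv(out / "training_features.csv", index=False)
    val_features.to_csv(out / "validation_features.csv", index=False)

    trainable = train_features[train_features["label"] != "INSUFFICIENT"]
    summary["cohorts"] = {
        "training": _cohort_summary(train_manifest, trainable),
        "validation": _cohort_summary(val_manifest, val_features),
    }

    # -- internal validation: LOSO on the training cohort ------------------
    if cfg.run_loso:
        @stage("loso_internal_validation")
        def loso_summary():
            preds = loso_cross_validate(
                trainable, AF_BINARY, cfg.classifier, rng=loso_seed
            )
            preds.to_csv(out / "loso_predictions.csv", index=False)
            records = _evaluation_records(train_manifest, preds)
            rep = evaluation.build_report(
                records, gate=cfg.gate,
                positive_definition=evaluation.AF_ONLY, score_column="p_AF",
            )
            (out / "internal_report.json").write_text(
                json.dumps(_jsonable(rep.to_dict()), sort_keys=True, indent=1)
            )
            return rep.to_dict()

        summary["internal_validation_af"] = loso_summary

    # -- final models -------------------------------------------------------
    @stage("train_final_models")
    def models():
        af = train_classifier(trainable, AF_BINARY, cfg.classifier, rng=clf_seed)
        afl = train_classifier(
            trainable, AFL_3CLASS, cfg.classifier, rng=clf_seed + 1
        )
        af.save(out / "model_af.json")
        afl.save(out / "model_afl.json")
        return af, afl

    model_af, model_afl = models

    # provenance: the final models must have seen no validation subject
    for m in (model_af, model_afl):
        assert not set(m.metadata["training_subjects"]) & set(
            val_manifest["subject_id"]
        )

    # -- external validation ------------------------------------------------
    @stage("predict_validation")
    def predictions():
        p_af = predict_batch(model_af, val_features)
        p_afl = predict_batch(model_afl, val_features)
        p_afl["p_af_or_afl"] = p_afl["p_AF"] + p_afl["p_AFL"]
        p_af.to_csv(out / "validation_predictions_af.csv", index=False)
        p_afl.to_csv(out / "validation_predictions_afl.csv", index=False)
        return p_af, p_afl

    preds_af, preds_afl = predictions

    @stage("evaluate")
    def reports():
        rec_af = _evaluation_records(val_manifest, preds_af)
        rec_afl = _evaluation_records(val_manifest, preds_afl)
        rep_af = evaluation.build_report(
            rec_af, gate=cfg.gate,
            positive_definition=evaluation.AF_ONLY, score_column="p_AF",
        )
        rep_afl = evaluation.build_report(
            rec_afl, gate=cfg.gate,
            positive_definition=evaluation.AF_OR_AFL, score_column="p_af_or_afl",
        )
        analysis_af, _ = evaluation.apply_exclusions(rec_af, gate=cfg.gate)
        agreement = evaluation.per_participant_agreement(analysis_af)

        result = {
            "external_af_only": rep_af.to_dict(),
            "external_af_or_afl": rep_afl.to_dict(),
            "per_participant_agreement": {
                k: v for k, v in agreement.items()
                if k != "disagreements_per_subject"
            },
        }
        if cfg.validation_changepoint is not None:
            pre = rec_af[rec_af["artifact_regime"] == "pre_revision"]
            post = rec_af[rec_af["artifact_regime"] == "post_revision"]
            rep_pre = evaluation.build_report(
                pre, gate=cfg.gate,
                positive_definition=evaluation.AF_ONLY, score_column="p_AF",
            )
            rep_post = evaluation.build_report(
                post, gate=cfg.gate,
                positive_definition=evaluation.AF_ONLY, score_column="p_AF",
            )
            comp = evaluation.comparison_report(rep_pre, rep_post)
            result["revision_comparison"] = comp
            (out / "revision_comparison.md").write_text(
                evaluation.comparison_markdown(comp)
            )
        (out / "external_report_af.md").write_text(rep_af.to_markdown())
        (out / "external_report_afl.md").write_text(rep_afl.to_markdown())
        return result, rec_af

    report_dict, rec_af = reports
    summary.update(report_dict)

    # -- visualization ------------------------------------------------------
    if cfg.run_viz:
        @stage("viz")
        def figures():
            viz.plot_quality_per_subject(val_manifest, out / "fig_quality.png")
            viz.plot_certainty_distribution(
                preds_af, out / "fig_certainty.png", gate=cfg.gate
            )
            non_afl = val_features[val_features["label"] != "AFL"]
            X = non_afl[FEATURE_NAMES].to_numpy(float)
            Xz = (X - model_af.scaler_mean) / model_af.scaler_scale
            merged = non_afl.merge(
                preds_af[["subject_id", "day", "rec_idx", "certainty"]],
                on=["subject_id", "day", "rec_idx"],
            )
            tsne_cfg = dataclasses.replace(cfg.tsne, seed=tsne_seed)
            emb = viz.embed_tsne(
                Xz, non_afl["label"].to_numpy(), merged["certainty"].to_numpy(),
                tsne_cfg,
            )
            emb.to_frame().to_csv(out / "tsne_coords.csv", index=False)
            viz.plot_embedding(emb, out / "fig_tsne.png")

        figures

    summary_text = json.dumps(_jsonable(summary), sort_keys=True, indent=1)
    (out / "summary.json").write_text(summary_text)
    return summary


def _cohort_summary(manifest: pd.DataFrame, features: pd.DataFrame) -> dict:
    n_subj = int(manifest["subject_id"].nunique())
    return {
        "n_subjects": n_subj,
        "n_recordings": int(len(manifest)),
        "recordings_per_subject": float(len(manifest)) / n_subj,
        "n_sufficient": int(manifest["ppg_sufficient"].sum()),
        "frac_insufficient": float(1.0 - manifest["ppg_sufficient"].mean()),
        "label_counts": {
            k: int(v) for k, v in manifest["ecg_label"].value_counts().items()
        },
        "n_feature_rows": int(len(features)),
    }
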