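"""SVM rhythm classification with calibrated certainty and abstention.

Two tasks mirror the two deployed classifiers:

* ``AF_BINARY`` — SR vs AF, trained with AFL-labelled recordings excluded
  ("the AF classifier").
* ``AFL_3CLASS`` — SR vs AF vs AFL ("the AFL classifier"), one-vs-rest.

Hyperparameters are fixed (RBF kernel, C = 1, gamma = 1/(d * Var(X))); no
search is performed.  Decision values are mapped to posterior probabilities
by Platt sigmoid calibration fitted on out-of-fold decision values from an
internal cross-validation, so the calibration never sees the decision values
of points the SVM was fitted on.  The reported *certainty* is the top-class
calibrated posterior; for a binary classifier it therefore lives in
[0.5, 1].  Classifications with certainty < 0.9 (strictly) are flagged as
low-certainty and abstained from downstream diagnostic analysis.

Models serialize losslessly to a single JSON document (support vectors, dual
coefficients, scaler statistics, sigmoid coefficients, metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .beats_features import FEATURE_NAMES

AF_BINARY = "AF_BINARY"
AFL_3CLASS = "AFL_3CLASS"

CERTAINTY_GATE = 0.9
MIN_CLASS_COUNT = 5


@dataclass
class ClassifierConfig:
    C: float = 1.0
    kernel: str = "rbf"
    calibration_folds: int = 5
    gate: float = CERTAINTY_GATE
    min_class_count: int = MIN_CLASS_COUNT
    balanced_weights_3class: bool = True  # AFL is rare; reweight for it


@dataclass
class Classification:
    label: str  # "SR", "AF" or "AFL"
    certainty: float  # top-class calibrated posterior
    gated_low_certainty: bool
    posterior: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Platt sigmoid calibration
# ---------------------------------------------------------------------------


def fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit p(y=1|f) = 1 / (1 + exp(a f + b)) by penalized maximum likelihood.

    Uses Platt's prior-corrected targets so the map stays bounded away from
    0/1 on (near-)separable data.
    """
    decision = np.asarray(decision, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        # log(1+e^z) and z + log(1+e^-z), stably
        log1p_ez = np.logaddexp(0.0, z)
        return np.sum(t * log1p_ez + (1 - t) * (log1p_ez - z))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = res.x
    return float(a), float(b)


def platt_apply(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decision, dtype=float) + b
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# Serializable RBF-SVM + model container
# ---------------------------------------------------------------------------


@dataclass
class _BinarySvm:
    """Minimal RBF SVM evaluator: f(x) = sum_i alpha_i K(sv_i, x) + b."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    platt_a: float = -1.0
    platt_b: float = 0.0

    @classmethod
    def from_sklearn(cls, svc: SVC) -> "_BinarySvm":
        return cls(
            support_vectors=np.asarray(svc.support_vectors_),
            dual_coef=np.asarray(svc.dual_coef_[0]),
            intercept=float(svc.intercept_[0]),
            gamma=float(svc._gamma),
        )

    def decision(self, X: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2 * X @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        return np.exp(-self.gamma * np.maximum(d2, 0)) @ self.dual_coef + self.intercept

    def posterior_pos(self, X: np.ndarray) -> np.ndarray:
        return platt_apply(self.decision(X), self.platt_a, self.platt_b)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_BinarySvm":
        return cls(
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
        )


@dataclass
class TrainedModel:
    task: str  # AF_BINARY | AFL_3CLASS
    classes: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    submodels: list[_BinarySvm]  # 1 for binary, one-vs-rest per class for 3-class
    gate: float
    metadata: dict

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Calibrated class posteriors, rows summing to 1; column order = classes."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        Z = self._standardize(X)
        if self.task == AF_BINARY:
            p_pos = self.submodels[0].posterior_pos(Z)
            post = np.column_stack([1.0 - p_pos, p_pos])
        else:
            cols = [m.posterior_pos(Z) for m in self.submodels]
            post = np.column_stack(cols)
            post = post / post.sum(axis=1, keepdims=True)
        return post

    def to_json(self) -> str:
        doc = {
            "task": self.task,
            "classes": self.classes,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "submodels": [m.to_dict() for m in self.submodels],
            "gate": self.gate,
            "metadata": self.metadata,
        }
        return json.dumps(doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            task=d["task"],
            classes=list(d["classes"]),
            scaler_mean=np.array(d["scaler_mean"], dtype=float),
            scaler_scale=np.array(d["scaler_scale"], dtype=float),
            submodels=[_BinarySvm.from_dict(m) for m in d["submodels"]],
            gate=float(d["gate"]),
            metadata=d["metadata"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _task_frame(features: pd.DataFrame, task: str) -> pd.DataFrame:
    if task == AF_BINARY:
        return features[features["label"].isin(["SR", "AF"])].reset_index(drop=True)
    if task == AFL_3CLASS:
        return features[features["label"].isin(["SR", "AF", "AFL"])].reset_index(
            drop=True
        )
    raise ValueError(f"unknown task {task!r}")


def _balanced_sample_weight(y: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[v] for v in y])


def _fit_calibrated_ovr(
    Z: np.ndarray,
    y_bin: np.ndarray,
    cfg: ClassifierConfig,
    seed: int,
    balanced: bool,
) -> _BinarySvm:
    """Fit one RBF SVM for y_bin with Platt calibration on out-of-fold values."""
    sw = _balanced_sample_weight(y_bin) if balanced else None

    def make_svc() -> SVC:
        return SVC(C=cfg.C, kernel=cfg.kernel, gamma="scale")

    n_folds = min(cfg.calibration_folds, int(np.min(np.bincount(y_bin))))
    oof = np.zeros(len(y_bin))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(Z, y_bin):
        svc = make_svc()
        svc.fit(Z[tr], y_bin[tr], sample_weight=None if sw is None else sw[tr])
        oof[te] = svc.decision_function(Z[te])
    a, b = fit_platt(oof, y_bin)

    final = make_svc()
    final.fit(Z, y_bin, sample_weight=sw)
    model = _BinarySvm.from_sklearn(final)
    model.platt_a, model.platt_b = a, b
    return model


def train_classifier(
    features: pd.DataFrame,
    task: str = AF_BINARY,
    cfg: ClassifierConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrainedModel:
    """Train a rhythm classifier with fixed hyperparameters (no search).

    `features` needs columns ``subject_id``, ``label`` (SR/AF/AFL) and the 13
    feature columns.  Standardization statistics and calibration are fitted
    on the training data only and stored in the model.
    """
    cfg = cfg or ClassifierConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = int(rng.integers(2**31))

    df = _task_frame(features, task)
    counts = df["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to train")
    small = counts[counts < cfg.min_class_count]
    if len(small):
        raise ValueError(
            "refusing to train: class(es) with fewer than "
            f"{cfg.min_class_count} recordings: {dict(small)}"
        )

    X = df[FEATURE_NAMES].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale

    classes = ["SR", "AF"] if task == AF_BINARY else ["SR", "AF", "AFL"]
    if task == AF_BINARY:
        y = (df["label"] == "AF").to_numpy(int)
        submodels = [_fit_calibrated_ovr(Z, y, cfg, seed, balanced=False)]
    else:
        balanced = cfg.balanced_weights_3class
        submodels = [
            _fit_calibrated_ovr(
                Z, (df["label"] == c).to_numpy(int), cfg, seed + i, balanced
            )
            for i, c in enumerate(classes)
        ]

    metadata = {
        "task": task,
        "n_recordings": int(len(df)),
        "label_counts": {k: int(v) for k, v in counts.items()},
        "training_subjects": sorted(df["subject_id"].unique().tolist()),
        "hyperparameters": {"kernel": cfg.kernel, "C": cfg.C, "gamma": "scale"},
        "calibration": "platt_oof",
        "calibration_folds": cfg.calibration_folds,
        "seed": seed,
    }
    return TrainedModel(
        task=task,
        classes=classes,
        scaler_mean=mean,
        scaler_scale=scale,
        submodels=submodels,
        gate=cfg.gate,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict(model: TrainedModel, fv: np.ndarray | dict) -> Classification:
    """Classify one feature vector; certainty = top-class posterior."""
    if isinstance(fv, dict):
        fv = np.array([fv[k] for k in FEATURE_NAMES], dtype=float)
    post = model.posterior(np.asarray(fv, dtype=float))[0]
    i = int(np.argmax(post))
    certainty = float(post[i])
    return Classification(
        label=model.classes[i],
        certainty=certainty,
        gated_low_certainty=certainty < model.gate,
        posterior={c: float(p) for c, p in zip(model.classes, post)},
    )


def predict_batch(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Vectorized prediction; returns per-class posteriors, label, certainty."""
    X = features[FEATURE_NAMES].to_numpy(dtype=float)
    post = model.posterior(X)
    idx = post.argmax(axis=1)
    out = features.drop(columns=FEATURE_NAMES).copy()
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = post[:, j]
    out["pred_label"] = [model.classes[i] for i in idx]
    out["certainty"] = post[np.arange(len(idx)), idx]
    out["gated_low_certainty"] = out["certainty"] < model.gate
    return out


# ---------------------------------------------------------------------------
# Leave-one-subject-out cross-validation
# ---------------------------------------------------------------------------


def loso_cross_validate(
    features: pd.DataFrame,
    task: str = AF_BINARY,
    cfg: ClassifierConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One fold per subject; every prediction is out-of-subject.

    Returns the per-recording out-of-fold predictions with a ``fold_subject``
    column recording the held-out subject of each fold.
    """
    cfg = cfg or ClassifierConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    df = _task_frame(features, task)
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("LOSO cross-validation needs at least 3 subjects")

    fold_seeds = rng.integers(2**31, size=len(subjects))
    out_frames = []
    for subj, fseed in zip(subjects, fold_seeds):
        train_df = df[df["subject_id"] != subj]
        test_df = df[df["subject_id"] == subj]
        model = train_classifier(train_df, task, cfg, rng=int(fseed))
        assert subj not in model.metadata["training_subjects"]
        pred = predict_batch(model, test_df)
        pred["fold_subject"] = subj
        out_frames.append(pred)
    return pd.concat(out_frames, ignore_index=True)
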