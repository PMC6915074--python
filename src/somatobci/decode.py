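"""Linear SVM decoding under run-structured cross-validation.

Training features are z-scored per voxel with statistics computed on the
training rows only and reused unchanged at test time (no leakage); a
linear C-SVM (C = 1 by default) separates foot (+1) from hand (-1) trial
patterns. Cross-validation respects the run structure: leave-one-run-out,
train-on-k-runs/test-on-one over all combinations, and a simulated
real-time scheme that trains on the runs immediately preceding an answer
run. Discriminative weights averaged across splits and z-scored over the
mask form the somatotopy-bearing weight map (positive = foot evidence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .data_io import ANSWER_MEANING, LABEL_CLASSES, SubjectSession
from .features import FeatureConfig, TrialFeatures, extract_features


class DecodingError(ValueError):
    pass


@dataclass(frozen=True)
class SvmConfig:
    """Linear C-SVM settings (kernel fixed to linear)."""

    C: float = 1.0
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise DecodingError("C must be positive")


@dataclass
class SvmModel:
    """Fitted linear SVM plus the training standardisation it depends on."""

    weights: np.ndarray  # in standardised feature space
    bias: float
    train_mean: np.ndarray
    train_sd: np.ndarray  # zero-variance voxels carry sd = inf (zeroed out)

    @property
    def n_features(self) -> int:
        return self.weights.size

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.train_mean) / self.train_sd

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise DecodingError(
                f"feature dimension {X.shape[1]} != model {self.n_features}"
            )
        return self.standardize(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # ties at exactly 0 go to hand (-1)
        return np.where(self.decision_values(X) > 0, 1, -1)


def train_svm(features: TrialFeatures, cfg: SvmConfig | None = None) -> SvmModel:
    """Z-score per voxel on the training rows, then fit a linear C-SVM.

    Voxels with zero training variance are removed from the decision
    function (their standardised value is forced to 0 via an infinite sd).
    """
    cfg = cfg or SvmConfig()
    X, y = np.asarray(features.X, dtype=float), np.asarray(features.y)
    if len(np.unique(y)) < 2:
        raise DecodingError("training set must contain both classes")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, np.inf, sd)
    Xz = (X - mean) / sd_safe
    svc = SVC(kernel="linear", C=cfg.C, tol=cfg.tol)
    svc.fit(Xz, y)
    return SvmModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        train_mean=mean,
        train_sd=sd_safe,
    )


def test_svm(model: SvmModel, features: TrialFeatures):
    """Predictions (+ accuracy when labels are known) on held-out trials."""
    pred = model.predict(features.X)
    acc = float(np.mean(pred == features.y)) if features.y.size else np.nan
    return pred, acc


@dataclass
class Split:
    train_run_ids: tuple[str, ...]
    test_run_id: str
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    weights: np.ndarray
    bias: float


@dataclass
class DecodingResult:
    """Per-split predictions and weights of a run-structured CV."""

    splits: list[Split]
    mask_indices: np.ndarray | None = None
    voxel_coords: np.ndarray | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean([s.accuracy for s in self.splits]))

    @property
    def error(self) -> float:
        return 1.0 - self.accuracy

    @property
    def n_correct(self) -> int:
        return int(sum(np.sum(s.y_true == s.y_pred) for s in self.splits))

    @property
    def n_trials(self) -> int:
        return int(sum(len(s.y_true) for s in self.splits))

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for s in self.splits:
            for i, (t, p) in enumerate(zip(s.y_true, s.y_pred)):
                rows.append(
                    {
                        "run_id": s.test_run_id,
                        "trial_index": i,
                        "true": LABEL_CLASSES[int(t)],
                        "predicted": LABEL_CLASSES[int(p)],
                        "correct": bool(t == p),
                    }
                )
        return pd.DataFrame(rows)


def cv_leave_one_run_out(
    features: TrialFeatures, cfg: SvmConfig | None = None
) -> DecodingResult:
    """Each run serves once as the held-out test set."""
    runs = features.runs
    if len(runs) < 2:
        raise DecodingError("leave-one-run-out needs at least 2 runs")
    splits = []
    for test_run in runs:
        train_runs = tuple(r for r in runs if r != test_run)
        model = train_svm(features.subset_runs(train_runs), cfg)
        test = features.subset_runs([test_run])
        pred, acc = test_svm(model, test)
        splits.append(
            Split(
                train_run_ids=train_runs,
                test_run_id=test_run,
                y_true=test.y,
                y_pred=pred,
                accuracy=acc,
                weights=model.weights,
                bias=model.bias,
            )
        )
    return DecodingResult(
        splits=splits,
        mask_indices=features.mask_indices,
        voxel_coords=features.voxel_coords,
    )


def cv_training_size(
    features: TrialFeatures, cfg: SvmConfig | None = None, k: int | None = None
) -> pd.DataFrame:
    """Train on every k-subset of runs, test on each remaining run.

    Returns one row per (k, test run, training combination) with overall
    and per-class accuracies. With n runs and k = n - 1 this reduces to
    leave-one-run-out; k = 1 gives n x (n - 1) evaluations.
    """
    runs = features.runs
    n = len(runs)
    ks = range(1, n) if k is None else [k]
    rows = []
    for kk in ks:
        if not 1 <= kk <= n - 1:
            raise DecodingError(f"k={kk} out of range for {n} runs")
        for test_run in runs:
            others = [r for r in runs if r != test_run]
            for combo in combinations(others, kk):
                model = train_svm(features.subset_runs(combo), cfg)
                test = features.subset_runs([test_run])
                pred, acc = test_svm(model, test)
                foot = test.y == 1
                hand = test.y == -1
                rows.append(
                    {
                        "k": kk,
                        "test_run": test_run,
                        "train_runs": "+".join(combo),
                        "accuracy": acc,
                        "accuracy_foot": float(np.mean(pred[foot] == 1))
                        if foot.any()
                        else np.nan,
                        "accuracy_hand": float(np.mean(pred[hand] == -1))
                        if hand.any()
                        else np.nan,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class AnswerResult:
    """Decoded yes/no answer of one answer run."""

    run_id: str
    n_train: int
    predictions: np.ndarray  # +1 foot / -1 hand per trial
    encoded_class: str | None
    proportion_correct: float | None
    answer_call: str  # "yes" (hand majority) or "no" (foot majority)

    @property
    def call_correct(self) -> bool | None:
        if self.encoded_class is None:
            return None
        return self.answer_call == ANSWER_MEANING[self.encoded_class]


def decode_answer_run(
    predictions: np.ndarray, encoded_class: str | None
) -> tuple[float | None, str]:
    """Proportion correct vs the encoded class and the majority-vote call.

    Majority of hand (-1) predictions means "yes", majority of foot (+1)
    means "no"; exact ties (possible only for even trial counts) go to
    "yes"/hand, matching the tie convention of the decision function.
    """
    predictions = np.asarray(predictions)
    n_hand = int(np.sum(predictions == -1))
    call = "yes" if n_hand >= predictions.size - n_hand else "no"
    proportion = None
    if encoded_class is not None:
        from .data_io import CLASS_LABELS

        want = CLASS_LABELS[encoded_class]
        proportion = float(np.mean(predictions == want))
    return proportion, call


def simulated_realtime_decode(
    session: SubjectSession,
    answer_run,
    n_train: int,
    cfg: SvmConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    mask: np.ndarray | None = None,
) -> AnswerResult:
    """Replay the online answer-decoding procedure on recorded runs.

    Training uses the ``n_train`` runs immediately preceding the answer run
    in session order (temporal adjacency, as online). Features follow the
    real-time pipeline: 4 mm FWHM smoothing before the trial-wise GLM.
    ``answer_run`` is a Run or an index into ``session.answer_runs``.
    """
    if isinstance(answer_run, int):
        answer_run = session.answer_runs[answer_run]
    if not 1 <= n_train <= len(session.training_runs):
        raise DecodingError(
            f"n_train={n_train} with {len(session.training_runs)} training runs"
        )
    feature_cfg = feature_cfg or FeatureConfig.realtime()
    if mask is None:
        h = session.masks
        mask = h.select_indices(h.regions, min(h.levels(h.regions[0])))
    train_runs = session.training_runs[-n_train:]
    train_feats = extract_features(train_runs, mask, feature_cfg)
    model = train_svm(train_feats, cfg)
    answer_feats = extract_features([answer_run], mask, feature_cfg)
    pred = model.predict(answer_feats.X)

    conditions = set(answer_run.events.frame["condition"])
    encoded = conditions.pop() if len(conditions) == 1 else None
    proportion, call = decode_answer_run(pred, encoded)
    return AnswerResult(
        run_id=answer_run.meta.run_id,
        n_train=n_train,
        predictions=pred,
        encoded_class=encoded,
        proportion_correct=proportion,
        answer_call=call,
    )


@dataclass
class WeightMap:
    """Split-averaged, z-scored discriminative weights on mask voxels.

    Positive values vote for foot imagery, negative for hand imagery.
    """

    values: np.ndarray
    voxel_coords: np.ndarray
    mask_indices: np.ndarray | None = None
    grid_shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def to_nifti(self) -> nib.Nifti1Image:
        if self.grid_shape is None or self.affine is None:
            raise ValueError("weight map lacks grid information")
        vol = np.zeros(int(np.prod(self.grid_shape)), dtype=np.float32)
        vol[self.mask_indices] = self.values
        return nib.Nifti1Image(vol.reshape(self.grid_shape), self.affine)


def average_weight_map(
    result: DecodingResult,
    voxel_coords: np.ndarray | None = None,
    grid_shape=None,
    affine=None,
) -> WeightMap:
    """Element-wise mean of split weights, z-scored across mask voxels."""
    if not result.splits:
        raise DecodingError("no splits with weights")
    W = np.vstack([s.weights for s in result.splits])
    mean_w = W.mean(axis=0)
    sd = mean_w.std(ddof=0)
    if sd == 0:
        z = np.zeros_like(mean_w)
    else:
        z = (mean_w - mean_w.mean()) / sd
    coords = voxel_coords if voxel_coords is not None else result.voxel_coords
    if coords is None:
        raise DecodingError("voxel coordinates required for a weight map")
    return WeightMap(
        values=z,
        voxel_coords=np.asarray(coords),
        mask_indices=result.mask_indices,
        grid_shape=grid_shape,
        affine=affine,
    )
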