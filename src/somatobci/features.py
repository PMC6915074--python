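"""Trial-wise GLM feature extraction.

Each imagery trial is summarised, per voxel, by the t-statistic of a
two-regressor ordinary-least-squares fit (intercept + hrf-convolved trial
boxcar) inside a fixed peri-trial window: one volume (2 s) before the
auditory cue to 14 volumes (28 s) after it, i.e. 16 volumes at TR 2. The
trials-by-voxels t-value matrix is the multivariate feature set handed to
the decoder.

Each trial is fitted separately; hemodynamic spill-over from neighbouring
trials is deliberately not modelled. Slow drift is absorbed by the
intercept (an optional linear-trend column is available); full temporal
filtering belongs to preprocessing, which is outside this pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .data_io import CLASS_LABELS, Run, SubjectSession
from .hrf import HrfModel, convolve_boxcar

#: zero-residual trials get this sentinel t so downstream z-scoring stays finite
T_SENTINEL = 1e6


class FeatureExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Peri-trial window and preprocessing of the trial-wise GLM.

    ``window_pre``/``window_post`` are counted in volumes around the cue
    (defaults 1 and 14: a 16-volume window). ``smoothing_fwhm`` (mm)
    enables volume-wise Gaussian smoothing before fitting; the real-time
    pipeline uses 4 mm, the offline pipeline none.
    """

    window_pre: int = 1
    window_post: int = 14
    hrf: HrfModel = field(default_factory=HrfModel)
    smoothing_fwhm: float = 0.0
    linear_trend: bool = False

    @property
    def window_length(self) -> int:
        return self.window_pre + 1 + self.window_post

    @classmethod
    def realtime(cls, **overrides) -> "FeatureConfig":
        overrides.setdefault("smoothing_fwhm", 4.0)
        return cls(**overrides)


@dataclass
class TrialFeatures:
    """Trials x voxels t-value matrix with labels and run bookkeeping.

    Labels follow the project-wide convention foot = +1, hand = -1. Rows
    are grouped by run in acquisition order.
    """

    X: np.ndarray
    y: np.ndarray
    run_ids: np.ndarray
    trial_onsets: np.ndarray
    mask_indices: np.ndarray | None = None
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.run_ids) == len(self.trial_onsets) == n):
            raise ValueError("inconsistent trial bookkeeping")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def runs(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.run_ids:
            seen.setdefault(str(r), None)
        return list(seen)

    def subset_runs(self, run_ids: Sequence[str]) -> "TrialFeatures":
        keep = np.isin(self.run_ids, list(run_ids))
        return TrialFeatures(
            X=self.X[keep],
            y=self.y[keep],
            run_ids=self.run_ids[keep],
            trial_onsets=self.trial_onsets[keep],
            mask_indices=self.mask_indices,
            voxel_coords=self.voxel_coords,
        )

    def with_labels(self, y: np.ndarray) -> "TrialFeatures":
        return TrialFeatures(
            X=self.X,
            y=np.asarray(y),
            run_ids=self.run_ids,
            trial_onsets=self.trial_onsets,
            mask_indices=self.mask_indices,
            voxel_coords=self.voxel_coords,
        )


def trial_regressor(
    trial_onset: float,
    trial_duration: float,
    window_times: np.ndarray,
    hrf: HrfModel,
) -> np.ndarray:
    """Hrf-convolved trial boxcar sampled at the window's volume times.

    ``window_times`` are absolute times (s); the boxcar is one on
    [onset, onset + duration). Causality makes pre-cue samples exactly 0.
    """
    window_times = np.asarray(window_times, dtype=float)
    if trial_duration <= 0:
        return np.zeros_like(window_times)
    return convolve_boxcar(window_times, [trial_onset], [trial_duration], hrf)


def fit_trial_glm(y: np.ndarray, x: np.ndarray, linear_trend: bool = False):
    """OLS t-value(s) of ``y`` on [1, x] (optionally + linear trend).

    ``y`` may be a single window (n,) or stacked voxels (v, n). Returns the
    t-statistic of the trial-regressor slope with n - p degrees of freedom.
    A perfect fit (zero residual variance) yields the signed sentinel
    ``T_SENTINEL`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise FeatureExtractionError("window needs at least 3 samples")
    if np.ptp(x) == 0:
        raise FeatureExtractionError("constant trial regressor")
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != n:
        raise FeatureExtractionError("signal window and regressor disagree")

    cols = [np.ones(n), x]
    if linear_trend:
        cols.append(np.arange(n, dtype=float))
    X = np.column_stack(cols)
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # p x v
    resid = Y.T - X @ beta
    rss = np.sum(resid**2, axis=0)
    df = n - p
    scale = np.maximum(np.sum(Y**2, axis=1), 1.0)
    perfect = rss <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df * XtX_inv[1, 1])
        t = beta[1] / se
    if np.any(perfect):
        warnings.warn(
            "zero residual variance: t capped at sentinel", stacklevel=2
        )
        t[perfect] = np.where(beta[1][perfect] >= 0, T_SENTINEL, -T_SENTINEL)
        t[perfect & (beta[1] == 0)] = 0.0
    t = np.clip(t, -T_SENTINEL, T_SENTINEL)
    return float(t[0]) if single else t


def _smooth_run(run: Run, fwhm: float) -> np.ndarray:
    """Volume-wise Gaussian smoothing on the run's 3D grid."""
    voxel_sizes = np.abs(np.diag(run.affine)[:3])
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_sizes
    vols = run.data.reshape(*run.grid_shape, run.meta.n_volumes)
    smoothed = ndimage.gaussian_filter(
        np.asarray(vols, dtype=np.float64), sigma=(*sigma_vox, 0.0)
    )
    return smoothed.reshape(run.data.shape)


def extract_features(
    runs: SubjectSession | Sequence[Run],
    mask: np.ndarray,
    cfg: FeatureConfig | None = None,
) -> TrialFeatures:
    """One t-value row per imagery trial of every requested run.

    ``runs`` may be a session (its training runs are used) or an explicit
    run sequence; ``mask`` is a flat voxel-index array (or boolean mask)
    over the session grid. Six training runs with nine trials per class
    yield 54 feature rows per class; five runs yield 45.
    """
    cfg = cfg or FeatureConfig()
    if isinstance(runs, SubjectSession):
        run_list = runs.training_runs
    else:
        run_list = list(runs)
    if not run_list:
        raise FeatureExtractionError("no runs to extract from")
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if mask.size == 0:
        raise FeatureExtractionError("empty mask: no features to extract")

    rows, labels, run_ids, onsets = [], [], [], []
    for run in run_list:
        tr = run.meta.tr
        data = (
            _smooth_run(run, cfg.smoothing_fwhm)
            if cfg.smoothing_fwhm > 0
            else run.data
        )
        data = np.asarray(data[mask], dtype=np.float64)
        for trial_index, ev in enumerate(run.events):
            onset_idx = int(round(ev.onset / tr))
            if abs(onset_idx * tr - ev.onset) > 1e-6:
                raise FeatureExtractionError(
                    f"{run.meta.run_id} trial {trial_index}: onset "
                    f"{ev.onset} s is not volume-aligned at TR {tr}"
                )
            lo = onset_idx - cfg.window_pre
            hi = onset_idx + cfg.window_post
            if lo < 0 or hi >= run.meta.n_volumes:
                raise FeatureExtractionError(
                    f"{run.meta.run_id} trial {trial_index}: window "
                    f"[{lo}, {hi}] exceeds run bounds"
                )
            window_times = np.arange(lo, hi + 1) * tr
            reg = trial_regressor(ev.onset, ev.duration, window_times, cfg.hrf)
            t = fit_trial_glm(
                data[:, lo : hi + 1], reg, linear_trend=cfg.linear_trend
            )
            rows.append(t)
            labels.append(CLASS_LABELS[ev.condition])
            run_ids.append(run.meta.run_id)
            onsets.append(ev.onset)
    if not rows:
        raise FeatureExtractionError("runs contain no imagery trials")
    first_run = run_list[0]
    return TrialFeatures(
        X=np.vstack(rows),
        y=np.asarray(labels),
        run_ids=np.asarray(run_ids),
        trial_onsets=np.asarray(onsets),
        mask_indices=mask,
        voxel_coords=first_run.voxel_coords[mask],
    )
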