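"""Shared data model and NIfTI / events-table input-output.

A :class:`Run` is one continuous fMRI acquisition: a voxels-by-volumes
signal matrix with its repetition time, event table and per-voxel world
coordinates (mm) derived from the NIfTI affine.

Coordinate convention (used everywhere in the package): world x is
positive toward the subject's right. Under this convention the foot
representation of the left-foot imagery condition sits at positive x
(medial, right hemisphere) and the right-hand representation at negative x
(lateral, left hemisphere).

Event tables carry times in seconds from the first retained volume. Any
discarding of initial volumes is the generator's / preprocessing's concern;
``read_run`` performs no trimming.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

CONDITIONS = ("foot", "hand")

#: numeric class labels used project-wide: foot = +1 ("no"), hand = -1 ("yes")
CLASS_LABELS = {"foot": 1, "hand": -1}
LABEL_CLASSES = {1: "foot", -1: "hand"}
ANSWER_MEANING = {"hand": "yes", "foot": "no"}


class EventValidationError(ValueError):
    """An events table violates the design invariants."""


class DimensionError(ValueError):
    """A volume file does not have the expected dimensionality."""


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class EventTable:
    """Imagery events of one run: onset (s), duration (s), condition.

    Onsets are strictly increasing and imagery blocks never overlap.
    BIDS-style ``trial_type`` is accepted as a synonym of ``condition``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "trial_type" in df.columns and "condition" not in df.columns:
            df = df.rename(columns={"trial_type": "condition"})
        missing = {"onset", "duration", "condition"} - set(df.columns)
        if missing:
            raise EventValidationError(
                f"events table missing columns: {sorted(missing)}"
            )
        df = df.loc[:, ["onset", "duration", "condition"]].reset_index(drop=True)
        df["onset"] = df["onset"].astype(float)
        df["duration"] = df["duration"].astype(float)
        for i, row in df.iterrows():
            if row.duration <= 0:
                raise EventValidationError(
                    f"row {i}: non-positive duration {row.duration}"
                )
            if i > 0:
                prev = df.iloc[i - 1]
                if row.onset <= prev.onset:
                    raise EventValidationError(
                        f"row {i}: onsets not strictly increasing"
                    )
                if row.onset < prev.onset + prev.duration:
                    raise EventValidationError(
                        f"row {i}: event overlaps previous block"
                    )
        object.__setattr__(self, "frame", df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[float, float, str]]
    ) -> "EventTable":
        return cls(
            pd.DataFrame(records, columns=["onset", "duration", "condition"])
        )

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(pd.DataFrame(columns=["onset", "duration", "condition"]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def class_counts(self) -> pd.Series:
        return self.frame["condition"].value_counts()

    def __iter__(self):
        return iter(self.frame.itertuples(index=False))

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# runs


@dataclass(frozen=True)
class RunMeta:
    run_id: str
    tr: float = 2.0
    n_volumes: int = 0
    run_kind: str = "training"  # "training" | "answer"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_volumes <= 0:
            raise ValueError("n_volumes must be positive")
        if self.run_kind not in ("training", "answer"):
            raise ValueError(f"unknown run_kind {self.run_kind!r}")


@dataclass
class Run:
    """One functional run on a fixed voxel grid.

    ``data`` is voxels x volumes (C-order flattening of the i,j,k grid);
    ``voxel_coords`` holds the matching world coordinates in mm.
    """

    meta: RunMeta
    data: np.ndarray
    events: EventTable
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise DimensionError("run data must be voxels x volumes")
        if self.data.shape[1] != self.meta.n_volumes:
            raise ValueError(
                f"data has {self.data.shape[1]} volumes, "
                f"meta says {self.meta.n_volumes}"
            )
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError("voxel_coords must be voxels x 3")
        if int(np.prod(self.grid_shape)) != self.data.shape[0]:
            raise ValueError("grid_shape inconsistent with voxel count")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.meta.n_volumes) * self.meta.tr


@dataclass
class SubjectSession:
    """All runs of one synthetic subject on a common voxel grid."""

    training_runs: list[Run]
    answer_runs: list[Run] = field(default_factory=list)
    masks: "object | None" = None  # MaskHierarchy; avoids circular import
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        runs = self.training_runs + self.answer_runs
        if not runs:
            raise ValueError("session needs at least one run")
        shape = runs[0].grid_shape
        for r in runs:
            if r.grid_shape != shape:
                raise ValueError("all runs must share one voxel grid")

    @property
    def all_runs(self) -> list[Run]:
        return self.training_runs + self.answer_runs


def grid_world_coords(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel, C-order flattened."""
    idx = np.indices(tuple(shape)).reshape(3, -1).T
    return nib.affines.apply_affine(affine, idx)


def read_run(
    volume_path: str | Path,
    events_path: str | Path,
    run_id: str | None = None,
    run_kind: str = "training",
) -> Run:
    """Load a 4D NIfTI plus its tab-separated events file.

    Raises :class:`DimensionError` for non-4D images and
    :class:`EventValidationError` for malformed event tables. Conditions
    are restricted to foot / hand.
    """
    img = nib.load(str(volume_path))
    if img.ndim != 4:
        raise DimensionError(
            f"{volume_path}: expected a 4D volume, got {img.ndim}D"
        )
    arr = np.asarray(img.get_fdata(), dtype=np.float64)
    shape = arr.shape[:3]
    data = arr.reshape(-1, arr.shape[3])
    events = EventTable.from_tsv(events_path)
    bad = set(events.frame["condition"]) - set(CONDITIONS)
    if bad:
        raise EventValidationError(f"unknown conditions {sorted(bad)}")
    tr = float(img.header.get_zooms()[3]) if img.header.get_zooms()[3] else 2.0
    meta = RunMeta(
        run_id=run_id or Path(volume_path).name.split(".")[0],
        tr=tr,
        n_volumes=arr.shape[3],
        run_kind=run_kind,
    )
    return Run(
        meta=meta,
        data=data,
        events=events,
        voxel_coords=grid_world_coords(shape, img.affine),
        grid_shape=tuple(shape),
        affine=np.asarray(img.affine),
    )


def write_run(run: Run, volume_path: str | Path, events_path: str | Path) -> None:
    """Write a run as 4D NIfTI (float32) + events.tsv."""
    arr = run.data.reshape(*run.grid_shape, run.meta.n_volumes)
    img = nib.Nifti1Image(arr.astype(np.float32), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.meta.tr))
    nib.save(img, str(volume_path))
    run.events.to_tsv(events_path)


# ---------------------------------------------------------------------------
# result output


def config_hash(obj) -> str:
    """Stable short hash of a (nested dataclass / dict) configuration."""

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: norm(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {str(k): norm(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [norm(v) for v in o]
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    payload = json.dumps(norm(obj), sort_keys=True).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_results(results, path: str | Path, config=None, seed: int | None = None) -> dict:
    """Write pipeline outputs to ``path`` and return the JSON manifest.

    Tabular results become CSV, maps become NIfTI; the manifest lists every
    file with its configuration hash and seed.
    """
    from .decode import DecodingResult, WeightMap  # local: avoid cycle

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def save_frame(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        files.append(name)

    if isinstance(results, DecodingResult):
        save_frame(results.trial_table(), "trial_predictions.csv")
    elif isinstance(results, WeightMap):
        nib.save(results.to_nifti(), str(out / "weight_map.nii.gz"))
        files.append("weight_map.nii.gz")
    elif isinstance(results, Run):
        write_run(results, out / "run.nii.gz", out / "events.tsv")
        files += ["run.nii.gz", "events.tsv"]
    elif isinstance(results, pd.DataFrame):
        save_frame(results, "results.csv")
    elif isinstance(results, dict):
        for key, value in results.items():
            if isinstance(value, pd.DataFrame):
                save_frame(value, f"{key}.csv")
            else:
                (out / f"{key}.json").write_text(json.dumps(value, indent=2, default=float))
                files.append(f"{key}.json")
    else:
        raise TypeError(f"cannot serialise result of type {type(results).__name__}")

    manifest = {
        "files": sorted(files),
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
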