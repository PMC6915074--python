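"""Synthetic subject generator.

Emulates the temporal and spatial structure of a somatosensory-imagery
block-design BCI experiment so every downstream stage (feature extraction,
decoding, inference, somatotopy) is testable without real data:

* classifier-training runs: a pseudorandom sequence of 9 left-foot and 9
  right-hand imagery trials of 18 s, each followed by a 16, 18 or 20 s rest
  (balanced multiset), at TR = 2 s — 340 volumes per run under defaults;
* answer runs: 5 trials of one class (the encoded yes/no answer), 96
  volumes under defaults;
* a somatotopic spatial layout: a foot-selective cluster at medial/right
  world x and a hand-selective cluster at lateral/left x inside an "S1"
  band, plus a weaker, spatially mixed cluster in an "S2" band;
* hemodynamically convolved boxcar responses on a baseline, with Gaussian
  noise and a slow sinusoidal drift;
* nested probability-level masks that shrink as the level rises.

All randomness flows through explicit seeds; identical seeds give
bit-identical sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data_io import EventTable, Run, RunMeta, SubjectSession, grid_world_coords
from .hrf import HrfModel, convolve_boxcar
from .masks import MaskHierarchy


class ConfigError(ValueError):
    """Inconsistent generator configuration."""


# ---------------------------------------------------------------------------
# temporal design


@dataclass(frozen=True)
class DesignSpec:
    """Trial/rest timing of one run.

    Defaults reproduce the study design: 9 trials per class of 18 s with
    rests drawn without replacement from a balanced {16, 18, 20} s multiset,
    16 s lead-in and trailing rest (340 volumes at TR 2); answer runs have
    5 trials, 18 s rests and a 12 s lead-in (96 volumes). Lead-in and
    trailing rest are reconciliation choices that make the stated volume
    counts exact.
    """

    n_trials_per_class: int = 9
    trial_duration: float = 18.0
    rest_durations: tuple[float, ...] | None = None
    lead_in: float = 16.0
    trailing_rest: float = 16.0
    n_answer_trials: int = 5
    answer_rest: float = 18.0
    answer_lead_in: float = 12.0

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_class

    def rest_multiset(self) -> tuple[float, ...]:
        """One rest duration per trial; balanced 16/18/20 cycle by default."""
        if self.rest_durations is not None:
            rests = tuple(float(r) for r in self.rest_durations)
            if len(rests) != self.n_trials:
                raise ConfigError(
                    f"rest multiset has {len(rests)} entries for "
                    f"{self.n_trials} trials"
                )
            return rests
        base = (16.0, 18.0, 20.0)
        return tuple(base[i % 3] for i in range(self.n_trials))

    def total_duration(self, run_kind: str = "training") -> float:
        if run_kind == "training":
            return (
                self.lead_in
                + self.n_trials * self.trial_duration
                + sum(self.rest_multiset())
                + self.trailing_rest
            )
        return self.answer_lead_in + self.n_answer_trials * (
            self.trial_duration + self.answer_rest
        )

    def n_volumes(self, tr: float, run_kind: str = "training") -> int:
        total = self.total_duration(run_kind)
        n, rem = divmod(total, tr)
        if rem > 1e-9:
            raise ConfigError(
                f"run duration {total} s is not a multiple of TR {tr} s"
            )
        return int(round(n))


def make_design(
    spec: DesignSpec,
    seed: int,
    run_kind: str = "training",
    answer_class: str | None = None,
) -> EventTable:
    """Pseudorandom balanced class order with without-replacement rests.

    Deterministic given ``seed``. Answer runs repeat the encoded class for
    every trial with a fixed rest.
    """
    if run_kind == "answer":
        if answer_class not in ("foot", "hand"):
            raise ConfigError("answer runs need answer_class foot or hand")
        step = spec.trial_duration + spec.answer_rest
        records = [
            (spec.answer_lead_in + i * step, spec.trial_duration, answer_class)
            for i in range(spec.n_answer_trials)
        ]
        return EventTable.from_records(records)

    if spec.n_trials_per_class == 0:
        return EventTable.empty()
    rng = np.random.default_rng(seed)
    order = np.array(
        ["foot"] * spec.n_trials_per_class + ["hand"] * spec.n_trials_per_class
    )
    rng.shuffle(order)
    rests = np.array(spec.rest_multiset())
    rng.shuffle(rests)
    records = []
    t = spec.lead_in
    for cond, rest in zip(order, rests):
        records.append((t, spec.trial_duration, str(cond)))
        t += spec.trial_duration + rest
    return EventTable.from_records(records)


# ---------------------------------------------------------------------------
# spatial layout


_DEFAULT_HALF_EXTENT = (39.0, 39.0, 19.0)  # default 40x40x20 grid at 2 mm


@dataclass(frozen=True)
class SomatotopicLayout:
    """Spatial ground truth of the synthetic somatotopic signal.

    World x is positive toward the subject's right, so the (left-) foot
    cluster sits at positive/medial x and the (right-) hand cluster at
    negative/lateral x; the layout invariant foot_centroid_x >
    hand_centroid_x encodes exactly that. Selectivities are response
    weights in [0, 1]: a foot-cluster voxel responds to foot blocks with
    weight ``s1_selectivity`` and to hand blocks with the complement.
    The S2 cluster responds with the weaker ``s2_selectivity`` and
    checkerboard-mixed class preference.
    """

    foot_centroid_x: float = 10.0
    hand_centroid_x: float = -30.0
    cluster_radius: float = 8.0
    s1_selectivity: float = 0.9
    s2_selectivity: float = 0.4
    s2_mixing: float = 0.5
    # geometry of the cortical bands (mm, in-plane core of each cylinder)
    s1_core_y: float = -4.0
    s1_core_z: float = 8.0
    s2_core_y: float = 12.0
    s2_core_z: float = -12.0
    s2_cluster_x: float = -10.0
    mask_radius_low: float = 12.0  # cylinder radius at the lowest level
    mask_radius_high: float = 5.0  # cylinder radius at the 80% level

    def __post_init__(self) -> None:
        if not self.foot_centroid_x > self.hand_centroid_x:
            raise ConfigError(
                "foot centroid must be right (positive x) of hand centroid"
            )
        for name in ("s1_selectivity", "s2_selectivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")

    @classmethod
    def for_grid(
        cls, grid_shape, voxel_size: float = 2.0, **overrides
    ) -> "SomatotopicLayout":
        """Scale the default geometry onto an arbitrary centred grid."""
        half = [(n - 1) * voxel_size / 2 for n in grid_shape]
        fx, fy, fz = (h / d for h, d in zip(half, _DEFAULT_HALF_EXTENT))
        fr = min(fy, fz)
        scaled = dict(
            foot_centroid_x=round(10.0 * fx, 1),
            hand_centroid_x=round(-30.0 * fx, 1),
            cluster_radius=max(3.0, round(8.0 * fr, 1)),
            s1_core_y=round(-4.0 * fy, 1),
            s1_core_z=round(8.0 * fz, 1),
            s2_core_y=round(12.0 * fy, 1),
            s2_core_z=round(-12.0 * fz, 1),
            s2_cluster_x=round(-10.0 * fx, 1),
            mask_radius_low=max(4.0, round(12.0 * fr, 1)),
            mask_radius_high=max(2.0, round(5.0 * fr, 1)),
        )
        scaled.update(overrides)
        return cls(**scaled)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise plus a slow sinusoidal drift (< 0.01 Hz)."""

    sigma: float = 1.0
    drift_amplitude: float = 0.5
    drift_period: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError("sigma must be non-negative")
        if self.drift_period <= 0:
            raise ConfigError("drift_period must be positive")


def centered_affine(grid_shape, voxel_size: float = 2.0) -> np.ndarray:
    """Axis-aligned affine placing the grid centre at world origin."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    aff[:3, 3] = [-(n - 1) * voxel_size / 2 for n in grid_shape]
    return aff


def make_masks(
    grid_shape,
    affine: np.ndarray,
    levels,
    layout: SomatotopicLayout,
) -> MaskHierarchy:
    """Nested S1/S2 probability-level masks on the given grid.

    Each region is a cylinder around a core line parallel to the x axis;
    the radius shrinks linearly with the probability level (through the
    layout's low/80% radii), which makes nesting automatic and mirrors the
    atlas property that higher-probability masks are smaller. S1 contains
    both class centroids; S2 is a disjoint band.
    """
    levels = sorted(int(l) for l in levels)
    if not levels or levels[0] <= 0 or levels[-1] > 100:
        raise ConfigError("levels must be percentages in (0, 100]")
    coords = grid_world_coords(grid_shape, affine)
    vox = float(abs(affine[0, 0]))

    def radius(level: int) -> float:
        r = layout.mask_radius_low + (
            layout.mask_radius_high - layout.mask_radius_low
        ) * (level - levels[0]) / max(80 - levels[0], 1)
        return max(r, vox / 2)

    d_s1 = np.hypot(
        coords[:, 1] - layout.s1_core_y, coords[:, 2] - layout.s1_core_z
    )
    d_s2 = np.hypot(
        coords[:, 1] - layout.s2_core_y, coords[:, 2] - layout.s2_core_z
    )
    masks = {
        "S1": {lev: d_s1 <= radius(lev) for lev in levels},
        "S2": {lev: d_s2 <= radius(lev) for lev in levels},
    }
    if np.any(masks["S1"][levels[0]] & masks["S2"][levels[0]]):
        raise ConfigError("S1 and S2 bands overlap; move the cores apart")
    return MaskHierarchy(
        masks=masks,
        voxel_coords=coords,
        grid_shape=tuple(grid_shape),
        affine=np.asarray(affine),
    )


def response_weights(
    layout: SomatotopicLayout, grid_shape, affine: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel response weights (foot_w, hand_w) over the flat grid.

    Cluster responses fall off as a Gaussian of the distance to the
    centroid (sigma = cluster_radius / 2) and are zero outside the cluster
    sphere. The S2 cluster alternates class preference on a voxel
    checkerboard, giving the weaker, spatially mixed code.
    """
    coords = grid_world_coords(grid_shape, affine)
    foot_w = np.zeros(coords.shape[0])
    hand_w = np.zeros(coords.shape[0])
    sigma = layout.cluster_radius / 2.0

    def bump(center):
        d = np.linalg.norm(coords - np.asarray(center), axis=1)
        g = np.exp(-(d**2) / (2 * sigma**2))
        g[d > layout.cluster_radius] = 0.0
        return g

    g_foot = bump((layout.foot_centroid_x, layout.s1_core_y, layout.s1_core_z))
    g_hand = bump((layout.hand_centroid_x, layout.s1_core_y, layout.s1_core_z))
    foot_w += layout.s1_selectivity * g_foot + (1 - layout.s1_selectivity) * g_hand
    hand_w += layout.s1_selectivity * g_hand + (1 - layout.s1_selectivity) * g_foot

    g_s2 = bump((layout.s2_cluster_x, layout.s2_core_y, layout.s2_core_z))
    ijk = np.indices(tuple(grid_shape)).reshape(3, -1)
    prefers_foot = (ijk.sum(axis=0) % 2) == 0
    s2_hi = layout.s2_selectivity
    s2_lo = layout.s2_selectivity * layout.s2_mixing
    foot_w += g_s2 * np.where(prefers_foot, s2_hi, s2_lo)
    hand_w += g_s2 * np.where(prefers_foot, s2_lo, s2_hi)
    return foot_w, hand_w


# ---------------------------------------------------------------------------
# run / subject simulation


def simulate_run(
    spec: DesignSpec,
    layout: SomatotopicLayout,
    hrf: HrfModel,
    noise: NoiseModel,
    masks: MaskHierarchy,
    amplitude: float,
    run_kind: str = "training",
    answer_class: str | None = None,
    tr: float = 2.0,
    run_id: str = "run",
    seed: int | None = None,
    baseline: float = 100.0,
) -> Run:
    """One synthetic run on the hierarchy's grid.

    Voxel time series = baseline + amplitude x (selectivity-weighted,
    hrf-convolved class boxcars) + drift + Gaussian noise. With zero noise
    and zero drift a foot-cluster voxel's demeaned time course equals the
    scaled convolved foot regressor exactly.
    """
    if amplitude < 0:
        raise ConfigError("amplitude must be non-negative")
    seed = noise.seed if seed is None else int(seed)
    events = make_design(spec, seed, run_kind=run_kind, answer_class=answer_class)
    n_vol = spec.n_volumes(tr, run_kind)
    times = np.arange(n_vol) * tr

    foot_w, hand_w = response_weights(layout, masks.grid_shape, masks.affine)
    n_vox = foot_w.size
    data = np.full((n_vox, n_vol), baseline, dtype=np.float64)
    if amplitude > 0 and len(events) > 0:
        df = events.frame
        for cond, w in (("foot", foot_w), ("hand", hand_w)):
            sub = df[df.condition == cond]
            if len(sub):
                reg = convolve_boxcar(
                    times, sub.onset.to_numpy(), sub.duration.to_numpy(), hrf
                )
                data += amplitude * np.outer(w, reg)

    rng = np.random.default_rng(seed)
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi, size=n_vox)
        data += noise.drift_amplitude * np.sin(
            2 * np.pi * times[None, :] / noise.drift_period + phase[:, None]
        )
    if noise.sigma > 0:
        data += rng.normal(0.0, noise.sigma, size=(n_vox, n_vol))

    meta = RunMeta(run_id=run_id, tr=tr, n_volumes=n_vol, run_kind=run_kind)
    return Run(
        meta=meta,
        data=data.astype(np.float32),
        events=events,
        voxel_coords=masks.voxel_coords,
        grid_shape=masks.grid_shape,
        affine=masks.affine,
    )


@dataclass
class GeneratorConfig:
    """Full configuration of a synthetic subject session."""

    grid_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size: float = 2.0
    tr: float = 2.0
    n_training_runs: int = 6
    n_answer_runs: int = 2
    answer_classes: tuple[str, ...] | None = None  # default: alternate hand/foot
    amplitude: float = 1.0
    amplitude_jitter: float = 0.0
    mask_levels: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    design: DesignSpec = field(default_factory=DesignSpec)
    layout: SomatotopicLayout | None = None  # default: scaled to the grid
    hrf: HrfModel = field(default_factory=HrfModel)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def resolved_layout(self) -> SomatotopicLayout:
        if self.layout is not None:
            return self.layout
        return SomatotopicLayout.for_grid(self.grid_shape, self.voxel_size)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_subject(config: GeneratorConfig, seed: int) -> SubjectSession:
    """Generate one subject: training runs, answer runs, masks, ground truth.

    Per-run design/noise seeds are drawn from a master generator seeded by
    ``seed``, so the whole session is reproducible from (config, seed).
    """
    if config.n_training_runs < 1:
        raise ConfigError("need at least one training run")
    layout = config.resolved_layout()
    affine = centered_affine(config.grid_shape, config.voxel_size)
    hierarchy = make_masks(config.grid_shape, affine, config.mask_levels, layout)
    rng = np.random.default_rng(seed)

    def run_amplitude() -> float:
        if config.amplitude_jitter > 0:
            jit = rng.uniform(-config.amplitude_jitter, config.amplitude_jitter)
            return max(0.0, config.amplitude * (1 + jit))
        return config.amplitude

    def draw_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    training = [
        simulate_run(
            config.design,
            layout,
            config.hrf,
            config.noise,
            hierarchy,
            run_amplitude(),
            run_kind="training",
            tr=config.tr,
            run_id=f"run-{i + 1:02d}",
            seed=draw_seed(),
        )
        for i in range(config.n_training_runs)
    ]
    classes = config.answer_classes or tuple(
        ("hand", "foot")[i % 2] for i in range(config.n_answer_runs)
    )
    if len(classes) != config.n_answer_runs:
        raise ConfigError("answer_classes length must match n_answer_runs")
    answers = [
        simulate_run(
            config.design,
            layout,
            config.hrf,
            config.noise,
            hierarchy,
            run_amplitude(),
            run_kind="answer",
            answer_class=cls,
            tr=config.tr,
            run_id=f"run-{config.n_training_runs + i + 1:02d}",
            seed=draw_seed(),
        )
        for i, cls in enumerate(classes)
    ]

    foot_w, hand_w = response_weights(layout, config.grid_shape, affine)
    ground_truth = {
        "foot_centroid_x": layout.foot_centroid_x,
        "hand_centroid_x": layout.hand_centroid_x,
        "cluster_radius": layout.cluster_radius,
        "foot_cluster": np.flatnonzero(foot_w > hand_w),
        "hand_cluster": np.flatnonzero(hand_w > foot_w),
        "amplitude": config.amplitude,
        "seed": int(seed),
    }
    return SubjectSession(
        training_runs=training,
        answer_runs=answers,
        masks=hierarchy,
        ground_truth=ground_truth,
    )
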