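"""End-to-end orchestration of the synthetic study.

``run_full_study`` strings every stage together for a cohort of generated
subjects: feature extraction from the most inclusive S1 + S2 mask,
leave-one-run-out decoding with permutation inference, the
training-set-size analysis with repeated-measures ANOVA and polynomial
contrasts, the S1-vs-S2 probability-level comparison under the >500-voxel
inclusion rule, simulated real-time answer decoding in the answer-table
layout, and the somatotopy summary with cohort-level Wilcoxon and
Spearman statistics. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .data_io import config_hash
from .decode import (
    SvmConfig,
    average_weight_map,
    cv_leave_one_run_out,
    cv_training_size,
    simulated_realtime_decode,
)
from .features import FeatureConfig, extract_features
from .hrf import HrfModel
from .somatotopy import (
    SomatotopyConfig,
    recover_layout,
    spearman_correlation,
    summarize_weight_map,
    wilcoxon_signed_rank,
)
from .synthgen import (
    DesignSpec,
    GeneratorConfig,
    NoiseModel,
    SomatotopicLayout,
    simulate_subject,
)

log = logging.getLogger("somatobci")


@dataclass
class PipelineConfig:
    """Study-level configuration; YAML-serialisable, hashed into manifests."""

    n_subjects: int = 3
    subject_amplitudes: tuple[float, ...] | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    perm: st.PermConfig = field(default_factory=lambda: st.PermConfig(n_perm=200))
    topo: SomatotopyConfig = field(default_factory=SomatotopyConfig)
    min_mask_voxels: int = 500
    run_permutation_tests: bool = True
    run_training_size: bool = True
    run_region_comparison: bool = True
    run_answer_decoding: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)

        def build(key, typ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in d[key].items()
                })

        gen = d.get("generator")
        if isinstance(gen, dict):
            gen = dict(gen)
            for key, typ in (
                ("design", DesignSpec),
                ("layout", SomatotopicLayout),
                ("hrf", HrfModel),
                ("noise", NoiseModel),
            ):
                if isinstance(gen.get(key), dict):
                    gen[key] = typ(**gen[key])
            for key in ("grid_shape", "mask_levels", "answer_classes"):
                if isinstance(gen.get(key), list):
                    gen[key] = tuple(gen[key])
            d["generator"] = GeneratorConfig(**gen)
        feats = d.get("features")
        if isinstance(feats, dict):
            feats = dict(feats)
            if isinstance(feats.get("hrf"), dict):
                feats["hrf"] = HrfModel(**feats["hrf"])
            d["features"] = FeatureConfig(**feats)
        build("svm", SvmConfig)
        build("perm", st.PermConfig)
        build("topo", SomatotopyConfig)
        if isinstance(d.get("subject_amplitudes"), list):
            d["subject_amplitudes"] = tuple(d["subject_amplitudes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def desk_scale(cls, **overrides) -> "PipelineConfig":
        """A small configuration that exercises every stage in minutes."""
        gen = GeneratorConfig(
            grid_shape=(24, 24, 12),
            n_training_runs=4,
            n_answer_runs=2,
            amplitude=1.5,
        )
        defaults = dict(
            n_subjects=3,
            generator=gen,
            perm=st.PermConfig(n_perm=100),
            topo=SomatotopyConfig(top_k=60),
            min_mask_voxels=200,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StudyReport:
    subjects: pd.DataFrame
    training_size: pd.DataFrame | None
    training_size_anova: pd.DataFrame | None
    training_size_contrasts: pd.DataFrame | None
    region_level: pd.DataFrame | None
    answer_table: pd.DataFrame | None
    answer_overall: pd.DataFrame | None
    cohort_stats: dict
    config_hash: str
    seed: int


def _answer_column(n_train: int, n_runs: int) -> str:
    first = n_runs - n_train + 1
    return str(n_runs) if n_train == 1 else f"{first}-{n_runs}"


def run_full_study(
    cfg: PipelineConfig, seed: int = 0, out_dir: str | Path | None = None
) -> StudyReport:
    """Run every analysis stage on a generated cohort; see module docs."""
    rng = np.random.default_rng(seed)
    amplitudes = cfg.subject_amplitudes or tuple(
        [cfg.generator.amplitude] * cfg.n_subjects
    )
    if len(amplitudes) != cfg.n_subjects:
        raise ValueError("subject_amplitudes length must equal n_subjects")

    subject_rows = []
    size_rows = []
    region_rows = []
    answer_rows = []
    pairs = []
    n_runs = cfg.generator.n_training_runs

    for si in range(cfg.n_subjects):
        t0 = time.perf_counter()
        subject = f"S{si + 1:02d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        gen = dataclasses.replace(cfg.generator, amplitude=amplitudes[si])
        session = simulate_subject(gen, sub_seed)
        h = session.masks
        lowest = min(h.levels("S1"))
        mask = h.select_indices(h.regions, lowest)
        feats = extract_features(session, mask, cfg.features)
        log.info("[%s] simulated + extracted %d trials x %d voxels",
                 subject, feats.n_trials, feats.n_voxels)

        result = cv_leave_one_run_out(feats, cfg.svm)
        p_perm = np.nan
        if cfg.run_permutation_tests:
            perm_cfg = dataclasses.replace(cfg.perm, seed=sub_seed)
            p_perm = st.permutation_test(
                feats, cfg=perm_cfg, svm_cfg=cfg.svm
            ).p

        wmap = average_weight_map(
            result, grid_shape=h.grid_shape, affine=h.affine
        )
        topo = summarize_weight_map(wmap, cfg.topo, accuracy=result.accuracy)
        recovery = recover_layout(session, topo)
        pairs.append((topo.median_x_pos, topo.median_x_neg))
        subject_rows.append(
            {
                "subject": subject,
                "seed": sub_seed,
                "amplitude": amplitudes[si],
                "accuracy": result.accuracy,
                "p_perm": p_perm,
                "median_x_pos": topo.median_x_pos,
                "median_x_neg": topo.median_x_neg,
                "separation": topo.separation,
                "foot_error_mm": recovery.foot_error_mm,
                "hand_error_mm": recovery.hand_error_mm,
            }
        )

        if cfg.run_training_size and n_runs >= 2:
            frame = cv_training_size(feats, cfg.svm)
            frame.insert(0, "subject", subject)
            size_rows.append(frame)

        if cfg.run_region_comparison:
            for region in h.regions:
                for level in h.usable_levels(region, cfg.min_mask_voxels):
                    rfeats = extract_features(
                        session, h.select_indices([region], level), cfg.features
                    )
                    racc = cv_leave_one_run_out(rfeats, cfg.svm).accuracy
                    region_rows.append(
                        {
                            "subject": subject,
                            "region": region,
                            "level": level,
                            "n_voxels": h.voxel_count(region, level),
                            "accuracy": racc,
                        }
                    )

        if cfg.run_answer_decoding:
            for answer_run in session.answer_runs:
                row = {
                    "subject": subject,
                    "run": answer_run.meta.run_id,
                }
                for n_train in range(1, n_runs + 1):
                    ans = simulated_realtime_decode(
                        session, answer_run, n_train, cfg.svm
                    )
                    row[_answer_column(n_train, n_runs)] = ans.proportion_correct
                full = simulated_realtime_decode(
                    session, answer_run, n_runs, cfg.svm
                )
                row["encoded_answer"] = (
                    {"hand": "yes", "foot": "no"}[full.encoded_class]
                    if full.encoded_class
                    else None
                )
                row["answer_call"] = full.answer_call
                answer_rows.append(row)
        log.info("[%s] done in %.1f s", subject, time.perf_counter() - t0)

    subjects = pd.DataFrame(subject_rows)

    training_size = anova_table = contrasts = None
    if size_rows:
        training_size = pd.concat(size_rows, ignore_index=True)
        if cfg.n_subjects >= 3:
            anova_table, contrasts = _training_size_inference(
                training_size, cfg
            )

    region_level = pd.DataFrame(region_rows) if region_rows else None

    answer_table = answer_overall = None
    if answer_rows:
        answer_table = pd.DataFrame(answer_rows)
        value_cols = [
            _answer_column(j, n_runs) for j in range(1, n_runs + 1)
        ]
        answer_overall = st.aggregate_answer_table(answer_table, value_cols)

    cohort: dict = {}
    if cfg.n_subjects >= 3:
        try:
            rho, p_rho = spearman_correlation(
                subjects["separation"].to_numpy(),
                subjects["accuracy"].to_numpy(),
            )
            cohort["spearman_rho"] = rho
            cohort["spearman_p"] = p_rho
        except ValueError as exc:  # e.g. all accuracies at ceiling
            log.warning("separation-accuracy correlation skipped: %s", exc)
    if cfg.n_subjects >= 5:
        try:
            z, p_w = wilcoxon_signed_rank(np.asarray(pairs))
            cohort["wilcoxon_z"] = z
            cohort["wilcoxon_p"] = p_w
        except ValueError as exc:
            log.warning("median-x Wilcoxon test skipped: %s", exc)

    report = StudyReport(
        subjects=subjects,
        training_size=training_size,
        training_size_anova=anova_table,
        training_size_contrasts=contrasts,
        region_level=region_level,
        answer_table=answer_table,
        answer_overall=answer_overall,
        cohort_stats=cohort,
        config_hash=config_hash(cfg),
        seed=int(seed),
    )
    if out_dir is not None:
        _write_report(report, cfg, Path(out_dir))
    return report


def _training_size_inference(training_size: pd.DataFrame, cfg: PipelineConfig):
    """Class x training-size within-subject ANOVA on logit accuracies."""
    n_per_class = cfg.generator.design.n_trials_per_class
    cells = []
    ks = sorted(training_size["k"].unique())
    for subject, sub in training_size.groupby("subject"):
        row = []
        for cls_col in ("accuracy_foot", "accuracy_hand"):
            for k in ks:
                vals = sub.loc[sub["k"] == k, cls_col].dropna()
                total = len(vals) * n_per_class
                correct = float(vals.sum()) * n_per_class
                row.append(
                    st.logit(st.edge_corrected_proportion(round(correct), total))
                )
        cells.append(row)
    data = np.asarray(cells)
    anova = st.rm_anova(
        data, [("class", 2), ("training_runs", len(ks))]
    ).table().reset_index()
    # trend over training-set size, averaged over class
    k_means = (
        data.reshape(len(cells), 2, len(ks)).mean(axis=1)
    )
    contrasts = st.polynomial_contrasts(k_means)
    return anova, contrasts


def _write_report(report: StudyReport, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name in (
        "subjects",
        "training_size",
        "training_size_anova",
        "training_size_contrasts",
        "region_level",
        "answer_table",
    ):
        frame = getattr(report, name)
        if frame is not None:
            frame.to_csv(out / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
    if report.answer_overall is not None:
        report.answer_overall.to_csv(out / "answer_overall.csv")
        files.append("answer_overall.csv")
    (out / "cohort_stats.json").write_text(
        json.dumps(report.cohort_stats, indent=2)
    )
    files.append("cohort_stats.json")
    cfg.to_yaml(out / "config.yaml")
    files.append("config.yaml")
    manifest = {
        "files": sorted(files),
        "config_hash": report.config_hash,
        "seed": report.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
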