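"""Configured, reproducible end-to-end runs: simulate -> cluster -> dynamics
-> stats -> classify.

A run directory accumulates per-stage outputs in plain text (TSV/JSON), the
verbatim config, and a config hash. Each completed stage writes a stamp file
carrying that hash; re-running with an unchanged config skips stages whose
stamps match, so interrupted runs resume from the last completed stage.
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
import yaml

from . import __version__
from .cap_clustering import (
    attribute_networks,
    cap_similarity,
    compute_cap_zmaps,
    compute_validity,
    kmeans_correlation,
    pool_frames,
)
from .classification import (
    feature_matrix,
    nested_cv_svm,
    permutation_test,
    select_features,
)
from .dynamics import dynamic_profile, profiles_to_long
from .group_stats import (
    DEFAULT_COVARIATES,
    dynamics_stat_table,
    symptom_correlation_table,
)
from .io_model import load_cohort, zscore_series
from .synthetic import make_truth, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into the run directory."""

    out_dir: str = "run"
    data_dir: str | None = None  # existing cohort; None -> simulate
    k: int = 7
    k_range: tuple[int, int] | None = None  # enables the validity stage
    seed: int = 0
    z_threshold: float = 1.96
    tr_seconds: float = 2.0
    n_init: int = 5
    max_iter: int = 500
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("HC", "MDD")])
    alpha: float = 0.05
    entropy_base: float = 2.0
    dwell_metric: str = "dwell"  # or "total_dwell"
    # simulation block (used when data_dir is None)
    n_control: int = 60
    n_patient: int = 60
    t_frames: int = 240
    snr: float = 2.0
    effect_cap: int = 0
    effect_delta: float = 0.15
    # classification block
    outer_folds: int = 5
    inner_folds: int = 5
    n_perm: int = 0  # 0 disables the permutation test
    c_grid: list[float] | None = None
    gamma_grid: list[float] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.k_range is not None:
            cfg.k_range = tuple(cfg.k_range)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(run_dir: Path, stage: str) -> Path:
    return run_dir / f".stamp_{stage}.json"


def _stage_done(run_dir: Path, stage: str, cfg_hash: str) -> bool:
    p = _stamp(run_dir, stage)
    if not p.exists():
        return False
    return json.loads(p.read_text()).get("config_hash") == cfg_hash


def _mark_done(run_dir: Path, stage: str, cfg_hash: str) -> None:
    _stamp(run_dir, stage).write_text(
        json.dumps({"config_hash": cfg_hash, "version": __version__})
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages in order; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    with open(run_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    (run_dir / "config_hash.txt").write_text(cfg_hash + "\n")

    # --- stage: simulate (or point at existing data) ---
    if config.data_dir is None:
        data_dir = run_dir / "data"
        if not _stage_done(run_dir, "simulate", cfg_hash):
            truth = make_truth(
                k=config.k,
                snr=config.snr,
                effect_cap=config.effect_cap,
                effect_delta=config.effect_delta,
                tr_seconds=config.tr_seconds,
                seed=config.seed,
            )
            simulate_cohort(
                truth,
                n_control=config.n_control,
                n_patient=config.n_patient,
                t=config.t_frames,
                seed=config.seed,
                out_dir=data_dir,
            )
            _mark_done(run_dir, "simulate", cfg_hash)
            logger.info("simulate: wrote cohort to %s", data_dir)
    else:
        data_dir = Path(config.data_dir)

    manifest, series, atlas = load_cohort(
        data_dir / "manifest.csv",
        data_dir / "series",
        data_dir / "atlas.csv",
        tr_seconds=config.tr_seconds,
    )
    series = [zscore_series(ts) for ts in series]

    # --- stage: validity (optional) ---
    if config.k_range is not None and not _stage_done(run_dir, "validity", cfg_hash):
        pool, _ = pool_frames(series)
        table = compute_validity(
            pool, config.k_range, seed=config.seed,
            n_init=config.n_init, max_iter=config.max_iter,
        )
        table.to_csv(run_dir / "validity.tsv", sep="\t", index=False)
        _mark_done(run_dir, "validity", cfg_hash)

    # --- stage: cluster ---
    if not _stage_done(run_dir, "cluster", cfg_hash):
        pool, frame_map = pool_frames(series)
        model = kmeans_correlation(
            pool, config.k, frame_map,
            n_init=config.n_init, max_iter=config.max_iter, seed=config.seed,
        )
        zmaps, n_per_cap = compute_cap_zmaps(series, model.assignments, config.k)
        model.zmaps = zmaps
        np.savetxt(run_dir / "centroids.tsv", model.centroids, delimiter="\t", fmt="%.17g")
        np.savetxt(run_dir / "zmaps.tsv", zmaps, delimiter="\t", fmt="%.17g")
        adir = run_dir / "assignments"
        adir.mkdir(exist_ok=True)
        for sid, labels in model.assignments.items():
            np.savetxt(adir / f"{sid}.tsv", labels[:, None], fmt="%d")
        with open(run_dir / "capmodel.json", "w") as fh:
            json.dump(
                {
                    "k": config.k,
                    "seed": config.seed,
                    "inertia": model.inertia,
                    "n_subjects_per_cap": n_per_cap.tolist(),
                    "config_hash": cfg_hash,
                },
                fh,
                indent=2,
            )
        attribute_networks(zmaps, atlas, config.z_threshold).to_csv(
            run_dir / "attribution.tsv", sep="\t", index=False
        )
        np.savetxt(run_dir / "similarity.tsv", cap_similarity(zmaps), delimiter="\t", fmt="%.6f")
        _mark_done(run_dir, "cluster", cfg_hash)

    # --- stage: dynamics ---
    if not _stage_done(run_dir, "dynamics", cfg_hash):
        adir = run_dir / "assignments"
        profiles = []
        for ts in series:
            labels = np.loadtxt(adir / f"{ts.subject_id}.tsv", dtype=int, ndmin=1)
            profiles.append(
                dynamic_profile(
                    ts.subject_id, labels, config.k, config.tr_seconds,
                    entropy_base=config.entropy_base,
                )
            )
        long_df = profiles_to_long(profiles)
        long_df.insert(0, "config_hash", cfg_hash)
        long_df.to_csv(run_dir / "dynamics.tsv", sep="\t", index=False)
        _mark_done(run_dir, "dynamics", cfg_hash)

    long_df = pd.read_csv(run_dir / "dynamics.tsv", sep="\t")

    # --- stage: stats ---
    if not _stage_done(run_dir, "stats", cfg_hash):
        for contrast in config.contrasts:
            table = dynamics_stat_table(
                long_df, manifest.table, contrast, config.covariates
            )
            name = f"stats_{contrast[0]}_vs_{contrast[1]}.tsv"
            table.to_csv(run_dir / name, sep="\t", index=False)
        patient_groups = {g for c in config.contrasts for g in c} - {"HC"}
        if patient_groups and manifest.table["hamd"].notna().any():
            corr = symptom_correlation_table(
                long_df, manifest.table, sorted(patient_groups)[0],
                covariates=config.covariates,
            )
            corr.to_csv(run_dir / "correlations.tsv", sep="\t", index=False)
        _mark_done(run_dir, "stats", cfg_hash)

    # --- stage: classify ---
    if not _stage_done(run_dir, "classify", cfg_hash):
        for contrast in config.contrasts:
            name = f"stats_{contrast[0]}_vs_{contrast[1]}.tsv"
            try:
                table = pd.read_csv(run_dir / name, sep="\t")
            except pd.errors.EmptyDataError:
                logger.warning("classify %s skipped: empty stats table", contrast)
                continue
            try:
                feats = select_features(table, config.alpha)
            except ValueError as err:
                logger.warning("classify %s skipped: %s", contrast, err)
                continue
            man = manifest.table[manifest.table["group"].isin(contrast)]
            sids = list(man["subject_id"])
            x = feature_matrix(long_df, feats, sids)
            keep = ~np.isnan(x).any(axis=1)
            y = (man["group"].to_numpy() == contrast[1]).astype(int)[keep]
            x = x[keep]
            kwargs = dict(
                outer_folds=config.outer_folds,
                inner_folds=config.inner_folds,
                seed=config.seed,
                contrast=f"{contrast[0]}_vs_{contrast[1]}",
            )
            if config.c_grid:
                kwargs["c_grid"] = tuple(config.c_grid)
            if config.gamma_grid:
                kwargs["gamma_grid"] = tuple(config.gamma_grid)
            if config.n_perm:
                res = permutation_test(x, y, n_perm=config.n_perm, **kwargs)
                report = res.pop("report")
                extra = {
                    "p_accuracy": res["p_accuracy"],
                    "p_auc": res["p_auc"],
                }
            else:
                report = nested_cv_svm(x, y, **kwargs)
                extra = {}
            out = {
                "contrast": report.contrast,
                "features": [f"{m}:{cf}" + ("" if ct is None else f"->{ct}") for m, cf, ct in feats],
                "summary": report.summary(),
                "folds": [dataclasses.asdict(f) for f in report.folds],
                "grid": report.grid,
                "seed": config.seed,
                "config_hash": cfg_hash,
                **extra,
            }
            with open(
                run_dir / f"classification_{contrast[0]}_vs_{contrast[1]}.json", "w"
            ) as fh:
                json.dump(out, fh, indent=2)
        _mark_done(run_dir, "classify", cfg_hash)

    return run_dir
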