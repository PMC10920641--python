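"""Stage orchestration: simulate -> extract -> synchronize -> featurize ->
classify -> importance -> posthoc.

Every stage reads the artifacts of its upstream stage from disk, writes its
own outputs under the run directory, and records provenance (config hash,
seed, package version) in a JSON sidecar, so stages are individually
re-runnable and deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import features as feat
from . import motion_energy as mea
from . import posthoc
from . import synchrony as sync
from .classifier import (
    C_GRID,
    CVScheme,
    InFoldPreprocSpec,
    ModelRecord,
    LinearModel,
    compute_cvr,
    run_nested_cv,
    sign_consistency,
)
from .synthetic import DyadSimConfig, simulate_cohort

STAGES = (
    "simulate", "extract", "synchronize", "featurize",
    "classify", "importance", "posthoc",
)

#: Diagnoses counted as positive under the neurodevelopmental-disorder
#: relabeling (vs the autism-only labeling).
NDD_LABELS = ("ASD", "ADHD", "ID", "DD", "Tourette", "PDD-NOS")


@dataclass
class RunConfig:
    """All tunables of a pipeline run, loadable from YAML."""

    outdir: str = "run"
    seed: int = 0
    # simulate
    n_per_group: int = 20
    duration_sec: float | None = None
    fps: float = 29.95
    coupling: Mapping[str, float] | None = None  # per-group override
    # extract
    mea_threshold: float = 8.0
    # synchronize
    sd_scale: bool = True
    smooth_sec: float = 0.5
    lag_increment_sec: float = 1.0
    window_sec: float = 60.0
    step_sec: float = 30.0
    intra_window_sec: float = 30.0
    intra_step_sec: float = 15.0
    max_lag_sec: float = 5.0
    # featurize / classify
    feature_mode: str = "mea"  # or "mea+demo"
    labeling: str = "asd-cc"  # or "ndd-cc"
    outer_folds: int = 10
    outer_perms: int = 10
    inner_folds: int = 10
    c_grid: Sequence[float] = C_GRID
    permutations: int = 0  # label-permutation test size, 0 = skip

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def positive_labels(self) -> tuple[str, ...]:
        if self.labeling == "asd-cc":
            return ("ASD",)
        if self.labeling == "ndd-cc":
            return NDD_LABELS
        raise ValueError("labeling must be 'asd-cc' or 'ndd-cc'")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str, extra: dict | None = None) -> dict:
    out = {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "dyadsync_version": __version__,
    }
    if extra:
        out.update(extra)
    return out


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig) -> Path:
    """Generate a synthetic cohort and write per-dyad series + metadata."""
    out = Path(config.outdir)
    (out / "series").mkdir(parents=True, exist_ok=True)
    from .synthetic import DEFAULT_GROUP_PARAMS, GroupParams

    group_params = dict(DEFAULT_GROUP_PARAMS)
    if config.coupling:
        # unknown groups inherit the clinical-control score distributions
        template = DEFAULT_GROUP_PARAMS["CC"]
        group_params = {
            g: dataclasses.replace(group_params.get(g, template), coupling=rho)
            for g, rho in config.coupling.items()
        }
    cohort = simulate_cohort(
        n_per_group=config.n_per_group,
        cfg=DyadSimConfig(duration_sec=config.duration_sec, fps=config.fps),
        group_params=group_params,
        seed=config.seed,
    )
    for dyad_id, series in cohort.series.items():
        mea.write_series_csv(
            series, out / "series" / f"{dyad_id}.csv",
            sidecar={"dyad_id": dyad_id, "config_hash": config.hash()},
        )
    cohort.metadata.to_csv(out / "metadata.csv")
    _write_json(out / "simulate.json",
                _provenance(config, "simulate", {"n_dyads": len(cohort.series)}))
    return out


def stage_extract(
    config: RunConfig, video_dir: str | Path, roi_json: str | Path,
    dyad_id: str = "dyad",
) -> Path:
    """Extract motion energy from an image-sequence directory."""
    out = Path(config.outdir)
    (out / "series").mkdir(parents=True, exist_ok=True)
    video = mea.load_frame_sequence(video_dir, fps=config.fps)
    rois = mea.load_rois(roi_json)
    series = mea.extract_motion_energy(
        video, rois, mea.MEAConfig(config.mea_threshold)
    )
    mea.write_series_csv(
        series, out / "series" / f"{dyad_id}.csv",
        sidecar={"dyad_id": dyad_id, "threshold": config.mea_threshold,
                 "config_hash": config.hash()},
    )
    _write_json(out / "extract.json", _provenance(config, "extract"))
    return out


def _crosscorr_configs(config: RunConfig) -> tuple[sync.CrossCorrConfig, sync.CrossCorrConfig]:
    inter = sync.CrossCorrConfig(
        fps=config.fps, window_sec=config.window_sec,
        max_lag_sec=config.max_lag_sec, step_sec=config.step_sec,
        lag_increment_sec=config.lag_increment_sec,
    )
    intra = sync.CrossCorrConfig(
        fps=config.fps, window_sec=config.intra_window_sec,
        max_lag_sec=config.max_lag_sec, step_sec=config.intra_step_sec,
        lag_increment_sec=config.lag_increment_sec,
    )
    return inter, intra


def stage_synchronize(config: RunConfig) -> Path:
    """Compute per-dyad synchrony matrices and movement quantities."""
    out = Path(config.outdir)
    series_dir = out / "series"
    if not series_dir.is_dir():
        raise FileNotFoundError("run the simulate or extract stage first")
    (out / "matrices").mkdir(exist_ok=True)
    pre_cfg = sync.PreprocessConfig(config.sd_scale, config.smooth_sec)
    inter_cfg, intra_cfg = _crosscorr_configs(config)
    movement_rows = []
    for csv_path in sorted(series_dir.glob("*.csv")):
        dyad_id = csv_path.stem
        series = mea.read_series_csv(csv_path)
        pre = {role: sync.preprocess_series(s, pre_cfg) for role, s in series.items()}
        matrices = {
            "head": sync.windowed_crosslag(
                pre["participant_head"], pre["administrator_head"], inter_cfg),
            "body": sync.windowed_crosslag(
                pre["participant_body"], pre["administrator_body"], inter_cfg),
            "intra": sync.windowed_crosslag(
                pre["participant_head"], pre["participant_body"], intra_cfg),
        }
        for kind, m in matrices.items():
            m.to_frame().to_csv(out / "matrices" / f"{dyad_id}_{kind}.csv", index=False)
        movement_rows.append(
            {"dyad_id": dyad_id, **{
                f"movement_{role}": mea.movement_quantity(s)
                for role, s in series.items()
            }}
        )
    pd.DataFrame(movement_rows).set_index("dyad_id").to_csv(out / "movement.csv")
    _write_json(out / "synchronize.json", _provenance(config, "synchronize"))
    return out


def _matrix_from_frame(df: pd.DataFrame) -> sync.CrossCorrMatrix:
    wide = df.pivot(index="window_start", columns="lag", values="value")
    return sync.CrossCorrMatrix(
        wide.to_numpy(), wide.index.to_numpy(), wide.columns.to_numpy()
    )


def stage_featurize(config: RunConfig) -> Path:
    """Assemble the dyad feature table from matrices + movement + metadata."""
    out = Path(config.outdir)
    movement = pd.read_csv(out / "movement.csv", index_col="dyad_id")
    metadata = pd.read_csv(out / "metadata.csv", index_col="dyad_id")
    mode = config.feature_mode
    rows = {}
    for dyad_id in movement.index:
        mats = {
            kind: _matrix_from_frame(
                pd.read_csv(out / "matrices" / f"{dyad_id}_{kind}.csv"))
            for kind in ("head", "body", "intra")
        }
        demo = None
        if mode == "mea+demo":
            demo = {"iq": metadata.loc[dyad_id, "iq"],
                    "sex": metadata.loc[dyad_id, "sex"]}
        vec = feat.assemble_features(
            mats["head"], mats["body"], mats["intra"],
            movement={role: movement.loc[dyad_id, f"movement_{role}"]
                      for role in mea.ROLES},
            demographics=demo, mode=mode,
        )
        vec["label"] = metadata.loc[dyad_id, "label"]
        vec["age"] = metadata.loc[dyad_id, "age"]
        rows[dyad_id] = vec
    table = feat.make_feature_table(rows)
    cols = feat.feature_columns(mode) + ["label", "age"]
    table = table[cols]
    table.to_csv(out / "features.csv")
    _write_json(out / "featurize.json",
                _provenance(config, "featurize",
                            {"mode": mode, "n_features": len(cols) - 2}))
    return out


def stage_classify(config: RunConfig) -> Path:
    """Nested-CV SVM classification; writes scores, metrics, model store."""
    out = Path(config.outdir)
    table = pd.read_csv(out / "features.csv", index_col="dyad_id")
    scheme = CVScheme(
        outer_folds=config.outer_folds, outer_perms=config.outer_perms,
        inner_folds=config.inner_folds, seed=config.seed,
    )
    spec = InFoldPreprocSpec(impute=(config.feature_mode == "mea+demo"))
    result = run_nested_cv(
        table, scheme, config.c_grid, spec,
        positive_label=config.positive_labels(),
    )
    result.scores.to_csv(out / "pooled_scores.csv")
    metrics = result.metrics.as_dict()
    if config.permutations:
        from .classifier import permutation_test

        perm = permutation_test(
            table, scheme, config.c_grid, spec,
            B=config.permutations, seed=config.seed,
            positive_label=config.positive_labels(),
        )
        metrics["permutation_p"] = perm["p"]
    _write_json(out / "metrics.json",
                _provenance(config, "classify", {"metrics": metrics}))
    # model store: weights in the full feature space + training-id manifest
    weights = pd.DataFrame(
        [rec.weights_full(len(result.feature_names)) for rec in result.models],
        columns=result.feature_names,
    )
    meta = pd.DataFrame(
        [{"outer_perm": r.outer_perm, "outer_fold": r.outer_fold,
          "inner_fold": r.inner_fold, "C": r.C} for r in result.models]
    )
    pd.concat([meta, weights], axis=1).to_csv(out / "model_store.csv", index=False)
    _write_json(out / "model_manifest.json", {
        "provenance": _provenance(config, "classify"),
        "feature_names": result.feature_names,
        "train_ids": [sorted(r.train_ids) for r in result.models],
    })
    return out


def load_model_store(out: Path) -> tuple[list[ModelRecord], list[str]]:
    """Rebuild lightweight model records from the serialized store."""
    store = pd.read_csv(out / "model_store.csv")
    with open(out / "model_manifest.json") as fh:
        manifest = json.load(fh)
    names = manifest["feature_names"]
    records = []
    for i, row in store.iterrows():
        w_full = row[names].to_numpy(dtype=float)
        mask = ~np.isnan(w_full)
        records.append(ModelRecord(
            outer_perm=int(row.outer_perm), outer_fold=int(row.outer_fold),
            inner_fold=int(row.inner_fold), C=float(row.C),
            model=LinearModel(w_full[mask], 0.0, float(row.C), ()),
            keep_mask=mask, train_ids=frozenset(manifest["train_ids"][i]),
        ))
    return records, names


def stage_importance(config: RunConfig) -> Path:
    """CVR and sign-based consistency from the serialized model store."""
    out = Path(config.outdir)
    records, names = load_model_store(out)
    cvr = compute_cvr(records, names)
    cons = sign_consistency(records, names)
    imp = cvr.join(cons[["n_positive", "p", "neg_log10_p", "fdr_significant"]])
    imp.to_csv(out / "importance.csv")
    _write_json(out / "importance.json", _provenance(config, "importance"))
    return out


def stage_posthoc(config: RunConfig) -> Path:
    """Clinical correlations of decision scores and group comparisons."""
    out = Path(config.outdir)
    scores = pd.read_csv(out / "pooled_scores.csv", index_col="dyad_id")
    metadata = pd.read_csv(out / "metadata.csv", index_col="dyad_id")
    battery = posthoc.pearson_with_fdr(
        scores["score_median"], metadata, scales=posthoc.CLINICAL_SCALES
    )
    battery.to_csv(out / "score_correlations.csv")
    groups = sorted(metadata["label"].unique())[:2]
    comp = posthoc.group_comparisons(
        metadata,
        [v for v in ("age", "iq") + posthoc.CLINICAL_SCALES
         if v in metadata.columns],
        groups=(groups[0], groups[1]),
    )
    comp.to_csv(out / "group_comparisons.csv")
    sex_table = pd.crosstab(
        metadata["label"].isin(config.positive_labels()), metadata["sex"]
    ).to_numpy()
    if sex_table.shape == (2, 2) and (sex_table.sum(0) > 0).all():
        chi2, dof, p = posthoc.chi2_yates(sex_table)
    else:  # a sex absent from the cohort: independence test undefined
        chi2 = p = None
    _write_json(out / "posthoc.json",
                _provenance(config, "posthoc",
                            {"sex_chi2": chi2, "sex_chi2_p": p}))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "synchronize": stage_synchronize,
    "featurize": stage_featurize,
    "classify": stage_classify,
    "importance": stage_importance,
    "posthoc": stage_posthoc,
}


def run(stage: str, config: RunConfig, **kwargs) -> Path:
    """Run one pipeline stage (``extract`` takes video_dir/roi_json kwargs)."""
    if stage == "extract":
        return stage_extract(config, **kwargs)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage](config)


def run_all(config: RunConfig, stages: Sequence[str] = (
        "simulate", "synchronize", "featurize", "classify", "importance",
        "posthoc")) -> Path:
    """Run a sequence of stages end to end on one run directory."""
    out = Path(config.outdir)
    for stage in stages:
        run(stage, config)
    return out
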