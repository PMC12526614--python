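"""End-to-end orchestration: synth -> preprocess -> segment -> featurize ->
rank -> train -> evaluate, driven by one nested config with a single seed.

Every stage writes plain CSV/JSON artifacts into the output directory and the
final manifest records the seed, a hash of the config, library versions and
per-stage record counts, so a rerun with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, features as feat, preprocess, segment, select, synth
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STAGE_NAMES = ("streams", "synced", "cycles", "dataset", "ranking", "models", "report")


@dataclass
class FilterConfig:
    cutoff: float = 5.0
    order: int = 4
    zero_phase: bool = True


@dataclass
class SegmentationConfig:
    min_depth: float = 0.15
    dur_min: float = 1.0
    dur_max: float = 10.0
    onset_floor: float = 0.005


@dataclass
class FeatureConfig:
    ks_mode: str = "magnitude"
    label_threshold: float = 0.03
    label_stat: str = "max"
    n_samples: int = 20
    scope: str = "per_subject"


@dataclass
class PipelineConfig:
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: classify.TrainConfig = field(default_factory=classify.TrainConfig)
    sets: tuple[str, ...] = tuple(",".join(map(str, s)) for s in select.PAPER_FEATURE_SETS)
    models: tuple[str, ...] = ("lstm", "svm")
    out_dir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        # one pipeline seed drives generation and training
        self.synth.seed = self.seed
        self.train.seed = self.seed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where artifacts land does not change identity
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _build_dataclass(cls, data: dict, path: str, diagnostics: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            diagnostics.append(f"unknown key {path}{key!r}")
            continue
        f = known[key]
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.default_factory, type)
                and dataclasses.is_dataclass(f.default_factory)):
            sub_cls = f.default_factory
            kwargs[key] = _build_dataclass(sub_cls, value or {},
                                           f"{path}{key}.", diagnostics)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except Exception as exc:  # surfaced as a diagnostic, not a crash
        diagnostics.append(f"{path or 'config '}: {exc}")
        return cls()


def load_config(path) -> PipelineConfig:
    cfg, diagnostics = _load_config_checked(path)
    if diagnostics:
        raise ConfigurationError("; ".join(diagnostics))
    return cfg


def _load_config_checked(path) -> tuple[PipelineConfig, list[str]]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    diagnostics: list[str] = []
    cfg = _build_dataclass(PipelineConfig, data, "", diagnostics)
    return cfg, diagnostics


def validate(path) -> list[str]:
    """Schema and invariant check of a config file; returns diagnostics
    (empty for a valid file). Unknown keys are errors (typo safety)."""
    cfg, diagnostics = _load_config_checked(path)
    try:
        cfg.synth.validate()
    except ConfigurationError as exc:
        diagnostics.append(str(exc))
    grid_nyquist = 0.5 * synth.SynthConfig().plate_rate  # common grid at 50 Hz
    if cfg.filter.cutoff >= grid_nyquist:
        diagnostics.append(
            f"filter cutoff {cfg.filter.cutoff} Hz >= Nyquist {grid_nyquist} Hz of the grid")
    for s in cfg.sets:
        try:
            select.FeatureSet.parse(s)
        except Exception as exc:
            diagnostics.append(f"invalid feature set {s!r}: {exc}")
    return diagnostics


def dataset_from_cohort(synth_cfg: synth.SynthConfig,
                        filter_cfg: FilterConfig | None = None,
                        seg_cfg: SegmentationConfig | None = None,
                        feat_cfg: FeatureConfig | None = None):
    """In-memory synth -> preprocess -> segment -> featurize convenience.

    Returns (dataset, truth_table, n_detected). Ground-truth flags are
    attached to the dataset when every generated squat was recovered, so
    label/ground-truth agreement can be read off directly.
    """
    filter_cfg = filter_cfg or FilterConfig()
    seg_cfg = seg_cfg or SegmentationConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    sessions, truth = synth.generate_cohort(synth_cfg)
    feats = []
    n_detected = 0
    for sess in sessions:
        session = preprocess.synchronize(sess.camera, sess.plate, subject=sess.subject)
        session = preprocess.lowpass(session, filter_cfg.cutoff, filter_cfg.order,
                                     zero_phase=filter_cfg.zero_phase)
        bounds = segment.detect_squats(
            session, min_depth=seg_cfg.min_depth,
            dur_bounds=(seg_cfg.dur_min, seg_cfg.dur_max),
            onset_floor=seg_cfg.onset_floor)
        n_detected += len(bounds)
        for i, b in enumerate(bounds):
            cyc = segment.extract_window(session, b, index=i)
            feats.append(feat.compute_cycle_features(
                cyc, ks_mode=feat_cfg.ks_mode, threshold=feat_cfg.label_threshold,
                label_stat=feat_cfg.label_stat))
    dataset = feat.build_dataset(feats, scope=feat_cfg.scope,
                                 n_samples=feat_cfg.n_samples)
    if n_detected == len(truth):
        dataset.truth = truth["true_unstable"].to_numpy(dtype=bool)
    return dataset, truth, n_detected


# ---------------------------------------------------------------- stages

def stage_synth(cfg: PipelineConfig, out: str) -> dict:
    d = os.path.join(out, "streams")
    os.makedirs(d, exist_ok=True)
    sessions, truth = synth.generate_cohort(cfg.synth)
    for s in sessions:
        synth.write_session(s, d)
    truth.to_csv(os.path.join(d, "ground_truth.csv"), index=False, float_format="%.9g")
    return {"path": d, "n_subjects": len(sessions), "n_squats": len(truth),
            "n_unstable": int(truth["true_unstable"].sum())}


def _subject_ids(out: str) -> list[int]:
    d = os.path.join(out, "streams")
    ids = sorted(int(f.split("_")[1]) for f in os.listdir(d)
                 if f.endswith("_camera.csv"))
    return ids


def stage_preprocess(cfg: PipelineConfig, out: str) -> dict:
    d = os.path.join(out, "synced")
    os.makedirs(d, exist_ok=True)
    n = 0
    for sid in _subject_ids(out):
        cam = preprocess.read_stream(
            os.path.join(out, "streams", f"subject_{sid:03d}_camera.csv"), "camera")
        plate = preprocess.read_stream(
            os.path.join(out, "streams", f"subject_{sid:03d}_plate.csv"), "plate")
        session = preprocess.synchronize(cam, plate, subject=sid)
        session = preprocess.lowpass(session, cfg.filter.cutoff, cfg.filter.order,
                                     zero_phase=cfg.filter.zero_phase)
        session.write_csv(os.path.join(d, f"subject_{sid:03d}.csv"))
        n += 1
    return {"path": d, "n_sessions": n}


def _load_synced(out: str, sid: int) -> preprocess.SyncedSession:
    return preprocess.SyncedSession.read_csv(
        os.path.join(out, "synced", f"subject_{sid:03d}.csv"), subject=sid)


def stage_segment(cfg: PipelineConfig, out: str) -> dict:
    d = os.path.join(out, "cycles")
    os.makedirs(d, exist_ok=True)
    brows, crows = [], []
    for sid in _subject_ids(out):
        session = _load_synced(out, sid)
        bounds = segment.detect_squats(
            session, min_depth=cfg.segmentation.min_depth,
            dur_bounds=(cfg.segmentation.dur_min, cfg.segmentation.dur_max),
            onset_floor=cfg.segmentation.onset_floor)
        for i, b in enumerate(bounds):
            brows.append({"subject": sid, "squat": i, "onset": b.onset,
                          "hold_start": b.hold_start, "hold_end": b.hold_end,
                          "end": b.end, "peak_depth": b.peak_depth, "y_t1": b.y_t1})
            cyc = segment.time_normalize(segment.extract_window(session, b, index=i),
                                         n=cfg.features.n_samples)
            for r in range(cyc.n):
                crows.append({"subject": sid, "squat": i, "row": r,
                              "t_sec": cyc.t[r],
                              **{c: cyc.channels[c][r] for c in session.CHANNELS}})
    pd.DataFrame(brows).to_csv(os.path.join(d, "boundaries.csv"),
                               index=False, float_format="%.9g")
    pd.DataFrame(crows).to_csv(os.path.join(d, "cycles.csv"),
                               index=False, float_format="%.9g")
    return {"path": d, "n_cycles": len(brows)}


def stage_featurize(cfg: PipelineConfig, out: str) -> dict:
    d = os.path.join(out, "dataset")
    os.makedirs(d, exist_ok=True)
    bounds = pd.read_csv(os.path.join(out, "cycles", "boundaries.csv"))
    feats = []
    for sid, grp in bounds.groupby("subject"):
        session = _load_synced(out, int(sid))
        for _, row in grp.iterrows():
            b = segment.CycleBoundary(
                onset=int(row["onset"]), hold_start=int(row["hold_start"]),
                hold_end=int(row["hold_end"]), end=int(row["end"]),
                peak_depth=float(row["peak_depth"]), y_t1=float(row["y_t1"]))
            cyc = segment.extract_window(session, b, index=int(row["squat"]))
            feats.append(feat.compute_cycle_features(
                cyc, ks_mode=cfg.features.ks_mode,
                threshold=cfg.features.label_threshold,
                label_stat=cfg.features.label_stat))
    dataset = feat.build_dataset(feats, scope=cfg.features.scope,
                                 n_samples=cfg.features.n_samples)
    feat.write_dataset(dataset, os.path.join(d, "features.csv"),
                       os.path.join(d, "labels.csv"))
    dataset.summaries.to_csv(os.path.join(d, "summaries.csv"),
                             index=False, float_format="%.9g")
    nki, ki = dataset.class_counts()
    logger.info("featurize: %d squats labeled, %d NKI / %d KI", dataset.n, nki, ki)
    return {"path": d, "n_squats": dataset.n, "n_nki": nki, "n_ki": ki}


def load_dataset(out: str, n_samples: int = 20) -> feat.LabeledDataset:
    d = os.path.join(out, "dataset")
    dataset = feat.read_dataset(os.path.join(d, "features.csv"),
                                os.path.join(d, "labels.csv"), n_samples=n_samples)
    summaries = pd.read_csv(os.path.join(d, "summaries.csv"))
    dataset.summaries = summaries
    gt_path = os.path.join(out, "streams", "ground_truth.csv")
    if os.path.exists(gt_path):
        truth = pd.read_csv(gt_path)
        key = pd.DataFrame({"subject": dataset.subjects, "squat": dataset.squat_index})
        merged = key.merge(truth, on=["subject", "squat"], how="left")
        if merged["true_unstable"].notna().all():
            dataset.truth = merged["true_unstable"].to_numpy(dtype=bool)
    return dataset


def stage_rank(cfg: PipelineConfig, out: str) -> dict:
    dataset = load_dataset(out, n_samples=cfg.features.n_samples)
    ranking = select.rank_features(dataset)
    path = os.path.join(out, "ranking.csv")
    ranking.write_csv(path)
    return {"path": path, "top_by_rho": ranking.top_by_rho()}


def _model_path(out: str, model: str, set_name: str) -> str:
    return os.path.join(out, "models", f"{model}_{set_name.replace(',', '')}.pkl")


def stage_train(cfg: PipelineConfig, out: str) -> dict:
    os.makedirs(os.path.join(out, "models"), exist_ok=True)
    dataset = load_dataset(out, n_samples=cfg.features.n_samples)
    tr_idx, _ = evaluate.stratified_split(dataset, cfg.train.split_fraction,
                                          cfg.train.seed)
    n_models = 0
    for set_name in cfg.sets:
        fs = select.FeatureSet.parse(set_name)
        sub = select.make_set(dataset, fs)
        train = evaluate._subset(sub, tr_idx)
        for model_name in cfg.models:
            trainer = classify.train_lstm if model_name == "lstm" else classify.train_svm
            model = trainer(train, cfg.train)
            with open(_model_path(out, model_name, set_name), "wb") as fh:
                pickle.dump(model, fh)
            n_models += 1
    return {"path": os.path.join(out, "models"), "n_models": n_models}


def stage_evaluate(cfg: PipelineConfig, out: str) -> dict:
    dataset = load_dataset(out, n_samples=cfg.features.n_samples)
    _, te_idx = evaluate.stratified_split(dataset, cfg.train.split_fraction,
                                          cfg.train.seed)
    split_desc = (f"stratified holdout {cfg.train.split_fraction:.0%}/"
                  f"{1 - cfg.train.split_fraction:.0%}")
    rows = []
    for model_name in cfg.models:
        for set_name in cfg.sets:
            fs = select.FeatureSet.parse(set_name)
            test = evaluate._subset(select.make_set(dataset, fs), te_idx)
            with open(_model_path(out, model_name, set_name), "rb") as fh:
                model = pickle.load(fh)
            scores, pred = classify.predict(model, test)
            res = evaluate.evaluate_predictions(test.y, pred, scores)
            rows.append({"model": model_name, "feature_sets": set_name, **res,
                         "split": split_desc, "seed": cfg.train.seed})
    report = pd.DataFrame(rows)
    report.to_csv(os.path.join(out, "report.csv"), index=False, float_format="%.9g")
    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write(evaluate.format_report(report) + "\n")
    return {"path": os.path.join(out, "report.csv"), "n_rows": len(report)}


_STAGES = {
    "streams": stage_synth,
    "synced": stage_preprocess,
    "cycles": stage_segment,
    "dataset": stage_featurize,
    "ranking": stage_rank,
    "models": stage_train,
    "report": stage_evaluate,
}


def run(config: PipelineConfig) -> str:
    """Run all stages and write the manifest; returns the artifact directory."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    stages = {}
    for name, fn in _STAGES.items():
        logger.info("stage %s ...", name)
        try:
            stages[name] = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    import scipy, sklearn
    manifest = {
        "seed": config.seed,
        "config_sha256": config.sha256(),
        "stages": stages,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "scikit-learn": sklearn.__version__},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
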