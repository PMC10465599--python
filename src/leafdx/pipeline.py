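"""End-to-end orchestration: generate -> preprocess -> segment -> extract
-> train -> evaluate, with config validation and reproducibility plumbing.

Each stage writes its artifacts into the run directory and reads its
inputs back from the previous stage's files, so stages can be re-run in
isolation (deleting downstream outputs and re-running only downstream
stages reproduces identical results). All randomness flows from one root
seed; each stage consumes a seed derived as
``(root * 100003 + stage_offset * 7919) mod 2^31`` (offsets in
``STAGE_OFFSETS``), and every derived seed is recorded in the run record.
Images and masks are written as 8-bit PNG, tabular artifacts as CSV,
metric reports as JSON; repeated runs of an identical config are
bit-identical on manifests, masks, feature CSVs and metric JSONs.

The classifier trunk input is configurable (``network.trunk_input``):
``rgb`` (ROI-masked colour image), ``gabor`` (ROI-masked Gabor response),
or the default ``rgb+gabor`` which stacks both into a four-channel input
so colour and texture cues are both available.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import data, gabor, metrics, rtgo, segmentation, squeezenet
from .adam import AdamHyperparams
from .hdl import HDLModel, HDLSpec, TrainConfig, predict, train_hdl

STAGE_OFFSETS = {
    "generate": 1,
    "preprocess": 2,
    "segment": 3,
    "extract": 4,
    "train": 5,
    "tune": 6,
    "split": 7,
    "evaluate": 8,
}


def stage_seed(root_seed: int, stage: str) -> int:
    return (root_seed * 100003 + STAGE_OFFSETS[stage] * 7919) % (2**31)


class ConfigError(ValueError):
    """Aggregated, human-readable config validation failures."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "dataset": {
        "class_counts": dict(data.STUDY_CLASS_COUNTS),
        "image_size": [64, 64],
        "noise_sigma": 0.05,
    },
    "preprocess": {
        "omega": 2.0,
        "u": 0.125,
        "v": 0.0,
        "half_size": 12,
        "response": "modulus",
        "equalize": False,
    },
    "segmentation": {"k": 3, "local_mean": False, "n_restarts": 1},
    "network": {
        "trunk_input": "rgb+gabor",
        "n_cr": 1,
        "n_crp": 3,
        "lstm_hidden": 32,
        "base_width": 8,
        "head_arrangement": "parallel",
        "use_squeezenet_features": True,
        "feature_dim": 16,
        "squeezenet_epochs": 4,
        "dropout": 0.5,
    },
    "optimizer": {
        "alpha": 0.005,
        "beta1": 0.9,
        "beta2": 0.999,
        "eta": 1e-8,
        "epochs": 25,
        "batch_size": 16,
        "coarse_loss_weight": 0.5,
    },
    "split": {"train_fraction": 0.8},
    "tuning": {
        "population": 4,
        "iterations": 3,
        "epochs": 3,
        "lower": [-3.5, 0.0, 8, 8],
        "upper": [-2.0, 0.6, 48, 32],
    },
}


def _merge_defaults(config: dict, defaults: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (config or {}).items():
        if key not in defaults:
            errors.append(f"unknown config key: {path}{key}")
            continue
        if isinstance(defaults[key], dict) and key != "class_counts":
            if not isinstance(value, dict):
                errors.append(f"{path}{key} must be a mapping")
            else:
                out[key] = _merge_defaults(value, defaults[key], f"{path}{key}.", errors)
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(config: dict | str | Path | None) -> dict:
    """Fill defaults, check ranges, reject unknown keys; errors aggregate."""
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    errors: list[str] = []
    cfg = _merge_defaults(config, DEFAULT_CONFIG, "", errors)

    net, opt, split, ds = cfg["network"], cfg["optimizer"], cfg["split"], cfg["dataset"]
    if not 1 <= net["n_cr"] <= 5:
        errors.append(f"network.n_cr={net['n_cr']} outside [1, 5]")
    if net["trunk_input"] not in ("rgb", "gabor", "rgb+gabor"):
        errors.append(f"network.trunk_input={net['trunk_input']!r} not in rgb|gabor|rgb+gabor")
    if not 0.0 < split["train_fraction"] < 1.0:
        errors.append(f"split.train_fraction={split['train_fraction']} outside (0, 1)")
    if cfg["preprocess"]["omega"] <= 0:
        errors.append("preprocess.omega must be > 0")
    if cfg["segmentation"]["k"] < 2:
        errors.append("segmentation.k must be >= 2")
    if ds["noise_sigma"] < 0:
        errors.append("dataset.noise_sigma must be >= 0")
    if opt["epochs"] < 1 or opt["batch_size"] < 1:
        errors.append("optimizer.epochs and batch_size must be >= 1")
    try:
        for name in ds["class_counts"]:
            data.label_of(name)
    except ValueError as exc:
        errors.append(str(exc))
    if errors:
        raise ConfigError(errors)
    return cfg


# -- small IO helpers --------------------------------------------------------

def _write_gray_png(path: Path, arr: np.ndarray) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(data.to_uint8(arr)).save(path)


def _read_gray_png(path: Path) -> np.ndarray:
    return data.from_uint8(np.asarray(Image.open(path).convert("L")))


def _json_dump(path: Path, obj: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _gabor_params(cfg: dict) -> gabor.GaborParams:
    p = cfg["preprocess"]
    return gabor.GaborParams(
        omega=float(p["omega"]), u=float(p["u"]), v=float(p["v"]), half_size=int(p["half_size"])
    )


def build_trunk_inputs(
    rgb_images: list[np.ndarray],
    gabor_images: list[np.ndarray],
    masks: list[np.ndarray],
    trunk_input: str,
) -> np.ndarray:
    """Stack per-image NCHW classifier inputs from the stage artifacts."""
    batches = []
    for rgb, gab, mask in zip(rgb_images, gabor_images, masks):
        chans = []
        if trunk_input in ("rgb", "rgb+gabor"):
            chans.extend(segmentation.apply_roi(rgb, mask).transpose(2, 0, 1))
        if trunk_input in ("gabor", "rgb+gabor"):
            chans.append(segmentation.apply_roi(gab, mask))
        batches.append(np.stack(chans))
    return np.stack(batches)


# -- stages ------------------------------------------------------------------

def stage_generate(cfg: dict, out: Path) -> None:
    """Render the synthetic dataset and write images + manifest.csv."""
    spec = data.DatasetSpec(
        class_counts=dict(cfg["dataset"]["class_counts"]),
        image_size=tuple(cfg["dataset"]["image_size"]),
        noise_sigma=float(cfg["dataset"]["noise_sigma"]),
        seed=stage_seed(int(cfg["seed"]), "generate"),
    )
    images, manifest = data.generate_dataset(spec)
    data.write_dataset(images, manifest, out / "images")


def stage_preprocess(cfg: dict, out: Path) -> None:
    """Gabor-filter every image; writes preprocessed/<id>.png."""
    images, _ = data.read_dataset(out / "images" / "manifest.csv")
    params = _gabor_params(cfg)
    for img in images:
        resp = gabor.gabor_filter(img.pixels, params, response=cfg["preprocess"]["response"])
        _write_gray_png(out / "preprocessed" / f"{img.id}.png", resp)


def stage_segment(cfg: dict, out: Path) -> None:
    """K-means ROI masks; writes masks/<id>.png and segmentation.csv."""
    images, _ = data.read_dataset(out / "images" / "manifest.csv")
    seed = stage_seed(int(cfg["seed"]), "segment")
    rows = []
    for img in images:
        seg = segmentation.segment_image(
            img.pixels,
            k=int(cfg["segmentation"]["k"]),
            use_local_mean=bool(cfg["segmentation"]["local_mean"]),
            seed=seed,
            equalize=bool(cfg["preprocess"]["equalize"]),
            n_restarts=int(cfg["segmentation"]["n_restarts"]),
        )
        _write_gray_png(out / "masks" / f"{img.id}.png", seg.roi_mask.astype(float))
        rows.append(
            {
                "id": img.id,
                "k": int(cfg["segmentation"]["k"]),
                "inertia": seg.inertia,
                "roi_area_fraction": float(seg.roi_mask.mean()),
            }
        )
    pd.DataFrame(rows).to_csv(out / "segmentation.csv", index=False, float_format="%.8g")


def load_stage_inputs(cfg: dict, out: Path):
    """Rebuild classifier inputs from on-disk artifacts.

    Returns (ids, labels, NCHW inputs, train indices, test indices). The
    split is recomputed deterministically from the manifest and seed.
    """
    images, manifest = data.read_dataset(out / "images" / "manifest.csv")
    ids = [img.id for img in images]
    labels = np.array([img.label.id for img in images])
    rgb = [img.pixels for img in images]
    filtered = [_read_gray_png(out / "preprocessed" / f"{i}.png") for i in ids]
    masks = [_read_gray_png(out / "masks" / f"{i}.png") > 0.5 for i in ids]
    inputs = build_trunk_inputs(rgb, filtered, masks, cfg["network"]["trunk_input"])
    train_imgs, test_imgs = data.split_dataset(
        images, float(cfg["split"]["train_fraction"]), seed=stage_seed(int(cfg["seed"]), "split")
    )
    index = {img_id: i for i, img_id in enumerate(ids)}
    train_idx = np.array(sorted(index[img.id] for img in train_imgs))
    test_idx = np.array(sorted(index[img.id] for img in test_imgs))
    return ids, labels, inputs, train_idx, test_idx


def stage_extract(cfg: dict, out: Path) -> None:
    """Train the SqueezeNet extractor on the train split; write features.csv."""
    net_cfg = cfg["network"]
    ids, labels, inputs, train_idx, _ = load_stage_inputs(cfg, out)
    seed = stage_seed(int(cfg["seed"]), "extract")
    extractor = squeezenet.build_modified_squeezenet(
        feature_dim=int(net_cfg["feature_dim"]),
        dropout_rate=float(net_cfg["dropout"]),
        in_channels=inputs.shape[1],
        base_width=int(net_cfg["base_width"]),
        seed=seed,
    )
    squeezenet.train_feature_extractor(
        extractor,
        inputs[train_idx],
        labels[train_idx] - 1,
        epochs=int(net_cfg["squeezenet_epochs"]),
        seed=seed,
    )
    squeezenet.save_weights(out / "squeezenet.npz", extractor)
    feats = np.vstack(
        [squeezenet.extract_features(inputs[s : s + 64], extractor)
         for s in range(0, inputs.shape[0], 64)]
    )
    df = pd.DataFrame(feats, columns=[f"f{i+1}" for i in range(feats.shape[1])])
    df.insert(0, "id", ids)
    df.to_csv(out / "features.csv", index=False, float_format="%.8g")


def _load_features(out: Path, ids: list[str]) -> np.ndarray:
    df = pd.read_csv(out / "features.csv").set_index("id")
    return df.loc[ids].to_numpy(dtype=float)


def _hdl_spec(cfg: dict, in_channels: int, extra_dim: int) -> HDLSpec:
    net = cfg["network"]
    return HDLSpec(
        n_cr=int(net["n_cr"]),
        n_crp=int(net["n_crp"]),
        lstm_hidden=int(net["lstm_hidden"]),
        head_arrangement=net["head_arrangement"],
        in_channels=in_channels,
        base_width=int(net["base_width"]),
        extra_feature_dim=extra_dim,
    )


def stage_train(cfg: dict, out: Path) -> None:
    """Train the CNN-LSTM classifier; write checkpoint + model metadata."""
    ids, labels, inputs, train_idx, _ = load_stage_inputs(cfg, out)
    use_features = bool(cfg["network"]["use_squeezenet_features"])
    extra_all = _load_features(out, ids) if use_features else None
    spec = _hdl_spec(cfg, inputs.shape[1], extra_all.shape[1] if use_features else 0)
    opt = cfg["optimizer"]
    config = TrainConfig(
        epochs=int(opt["epochs"]),
        batch_size=int(opt["batch_size"]),
        coarse_loss_weight=float(opt["coarse_loss_weight"]),
        seed=stage_seed(int(cfg["seed"]), "train"),
        hyperparams=AdamHyperparams(
            alpha=float(opt["alpha"]), beta1=float(opt["beta1"]),
            beta2=float(opt["beta2"]), eta=float(opt["eta"]),
        ),
    )
    model = train_hdl(
        inputs[train_idx], labels[train_idx], spec, config,
        extra_features=extra_all[train_idx] if use_features else None,
    )
    squeezenet.save_weights(out / "hdl_checkpoint.npz", model)
    _json_dump(
        out / "model_meta.json",
        {
            "schema": "leafdx-model-1",
            "image_size": list(inputs.shape[2:]),
            "in_channels": inputs.shape[1],
            "extra_feature_dim": spec.extra_feature_dim,
            "history": model.history,
        },
    )


def load_model(cfg: dict, out: Path) -> HDLModel:
    """Rebuild the trained classifier from checkpoint + metadata."""
    meta = json.loads((out / "model_meta.json").read_text())
    spec = _hdl_spec(cfg, int(meta["in_channels"]), int(meta["extra_feature_dim"]))
    model = HDLModel(spec, image_size=tuple(meta["image_size"]))
    squeezenet.load_weights(out / "hdl_checkpoint.npz", model)
    model.trained = True
    return model


def evaluate_model(model, inputs, fine_labels, extra=None) -> tuple[dict, np.ndarray]:
    """Predict and score a split; returns (report, confusion matrix)."""
    fine_pred, _, _ = predict(inputs, model, extra_features=extra)
    true_names = [data.label_of(int(f)).name for f in fine_labels]
    pred_names = [data.label_of(int(p)).name for p in fine_pred]
    cm = metrics.confusion_matrix(true_names, pred_names)
    return metrics.metrics_report(cm), cm


def stage_evaluate(cfg: dict, out: Path) -> dict:
    """Score train and test splits; write metrics JSON + confusion CSVs."""
    ids, labels, inputs, train_idx, test_idx = load_stage_inputs(cfg, out)
    use_features = bool(cfg["network"]["use_squeezenet_features"])
    extra_all = _load_features(out, ids) if use_features else None
    model = load_model(cfg, out)
    report = {}
    for split_name, idx in (("train", train_idx), ("test", test_idx)):
        extra = extra_all[idx] if use_features else None
        split_report, cm = evaluate_model(model, inputs[idx], labels[idx], extra)
        report[split_name] = split_report
        _json_dump(out / f"metrics_{split_name}.json", split_report)
        pd.DataFrame(cm, index=list(data.CLASS_NAMES), columns=list(data.CLASS_NAMES)).to_csv(
            out / f"confusion_{split_name}.csv"
        )
        fine_pred, coarse_pred, probs = predict(inputs[idx], model, extra_features=extra)
        from .hdl import COARSE_NAMES

        preds = pd.DataFrame(probs, columns=[f"p{i}" for i in range(1, 7)])
        preds.insert(0, "coarse_label", [COARSE_NAMES[c] for c in coarse_pred])
        preds.insert(0, "fine_label", [data.label_of(int(f)).name for f in fine_pred])
        preds.insert(0, "id", [ids[i] for i in idx])
        preds.sort_values("id").to_csv(
            out / f"predictions_{split_name}.csv", index=False, float_format="%.8g"
        )
    return report


PIPELINE_STAGES = ("generate", "preprocess", "segment", "extract", "train", "evaluate")


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path) -> tuple[dict, dict]:
    """Execute all stages in order; returns (run_record, report).

    ``report`` carries the test-split metrics under ``"test"`` and the
    training-split metrics under ``"train"``, each shaped like the
    tabulated per-class + average reports.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {}
    stage_fns = {
        "generate": stage_generate,
        "preprocess": stage_preprocess,
        "segment": stage_segment,
        "extract": stage_extract,
        "train": stage_train,
        "evaluate": stage_evaluate,
    }
    for name in PIPELINE_STAGES:
        if name == "extract" and not cfg["network"]["use_squeezenet_features"]:
            continue
        t0 = time.perf_counter()
        try:
            result = stage_fns[name](cfg, out)
        except FileNotFoundError as exc:
            raise RuntimeError(f"stage '{name}' is missing an upstream artifact: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        if name == "evaluate":
            report = result
    record = {
        "schema": "leafdx-run-1",
        "config": cfg,
        "seeds": {name: stage_seed(int(cfg["seed"]), name) for name in STAGE_OFFSETS},
        "timings": timings,
        "input_hash": hashlib.sha256((out / "images" / "manifest.csv").read_bytes()).hexdigest(),
        "artifacts": {
            "manifest": str(out / "images" / "manifest.csv"),
            "metrics_test": str(out / "metrics_test.json"),
            "metrics_train": str(out / "metrics_train.json"),
        },
    }
    _json_dump(out / "run_record.json", record)
    return record, report


def tune_hyperparams(
    config: dict | str | Path | None,
    out_dir: str | Path | None = None,
    population: int | None = None,
    iterations: int | None = None,
) -> tuple[rtgo.OptimizationResult, dict]:
    """RTGO over the 4-D hyperparameter space at reduced training budget.

    Builds a reduced dataset/pipeline in memory from the config's dataset
    block, splits train/validation, and minimizes the validation error
    rate. Returns the optimization result and the decoded best
    hyperparameters.
    """
    cfg = validate_config(config)
    root = int(cfg["seed"])
    spec = data.DatasetSpec(
        class_counts=dict(cfg["dataset"]["class_counts"]),
        image_size=tuple(cfg["dataset"]["image_size"]),
        noise_sigma=float(cfg["dataset"]["noise_sigma"]),
        seed=stage_seed(root, "generate"),
    )
    images, _ = data.generate_dataset(spec)
    gparams = _gabor_params(cfg)
    rgb = [img.pixels for img in images]
    filtered = [gabor.gabor_filter(a, gparams) for a in rgb]
    seg_seed = stage_seed(root, "segment")
    masks = [
        segmentation.segment_image(a, k=int(cfg["segmentation"]["k"]), seed=seg_seed).roi_mask
        for a in rgb
    ]
    inputs = build_trunk_inputs(rgb, filtered, masks, cfg["network"]["trunk_input"])
    labels = np.array([img.label.id for img in images])
    train_imgs, val_imgs = data.split_dataset(
        images, float(cfg["split"]["train_fraction"]), seed=stage_seed(root, "split")
    )
    index = {img.id: i for i, img in enumerate(images)}
    tr = np.array(sorted(index[img.id] for img in train_imgs))
    va = np.array(sorted(index[img.id] for img in val_imgs))
    context = rtgo.TuningContext(
        train_images=inputs[tr],
        train_labels=labels[tr],
        val_images=inputs[va],
        val_labels=labels[va],
        spec_template=_hdl_spec(cfg, inputs.shape[1], 0),
        epochs=int(cfg["tuning"]["epochs"]),
        seed=stage_seed(root, "tune"),
    )
    space = rtgo.SearchSpace(
        lower=tuple(float(x) for x in cfg["tuning"]["lower"]),
        upper=tuple(float(x) for x in cfg["tuning"]["upper"]),
        integral=(False, False, True, True),
    )
    result = rtgo.rtgo_optimize(
        lambda x: rtgo.classifier_error_fitness(x, context),
        space,
        n=population or int(cfg["tuning"]["population"]),
        iterations=iterations or int(cfg["tuning"]["iterations"]),
        seed=stage_seed(root, "tune"),
    )
    best = rtgo.decode_hyperparams(result.best_position)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"iteration": range(1, len(result.trace) + 1), "best_fitness": result.trace}
        ).to_csv(out / "tuning_trace.csv", index=False, float_format="%.8g")
        _json_dump(out / "best_hyperparams.json", {"best_error_rate": result.best_objective, **best})
    return result, best
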