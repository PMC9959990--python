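"""End-to-end pipeline: generate -> segment -> repair -> features -> select
-> train -> evaluate, driven by a nested YAML config with strict key
validation.  Every stage persists its artifacts under the run directory and
the run log records seeds, the config hash, and sha256 hashes of all
artifacts for bit-reproducibility checks."""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import border_repair as br
from . import classifier as clf
from . import evaluation as ev
from . import features as ft
from . import imageio as sio
from . import phantom as ph
from . import segmentation as seg
from . import stoa


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "run",
    "log_level": "INFO",
    "phantom": {"n_per_class": 20, "image_size": 256, "noise_sd": 2.0},
    "segmentation": {"air_threshold": 40, "grow_threshold": 25,
                     "dark_majority_fraction": 0.5, "connectivity": 8},
    "repair": {"line_width": 4, "opening_radius": 3},
    "features": {"radius": 1, "neighbours": 8},
    "selection": {"pop_size": 20, "max_iter": 30, "alpha": 0.01},
    "classifier": {"epochs": 15, "learning_rate": 0.05, "batch_size": 64,
                   "drop_rate": 0.25, "input_mode": "nodule_crop"},
    "evaluation": {"train_fraction": 0.7},
}


class ConfigError(ValueError):
    pass


def load_config(source) -> dict:
    """Merge a YAML file / dict over the defaults, rejecting unknown keys
    and missing sections."""
    if source is None:
        user: dict = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config section or key: {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, sval in value.items():
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown key {key}.{sub}")
                cfg[key][sub] = sval
        else:
            cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def mine_nodule_candidate(img: np.ndarray,
                          assrg: seg.AssrgParams | None = None,
                          nhbcc: br.NhbccParams | None = None,
                          min_area: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Candidate-nodule mask via segmentation, repair, and component analysis.

    Bright structures *inside* the border-corrected lobes but outside the
    grown air region (nodules, vessels) are labelled; the largest connected
    component of at least ``min_area`` pixels is the candidate.  Returns
    (candidate mask, corrected-lobe union mask); the candidate mask is empty
    when the lobes contain no bright structure (a normal slice).
    """
    assrg = assrg or seg.AssrgParams()
    nhbcc = nhbcc or br.NhbccParams()
    left, right, _ = seg.segment_lungs(img, assrg)
    union = np.zeros(img.shape, dtype=bool)
    for mask in (left, right):
        try:
            union |= br.close_border(mask, nhbcc)
        except (br.BorderRepairFailure, ValueError):
            union |= mask
    from scipy import ndimage as ndi

    bright = union & ~(left | right) & (img >= assrg.air_threshold)
    labels, n = ndi.label(bright, structure=np.ones((3, 3), int))
    best = np.zeros(img.shape, dtype=bool)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        if areas.max() >= min_area:
            best = labels == 1 + int(np.argmax(areas))
    return best, union


def _crop_window(img: np.ndarray, center: tuple[float, float], size: int) -> np.ndarray:
    r = int(round(center[0] - size / 2))
    c = int(round(center[1] - size / 2))
    r = min(max(r, 0), img.shape[0] - size)
    c = min(max(c, 0), img.shape[1] - size)
    return img[r: r + size, c: c + size]


def prepare_classifier_inputs(manifest: pd.DataFrame, mode: str = "nodule_crop",
                              assrg: seg.AssrgParams | None = None,
                              nhbcc: br.NhbccParams | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Build (X, y) for the CNN-GRU from a manifest.

    ``nodule_crop`` (default): mine the candidate-nodule component inside
    the border-corrected lobes (:func:`mine_nodule_candidate`) and crop a
    50x50 window around its centroid at native resolution; slices with no
    candidate (normal) are cropped at the lobe-union centroid.
    ``lobe_crop``: crop the union bounding box of the corrected lobes and
    resize.  ``raw``: resize whole images.
    """
    if mode not in ("nodule_crop", "lobe_crop", "raw"):
        raise ValueError(f"unknown input mode {mode!r}")
    assrg = assrg or seg.AssrgParams()
    nhbcc = nhbcc or br.NhbccParams()
    size = 50
    images = []
    for path in manifest["path"]:
        img = sio.load_image(path)
        if mode == "raw":
            images.append(img)
            continue
        if mode == "nodule_crop":
            candidate, union = mine_nodule_candidate(img, assrg, nhbcc)
            target = candidate if candidate.any() else union
            if target.any():
                center = tuple(np.argwhere(target).mean(axis=0))
            else:
                center = (img.shape[0] / 2, img.shape[1] / 2)
            images.append(_crop_window(img, center, size))
            continue
        left, right, _ = seg.segment_lungs(img, assrg)
        union = np.zeros(img.shape, dtype=bool)
        for mask in (left, right):
            try:
                union |= br.close_border(mask, nhbcc)
            except (br.BorderRepairFailure, ValueError):
                union |= mask
        rows, cols = np.nonzero(union)
        if len(rows) == 0:
            images.append(img)
            continue
        r0, r1 = max(rows.min() - 4, 0), min(rows.max() + 5, img.shape[0])
        c0, c1 = max(cols.min() - 4, 0), min(cols.max() + 5, img.shape[1])
        images.append(img[r0:r1, c0:c1])
    return clf.prepare_images(images), clf.labels_to_int(manifest["label"])


def run_pipeline(config=None, out_dir: str | Path | None = None) -> Path:
    """Execute all stages; returns the run directory."""
    cfg = load_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    run_dir = Path(cfg["out_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log_path = run_dir / "run_log.jsonl"
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    (run_dir / "config.yaml").write_text(cfg_text)

    def log(stage: str, **info) -> None:
        entry = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **info}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    log("start", seed=seed,
        config_sha256=hashlib.sha256(cfg_text.encode()).hexdigest(),
        numpy_version=np.__version__)

    # 1. generate ----------------------------------------------------------
    data_dir = run_dir / "data"
    manifest_path = ph.generate_dataset(
        int(cfg["phantom"]["n_per_class"]), data_dir, seed,
        spec_overrides={"image_size": int(cfg["phantom"]["image_size"]),
                        "noise_sd": float(cfg["phantom"]["noise_sd"])})
    manifest = sio.load_manifest(manifest_path)
    log("generate", manifest=str(manifest_path), n=len(manifest))

    # 2-3. segment + repair ------------------------------------------------
    assrg = seg.AssrgParams(**{k: v for k, v in cfg["segmentation"].items()})
    nhbcc = br.NhbccParams(**{k: v for k, v in cfg["repair"].items()})
    seg_dir = run_dir / "segmentation"
    seg_dir.mkdir(exist_ok=True)
    repaired_masks, dice_scores = [], []
    for i, row in manifest.iterrows():
        img = sio.load_image(row["path"])
        left, right, _ = seg.segment_lungs(img, assrg)
        stem = Path(row["path"]).stem
        union = np.zeros(img.shape, dtype=bool)
        for side, mask in (("left", left), ("right", right)):
            sio.save_mask(mask, seg_dir / f"{stem}_{side}_assrg.png")
            try:
                fixed = br.close_border(mask, nhbcc)
            except (br.BorderRepairFailure, ValueError):
                fixed = mask
            sio.save_mask(fixed, seg_dir / f"{stem}_{side}_ibcl.png")
            union |= fixed
        repaired_masks.append(union)
        truth = sio.load_mask(row["lobe_left"]) | sio.load_mask(row["lobe_right"])
        dice_scores.append(ev.dice(left | right, truth))
    log("segment_repair", mean_dice_vs_truth=float(np.mean(dice_scores)))

    # 4. features ----------------------------------------------------------
    lbp = ft.LbpParams(**{k: int(v) for k, v in cfg["features"].items()})
    images = [sio.load_image(p) for p in manifest["path"]]
    X_feat, names = ft.extract_feature_matrix(images, repaired_masks, lbp)
    sio.features_to_csv(X_feat, names, run_dir / "features.csv")
    log("features", shape=list(X_feat.shape))

    # 5. select ------------------------------------------------------------
    sel_cfg = cfg["selection"]
    fm = stoa.select_features(
        X_feat, manifest["label"].to_numpy(),
        stoa.StoaParams(pop_size=int(sel_cfg["pop_size"]),
                        max_iter=int(sel_cfg["max_iter"]), seed=seed),
        alpha=float(sel_cfg["alpha"]), names=names)
    pd.DataFrame({"feature": names, "selected": fm.mask.astype(int)}).to_csv(
        run_dir / "feature_mask.csv", index=False)
    log("select", n_selected=fm.n_selected, fitness=fm.fitness)

    # 6. train -------------------------------------------------------------
    ccfg = cfg["classifier"]
    train_df, test_df = ev.split(manifest, float(cfg["evaluation"]["train_fraction"]),
                                 seed=seed)
    X_tr, y_tr = prepare_classifier_inputs(train_df, ccfg["input_mode"], assrg, nhbcc)
    X_te, y_te = prepare_classifier_inputs(test_df, ccfg["input_mode"], assrg, nhbcc)
    model = clf.build_model(seed=seed, drop_rate=ccfg["drop_rate"])
    tc = clf.TrainConfig(learning_rate=float(ccfg["learning_rate"]),
                         epochs=int(ccfg["epochs"]),
                         batch_size=int(ccfg["batch_size"]),
                         drop_rate=ccfg["drop_rate"], seed=seed)
    history = clf.train(model, (X_tr, y_tr), tc)
    ckpt = run_dir / "model.npz"
    clf.save_checkpoint(model, ckpt)
    log("train", final_loss=history["loss"][-1], final_acc=history["accuracy"][-1])

    # 7. evaluate ----------------------------------------------------------
    probs, pred_labels = clf.predict(model, X_te)
    true_labels = [sio.CLASS_LABELS[k] for k in y_te]
    cm, classes = ev.confusion(true_labels, pred_labels,
                               classes=list(sio.CLASS_LABELS))
    report = ev.metrics(cm, classes)
    report.table.to_csv(run_dir / "metrics.csv")
    roc_points, auc_value = ev.roc_auc(1.0 - probs[:, 0],
                                       ev.pooled_positive_labels(true_labels))
    roc_points.to_csv(run_dir / "roc.csv", index=False)
    log("evaluate", test_accuracy=report.accuracy, auc=auc_value)

    hashes = {str(p.relative_to(run_dir)): _sha256(p)
              for p in sorted(run_dir.rglob("*"))
              if p.is_file() and p.name != "run_log.jsonl"}
    (run_dir / "artifact_hashes.json").write_text(json.dumps(hashes, indent=1))
    log("done", n_artifacts=len(hashes))
    return run_dir
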