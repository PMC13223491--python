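"""End-to-end run: phantoms → POA tuning → DnCNN → masks → classifier → metrics.

The flow mirrors the accelerator study's software pipeline: generate the
synthetic dataset, optionally tune segmentation hyperparameters with POA
(the default configuration is warm-started into the population, so tuning
can only match or improve on it), train the denoiser and the segmenter,
run inference through the selected arithmetic backend, post-process the
masks, classify the lesions, and score everything.  The JSON report is a
pure function of (config, seed): no wall-clock values enter it, so two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
import time
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import classifier as clf
from . import dncnn_model as dm
from . import metrics as mx
from . import phantom_data as pd_
from . import poa_optimizer as poa

__all__ = ["RunConfig", "DataConfig", "ModelConfig", "OptimizerConfig",
           "run_pipeline", "load_config"]

log = logging.getLogger("vedicnn")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Section):
    n: int = 30
    size: int = 64
    lesion_area_frac: float = 0.08
    speckle_scale: float = 0.5
    gaussian_sigma: float = 0.02
    split_ratio: float = 0.8


class ModelConfig(_Section):
    depth: int = 5
    width: int = 16
    learning_rate: float = 2e-3
    denoise_learning_rate: float = 3e-3
    denoise_epochs: int = 40
    segment_epochs: int = 25
    batch_size: int = 4
    mask_threshold: float = 0.5
    postprocess_radius: int = 1


class OptimizerConfig(_Section):
    enabled: bool = True
    pop: int = 4
    iters: int = 3
    budget_epochs: int = 6
    fitness_train: int = 8       # phantoms used inside the fitness function
    fitness_val: int = 4


class MetricsConfig(_Section):
    peak: float = 1.0


class RunConfig(_Section):
    seed: int = 0
    backend: Literal["exact", "cutin_fp32", "cutin_fp16"] = "exact"
    output_dir: str | None = None
    data: DataConfig = DataConfig()
    model: ModelConfig = ModelConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    metrics: MetricsConfig = MetricsConfig()


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _stage(name: str):
    log.info("stage=%s start", name)
    return time.monotonic()


def _stage_done(name: str, t0: float) -> None:
    log.info("stage=%s wall=%.2fs", name, time.monotonic() - t0)


def _mean(vals) -> float:
    vals = [v for v in vals if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def run_pipeline(cfg: RunConfig, save_outputs: bool = True) -> dict:
    """Execute every stage; returns (and optionally writes) the JSON report."""
    cfg_json = cfg.model_dump_json()
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    out = Path(cfg.output_dir) if (cfg.output_dir and save_outputs) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- data ------------------------------------------------------------
    t0 = _stage("gen-data")
    d = cfg.data
    train_ph, test_ph = pd_.generate_dataset(
        d.n, split_ratio=d.split_ratio, seed=cfg.seed,
        size=(d.size, d.size), lesion_area_frac=d.lesion_area_frac,
        speckle_scale=d.speckle_scale, gaussian_sigma=d.gaussian_sigma)
    if out:
        pd_.write_manifest(out / "manifest.csv", train_ph + test_ph)
    _stage_done("gen-data", t0)

    # ---- denoiser --------------------------------------------------------
    t0 = _stage("train-denoise")
    m = cfg.model
    den_net = dm.build(dm.NetworkSpec(depth=m.depth, width=m.width,
                                      head="denoise"), seed=cfg.seed)
    dm.train(den_net, [(p.image, p.clean) for p in train_ph],
             dm.TrainConfig(learning_rate=m.denoise_learning_rate,
                            epochs=m.denoise_epochs,
                            batch_size=m.batch_size, seed=cfg.seed + 1))
    psnr_noisy = [mx.psnr(p.clean, p.image, cfg.metrics.peak) for p in test_ph]
    denoised_test = [dm.denoise(den_net, p.image) for p in test_ph]
    psnr_den = [mx.psnr(p.clean, den, cfg.metrics.peak)
                for p, den in zip(test_ph, denoised_test)]
    _stage_done("train-denoise", t0)

    # ---- hyperparameter tuning ------------------------------------------
    t0 = _stage("optimize")
    o = cfg.optimizer
    default_pos = np.array([math.log10(m.learning_rate), m.depth, m.width,
                            m.mask_threshold, m.postprocess_radius],
                           dtype=float)
    fit_train = train_ph[:o.fitness_train]
    fit_val = train_ph[o.fitness_train:o.fitness_train + o.fitness_val]
    if o.enabled and fit_val:
        def fitness(pos):
            return poa.dncnn_fitness(pos, fit_train, fit_val,
                                     epochs=o.budget_epochs,
                                     seed=cfg.seed + 2)
        default_fitness = fitness(default_pos)
        best, trace = poa.optimize(fitness, poa.HYPERPARAM_BOUNDS,
                                   poa.POAConfig(o.pop, o.iters,
                                                 seed=cfg.seed + 3),
                                   warm_starts=[default_pos])
        hp = poa.decode_candidate(best.position)
        poa_report = {
            "enabled": True,
            "default_fitness": default_fitness,
            "tuned_fitness": best.fitness,
            "best_position": [float(v) for v in best.position],
            "trace": trace,
            "hyperparameters": hp,
        }
    else:
        hp = poa.decode_candidate(default_pos)
        poa_report = {"enabled": False, "hyperparameters": hp}
    if out:
        (out / "poa_trace.json").write_text(json.dumps(poa_report, indent=2))
    _stage_done("optimize", t0)

    # ---- segmenter on denoised images -----------------------------------
    t0 = _stage("train-segment")
    seg_net = dm.build(dm.NetworkSpec(depth=hp["depth"], width=hp["width"],
                                      head="segment"), seed=cfg.seed + 4)
    denoised_train = [dm.denoise(den_net, p.image) for p in train_ph]
    dm.train(seg_net, [(img, p.mask)
                       for img, p in zip(denoised_train, train_ph)],
             dm.TrainConfig(learning_rate=hp["learning_rate"],
                            epochs=m.segment_epochs,
                            batch_size=m.batch_size, seed=cfg.seed + 5,
                            mask_threshold=hp["mask_threshold"]))
    _stage_done("train-segment", t0)

    # ---- segment + postprocess + evaluate -------------------------------
    t0 = _stage("segment")
    per_image = []
    pred_masks = []
    for p, den in zip(test_ph, denoised_test):
        mask = dm.segment(seg_net, den, hp["mask_threshold"],
                          backend=cfg.backend)
        mask = dm.postprocess(mask, hp["radius"])
        pred_masks.append(mask)
        sc = mx.scores(mx.confusion(mask, p.mask))
        sc.pop("defined")
        per_image.append(sc)
    seg_report = {k: _mean(s[k] for s in per_image)
                  for k in ("accuracy", "precision", "specificity",
                            "sensitivity", "f_score", "iou", "dsc")}
    _stage_done("segment", t0)

    # ---- classifier ------------------------------------------------------
    t0 = _stage("classify")
    lab = {"benign": 0, "malignant": 1}
    feats, labels = [], []
    for p in train_ph:
        if p.label in lab and p.mask.any():
            feats.append(clf.extract_features(p.image, p.mask))
            labels.append(lab[p.label])
    cls_report: dict = {"n_train": len(labels)}
    if len(set(labels)) >= 2:
        model = clf.fit(feats, labels)
        tp = tn = fp = fn = 0
        skipped = 0
        for p, mask in zip(test_ph, pred_masks):
            if p.label not in lab:
                continue
            use_mask = mask if mask.any() else p.mask
            if not mask.any():
                skipped += 1
            pred, _margin = model.predict(
                clf.extract_features(p.image, use_mask))
            truth = lab[p.label]
            if truth == 1:
                tp += pred == 1
                fn += pred == 0
            else:
                tn += pred == 0
                fp += pred == 1
        total = tp + tn + fp + fn
        cls_report.update({
            "confusion": {"tp": int(tp), "tn": int(tn),
                          "fp": int(fp), "fn": int(fn)},
            "accuracy": (tp + tn) / total if total else float("nan"),
            "misclassified": int(fp + fn),
            "empty_prediction_fallbacks": skipped,
        })
    _stage_done("classify", t0)

    report = {
        "seed": cfg.seed,
        "backend": cfg.backend,
        "config_hash": cfg_hash,
        "config": json.loads(cfg_json),
        "denoise": {
            "psnr_noisy_mean_db": _mean(psnr_noisy),
            "psnr_denoised_mean_db": _mean(psnr_den),
            "psnr_gain_db": _mean(pd - pn
                                  for pd, pn in zip(psnr_den, psnr_noisy)),
        },
        "poa": poa_report,
        "segmentation": seg_report,
        "segmentation_per_image": per_image,
        "classification": cls_report,
    }
    if out:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        _write_images(out, test_ph, denoised_test, pred_masks)
    return report


def _write_images(out: Path, phantoms, denoised, masks) -> None:
    import imageio.v3 as iio

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for i, (p, den, mask) in enumerate(zip(phantoms, denoised, masks)):
        iio.imwrite(img_dir / f"test_{i:03d}_noisy.png",
                    (p.image * 255).astype(np.uint8))
        iio.imwrite(img_dir / f"test_{i:03d}_denoised.png",
                    (den * 255).astype(np.uint8))
        iio.imwrite(img_dir / f"test_{i:03d}_mask.png",
                    (mask * 255).astype(np.uint8))
        iio.imwrite(img_dir / f"test_{i:03d}_truth.png",
                    (p.mask * 255).astype(np.uint8))
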