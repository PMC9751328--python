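"""Stage orchestration: one verb per pipeline box, with manifests.

Each stage reads its upstream artifacts from the run directory, writes its
outputs there and drops a ``<stage>_manifest.json`` echoing the config,
the derived stage seed, SHA-256 hashes of the inputs it consumed and the
files it produced. Reruns with identical inputs and config are idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import checkpoint, io as sio
from .config import RunConfig
from .downstream import (predict_batch, train_binary_head,
                         train_supervised_baseline)
from .evaluate import (LabelOracle, class_distribution_heatmap, cross_validate,
                       format_report_table, generate_cam, heatmap_table)
from .patches import (Patch, derive_labels, extract_patches, label_table,
                      split_dataset)
from .preprocess import preprocess_image
from .ssl import pretrain
from .synthetic import generate_dataset
from .types import CLASS_ORDER, CLASS_NAMES

logger = logging.getLogger("semssl")

STAGES = ("synth", "preprocess", "patchify", "pretrain", "linear-eval",
          "finetune", "baseline", "evaluate", "cam", "heatmap")


class DependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} requires outputs that do not exist yet: "
            f"{missing}; run the upstream stage first")


def _write_manifest(stage: str, out_dir: Path, cfg: RunConfig,
                    inputs: Sequence[Path], outputs: Sequence[Path]) -> Path:
    from importlib.metadata import version
    try:
        ver = version("semssl")
    except Exception:
        ver = "unknown"
    manifest = {
        "stage": stage,
        "seed": cfg.stage_seed(stage),
        "config": cfg.to_dict(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in sorted(map(Path, outputs))},
        "semssl_version": ver,
    }
    path = out_dir / f"{stage.replace('-', '_')}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _load_patches(out_dir: Path, stage: str):
    """Rebuild patches + labels + splits from the patchify stage outputs."""
    table_path = out_dir / "patches.tsv"
    pre_dir = out_dir / "preprocessed"
    _require(stage, table_path, pre_dir / "metadata.tsv")
    table = pd.read_csv(table_path, sep="\t")
    images = {img.source_id: img for img in sio.load_dataset(pre_dir)}
    patches, splits = [], {"repr": [], "finetune": [], "test": []}
    for i, row in table.iterrows():
        img = images[row["source_id"]]
        k = int(row["kernel"])
        r, c = int(row["row"]), int(row["col"])
        patches.append(Patch(pixels=img.pixels[r:r + k, c:c + k],
                             annotation=img.annotation[r:r + k, c:c + k],
                             origin=(r, c), source_id=img.source_id, m=k))
        splits[row["split"]].append(i)
    # labels come from the stored flags: the table is the single source of
    # truth once patchify has run
    from .patches import MultiLabel
    labels = [MultiLabel(bool(r.byproduct), bool(r.cell), bool(r.surface))
              for r in table.itertuples()]
    return patches, labels, splits, [table_path]


def run_stage(stage: str, cfg: RunConfig) -> Dict:
    """Execute one pipeline stage; returns a summary dict."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed(stage)
    logger.info("stage=%s seed=%d out=%s", stage, seed, out_dir)
    return _DISPATCH[stage](cfg, out_dir, seed)


# ---------------------------------------------------------------------------

def _stage_synth(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    data_dir = out_dir / "raw"
    images = generate_dataset(cfg.synth.n_images, cfg.synth.scene, seed,
                              out_dir=str(data_dir))
    outputs = sorted(data_dir.iterdir())
    _write_manifest("synth", out_dir, cfg, [], outputs)
    return {"n_images": len(images), "dir": str(data_dir)}


def _stage_preprocess(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    raw_dir = out_dir / "raw"
    _require("preprocess", raw_dir / "metadata.tsv")
    images = sio.load_dataset(raw_dir)
    processed = [preprocess_image(img, cfg.preprocess) for img in images]
    pre_dir = out_dir / "preprocessed"
    sio.save_dataset(processed, pre_dir)
    _write_manifest("preprocess", out_dir, cfg,
                    sorted(raw_dir.iterdir()), sorted(pre_dir.iterdir()))
    return {"n_images": len(processed), "dir": str(pre_dir)}


def _stage_patchify(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    pre_dir = out_dir / "preprocessed"
    _require("patchify", pre_dir / "metadata.tsv")
    images = sio.load_dataset(pre_dir)
    kernel = cfg.patchify.kernel
    stride = cfg.patchify.resolved_stride()
    patches, labels = [], []
    for img in images:
        for p in extract_patches(img, kernel, stride):
            patches.append(p)
            labels.append(derive_labels(p.annotation, cfg.patchify.min_fraction))
    plan = cfg.patchify.split
    plan.seed = seed
    splits = split_dataset(patches, plan)
    table = label_table(patches, labels, splits)
    table_path = out_dir / "patches.tsv"
    table.to_csv(table_path, sep="\t", index=False)
    _write_manifest("patchify", out_dir, cfg, sorted(pre_dir.iterdir()),
                    [table_path])
    return {"n_patches": len(patches), "kernel": kernel, "stride": stride,
            "split_sizes": {k: len(v) for k, v in splits.items()}}


def _stage_pretrain(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    patches, _labels, splits, inputs = _load_patches(out_dir, "pretrain")
    repr_patches = [patches[i] for i in splits["repr"]]
    ssl_cfg = cfg.ssl
    ssl_cfg.seed = seed
    variant = ssl_cfg_variant(cfg)
    state, trace = pretrain(repr_patches, variant, ssl_cfg)
    ckpt = out_dir / f"encoder_{variant}.npz"
    checkpoint.save_state(state, ckpt)
    trace_path = out_dir / f"loss_trace_{variant}.tsv"
    pd.DataFrame({"epoch": np.arange(1, len(trace) + 1),
                  "mean_loss": trace}).to_csv(trace_path, sep="\t", index=False)
    _write_manifest("pretrain", out_dir, cfg, inputs, [ckpt, trace_path])
    return {"variant": variant, "loss_trace": trace, "checkpoint": str(ckpt)}


def ssl_cfg_variant(cfg: RunConfig) -> str:
    return getattr(cfg, "_variant", "noncontrastive")


def set_variant(cfg: RunConfig, variant: str) -> RunConfig:
    cfg._variant = variant  # transient CLI selection, not serialized
    return cfg


def _train_heads(cfg: RunConfig, out_dir: Path, seed: int, mode: str,
                 stage: str) -> Dict:
    patches, labels, splits, inputs = _load_patches(out_dir, stage)
    variant = ssl_cfg_variant(cfg)
    ckpt = out_dir / f"encoder_{variant}.npz"
    _require(stage, ckpt)
    state = checkpoint.load_state(ckpt)
    ft_idx = splits["finetune"]
    probe = cfg.downstream
    probe.mode = mode
    probe.seed = seed
    models = {c: train_binary_head(state, [patches[i] for i in ft_idx],
                                   [labels[i] for i in ft_idx], c, probe)
              for c in CLASS_ORDER}
    heads_path = out_dir / f"heads_{variant}_{mode}.npz"
    checkpoint.save_heads(models, heads_path)
    # test-set accuracy summary
    test_idx = splits["test"]
    preds = predict_batch(models, [patches[i] for i in test_idx],
                          probe.decision_threshold)
    pred_arr = np.array([p.decisions for p in preds])
    truth = np.stack([labels[i].as_array() for i in test_idx])
    acc = {name: float((pred_arr[:, j] == truth[:, j]).mean())
           for j, name in enumerate(CLASS_NAMES)}
    acc["overall"] = float(np.mean(list(acc.values())))
    _write_manifest(stage, out_dir, cfg, inputs + [ckpt], [heads_path])
    return {"variant": variant, "mode": mode, "test_accuracy": acc,
            "heads": str(heads_path)}


def _stage_linear_eval(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    return _train_heads(cfg, out_dir, seed, "linear_frozen", "linear-eval")


def _stage_finetune(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    return _train_heads(cfg, out_dir, seed, "finetune", "finetune")


def _stage_baseline(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    patches, labels, splits, inputs = _load_patches(out_dir, "baseline")
    ft_idx = splits["finetune"]
    probe = cfg.downstream
    probe.mode = "finetune"
    probe.seed = seed
    models = train_supervised_baseline([patches[i] for i in ft_idx],
                                       [labels[i] for i in ft_idx], probe,
                                       tuple(cfg.ssl.encoder_channels))
    heads_path = out_dir / "heads_supervised.npz"
    checkpoint.save_heads(models, heads_path)
    test_idx = splits["test"]
    preds = predict_batch(models, [patches[i] for i in test_idx],
                          probe.decision_threshold)
    pred_arr = np.array([p.decisions for p in preds])
    truth = np.stack([labels[i].as_array() for i in test_idx])
    acc = {name: float((pred_arr[:, j] == truth[:, j]).mean())
           for j, name in enumerate(CLASS_NAMES)}
    acc["overall"] = float(np.mean(list(acc.values())))
    _write_manifest("baseline", out_dir, cfg, inputs, [heads_path])
    return {"mode": "supervised", "test_accuracy": acc, "heads": str(heads_path)}


def _stage_evaluate(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    patches, labels, splits, inputs = _load_patches(out_dir, "evaluate")
    variant = ssl_cfg_variant(cfg)
    ckpt = out_dir / f"encoder_{variant}.npz"
    _require("evaluate", ckpt)
    state = checkpoint.load_state(ckpt)
    pool = splits["finetune"] + splits["test"]
    pool_patches = [patches[i] for i in pool]
    pool_labels = [labels[i] for i in pool]
    probe = cfg.downstream

    def pipeline_fn(train_idx, test_idx, repeat_seed):
        import dataclasses
        p = dataclasses.replace(probe, seed=repeat_seed)
        models = {c: train_binary_head(
            state, [pool_patches[i] for i in train_idx],
            [pool_labels[i] for i in train_idx], c, p) for c in CLASS_ORDER}
        preds = predict_batch(models, [pool_patches[i] for i in test_idx],
                              p.decision_threshold)
        pred = np.array([q.decisions for q in preds])
        truth = np.stack([pool_labels[i].as_array() for i in test_idx])
        return pred, truth

    report = cross_validate(pipeline_fn, len(pool), folds=cfg.evaluate.folds,
                            seed=seed, protocol=probe.mode,
                            scheme=cfg.evaluate.scheme,
                            config_echo={"variant": variant,
                                         **_probe_echo(probe)})
    report_path = out_dir / f"eval_report_{variant}_{probe.mode}.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2))
    text_path = out_dir / f"eval_report_{variant}_{probe.mode}.txt"
    text_path.write_text(format_report_table({f"{variant} ({probe.mode})": report}))
    _write_manifest("evaluate", out_dir, cfg, inputs + [ckpt],
                    [report_path, text_path])
    return {"report": report.to_dict(), "paths": [str(report_path)]}


def _probe_echo(probe) -> Dict:
    import dataclasses
    d = dataclasses.asdict(probe)
    return d


def _stage_cam(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    patches, labels, splits, inputs = _load_patches(out_dir, "cam")
    variant = ssl_cfg_variant(cfg)
    heads_path = out_dir / f"heads_{variant}_{cfg.downstream.mode}.npz"
    _require("cam", heads_path)
    models = checkpoint.load_heads(heads_path)
    rng = np.random.default_rng(seed)
    pick = rng.choice(splits["test"], size=min(4, len(splits["test"])),
                      replace=False)
    cam_dir = out_dir / "cams"
    cam_dir.mkdir(exist_ok=True)
    outputs = []
    for i in pick:
        patch = patches[i]
        fig, axes = plt.subplots(1, 4, figsize=(12, 3))
        axes[0].imshow(patch.pixels, cmap="gray")
        axes[0].set_title("patch")
        for ax, c in zip(axes[1:], CLASS_ORDER):
            ax.imshow(generate_cam(models[c], patch), cmap="jet", vmin=0, vmax=1)
            ax.set_title(c.name.capitalize())
        for ax in axes:
            ax.axis("off")
        path = cam_dir / f"cam_{patch.source_id}_{patch.origin[0]}_{patch.origin[1]}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=90)
        plt.close(fig)
        outputs.append(path)
    _write_manifest("cam", out_dir, cfg, inputs + [heads_path], outputs)
    return {"n_cams": len(outputs), "dir": str(cam_dir)}


def _stage_heatmap(cfg: RunConfig, out_dir: Path, seed: int) -> Dict:
    from .evaluate import save_heatmap_png
    pre_dir = out_dir / "preprocessed"
    variant = ssl_cfg_variant(cfg)
    heads_path = out_dir / f"heads_{variant}_{cfg.downstream.mode}.npz"
    _require("heatmap", pre_dir / "metadata.tsv", heads_path)
    models = checkpoint.load_heads(heads_path)
    images = sio.load_dataset(pre_dir)
    hm_dir = out_dir / "heatmaps"
    hm_dir.mkdir(exist_ok=True)
    kernel = cfg.patchify.kernel
    stride = cfg.patchify.resolved_stride()
    outputs = []
    for img in images:
        hms = class_distribution_heatmap(img, models, kernel, stride,
                                         cfg.downstream.decision_threshold)
        png = hm_dir / f"{img.source_id}_heatmap.png"
        save_heatmap_png(hms, img, str(png))
        tsv = hm_dir / f"{img.source_id}_heatmap.tsv"
        heatmap_table(hms).to_csv(tsv, sep="\t", index=False)
        outputs += [png, tsv]
    _write_manifest("heatmap", out_dir, cfg, [pre_dir / "metadata.tsv",
                                              heads_path], outputs)
    return {"n_images": len(images), "dir": str(hm_dir)}


_DISPATCH = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "patchify": _stage_patchify,
    "pretrain": _stage_pretrain,
    "linear-eval": _stage_linear_eval,
    "finetune": _stage_finetune,
    "baseline": _stage_baseline,
    "evaluate": _stage_evaluate,
    "cam": _stage_cam,
    "heatmap": _stage_heatmap,
}
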