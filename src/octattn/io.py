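"""Dataset readers, checkpoint serialization and the end-to-end experiment.

The on-disk dataset layout is ``<root>/<case>/<class>/<image>.png`` with two
orientation cases (``left_to_right``, ``top_to_bottom``) and alphabetically
ordered class folders.  Checkpoints are single ``.npz`` archives carrying
the architecture config, every parameter array, batch-norm running
statistics, the input-centering means, the class-name list and the seeds;
``load_checkpoint(save_checkpoint(...))`` reproduces bit-identical forward
passes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, UnidentifiedImageError

from .metrics import MetricReport, confusion_matrix, metric_report
from .network import AttentionGatedNet, NetworkConfig, StageConfig, build_network
from .synthetic import (
    CASES,
    DatasetManifest,
    SyntheticConfig,
    fixed_split,
    generate_dataset,
)
from .training import TrainConfig, TrainResult, predict, stratified_split, train

logger = logging.getLogger("octattn")

__all__ = [
    "ExperimentConfig",
    "load_image_folder",
    "load_images",
    "save_checkpoint",
    "load_checkpoint",
    "run_experiment",
    "surrogate_config",
]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def load_image_folder(root, case: str = "merged") -> DatasetManifest:
    """Scan a class-per-folder dataset into a manifest.

    ``case`` selects one orientation folder or ``"merged"`` for both.
    Classes are ordered alphabetically over folder names.  Undecodable
    files are skipped with a warning; an empty class folder is an error.
    """
    root = Path(root)
    cases = list(CASES) if case == "merged" else [case]
    rows = []
    for c in cases:
        case_dir = root / c
        if not case_dir.is_dir():
            raise FileNotFoundError(f"case folder not found: {case_dir}")
        class_dirs = sorted(p for p in case_dir.iterdir() if p.is_dir())
        if not class_dirs:
            raise ValueError(f"no class folders under {case_dir}")
        for cls_dir in class_dirs:
            files = sorted(p for p in cls_dir.iterdir()
                           if p.suffix.lower() in _IMAGE_SUFFIXES)
            kept = 0
            for p in files:
                try:
                    with Image.open(p) as im:
                        im.verify()
                except (UnidentifiedImageError, OSError):
                    logger.warning("skipping undecodable image: %s", p)
                    continue
                rows.append((p.stem, c, cls_dir.name, "unsplit", str(p)))
                kept += 1
            if kept == 0:
                raise ValueError(f"class folder {cls_dir} contains no decodable images")
    records = pd.DataFrame(rows, columns=["id", "case", "class", "split", "path"])
    return DatasetManifest(records=records, provenance={"root": str(root), "case": case})


def load_images(records: pd.DataFrame, side: int = 224,
                class_names: list[str] | None = None,
                dtype=np.float32) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a manifest subset into (N, 3, side, side) arrays plus labels.

    Images are read as 8-bit, converted to 3 channels (grayscale is
    replicated), resized bilinearly to ``side`` and scaled to [0, 1].
    Labels are indices into the alphabetical class-name list.
    """
    if class_names is None:
        class_names = sorted(records["class"].unique())
    index = {c: i for i, c in enumerate(class_names)}
    X = np.empty((len(records), 3, side, side), dtype=dtype)
    y = np.empty(len(records), dtype=np.int64)
    for i, (path, cls) in enumerate(zip(records["path"], records["class"])):
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (side, side):
                im = im.resize((side, side), Image.BILINEAR)
            arr = np.asarray(im, dtype=dtype) / 255.0
        X[i] = arr.transpose(2, 0, 1)
        y[i] = index[cls]
    return X, y, class_names


# -- checkpoints ---------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, network: AttentionGatedNet, class_names: list[str],
                    seeds: dict | None = None, summary: dict | None = None) -> None:
    """Serialize config, parameters, BN statistics and metadata to .npz."""
    from .nn.layers import BatchNorm2d

    cfg = network.config
    header = {
        "version": _CHECKPOINT_VERSION,
        "config": {
            "input_side": cfg.input_side,
            "input_channels": cfg.input_channels,
            "stem_filters": cfg.stem_filters,
            "stem_kernel": cfg.stem_kernel,
            "stem_stride": cfg.stem_stride,
            "stages": [[s.filters, s.repeats, s.followed_by_downsample]
                       for s in cfg.stages],
            "num_classes": cfg.num_classes,
        },
        "dtype": np.dtype(network.dtype).name,
        "class_names": list(class_names),
        "seeds": seeds or {},
        "summary": summary or {},
    }
    arrays = {"input_mean": network.input_mean}
    for name, layer, pname, arr in network.named_parameters():
        arrays[f"param/{name}"] = arr
    for lname, layer in network.named_layers():
        if isinstance(layer, BatchNorm2d):
            arrays[f"state/{lname}.running_mean"] = layer.running_mean
            arrays[f"state/{lname}.running_var"] = layer.running_var
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> tuple[AttentionGatedNet, list[str], dict]:
    """Rebuild a network from a checkpoint; returns (network, classes, header)."""
    from .nn.layers import BatchNorm2d

    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        if header["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        c = header["config"]
        cfg = NetworkConfig(
            input_side=c["input_side"],
            input_channels=c["input_channels"],
            stem_filters=c["stem_filters"],
            stem_kernel=c["stem_kernel"],
            stem_stride=c["stem_stride"],
            stages=tuple(StageConfig(f, r, d) for f, r, d in c["stages"]),
            num_classes=c["num_classes"],
        )
        net = build_network(cfg, seed=0, dtype=np.dtype(header["dtype"]))
        net.input_mean = z["input_mean"]
        for name, layer, pname, arr in net.named_parameters():
            layer.params[pname] = z[f"param/{name}"]
        for lname, layer in net.named_layers():
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = z[f"state/{lname}.running_mean"]
                layer.running_var = z[f"state/{lname}.running_var"]
    for _, layer in net.named_layers():
        layer.zero_grad()
    return net, header["class_names"], header


# -- experiment orchestration -------------------------------------------


@dataclass
class ExperimentConfig:
    """One end-to-end run: data source, case, architecture, training, output.

    Exactly one of ``dataset_root`` (an existing folder layout) or
    ``synthetic`` (a generator config; images are written under
    ``output_dir/dataset``) must be provided.
    """

    output_dir: str = "octattn_run"
    case: str = "merged"
    dataset_root: str | None = None
    synthetic: SyntheticConfig | None = None
    train_counts: dict | None = None  # (case, class) -> n, default Table-style
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    gradcam_samples: int = 4

    def __post_init__(self) -> None:
        if (self.dataset_root is None) == (self.synthetic is None):
            raise ValueError(
                "provide exactly one data source: dataset_root or synthetic"
            )
        if self.case not in (*CASES, "merged"):
            raise ValueError(f"unknown case {self.case!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            from .synthetic import LayerBandSpec

            syn = dict(kwargs["synthetic"])
            if "bands" in syn:
                syn["bands"] = tuple(
                    LayerBandSpec(**b) if isinstance(b, dict) else LayerBandSpec(*b)
                    for b in syn["bands"]
                )
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "network" in kwargs and kwargs["network"] is not None:
            nc = dict(kwargs["network"])
            if "stages" in nc:
                nc["stages"] = tuple(StageConfig(*s) if isinstance(s, (list, tuple))
                                     else StageConfig(**s) for s in nc["stages"])
            kwargs["network"] = NetworkConfig(**nc)
        if "training" in kwargs and kwargs["training"] is not None:
            kwargs["training"] = TrainConfig(**kwargs["training"])
        if "train_counts" in kwargs and kwargs["train_counts"] is not None:
            kwargs["train_counts"] = {
                tuple(k.split("/")): v for k, v in kwargs["train_counts"].items()
            }
        return cls(**kwargs)


def surrogate_config(seed: int, output_dir: str,
                     train_per_class: int = 60, test_per_class: int = 20,
                     epochs: int = 10) -> ExperimentConfig:
    """The scaled-down surrogate experiment for the headline result.

    One orientation, 60 train + 20 test images per class at 224x224, 40%
    RNFL thinning, speckle log-sd 0.05, full default architecture, the
    published hyperparameters, 10 epochs.  Every random stream derives from
    ``seed``.
    """
    n = train_per_class + test_per_class
    return ExperimentConfig(
        output_dir=output_dir,
        case="left_to_right",
        synthetic=SyntheticConfig(
            counts={"bipolar": n, "control": n},
            rnfl_thinning=0.40,
            speckle_sd=0.05,
            seed=seed,
        ),
        train_counts={(case, cls): train_per_class
                      for case in CASES for cls in ("bipolar", "control")},
        network=NetworkConfig(),
        training=TrainConfig(epochs=epochs, seed=seed),
        seed=seed,
        gradcam_samples=2,
    )


def _stage(name: str):
    """Context wrapper: re-raise any failure with the stage named."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        t0 = time.time()
        logger.info("stage %s started", name)
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"experiment stage '{name}' failed: {exc}") from exc
        logger.info("stage %s finished in %.1fs", name, time.time() - t0)

    return ctx()


def run_experiment(config: ExperimentConfig) -> tuple[TrainResult, MetricReport]:
    """Run split -> train -> evaluate -> explain, writing all artifacts.

    Writes under ``config.output_dir``: the dataset manifest, the training
    iteration log, metrics as JSON and CSV, a labeled confusion-matrix
    table, the model checkpoint and Grad-CAM panels for a few test images.
    Deterministic under the config seeds (partial outputs are retained if a
    later stage fails).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("data"):
        if config.synthetic is not None:
            manifest = generate_dataset(config.synthetic, out / "dataset")
        else:
            manifest = load_image_folder(config.dataset_root, case="merged")
        counts = config.train_counts
        if counts is None:
            per_stratum = {}
            for (case, cls), group in manifest.records.groupby(["case", "class"]):
                per_stratum[(case, cls)] = round(len(group) * 0.75)
            counts = per_stratum
        manifest = fixed_split(manifest, counts, seed=config.seed)
        manifest.to_csv(out / "manifest.csv")

    with _stage("split"):
        train_df = manifest.subset(case=config.case, split="train")
        test_df = manifest.subset(case=config.case, split="test")
        tr_df, val_df = stratified_split(
            train_df, config.training.val_fraction, seed=config.seed
        )

    with _stage("load"):
        side = config.network.input_side
        class_names = sorted(manifest.records["class"].unique())
        Xtr, ytr, _ = load_images(tr_df, side, class_names)
        Xva, yva, _ = load_images(val_df, side, class_names)
        Xte, yte, _ = load_images(test_df, side, class_names)

    with _stage("train"):
        net = build_network(
            config.network.with_classes(len(class_names)), seed=config.seed
        )
        result = train(net, (Xtr, ytr), (Xva, yva), config.training)
        result.iteration_log.to_csv(out / "training_log.csv", index=False)
        with open(out / "validation_accuracy.csv", "w") as fh:
            fh.write("epoch,val_accuracy\n")
            for e, va in enumerate(result.val_accuracy, start=1):
                fh.write(f"{e},{va:.4f}\n")

    with _stage("evaluate"):
        pred, _probs = predict(net, Xte, batch=config.training.mini_batch)
        cm = confusion_matrix(
            [class_names[i] for i in yte], [class_names[i] for i in pred],
            positive="bipolar" if "bipolar" in class_names else class_names[0],
        )
        report = metric_report(cm)
        report.to_json(out / "metrics.json")
        report.to_csv(out / "metrics.csv")
        (out / "confusion_matrix.txt").write_text(cm.as_table() + "\n")

    with _stage("checkpoint"):
        save_checkpoint(
            out / "checkpoint.npz", net, class_names,
            seeds={"seed": config.seed, "training_seed": config.training.seed},
            summary={"final_val_accuracy": result.final_val_accuracy,
                     "test_accuracy": report.accuracy},
        )

    with _stage("explain"):
        from .explain import grad_cam, save_panel

        k = min(config.gradcam_samples, len(Xte))
        for i in range(k):
            hm = grad_cam(net, Xte[i])
            save_panel(out / f"gradcam_{test_df.iloc[i]['id']}.png",
                       Xte[i], hm)

    return result, report
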