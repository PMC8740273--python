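"""End-to-end orchestration: preprocess -> split -> balance -> train ->
n-search -> fuse -> report.

A run is driven by a :class:`RunConfig` (optionally loaded from YAML) and
writes every stage's artifacts under one run directory, so the stages are
resumable and inspectable: processed images and their manifest, the three
split manifests, the augmented training tree with provenance, per-model
training logs and probability CSVs, the amplification search table, the
fusion weights, fused predictions and a metrics report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import balance, datasets, ensemble, imaging, metrics, models, synth
from .errors import ConfigError

__all__ = ["RunConfig", "run_pipeline"]

N_GRADES = 5


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``input_dir``/``manifest`` point at an existing image tree, or
    ``synth_counts`` asks for a synthetic set of those per-class sizes.
    """

    out_dir: str = "runs"
    seed: int = 0
    # data source
    input_dir: str | None = None
    manifest: str | None = None
    synth_counts: Sequence[int] | None = None
    synth_side: int = 96
    synth_border: int = 8
    # preprocessing
    dark_threshold: int = 7
    target_side: int = 64
    # models
    classifiers: Sequence[dict] = field(default_factory=lambda: [{"backbone_name": "tiny_test"}] * 3)
    train: dict = field(default_factory=dict)
    use_class_weights: bool = False
    # ensemble
    coarse_grid: Sequence[float] = ensemble.COARSE_GRID
    fine_grid: Sequence[float] = ensemble.FINE_GRID

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.synth_counts is None:
            if self.input_dir is None or self.manifest is None:
                raise ConfigError("either synth_counts or input_dir+manifest is required")
            if not Path(self.manifest).exists():
                raise ConfigError(f"manifest not found: {self.manifest}")
        if not self.classifiers:
            raise ConfigError("at least one classifier is required")
        for c in self.classifiers:
            name = c.get("backbone_name", "tiny_test")
            if name not in models.available_backbones():
                raise ConfigError(
                    f"backbone {name!r} is not available; installed: {models.available_backbones()}"
                )
        if self.target_side < 8:
            raise ConfigError("target_side must be >= 8 for the conv/pool stack")


def _load_images(root: Path, ds: datasets.LabeledDataset) -> np.ndarray:
    return np.stack([imaging.load_image(root / p) for p in ds.paths])


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; return the run directory.

    Deterministic given ``config.seed``: the same config and seed yield
    identical fused predictions.
    """
    config.validate()
    stamp = time.strftime("run-%Y%m%d-%H%M%S")
    run_dir = Path(config.out_dir) / stamp
    k = 1
    while run_dir.exists():
        run_dir = Path(config.out_dir) / f"{stamp}-{k}"
        k += 1
    run_dir.mkdir(parents=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {msg}")

    seeds = np.random.SeedSequence(config.seed).generate_state(6 + len(config.classifiers))
    seeds = [int(s % (2**31)) for s in seeds]

    # stage 1: raw data
    if config.synth_counts is not None:
        raw_dir = run_dir / "raw"
        params = synth.FundusParams(side=config.synth_side, border=config.synth_border)
        raw = synth.make_labelled_set(config.synth_counts, params, seeds[0], raw_dir)
        log(f"synthesised {len(raw)} images, counts {raw.class_counts}")
    else:
        raw_dir = Path(config.input_dir)
        raw = datasets.read_manifest(config.manifest, check_files="error")
        log(f"loaded {len(raw)} images from {raw_dir}")

    # stage 2: preprocessing
    proc_dir = run_dir / "processed"
    pconf = imaging.PreprocessConfig(config.dark_threshold, config.target_side)
    rows = []
    entries = []
    for path, grade in raw.entries:
        img = imaging.load_image(raw_dir / path)
        out = imaging.preprocess(img, pconf)
        imaging.save_image(out, proc_dir / path)
        rows.append((str(raw_dir / path), path, img.shape[0], img.shape[1]))
        entries.append((path, grade))
    pd.DataFrame(rows, columns=["source_path", "output_path", "original_h", "original_w"]).to_csv(
        run_dir / "preprocess_manifest.csv", index=False
    )
    processed = datasets.LabeledDataset(tuple(entries))
    log(f"preprocessed to {config.target_side}x{config.target_side}")

    # stage 3: split
    split = datasets.split_311(processed, seeds[1])
    parts = {"train": split.train, "valid": split.valid, "test": split.test}
    for name, idx in parts.items():
        datasets.write_manifest(processed.subset(idx), run_dir / f"{name}.csv")
    log(f"split sizes {split.sizes}")

    # stage 4: balance the training set
    train_ds = processed.subset(split.train)
    counts = train_ds.class_counts
    minority = [c for c in counts[1:]]
    plan = balance.compute_balance_plan(counts[0], minority)
    aug_images: list[np.ndarray] = []
    aug_labels: list[int] = []
    prov_rows = []
    labels_arr = train_ds.labels
    for grade in range(len(counts)):
        grade_paths = [p for p, g in train_ds.entries if g == grade]
        grade_imgs = [imaging.load_image(proc_dir / p) for p in grade_paths]
        add = 0 if grade == 0 else plan.add_per_image[grade - 1]
        aug = balance.upsample_class(grade_imgs, add, rng_seed=seeds[2] + grade, label=grade)
        aug_images.extend(aug.images)
        aug_labels.extend(aug.labels)
        for prov in aug.provenance:
            prov_rows.append((grade, grade_paths[prov.source_index], prov.transform, prov.angle_deg))
    pd.DataFrame(prov_rows, columns=["grade", "source_path", "transform", "angle_deg"]).to_csv(
        run_dir / "augmentation_provenance.csv", index=False
    )
    log(f"balanced train set: {len(labels_arr)} -> {len(aug_labels)} images")

    # stage 5: train base classifiers
    x_train = np.stack(aug_images)
    y_train = np.asarray(aug_labels)
    valid_ds = processed.subset(split.valid)
    test_ds = processed.subset(split.test)
    x_valid, y_valid = _load_images(proc_dir, valid_ds), valid_ds.labels
    x_test, y_test = _load_images(proc_dir, test_ds), test_ds.labels

    train_kwargs = dict(config.train)
    if config.use_class_weights:
        train_kwargs["class_weights"] = balance.class_weights(y_train.tolist())
    f1_list: list[float] = []
    valid_probs: list[np.ndarray] = []
    test_probs: list[np.ndarray] = []
    for i, cdict in enumerate(config.classifiers):
        spec = models.ClassifierSpec(
            input_side=config.target_side,
            **{k: v for k, v in cdict.items() if k != "input_side"},
        )
        clf = models.build_classifier(spec, seed=seeds[3] + i)
        tconf = models.TrainConfig(rng_seed=seeds[4] + i, **train_kwargs)
        trained = models.train_two_phase(clf, (x_train, y_train), (x_valid, y_valid), tconf)
        mdir = run_dir / f"model_{i}_{spec.backbone_name}"
        models.save_classifier(clf, mdir)
        pd.DataFrame(trained.history).to_csv(mdir / "training_log.csv", index=False)
        f1_list.append(trained.validation_f1)
        vp = clf.predict_proba(x_valid)
        tp = clf.predict_proba(x_test)
        valid_probs.append(vp)
        test_probs.append(tp)
        pd.DataFrame(vp).to_csv(mdir / "valid_probs.csv", index=False, header=False)
        pd.DataFrame(tp).to_csv(mdir / "test_probs.csv", index=False, header=False)
        log(f"model {i} ({spec.backbone_name}): val macro-F1 {trained.validation_f1:.4f}")

    # stage 6: amplification search on the validation set, then fuse
    search = ensemble.select_n(f1_list, valid_probs, y_valid, config.coarse_grid, config.fine_grid)
    search.table.to_csv(run_dir / "n_search.csv", index=False)
    weights = ensemble.compute_lambdas(f1_list, search.n)
    fused = ensemble.fuse(test_probs, weights)
    pd.DataFrame(fused.probabilities).to_csv(run_dir / "fused_probs.csv", index=False, header=False)
    pd.DataFrame({"true": y_test, "predicted": fused.grades}).to_csv(
        run_dir / "fused_predictions.csv", index=False
    )
    log(f"selected n={search.n}, lambdas={np.round(weights.lambdas, 4).tolist()}")

    # stage 7: report
    rep = metrics.report(y_test, fused.grades, fused.probabilities, n_classes=N_GRADES)
    rep.to_frame().to_csv(run_dir / "report.csv")
    (run_dir / "report.txt").write_text(rep.to_text() + "\n")
    base_acc = [float((m.argmax(axis=1) == y_test).mean()) for m in test_probs]
    summary = {
        "seed": config.seed,
        "n": search.n,
        "f1_list": f1_list,
        "lambdas": weights.lambdas.tolist(),
        "base_test_accuracy": base_acc,
        "fused_test_accuracy": rep.accuracy,
        "macro_f1": rep.macro_f1,
        "micro_f1": rep.micro_f1,
        "aca": rep.aca,
        "auc": rep.auc,
    }
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (run_dir / "config.json").write_text(json.dumps(asdict(config), default=list, indent=2))
    log(f"fused accuracy {rep.accuracy:.4f} (bases {np.round(base_acc, 4).tolist()})")
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return run_dir
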