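"""End-to-end two-stage pipeline: data -> base model -> per-class WGAN-GP ->
CTST checkpoint selection -> synthetic generation -> fine-tuning -> evaluation.

One :class:`RunConfig` drives the whole run.  A single master seed fans out
to named sub-seeds (split, stage-1 init/shuffle, per-class GANs, synthetic
sampling, fine-tuning), all recorded in the report so any stage can be
reproduced in isolation.  Expensive stage artifacts (stage-1 checkpoint, GAN
checkpoints) are written under the output directory together with a hash of
the configuration that produced them; a rerun with an unchanged
configuration resumes from the cached artifacts.

The final report carries test-set metrics for BOTH the stage-1 model and the
fine-tuned model, scored on the identical test records, so the effect of
feature-synthesis fine-tuning is read off as a paired comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ctst import evaluate_checkpoints
from .finetune import FinetuneConfig, finetune_stage2
from .gan import FeatureBatch, GanCheckpoint, GanConfig, extract_features, \
    generate_synthetic, train_wgan_gp
from .metrics import evaluate_scores
from .network import (ModelState, NetworkSpec, TrainingConfig, compact_spec,
                      predict_proba, train_stage1)
from .seqio import (SequenceRecord, encode_batch, make_splits, read_benchmark,
                    subset, write_split_manifest)
from .simulate import default_motif, generate_motif_dataset

log = logging.getLogger("methylgan.pipeline")


@dataclass(frozen=True)
class SimulateParams:
    n_pos: int = 1000
    n_neg: int = 1000
    length: int = 41
    strength: float = 0.8


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: Path
    seed: int = 0
    # data source: benchmark file paths, or simulation parameters
    positive_path: Path | None = None
    negative_path: Path | None = None
    simulate: SimulateParams | None = None
    spec: NetworkSpec = field(default_factory=compact_spec)
    train: TrainingConfig = field(default_factory=TrainingConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    block_index: int = 3

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        have_files = self.positive_path is not None and self.negative_path is not None
        if have_files == (self.simulate is not None):
            raise ValueError("configure exactly one data source: benchmark "
                             "paths or simulation parameters")
        if self.block_index != self.finetune.frozen_blocks:
            raise ValueError("extraction block must equal the frozen prefix "
                             "depth so synthetic maps enter where real "
                             "features leave")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            kwargs["simulate"] = SimulateParams(**kwargs["simulate"])
        if "spec" in kwargs:
            kwargs["spec"] = NetworkSpec(**kwargs["spec"])
        for key, klass in (("train", TrainingConfig), ("gan", GanConfig),
                           ("finetune", FinetuneConfig)):
            if key in kwargs:
                sub = dict(kwargs[key])
                for tup in ("adam_betas", "hidden_sizes", "fc_widths"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, (Path,)):
                return str(o)
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            return o
        blob = json.dumps({k: enc(v) for k, v in dataclasses.asdict(self).items()
                           if k != "out_dir"}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seeds(master: int) -> dict[str, int]:
    """Named per-stage sub-seeds derived deterministically from one master."""
    rng = np.random.default_rng(master)
    names = ("split", "stage1", "gan_pos", "gan_neg", "synth", "finetune",
             "simulate")
    return {name: int(s) for name, s in
            zip(names, rng.integers(0, 2 ** 31 - 1, size=len(names)))}


def _cached(path: Path, cfg_hash: str, compute, save, load):
    """Load a stage artifact if its config hash matches, else recompute."""
    meta = path.with_suffix(".hash")
    if path.exists() and meta.exists() and meta.read_text() == cfg_hash:
        log.info("resuming from cached %s", path.name)
        return load(path)
    result = compute()
    save(result, path)
    meta.write_text(cfg_hash)
    return result


def load_or_simulate(config: RunConfig, seeds: dict[str, int]
                     ) -> list[SequenceRecord]:
    if config.simulate is not None:
        p = config.simulate
        motif = default_motif(strength=p.strength)
        return generate_motif_dataset(p.n_pos, p.n_neg, p.length, motif,
                                      seed=seeds["simulate"])
    return read_benchmark(config.positive_path, config.negative_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-stage procedure and return the JSON-able report."""
    t0 = time.time()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    cfg_hash = config.config_hash()
    seeds = derive_seeds(config.seed)
    try:
        return _run(config, seeds, cfg_hash, out, t0)
    except Exception as e:  # annotate the failing stage, keep partial artifacts
        log.error("pipeline aborted: %s", e)
        raise
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()


def _run(config: RunConfig, seeds: dict[str, int], cfg_hash: str,
         out: Path, t0: float) -> dict:
    log.info("stage: data")
    records = load_or_simulate(config, seeds)
    split = make_splits(records, seed=seeds["split"])
    write_split_manifest(split, "dataset", out / "split.tsv")

    log.info("stage: stage-1 training (%d train records)", len(split.train_ids))
    train_cfg = dataclasses.replace(config.train, seed=seeds["stage1"])

    def compute_stage1():
        return train_stage1(records, split, config.spec, train_cfg)

    def save_stage1(result, path):
        state, history = result
        state.save(path)
        path.with_name("stage1_history.json").write_text(json.dumps(
            {"val_auc": history.val_auc, "best_epoch": history.best_epoch}))

    def load_stage1(path):
        hist = json.loads(path.with_name("stage1_history.json").read_text())
        from .network import TrainingHistory
        return ModelState.load(path), TrainingHistory(hist["val_auc"],
                                                      hist["best_epoch"])

    stage1, hist1 = _cached(out / "stage1.npz", cfg_hash, compute_stage1,
                            save_stage1, load_stage1)

    log.info("stage: feature extraction (block %d)", config.block_index)
    train_recs = subset(records, split.train_ids)
    feats = extract_features(stage1, train_recs, config.block_index)

    selected: dict[str, int] = {}
    traces: dict[str, dict[int, float]] = {}
    synth: dict[str, FeatureBatch] = {}
    val_recs = subset(records, split.val_ids)
    for cls_name, label, seed_key in (("pos", 1, "gan_pos"),
                                      ("neg", 0, "gan_neg")):
        log.info("stage: WGAN-GP (%s class)", cls_name)
        real_cls = feats.restrict(label)
        gan_cfg = dataclasses.replace(config.gan, seed=seeds[seed_key])

        def compute_gan(real_cls=real_cls, gan_cfg=gan_cfg):
            return train_wgan_gp(real_cls, gan_cfg)

        def save_gan(cks, path):
            path.mkdir(exist_ok=True)
            for ck in cks:
                ck.save(path / f"epoch_{ck.epoch:06d}.npz")

        def load_gan(path):
            return [GanCheckpoint.load(p)
                    for p in sorted(path.glob("epoch_*.npz"))]

        ckpts = _cached(out / f"gan_{cls_name}", cfg_hash, compute_gan,
                        save_gan, load_gan)

        log.info("stage: CTST selection (%s class)", cls_name)
        result = evaluate_checkpoints(real_cls, ckpts, seed=seeds["synth"])
        result.save(out / f"ctst_{cls_name}.json", class_label=label)
        selected[cls_name] = result.selected_epoch
        traces[cls_name] = result.accuracies
        best = next(c for c in ckpts if c.epoch == result.selected_epoch)
        # synthetic sample count per class mirrors that class's validation size
        n_val_cls = sum(1 for r in val_recs if r.label == label)
        synth[cls_name] = generate_synthetic(best, n_val_cls, label,
                                             feats.layer_shape,
                                             seed=seeds["synth"] + label)
        synth[cls_name].save(out / f"synth_{cls_name}.npz")

    log.info("stage: fine-tuning (frozen prefix: %d blocks)",
             config.finetune.frozen_blocks)
    ft_cfg = dataclasses.replace(config.finetune, seed=seeds["finetune"])
    stage2, hist2 = finetune_stage2(stage1, records, split,
                                    synth["pos"], synth["neg"], ft_cfg)
    stage2.save(out / "stage2.npz")

    log.info("stage: evaluation")
    test_recs = subset(records, split.test_ids)
    X_te, y_te = encode_batch(test_recs)
    y_te = y_te.astype(int)
    report_s1 = evaluate_scores(y_te, predict_proba(stage1, X_te),
                                threshold=config.train.threshold)
    report_s2 = evaluate_scores(y_te, predict_proba(stage2, X_te),
                                threshold=config.finetune.threshold)

    report = {
        "config_hash": cfg_hash,
        "seeds": seeds,
        "n_records": len(records),
        "split_sizes": {"train": len(split.train_ids),
                        "val": len(split.val_ids),
                        "test": len(split.test_ids)},
        "test_ids": sorted(split.test_ids),
        "stage1": report_s1.to_dict(),
        "finetuned": report_s2.to_dict(),
        "stage1_best_epoch": hist1.best_epoch,
        "stage1_val_auc": hist1.val_auc,
        "finetune_best_epoch": hist2.best_epoch,
        "finetune_val_auc": hist2.val_auc,
        "selected_gan_epoch": selected,
        "ctst_traces": {k: {str(e): a for e, a in v.items()}
                        for k, v in traces.items()},
        "runtime_seconds": round(time.time() - t0, 2),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("done in %.1f s; stage-1 AUC %.4f -> fine-tuned AUC %.4f",
             report["runtime_seconds"], report_s1.auc, report_s2.auc)
    return report
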