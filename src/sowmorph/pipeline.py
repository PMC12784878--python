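"""End-to-end orchestration: simulate -> split -> segment -> regress -> explain.

The dataset split is performed at the *subject* (animal) level so that no
individual contributes samples to more than one of train/validation/test
— frames of the same sow are highly correlated and pooling them across
partitions would leak information.  Ratios default to 3:1:1; counts for
non-divisible cases use largest-remainder apportionment.

``run_pipeline`` executes the stages in order on a fully synthetic
dataset, writing every artifact (manifest, split, training histories,
metric reports, coloured saliency clouds) into one directory with the
configuration and seed embedded.  Each stage is resumable: when its
report already exists and ``resume`` is set, it is skipped.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dbmonet import DbmoNet, NetConfig, RegressionSample, predict, train_regressor
from .kpconv import (ConfusionCounts, SegConfig, segment, segmentation_metrics,
                     train_segmentation)
from .metrics import METRIC_NAMES, regression_report
from .pam import pam_from_taps
from .synthetic import generate_dataset

__all__ = ["DatasetSplit", "split_subjects", "PipelineConfig", "run_pipeline"]

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class DatasetSplit:
    """Subject-level partition assignment."""

    ratios: tuple
    assignment: dict              # subject id -> partition name
    counts: dict                  # partition name -> number of subjects
    seed: int

    def subjects(self, partition: str):
        return sorted(s for s, p in self.assignment.items() if p == partition)


def split_subjects(subject_ids, ratios=(3, 1, 1), seed: int = 0) -> DatasetSplit:
    """Deterministically assign subjects to train/val/test.

    Subjects are shuffled by the seed and partition sizes follow
    largest-remainder apportionment of the ratios; every subject is
    assigned and partitions are disjoint by construction.
    """
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    if any(r <= 0 for r in ratios) or len(ratios) != 3:
        raise ValueError("ratios must be three positive numbers")
    n = len(subject_ids)
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} subjects, got {n}")
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    # distribute leftover seats by largest remainder (ties: earlier partition)
    for _ in range(n - sum(sizes)):
        j = int(np.argmax(remainders))
        sizes[j] += 1
        remainders[j] = -1.0
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(subject_ids)))
    assignment = {}
    pos = 0
    for part, size in zip(PARTITIONS, sizes):
        for i in order[pos:pos + size]:
            assignment[subject_ids[i]] = part
        pos += size
    counts = {p: s for p, s in zip(PARTITIONS, sizes)}
    return DatasetSplit(ratios=tuple(ratios), assignment=assignment,
                        counts=counts, seed=seed)


@dataclass
class PipelineConfig:
    """One config object for the whole synthetic workflow.

    Defaults are desk-scale (small counts, few epochs); the full study
    scale is 60 subjects x 4 sets x 50 frames.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_subjects: int = 12
    sets_per_subject: int = 2
    frames_per_set: int = 2
    ratios: tuple = (3, 1, 1)
    scene_kwargs: dict = field(default_factory=dict)
    # segmentation stage
    seg_config: SegConfig = field(default_factory=lambda: SegConfig(n_points=512))
    seg_epochs: int = 4
    seg_lr: float = 1e-3
    # regression stage
    net_config: NetConfig = field(default_factory=lambda: NetConfig.reduced())
    reg_epochs: int = 10
    reg_lr: float = 1e-3
    batch_size: int = 8
    use_predicted_segmentation: bool = False
    pam_samples: int = 1
    resume: bool = False

    def stage_seeds(self):
        """Fan the global seed out to fixed per-stage seeds."""
        ss = np.random.SeedSequence(self.seed).spawn(4)
        return {name: int(s.generate_state(1)[0] % (2**31))
                for name, s in zip(("simulate", "split", "segment", "regress"), ss)}


def _write_json(path: Path, payload: dict):
    path.write_text(json.dumps(payload, indent=1, default=str))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate -> split -> segment -> regress -> explain; returns the
    artifact directory.  Any stage failure raises with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    _write_json(out / "config.json", {
        "package_version": _pkg_version, "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
    })
    state: dict = {}
    for name, fn in (("simulate", _stage_simulate), ("split", _stage_split),
                     ("segment", _stage_segment), ("regress", _stage_regress),
                     ("pam", _stage_pam)):
        t0 = time.time()
        try:
            fn(config, seeds, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        print(f"[sowmorph] stage {name} done in {time.time() - t0:.1f} s")
    return out


def _stage_simulate(cfg, seeds, out, state):
    samples, manifest = generate_dataset(
        cfg.n_subjects, cfg.sets_per_subject, cfg.frames_per_set,
        seed=seeds["simulate"], scene_kwargs=cfg.scene_kwargs)
    state["samples"], state["manifest"] = samples, manifest


def _stage_split(cfg, seeds, out, state):
    manifest = state["manifest"]
    split = split_subjects(sorted(manifest["subject_id"].unique()),
                           ratios=cfg.ratios, seed=seeds["split"])
    manifest["split"] = manifest["subject_id"].map(split.assignment)
    # leakage assertion on the manifest itself
    per_subject = manifest.groupby("subject_id")["split"].nunique()
    if (per_subject > 1).any():
        raise ValueError("subject assigned to more than one partition")
    manifest.to_csv(out / "manifest.csv", index=False)
    _write_json(out / "split.json", {"seed": split.seed, "ratios": split.ratios,
                                     "counts": split.counts,
                                     "assignment": {str(k): v for k, v in
                                                    split.assignment.items()}})
    state["split"] = split


def _partition_samples(state, part):
    mask = state["manifest"]["split"] == part
    return [state["samples"][i] for i in state["manifest"].index[mask]]


def _stage_segment(cfg, seeds, out, state):
    report_path = out / "segmentation_report.json"
    if cfg.resume and report_path.exists():
        state["seg_model"] = None
        return
    train = _partition_samples(state, "train")
    val = _partition_samples(state, "val")
    test = _partition_samples(state, "test")
    model, history = train_segmentation(train, cfg.seg_config, val_samples=val,
                                        epochs=cfg.seg_epochs, lr=cfg.seg_lr,
                                        seed=seeds["segment"])
    pd.DataFrame(history).to_csv(out / "segmentation_history.csv", index=False)
    rng = np.random.default_rng(seeds["segment"] + 1)
    tp = fp = fn = tn = 0
    for si, s in enumerate(test):
        n = len(s.cloud)
        sel = rng.choice(n, size=min(cfg.seg_config.n_points, n), replace=False)
        sub = type(s.cloud)(points=s.cloud.points[sel])
        pred, _ = segment(model, sub)
        truth = s.cloud.labels[sel]
        c = ConfusionCounts.from_predictions(truth, pred)
        tp += c.TP; fp += c.FP; fn += c.FN; tn += c.TN
        if si == 0:  # one labeled prediction cloud for inspection
            from .geometry import write_cloud
            sub.labels = pred.astype(np.int64)
            write_cloud(sub, out / "segmentation_prediction_0.ply")
    report = segmentation_metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
    _write_json(report_path, report.to_dict())
    state["seg_model"] = model
    state["seg_report"] = report


def _back_points(cfg, state, sample, rng):
    """Back cloud for regression: ground-truth labels by default, or the
    trained segmenter's prediction when configured."""
    if cfg.use_predicted_segmentation and state.get("seg_model") is not None:
        n = len(sample.cloud)
        sel = rng.choice(n, size=min(cfg.seg_config.n_points, n), replace=False)
        sub = type(sample.cloud)(points=sample.cloud.points[sel])
        pred, _ = segment(state["seg_model"], sub)
        pts = sub.points[pred == 1]
        if len(pts) >= 32:
            return pts
    return sample.cloud.points[sample.cloud.labels == 1]


def _stage_regress(cfg, seeds, out, state):
    report_path = out / "regression_report.json"
    if cfg.resume and report_path.exists():
        state["reg_model"] = None
        return
    manifest = state["manifest"]
    rng = np.random.default_rng(seeds["regress"])

    def build(part):
        mask = manifest["split"] == part
        out_samples = []
        for i in manifest.index[mask]:
            s = state["samples"][i]
            out_samples.append(RegressionSample(
                points=_back_points(cfg, state, s, rng),
                target=s.metrics.to_array(),
                subject_id=int(manifest.loc[i, "subject_id"])))
        return out_samples

    train, val, test = build("train"), build("val"), build("test")
    model, history = train_regressor(train, val, cfg.net_config,
                                     epochs=cfg.reg_epochs, lr=cfg.reg_lr,
                                     batch_size=cfg.batch_size,
                                     seed=seeds["regress"])
    pd.DataFrame(history).to_csv(out / "regression_history.csv", index=False)
    truth = np.stack([s.target for s in test])
    preds = np.stack([predict(model, s.points, seed=seeds["regress"] + i)
                      for i, s in enumerate(test)])
    report = regression_report(truth, preds)
    _write_json(report_path, report.to_dict())
    pd.DataFrame({"sample": np.arange(len(test)),
                  **{f"true_{k}": truth[:, j] for j, k in enumerate(METRIC_NAMES)},
                  **{f"pred_{k}": preds[:, j] for j, k in enumerate(METRIC_NAMES)}}
                 ).to_csv(out / "predictions.csv", index=False)
    state["reg_model"] = model
    state["reg_report"] = report


def _stage_pam(cfg, seeds, out, state):
    model: DbmoNet | None = state.get("reg_model")
    if model is None:
        return
    manifest = state["manifest"]
    test_idx = manifest.index[manifest["split"] == "test"][:cfg.pam_samples]
    rng = np.random.default_rng(seeds["regress"] + 7)
    for j, i in enumerate(test_idx):
        s = state["samples"][i]
        pts = s.cloud.points[s.cloud.labels == 1]
        from .dbmonet import subsample_points
        sub = subsample_points(pts, model.config.n_points, rng)
        _, inter = model.forward(sub, return_intermediates=True)
        levels = [(sub, f) for f in inter["edgeconv_features"]]
        pam_from_taps(levels, sub, out_ply=out / f"pam_{j}.ply",
                      out_csv=out / f"pam_{j}.csv")
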