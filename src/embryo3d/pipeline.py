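"""End-to-end orchestration: synthesize -> segment -> reconstruct -> encode ->
train -> evaluate, with per-stage caching keyed by a config hash."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cee_features import cee_feature_matrix, load_default_specs
from .classifier import (ClassifierData, TrainConfig, assert_no_leakage,
                         make_cv_plan, predict_scores, train_classifier)
from .evaluation import (confusion_stats, mann_whitney, roc_auc, subgroup_auc,
                         youden_cutoff)
from .io_utils import (read_cee, read_manifest, read_stack, save_volume,
                       load_volume, write_cohort)
from .reconstruction import reconstruct_volume
from .segmentation import (SegTrainConfig, eliminate_background, load_model,
                           mean_iou, save_model, train_segmenter)
from .synthetic_data import PhantomParams, generate_cohort

log = logging.getLogger("embryo3d")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 1
    n_embryos: int = 60
    image_px: int = 128
    weight_image: float = 0.5
    target_px: int = 111
    variant: str = "fusion3d"
    seg_epochs: int = 8
    seg_pairs: int = 150
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=3e-3, augment_times=2, max_epochs=10))
    stages: tuple[str, ...] = ("synthesize", "segment", "reconstruct",
                               "train", "evaluate")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Stage-local seed derived by stable hashing from the single run seed."""
    return int(np.random.default_rng([seed, zlib.crc32(stage.encode())])
               .integers(2 ** 31))


def _marker(out: Path, stage: str) -> Path:
    return out / f".stage_{stage}.json"


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark_done(out: Path, stage: str, cfg_hash: str, elapsed: float):
    _marker(out, stage).write_text(json.dumps(
        {"config_hash": cfg_hash, "elapsed_s": round(elapsed, 3)}))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the staged flow; stages whose outputs match the current config
    hash are skipped, making reruns idempotent. Returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (out / "provenance.json").write_text(json.dumps({
        "config": asdict(config), "config_hash": cfg_hash,
        "package_version": __version__}, indent=2, default=str))
    specs = load_default_specs()

    def timed(stage, fn):
        if stage not in config.stages:
            return
        if _stage_done(out, stage, cfg_hash):
            log.info("stage %s: cached, skipping", stage)
            return
        t0 = time.time()
        fn()
        _mark_done(out, stage, cfg_hash, time.time() - t0)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)

    # -- synthesize ---------------------------------------------------------
    def synthesize():
        params = PhantomParams(image_px=config.image_px,
                               seed=stage_seed(config.seed, "synthesize"))
        embryos = generate_cohort(config.n_embryos,
                                  stage_seed(config.seed, "cohort"),
                                  specs, params=params,
                                  weight_image=config.weight_image)
        write_cohort(embryos, out)

    timed("synthesize", synthesize)

    manifest = read_manifest(out / "manifest.csv")
    cee = read_cee(out / "cee.csv")
    from .io_utils import join_manifest_cee, read_masks

    joined = join_manifest_cee(manifest, cee)

    # -- segment ------------------------------------------------------------
    def segment():
        rng = np.random.default_rng(stage_seed(config.seed, "segment"))
        pairs = []
        pick = rng.choice(len(manifest), size=min(len(manifest), 40),
                          replace=False)
        for i in pick:
            row = manifest.iloc[i]
            stack = read_stack(out / row["stack_path"])
            masks = read_masks(out / row["mask_dir"])
            for j in rng.choice(stack.n_slices,
                                size=min(stack.n_slices, 5), replace=False):
                pairs.append((stack.slices[j], masks[j]))
            if len(pairs) >= config.seg_pairs:
                break
        model = train_segmenter(pairs, SegTrainConfig(
            epochs=config.seg_epochs, seed=stage_seed(config.seed, "seg-train")))
        save_model(model, out / "segmenter.npz")
        masked_dir = out / "masked"
        masked_dir.mkdir(exist_ok=True)
        from .io_utils import write_stack

        for _, row in manifest.iterrows():
            stack = read_stack(out / row["stack_path"])
            masked = eliminate_background(model, stack)
            write_stack(masked, masked_dir / f"{row['embryo_id']}.tiff")
        # held-out IOU report on ground-truth masks
        eval_pairs = []
        for i in range(min(10, len(manifest))):
            row = manifest.iloc[i]
            stack = read_stack(out / row["stack_path"])
            masks = read_masks(out / row["mask_dir"])
            eval_pairs.append((stack.slices[stack.center_index],
                               masks[stack.center_index]))
        met = mean_iou(model, eval_pairs)
        (out / "segmentation_metrics.json").write_text(json.dumps({
            "miou": met.miou, "miou_sd": met.miou_sd,
            "iou_min": met.iou_min, "iou_max": met.iou_max}))

    timed("segment", segment)

    # -- reconstruct --------------------------------------------------------
    def reconstruct():
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        src = out / "masked" if (config.variant != "no_background"
                                 and (out / "masked").exists()) else out
        for _, row in manifest.iterrows():
            if config.variant == "no_background":
                stack = read_stack(out / row["stack_path"])
            else:
                stack = read_stack(src / f"{row['embryo_id']}.tiff")
            vol = reconstruct_volume(stack, target_px=config.target_px)
            save_volume(vol, vol_dir / f"{row['embryo_id']}.npz")

    timed("reconstruct", reconstruct)

    # -- train --------------------------------------------------------------
    def train():
        vols, ids = [], []
        for _, row in joined.iterrows():
            v = load_volume(out / "volumes" / f"{row['embryo_id']}.npz")
            vox = v.voxels
            if config.variant == "single_image":
                vox = vox[[vox.shape[0] // 2]]
            vols.append(vox.astype(np.float32))
            ids.append(row["embryo_id"])
        data = ClassifierData(
            volumes=np.stack(vols),
            cee=cee_feature_matrix(joined, specs),
            labels=joined["outcome"].to_numpy(int),
            ids=np.asarray(ids))
        plan = make_cv_plan(len(data), data.labels, seed=stage_seed(config.seed, "cv"))
        tr_idx, va_idx = plan.inner_folds[0]
        cfg = config.train
        aug = data.subset(tr_idx).augmented(cfg.augment_times,
                                            seed=stage_seed(config.seed, "augment"))
        val = data.subset(va_idx)
        test = data.subset(plan.test_idx)
        assert_no_leakage(aug.ids, val.ids, test.ids)
        model = train_classifier(aug, val, cfg, variant=config.variant)
        scores = predict_scores(model, test)
        res = pd.DataFrame({
            "embryo_id": test.ids, "score": scores, "label": test.labels,
            "age": joined.set_index("embryo_id").loc[test.ids, "female_age"].to_numpy(),
        })
        res.to_csv(out / "scores.csv", index=False)
        (out / "training_history.json").write_text(
            json.dumps(model.history, default=float))

    timed("train", train)

    # -- evaluate -----------------------------------------------------------
    def evaluate():
        res = pd.read_csv(out / "scores.csv")
        metrics = evaluate_scores(res["score"].to_numpy(),
                                  res["label"].to_numpy(int),
                                  ages=res["age"].to_numpy()
                                  if "age" in res else None)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        roc = roc_auc(res["score"].to_numpy(), res["label"].to_numpy(int))
        pd.DataFrame(roc.curve, columns=["fpr", "tpr", "threshold"]).to_csv(
            out / "roc_curve.tsv", sep="\t", index=False)

    timed("evaluate", evaluate)
    return out


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    ages: np.ndarray | None = None) -> dict:
    """Metrics bundle used by the evaluate stage and the CLI."""
    roc = roc_auc(scores, labels)
    cut = youden_cutoff(roc)
    cs = confusion_stats(scores, labels, cut.threshold)
    mw = mann_whitney(scores[labels == 1], scores[labels == 0])
    metrics = {
        "auc": roc.auc, "auc_se": roc.se,
        "auc_ci95": list(roc.ci95),
        "cutoff": cut.threshold, "youden_j": cut.j,
        "confusion": {"tp": cs.tp, "fp": cs.fp, "fn": cs.fn, "tn": cs.tn,
                      **cs.rounded()},
        "score_mean_implantation": float(scores[labels == 1].mean()),
        "score_mean_non_implantation": float(scores[labels == 0].mean()),
        "mann_whitney_u": mw.u, "mann_whitney_p": mw.p,
        "n": int(labels.size),
    }
    if ages is not None:
        bands = {}
        for name, res in subgroup_auc(scores, labels, ages).items():
            bands[name] = ({"auc": res.roc.auc, "se": res.roc.se,
                            "n_pos": res.n_pos, "n_neg": res.n_neg}
                           if res.defined else
                           {"auc": None, "n_pos": res.n_pos, "n_neg": res.n_neg})
        metrics["age_bands"] = bands
    return metrics
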