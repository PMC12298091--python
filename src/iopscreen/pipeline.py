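"""End-to-end pipeline: synth -> augment -> qc -> pretrain -> train -> eval -> explain.

Every stage writes its artifacts under the configured output directory and
the whole run is deterministic in the single global seed. A stage failure
is re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import ClassicAugmenter, CycleConfig, CycleGANAugmenter
from .backbone import SwinBackboneClassifier
from .config import RunConfig, save_config
from .explain import attribution_report, grad_cam
from .fusion import CLINICAL_FEATURES, KANFusionClassifier
from .io import save_image, write_cohort
from .phantom import PhantomConfig, generate_cohort, region_mask
from .qc import BLSQualityMonitor, build_quality_dataset, edge_integrity_check
from .train_eval import compute_metrics, split_dataset

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("iopscreen")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(name, e) from e
    log.info("stage %s: done", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the evaluation summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    seed = config.seed

    with _stage("synth"):
        pcfg = PhantomConfig(
            image_height=config.synth.image_size,
            image_width=config.synth.image_size,
            noise_sd=config.synth.noise_sd,
            seed=seed,
        )
        cohort = generate_cohort(pcfg, config.synth.n, seed=seed)
        write_cohort(cohort, out / "cohort")
        X = np.stack([s.image for s in cohort])
        y = np.array([s.label for s in cohort])
        pids = np.array([s.patient_id for s in cohort])
        clin = np.array(
            [[getattr(s.record, a) for a in CLINICAL_FEATURES] for s in cohort]
        )
        plan = split_dataset(y, pids, seed=seed)
        (out / "split_plan.json").write_text(json.dumps(plan.as_dict(), indent=2))

    tr, va, te = plan.train, plan.val, plan.test

    with _stage("augment"):
        normal, high = X[tr][y[tr] == "normal"], X[tr][y[tr] == "high"]
        if config.augment.mode == "cyclegan":
            aug = CycleGANAugmenter(
                CycleConfig(
                    image_size=config.synth.image_size,
                    generator_width=config.augment.width,
                    cycle_weight=config.augment.cycle_weight,
                    epochs=config.augment.epochs,
                    seed=seed,
                )
            ).fit(normal, high)
        elif config.augment.mode == "classic":
            aug = ClassicAugmenter().fit(normal, high)
        else:
            raise ValueError(f"unknown augment mode {config.augment.mode!r}")
        aset = aug.generate(config.augment.n_per_class, seed=seed + 1)
        aug_imgs = np.stack(aset.images)
        aug_dom = np.array(aset.domains)

    with _stage("qc"):
        if config.qc.enabled:
            qi, qt, _ = build_quality_dataset(
                [cohort[i] for i in tr[: min(len(tr), 300)]], seed=seed + 2
            )
            gate = BLSQualityMonitor(
                n_feature_nodes=config.qc.feature_nodes,
                n_enhancement_nodes=config.qc.enhancement_nodes,
                ridge_lambda=config.qc.ridge_lambda,
                threshold=config.qc.threshold,
                random_state=seed,
            ).fit(qi, qt)
            scores = gate.score_samples(aug_imgs)
            passed = scores >= config.qc.threshold
            verdicts = pd.DataFrame(
                {
                    "index": np.arange(len(aug_imgs)),
                    "domain": aug_dom,
                    "score": scores,
                    "passed": passed,
                    "flags": [
                        ";".join(edge_integrity_check(im)) for im in aug_imgs
                    ],
                }
            )
            verdicts.to_csv(out / "qc_verdicts.csv", index=False)
            if passed.sum() >= 20:
                aug_imgs, aug_dom = aug_imgs[passed], aug_dom[passed]
            log.info("qc gate kept %d/%d augmented images", len(aug_imgs), len(passed))
        else:
            log.info("qc disabled: augmented set passed through unfiltered")

    with _stage("pretrain"):
        if config.backbone.init == "phantom-pretrain":
            pre = SwinBackboneClassifier(
                epochs=config.backbone.pretrain_epochs, lr=config.backbone.lr,
                random_state=seed,
            ).fit(aug_imgs, aug_dom)
            init, pre_model = "pretrained", pre
            freeze = tuple(config.backbone.freeze)
        elif config.backbone.init == "random":
            init, pre_model, freeze = "random", None, ()
        else:
            raise ValueError(f"unknown backbone init {config.backbone.init!r}")

    with _stage("train"):
        backbone = SwinBackboneClassifier(
            epochs=config.backbone.epochs, lr=config.backbone.lr, init=init,
            pretrained_model=pre_model, freeze=freeze, random_state=seed + 3,
        ).fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        feats_tr = backbone.transform(X[tr])
        head = KANFusionClassifier(
            n_clinical=clin.shape[1],
            width=config.fusion.width,
            n_knots=config.fusion.n_knots,
            degree=config.fusion.degree,
            l1_lambda=config.fusion.l1_lambda,
            dropout_p0=config.fusion.dropout_p0,
            dropout_beta=config.fusion.dropout_beta,
            epochs=config.fusion.epochs,
            patience=config.fusion.patience,
            random_state=seed,
        ).fit(np.hstack([feats_tr, clin[tr]]), y[tr])
        backbone.model_.save(out / "backbone.npz")
        pd.DataFrame({"epoch_loss": backbone.loss_history_}).to_csv(
            out / "train_log.csv", index=False
        )

    with _stage("eval"):
        feats_te = backbone.transform(X[te])
        pred = head.predict(np.hstack([feats_te, clin[te]]))
        report = compute_metrics(y[te], pred, positive="high")
        summary = {
            "test_metrics": report.as_dict(),
            "n": {"train": len(tr), "val": len(va), "test": len(te)},
            "modality_weights": head.modality_weights_.tolist(),
            "qc_enabled": config.qc.enabled,
        }
        (out / "metrics.json").write_text(json.dumps(summary, indent=2))

    with _stage("explain"):
        hm_dir = out / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        take = te[: config.explain.n_images]
        heatmaps, band_masks = [], []
        hi_idx = int(np.where(backbone.classes_ == "high")[0][0])
        for i in take:
            s = cohort[i]
            tc = hi_idx if s.label == "high" else 1 - hi_idx
            hm = grad_cam(backbone, s.image, tc, stage=config.explain.stage)
            heatmaps.append(hm)
            band_masks.append(region_mask(s.truth, s.image.shape))
            save_image(hm, hm_dir / f"heatmap_{i:05d}.png")
        report = attribution_report(heatmaps, {"band_wedge": band_masks})
        (out / "attribution.json").write_text(
            json.dumps(
                {k: {"mean": float(v.mean()), "per_image": v.tolist()}
                 for k, v in report.items()},
                indent=2,
            )
        )
    return summary
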