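"""Training utilities, data splitting, metrics, baselines, and ablations.

Covers the evaluation protocol of the screening pipeline: stratified
patient-grouped 8:1:1 splits (no patient contributes to two subsets),
confusion-matrix metrics (precision, recall/sensitivity, F1, specificity,
Matthews correlation coefficient), 5-fold cross-validation with median
reporting, classical tabular baselines (SVM, random forest, logistic
regression) on the six structural clinical features, Pearson correlation
analysis, and the ablation harness comparing the full multimodal model
against image-only and non-pretrained variants.

Conventions adopted where the printed formulas are ambiguous: specificity
is TN / (TN + FP) and F1 is the harmonic mean of precision and recall (the
two are distinct metrics); MCC with a zero denominator is defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import Tensor

__all__ = [
    "MetricsReport",
    "SplitPlan",
    "EarlyStopping",
    "total_loss",
    "dropout_schedule",
    "split_dataset",
    "compute_metrics",
    "crossval_5fold",
    "CrossValResult",
    "fit_baselines",
    "pearson_corr",
    "run_ablation",
]


# ---------------------------------------------------------------------------
# losses / schedules
# ---------------------------------------------------------------------------


def total_loss(task_loss, weights, l1_lambda: float):
    """Task loss plus L1 penalty: ``L = L_task + lambda * sum_i |w_i|``.

    Accepts autograd tensors (used inside training loops) or plain
    floats/arrays (analytic checks).
    """
    if l1_lambda < 0:
        raise ValueError("l1_lambda must be >= 0")
    if isinstance(task_loss, Tensor):
        if l1_lambda == 0:
            return task_loss
        penalty = None
        for w in weights:
            term = w.abs().sum()
            penalty = term if penalty is None else penalty + term
        return task_loss + l1_lambda * penalty
    flat = np.concatenate([np.ravel(np.asarray(w, dtype=float)) for w in weights]) \
        if len(weights) else np.zeros(0)
    return float(task_loss) + l1_lambda * float(np.abs(flat).sum())


def dropout_schedule(p0: float, beta: float, t: float) -> float:
    """Dynamic dropout rate ``p(t) = p0 / (1 + beta * t)``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return p0 / (1.0 + beta * t)


class EarlyStopping:
    """Stop when the monitored value fails to improve for ``patience`` epochs.

    "No improvement" means not exceeding the running best by more than
    ``tol`` (strict float equality would never trigger).
    """

    def __init__(self, patience: int = 10, tol: float = 1e-6):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.tol = tol
        self.best = -np.inf
        self.stall = 0

    def update(self, value: float) -> bool:
        """Record a new validation value; returns True when training should stop."""
        if value > self.best + self.tol:
            self.best = value
            self.stall = 0
        else:
            self.stall += 1
        return self.stall >= self.patience


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Patient-grouped stratified train/validation/test partition."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    class_counts: dict[str, dict] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "train": self.train.tolist(),
            "val": self.val.tolist(),
            "test": self.test.tolist(),
            "class_counts": self.class_counts,
        }


def split_dataset(
    labels,
    patient_ids,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitPlan:
    """Stratified, patient-grouped split into train/val/test.

    Every patient's samples land in exactly one subset; per-class subset
    sizes follow the ratios as closely as the grouping allows (exactly, for
    single-sample patients). Quotas per class come from largest-remainder
    apportionment; patient groups are then assigned greedily (largest group
    first, randomized tie order) to the subset with the largest remaining
    deficit for the group's class.
    """
    labels = np.asarray(labels)
    patient_ids = np.asarray(patient_ids)
    if labels.shape != patient_ids.shape:
        raise ValueError("labels and patient_ids must align")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    # group samples by patient; a patient's class is its majority label
    uniq_p, inv_p = np.unique(patient_ids, return_inverse=True)
    groups = [np.flatnonzero(inv_p == g) for g in range(len(uniq_p))]
    group_cls = []
    for g in groups:
        vals, cnts = np.unique(labels[g], return_counts=True)
        group_cls.append(vals[np.argmax(cnts)])
    group_cls = np.array(group_cls)
    splits: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for cls in classes:
        cls_groups = [groups[i] for i in np.flatnonzero(group_cls == cls)]
        n_cls = sum(len(g) for g in cls_groups)
        # largest-remainder quotas for this class
        quota = np.array([r * n_cls for r in ratios])
        base = np.floor(quota).astype(int)
        rem = quota - base
        for k in np.argsort(-rem, kind="stable")[: n_cls - base.sum()]:
            base[k] += 1
        order = rng.permutation(len(cls_groups))
        cls_groups = sorted((cls_groups[i] for i in order), key=len, reverse=True)
        if cls_groups and len(cls_groups[0]) > max(ratios) * n_cls:
            warnings.warn(
                f"patient group of size {len(cls_groups[0])} exceeds the largest "
                f"subset quota for class {cls!r}; split is best-effort",
                stacklevel=2,
            )
        deficit = base.astype(float).copy()
        for g in cls_groups:
            k = int(np.argmax(deficit))
            splits[k].extend(g.tolist())
            deficit[k] -= len(g)
    tr, va, te = (np.sort(np.array(splits[k], dtype=int)) for k in (0, 1, 2))
    counts = {
        name: {str(c): int((labels[part] == c).sum()) for c in classes}
        for name, part in (("train", tr), ("val", va), ("test", te))
    }
    return SplitPlan(tr, va, te, counts)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "specificity": self.specificity, "mcc": self.mcc,
        }


def compute_metrics(y_true, y_pred, positive=None) -> MetricsReport:
    """Confusion counts and the six classification metrics.

    ``positive`` names the positive class (default: "high" for string
    labels, else the larger label). Division-by-zero conventions: a rate
    with an empty denominator is 0; MCC with a zero denominator is 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if positive is None:
        positive = "high" if y_true.dtype.kind in "UO" else np.max(
            np.concatenate([np.unique(y_true), np.unique(y_pred)])
        )
    t = y_true == positive
    p = y_pred == positive
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(tp, tn, fp, fn, acc, prec, rec, f1, spec, float(mcc))


# ---------------------------------------------------------------------------
# cross-validation and baselines
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    fold_reports: list[MetricsReport]
    fold_test_indices: list[np.ndarray]

    @property
    def median_report(self) -> dict[str, float]:
        keys = ("accuracy", "precision", "recall", "f1", "specificity", "mcc")
        return {
            k: float(np.median([getattr(r, k) for r in self.fold_reports]))
            for k in keys
        }


def crossval_5fold(model_factory, X, y, seed: int = 0, n_folds: int = 5,
                   positive=None) -> CrossValResult:
    """Stratified k-fold CV, retraining from scratch per fold.

    Metrics are reported per fold and as medians across folds. Fold
    assignments are deterministic in ``seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"stratification error: every class needs >= {n_folds} samples"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports, test_idx = [], []
    for tr, te in skf.split(X, y):
        model = model_factory()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        reports.append(compute_metrics(y[te], pred, positive=positive))
        test_idx.append(te)
    return CrossValResult(reports, test_idx)


def fit_baselines(clinical_features, labels, seed: int = 0) -> dict[str, CrossValResult]:
    """SVM / random forest / logistic regression on standardized features.

    Features are standardized inside each training fold (pipeline) to avoid
    leakage; the three models share the same 5-fold protocol and seed.
    """
    X = np.asarray(clinical_features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("baselines need both classes present")
    factories = {
        "svm": lambda: make_pipeline(StandardScaler(), SVC(random_state=seed)),
        "random_forest": lambda: make_pipeline(
            StandardScaler(), RandomForestClassifier(random_state=seed)
        ),
        "logistic_regression": lambda: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        ),
    }
    return {
        name: crossval_5fold(factory, X, y, seed=seed)
        for name, factory in factories.items()
    }


def pearson_corr(x, y) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "image_only", "no_pretrain")


def run_ablation(
    n: int = 800,
    variants: tuple[str, ...] = ABLATION_VARIANTS,
    seed: int = 0,
    image_size: int = 64,
    pretrain_n_per_class: int = 200,
    pretrain_epochs: int = 5,
    epochs: int = 8,
    kan_epochs: int = 60,
    qc_gate: bool = True,
    return_models: bool = False,
):
    """Train and evaluate ablation variants on a phantom cohort.

    Variants: ``full`` (pretrained backbone + clinical fusion),
    ``image_only`` (pretrained backbone, no clinical block) and
    ``no_pretrain`` (randomly initialized backbone, no clinical block).
    All variants share the same patient-grouped split and test set.
    Returns a dict variant -> MetricsReport (plus a context dict with the
    trained models when ``return_models``).
    """
    from .augment import ClassicAugmenter
    from .backbone import SwinBackboneClassifier
    from .fusion import CLINICAL_FEATURES, KANFusionClassifier
    from .phantom import PhantomConfig, generate_cohort
    from .qc import BLSQualityMonitor, build_quality_dataset

    unknown = set(variants) - set(ABLATION_VARIANTS)
    if unknown:
        raise ValueError(f"unknown ablation variants: {sorted(unknown)}")
    cfg = PhantomConfig(image_height=image_size, image_width=image_size)
    cohort = generate_cohort(cfg, n, seed=seed)
    X = np.stack([s.image for s in cohort])
    y = np.array([s.label for s in cohort])
    pids = np.array([s.patient_id for s in cohort])
    clin = np.array(
        [[getattr(s.record, a) for a in CLINICAL_FEATURES] for s in cohort]
    )
    plan = split_dataset(y, pids, seed=seed)
    tr, va, te = plan.train, plan.val, plan.test

    # --- augmentation (+ optional quality gate) over the training split ----
    aug = ClassicAugmenter().fit(
        X[tr][y[tr] == "normal"], X[tr][y[tr] == "high"]
    )
    aset = aug.generate(pretrain_n_per_class, seed=seed + 1)
    aug_imgs = np.stack(aset.images)
    aug_dom = np.array(aset.domains)
    if qc_gate:
        qi, qt, _ = build_quality_dataset(
            [cohort[i] for i in tr[: min(len(tr), 300)]], seed=seed + 2
        )
        gate = BLSQualityMonitor(
            n_feature_nodes=200, n_enhancement_nodes=100, random_state=seed
        ).fit(qi, qt)
        keep = gate.predict(aug_imgs)
        if keep.sum() >= 20:  # keep the pretraining set non-trivial
            aug_imgs, aug_dom = aug_imgs[keep], aug_dom[keep]

    # --- backbone training -------------------------------------------------
    pretrained = SwinBackboneClassifier(
        epochs=pretrain_epochs, random_state=seed
    ).fit(aug_imgs, aug_dom)
    finetuned = SwinBackboneClassifier(
        epochs=epochs, init="pretrained", pretrained_model=pretrained,
        freeze=("patch_embed", "stage0"), random_state=seed + 3,
    ).fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    scratch = None
    if "no_pretrain" in variants:
        scratch = SwinBackboneClassifier(
            epochs=epochs, random_state=seed + 3
        ).fit(X[tr], y[tr], X_val=X[va], y_val=y[va])

    def kan_head(backbone, with_clinical: bool):
        feats_tr = backbone.transform(X[tr])
        feats_te = backbone.transform(X[te])
        if with_clinical:
            Xtr = np.hstack([feats_tr, clin[tr]])
            Xte = np.hstack([feats_te, clin[te]])
            n_clin = clin.shape[1]
        else:
            Xtr, Xte, n_clin = feats_tr, feats_te, 0
        head = KANFusionClassifier(
            n_clinical=n_clin, epochs=kan_epochs, random_state=seed
        ).fit(Xtr, y[tr])
        return head, head.predict(Xte)

    results: dict[str, MetricsReport] = {}
    models: dict[str, object] = {"pretrained": pretrained, "finetuned": finetuned,
                                 "scratch": scratch, "plan": plan, "cohort": cohort}
    for variant in variants:
        if variant == "full":
            head, pred = kan_head(finetuned, with_clinical=True)
        elif variant == "image_only":
            head, pred = kan_head(finetuned, with_clinical=False)
        else:  # no_pretrain
            head, pred = kan_head(scratch, with_clinical=False)
        results[variant] = compute_metrics(y[te], pred, positive="high")
        models[f"head_{variant}"] = head
    if return_models:
        return results, models
    return results
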