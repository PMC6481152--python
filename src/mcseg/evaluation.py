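"""Metric suite: per-class patch error rates, balanced patch accuracy,
whole-image pixel accuracy/FPR, and lesionwise recall.

Patch metrics mirror the per-class error table of the study design:
each class C1..C4 contributes an error rate (misclassified fraction under
the network role's label mapping, in percent), plus an overall accuracy
on a balanced pool.  Whether the overall pool is balanced per binary
label or per four-way class is ambiguous in the source protocol, so both
are reported.  Pixel metrics (accuracy, FPR = FP/(FP+TN)) are reported
both over all pixels and restricted to the Otsu foreground, since a
mostly-background mammogram makes the all-pixel numbers look far better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patches import PATCH_CLASSES, Role, role_positive_classes
from .phantom import MCMask
from .nn.network import TrainedModel


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN over an evaluated pixel or patch population."""

    tp: int
    fp: int
    tn: int
    fn: int
    scope: str = "pixel"        # "pixel" | "patch"
    pixel_domain: str = "all"   # "all" | "foreground"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def fpr_pct(self) -> float:
        neg = self.fp + self.tn
        return 100.0 * self.fp / neg if neg else float("nan")


@dataclass
class ClassErrorTable:
    """Per-class error rates (%) and overall accuracies for one network."""

    role: str
    padding_mode: str
    error_pct: dict[str, float] = field(default_factory=dict)
    overall_accuracy_label_balanced_pct: float = float("nan")
    overall_accuracy_class_balanced_pct: float = float("nan")
    n_per_class: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {f"{k}_error_pct": self.error_pct.get(k, float("nan")) for k in PATCH_CLASSES}
        row["overall_accuracy_pct"] = self.overall_accuracy_label_balanced_pct
        return row


def patch_error_table(
    model: TrainedModel,
    patches_by_class: dict[str, np.ndarray],
    role: Role,
    rng: np.random.Generator | None = None,
) -> ClassErrorTable:
    """Per-class error rates and balanced overall accuracy.

    ``patches_by_class`` maps each class C1..C4 to an array of shape
    (n, 1, N, N) of normalized patches.  Every class must be represented.
    The label-balanced overall pool uses equal positive/negative counts,
    the class-balanced pool equal counts per class (both capped by the
    rarest contributing group).
    """
    missing = [k for k in PATCH_CLASSES if k not in patches_by_class or len(patches_by_class[k]) == 0]
    if missing:
        raise ValueError(f"classes missing from the evaluation pool: {missing}")
    rng = rng if rng is not None else np.random.default_rng(0)
    pos_classes = role_positive_classes(role)

    table = ClassErrorTable(role=role, padding_mode=model.config.padding_mode)
    correct_by_class: dict[str, np.ndarray] = {}
    for klass in PATCH_CLASSES:
        x = patches_by_class[klass]
        truth = int(klass in pos_classes)
        pred = model.predict(x)
        correct = pred == truth
        correct_by_class[klass] = correct
        table.error_pct[klass] = 100.0 * float((~correct).mean())
        table.n_per_class[klass] = len(x)

    # class-balanced pool: equal counts per class, capped by the rarest
    m = min(len(v) for v in correct_by_class.values())
    sub = [rng.permutation(len(v))[:m] for v in correct_by_class.values()]
    acc_class = np.mean(
        [correct_by_class[k][idx].mean() for k, idx in zip(PATCH_CLASSES, sub)]
    )
    table.overall_accuracy_class_balanced_pct = 100.0 * float(acc_class)

    # label-balanced pool: equal positives and negatives
    pos = np.concatenate([correct_by_class[k] for k in PATCH_CLASSES if k in pos_classes])
    neg = np.concatenate([correct_by_class[k] for k in PATCH_CLASSES if k not in pos_classes])
    m2 = min(len(pos), len(neg))
    pos = pos[rng.permutation(len(pos))[:m2]]
    neg = neg[rng.permutation(len(neg))[:m2]]
    table.overall_accuracy_label_balanced_pct = 100.0 * float(
        np.concatenate([pos, neg]).mean()
    )
    return table


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, domain: np.ndarray | None = None,
    scope: str = "pixel", pixel_domain: str = "all",
) -> ConfusionCounts:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if domain is not None:
        pred, truth = pred[domain], truth[domain]
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        scope=scope,
        pixel_domain=pixel_domain,
    )


def pixel_metrics(
    pred: MCMask | np.ndarray,
    truth: MCMask | np.ndarray,
    fg: np.ndarray | None = None,
) -> dict[str, ConfusionCounts]:
    """Pixel confusion counts over all pixels and, if given, the foreground.

    Accuracy = (TP+TN)/total * 100; FPR = FP/(FP+TN) * 100.  The all-pixel
    domain is the headline (background TNs dominate); the foreground-only
    domain is the stricter view.
    """
    p = pred.pixels if isinstance(pred, MCMask) else np.asarray(pred)
    t = truth.pixels if isinstance(truth, MCMask) else np.asarray(truth)
    out = {"all": confusion_counts(p, t, None, "pixel", "all")}
    if fg is not None:
        fg_arr = fg if isinstance(fg, np.ndarray) else fg.pixels
        out["foreground"] = confusion_counts(
            p, t, fg_arr.astype(bool), "pixel", "foreground"
        )
    return out


def lesionwise_recall(
    pred: MCMask | np.ndarray, truth: MCMask | np.ndarray, connectivity: int = 8
) -> float:
    """Fraction of true MC components touched by >= 1 predicted pixel.

    A lesion counts as found when any of its pixels is predicted positive,
    regardless of boundary accuracy.  Returns NaN when the truth holds no
    lesion.
    """
    p = pred.pixels if isinstance(pred, MCMask) else np.asarray(pred)
    t = truth.pixels if isinstance(truth, MCMask) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    from scipy import ndimage

    from .clusters import _STRUCTURES

    labeled, n = ndimage.label(t, structure=_STRUCTURES[connectivity])
    if n == 0:
        return float("nan")
    touched = np.unique(labeled[p.astype(bool)])
    return float((touched > 0).sum() / n)
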