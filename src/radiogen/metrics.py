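"""ROC/PR metrics, precision/recall/F1, and the per-arm mutation and
subtype experiments.

Conventions, stated because the toy examples depend on them: ROC-AUC is
the Mann-Whitney concordance probability with ties counted 1/2; PR-AUC
uses step-wise interpolation (precision held between achieved recall
levels, i.e. average precision); zero-denominator precision/recall score
0 with a warning; multiclass averaging is macro (unweighted class mean).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .classify import (CnnConfig, build_mutation_cnn, build_subtype_cnn,
                       logistic_l1_baseline, predict_proba, train_classifier)
from .volio import split_train_test


@dataclass
class EvalReport:
    """Metrics bundle for one experiment arm."""

    task: str
    arm: str                               # real | generated | combined | omic-baseline
    n_test: int
    roc_auc: float | None = None
    pr_auc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    fold_table: list | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _check_binary(truth, scores):
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and scores must have equal length")
    classes = np.unique(truth)
    return truth, scores, classes


def roc_curve_auc(truth, scores) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr per threshold) and its AUC."""
    truth, scores, classes = _check_binary(truth, scores)
    if len(classes) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    return np.column_stack([fpr, tpr]), auc


def pr_curve_auc(truth, scores) -> tuple[np.ndarray, float]:
    """Precision-recall curve points and step-interpolated AUC."""
    truth, scores, _ = _check_binary(truth, scores)
    if truth.sum() == 0:
        raise ValueError("PR curve requires at least one positive")
    precision, recall, _ = precision_recall_curve(truth, scores)
    auc = float(average_precision_score(truth, scores))
    return np.column_stack([recall, precision]), auc


def precision_recall_f1(truth, predicted, averaging: str = "macro"):
    """Per-class P/R/F1 aggregated as requested.

    ``averaging="binary"`` reports the positive class of a 0/1 problem;
    ``"macro"`` the unweighted mean over the label set (union of truth
    and predictions).  Zero-denominator ratios score 0 with a warning.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if averaging not in ("macro", "binary"):
        raise ValueError(f"unknown averaging {averaging!r}")
    labels = [1] if averaging == "binary" else \
        sorted(set(truth.tolist()) | set(predicted.tolist()))
    ps, rs, fs = [], [], []
    for lab in labels:
        tp = int(np.sum((predicted == lab) & (truth == lab)))
        fp = int(np.sum((predicted == lab) & (truth != lab)))
        fn = int(np.sum((predicted != lab) & (truth == lab)))
        if tp + fp == 0:
            warnings.warn(f"class {lab}: no positive predictions; precision=0")
            p = 0.0
        else:
            p = tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"class {lab}: no true members; recall=0")
            r = 0.0
        else:
            r = tp / (tp + fn)
        f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


# ---------------------------------------------------------------------------
# experiment arms


@dataclass
class ArmData:
    """Volumes + labels (+ latents for the omic baseline) for one arm."""

    volumes: list = field(default_factory=list)
    labels: np.ndarray | None = None
    latents: np.ndarray | None = None


def _cnn_arm_report(task, arm, volumes, labels, config: CnnConfig,
                    test_fraction: float, seed: int) -> EvalReport:
    idx = np.arange(len(volumes))
    pairs = list(zip(idx, labels))
    train, test = split_train_test(pairs, test_fraction=test_fraction,
                                   stratify_key=lambda p: int(p[1]), seed=seed)
    tr_idx = [i for i, _ in train]
    te_idx = [i for i, _ in test]
    binary = config.n_outputs == 1
    model = build_mutation_cnn(config) if binary else build_subtype_cnn(config)
    train_classifier(model, [volumes[i] for i in tr_idx], labels[tr_idx], config)
    scores = predict_proba(model, [volumes[i] for i in te_idx],
                           config.volume_shape)
    y = labels[te_idx]
    if binary:
        _, roc = roc_curve_auc(y, scores)
        _, pr = pr_curve_auc(y, scores)
        p, r, f = precision_recall_f1(y, (scores >= 0.5).astype(int),
                                      averaging="binary")
        return EvalReport(task=task, arm=arm, n_test=len(te_idx), roc_auc=roc,
                          pr_auc=pr, precision=p, recall=r, f1=f, seed=seed)
    pred = scores.argmax(axis=1)
    p, r, f = precision_recall_f1(y, pred, averaging="macro")
    return EvalReport(task=task, arm=arm, n_test=len(te_idx), precision=p,
                      recall=r, f1=f, seed=seed)


def run_mutation_experiment(arms: dict[str, ArmData], gene: str,
                            config: CnnConfig, test_fraction: float = 0.2,
                            seed: int = 0) -> dict[str, EvalReport]:
    """Per-arm 20% stratified split, train, and ROC/PR evaluation.

    ``arms`` maps arm names (real / generated / combined / omic-baseline)
    to their data; the omic-baseline arm uses the latent features with the
    L1-logistic model instead of a CNN.
    """
    reports = {}
    for arm, data in arms.items():
        labels = np.asarray(data.labels)
        if arm == "omic-baseline":
            _, probs, y_te = logistic_l1_baseline(
                data.latents, labels, test_fraction=test_fraction, seed=seed)
            _, roc = roc_curve_auc(y_te, probs)
            _, pr = pr_curve_auc(y_te, probs)
            p, r, f = precision_recall_f1(y_te, (probs >= 0.5).astype(int),
                                          averaging="binary")
            reports[arm] = EvalReport(task=gene, arm=arm, n_test=len(y_te),
                                      roc_auc=roc, pr_auc=pr, precision=p,
                                      recall=r, f1=f, seed=seed)
        else:
            reports[arm] = _cnn_arm_report(gene, arm, data.volumes, labels,
                                           config, test_fraction, seed)
    return reports


def run_subtype_experiment(arms: dict[str, ArmData], config: CnnConfig,
                           test_fraction: float = 0.2,
                           seed: int = 0) -> dict[str, EvalReport]:
    """5-class subtype experiment; reports macro precision/recall/F1."""
    if config.n_outputs != 5:
        raise ValueError("subtype experiment requires n_outputs=5")
    return {arm: _cnn_arm_report("subtype", arm, data.volumes,
                                 np.asarray(data.labels), config,
                                 test_fraction, seed)
            for arm, data in arms.items()}


def plot_curves(truth, scores, out_prefix: str) -> list[str]:
    """Write ROC and PR curve PNGs; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    roc_pts, roc = roc_curve_auc(truth, scores)
    pr_pts, pr = pr_curve_auc(truth, scores)
    for name, pts, auc, (xl, yl) in [
            ("roc", roc_pts, roc, ("FPR", "TPR")),
            ("pr", pr_pts, pr, ("Recall", "Precision"))]:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post" if name == "pr" else None)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.set_title(f"{name.upper()} AUC = {auc:.4f}")
        path = f"{out_prefix}_{name}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
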