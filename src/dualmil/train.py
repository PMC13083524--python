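"""End-to-end joint training, data splitting, metrics and significance.

The whole stack — patch backbone, both transformer branches, the two
cross-attention modules and the linear classifier — is optimized jointly
by Adam on a cross-entropy loss, one patient bag per step.  Gene latents
come from the separately-trained autoencoder and stay fixed, mirroring
the protocol where gene-set identification and latent extraction sit
outside the end-to-end graph.

Evaluation follows the standard protocol: an 80/20 stratified train/test
split with stratified five-fold cross-validation inside the training
portion; sensitivity, specificity, F1, PR-AUC and ROC-AUC per fold; and
paired t-tests on fold-level AUCs between model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .backbone import Backbone, BackboneSpec, patches_to_input
from .genes import GeneLatent
from .mil import DualAttentionMIL, FusionOutput, MILConfig
from .tiling import PatchBag


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]   # (fold_train, fold_val)
    seed: int


def make_splits(labels: dict[str, int], seed: int = 0,
                test_size: float = 0.2, n_folds: int = 5) -> SplitPlan:
    """Stratified 80/20 split plus stratified K folds of the train portion."""
    ids = sorted(labels)
    y = np.array([labels[i] for i in ids])
    for cls in (0, 1):
        if (y == cls).sum() < 10:
            raise ValueError(f"need >= 10 patients per class, class {cls} "
                             f"has {(y == cls).sum()}")
    train_ids, test_ids = train_test_split(
        ids, test_size=test_size, stratify=y, random_state=seed)
    y_train = np.array([labels[i] for i in train_ids])
    for cls in (0, 1):
        if (y_train == cls).sum() < n_folds:
            raise ValueError(f"class {cls} has fewer than {n_folds} train patients")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    train_arr = np.array(train_ids)
    for tr_idx, va_idx in skf.split(train_arr, y_train):
        folds.append((train_arr[tr_idx].tolist(), train_arr[va_idx].tolist()))
    return SplitPlan(list(train_ids), list(test_ids), folds, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(y_true, y_pred, positive: int = 1) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1) for a designated positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    pos = yt == positive
    neg = ~pos
    if not pos.any():
        raise ValueError("sensitivity undefined: no positives in y_true")
    tp = int((pos & (yp == positive)).sum())
    fn = int((pos & (yp != positive)).sum())
    tn = int((neg & (yp != positive)).sum())
    fp = int((neg & (yp == positive)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return sens, spec, f1


def _interpolated_pr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the monotone-interpolated precision-recall curve.

    p_interp(r) = max precision over operating points with recall >= r,
    integrated stepwise over the observed recall levels.
    """
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    tp = np.cumsum(y_sorted == 1)
    n_pos = tp[-1]
    k = np.arange(1, len(y_sorted) + 1)
    precision = tp / k
    recall = tp / n_pos
    # keep the last point at each distinct score (threshold boundaries)
    s_sorted = scores[order]
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision, recall = precision[boundary], recall[boundary]
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    area = 0.0
    for p, r in zip(p_interp, recall):
        area += (r - prev_r) * p
        prev_r = r
    return float(area)


def auc_metrics(y_true, scores) -> tuple[float, float]:
    """(PR-AUC, ROC-AUC); errors if only one class is present."""
    yt = np.asarray(y_true)
    sc = np.asarray(scores, dtype=np.float64)
    if len(np.unique(yt)) < 2:
        raise ValueError("both classes must be present for AUCs")
    roc = float(roc_auc_score(yt, sc))
    pr = _interpolated_pr_auc(yt, sc)
    return pr, roc


def paired_t(fold_values_a, fold_values_b) -> tuple[float, float]:
    """Two-sided paired t-test (df = n - 1) on fold-level metric values."""
    a = np.asarray(fold_values_a, dtype=np.float64)
    b = np.asarray(fold_values_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    f1: float
    pr_auc: float
    roc_auc: float
    fold_values: dict[str, list[float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "f1": self.f1, "pr_auc": self.pr_auc, "roc_auc": self.roc_auc}

    @staticmethod
    def from_folds(fold_values: dict[str, list[float]]) -> "MetricsReport":
        means = {k: float(np.mean(v)) for k, v in fold_values.items()}
        return MetricsReport(means["sensitivity"], means["specificity"],
                             means["f1"], means["pr_auc"], means["roc_auc"],
                             fold_values)


# ---------------------------------------------------------------------------
# Joint model and training
# ---------------------------------------------------------------------------

class MultimodalClassifier(nn.Module):
    """Backbone + dual-attention MIL head, trained end to end."""

    def __init__(self, backbone_spec: BackboneSpec, mil_config: MILConfig,
                 seed: int = 0):
        if backbone_spec.feature_dim != mil_config.dim:
            raise ValueError("backbone feature dim must equal MIL dim")
        self.backbone = Backbone(backbone_spec, seed=seed)
        self.mil = DualAttentionMIL(mil_config)
        self.config = mil_config

    def forward_patient(self, images: np.ndarray,
                        gene_latent: np.ndarray) -> tuple[nn.Tensor, FusionOutput]:
        if self.config.modality == "gene":
            feats = None          # backbone unused in the gene-only ablation
        else:
            feats = self.backbone(nn.Tensor(patches_to_input(images)))
        return self.mil.forward_patient(
            feats, nn.Tensor(np.asarray(gene_latent, dtype=np.float32)))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    lr: float = 1e-3
    positive_class: int = 1
    frozen_backbone: bool = False


def train_model(model: MultimodalClassifier, bags: dict[str, PatchBag],
                gene_latents: dict[str, GeneLatent], labels: dict[str, int],
                config: TrainConfig, seed: int = 0,
                patient_ids: list[str] | None = None) -> list[float]:
    """Joint optimization by Adam, one patient bag per step.

    Returns the per-epoch mean cross-entropy trace.  Deterministic under a
    fixed seed: initialization, shuffling and all kernels are seeded pure
    numpy.  ``frozen_backbone`` excludes backbone parameters from the
    optimizer (features still flow through it).
    """
    ids = sorted(patient_ids if patient_ids is not None else bags.keys())
    for pid in ids:
        if pid not in bags:
            raise KeyError(f"patient {pid} has no patch bag")
        if pid not in gene_latents:
            raise KeyError(f"patient {pid} has no gene latent")
    params = model.mil.parameters() if config.frozen_backbone else model.parameters()
    opt = nn.Adam(params, lr=config.lr)
    rng = np.random.default_rng(seed)
    images = {pid: bags[pid].stack() for pid in ids}
    latents = {pid: gene_latents[pid].features for pid in ids}
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(len(ids))
        total = 0.0
        for i in order:
            pid = ids[i]
            opt.zero_grad()
            logits, _ = model.forward_patient(images[pid], latents[pid])
            loss = nn.cross_entropy_logits(logits, labels[pid])
            loss.backward()
            opt.step()
            total += loss.item()
        trace.append(total / len(ids))
    return trace


def predict(model: MultimodalClassifier, bags: dict[str, PatchBag],
            gene_latents: dict[str, GeneLatent], patient_ids: list[str],
            positive_class: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """(positive-class probabilities, argmax predictions) per patient."""
    scores, preds = [], []
    for pid in patient_ids:
        logits, _ = model.forward_patient(bags[pid].stack(),
                                          gene_latents[pid].features)
        z = logits.data.reshape(-1).astype(np.float64)
        p = np.exp(z - z.max())
        p /= p.sum()
        scores.append(p[positive_class])
        preds.append(int(np.argmax(z)))
    return np.array(scores), np.array(preds)


def evaluate(model: MultimodalClassifier, bags: dict[str, PatchBag],
             gene_latents: dict[str, GeneLatent], labels: dict[str, int],
             patient_ids: list[str], positive_class: int = 1) -> MetricsReport:
    """Threshold-free AUCs plus argmax-threshold confusion metrics."""
    scores, preds = predict(model, bags, gene_latents, patient_ids, positive_class)
    y = np.array([labels[p] for p in patient_ids])
    sens, spec, f1 = confusion_metrics(y, preds, positive=positive_class)
    pr, roc = auc_metrics((y == positive_class).astype(int), scores)
    return MetricsReport(sens, spec, f1, pr, roc)


def save_checkpoint(model: MultimodalClassifier, path) -> None:
    """Store all parameter arrays in discovery order (npz archive)."""
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)


def load_checkpoint(model: MultimodalClassifier, path) -> MultimodalClassifier:
    """Load parameters saved by :func:`save_checkpoint` into a fresh model."""
    with np.load(path) as archive:
        params = model.parameters()
        if len(archive.files) != len(params):
            raise ValueError("checkpoint does not match model architecture")
        for i, p in enumerate(params):
            arr = archive[f"p{i:04d}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.astype(p.data.dtype)
    return model


def cross_validate(backbone_spec: BackboneSpec, mil_config: MILConfig,
                   bags: dict[str, PatchBag], gene_latents: dict[str, GeneLatent],
                   labels: dict[str, int], plan: SplitPlan,
                   train_config: TrainConfig, seed: int = 0) -> MetricsReport:
    """Stratified K-fold CV inside the train portion of a split plan."""
    fold_values: dict[str, list[float]] = {k: [] for k in
                                           ("sensitivity", "specificity", "f1",
                                            "pr_auc", "roc_auc")}
    for fold_i, (tr, va) in enumerate(plan.folds):
        model = MultimodalClassifier(backbone_spec, mil_config,
                                     seed=seed + 1000 * fold_i)
        train_model(model, bags, gene_latents, labels, train_config,
                    seed=seed + fold_i, patient_ids=tr)
        rep = evaluate(model, bags, gene_latents, labels, va,
                       train_config.positive_class)
        for k, v in rep.as_dict().items():
            fold_values[k].append(v)
    return MetricsReport.from_folds(fold_values)
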