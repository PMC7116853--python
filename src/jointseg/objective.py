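"""The decomposed joint training objective.

Because the tissue and lesion label sets are disjoint, a joint label map
``y`` splits exactly into ``y = y^T + y^L`` and the segmentation loss splits
into group-restricted terms ``L^T`` and ``L^L``.  The expected tissue risk on
the lesion domain is intractable (no tissue labels there); since the
probabilistic Jaccard distance satisfies the triangle inequality,

    L^T(h(x), y^T)  ≤  L^T(h(x), h(x^T1))  +  L^T(h(x^T1), y^T),

and the right-hand side *is* tractable: a consistency term between the
full-input and shared-modality predictions, plus a tissue term supervised on
the control (or pseudo-healthy) cohort.  ``seg_loss`` assembles this upper
bound for a sampled batch; ``total_loss`` adds the λ-weighted domain
adaptation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import JointLabelMap, Subject
from .jaccard import prob_multiclass_jaccard
from .taxonomy import ClassTaxonomy, ClassWeights

__all__ = ["decompose_labels", "one_hot", "tissue_loss", "lesion_loss",
           "LossReport", "Batch", "seg_loss", "total_loss",
           "check_tissue_upper_bound"]


def decompose_labels(labels, taxonomy: ClassTaxonomy | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Split a joint label map into its tissue and lesion parts.

    Tissue part keeps tissue labels and zeroes lesion labels; the lesion part
    the reverse.  Their voxel-wise sum reconstructs the input exactly.
    """
    if isinstance(labels, JointLabelMap):
        taxonomy = labels.taxonomy
        labels = labels.labels
    if taxonomy is None:
        raise ValueError("a taxonomy is required for plain-array input")
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    allowed = set(taxonomy.all_classes)
    if not present <= allowed:
        raise ValueError(f"labels {sorted(present - allowed)} outside taxonomy")
    lesion_mask = np.isin(labels, list(taxonomy.lesion_classes))
    tissue = np.where(lesion_mask, 0, labels)
    lesion = np.where(lesion_mask, labels, 0)
    return tissue, lesion


def one_hot(labels: np.ndarray, taxonomy: ClassTaxonomy) -> np.ndarray:
    """One-hot encode a label map to ``(C, *spatial)`` float32 in taxonomy
    channel order (background first)."""
    labels = np.asarray(labels)
    out = np.zeros((taxonomy.num_classes, *labels.shape), dtype=np.float32)
    for ch, cls in enumerate(taxonomy.all_classes):
        out[ch] = labels == cls
    return out


def _as_target(target, taxonomy: ClassTaxonomy):
    """Accept a probability map (ndarray or Tensor, (C,*S)) or an integer
    label map and return a (C,*S) representation."""
    if isinstance(target, Tensor):
        return target
    target = np.asarray(target)
    if target.ndim >= 1 and target.shape[0] == taxonomy.num_classes \
            and target.dtype.kind == "f":
        return target
    return one_hot(target, taxonomy)


def tissue_loss(pred, target, w: ClassWeights):
    """Group-restricted distance L^T: the probabilistic Jaccard summed over
    the tissue classes (plus background, under a weight policy that counts
    it toward the tissue half).  ``target`` may be a one-hot/label map (the
    supervised term) or another probability map (the consistency term)."""
    return prob_multiclass_jaccard(pred, _as_target(target, w.taxonomy), w,
                                   class_subset=w.tissue_subset)


def lesion_loss(pred, target, w: ClassWeights):
    """Group-restricted distance L^L over the lesion classes."""
    return prob_multiclass_jaccard(pred, _as_target(target, w.taxonomy), w,
                                   class_subset=w.taxonomy.lesion_classes)


@dataclass
class LossReport:
    """Named scalar loss components and their total.

    ``total = Σ components`` with the λ weighting already applied to the
    stored ``da`` component.  ``total_tensor`` (when built from live graph
    tensors) backs propagation; the float fields are for logging.
    """

    components: dict[str, float] = field(default_factory=dict)
    lambda_da: float = 0.0
    total_tensor: Tensor | None = None
    pred_cache: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def as_row(self) -> dict[str, float]:
        row = dict(self.components)
        row["total"] = self.total
        return row


@dataclass
class Batch:
    """One sampled training batch: per-group subject lists."""

    lesion: list[Subject] = field(default_factory=list)
    control: list[Subject] = field(default_factory=list)
    pseudo: list[Subject] = field(default_factory=list)


def _scalar(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


def _stack(subjects: list[Subject]) -> np.ndarray:
    return np.stack([s.image.channels for s in subjects])


def _group_mean(terms):
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def seg_loss(batch: Batch, model, w: ClassWeights, mode: str = "no_da",
             epoch: int = 0, consistency_warmup: int = 50) -> LossReport:
    """Tractable segmentation loss for one batch.

    ``no_da`` mode:  L^L(h(x_l), y^L) + L^T(h(x_l), h(x_l^T1))
                     + L^T(h(x_c^T1), y^T_c);
    ``pseudo`` mode: the control tissue term is replaced by the average
    (1/2)[L^T(h(x_p^T1), y^T_p) + L^T(h(x_c^T1), y^T_c)].

    The consistency term is included only once ``epoch >=
    consistency_warmup``; training starts from the supervised terms alone.
    Prediction-side tensors of shape (C, *S) come from a shared batched
    forward pass so the graph is built once per group.
    """
    if mode not in ("no_da", "pseudo", "fully_sup", "tissue_only",
                    "lesion_only"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    tax = w.taxonomy
    need_lesion = mode in ("no_da", "pseudo", "fully_sup", "lesion_only")
    need_control = mode in ("no_da", "pseudo", "tissue_only")
    if need_lesion and not batch.lesion:
        raise ValueError(f"mode {mode!r} requires a lesion group in the batch")
    if need_control and not batch.control:
        raise ValueError(f"mode {mode!r} requires a control group in the batch")
    if mode == "pseudo" and not batch.pseudo:
        raise ValueError("pseudo mode requires a pseudo-healthy group")

    report = LossReport()
    terms: list[Tensor] = []

    def add(name: str, value) -> None:
        report.components[name] = _scalar(value)
        terms.append(value)

    full_mask = np.ones(model.config.num_modalities, dtype=bool)
    shared_mask = np.zeros_like(full_mask)
    shared_mask[model.config.shared_modality] = True

    # one batched forward per input regime: [lesion^T1 | control | pseudo]
    consistency_on = (mode in ("no_da", "pseudo")
                      and epoch >= consistency_warmup and need_lesion)
    shared_groups: list[tuple[str, list[Subject]]] = []
    if consistency_on:
        shared_groups.append(("lesion_shared", batch.lesion))
    if need_control:
        shared_groups.append(("control", batch.control))
    if mode == "pseudo":
        shared_groups.append(("pseudo", batch.pseudo))
    shared_preds: dict[str, Tensor] = {}
    if shared_groups:
        x_s = np.concatenate([_stack(g) for _, g in shared_groups])
        pred_s = model.forward(x_s, shared_mask)
        lo = 0
        for name, g in shared_groups:
            shared_preds[name] = pred_s[lo:lo + len(g)]
            lo += len(g)

    if need_lesion:
        x_l = _stack(batch.lesion)
        pred_full = model.forward(x_l, full_mask)
        report.pred_cache["lesion_full"] = pred_full.data
        if mode == "fully_sup":
            joint = [prob_multiclass_jaccard(
                pred_full[i], one_hot(s.labels, tax), w)
                for i, s in enumerate(batch.lesion)]
            add("lesion_joint", _group_mean(joint))
        else:
            les = [lesion_loss(pred_full[i], s.labels, w)
                   for i, s in enumerate(batch.lesion)]
            add("lesion", _group_mean(les))
        if consistency_on:
            pred_shared_l = shared_preds["lesion_shared"]
            report.pred_cache["lesion_shared"] = pred_shared_l.data
            cons = [tissue_loss(pred_full[i], pred_shared_l[i], w)
                    for i in range(len(batch.lesion))]
            add("consistency", _group_mean(cons))

    if need_control:
        pred_c = shared_preds["control"]
        ctrl = [tissue_loss(pred_c[i], s.labels, w)
                for i, s in enumerate(batch.control)]
        ctrl_mean = _group_mean(ctrl)
        if mode == "pseudo":
            pred_p = shared_preds["pseudo"]
            pse = [tissue_loss(pred_p[i], s.labels, w)
                   for i, s in enumerate(batch.pseudo)]
            add("tissue_control", ctrl_mean * 0.5)
            add("tissue_pseudo", _group_mean(pse) * 0.5)
        else:
            add("tissue_control", ctrl_mean)

    total = terms[0]
    for t in terms[1:]:
        total = total + t
    report.total_tensor = total
    return report


def total_loss(seg: LossReport, da_term, lam: float) -> LossReport:
    """Total objective ``L_total = L_seg + λ · L_DA``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = LossReport(components=dict(seg.components), lambda_da=lam)
    out.total_tensor = seg.total_tensor
    if da_term is not None and lam > 0:
        out.components["da"] = lam * _scalar(da_term)
        out.total_tensor = seg.total_tensor + lam * da_term
    return out


def check_tissue_upper_bound(pred_full, pred_shared, tissue_target,
                             w: ClassWeights, tol: float = 1e-9) -> float:
    """Verify the triangle-inequality bound

        L^T(h(x), y^T) <= L^T(h(x), h(x^T1)) + L^T(h(x^T1), y^T)

    on concrete maps (numpy, float64).  Returns the slack (rhs - lhs);
    raises if the bound is violated beyond ``tol``.  The trainer runs this
    every iteration — a violation means the loss is not a metric and the
    whole decomposition is unsound.
    """
    pf = np.asarray(getattr(pred_full, "data", pred_full), dtype=np.float64)
    ps = np.asarray(getattr(pred_shared, "data", pred_shared), dtype=np.float64)
    tgt = _as_target(tissue_target, w.taxonomy)
    tgt = np.asarray(getattr(tgt, "data", tgt), dtype=np.float64)
    lhs = _scalar(tissue_loss(pf, tgt, w))
    rhs = _scalar(tissue_loss(pf, ps, w)) + _scalar(tissue_loss(ps, tgt, w))
    slack = rhs - lhs
    if slack < -tol:
        raise AssertionError(
            f"tissue upper bound violated by {-slack:.3e} (tol {tol:g})")
    return slack
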