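"""Class taxonomy for the joint tissue + lesion segmentation problem.

The joint label space is ``{0} ∪ C_T ∪ C_L``: background, a set of tissue
classes and a disjoint set of lesion classes.  The per-class weights ω_c of
the segmentation distance are constrained so that the tissue group and the
lesion group each carry half of the total weight, which gives the two tasks
equal importance regardless of how many classes they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClassTaxonomy", "ClassWeights", "make_class_weights",
           "make_training_weights"]


@dataclass(frozen=True)
class ClassTaxonomy:
    """Disjoint tissue and lesion class sets plus background 0."""

    tissue_classes: tuple[int, ...]
    lesion_classes: tuple[int, ...]
    background: int = 0

    def __post_init__(self) -> None:
        ct, cl = set(self.tissue_classes), set(self.lesion_classes)
        if ct & cl:
            raise ValueError(f"tissue and lesion classes overlap: {sorted(ct & cl)}")
        if self.background in ct | cl:
            raise ValueError("background value must not appear in a class group")
        if any(c <= 0 for c in ct | cl):
            raise ValueError("class labels must be positive integers")
        object.__setattr__(self, "tissue_classes", tuple(self.tissue_classes))
        object.__setattr__(self, "lesion_classes", tuple(self.lesion_classes))

    @property
    def all_classes(self) -> tuple[int, ...]:
        """Background + tissue + lesion, in that order."""
        return (self.background, *self.tissue_classes, *self.lesion_classes)

    @property
    def num_classes(self) -> int:
        return 1 + len(self.tissue_classes) + len(self.lesion_classes)

    def channel_of(self, label: int) -> int:
        """Channel index of a label in the canonical class ordering."""
        return self.all_classes.index(label)

    def channels_of(self, labels) -> np.ndarray:
        return np.array([self.channel_of(int(c)) for c in labels], dtype=int)


@dataclass(frozen=True)
class ClassWeights:
    """One non-negative weight per class, in taxonomy channel order.

    Invariants: weights sum to 1 and the tissue and lesion groups each sum
    to 1/2, so the two tasks contribute equally to the distance.  With the
    default policy the background weight is zero; a weight policy may
    instead count background toward the tissue half
    (``background_in_tissue``), which supervises the background channel
    during training while preserving the half/half task balance.
    """

    taxonomy: ClassTaxonomy
    weights: np.ndarray = field(repr=False)
    background_in_tissue: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.taxonomy.num_classes,):
            raise ValueError("one weight per class required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        nt = len(self.taxonomy.tissue_classes)
        wt = w[1 : 1 + nt].sum()
        if self.background_in_tissue:
            wt += w[0]
        elif w[0] != 0.0:
            raise ValueError("background weight must be 0 under the default policy")
        wl = w[1 + nt :].sum()
        if abs(wt - 0.5) > 1e-12 or abs(wl - 0.5) > 1e-12:
            raise ValueError("tissue and lesion groups must each carry weight 1/2")
        object.__setattr__(self, "weights", w)

    @property
    def tissue_subset(self) -> tuple[int, ...]:
        """Classes whose terms make up L^T: C_T, plus background when the
        weight policy counts it toward the tissue half."""
        if self.background_in_tissue:
            return (self.taxonomy.background, *self.taxonomy.tissue_classes)
        return self.taxonomy.tissue_classes

    def subset_vector(self, classes) -> np.ndarray:
        """Weight vector with zeros outside ``classes`` (taxonomy labels)."""
        keep = set(int(c) for c in classes)
        mask = np.array([c in keep for c in self.taxonomy.all_classes])
        return np.where(mask, self.weights, 0.0)


def make_class_weights(taxonomy: ClassTaxonomy) -> ClassWeights:
    """Uniform-within-group weights: ω_0 = 0, each tissue class gets
    (1/2)/|C_T| and each lesion class (1/2)/|C_L|."""
    nt, nl = len(taxonomy.tissue_classes), len(taxonomy.lesion_classes)
    if nt == 0 or nl == 0:
        raise ValueError("both tissue and lesion groups must be non-empty")
    w = np.concatenate([[0.0], np.full(nt, 0.5 / nt), np.full(nl, 0.5 / nl)])
    return ClassWeights(taxonomy, w)


def make_training_weights(taxonomy: ClassTaxonomy) -> ClassWeights:
    """Uniform weights with background folded into the tissue half:
    each of {0} ∪ C_T gets (1/2)/(|C_T|+1), each lesion class (1/2)/|C_L|.

    The zero-background-weight metric leaves the background channel
    unsupervised, which admits a degenerate optimum where a foreground
    class colonises the background with a saturated (zero-gradient)
    Jaccard term; counting background as one more tissue-half class keeps
    the printed half/half task balance while closing that failure mode.
    """
    nt, nl = len(taxonomy.tissue_classes), len(taxonomy.lesion_classes)
    if nt == 0 or nl == 0:
        raise ValueError("both tissue and lesion groups must be non-empty")
    w = np.concatenate([[0.5 / (nt + 1)], np.full(nt, 0.5 / (nt + 1)),
                        np.full(nl, 0.5 / nl)])
    return ClassWeights(taxonomy, w, background_in_tissue=True)
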