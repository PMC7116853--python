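"""Probabilistic multi-class Jaccard distance and its binary / per-class forms.

The binary Jaccard distance ``1 - |A∩B| / |A∪B|`` is a true metric on sets.
Its soft extension used here,

    J(u, v) = Σ_c ω_c · 2 Σ_i |u_ci - v_ci| / Σ_i (|u_ci| + |v_ci| + |u_ci - v_ci|),

coincides with the binary Jaccard on binary inputs and — crucially — remains
a metric on per-voxel probability maps (a consequence of the Steinhaus
transform applied to the L1 distance).  The triangle inequality is what makes
the expected-risk upper bound of the joint training objective valid, so this
module is the load-bearing primitive of the whole package.

Functions here accept plain numpy arrays or autodiff ``Tensor`` objects
(anything supporting ``abs``, ``+``, ``-`` and ``.sum(axis=...)``), so the
same formula serves as evaluation metric and as differentiable loss.
"""

from __future__ import annotations

import numpy as np

from .taxonomy import ClassWeights

__all__ = [
    "binary_jaccard",
    "soft_jaccard_per_class",
    "prob_multiclass_jaccard",
    "check_probability_map",
]


def _shape(x):
    return x.shape


def _as_float(x):
    """Scalar value of a 0-d array / Tensor / python number."""
    data = getattr(x, "data", x)
    return float(np.asarray(data))


def binary_jaccard(a, b) -> float:
    """Binary Jaccard distance between two 0/1 voxel vectors.

    Returns ``1 - Σ a_i b_i / Σ (a_i + b_i - a_i b_i)``; the empty-vs-empty
    case (both vectors all zero) is defined as 0 so that identity of
    indiscernibles holds and absent classes are not penalised.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    for v in (a, b):
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("binary_jaccard requires 0/1 inputs")
    inter = float(a @ b)
    union = float(np.sum(a + b) - inter)
    if union == 0.0:
        return 0.0
    return 1.0 - inter / union


def soft_jaccard_per_class(u_c, v_c):
    """Soft (probabilistic) Jaccard distance for a single class channel.

    ``2 Σ|u - v| / Σ(|u| + |v| + |u - v|)`` with the 0/0 case defined as 0.
    Accepts numpy arrays (returns float) or autodiff tensors (returns a
    scalar tensor differentiable wherever the denominator is nonzero).
    """
    if _shape(u_c) != _shape(v_c):
        raise ValueError(f"shape mismatch: {_shape(u_c)} vs {_shape(v_c)}")
    d = abs(u_c - v_c)
    num = 2.0 * d.sum()
    den = (abs(u_c) + abs(v_c) + d).sum()
    if _as_float(den) == 0.0:
        return 0.0 * num  # preserves tensor type; value and gradient both 0
    return num / den


def prob_multiclass_jaccard(u, v, w: ClassWeights, class_subset=None):
    """Weighted probabilistic multi-class Jaccard distance.

    ``u``, ``v`` are probability maps of shape ``(C, *spatial)`` with classes
    in taxonomy channel order.  ``class_subset`` (taxonomy labels) restricts
    the sum to those classes' terms, which realises the group losses L^T and
    L^L of the decomposed objective; weights are taken from ``w`` unchanged,
    so the full-set distance decomposes exactly into its group restrictions.
    """
    if _shape(u) != _shape(v):
        raise ValueError(f"shape mismatch: {_shape(u)} vs {_shape(v)}")
    n_classes = w.taxonomy.num_classes
    if _shape(u)[0] != n_classes:
        raise ValueError(
            f"expected {n_classes} class channels on axis 0, got {_shape(u)[0]}"
        )
    wv = w.weights if class_subset is None else w.subset_vector(class_subset)
    total = 0.0
    for c in range(n_classes):
        if wv[c] == 0.0:
            continue
        total = total + wv[c] * soft_jaccard_per_class(u[c], v[c])
    return total


def check_probability_map(p, atol: float = 1e-6) -> np.ndarray:
    """Validate a ``(C, *spatial)`` probability map: values in [0,1] and the
    class axis summing to 1 per voxel within ``atol``.  Returns the array."""
    p = np.asarray(p, dtype=float)
    if p.min() < -atol or p.max() > 1 + atol:
        raise ValueError("probability map values outside [0, 1]")
    s = p.sum(axis=0)
    if np.max(np.abs(s - 1.0)) > atol:
        raise ValueError("per-voxel class probabilities do not sum to 1")
    return p
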