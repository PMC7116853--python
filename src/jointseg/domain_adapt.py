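"""Domain adaptation strategies for domain-shifted control/lesion cohorts.

Three mechanisms are provided:

* **augmentation consistency** — physically-inspired transforms (random bias
  field, ghosting-style motion artefact, Gaussian smoothing) generate a
  shifted copy of a control scan; a tissue-consistency term penalises
  disagreement between the predictions on the pair.  The transform family is
  shared with the phantom generator's simulated shift, so augmentation and
  shift are drawn from one physical model.
* **adversarial features** — a small convolutional discriminator classifies
  contracting-path features by domain; the segmenter earns a confusion term
  that drives the two feature distributions together.
* **pseudo-healthy synthesis** — for roughly bilaterally symmetric anatomy
  with a unilateral lesion, the inter-hemispheric symmetry plane is
  estimated and the healthy hemisphere mirrored over the lesioned one,
  producing a lesion-free scan in the lesion cohort's acquisition style to
  which tissue labels can be attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .autodiff import Tensor
from .jaccard import ClassWeights
from .objective import tissue_loss
from .phantom import gaussian_smooth, random_bias_field
from .taxonomy import ClassTaxonomy

__all__ = ["AugmentationRanges", "AugmentationTransform", "sample_augmentation",
           "augmentation_da_loss", "adversarial_da_losses", "SymmetryPlane",
           "estimate_symmetry_plane", "make_pseudo_healthy"]

_P_CLAMP = 1e-7  # discriminator probability clamp before taking logs


# ---------------------------------------------------------------------------
# augmentation consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationRanges:
    """Sampling distribution D_ψ for the augmentation parameters."""

    bias_amplitude: tuple[float, float] = (0.0, 0.3)
    bias_order: int = 2
    smooth_sigma: tuple[float, float] = (0.0, 1.0)
    ghost_alpha: tuple[float, float] = (0.0, 0.15)
    ghost_shift: tuple[int, int] = (2, 4)


@dataclass(frozen=True)
class AugmentationTransform:
    """One drawn ψ: a fixed composition of bias field, ghosting and
    smoothing.  Applying the same transform twice gives identical output;
    all-zero amplitudes give the identity."""

    bias_amplitude: float
    bias_order: int
    bias_seed: int
    smooth_sigma: float
    ghost_alpha: float
    ghost_shift: int

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Transform a single-channel spatial array (or (1, *S) array)."""
        arr = np.asarray(image, dtype=np.float32)
        squeeze = False
        if arr.ndim >= 3 and arr.shape[0] == 1:
            arr, squeeze = arr[0], True
        out = arr
        if self.bias_amplitude > 0:
            rng = np.random.default_rng(self.bias_seed)
            out = out * random_bias_field(out.shape, self.bias_amplitude,
                                          self.bias_order, rng)
        if self.ghost_alpha > 0:
            echo = np.roll(out, self.ghost_shift, axis=-1)
            out = (1.0 - self.ghost_alpha) * out + self.ghost_alpha * echo
        if self.smooth_sigma > 0:
            out = gaussian_smooth(out, self.smooth_sigma)
        out = np.asarray(out, dtype=np.float32)
        return out[None] if squeeze else out

    def is_identity(self) -> bool:
        return (self.bias_amplitude == 0 and self.ghost_alpha == 0
                and self.smooth_sigma == 0)


def sample_augmentation(seed: int,
                        ranges: AugmentationRanges = AugmentationRanges()
                        ) -> AugmentationTransform:
    """Draw ψ ~ D_ψ deterministically from ``seed``."""
    for lo, hi in (ranges.bias_amplitude, ranges.smooth_sigma,
                   ranges.ghost_alpha):
        if lo < 0 or hi < lo:
            raise ValueError("invalid amplitude range")
    rng = np.random.default_rng(seed)
    return AugmentationTransform(
        bias_amplitude=float(rng.uniform(*ranges.bias_amplitude)),
        bias_order=ranges.bias_order,
        bias_seed=int(rng.integers(0, 2 ** 31)),
        smooth_sigma=float(rng.uniform(*ranges.smooth_sigma)),
        ghost_alpha=float(rng.uniform(*ranges.ghost_alpha)),
        ghost_shift=int(rng.integers(ranges.ghost_shift[0],
                                     ranges.ghost_shift[1] + 1)),
    )


def augmentation_da_loss(model, control_images: np.ndarray,
                         transform: AugmentationTransform,
                         w: ClassWeights) -> Tensor:
    """Paired consistency term L^T(h(x_c^T1), h(T_ψ(x_c^T1))).

    ``control_images``: (B, M, *S) shared-modality-regime batch.  Gradients
    flow through both forward passes.
    """
    x = np.asarray(control_images, dtype=np.float32)
    sm = model.config.shared_modality
    shared_mask = np.zeros(model.config.num_modalities, dtype=bool)
    shared_mask[sm] = True
    x_aug = x.copy()
    for b in range(x.shape[0]):
        x_aug[b, sm] = transform.apply(x[b, sm])
    pred = model.forward(x, shared_mask)
    pred_aug = model.forward(x_aug, shared_mask)
    terms = [tissue_loss(pred[i], pred_aug[i], w) for i in range(x.shape[0])]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


# ---------------------------------------------------------------------------
# adversarial feature alignment
# ---------------------------------------------------------------------------

def adversarial_da_losses(disc, feat_control, feat_lesion
                          ) -> tuple[Tensor, Tensor]:
    """Segmenter and discriminator adversarial terms on feature batches.

    The discriminator outputs the probability that features come from the
    lesion domain; its term is the binary cross-entropy with the true domain
    labels (lesion → 1, control → 0).  The segmenter term is the confusion
    objective −[log D(f_c) + log(1 − D(f_l))]: minimising it pushes control
    features to look lesion-like and vice versa, driving the discriminator
    toward chance.  Probabilities are clamped to [1e-7, 1 − 1e-7] before the
    logarithms for numerical stability.

    Returns ``(segmenter_term, discriminator_term)``; the caller decides
    which parameters each gradient reaches.
    """
    p_c = disc(feat_control).clip(_P_CLAMP, 1.0 - _P_CLAMP)
    p_l = disc(feat_lesion).clip(_P_CLAMP, 1.0 - _P_CLAMP)
    disc_term = -(p_l.log().mean() + (1.0 - p_c).log().mean())
    seg_term = -(p_c.log().mean() + (1.0 - p_l).log().mean())
    return seg_term, disc_term


# ---------------------------------------------------------------------------
# pseudo-healthy synthesis by hemispheric symmetrisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymmetryPlane:
    """Inter-hemispheric mirror plane: offset (voxels) of the plane from the
    grid centre along the last axis, plus an in-plane rotation (degrees)
    about the centre, tilting the plane normal within the (first axis, last
    axis) plane."""

    offset: float
    angle_deg: float

    def point_normal(self, shape: tuple[int, ...]
                     ) -> tuple[np.ndarray, np.ndarray]:
        ndim = len(shape)
        center = (np.array(shape, dtype=float) - 1) / 2
        p0 = center.copy()
        p0[-1] += self.offset
        a = np.deg2rad(self.angle_deg)
        n = np.zeros(ndim)
        n[0] = -np.sin(a)
        n[-1] = np.cos(a)
        return p0, n


def _reflect(image: np.ndarray, plane: SymmetryPlane, order: int = 1
             ) -> np.ndarray:
    """Reflect an image across the plane (its own inverse, so the same map
    serves for resampling)."""
    p0, n = plane.point_normal(image.shape)
    h = np.eye(len(image.shape)) - 2.0 * np.outer(n, n)
    offset = p0 - h @ p0
    return ndimage.affine_transform(image, h, offset=offset, order=order,
                                    mode="constant", cval=0.0,
                                    output=np.float64 if order else image.dtype)


def _mirror_ncc(image: np.ndarray, plane: SymmetryPlane,
                fg: np.ndarray) -> float:
    """Normalised cross-correlation between the image and its reflection,
    over the foreground mask."""
    ref = _reflect(image, plane)
    a, b = image[fg].astype(float), ref[fg].astype(float)
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def estimate_symmetry_plane(image: np.ndarray,
                            offset_frac: float = 0.1,
                            angle_max_deg: float = 10.0,
                            coarse: int = 11,
                            fg_threshold: float | None = None
                            ) -> SymmetryPlane:
    """Estimate the inter-hemispheric symmetry plane of a single-modality
    volume by maximising the mirror normalised cross-correlation.

    Coarse grid search over offset (± ``offset_frac`` of the last-axis
    width) and rotation (± ``angle_max_deg``), then Nelder–Mead refinement.
    """
    image = np.asarray(image, dtype=float)
    if fg_threshold is None:
        fg_threshold = 0.1 * float(image.max())
    fg = image > fg_threshold
    if not fg.any():
        raise ValueError("empty foreground: cannot estimate a symmetry plane")
    width = image.shape[-1]
    best, best_ncc = SymmetryPlane(0.0, 0.0), -np.inf
    for off in np.linspace(-offset_frac * width, offset_frac * width, coarse):
        for ang in np.linspace(-angle_max_deg, angle_max_deg, coarse):
            ncc = _mirror_ncc(image, SymmetryPlane(off, ang), fg)
            if ncc > best_ncc:
                best, best_ncc = SymmetryPlane(off, ang), ncc

    res = optimize.minimize(
        lambda p: -_mirror_ncc(image, SymmetryPlane(p[0], p[1]), fg),
        x0=[best.offset, best.angle_deg], method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 1e-6, "maxiter": 120})
    refined = SymmetryPlane(float(res.x[0]), float(res.x[1]))
    if -res.fun >= best_ncc:
        return refined
    return best


def make_pseudo_healthy(image: np.ndarray, label_map: np.ndarray,
                        plane: SymmetryPlane, taxonomy: ClassTaxonomy,
                        healthy_side: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Replace the lesioned hemisphere with the mirror of the healthy one.

    ``image``: single- or multi-channel ((M, *S)) volume; ``label_map``:
    joint labels.  Lesions must be confined to one side of the plane.
    Returns the symmetrised image and lesion-free tissue labels.
    """
    image = np.asarray(image, dtype=np.float32)
    multi = image.ndim == np.asarray(label_map).ndim + 1
    label_map = np.asarray(label_map)
    shape = label_map.shape
    p0, n = plane.point_normal(shape)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    signed = sum((g - p) * ni for g, p, ni in zip(grids, p0, n))

    lesion_mask = np.isin(label_map, list(taxonomy.lesion_classes))
    if healthy_side is None:
        if not lesion_mask.any():
            healthy_side = 1
        else:
            s = signed[lesion_mask]
            # allow boundary voxels within half a voxel of the plane
            if (s > 0.5).any() and (s < -0.5).any():
                raise ValueError(
                    "lesions straddle the symmetry plane; pseudo-healthy "
                    "synthesis requires a unilateral lesion")
            healthy_side = -1 if np.median(s) > 0 else 1
    replace = (signed * healthy_side) < 0  # the lesioned half

    def symmetrise(arr: np.ndarray, order: int) -> np.ndarray:
        ref = _reflect(arr.astype(np.float64 if order else arr.dtype),
                       plane, order=order)
        out = np.where(replace, ref, arr)
        return out.astype(arr.dtype)

    if multi:
        pseudo_img = np.stack([symmetrise(ch, order=1) for ch in image])
    else:
        pseudo_img = symmetrise(image, order=1)
    pseudo_lab = symmetrise(label_map, order=0)
    # residual lesion voxels can only arise at the plane from resampling;
    # reassign them to the dominant neighbouring tissue class
    residual = np.isin(pseudo_lab, list(taxonomy.lesion_classes))
    if residual.any():
        tissue_only = np.where(
            np.isin(pseudo_lab, list(taxonomy.lesion_classes)), 0, pseudo_lab)
        filled = tissue_only.copy()
        missing = residual.copy()
        while missing.any():
            grown = ndimage.grey_dilation(filled, size=(3,) * filled.ndim)
            filled = np.where(missing, grown, filled)
            missing = missing & (filled == 0)
        pseudo_lab = filled
    return pseudo_img, pseudo_lab.astype(label_map.dtype)
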