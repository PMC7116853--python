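"""Seeded synthetic brain phantoms with exact joint ground truth.

The generator emulates the data situation the training framework is built
for: a *control* cohort offering one modality (T1-like) with tissue labels,
a *lesion* cohort offering the full modality set with lesion labels only,
a small *pseudo-healthy* cohort in the lesion cohort's acquisition style,
and a fully-annotated held-out *test* cohort.  Anatomy is a set of nested,
smoothly perturbed concentric regions (ventricle core, deep grey, white
matter, cortical grey rim) — not realistic anatomy, but it reproduces the
class structure, the modality contrast asymmetry (tissue contrast lives in
modality 1, lesion contrast in modality 2) and, optionally, an
acquisition-style domain shift (bias field, smoothing, contrast change)
between the cohorts.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .data import DatasetManifest, JointLabelMap, MultiModalImage, Subject
from .taxonomy import ClassTaxonomy

__all__ = [
    "TissueLayout", "LesionParams", "ModalityProfile", "ShiftParams",
    "PhantomConfig", "GenerationError", "default_taxonomy",
    "wmh_scenario", "glioma_scenario",
    "generate_phantom", "apply_domain_shift", "build_task_datasets",
    "random_bias_field", "gaussian_smooth",
]


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be generated under the configuration."""


def default_taxonomy() -> ClassTaxonomy:
    """Four tissue classes (1 ventricles, 2 deep grey, 3 white matter,
    4 cortical grey) and one lesion class (5)."""
    return ClassTaxonomy(tissue_classes=(1, 2, 3, 4), lesion_classes=(5,))


@dataclass(frozen=True)
class TissueLayout:
    """Nested-region anatomy: outer radii of the concentric tissue shells as
    fractions of the brain radius, innermost first, and the smooth random
    boundary perturbation applied per subject."""

    radii: tuple[float, ...] = (0.20, 0.38, 0.82, 1.0)  # vent, deep, WM, cortex
    brain_radius_frac: float = 0.44    # brain radius / min(grid)
    boundary_noise: float = 0.05       # rms of the radial perturbation field
    noise_smoothness: float = 0.12     # perturbation corr. length / min(grid)
    axis_scale_range: tuple[float, float] = (0.92, 1.08)
    center_jitter: float = 1.0         # voxels


@dataclass(frozen=True)
class LesionParams:
    count_range: tuple[int, int] = (2, 4)
    radius_range: tuple[float, float] = (2.5, 6.0)
    host_class: int = 3                # lesions grow inside white matter
    margin: float = 1.0                # voxels kept clear of the host border
    max_tries: int = 500


@dataclass(frozen=True)
class ModalityProfile:
    """Per-class mean intensity and additive noise s.d. for one modality."""

    means: dict[int, float]
    noise_sd: float = 0.03

    def lookup(self, max_label: int) -> np.ndarray:
        table = np.zeros(max_label + 1, dtype=np.float32)
        for lab, mu in self.means.items():
            table[lab] = mu
        return table


@dataclass(frozen=True)
class ShiftParams:
    """Acquisition-style domain shift: multiplicative bias field, Gaussian
    smoothing and a gamma contrast change.  All-zero amplitudes (``gamma=1``)
    give the identity."""

    bias_amplitude: float = 0.3
    bias_order: int = 2
    smooth_sigma: float = 0.8
    contrast_gamma: float = 1.5

    def is_identity(self) -> bool:
        return (self.bias_amplitude == 0 and self.smooth_sigma == 0
                and self.contrast_gamma == 1.0)


def _default_profiles() -> tuple[ModalityProfile, ...]:
    # Modality 0 (T1-like): strong tissue contrast, lesion nearly isointense
    # with its white-matter host.  Modality 1 (FLAIR-like): tissue classes
    # nearly isointense, lesion bright.
    t1 = ModalityProfile(
        means={0: 0.02, 1: 0.20, 2: 0.55, 3: 0.85, 4: 0.60, 5: 0.80})
    flair = ModalityProfile(
        means={0: 0.02, 1: 0.45, 2: 0.50, 3: 0.55, 4: 0.52, 5: 0.95})
    return (t1, flair)


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, ...] = (64, 64)
    taxonomy: ClassTaxonomy = field(default_factory=default_taxonomy)
    tissue_layout: TissueLayout = field(default_factory=TissueLayout)
    lesion_params: LesionParams = field(default_factory=LesionParams)
    modality_profiles: tuple[ModalityProfile, ...] = field(
        default_factory=_default_profiles)
    shift_params: ShiftParams = field(default_factory=ShiftParams)
    psf_sigma: float = 0.5   # partial-volume blur at rendering, in voxels
    spacing: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def num_modalities(self) -> int:
        return len(self.modality_profiles)

    def validate(self) -> None:
        """Check the hetero-modal contrast premise: modality 0 separates the
        tissue classes better than it separates lesions from their host, and
        modality 1 the reverse."""
        tax = self.taxonomy
        host = self.lesion_params.host_class

        def tissue_contrast(p: ModalityProfile) -> float:
            mus = [p.means[c] for c in tax.tissue_classes]
            pairs = list(itertools.combinations(mus, 2))
            return float(np.mean([abs(a - b) for a, b in pairs]))

        def lesion_contrast(p: ModalityProfile) -> float:
            return float(np.mean([abs(p.means[c] - p.means[host])
                                  for c in tax.lesion_classes]))

        p0, p1 = self.modality_profiles[0], self.modality_profiles[1]
        if not (tissue_contrast(p0) > lesion_contrast(p0)
                and lesion_contrast(p1) > tissue_contrast(p1)):
            raise ValueError(
                "modality profiles must give modality 0 the tissue contrast "
                "and modality 1 the lesion contrast")


def _scaled_lesions(base: LesionParams, overrides: dict) -> None:
    """When the grid is overridden without explicit lesion parameters, keep
    the lesion burden proportionate: the radius scales with the grid and
    the count shrinks so a smaller hemisphere can still host every lesion."""
    if "lesion_params" in overrides:
        return
    grid = overrides.get("grid_shape")
    if grid is None:
        overrides["lesion_params"] = base
        return
    f = min(grid) / 64.0
    lo, hi = base.count_range
    counts = (max(1, round(lo * min(f, 1.0))), max(1, round(hi * min(f, 1.0))))
    overrides["lesion_params"] = replace(
        base, radius_range=(base.radius_range[0] * f,
                            base.radius_range[1] * f),
        count_range=counts)


def wmh_scenario(seed: int = 0, **overrides) -> PhantomConfig:
    """White-matter-hyperintensity-like study conditions: several small
    lesions, nearly isointense with white matter in modality 0 and bright in
    modality 1 (the generator defaults)."""
    _scaled_lesions(LesionParams(), overrides)
    return PhantomConfig(seed=seed, **overrides)


def glioma_scenario(seed: int = 0, **overrides) -> PhantomConfig:
    """Tumour-like study conditions: a single large lesion that is clearly
    visible in modality 0 (hypointense to its white-matter host, between
    the grey- and white-matter bands), emulating the case where a large
    pathology perturbs a control-trained tissue model.  The lesion occupies
    its own intensity mode: were it exactly isointense with a tissue class,
    the shared modality could not identify it and the consistency and
    tissue objectives would conflict."""
    t1 = ModalityProfile(
        means={0: 0.02, 1: 0.20, 2: 0.55, 3: 0.85, 4: 0.60, 5: 0.70})
    flair = ModalityProfile(
        means={0: 0.02, 1: 0.45, 2: 0.50, 3: 0.55, 4: 0.52, 5: 0.95})
    _scaled_lesions(LesionParams(count_range=(1, 1), radius_range=(4.5, 6.0)),
                    overrides)
    overrides.setdefault("modality_profiles", (t1, flair))
    # widen the white-matter shell (outer boundary only) so the large
    # lesion always fits; inner structures keep the default sizes
    overrides.setdefault("tissue_layout",
                         TissueLayout(radii=(0.20, 0.36, 0.86, 1.0)))
    return PhantomConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# field primitives (shared with the augmentation-based domain adaptation)
# ---------------------------------------------------------------------------

def random_bias_field(shape: tuple[int, ...], amplitude: float, order: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: the exponential of a random polynomial
    of total degree ≤ ``order``, scaled so the field lies in
    ``[1/(1+a), 1+a] ⊆ [1-a, 1+a]``.  Amplitude 0 gives a field of ones."""
    if amplitude < 0:
        raise ValueError("bias amplitude must be >= 0")
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    coords = np.meshgrid(*[np.linspace(-1.0, 1.0, n) for n in shape],
                         indexing="ij")
    poly = np.zeros(shape)
    for powers in itertools.product(range(order + 1), repeat=len(shape)):
        if not 0 < sum(powers) <= order:
            continue
        mono = np.ones(shape)
        for ax, p in enumerate(powers):
            if p:
                mono = mono * coords[ax] ** p
        poly += rng.normal() * mono
    peak = np.max(np.abs(poly))
    if peak > 0:
        poly /= peak
    return np.exp(np.log1p(amplitude) * poly).astype(np.float32)


def gaussian_smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma < 0:
        raise ValueError("smoothing kernel width must be >= 0")
    if sigma == 0:
        return arr
    return ndimage.gaussian_filter(arr, sigma=sigma).astype(arr.dtype)


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _anatomy(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Tissue-only label map from nested perturbed shells; mirror-symmetric
    anatomy about the mid-plane of the last axis (up to rendering noise)."""
    shape = config.grid_shape
    lay = config.tissue_layout
    ndim = len(shape)
    center = (np.array(shape, dtype=float) - 1) / 2
    center = center + rng.uniform(-lay.center_jitter, lay.center_jitter, ndim)
    center[-1] = (shape[-1] - 1) / 2  # keep the mid-sagittal plane central
    scales = rng.uniform(*lay.axis_scale_range, size=ndim)
    radius = lay.brain_radius_frac * min(shape)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    r2 = sum(((g - c) / (radius * s)) ** 2
             for g, c, s in zip(grids, center, scales))
    r = np.sqrt(r2)
    noise = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=lay.noise_smoothness * min(shape))
    noise = 0.5 * (noise + np.flip(noise, axis=-1))  # bilateral symmetry
    rms = np.sqrt(np.mean(noise ** 2))
    if rms > 0:
        noise *= lay.boundary_noise / rms
    r_eff = r + noise
    labels = np.zeros(shape, dtype=np.int32)
    tissue = config.taxonomy.tissue_classes
    if len(lay.radii) != len(tissue):
        raise ValueError("tissue layout must provide one radius per class")
    prev = 0.0
    for cls, outer in zip(tissue, lay.radii):
        labels[(r_eff >= prev) & (r_eff < outer)] = cls
        prev = outer
    return labels


def _place_lesions(labels: np.ndarray, config: PhantomConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Add lesion disks strictly inside the host tissue class, confined to
    one randomly chosen hemisphere and pairwise non-adjacent (so the emitted
    connected-component count equals the drawn lesion count)."""
    les = config.lesion_params
    lesion_class = config.taxonomy.lesion_classes[0]
    k = int(rng.integers(les.count_range[0], les.count_range[1] + 1))
    if k == 0:
        return labels
    shape = labels.shape
    host = labels == les.host_class
    dist_in_host = ndimage.distance_transform_edt(host)
    mid = (shape[-1] - 1) / 2
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    r_min, r_max = les.radius_range

    # choose a hemisphere that can host at least the smallest lesion
    sides = [-1.0, 1.0] if rng.random() < 0.5 else [1.0, -1.0]
    side = None
    for cand in sides:
        feas = (side_mask := cand * (grids[-1] - mid) > r_min + 1.0) \
            & (dist_in_host > r_min + les.margin)
        if feas.any():
            side = cand
            break
    if side is None:
        raise GenerationError(
            f"no hemisphere can host a lesion of radius {r_min} inside "
            f"host class {les.host_class}")

    out = labels.copy()
    lesion_mask = np.zeros(shape, dtype=bool)
    dist_to_lesion = np.full(shape, np.inf)
    placed = 0
    for attempt in range(les.max_tries):
        if placed == k:
            break
        # decay the upper radius toward the minimum as attempts fail, so a
        # crowded or thin hemisphere still admits the configured count
        r_hi = r_max - (r_max - r_min) * attempt / les.max_tries
        radius = rng.uniform(r_min, r_hi)
        # candidate centres: inside the host with margin, on the chosen
        # side, and clear of already-placed lesions
        ok = (dist_in_host > radius + les.margin) \
            & (side * (grids[-1] - mid) > radius + 1.0) \
            & (dist_to_lesion > radius + 1.5)
        idx = np.flatnonzero(ok.ravel())
        if idx.size == 0:
            continue
        c = np.unravel_index(rng.choice(idx), shape)
        ball = sum((g - ci) ** 2 for g, ci in zip(grids, c)) <= radius ** 2
        lesion_mask |= ball
        dist_to_lesion = ndimage.distance_transform_edt(~lesion_mask)
        placed += 1
    if placed < k:
        raise GenerationError(
            f"could only place {placed}/{k} lesions of radius range "
            f"{les.radius_range} inside host class {les.host_class}; "
            f"enlarge the host region or shrink the lesions")
    out[lesion_mask] = lesion_class
    return out


def _render(labels: np.ndarray, config: PhantomConfig,
            rng: np.random.Generator) -> np.ndarray:
    max_label = max(config.taxonomy.all_classes)
    chans = []
    for prof in config.modality_profiles:
        table = prof.lookup(max_label)
        img = table[labels].astype(np.float64)
        if config.psf_sigma > 0:  # partial-volume blur (scanner PSF)
            img = ndimage.gaussian_filter(img, config.psf_sigma)
        img = img + rng.normal(0.0, prof.noise_sd, labels.shape)
        chans.append(img.astype(np.float32))
    return np.stack(chans)


def generate_phantom(config: PhantomConfig, subject_seed: int,
                     with_lesions: bool = True
                     ) -> tuple[MultiModalImage, JointLabelMap]:
    """Generate one phantom subject; deterministic in (config, subject_seed).

    All modalities are rendered from the same label map plus per-modality
    noise, and lesions (if any) lie strictly inside the configured host
    tissue class, on one hemisphere only.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(subject_seed)]))
    labels = _anatomy(config, rng)
    if with_lesions:
        labels = _place_lesions(labels, config, rng)
    channels = _render(labels, config, rng)
    image = MultiModalImage(channels,
                            np.ones(config.num_modalities, dtype=bool),
                            config.spacing)
    return image, JointLabelMap(labels, config.taxonomy)


def apply_domain_shift(image: MultiModalImage | np.ndarray,
                       shift: ShiftParams, seed: int,
                       channels: list[int] | None = None):
    """Apply the acquisition-style shift to an image (bias field, Gaussian
    smoothing, gamma contrast change), deterministically in ``seed``.

    ``channels`` restricts the shift to those modality indices (default:
    every channel).  A zero-amplitude shift returns the input unchanged.
    """
    if shift.smooth_sigma < 0:
        raise ValueError("negative smoothing kernel width")
    if shift.bias_amplitude < 0:
        raise ValueError("negative bias amplitude")
    arr = image.channels if isinstance(image, MultiModalImage) else np.asarray(image)
    data = arr.copy()
    which = range(data.shape[0]) if channels is None else channels
    rng = np.random.default_rng(seed)
    for m in which:
        chan = data[m]
        if shift.bias_amplitude > 0:
            chan = chan * random_bias_field(chan.shape, shift.bias_amplitude,
                                            shift.bias_order, rng)
        if shift.smooth_sigma > 0:
            chan = gaussian_smooth(chan, shift.smooth_sigma)
        if shift.contrast_gamma != 1.0:
            chan = np.maximum(chan, 0.0) ** shift.contrast_gamma
        data[m] = chan
    if isinstance(image, MultiModalImage):
        return MultiModalImage(data, image.available.copy(), image.spacing)
    return data


def _subject_seed(master_seed: int, role_index: int, i: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), role_index, i])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_task_datasets(config: PhantomConfig,
                        counts: tuple[int, int, int, int] = (40, 40, 5, 20),
                        shifted: bool = False,
                        ) -> tuple[DatasetManifest, DatasetManifest,
                                   DatasetManifest, DatasetManifest]:
    """Build the four task-specific cohorts as in-memory manifests.

    Returns ``(control, lesion, pseudo, test)``:

    * control — modality 0 only, tissue labels, no lesions, unshifted;
    * lesion — full modality set, lesion labels only (exact joint ground
      truth is kept in a held-back sidecar, never exposed to training);
      modality 0 receives the domain shift if ``shifted``;
    * pseudo — lesion-free phantoms in the lesion cohort's acquisition style
      (shifted modality 0 if ``shifted``) with tissue labels;
    * test — fully annotated, full modality set, lesion-domain style.
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be >= 0")
    n_control, n_lesion, n_pseudo, n_test = counts
    tax = config.taxonomy
    lesion_set = set(tax.lesion_classes)
    shift = config.shift_params

    def tissue_only(labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        out[np.isin(out, list(lesion_set))] = 0
        return out

    def lesion_only(labels: np.ndarray) -> np.ndarray:
        out = labels.copy()
        out[~np.isin(out, list(lesion_set))] = 0
        return out

    control = DatasetManifest("control", taxonomy=tax)
    for i in range(n_control):
        seed = _subject_seed(config.seed, 0, i)
        img, lab = generate_phantom(config, seed, with_lesions=False)
        chans = img.channels.copy()
        chans[1:] = 0.0  # absent modalities carry no data
        mm = MultiModalImage(chans,
                             np.eye(config.num_modalities, dtype=bool)[0],
                             img.spacing)
        control.subjects.append(Subject(f"control_{i:03d}", mm,
                                        tissue_only(lab.labels), "tissue",
                                        "control"))

    lesion = DatasetManifest("lesion", taxonomy=tax)
    for i in range(n_lesion):
        seed = _subject_seed(config.seed, 1, i)
        img, lab = generate_phantom(config, seed, with_lesions=True)
        if shifted:
            img = apply_domain_shift(img, shift, seed=seed + 1, channels=[0])
        sid = f"lesion_{i:03d}"
        lesion.subjects.append(Subject(sid, img, lesion_only(lab.labels),
                                       "lesion", "lesion"))
        lesion.sidecar_joint[sid] = lab.labels

    pseudo = DatasetManifest("pseudo", taxonomy=tax)
    for i in range(n_pseudo):
        seed = _subject_seed(config.seed, 2, i)
        img, lab = generate_phantom(config, seed, with_lesions=False)
        if shifted:
            img = apply_domain_shift(img, shift, seed=seed + 1, channels=[0])
        chans = img.channels.copy()
        chans[1:] = 0.0
        mm = MultiModalImage(chans,
                             np.eye(config.num_modalities, dtype=bool)[0],
                             img.spacing)
        pseudo.subjects.append(Subject(f"pseudo_{i:03d}", mm,
                                       tissue_only(lab.labels), "tissue",
                                       "pseudo"))

    test = DatasetManifest("test", taxonomy=tax)
    for i in range(n_test):
        seed = _subject_seed(config.seed, 3, i)
        img, lab = generate_phantom(config, seed, with_lesions=True)
        if shifted:
            img = apply_domain_shift(img, shift, seed=seed + 1, channels=[0])
        test.subjects.append(Subject(f"test_{i:03d}", img, lab.labels,
                                     "joint", "lesion"))

    for m in (control, lesion, pseudo, test):
        m.validate()
    return control, lesion, pseudo, test
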