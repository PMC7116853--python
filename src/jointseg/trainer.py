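"""Training procedure for the joint segmenter.

Each iteration draws a randomly paired batch (2 lesion-domain + 2 control
subjects, plus 2 pseudo-healthy subjects in pseudo mode), applies geometric
augmentation (random rotation, additive Gaussian noise), assembles the
decomposed segmentation loss and the mode's domain-adaptation term, and
takes an Adam step.  The learning rate starts at 5e-4 and is halved every
10,000 iterations, and additionally halved after a configurable number of
epochs without improvement of an exponential moving average of the
validation loss (both schedules compose).  The consistency term is skipped
for the first ``consistency_warmup`` epochs and the DA term for the first
``da_warmup`` epochs (during which the adversarial discriminator, if any,
is trained alone).

Four training modes: ``no_da``, ``pseudo``, ``augm_da``, ``adv_da``; the
task-specific baselines (``tissue_only``, ``lesion_only``) and the
fully-supervised joint oracle (``fully_sup``) reuse the same loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .autodiff import Adam, no_grad
from .data import DatasetManifest, MultiModalImage, Subject
from .domain_adapt import (AugmentationRanges, adversarial_da_losses,
                           augmentation_da_loss, sample_augmentation)
from .nn import Discriminator, HeteroUNet
from .objective import Batch, check_tissue_upper_bound, one_hot, seg_loss, total_loss
from .taxonomy import ClassWeights, make_training_weights

__all__ = ["TrainingConfig", "TrainingDatasets", "split_dataset",
           "sample_paired_batch", "learning_rate", "train", "TrainingError"]

MODES = ("no_da", "pseudo", "augm_da", "adv_da",
         "fully_sup", "tissue_only", "lesion_only")

_DEFAULT_LAMBDA = {"augm_da": 1.0, "adv_da": 0.01}


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainingConfig:
    mode: str = "no_da"
    max_epochs: int = 12
    lambda_da: float | None = None          # per-mode default when None
    consistency_warmup: int = 50            # epochs without the consistency term
    da_warmup: int = 20                     # epochs without the DA term
    learning_rate: float = 5e-4
    betas: tuple[float, float] = (0.9, 0.999)
    lr_warm_epochs: int = 0                 # gentle start: reduced lr early
    lr_warm_factor: float = 1.0
    lr_halve_iters: int = 10_000            # fixed halving period
    plateau_patience: int = 15              # epochs without validation EMA drop
    ema_decay: float = 0.9
    batch_lesion: int = 2
    batch_control: int = 2
    batch_pseudo: int = 2
    rotation_deg: float = 10.0
    noise_sd: float = 0.01
    augmentation: AugmentationRanges = field(default_factory=AugmentationRanges)
    iters_per_epoch: int | None = None
    max_val_subjects: int = 4
    check_upper_bound: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.consistency_warmup < 0 or self.da_warmup < 0:
            raise ValueError("warmups must be >= 0")
        if self.lambda_da is None:
            self.lambda_da = _DEFAULT_LAMBDA.get(self.mode, 0.0)
        if self.lambda_da < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class TrainingDatasets:
    """Train/validation manifests per role."""

    control: DatasetManifest | None = None
    lesion: DatasetManifest | None = None
    pseudo: DatasetManifest | None = None
    val_control: DatasetManifest | None = None
    val_lesion: DatasetManifest | None = None


def learning_rate(config: TrainingConfig, iteration: int,
                  plateau_halvings: int = 0, epoch: int | None = None) -> float:
    """Learning rate at an iteration: base rate halved every
    ``lr_halve_iters`` iterations, composed with plateau halvings; during
    the first ``lr_warm_epochs`` epochs it is scaled by ``lr_warm_factor``
    (a gentle start that keeps rare classes from collapsing into the
    zero-gradient regime of a saturated Jaccard term)."""
    lr = (config.learning_rate
          * 0.5 ** (iteration // config.lr_halve_iters)
          * 0.5 ** plateau_halvings)
    if epoch is not None and epoch < config.lr_warm_epochs:
        lr *= config.lr_warm_factor
    return lr


def split_dataset(manifest: DatasetManifest, fold: int, seed: int
                  ) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Deterministic 70/10/20 train/validation/test split for a fold.

    Validation and test sizes are floored; the remainder goes to training.
    Folds rotate the seeded permutation so the three test shares are
    (nearly) disjoint across folds.
    """
    if fold not in (0, 1, 2):
        raise ValueError("fold must be 0, 1 or 2 (3-fold cross-validation)")
    n = len(manifest)
    n_val = int(np.floor(0.1 * n))
    n_test = int(np.floor(0.2 * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"{n} subjects are too few for a 70/10/20 split")
    perm = np.random.default_rng(seed).permutation(n)
    perm = np.roll(perm, fold * (n // 3))
    train = manifest.subset(perm[:n_train])
    val = manifest.subset(perm[n_train:n_train + n_val])
    test = manifest.subset(perm[n_train + n_val:])
    return train, val, test


# ---------------------------------------------------------------------------
# batch sampling and geometric augmentation
# ---------------------------------------------------------------------------

def _augment_subject(s: Subject, rot_deg: float, noise_sd: float,
                     rng: np.random.Generator) -> Subject:
    """Shared geometric augmentation: one random rotation (all channels and
    the label map) plus additive Gaussian noise on available channels."""
    angle = float(rng.uniform(-rot_deg, rot_deg)) if rot_deg > 0 else 0.0
    chans = s.image.channels
    if angle != 0.0:
        rotated = np.stack([
            ndimage.rotate(chans[m], angle, axes=(-2, -1), reshape=False,
                           order=1, mode="constant", cval=0.0)
            if s.image.available[m] else chans[m]
            for m in range(chans.shape[0])]).astype(np.float32)
        labels = ndimage.rotate(s.labels, angle, axes=(-2, -1), reshape=False,
                                order=0, mode="constant", cval=0)
    else:
        rotated, labels = chans.copy(), s.labels.copy()
    if noise_sd > 0:
        for m in range(rotated.shape[0]):
            if s.image.available[m]:
                rotated[m] += rng.normal(0.0, noise_sd,
                                         rotated[m].shape).astype(np.float32)
    img = MultiModalImage(rotated, s.image.available.copy(), s.image.spacing)
    return Subject(s.subject_id, img, labels, s.label_kind, s.domain)


def sample_paired_batch(datasets: TrainingDatasets, config: TrainingConfig,
                        rng: np.random.Generator) -> Batch:
    """Draw the mode's batch: lesion and control subjects independently at
    random (random pairing), geometric augmentation applied per subject.

    In ``augm_da`` mode the control group is a non-augmented/augmented pair
    of the *same* subject — the DA transform is applied later, by the DA
    loss, on the shared-modality channel; here the pair shares one geometric
    augmentation so the consistency target is well defined.
    """
    mode = config.mode

    def draw(manifest: DatasetManifest | None, k: int, what: str
             ) -> list[Subject]:
        if k == 0:
            return []
        if manifest is None or len(manifest) == 0:
            raise TrainingError(f"mode {mode!r} requires a non-empty "
                                f"{what} manifest")
        idx = rng.integers(0, len(manifest), size=k)
        return [_augment_subject(manifest.subjects[i], config.rotation_deg,
                                 config.noise_sd, rng) for i in idx]

    batch = Batch()
    if mode != "tissue_only":
        batch.lesion = draw(datasets.lesion, config.batch_lesion, "lesion")
    if mode not in ("lesion_only", "fully_sup"):
        if mode == "augm_da":
            base = draw(datasets.control, 1, "control")[0]
            twin = Subject(base.subject_id,
                           MultiModalImage(base.image.channels.copy(),
                                           base.image.available.copy(),
                                           base.image.spacing),
                           base.labels.copy(), base.label_kind, base.domain)
            batch.control = [base, twin]
        else:
            batch.control = draw(datasets.control, config.batch_control,
                                 "control")
    if mode == "pseudo":
        batch.pseudo = draw(datasets.pseudo, config.batch_pseudo, "pseudo")
    return batch


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def _seg_mode(mode: str) -> str:
    return mode if mode in ("no_da", "pseudo", "fully_sup", "tissue_only",
                            "lesion_only") else "no_da"


def _validation_loss(model, datasets: TrainingDatasets,
                     config: TrainingConfig, w: ClassWeights) -> float:
    """Segmentation loss (no DA term) on validation pairs."""
    cap = config.max_val_subjects
    mode = _seg_mode(config.mode)
    v_l = datasets.val_lesion.subjects[:cap] if datasets.val_lesion else []
    v_c = datasets.val_control.subjects[:cap] if datasets.val_control else []
    need_l = mode in ("no_da", "pseudo", "fully_sup", "lesion_only")
    need_c = mode in ("no_da", "pseudo", "tissue_only")
    if (need_l and not v_l) or (need_c and not v_c):
        return np.nan
    batch = Batch(
        lesion=v_l if need_l else [], control=v_c if need_c else [],
        pseudo=datasets.pseudo.subjects[:cap]
        if (mode == "pseudo" and datasets.pseudo) else [])
    with no_grad():
        rep = seg_loss(batch, model, w, mode=mode, epoch=10 ** 9,
                       consistency_warmup=config.consistency_warmup)
    return rep.total


def train(model: HeteroUNet, datasets: TrainingDatasets,
          config: TrainingConfig,
          weights: ClassWeights | None = None,
          log_path: str | Path | None = None
          ) -> tuple[HeteroUNet, list[dict]]:
    """Train the segmenter; returns the model and the iteration/epoch log.

    The log holds one record per iteration (loss components, learning rate,
    epoch, active terms) and one validation record per epoch.  Training is
    deterministic given ``config.seed`` and the datasets.
    """
    if weights is None:
        weights = make_training_weights(datasets_taxonomy(datasets))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    opt = Adam(model.parameters(), lr=config.learning_rate, betas=config.betas)

    disc = None
    disc_opt = None
    if config.mode == "adv_da":
        disc = Discriminator(model.feature_channels, ndim=model.config.ndim,
                             seed=config.seed + 1)
        disc_opt = Adam(disc.parameters(), lr=config.learning_rate,
                        betas=config.betas)

    n_l = len(datasets.lesion) if datasets.lesion else 0
    n_c = len(datasets.control) if datasets.control else 0
    group = max(config.batch_lesion, config.batch_control, 1)
    iters_per_epoch = config.iters_per_epoch or max(
        1, int(np.ceil(max(n_l, n_c) / group)))

    sm = model.config.shared_modality
    shared_mask = np.zeros(model.config.num_modalities, dtype=bool)
    shared_mask[sm] = True

    log: list[dict] = []
    iteration = 0
    plateau_halvings = 0
    ema = None
    best_ema = np.inf
    stale_epochs = 0

    for epoch in range(config.max_epochs):
        for _ in range(iters_per_epoch):
            batch = sample_paired_batch(datasets, config, rng)
            lr_now = learning_rate(config, iteration, plateau_halvings,
                                   epoch=epoch)
            opt.lr = lr_now

            da_active = (config.mode in ("augm_da", "adv_da")
                         and epoch >= config.da_warmup)

            # adversarial: discriminator step first (alternating updates)
            if config.mode == "adv_da":
                with no_grad():
                    feat_c = model.extract_da_features(
                        np.stack([s.image.channels for s in batch.control]),
                        shared_mask)
                    feat_l = model.extract_da_features(
                        np.stack([s.image.channels for s in batch.lesion]),
                        shared_mask)
                fc_const = feat_c.data.copy()
                fl_const = feat_l.data.copy()
                _, disc_term = adversarial_da_losses(disc, fc_const, fl_const)
                disc_opt.lr = lr_now
                disc_opt.zero_grad()
                disc_term.backward()
                disc_opt.step()

            rep = seg_loss(batch, model, weights, mode=_seg_mode(config.mode),
                           epoch=epoch,
                           consistency_warmup=config.consistency_warmup)

            da_term = None
            if da_active and config.mode == "augm_da":
                t = sample_augmentation(int(rng.integers(0, 2 ** 31)),
                                        config.augmentation)
                da_term = augmentation_da_loss(
                    model, np.stack([s.image.channels for s in batch.control]),
                    t, weights)
            elif da_active and config.mode == "adv_da":
                feat_c = model.extract_da_features(
                    np.stack([s.image.channels for s in batch.control]),
                    shared_mask)
                feat_l = model.extract_da_features(
                    np.stack([s.image.channels for s in batch.lesion]),
                    shared_mask)
                da_term, _ = adversarial_da_losses(disc, feat_c, feat_l)

            total = total_loss(rep, da_term, config.lambda_da if da_active
                               else 0.0)
            if not np.isfinite(total.total):
                raise TrainingError(
                    f"non-finite loss at iteration {iteration}: "
                    f"{total.components}")

            opt.zero_grad()
            total.total_tensor.backward()
            opt.step()

            # metric-property guard: the decomposition is only valid if the
            # triangle-inequality bound holds on live predictions
            if config.check_upper_bound and batch.lesion and batch.control:
                pf = rep.pred_cache.get("lesion_full")
                ps = rep.pred_cache.get("lesion_shared")
                if pf is not None:
                    if ps is None:  # consistency still warming up
                        with no_grad():
                            ps = model.forward(
                                batch.lesion[0].image.channels[None],
                                shared_mask).data
                    check_tissue_upper_bound(
                        pf[0], ps[0],
                        one_hot(batch.control[0].labels, weights.taxonomy),
                        weights)

            record = {"iteration": iteration, "epoch": epoch, "lr": lr_now,
                      "consistency_active":
                          epoch >= config.consistency_warmup,
                      "da_active": bool(da_active)}
            record.update(total.as_row())
            log.append(record)
            iteration += 1

        # epoch end: validation EMA plateau rule
        val = _validation_loss(model, datasets, config, weights)
        if np.isfinite(val):
            ema = val if ema is None else (config.ema_decay * ema
                                           + (1 - config.ema_decay) * val)
            if ema < best_ema - 1e-9:
                best_ema = ema
                stale_epochs = 0
            else:
                stale_epochs += 1
                if stale_epochs >= config.plateau_patience:
                    plateau_halvings += 1
                    stale_epochs = 0
        log.append({"iteration": iteration, "epoch": epoch,
                    "validation_loss": val, "validation_ema": ema,
                    "plateau_halvings": plateau_halvings})

    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return model, log


def datasets_taxonomy(datasets: TrainingDatasets):
    for m in (datasets.control, datasets.lesion, datasets.pseudo):
        if m is not None and m.taxonomy is not None:
            return m.taxonomy
    raise ValueError("no taxonomy found in the training datasets")
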