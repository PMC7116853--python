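# Methods

This note documents the model, the synthetic study conditions, the
numerical choices and the known limits of what the phantom experiments can
show. It states no number that the test suite or `scripts/acceptance.py`
does not itself compute.

## The segmentation distance

The core primitive is the probabilistic multi-class Jaccard distance
(`jointseg.jaccard`). Per class c, the soft term

    J_c(u, v) = 2 Σ_i |u_ci − v_ci| / Σ_i (|u_ci| + |v_ci| + |u_ci − v_ci|)

is the Steinhaus transform of the L1 distance on [0,1]^N, which makes the
weighted sum Σ_c ω_c J_c a true metric on per-voxel probability simplices:
it coincides with the binary Jaccard on one-hot maps and satisfies the
triangle inequality on soft maps. The 0/0 case (a class absent from both
maps) is defined as 0 so that identity of indiscernibles holds and absent
classes are never penalised. These properties are not assumed: the test
suite checks them on 10⁴ seeded random simplex triples, and the trainer
re-asserts the triangle-inequality bound on live predictions at every
iteration.

Why this distance matters: the decomposed objective replaces the
un-estimable tissue loss on the lesion domain with
`L^T(h(x), h(x^T1)) + L^T(h(x^T1), y^T)`. That replacement is an upper
bound **only if** L^T satisfies the triangle inequality; a cross-entropy or
soft-Dice loss would not give a valid bound.

## Class weights: metric policy vs training policy

Two weight policies exist (`jointseg.taxonomy`):

* **metric policy** (`make_class_weights`) — ω_0 = 0, each tissue class
  (1/2)/|C_T|, each lesion class (1/2)/|C_L|. This is the policy all
  metric-level identities are stated (and tested) under; the background
  term vanishes and the full distance splits exactly into tissue + lesion
  parts.
* **training policy** (`make_training_weights`) — background is folded into
  the tissue half: each of {0} ∪ C_T gets (1/2)/(|C_T|+1). The group
  balance Σ_tissue-half = Σ_lesion = 1/2 is preserved.

The training policy exists because a zero background weight leaves the
background channel entirely unsupervised, and the per-class Jaccard term
saturates (J_c → 1 with vanishing gradient) once a class's false-positive
mass is large. Together these admit a degenerate optimum in which a
foreground class colonises the background at no cost — a failure mode we
ran into on phantoms during development. Giving background a tissue-half
share closes it while keeping the two tasks equally weighted. The upper-bound inequality is
unaffected — it holds for any non-negative per-class weights.

## Architecture and optimisation

The segmenter is a U-Net-style encoder–decoder (default 3 resolution
levels, 8 base channels, 2-D; 3-D by configuration) with two input
branches: one ingesting the shared modality alone, one the concatenated
full modality set. Their first-level feature maps are arithmetically
averaged when the full set is present; with the shared modality alone the
shared branch feeds the trunk directly. Instance normalisation, leaky-ReLU
activations, He-style initialisation, softmax output. The contracting-path
bottleneck features are the adversarial discriminator's input. Fusion after
the first convolution block is a design choice; the trunk is agnostic to
it.

Everything runs on a small numpy reverse-mode autodiff core
(`jointseg.autodiff`): broadcast arithmetic, N-d same-padded convolution
lowered to per-offset matrix multiplies, average pooling, nearest
upsampling, a fused instance-norm primitive. Single precision, single
core, fully deterministic; every operation is finite-difference-checked in
the test suite and the convolution is verified against a scipy oracle.

Training (`jointseg.trainer`) follows Adam with β = (0.9, 0.999), base
learning rate 5·10⁻⁴ halved every 10,000 iterations, composed with a
plateau rule (halve after 15 epochs without improvement of an exponential
moving average, decay 0.9, of the validation segmentation loss — the EMA
constant is our choice; the plateau strategy follows common nnU-Net-style
practice). Batches pair 2 lesion-domain and 2 control subjects drawn
independently at random (plus 2 pseudo-healthy subjects in pseudo mode);
geometric augmentation is a shared random rotation in ±10° and additive
Gaussian noise. The consistency term is skipped for the first 50 epochs and
the DA term for the first 20 (defaults; during the adversarial warmup only
the discriminator trains). An epoch is one pass over the larger of the two
training manifests. Warmup epochs drop their terms without rescaling the
rest.

Gradients flow through both arguments of the consistency term (no
stop-gradient): the distance is symmetric and either prediction is an
equally valid target.

## Domain adaptation

* **Augmentation consistency** (λ default 1.0): T_ψ composes a random
  exponentiated-polynomial bias field, a ghosting-style motion echo and
  Gaussian smoothing; the DA term is the tissue distance between
  predictions on a control scan and its transformed copy. The same field
  primitives generate the phantom domain shift, so augmentation and
  simulated shift come from one physical family.
* **Adversarial** (λ default 0.01): a 3-block strided convolutional
  discriminator with global average pooling classifies bottleneck features
  by domain (lesion = 1). The discriminator minimises the usual binary
  cross-entropy; the segmenter minimises the confusion objective
  −[log D(f_control) + log(1 − D(f_lesion))], which drives held-out
  discriminator accuracy toward chance. Probabilities are clamped to
  [10⁻⁷, 1−10⁻⁷] before logs. One discriminator step then one segmenter
  step per iteration.
* **Pseudo-healthy synthesis**: the inter-hemispheric symmetry plane
  (offset along the left–right axis + in-plane rotation) is estimated by
  maximising the mirror normalised cross-correlation — coarse grid (±10% of
  width, ±10°) then Nelder–Mead refinement — and the healthy hemisphere is
  reflected over the lesioned one (linear interpolation for images, nearest
  for labels). Inputs with bilateral lesions are refused. For phantoms the
  pseudo-healthy tissue labels come from exact generator ground truth; for
  real data the function accepts externally produced labels. In pseudo
  mode the control tissue term is replaced by the average of the control
  and pseudo-healthy tissue terms.

## The phantom generator

`jointseg.phantom` emulates the data situation, not brain anatomy: nested
smoothly-perturbed shells (ventricle core, deep grey, white matter,
cortical rim) around a jittered centre with per-subject axis scaling; the
boundary perturbation field is symmetrised about the mid-sagittal plane so
anatomy is roughly bilateral. Lesion disks are placed strictly inside the
white-matter shell, confined to one hemisphere, pairwise non-adjacent (so
the connected-component count equals the drawn count); if a hemisphere is
too thin the placement retries with radii decaying toward the configured
minimum and fails loudly if even that cannot fit. Rendering assigns
per-class mean intensities, applies a 0.5-voxel Gaussian point-spread blur
(partial-volume effect), then adds white noise (σ = 0.03).

Two scenarios fix the study conditions:

* **wmh-like** (default): 2–4 lesions of radius 2.5–6 voxels on a 64×64
  grid, nearly isointense with white matter in modality 0 (0.80 vs 0.85)
  and bright in modality 1 (0.95 vs ≈0.5) — tissue knowledge must come from
  modality 0, lesion knowledge from modality 1 (checked as a config
  invariant: mean pairwise tissue contrast dominates lesion–host contrast
  in modality 0 and vice versa in modality 1).
* **glioma-like**: one large lesion (radius 4.5–6) that is hypointense to
  its white-matter host in modality 0 (0.70 vs 0.85) — a visible anomaly
  that a control-trained tissue model has never seen — and a wider
  white-matter shell so the lesion always fits. The lesion occupies its own
  intensity mode: an earlier variant placed it exactly on the deep-grey
  mean, which made lesion and deep grey unidentifiable from the shared
  modality and set the consistency and tissue objectives against each
  other.

The simulated acquisition shift multiplies the lesion-domain shared
modality by an exponentiated-polynomial bias field (amplitude 0.3, order
2; the field lies in [1−a, 1+a]), smooths with σ = 0.8 and applies a gamma
contrast change (γ = 1.5). These amplitudes were fixed, once, as a
"different scanner/protocol" magnitude: strong enough that tissue
intensities cross class boundaries, weak enough that anatomy stays
recognisable.

### What the phantoms do and do not show

The phantoms realise the *structural* premises — disjoint label sets,
hetero-modality, acquisition shift, unilateral lesions, exact joint ground
truth — but not real MR physics, real anatomy, partial-volume mixtures of
more than a PSF blur, registration error, or rater noise. Passing the
phantom study shows the training mechanics work (the bound is tight enough
to learn through, knowledge transfers across input regimes, DA recovers
shift-induced loss); it does not certify performance on clinical data.

## Benchmark sizing

The comparison study (`run_comparison_study`) trains, per seed, six to
seven models on 40 control + 40 lesion training subjects (plus 4 + 4
validation, 5 pseudo-healthy, 20 fully-annotated test) at 64×64 for 15
epochs of 20 iterations, with an 8-base-channel network, learning rate
5·10⁻³ and warmups scaled to 3 (consistency) / 2 (DA) epochs. These sizes
are chosen so a full three-seed study is a coffee-break computation on one
core; the defaults of `TrainingConfig` keep the publication-scale values
(5·10⁻⁴, 50/20-epoch warmups) for real runs. The scaled learning rate
compensates for having ~300 rather than tens of thousands of iterations.
The fully-supervised oracle uses batch 4 of joint-labelled lesion-domain
subjects so every model sees the same number of samples per iteration.

One failure mode needs active handling at this scale: the weighted Jaccard
admits a degenerate basin in which a class is never predicted — its term
saturates at J_c = 1 and, with the class's softmax logits collapsed, the
gradient vanishes, so the class cannot recover no matter how long training
continues. A small fraction of initialisations reach this basin (more
often in the tumour-like scenario), and it is detectable: after training,
the benchmark computes each class's soft Jaccard term against the
*validation* labels and treats a present class with a saturated term
(> 0.95) as collapsed, restarting that run from a fresh initialisation (at
most twice). Detection uses only training-side validation data, never the
test set.

## Numerical conventions

* Dice: both-empty class → 1; empty-vs-nonempty → 0.
* HD95: surfaces are voxels with a face-neighbour outside the mask;
  distances centre-to-centre scaled by voxel spacing; 95th percentile with
  linear interpolation; max over the two directions; an empty mask yields
  NaN and is excluded from aggregate means.
* Pipeline merge: lesion output has priority; tissue fills its background.
* Empty-vs-empty Jaccard terms are 0 (see above); algebraic identities are
  asserted to 1e-12 on binary inputs and metric axioms to 1e-9 on float
  maps (accumulation over voxels).
* Per-subject phantom seeds derive from the master seed by SeedSequence
  hashing; two cohorts built from the same master seed share anatomy,
  which is what lets the shifted and unshifted experiments differ only in
  the shift.

## Known limitations

* The 2-D desk-scale default is the tested path; 3-D runs are supported by
  configuration but only smoke-tested.
* The adversarial mode is validated mechanically (terms, gating, gradient
  flow, discriminator learning) but not included in the headline study —
  on these phantoms the pseudo-healthy route dominates, consistent with
  the supervised-beats-unsupervised ordering the method family reports.
* The symmetry-plane search assumes a roughly bilateral foreground and a
  mirror plane within ±10% offset / ±10°; pathological asymmetry outside
  that range requires an external estimate.
* Training runtime is numpy-bound; the autodiff core is adequate for
  phantom-scale experiments, not for full-resolution 3-D clinical volumes.
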