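"""Neural-network layers and models built on the autodiff core.

Contains the hetero-modal U-Net used as the joint segmenter: an
encoder-decoder with two input branches — one ingesting the shared modality
(T1) alone, one ingesting the concatenated full modality set — whose feature
maps are arithmetically averaged when the full set is present.  A single
parameter set therefore serves both input regimes, which is what lets the
network train from datasets with different modality subsets.

Also provides the small convolutional domain discriminator used by the
adversarial domain-adaptation strategy.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["Module", "ConvLayer", "InstanceNorm", "ConvBlock",
           "HeteroUNet", "Discriminator", "ArchConfig",
           "save_checkpoint", "load_checkpoint"]


class Module:
    """Minimal module base: parameter collection and state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when loading state")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch when loading state")
            p.data = np.asarray(a, dtype=p.data.dtype)


class ConvLayer(Module):
    """Same-padded stride-1 convolution with He-initialised weights."""

    def __init__(self, cin: int, cout: int, kernel: int, ndim: int,
                 rng: np.random.Generator):
        fan_in = cin * kernel ** ndim
        std = np.sqrt(2.0 / fan_in)
        shape = (cout, cin) + (kernel,) * ndim
        self.weight = Tensor(rng.normal(0.0, std, shape).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv(self.weight, self.bias)


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over spatial axes.

    Scale initialised to 1, shift to 0.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.instance_norm(self.gamma, self.beta, self.eps)


class ConvBlock(Module):
    """conv → instance norm → leaky ReLU."""

    def __init__(self, cin: int, cout: int, ndim: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.conv = ConvLayer(cin, cout, kernel, ndim, rng)
        self.norm = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu()


class ArchConfig:
    """Architecture description for the hetero-modal U-Net."""

    def __init__(self, num_modalities: int, num_classes: int, levels: int = 3,
                 base_channels: int = 8, ndim: int = 2, shared_modality: int = 0):
        if levels < 2:
            raise ValueError("at least 2 resolution levels required")
        if num_modalities < 1 or num_classes < 2:
            raise ValueError("invalid modality or class count")
        self.num_modalities = num_modalities
        self.num_classes = num_classes
        self.levels = levels
        self.base_channels = base_channels
        self.ndim = ndim
        self.shared_modality = shared_modality

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        return cls(**d)


class HeteroUNet(Module):
    """Hetero-modal U-Net segmenter.

    Two input branches (shared-modality and full-modality) are fused by
    arithmetic averaging of their feature maps after the first convolution
    block; the shared encoder-decoder trunk then produces per-voxel class
    probabilities via a softmax head.  Legal input regimes: the shared
    modality alone, or the full modality set.
    """

    def __init__(self, config: ArchConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = config.base_channels
        nd = config.ndim
        self.config = config
        self.branch_shared = ConvBlock(1, c, nd, rng)
        self.branch_full = ConvBlock(config.num_modalities, c, nd, rng)
        self.encoders = [ConvBlock(c * 2 ** (l - 1) if l else c,
                                   c * 2 ** l, nd, rng)
                         for l in range(config.levels)]
        self.decoders = [ConvBlock(c * 2 ** (l + 1) + c * 2 ** l,
                                   c * 2 ** l, nd, rng)
                         for l in reversed(range(config.levels - 1))]
        self.head = ConvLayer(c, config.num_classes, 1, nd, rng)

    # -- input handling ----------------------------------------------------

    def _regimes(self, available_mask) -> str:
        mask = np.asarray(available_mask, dtype=bool)
        if mask.shape != (self.config.num_modalities,):
            raise ValueError("available mask must cover all modalities")
        shared_only = np.zeros_like(mask)
        shared_only[self.config.shared_modality] = True
        if np.array_equal(mask, shared_only):
            return "shared"
        if mask.all():
            return "full"
        raise ValueError(
            f"unsupported modality subset {mask.tolist()}: expected the shared "
            f"modality alone or the full set")

    def _trunk(self, f: Tensor, return_features: bool):
        skips = []
        for enc in self.encoders[:-1]:
            f = enc(f)
            skips.append(f)
            f = f.avg_pool(2)
        bottleneck = self.encoders[-1](f)
        f = bottleneck
        for dec, skip in zip(self.decoders, reversed(skips)):
            f = concat([f.upsample_nearest(2), skip], axis=1)
            f = dec(f)
        probs = self.head(f).softmax(axis=1)
        return (probs, bottleneck) if return_features else probs

    def forward(self, image: Tensor | np.ndarray, available_mask,
                return_features: bool = False):
        """Run the segmenter on a batch (B, M, *spatial).

        Channels of absent modalities are ignored entirely; only the shared
        modality channel or all channels feed the network, per the mask.
        """
        x = image if isinstance(image, Tensor) else Tensor(image)
        regime = self._regimes(available_mask)
        sm = self.config.shared_modality
        f_shared = self.branch_shared(x[:, sm : sm + 1])
        if regime == "full":
            f_full = self.branch_full(x)
            fused = (f_shared + f_full) * 0.5
        else:
            fused = f_shared
        return self._trunk(fused, return_features)

    __call__ = forward

    def extract_da_features(self, image, available_mask) -> Tensor:
        """Deepest encoder (contracting-path bottleneck) feature maps, the
        input of the adversarial domain discriminator."""
        _, feats = self.forward(image, available_mask, return_features=True)
        return feats

    @property
    def feature_channels(self) -> int:
        return self.config.base_channels * 2 ** (self.config.levels - 1)


def save_checkpoint(model: "HeteroUNet", path) -> None:
    """Serialise parameters with the architecture config embedded."""
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, __config__=json.dumps(model.config.to_dict()), **arrays)


def load_checkpoint(path) -> "HeteroUNet":
    import json

    with np.load(path, allow_pickle=False) as z:
        cfg = ArchConfig.from_dict(json.loads(str(z["__config__"])))
        model = HeteroUNet(cfg, seed=0)
        arrays = [z[f"param_{i}"] for i in range(len(model.parameters()))]
    model.load_state_arrays(arrays)
    return model


class Discriminator(Module):
    """Small convolutional domain classifier on bottleneck feature grids.

    Strided-equivalent conv+pool blocks, global average pooling and a
    sigmoid output in (0, 1): the probability that features come from the
    lesion domain.
    """

    def __init__(self, in_channels: int, ndim: int = 2, hidden: int = 16,
                 blocks: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = [in_channels] + [hidden] * blocks
        self.blocks = [ConvLayer(ci, co, 3, ndim, rng)
                       for ci, co in zip(chans[:-1], chans[1:])]
        self.w_out = Tensor(rng.normal(0, np.sqrt(1.0 / hidden),
                                       (hidden, 1)).astype(np.float32),
                            requires_grad=True)
        self.b_out = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    def __call__(self, feats: Tensor) -> Tensor:
        f = feats if isinstance(feats, Tensor) else Tensor(feats)
        for i, blk in enumerate(self.blocks):
            f = blk(f).leaky_relu()
            if min(f.shape[2:]) >= 2:
                f = f.avg_pool(2)
        pooled = f.mean(axis=tuple(range(2, f.ndim)))  # (B, hidden)
        logit = pooled @ self.w_out + self.b_out
        return logit.sigmoid().reshape(-1)
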