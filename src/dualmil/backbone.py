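"""Reduced convolutional patch encoder.

The feature extractor is a truncated MobileNetV4-style network: a strided
stem convolution, a chain of universal inverted bottleneck (UIB) blocks,
and a high-channel 1x1 head convolution whose globally-average-pooled
output is the patch feature vector.  Two structural reductions make it
light enough for end-to-end multiple-instance training:

* **UIB removal** — stride-1 blocks with equal input/output channels are
  shape-neutral ("removable"); the reference configuration drops all ten
  of them.
* **APoZ channel pruning** — the Average Percentage of Zeros of each head
  channel (fraction of post-ReLU activations equal to zero over a
  calibration batch) ranks channel utility; the head keeps the channels
  with the lowest APoZ.

The pinned reference configuration counts 340,992 learnable scalars before
reduction and 68,880 after (an ~80% reduction); parameter counts are
computable in closed form from the spec alone and agree exactly with the
built network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .tiling import PatchBag

# Pinned reference configuration (channels chosen so the closed-form
# parameter counts hit the reference budgets exactly).
_REF_STEM = (16, 3, 2)
_REF_STAGES = (
    # (out_channels, expansion, n_removable_after)
    (24, 2.0, 4),
    (64, 2.0, 3),
    (96, 4.0, 3),
)
_REF_HEAD_FULL = 1052
_REF_HEAD_PRUNED = 164
REMOVABLE_UIB_COUNT = 10

PARAMS_ORIGINAL = 340_992
PARAMS_REDUCED = 68_880


@dataclass(frozen=True)
class UIBSpec:
    """One universal inverted bottleneck block.

    Optional depthwise convolutions sit before the expansion (``pre_dw``,
    carrying the block stride) and inside the expanded space (``mid_dw``).
    A block is removable iff it is stride 1 with equal in/out channels.
    """

    in_channels: int
    out_channels: int
    expansion: float
    stride: int = 1
    pre_dw: bool = True
    mid_dw: bool = True
    kernel: int = 3

    @property
    def removable(self) -> bool:
        return self.stride == 1 and self.in_channels == self.out_channels

    @property
    def expanded(self) -> int:
        return int(round(self.expansion * self.in_channels))

    def param_count(self) -> int:
        k2 = self.kernel * self.kernel
        e = self.expanded
        n = 0
        if self.pre_dw:
            n += k2 * self.in_channels + 2 * self.in_channels
        n += self.in_channels * e + 2 * e          # 1x1 expand + BN
        if self.mid_dw:
            n += k2 * e + 2 * e
        n += e * self.out_channels + 2 * self.out_channels   # 1x1 project + BN
        return n


@dataclass(frozen=True)
class BackboneSpec:
    """Declarative description of the patch encoder."""

    stem: tuple[int, int, int]             # (out_channels, kernel, stride)
    blocks: tuple[UIBSpec, ...]
    head_channels: int

    def __post_init__(self):
        prev = self.stem[0]
        for i, b in enumerate(self.blocks):
            if b.in_channels != prev:
                raise ValueError(f"block {i}: in_channels {b.in_channels} != "
                                 f"previous out {prev}")
            prev = b.out_channels

    @property
    def feature_dim(self) -> int:
        return self.head_channels

    @property
    def last_block_channels(self) -> int:
        return self.blocks[-1].out_channels if self.blocks else self.stem[0]


def count_params(spec: BackboneSpec) -> int:
    """Exact learnable-scalar count: conv kernels + normalization affines."""
    c, k, _ = spec.stem
    total = k * k * 3 * c + 2 * c
    total += sum(b.param_count() for b in spec.blocks)
    total += spec.last_block_channels * spec.head_channels + 2 * spec.head_channels
    return total


def reference_original_spec() -> BackboneSpec:
    """The pinned pre-reduction configuration (340,992 parameters)."""
    blocks: list[UIBSpec] = []
    prev = _REF_STEM[0]
    for out, exp, n_rem in _REF_STAGES:
        blocks.append(UIBSpec(prev, out, exp, stride=2, pre_dw=True, mid_dw=True))
        for _ in range(n_rem):
            blocks.append(UIBSpec(out, out, 2.0, stride=1, pre_dw=False, mid_dw=True))
        prev = out
    return BackboneSpec(_REF_STEM, tuple(blocks), _REF_HEAD_FULL)


def reference_reduced_spec() -> BackboneSpec:
    """Reference spec after UIB removal and APoZ head pruning (68,880)."""
    spec = remove_uibs(reference_original_spec(), REMOVABLE_UIB_COUNT)
    return replace(spec, head_channels=_REF_HEAD_PRUNED)


def tiny_backbone_spec(feature_dim: int = 32) -> BackboneSpec:
    """A desk-scale spec (same topology family) for small synthetic studies."""
    blocks = (
        UIBSpec(8, 16, 2.0, stride=2, pre_dw=True, mid_dw=True),
        UIBSpec(16, 32, 2.0, stride=2, pre_dw=True, mid_dw=True),
    )
    return BackboneSpec((8, 3, 2), blocks, feature_dim)


def remove_uibs(spec: BackboneSpec, k: int = REMOVABLE_UIB_COUNT) -> BackboneSpec:
    """Delete the first ``k`` removable (shape-neutral) blocks."""
    removable_idx = [i for i, b in enumerate(spec.blocks) if b.removable]
    if len(removable_idx) < k:
        raise ValueError(f"only {len(removable_idx)} removable blocks, need {k}")
    drop = set(removable_idx[:k])
    kept = tuple(b for i, b in enumerate(spec.blocks) if i not in drop)
    return replace(spec, blocks=kept)


# ---------------------------------------------------------------------------
# APoZ
# ---------------------------------------------------------------------------

@dataclass
class APoZReport:
    layer_id: str
    per_channel_apoz: np.ndarray
    calibration_count: int

    def __post_init__(self):
        a = np.asarray(self.per_channel_apoz, dtype=np.float64)
        if a.size and (a.min() < 0 or a.max() > 1):
            raise ValueError("APoZ values must lie in [0, 1]")
        if self.calibration_count <= 0:
            raise ValueError("calibration_count must be positive")
        self.per_channel_apoz = a


def apoz(activations: np.ndarray, layer_id: str = "head") -> APoZReport:
    """Per-channel fraction of zero post-activation entries.

    ``activations`` is (samples, channels, ...); entries <= 0 count as zero
    (post-ReLU values are non-negative, so this is exact zero counting).
    """
    act = np.asarray(activations)
    if act.size == 0:
        raise ValueError("empty calibration set")
    flat = np.moveaxis(act, 1, 0).reshape(act.shape[1], -1)
    frac = (flat <= 0).mean(axis=1)
    return APoZReport(layer_id, frac, flat.shape[1])


def prune_channels(spec: BackboneSpec, report: APoZReport, keep: int) -> BackboneSpec:
    """Keep the head channels with lowest APoZ (budget mode).

    Ties break by channel index ascending; the resulting parameter count is
    strictly smaller whenever ``keep`` < current head width.
    """
    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > spec.head_channels:
        raise ValueError(f"keep {keep} exceeds head width {spec.head_channels}")
    if report.per_channel_apoz.size != spec.head_channels:
        raise ValueError("APoZ report does not match the head layer")
    return replace(spec, head_channels=keep)


def kept_channel_indices(report: APoZReport, keep: int) -> np.ndarray:
    """Indices of the ``keep`` lowest-APoZ channels, ascending index order."""
    order = np.argsort(report.per_channel_apoz, kind="stable")[:keep]
    return np.sort(order)


# ---------------------------------------------------------------------------
# Built network
# ---------------------------------------------------------------------------

class _UIBBlock(nn.Module):
    def __init__(self, spec: UIBSpec, rng: np.random.Generator):
        k, pad = spec.kernel, spec.kernel // 2
        e = spec.expanded
        self.spec = spec
        if spec.pre_dw:
            self.pre = nn.Conv2d(spec.in_channels, spec.in_channels, k, rng,
                                 stride=spec.stride, padding=pad, depthwise=True)
            self.pre_bn = nn.BatchNorm2d(spec.in_channels)
        else:
            self.pre = None
        self.expand = nn.Conv2d(spec.in_channels, e, 1, rng)
        self.expand_bn = nn.BatchNorm2d(e)
        if spec.mid_dw:
            mid_stride = spec.stride if not spec.pre_dw else 1
            self.mid = nn.Conv2d(e, e, k, rng, stride=mid_stride, padding=pad,
                                 depthwise=True)
            self.mid_bn = nn.BatchNorm2d(e)
        else:
            self.mid = None
        self.project = nn.Conv2d(e, spec.out_channels, 1, rng)
        self.project_bn = nn.BatchNorm2d(spec.out_channels)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        identity = x if self.spec.removable else None
        if self.pre is not None:
            x = self.pre_bn(self.pre(x))
        x = nn.relu(self.expand_bn(self.expand(x)))
        if self.mid is not None:
            x = nn.relu(self.mid_bn(self.mid(x)))
        x = self.project_bn(self.project(x))
        if identity is not None:
            x = x + identity
        return x


class Backbone(nn.Module):
    """Patch encoder built from a :class:`BackboneSpec`."""

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        c, k, s = spec.stem
        self.spec = spec
        self.stem = nn.Conv2d(3, c, k, rng, stride=s, padding=k // 2)
        self.stem_bn = nn.BatchNorm2d(c)
        self.blocks = [_UIBBlock(b, rng) for b in spec.blocks]
        self.head = nn.Conv2d(spec.last_block_channels, spec.head_channels, 1, rng)
        self.head_bn = nn.BatchNorm2d(spec.head_channels)

    def feature_map(self, x: nn.Tensor) -> nn.Tensor:
        """Post-ReLU head feature map (N, head_channels, h, w)."""
        x = nn.relu(self.stem_bn(self.stem(x)))
        for blk in self.blocks:
            x = blk(x)
        return nn.relu(self.head_bn(self.head(x)))

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.global_avg_pool(self.feature_map(x))


def patches_to_input(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 NCHW in [-1, 1]."""
    x = np.asarray(images, dtype=np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def extract_features(model: Backbone, bag: PatchBag) -> nn.Tensor:
    """One feature row per patch, gradients flowing through the backbone."""
    images = bag.stack()
    if images.shape[3] != 3:
        raise ValueError("patches must be H x W x 3")
    return model(nn.Tensor(patches_to_input(images)))


def calibration_apoz(model: Backbone, images: np.ndarray) -> APoZReport:
    """APoZ of the head activations on a calibration batch of patches."""
    fmap = model.feature_map(nn.Tensor(patches_to_input(images)))
    return apoz(fmap.data, layer_id="head")


def calibration_batch(n: int = 256, patch_size: int = 64,
                      seed: int = 0) -> np.ndarray:
    """Seeded synthetic patch batch for APoZ calibration.

    Tissue-like patches: dark base intensity with Gaussian noise and a few
    darker spots, matching the statistics the encoder sees in training.
    """
    rng = np.random.default_rng(seed)
    gray = rng.normal(120.0, 12.0, size=(n, patch_size, patch_size))
    for i in range(n):
        for _ in range(rng.integers(0, 8)):
            y, x = rng.integers(0, patch_size, 2)
            r = int(rng.integers(2, max(3, patch_size // 16)))
            gray[i, max(0, y - r):y + r, max(0, x - r):x + r] = 40.0
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    return np.stack([gray, (gray * 0.88).astype(np.uint8), gray], axis=-1)


def prune_backbone(model: Backbone, kept: np.ndarray) -> Backbone:
    """Slice the head convolution/norm down to the kept channel indices."""
    kept = np.asarray(kept, dtype=int)
    new_spec = replace(model.spec, head_channels=int(kept.size))
    pruned = Backbone(new_spec, seed=0)
    pruned.stem.weight.data = model.stem.weight.data.copy()
    pruned.stem_bn.weight.data = model.stem_bn.weight.data.copy()
    pruned.stem_bn.bias.data = model.stem_bn.bias.data.copy()
    for dst, src in zip(pruned.blocks, model.blocks):
        for name in ("pre", "expand", "mid", "project"):
            s_conv = getattr(src, name)
            if s_conv is not None:
                getattr(dst, name).weight.data = s_conv.weight.data.copy()
                bn_s, bn_d = getattr(src, name + "_bn"), getattr(dst, name + "_bn")
                bn_d.weight.data = bn_s.weight.data.copy()
                bn_d.bias.data = bn_s.bias.data.copy()
    pruned.head.weight.data = model.head.weight.data[kept].copy()
    pruned.head_bn.weight.data = model.head_bn.weight.data[kept].copy()
    pruned.head_bn.bias.data = model.head_bn.bias.data[kept].copy()
    return pruned


# ---------------------------------------------------------------------------
# Serialization / reporting
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: BackboneSpec, path: str | Path) -> None:
    doc = {
        "stem": list(spec.stem),
        "head_channels": spec.head_channels,
        "blocks": [{"in_channels": b.in_channels, "out_channels": b.out_channels,
                    "expansion": b.expansion, "stride": b.stride,
                    "pre_dw": b.pre_dw, "mid_dw": b.mid_dw, "kernel": b.kernel}
                   for b in spec.blocks],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> BackboneSpec:
    doc = yaml.safe_load(Path(path).read_text())
    blocks = tuple(UIBSpec(**b) for b in doc["blocks"])
    return BackboneSpec(tuple(doc["stem"]), blocks, doc["head_channels"])


def parameter_report(spec: BackboneSpec) -> str:
    """Human-readable per-stage parameter breakdown."""
    c, k, _ = spec.stem
    lines = [f"stem ({k}x{k}, 3->{c}): {k*k*3*c + 2*c}"]
    for i, b in enumerate(spec.blocks):
        tag = "removable" if b.removable else f"stride {b.stride}"
        lines.append(f"block {i} ({b.in_channels}->{b.out_channels}, "
                     f"e={b.expansion:g}, {tag}): {b.param_count()}")
    head = spec.last_block_channels * spec.head_channels + 2 * spec.head_channels
    lines.append(f"head (1x1, {spec.last_block_channels}->{spec.head_channels}): {head}")
    lines.append(f"total: {count_params(spec)}")
    return "\n".join(lines)
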