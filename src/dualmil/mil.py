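"""Dual-attention multimodal MIL network.

Two transformer branches aggregate the per-patient bags: the image branch
(TransMIL-style: class token, Nystrom self-attention, a Pyramid Position
Encoding Generator between the two attention layers) and the gene branch
(same minus PPEG and square padding, so it is permutation-invariant over
gene sets).  Bidirectional cross-attention then queries each modality's
instance tokens with the other modality's aggregated vector.  The four
aggregated vectors — self-image, self-gene, cross-image, cross-gene — are
concatenated and classified by a linear head into two logits.

Attention weights reported to the interpretability stage are the exact
head-averaged class-token (or cross-query) softmax rows over real
instances, with padded positions excluded and the row renormalized;
Nystrom approximation is used for the full-sequence attention outputs,
not for the exported weight vectors (whose approximated rows could dip
below zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn

MECHANISMS = ("self_image", "self_gene", "cross_img_query_gene",
              "cross_gene_query_img")


@dataclass
class AttentionRecord:
    mechanism: str
    weights: np.ndarray          # over real instances; >= 0, sums to 1
    head_count: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.min() < -1e-9 or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("attention weights must be a distribution")
        self.weights = w


@dataclass
class TokenSequence:
    tokens: np.ndarray           # (1+N) x D, class token first
    modality: str                # "image" or "gene"
    grid_side: int | None = None


@dataclass
class FusionOutput:
    vec_self_image: np.ndarray
    vec_self_gene: np.ndarray
    vec_cross_image: np.ndarray
    vec_cross_gene: np.ndarray
    logits: np.ndarray
    attention: list[AttentionRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Nystrom attention
# ---------------------------------------------------------------------------

def _segment_mean_matrix(n: int, m: int) -> np.ndarray:
    """(m, n) row-stochastic matrix averaging n positions into m segments."""
    bounds = np.linspace(0, n, m + 1).round().astype(int)
    g = np.zeros((m, n), dtype=np.float32)
    for i in range(m):
        lo, hi = bounds[i], max(bounds[i + 1], bounds[i] + 1)
        hi = min(hi, n)
        lo = min(lo, hi - 1)
        g[i, lo:hi] = 1.0 / (hi - lo)
    return g


def _iterative_pinv(a: nn.Tensor, iters: int = 6) -> nn.Tensor:
    """Newton-Schulz pseudo-inverse of a (..., m, m) kernel matrix."""
    m = a.shape[-1]
    eye = nn.Tensor(np.broadcast_to(np.eye(m, dtype=np.float32), a.shape).copy())
    # scale constant from data (treated as fixed for differentiation)
    abs_a = np.abs(a.data)
    scale = float((abs_a.sum(axis=-1).max() * abs_a.sum(axis=-2).max()))
    z = nn.transpose(a, tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)) * (1.0 / max(scale, 1e-8))
    for _ in range(iters):
        az = a @ z
        z = 0.25 * (z @ (13.0 * eye - az @ (15.0 * eye - az @ (7.0 * eye - az))))
    return z


def nystrom_attention(q: nn.Tensor, k: nn.Tensor, v: nn.Tensor,
                      landmarks: int) -> nn.Tensor:
    """Landmark-approximated softmax attention on (..., n, d) inputs.

    Uses segment-mean landmarks and a fixed-iteration Newton-Schulz
    pseudo-inverse.  With ``landmarks >= n`` the exact dense attention is
    computed instead (the approximation is only useful below that).
    """
    if landmarks < 1:
        raise ValueError("landmarks must be >= 1")
    n, d = q.shape[-2], q.shape[-1]
    inv_sqrt_d = 1.0 / math.sqrt(d)
    kt = nn.transpose(k, tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2))
    if landmarks >= n:
        attn = nn.softmax((q @ kt) * inv_sqrt_d, axis=-1)
        return attn @ v
    g = nn.Tensor(_segment_mean_matrix(n, landmarks))
    q_l = g @ q                      # (..., m, d)
    k_l = g @ k
    klt = nn.transpose(k_l, tuple(range(k_l.ndim - 2)) + (k_l.ndim - 1, k_l.ndim - 2))
    f = nn.softmax((q @ klt) * inv_sqrt_d, axis=-1)       # n x m
    a = nn.softmax((q_l @ klt) * inv_sqrt_d, axis=-1)     # m x m
    b = nn.softmax((q_l @ kt) * inv_sqrt_d, axis=-1)      # m x n
    return f @ (_iterative_pinv(a) @ (b @ v))


def dense_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Plain softmax attention on numpy arrays (reference path)."""
    d = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / math.sqrt(d)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ v


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, heads: int, landmarks: int,
                 rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.landmarks = dim, heads, landmarks
        self.wq = nn.Linear(dim, dim, rng, bias=False)
        self.wk = nn.Linear(dim, dim, rng, bias=False)
        self.wv = nn.Linear(dim, dim, rng, bias=False)
        self.wo = nn.Linear(dim, dim, rng, bias=False)

    def _split(self, x: nn.Tensor) -> nn.Tensor:
        n = x.shape[0]
        dh = self.dim // self.heads
        return nn.transpose(nn.reshape(x, (n, self.heads, dh)), (1, 0, 2))

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, np.ndarray]:
        """Returns (output n x D, exact class-token attention row n-vector)."""
        n = x.shape[0]
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        out = nystrom_attention(q, k, v, self.landmarks)     # (h, n, dh)
        out = nn.reshape(nn.transpose(out, (1, 0, 2)), (n, self.dim))
        cls_row = dense_attention_row(q.data, k.data)
        return self.wo(out), cls_row


def dense_attention_row(q: np.ndarray, k: np.ndarray, row: int = 0) -> np.ndarray:
    """Exact head-averaged softmax attention row for one query position."""
    dh = q.shape[-1]
    scores = np.einsum("hd,hnd->hn", q[:, row], k) / math.sqrt(dh)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w.mean(axis=0)


class TransLayer(nn.Module):
    """Pre-norm residual attention block: x + MHSA(LN(x))."""

    def __init__(self, dim: int, heads: int, landmarks: int,
                 rng: np.random.Generator):
        self.norm = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, landmarks, rng)

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, np.ndarray]:
        out, cls_row = self.attn(self.norm(x))
        return x + out, cls_row


class PPEG(nn.Module):
    """Pyramid Position Encoding Generator.

    Instance tokens are laid out on their grid and receive the sum of
    depthwise 3x3, 5x5 and 7x7 convolutions, added residually; the class
    token passes through untouched.  The convolutions start at zero
    (identity mapping), so positional mixing is introduced only as
    training moves them away from zero.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.convs = [nn.Conv2d(dim, dim, k, rng, padding=k // 2, depthwise=True)
                      for k in (3, 5, 7)]
        for c in self.convs:
            c.weight.data[:] = 0.0

    def __call__(self, seq: nn.Tensor, grid_side: int) -> nn.Tensor:
        n_inst = grid_side * grid_side
        if seq.shape[0] != 1 + n_inst:
            raise ValueError("instance count must equal grid_side**2 (+1 class token)")
        cls_tok = seq[0:1]
        inst = seq[1:]
        dim = seq.shape[1]
        grid = nn.transpose(nn.reshape(inst, (grid_side, grid_side, dim)), (2, 0, 1))
        grid = nn.reshape(grid, (1, dim, grid_side, grid_side))
        out = grid
        for conv in self.convs:
            out = out + conv(grid)
        out = nn.reshape(out, (dim, n_inst))
        inst_out = nn.transpose(out, (1, 0))
        return nn.concat([cls_tok, inst_out], axis=0)


class CrossAttention(nn.Module):
    """Single-query multi-head attention over the other modality's tokens."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads = dim, heads
        self.wq = nn.Linear(dim, dim, rng, bias=False)
        self.wk = nn.Linear(dim, dim, rng, bias=False)
        self.wv = nn.Linear(dim, dim, rng, bias=False)
        self.wo = nn.Linear(dim, dim, rng, bias=False)

    def __call__(self, query_vec: nn.Tensor,
                 tokens: nn.Tensor) -> tuple[nn.Tensor, np.ndarray]:
        if tokens.shape[0] < 1:
            raise ValueError("cross-attention needs at least one key token")
        n = tokens.shape[0]
        dh = self.dim // self.heads
        q = nn.reshape(self.wq(nn.reshape(query_vec, (1, self.dim))),
                       (self.heads, 1, dh))
        k = nn.transpose(nn.reshape(self.wk(tokens), (n, self.heads, dh)), (1, 0, 2))
        v = nn.transpose(nn.reshape(self.wv(tokens), (n, self.heads, dh)), (1, 0, 2))
        kt = nn.transpose(k, (0, 2, 1))
        scores = (q @ kt) * (1.0 / math.sqrt(dh))
        w = nn.softmax(scores, axis=-1)                    # (h, 1, n)
        out = nn.reshape(nn.transpose(w @ v, (1, 0, 2)), (1, self.dim))
        weights = w.data[:, 0].mean(axis=0)
        return nn.reshape(self.wo(out), (self.dim,)), weights


def square_pad(features: nn.Tensor) -> tuple[nn.Tensor, int, int]:
    """Pad N instance rows to the next square count by repeating leading rows.

    Returns (padded M x D, grid_side, n_real) with M = ceil(sqrt(N))**2.
    """
    n = features.shape[0]
    if n < 1:
        raise ValueError("need at least one instance")
    side = math.isqrt(n)
    if side * side < n:
        side += 1
    pad = side * side - n
    if pad:
        features = nn.concat([features, features[0:pad]], axis=0)
    return features, side, n


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MILConfig:
    dim: int = 32
    heads: int = 2
    landmarks: int = 8
    gene_landmark_threshold: int = 64   # exact attention below this length
    self_only: bool = False             # ablation: drop both cross paths
    modality: str = "fused"             # "fused", "image" or "gene"
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("fused", "image", "gene"):
            raise ValueError("modality must be fused, image or gene")


class DualAttentionMIL(nn.Module):
    def __init__(self, config: MILConfig):
        rng = np.random.default_rng(config.seed)
        d, h, m = config.dim, config.heads, config.landmarks
        self.config = config
        self.cls_image = nn.Tensor(
            (rng.standard_normal(d) * 0.02).astype(np.float32), requires_grad=True)
        self.cls_gene = nn.Tensor(
            (rng.standard_normal(d) * 0.02).astype(np.float32), requires_grad=True)
        self.img_layer1 = TransLayer(d, h, m, rng)
        self.ppeg = PPEG(d, rng)
        self.img_layer2 = TransLayer(d, h, m, rng)
        self.img_norm = nn.LayerNorm(d)
        self.gene_layer1 = TransLayer(d, h, config.gene_landmark_threshold, rng)
        self.gene_layer2 = TransLayer(d, h, config.gene_landmark_threshold, rng)
        self.gene_norm = nn.LayerNorm(d)
        if config.modality == "fused" and not config.self_only:
            self.cross_image = CrossAttention(d, h, rng)   # query: gene vector
            self.cross_gene = CrossAttention(d, h, rng)    # query: image vector
        if config.modality != "fused":
            fan_in = d
        else:
            fan_in = (2 if config.self_only else 4) * d
        self.classifier = nn.Linear(fan_in, 2, rng)

    # -- branch encoders ----------------------------------------------------
    def encode_image_bag(self, features: nn.Tensor):
        """class token -> attention -> PPEG -> attention -> norm."""
        padded, side, n_real = square_pad(features)
        seq = nn.concat([nn.reshape(self.cls_image, (1, -1)), padded], axis=0)
        seq, _ = self.img_layer1(seq)
        seq = self.ppeg(seq, side)
        seq, cls_row = self.img_layer2(seq)
        seq = self.img_norm(seq)
        bag_vec = nn.reshape(seq[0:1], (self.config.dim,))
        attn = _cls_record("self_image", cls_row, n_real, self.config.heads)
        token_seq = TokenSequence(seq.data.copy(), "image", grid_side=side)
        return bag_vec, seq, token_seq, attn, n_real

    def encode_gene_bag(self, latents: nn.Tensor):
        """Same pipeline without PPEG or padding; order-invariant."""
        n = latents.shape[0]
        seq = nn.concat([nn.reshape(self.cls_gene, (1, -1)), latents], axis=0)
        seq, _ = self.gene_layer1(seq)
        seq, cls_row = self.gene_layer2(seq)
        seq = self.gene_norm(seq)
        bag_vec = nn.reshape(seq[0:1], (self.config.dim,))
        attn = _cls_record("self_gene", cls_row, n, self.config.heads)
        token_seq = TokenSequence(seq.data.copy(), "gene")
        return bag_vec, seq, token_seq, attn, n

    # -- full forward -------------------------------------------------------
    def forward_patient(self, image_features: nn.Tensor,
                        gene_latents: nn.Tensor) -> tuple[nn.Tensor, FusionOutput]:
        d = self.config.dim
        if self.config.modality == "image":
            v_si, _, _, a_si, _ = self.encode_image_bag(image_features)
            logits = self.classifier(nn.reshape(v_si, (1, -1)))
            out = FusionOutput(v_si.data.copy(), np.zeros(d), np.zeros(d),
                               np.zeros(d), logits.data.reshape(-1).copy(), [a_si])
            return logits, out
        if self.config.modality == "gene":
            v_sg, _, _, a_sg, _ = self.encode_gene_bag(gene_latents)
            logits = self.classifier(nn.reshape(v_sg, (1, -1)))
            out = FusionOutput(np.zeros(d), v_sg.data.copy(), np.zeros(d),
                               np.zeros(d), logits.data.reshape(-1).copy(), [a_sg])
            return logits, out
        v_si, img_seq, img_tokens, a_si, n_img = self.encode_image_bag(image_features)
        v_sg, gene_seq, gene_tokens, a_sg, n_gene = self.encode_gene_bag(gene_latents)
        records = [a_si, a_sg]
        if self.config.self_only:
            fused = nn.concat([v_si, v_sg], axis=0)
            logits = self.classifier(nn.reshape(fused, (1, -1)))
            out = FusionOutput(v_si.data.copy(), v_sg.data.copy(),
                               np.zeros_like(v_si.data), np.zeros_like(v_sg.data),
                               logits.data.reshape(-1).copy(), records)
            return logits, out
        img_inst = img_seq[1:1 + n_img]
        gene_inst = gene_seq[1:1 + n_gene]
        v_ci, w_ci = self.cross_image(v_sg, img_inst)
        v_cg, w_cg = self.cross_gene(v_si, gene_inst)
        records.append(AttentionRecord("cross_img_query_gene",
                                       w_ci / w_ci.sum(), self.config.heads))
        records.append(AttentionRecord("cross_gene_query_img",
                                       w_cg / w_cg.sum(), self.config.heads))
        logits = self.fuse_and_classify(v_si, v_sg, v_ci, v_cg)
        out = FusionOutput(v_si.data.copy(), v_sg.data.copy(), v_ci.data.copy(),
                           v_cg.data.copy(), logits.data.reshape(-1).copy(), records)
        return logits, out

    def fuse_and_classify(self, v_si: nn.Tensor, v_sg: nn.Tensor,
                          v_ci: nn.Tensor, v_cg: nn.Tensor) -> nn.Tensor:
        d = self.config.dim
        for v in (v_si, v_sg, v_ci, v_cg):
            if v.shape != (d,):
                raise ValueError("all fused vectors must have length D")
        fused = nn.concat([v_si, v_sg, v_ci, v_cg], axis=0)
        return self.classifier(nn.reshape(fused, (1, -1)))


def _cls_record(mechanism: str, cls_row: np.ndarray, n_real: int,
                heads: int) -> AttentionRecord:
    """Class-token row -> distribution over real instances.

    Drops the class position and any padded tail, then renormalizes.
    """
    w = cls_row[1:1 + n_real].astype(np.float64)
    total = w.sum()
    if total <= 0:
        w = np.full(n_real, 1.0 / n_real)
    else:
        w = w / total
    return AttentionRecord(mechanism, w, heads)
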