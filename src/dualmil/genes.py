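"""Gene-set expression features: TPM/log2, zero-padded set tensors, and a
masked-MSE autoencoder that compresses each gene set to the shared latent
dimension used by the image branch.

Gene sets arrive as GMT memberships plus a per-set adjusted p-value from an
upstream enrichment analysis; only sets with adjusted p strictly below the
significance level (default 0.01) enter the model.  Because sets differ in
size, each set's expression row is right-padded with zeros to the maximum
set size and a binary mask records which entries are real genes.  The
autoencoder is shared across sets and trained with a masked mean squared
error, so padding positions contribute exactly nothing to loss or
gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn


@dataclass(frozen=True)
class GeneSetDefinition:
    set_id: str
    source: str                      # "GO", "KEGG" or "synthetic"
    member_genes: tuple[str, ...]
    padj: float

    def __post_init__(self):
        if not self.member_genes:
            raise ValueError(f"gene set {self.set_id} has no members")
        if len(set(self.member_genes)) != len(self.member_genes):
            raise ValueError(f"gene set {self.set_id} has duplicate members")
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError("padj must lie in [0, 1]")


@dataclass
class GeneSetTensor:
    """Zero-padded per-patient gene-set expression with a validity mask."""

    patient_id: str
    values: np.ndarray               # S x P
    mask: np.ndarray                 # S x P binary

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values[self.mask == 0] != 0):
            raise ValueError("padded entries must be zero")


@dataclass
class GeneLatent:
    patient_id: str
    features: np.ndarray             # S x D


def definitions_from_tables(gene_sets: dict[str, list[str]],
                            set_padj: dict[str, float],
                            source: str = "synthetic") -> list[GeneSetDefinition]:
    return [GeneSetDefinition(sid, source, tuple(members), set_padj[sid])
            for sid, members in gene_sets.items()]


def select_significant(sets: list[GeneSetDefinition],
                       alpha: float = 0.01) -> list[GeneSetDefinition]:
    """Keep sets with adjusted p strictly below alpha, preserving order."""
    return [s for s in sets if s.padj < alpha]


def tpm_log(counts: pd.DataFrame, lengths_bp: pd.Series,
            pseudocount: float = 1.0) -> pd.DataFrame:
    """TPM-normalize a genes x patients count matrix, then log2(TPM + pc).

    TPM_g = (count_g / length_kb_g) / sum_g'(count_g' / length_kb_g') * 1e6,
    so each patient column sums to one million whenever any count is
    positive.  All-zero patient columns stay zero (with a warning).
    """
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[:3].tolist()
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        warnings.warn(f"all-zero count columns: {list(totals.index[zero_cols])}",
                      stacklevel=2)
    totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return np.log2(tpm + pseudocount)


def build_geneset_tensor(expr_column: pd.Series,
                         sets: list[GeneSetDefinition],
                         patient_id: str = "") -> GeneSetTensor:
    """Assemble one patient's S x P padded expression matrix and mask."""
    if not sets:
        raise ValueError("no gene sets supplied")
    p_max = max(len(s.member_genes) for s in sets)
    values = np.zeros((len(sets), p_max), dtype=np.float64)
    mask = np.zeros((len(sets), p_max), dtype=np.float64)
    for i, s in enumerate(sets):
        for j, g in enumerate(s.member_genes):
            if g not in expr_column.index:
                raise KeyError(f"gene {g!r} of set {s.set_id!r} missing from expression")
            values[i, j] = expr_column[g]
            mask[i, j] = 1.0
    return GeneSetTensor(patient_id, values, mask)


def masked_mse(x: np.ndarray, xhat: np.ndarray, mask: np.ndarray) -> float:
    """sum(mask * (x - xhat)^2) / sum(mask); padding contributes nothing."""
    x, xhat, mask = (np.asarray(a, dtype=np.float64) for a in (x, xhat, mask))
    if not (x.shape == xhat.shape == mask.shape):
        raise ValueError("shapes must match")
    denom = mask.sum()
    if denom == 0:
        raise ValueError("mask selects no entries")
    diff = x - xhat
    return float((mask * diff * diff).sum() / denom)


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

class GeneSetAutoencoder(nn.Module):
    """Shared two-layer autoencoder P -> 256 -> D -> 256 -> P (tanh)."""

    def __init__(self, input_dim: int, latent_dim: int, seed: int = 0,
                 hidden_dim: int = 256):
        if latent_dim >= input_dim:
            warnings.warn("latent_dim >= input width: no compression", stacklevel=2)
        rng = np.random.default_rng(seed)
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.enc1 = nn.Linear(input_dim, hidden_dim, rng)
        self.enc2 = nn.Linear(hidden_dim, latent_dim, rng)
        self.dec1 = nn.Linear(latent_dim, hidden_dim, rng)
        self.dec2 = nn.Linear(hidden_dim, input_dim, rng)

    def encode(self, x: nn.Tensor, mask: nn.Tensor | None = None) -> nn.Tensor:
        if mask is not None:
            x = x * mask          # padding carries no signal into the latent
        return self.enc2(nn.tanh(self.enc1(x)))

    def decode(self, z: nn.Tensor) -> nn.Tensor:
        return self.dec2(nn.tanh(self.dec1(z)))

    def __call__(self, x: nn.Tensor, mask: nn.Tensor | None = None) -> nn.Tensor:
        return self.decode(self.encode(x, mask))


def _stack_tensors(tensors: list[GeneSetTensor]) -> tuple[np.ndarray, np.ndarray]:
    rows = np.concatenate([t.values for t in tensors], axis=0)
    masks = np.concatenate([t.mask for t in tensors], axis=0)
    return rows.astype(np.float32), masks.astype(np.float32)


def train_autoencoder(tensors: list[GeneSetTensor], latent_dim: int,
                      epochs: int = 50, lr: float = 1e-3,
                      seed: int = 0) -> tuple[GeneSetAutoencoder, list[float]]:
    """Fit the shared autoencoder by masked MSE over all set rows.

    The masked loss normalizes by the total number of unmasked entries in
    the batch (one global scalar), so padded entries influence neither the
    loss value nor any gradient.  Returns the model and per-epoch losses.
    """
    widths = {t.values.shape[1] for t in tensors}
    if len(widths) != 1:
        raise ValueError("all tensors must share the padded width P")
    p = widths.pop()
    rows, masks = _stack_tensors(tensors)
    model = GeneSetAutoencoder(p, latent_dim, seed=seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    x = nn.Tensor(rows)
    m = nn.Tensor(masks)
    denom = float(masks.sum())
    losses = []
    for _ in range(epochs):
        opt.zero_grad()
        xhat = model(x, m)
        diff = x - xhat
        loss = (m * diff * diff).sum() / denom
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return model, losses


def encode_genesets(model: GeneSetAutoencoder, tensor: GeneSetTensor) -> GeneLatent:
    """Map each set row through the trained encoder; row order preserved."""
    if tensor.values.shape[1] != model.input_dim:
        raise ValueError(f"tensor width {tensor.values.shape[1]} != "
                         f"autoencoder input {model.input_dim}")
    z = model.encode(nn.Tensor(tensor.values.astype(np.float32)),
                     nn.Tensor(tensor.mask.astype(np.float32)))
    return GeneLatent(tensor.patient_id, z.data.astype(np.float64))


def scale_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across patients (keeps class shifts, tames scale).

    Log-TPM values span roughly [0, 20], which saturates the autoencoder's
    tanh units; per-gene standardization is the usual remedy.  Genes with
    zero variance become all-zero rows.
    """
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1).replace(0, np.nan)
    return expr.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def compute_gene_latents(counts: pd.DataFrame, lengths: pd.Series,
                         sets: list[GeneSetDefinition], latent_dim: int,
                         epochs: int = 50, lr: float = 1e-3, seed: int = 0,
                         pseudocount: float = 1.0) -> dict[str, GeneLatent]:
    """Counts -> TPM/log2 -> per-gene z-score -> padded tensors -> AE latents."""
    expr = scale_genes(tpm_log(counts, lengths, pseudocount))
    tensors = [build_geneset_tensor(expr[pid], sets, patient_id=pid)
               for pid in expr.columns]
    model, _ = train_autoencoder(tensors, latent_dim, epochs=epochs, lr=lr, seed=seed)
    return {t.patient_id: encode_genesets(model, t) for t in tensors}
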