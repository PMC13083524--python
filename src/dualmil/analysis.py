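"""Statistical analysis of gene-set attention weights and spatial rendering.

After training, every test patient contributes one attention-weight row
over the gene sets (from the gene self-attention or the image-queried
cross-attention).  For each gene set, the two label groups are compared
with a Mann-Whitney U test; Benjamini-Hochberg FDR correction flags sets
at adjusted p < 0.01.  A label-permutation check then verifies that each
flagged set's group difference (absolute difference of group mean
attention) is not reproduced under shuffled labels.

The spatial side renders a patch bag's attention weights as a heatmap on
a slide-shaped canvas and reports the top-attended patch coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mil import AttentionRecord
from .tiling import PatchBag

GENE_MECHANISMS = ("self_gene", "cross_gene_query_img")


@dataclass
class AttentionTable:
    """Patients x gene-sets attention weights with labels."""

    values: pd.DataFrame            # rows: patients, columns: set ids
    labels: pd.Series               # per-patient {0, 1}
    mechanism: str

    def __post_init__(self):
        if self.mechanism not in GENE_MECHANISMS:
            raise ValueError(f"mechanism must be one of {GENE_MECHANISMS}")
        if self.values.isna().any().any():
            raise ValueError("attention table has missing cells")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1")
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must be indexed by the same patients")


@dataclass
class SignificanceResult:
    set_id: str
    u_statistic: float
    p_raw: float
    p_fdr: float
    significant: bool
    perm_p: float | None = None


def collect_attention(model, bags: dict, gene_latents: dict,
                      labels: dict[str, int], patient_ids: list[str],
                      mechanism: str = "self_gene",
                      set_ids: list[str] | None = None) -> AttentionTable:
    """One renormalized attention row per patient from the trained model."""
    rows = {}
    for pid in patient_ids:
        _, out = model.forward_patient(bags[pid].stack(),
                                       gene_latents[pid].features)
        rec = next(r for r in out.attention if r.mechanism == mechanism)
        w = rec.weights / rec.weights.sum()
        rows[pid] = w
    n_sets = len(next(iter(rows.values())))
    cols = set_ids if set_ids is not None else [f"SET{i:03d}" for i in range(n_sets)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    lab = pd.Series({pid: labels[pid] for pid in patient_ids}).loc[df.index]
    return AttentionTable(df, lab, mechanism)


def mwu(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both groups are small (< 8) and tie-free,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) < 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, rank-preserving)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_table(table: AttentionTable, alpha: float = 0.01,
                       n_perm: int = 999, seed: int = 0,
                       run_permutation: bool = True) -> list[SignificanceResult]:
    """MWU + BH-FDR over all sets; permutation check on the significant ones."""
    set_ids = list(table.values.columns)
    y = table.labels.values
    g0 = table.values.values[y == 0]
    g1 = table.values.values[y == 1]
    stats_p = [mwu(g0[:, j], g1[:, j]) for j in range(len(set_ids))]
    p_raw = np.array([p for _, p in stats_p])
    p_adj = fdr_bh(p_raw)
    results = []
    for j, sid in enumerate(set_ids):
        sig = bool(p_adj[j] < alpha)
        perm_p = None
        if sig and run_permutation:
            perm_p = permutation_check(table, sid, n_perm=n_perm, seed=seed + j)
        results.append(SignificanceResult(sid, stats_p[j][0], float(p_raw[j]),
                                          float(p_adj[j]), sig, perm_p))
    return results


def permutation_check(table: AttentionTable, set_id: str, n_perm: int = 999,
                      seed: int = 0) -> float:
    """Label-permutation p-value for one set's group-mean attention gap.

    Statistic: |mean(attention | class 1) - mean(attention | class 0)|;
    perm_p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse",
                      stacklevel=2)
    col = table.values[set_id].values
    y = table.labels.values
    observed = abs(col[y == 1].mean() - col[y == 0].mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        stat = abs(col[yp == 1].mean() - col[yp == 0].mean())
        if stat >= observed - 1e-15:
            count += 1
    return (1 + count) / (n_perm + 1)


def results_frame(results: list[SignificanceResult]) -> pd.DataFrame:
    return pd.DataFrame([{"set_id": r.set_id, "U": r.u_statistic,
                          "p_raw": r.p_raw, "p_fdr": r.p_fdr,
                          "significant": r.significant, "perm_p": r.perm_p}
                         for r in results])


# ---------------------------------------------------------------------------
# Spatial rendering
# ---------------------------------------------------------------------------

def render_heatmap(bag: PatchBag, attn: AttentionRecord,
                   slide_shape: tuple[int, int],
                   patch_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Paint min-max-scaled attention onto a slide-shaped canvas.

    Returns (float canvas in [0, 1], top-patch (row, col)); cells without a
    selected patch stay at background 0.  Ties for the top patch resolve
    to the lowest (row, col).
    """
    weights = np.asarray(attn.weights, dtype=np.float64)
    if len(weights) != len(bag.patches):
        raise ValueError("attention length must equal bag length")
    lo, hi = weights.min(), weights.max()
    scaled = np.ones_like(weights) if hi == lo else (weights - lo) / (hi - lo)
    canvas = np.zeros(slide_shape, dtype=np.float64)
    best = None
    for p, w, s in sorted(zip(bag.patches, weights, scaled),
                          key=lambda t: (t[0].row_index, t[0].col_index)):
        y, x = p.pixel_origin
        canvas[y:y + patch_size, x:x + patch_size] = s
        if best is None or w > best[0] + 1e-15:
            best = (w, (p.row_index, p.col_index))
    return canvas, best[1]
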