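"""Seeded synthetic multimodal cohorts: slides, counts, gene sets, labels.

The generator emulates the two inputs the model consumes:

* **Slides** — white-background raster images with dark elliptical tissue
  blobs (H&E-like contrast, so Otsu separates tissue from glass).  Inside
  the tissue, a configurable fraction of patch-sized regions carries a
  class-dependent spot texture: class 1 tissue shows denser dark spots
  than class 0.  The texture is deliberately simple enough for a small CNN
  to learn.
* **Expression** — negative-binomial RNA-seq-like counts (gene x patient)
  with log-normally drawn per-gene base means.  Member genes of designated
  differentially-expressed (DE) gene sets have their mean multiplied by
  ``2**log_fold_change`` in class 1.  The emitted adjusted-p table marks
  the DE sets with small p-values directly from the known assignment;
  recomputing differential expression is deliberately out of scope here.

Everything is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

BACKGROUND_INTENSITY = 245.0
TISSUE_INTENSITY = 120.0


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients_per_class: int = 40
    slide_height: int = 512
    slide_width: int = 512
    patch_size: int = 64
    tissue_blob_count: int = 4
    tissue_coverage: float = 0.5
    signal_patch_fraction: float = 0.6
    n_genes: int = 800
    n_gene_sets: int = 10
    set_size_range: tuple[int, int] = (20, 60)
    de_set_fraction: float = 0.3
    log_fold_change: float = 1.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients_per_class, self.slide_height, self.slide_width,
               self.patch_size, self.n_genes, self.n_gene_sets,
               self.tissue_blob_count) <= 0:
            raise InvalidConfigError("all counts must be positive")
        for frac in (self.signal_patch_fraction, self.de_set_fraction,
                     self.tissue_coverage):
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError("fractions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be positive")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise InvalidConfigError("set_size_range must be an increasing positive pair")
        if self.set_size_range[1] > self.n_genes:
            raise InvalidConfigError("set sizes exceed the number of genes")
        if self.slide_height < 2 * self.patch_size or self.slide_width < 2 * self.patch_size:
            raise InvalidConfigError("slide must hold at least 2x2 patches")


@dataclass
class SyntheticCohort:
    """In-memory bundle of everything one cohort emits."""

    config: SyntheticCohortConfig
    patient_ids: list[str]
    labels: dict[str, int]
    slides: dict[str, np.ndarray]
    counts: pd.DataFrame                    # genes x patients
    gene_lengths: pd.Series                 # bp per gene
    gene_sets: dict[str, list[str]]
    set_padj: dict[str, float]
    de_sets: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Slides
# ---------------------------------------------------------------------------

def _blob_mask(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> np.ndarray:
    """Union of random ellipses grown until tissue coverage is reached."""
    h, w = cfg.slide_height, cfg.slide_width
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    target = cfg.tissue_coverage * h * w
    # expected per-blob area chosen so ~tissue_blob_count blobs reach target
    base_r = math_sqrt(target / (np.pi * cfg.tissue_blob_count))
    for _ in range(cfg.tissue_blob_count * 8):
        if mask.sum() >= target:
            break
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        ry = base_r * rng.uniform(0.7, 1.3)
        rx = base_r * rng.uniform(0.7, 1.3)
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask


def math_sqrt(x: float) -> float:
    return float(np.sqrt(x))


def make_slide(config: SyntheticCohortConfig, class_label: int,
               patient_seed: int) -> np.ndarray:
    """Render one synthetic H&E-like slide as an H x W x 3 uint8 array.

    Deterministic per (config, class_label, patient_seed).
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    rng = np.random.default_rng([config.seed, int(patient_seed), class_label, 7])
    h, w, ps = config.slide_height, config.slide_width, config.patch_size
    img = np.full((h, w), BACKGROUND_INTENSITY, dtype=np.float64)
    img += rng.normal(0.0, 2.0, size=(h, w))
    mask = _blob_mask(rng, config)
    tissue = TISSUE_INTENSITY + rng.normal(0.0, 8.0, size=(h, w))
    img[mask] = tissue[mask]

    # class texture: dark spots stamped in a seeded subset of tissue tiles
    n_rows, n_cols = h // ps, w // ps
    spot_rate = {0: 2, 1: 10}[class_label]   # spots per signal tile
    for r in range(n_rows):
        for c in range(n_cols):
            tile_mask = mask[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps]
            if tile_mask.mean() < 0.9:
                continue
            if rng.uniform() >= config.signal_patch_fraction:
                # non-signal tissue tile: shared, class-independent spot rate
                n_spots = 6
            else:
                n_spots = spot_rate
            tile = img[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps]
            for _ in range(n_spots):
                sy = rng.integers(2, ps - 2)
                sx = rng.integers(2, ps - 2)
                rad = int(rng.integers(2, max(3, ps // 16)))
                y0, y1 = max(0, sy - rad), min(ps, sy + rad + 1)
                x0, x1 = max(0, sx - rad), min(ps, sx + rad + 1)
                tile[y0:y1, x0:x1] = np.minimum(tile[y0:y1, x0:x1], 40.0)
    gray = np.clip(img, 0, 255).astype(np.uint8)
    rgb = np.stack([gray, (gray * 0.88).astype(np.uint8), gray], axis=-1)
    return rgb


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def make_expression(config: SyntheticCohortConfig, labels: np.ndarray):
    """Simulate counts, gene lengths, gene sets and a per-set adjusted-p table.

    Returns ``(counts, lengths, gene_sets, set_padj, de_sets)`` where counts
    is a genes x patients DataFrame.  Counts are NB with variance
    ``mu + dispersion * mu**2``; DE-set member genes have their mean scaled
    by ``2**log_fold_change`` in class 1.
    """
    labels = np.asarray(labels)
    if labels.size != 2 * config.n_patients_per_class:
        raise InvalidConfigError("labels length must equal 2*n_patients_per_class")
    lo, hi = config.set_size_range
    if hi > config.n_genes:
        raise InvalidConfigError("set sizes exceed the number of genes")
    rng = np.random.default_rng([config.seed, 13])
    genes = _gene_ids(config.n_genes)
    patients = [f"P{i:04d}" for i in range(labels.size)]

    lengths = pd.Series(
        rng.integers(500, 5001, size=config.n_genes), index=genes, name="length_bp")
    base_mu = np.exp(rng.normal(3.0, 1.0, size=config.n_genes))

    # disjoint gene sets so DE signal stays attributable to its set
    perm = rng.permutation(config.n_genes)
    gene_sets: dict[str, list[str]] = {}
    cursor = 0
    for s in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        if cursor + size > config.n_genes:
            raise InvalidConfigError("gene sets exhaust the gene universe")
        gene_sets[f"SET{s:03d}"] = [genes[i] for i in perm[cursor:cursor + size]]
        cursor += size

    n_de = int(round(config.de_set_fraction * config.n_gene_sets))
    de_sets = [f"SET{s:03d}" for s in range(n_de)]
    de_genes = {g for s in de_sets for g in gene_sets[s]}
    de_idx = np.array([i for i, g in enumerate(genes) if g in de_genes], dtype=int)

    fc = 2.0 ** config.log_fold_change
    disp = config.nb_dispersion
    n_param = 1.0 / disp
    counts = np.empty((config.n_genes, labels.size), dtype=np.int64)
    for j, lab in enumerate(labels):
        mu = base_mu.copy()
        if lab == 1 and de_idx.size:
            mu[de_idx] *= fc
        p = n_param / (n_param + mu)
        counts[:, j] = rng.negative_binomial(n_param, p)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=patients)

    set_padj = {}
    for s in gene_sets:
        if s in de_sets:
            set_padj[s] = float(rng.uniform(1e-6, 1e-3))
        else:
            set_padj[s] = float(rng.uniform(0.2, 0.95))
    return counts_df, lengths, gene_sets, set_padj, de_sets


# ---------------------------------------------------------------------------
# Cohort assembly and disk round-trip
# ---------------------------------------------------------------------------

def make_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full balanced cohort (slides + expression + labels)."""
    n = config.n_patients_per_class
    labels_vec = np.array([0] * n + [1] * n)
    counts, lengths, gene_sets, set_padj, de_sets = make_expression(config, labels_vec)
    patient_ids = list(counts.columns)
    labels = {pid: int(lab) for pid, lab in zip(patient_ids, labels_vec)}
    slides = {pid: make_slide(config, labels[pid], i)
              for i, pid in enumerate(patient_ids)}
    return SyntheticCohort(config, patient_ids, labels, slides, counts, lengths,
                           gene_sets, set_padj, de_sets)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort in the on-disk layout the pipeline stages consume."""
    out = Path(out_dir)
    slides_dir = out / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    for pid, img in cohort.slides.items():
        Image.fromarray(img).save(slides_dir / f"{pid}.png")
    cohort.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    cohort.gene_lengths.rename("length_bp").to_csv(
        out / "gene_lengths.tsv", sep="\t", index_label="gene_id")
    with open(out / "gene_sets.gmt", "w") as fh:
        for set_id, members in cohort.gene_sets.items():
            fh.write("\t".join([set_id, "synthetic"] + members) + "\n")
    with open(out / "set_padj.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["set_id", "padj"])
        for set_id, p in cohort.set_padj.items():
            writer.writerow([set_id, f"{p:.8g}"])
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label"])
        for pid in cohort.patient_ids:
            writer.writerow([pid, cohort.labels[pid]])
    return out


def make_attention_table(n_per_class: int = 40, n_sets: int = 10,
                         shifted_sets: int = 3, effect: float = 0.08,
                         concentration: float = 60.0, seed: int = 0):
    """Construct an attention table with a class shift forced on k sets.

    Rows are Dirichlet draws over ``n_sets`` gene sets.  For class-1
    patients, weight ``effect`` is moved *within* the first ``shifted_sets``
    sets (the first gains, the rest lose equal shares), so exactly those k
    sets differ between classes while the remaining sets keep an identical
    distribution and rows still sum to one.  ``shifted_sets`` must be >= 2
    — in a composition a single component cannot change alone.

    Returns ``(AttentionTable, shifted_set_ids)``.
    """
    from .analysis import AttentionTable   # deferred: avoids import cycle at init

    if shifted_sets < 2:
        raise InvalidConfigError("need at least two shifted sets in a composition")
    if shifted_sets > n_sets:
        raise InvalidConfigError("shifted_sets exceeds n_sets")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    alpha = np.full(n_sets, concentration / n_sets)
    rows = rng.dirichlet(alpha, size=n)
    delta = np.zeros(n_sets)
    delta[0] = effect
    delta[1:shifted_sets] = -effect / (shifted_sets - 1)
    rows[labels == 1] += delta
    rows = np.clip(rows, 1e-9, None)
    rows /= rows.sum(axis=1, keepdims=True)
    pids = [f"P{i:04d}" for i in range(n)]
    set_ids = [f"SET{i:03d}" for i in range(n_sets)]
    df = pd.DataFrame(rows, index=pids, columns=set_ids)
    lab = pd.Series(labels, index=pids)
    table = AttentionTable(df, lab, "self_gene")
    return table, set_ids[:shifted_sets]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return sets


def read_labels(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    return dict(zip(df["patient_id"].astype(str), df["label"].astype(int)))
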