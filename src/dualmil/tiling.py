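"""Slide tiling, Otsu tissue detection and per-patient patch budgeting.

A slide is cut into a non-overlapping grid of square patches (default
256 x 256, partial edge tiles dropped).  Tissue is separated from the
glass background with a single per-slide Otsu threshold on the grayscale
histogram; a patch is *valid* when strictly more than ``min_tissue`` of
its pixels are darker than the threshold.  Because tissue content varies
across patients, every patient contributes the same number of patches:
the cohort budget is the minimum valid-patch count over patients.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

PATCH_SIZE_DEFAULT = 256
MIN_TISSUE_DEFAULT = 0.90

# Rec. 601 luma weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateHistogramError(ValueError):
    """Raised when a slide has a constant grayscale histogram."""


class CohortError(ValueError):
    """Raised when patients cannot satisfy the uniform patch budget."""

    def __init__(self, patients: list[str]):
        self.patients = patients
        super().__init__(f"patients with no valid patches: {', '.join(patients)}")


@dataclass
class Patch:
    patient_id: str
    row_index: int
    col_index: int
    pixel_origin: tuple[int, int]
    image: np.ndarray                 # ps x ps x 3 uint8
    tissue_fraction: float | None = None


@dataclass
class PatchBag:
    """One patient's fixed-size set of patches — the MIL bag."""

    patient_id: str
    label: int
    patches: list[Patch]
    budget: int

    def __post_init__(self):
        if len(self.patches) != self.budget:
            raise ValueError("bag length must equal the cohort budget")
        if any(p.patient_id != self.patient_id for p in self.patches):
            raise ValueError("all patches must share the bag's patient_id")

    def stack(self) -> np.ndarray:
        """(N, ps, ps, 3) uint8 array in bag order."""
        return np.stack([p.image for p in self.patches])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB (or already-gray) uint8 image -> float grayscale in [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    return arr[..., :3].astype(np.float64) @ _LUMA


def tile_slide(slide: np.ndarray, patch_size: int = PATCH_SIZE_DEFAULT,
               patient_id: str = "") -> list[Patch]:
    """Cut a slide into row-major grid patches; partial edge tiles dropped."""
    h, w = slide.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError(f"slide {h}x{w} smaller than one {patch_size}px patch")
    patches = []
    for r in range(h // patch_size):
        for c in range(w // patch_size):
            y, x = r * patch_size, c * patch_size
            patches.append(Patch(patient_id, r, c, (y, x),
                                 slide[y:y + patch_size, x:x + patch_size]))
    return patches


def compute_otsu_threshold(slide: np.ndarray) -> float:
    """Otsu threshold of the slide's 8-bit grayscale histogram.

    Finds the gray level t maximizing between-class variance of the
    partition {pixels <= t} / {pixels > t} (ties resolved to the lowest t)
    and returns the boundary t + 0.5, so that "strictly below threshold"
    selects exactly the dark class.
    """
    gray = np.round(to_grayscale(slide)).astype(np.int64)
    hist = np.bincount(np.clip(gray.ravel(), 0, 255), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image has no Otsu threshold")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    w1 = total - w0
    cum = np.cumsum(hist * levels)
    mu_total = cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum / w0
        mu1 = (mu_total - cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[np.isnan(sigma_b)] = -1.0
    return float(np.argmax(sigma_b)) + 0.5


def tissue_fraction(patch: Patch, slide_threshold: float) -> float:
    """Fraction of patch pixels strictly darker than the slide threshold."""
    gray = to_grayscale(patch.image)
    return float((gray < slide_threshold).mean())


def annotate_tissue(patches: list[Patch], slide: np.ndarray) -> list[Patch]:
    """Set tissue_fraction on every patch from one per-slide Otsu threshold.

    A constant slide (degenerate histogram) is treated as all background.
    """
    try:
        thr = compute_otsu_threshold(slide)
    except DegenerateHistogramError:
        for p in patches:
            p.tissue_fraction = 0.0
        return patches
    for p in patches:
        p.tissue_fraction = tissue_fraction(p, thr)
    return patches


def filter_valid(patches: list[Patch], min_tissue: float = MIN_TISSUE_DEFAULT) -> list[Patch]:
    """Keep patches whose tissue fraction strictly exceeds ``min_tissue``."""
    if any(p.tissue_fraction is None for p in patches):
        raise ValueError("tissue_fraction must be set before filtering")
    return [p for p in patches if p.tissue_fraction > min_tissue]


def cohort_budget(valid_counts: dict[str, int]) -> int:
    """Uniform per-patient budget: the cohort-wide minimum valid-patch count."""
    empty = sorted(pid for pid, n in valid_counts.items() if n == 0)
    if empty:
        raise CohortError(empty)
    return min(valid_counts.values())


def select_patches(valid: list[Patch], budget: int, seed: int = 0,
                   label: int = 0, policy: str = "top_tissue") -> PatchBag:
    """Select exactly ``budget`` patches into a bag.

    ``top_tissue`` (default) takes the patches with highest tissue fraction,
    ties broken by (row, col); ``random`` draws a seeded uniform sample.
    """
    if not valid:
        raise ValueError("no valid patches to select from")
    if len(valid) < budget:
        raise ValueError(f"{len(valid)} valid patches < budget {budget}")
    pid = valid[0].patient_id
    if policy == "top_tissue":
        chosen = sorted(valid, key=lambda p: (-p.tissue_fraction,
                                              p.row_index, p.col_index))[:budget]
    elif policy == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(valid), size=budget, replace=False)
        chosen = [valid[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    return PatchBag(pid, label, chosen, budget)


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def build_bags(slides: dict[str, np.ndarray], labels: dict[str, int],
               patch_size: int = PATCH_SIZE_DEFAULT,
               min_tissue: float = MIN_TISSUE_DEFAULT,
               seed: int = 0, policy: str = "top_tissue",
               budget_cap: int | None = None) -> dict[str, PatchBag]:
    """Tile + filter every slide, equalize the budget, and build all bags.

    ``budget_cap`` optionally caps the uniform budget below the cohort
    minimum (the reference protocol used 64 patches per patient).
    """
    valid: dict[str, list[Patch]] = {}
    for pid, slide in slides.items():
        patches = annotate_tissue(tile_slide(slide, patch_size, pid), slide)
        valid[pid] = filter_valid(patches, min_tissue)
    budget = cohort_budget({pid: len(v) for pid, v in valid.items()})
    if budget_cap is not None:
        budget = min(budget, budget_cap)
    return {pid: select_patches(v, budget, seed=seed + i, label=labels[pid],
                                policy=policy)
            for i, (pid, v) in enumerate(sorted(valid.items()))}


def write_manifest(bags: dict[str, PatchBag], out_dir: str | Path,
                   save_patches: bool = False) -> Path:
    """Write a bag manifest CSV (and optionally per-patch PNGs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "bag_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "row", "col",
                         "tissue_fraction", "path"])
        for pid in sorted(bags):
            bag = bags[pid]
            for p in bag.patches:
                rel = f"patches/{pid}_r{p.row_index}_c{p.col_index}.png"
                if save_patches:
                    (out / "patches").mkdir(exist_ok=True)
                    Image.fromarray(p.image).save(out / rel)
                writer.writerow([pid, bag.label, p.row_index, p.col_index,
                                 f"{p.tissue_fraction:.6f}", rel])
    return manifest
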