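"""Seeded, logged, resumable orchestration of the full analysis.

One YAML configuration drives every stage: simulate (synthetic cohort),
tile (bags + manifest), genes (autoencoder latents), train (joint model),
eval (metrics CSV) and explain (attention significance CSV + heatmaps).
Stage outputs land in a run directory with a provenance manifest (config
hash + seed); completed stages are skipped on re-run unless forced, and a
determinism-mode rerun with the same config and seed reproduces output
files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field

from . import analysis, genes, synthetic, tiling, train
from .backbone import (BackboneSpec, reference_reduced_spec, spec_from_yaml,
                       tiny_backbone_spec)
from .mil import MILConfig

STAGES = ("simulate", "tile", "genes", "train", "eval", "explain")


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
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


class TilingSection(_Strict):
    patch_size: int = 256
    min_tissue: float = 0.90
    policy: str = "top_tissue"
    budget_cap: int | None = 64


class GenesSection(_Strict):
    alpha: float = 0.01
    latent_dim: int = 32
    pseudocount: float = 1.0
    epochs: int = 50
    lr: float = 1e-3


class BackboneSection(_Strict):
    preset: str = "tiny"            # "tiny", "reference_reduced" or "file"
    spec_path: str | None = None
    feature_dim: int = 32


class ModelSection(_Strict):
    heads: int = 2
    landmarks: int = 8
    self_only: bool = False
    modality: str = "fused"


class TrainingSection(_Strict):
    epochs: int = 15
    lr: float = 1e-3
    positive_class: int = 1
    frozen_backbone: bool = False
    test_size: float = 0.2
    n_folds: int = 5


class ExplainSection(_Strict):
    mechanism: str = "self_gene"
    alpha: float = 0.01
    n_perm: int = 999
    heatmaps: int = 2


class RunConfig(_Strict):
    data_dir: str = "cohort"
    seed: int = 0
    cohort: CohortSection = Field(default_factory=CohortSection)
    tiling: TilingSection = Field(default_factory=TilingSection)
    genes: GenesSection = Field(default_factory=GenesSection)
    backbone: BackboneSection = Field(default_factory=BackboneSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    explain: ExplainSection = Field(default_factory=ExplainSection)


def validate_config(path: str | Path) -> RunConfig:
    """Parse + validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = RunConfig(**raw)
    except Exception as exc:  # pydantic collects all offending keys
        raise ConfigError(str(exc)) from exc
    if cfg.backbone.preset == "file":
        if not cfg.backbone.spec_path or not Path(cfg.backbone.spec_path).exists():
            raise ConfigError(f"backbone spec file missing: {cfg.backbone.spec_path}")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _backbone_spec(cfg: RunConfig) -> BackboneSpec:
    if cfg.backbone.preset == "tiny":
        return tiny_backbone_spec(cfg.backbone.feature_dim)
    if cfg.backbone.preset == "reference_reduced":
        return reference_reduced_spec()
    if cfg.backbone.preset == "file":
        return spec_from_yaml(cfg.backbone.spec_path)
    raise ConfigError(f"unknown backbone preset {cfg.backbone.preset!r}")


# ---------------------------------------------------------------------------
# Stage implementations (pure functions of config + run dir)
# ---------------------------------------------------------------------------

def _cohort_config(cfg: RunConfig) -> synthetic.SyntheticCohortConfig:
    c = cfg.cohort
    return synthetic.SyntheticCohortConfig(
        n_patients_per_class=c.n_patients_per_class, slide_height=c.slide_height,
        slide_width=c.slide_width, patch_size=c.patch_size,
        tissue_blob_count=c.tissue_blob_count, tissue_coverage=c.tissue_coverage,
        signal_patch_fraction=c.signal_patch_fraction, n_genes=c.n_genes,
        n_gene_sets=c.n_gene_sets, set_size_range=tuple(c.set_size_range),
        de_set_fraction=c.de_set_fraction, log_fold_change=c.log_fold_change,
        nb_dispersion=c.nb_dispersion, seed=cfg.seed)


class PipelineRun:
    """Stage executor bound to one (config, run_dir) pair."""

    def __init__(self, cfg: RunConfig, run_dir: str | Path):
        self.cfg = cfg
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.data_dir = self.run_dir / cfg.data_dir
        self._cache: dict[str, object] = {}

    # -- state helpers ------------------------------------------------------
    def _marker(self, stage: str) -> Path:
        return self.run_dir / f".done_{stage}"

    def stage_done(self, stage: str) -> bool:
        return self._marker(stage).exists()

    def _finish(self, stage: str) -> None:
        self._marker(stage).write_text("done\n")
        with open(self.run_dir / "log.jsonl", "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": time.time()}) + "\n")

    # -- data loading -------------------------------------------------------
    def _load_cohort_inputs(self):
        if "cohort_inputs" in self._cache:
            return self._cache["cohort_inputs"]
        labels = synthetic.read_labels(self.data_dir / "labels.csv")
        slides = {pid: np.asarray(Image.open(self.data_dir / "slides" / f"{pid}.png"))
                  for pid in labels}
        counts = pd.read_csv(self.data_dir / "counts.tsv", sep="\t", index_col=0)
        lengths = pd.read_csv(self.data_dir / "gene_lengths.tsv", sep="\t",
                              index_col=0)["length_bp"]
        gene_sets = synthetic.read_gmt(self.data_dir / "gene_sets.gmt")
        padj = pd.read_csv(self.data_dir / "set_padj.csv", index_col=0)["padj"].to_dict()
        out = (labels, slides, counts, lengths, gene_sets, padj)
        self._cache["cohort_inputs"] = out
        return out

    def _bags(self):
        if "bags" not in self._cache:
            labels, slides, *_ = self._load_cohort_inputs()
            t = self.cfg.tiling
            self._cache["bags"] = tiling.build_bags(
                slides, labels, patch_size=t.patch_size, min_tissue=t.min_tissue,
                seed=self.cfg.seed, policy=t.policy, budget_cap=t.budget_cap)
        return self._cache["bags"]

    def _latents(self):
        if "latents" not in self._cache:
            _, _, counts, lengths, gene_sets, padj = self._load_cohort_inputs()
            g = self.cfg.genes
            defs = genes.definitions_from_tables(gene_sets, padj)
            sig = genes.select_significant(defs, g.alpha)
            if not sig:
                raise ConfigError("no significant gene sets at the chosen alpha")
            latents = genes.compute_gene_latents(
                counts, lengths, sig, g.latent_dim, epochs=g.epochs, lr=g.lr,
                seed=self.cfg.seed, pseudocount=g.pseudocount)
            self._cache["latents"] = latents
            self._cache["sig_sets"] = sig
        return self._cache["latents"], self._cache["sig_sets"]

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cohort = synthetic.make_cohort(_cohort_config(self.cfg))
        synthetic.write_cohort(cohort, self.data_dir)

    def tile(self) -> None:
        bags = self._bags()
        tiling.write_manifest(bags, self.run_dir)

    def genes_stage(self) -> None:
        latents, sig = self._latents()
        arrays = {pid: lat.features for pid, lat in latents.items()}
        np.savez(self.run_dir / "gene_latents.npz", **arrays)
        pd.DataFrame({"set_id": [s.set_id for s in sig],
                      "padj": [s.padj for s in sig]}).to_csv(
            self.run_dir / "gene_latents_manifest.csv", index=False)

    def train_stage(self) -> None:
        labels, *_ = self._load_cohort_inputs()
        bags = self._bags()
        latents, _ = self._latents()
        plan = train.make_splits(labels, seed=self.cfg.seed,
                                 test_size=self.cfg.training.test_size,
                                 n_folds=self.cfg.training.n_folds)
        spec = _backbone_spec(self.cfg)
        mcfg = MILConfig(dim=spec.feature_dim, heads=self.cfg.model.heads,
                         landmarks=self.cfg.model.landmarks,
                         self_only=self.cfg.model.self_only,
                         modality=self.cfg.model.modality, seed=self.cfg.seed)
        model = train.MultimodalClassifier(spec, mcfg, seed=self.cfg.seed)
        tcfg = train.TrainConfig(epochs=self.cfg.training.epochs,
                                 lr=self.cfg.training.lr,
                                 positive_class=self.cfg.training.positive_class,
                                 frozen_backbone=self.cfg.training.frozen_backbone)
        trace = train.train_model(model, bags, latents, labels, tcfg,
                                  seed=self.cfg.seed, patient_ids=plan.train_ids)
        train.save_checkpoint(model, self.run_dir / "checkpoint.npz")
        with open(self.run_dir / "loss_trace.jsonl", "w") as fh:
            for epoch, loss in enumerate(trace):
                fh.write(json.dumps({"epoch": epoch, "loss": round(loss, 10)}) + "\n")
        (self.run_dir / "split.json").write_text(json.dumps(
            {"train_ids": plan.train_ids, "test_ids": plan.test_ids,
             "seed": plan.seed}, indent=1))
        self._cache["model"] = model
        self._cache["plan"] = plan

    def _restore_model(self):
        if "model" in self._cache:
            return self._cache["model"], self._cache["plan"]
        spec = _backbone_spec(self.cfg)
        mcfg = MILConfig(dim=spec.feature_dim, heads=self.cfg.model.heads,
                         landmarks=self.cfg.model.landmarks,
                         self_only=self.cfg.model.self_only,
                         modality=self.cfg.model.modality, seed=self.cfg.seed)
        model = train.MultimodalClassifier(spec, mcfg, seed=self.cfg.seed)
        train.load_checkpoint(model, self.run_dir / "checkpoint.npz")
        split = json.loads((self.run_dir / "split.json").read_text())
        plan = train.SplitPlan(split["train_ids"], split["test_ids"], [],
                               split["seed"])
        self._cache["model"], self._cache["plan"] = model, plan
        return model, plan

    def eval_stage(self) -> None:
        labels, *_ = self._load_cohort_inputs()
        bags = self._bags()
        latents, _ = self._latents()
        model, plan = self._restore_model()
        rep = train.evaluate(model, bags, latents, labels, plan.test_ids,
                             self.cfg.training.positive_class)
        df = pd.DataFrame([{"split": "test", **{k: round(v, 10) for k, v in
                                                rep.as_dict().items()}}])
        df.to_csv(self.run_dir / "metrics.csv", index=False)

    def explain_stage(self) -> None:
        labels, *_ = self._load_cohort_inputs()
        bags = self._bags()
        latents, sig = self._latents()
        model, plan = self._restore_model()
        table = analysis.collect_attention(
            model, bags, latents, labels, plan.test_ids,
            mechanism=self.cfg.explain.mechanism,
            set_ids=[s.set_id for s in sig])
        results = analysis.significance_table(
            table, alpha=self.cfg.explain.alpha,
            n_perm=self.cfg.explain.n_perm, seed=self.cfg.seed)
        analysis.results_frame(results).round(10).to_csv(
            self.run_dir / "significance.csv", index=False)
        heat_dir = self.run_dir / "heatmaps"
        heat_dir.mkdir(exist_ok=True)
        shape = (self.cfg.cohort.slide_height, self.cfg.cohort.slide_width)
        for pid in plan.test_ids[: self.cfg.explain.heatmaps]:
            _, out = model.forward_patient(bags[pid].stack(),
                                           latents[pid].features)
            rec = next(r for r in out.attention if r.mechanism == "self_image")
            canvas, _ = analysis.render_heatmap(bags[pid], rec, shape,
                                                self.cfg.tiling.patch_size)
            Image.fromarray((canvas * 255).astype(np.uint8)).save(
                heat_dir / f"{pid}_self_image.png")

    STAGE_FN = {"simulate": simulate, "tile": tile, "genes": genes_stage,
                "train": train_stage, "eval": eval_stage, "explain": explain_stage}


_DEPS = {"simulate": (), "tile": ("simulate",), "genes": ("simulate",),
         "train": ("simulate",), "eval": ("train",), "explain": ("train",)}


def run_pipeline(cfg: RunConfig, run_dir: str | Path,
                 stages: tuple[str, ...] = STAGES, force: bool = False) -> Path:
    """Execute the requested stages; completed stages are skipped unless forced."""
    runner = PipelineRun(cfg, run_dir)
    manifest = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                "config": cfg.model_dump()}
    prov = runner.run_dir / "provenance.json"
    payload = json.dumps(manifest, indent=1)
    if not prov.exists() or prov.read_text() != payload:
        prov.write_text(payload)
    for stage in stages:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        for dep in _DEPS[stage]:
            if dep not in stages and not runner.stage_done(dep):
                raise ConfigError(f"stage {stage!r} requires {dep!r} first")
        if runner.stage_done(stage) and not force:
            continue
        PipelineRun.STAGE_FN[stage](runner)
        runner._finish(stage)
    return runner.run_dir
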