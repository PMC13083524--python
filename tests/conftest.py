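import numpy as np
import pytest

from dualmil import synthetic, tiling, genes


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 6 patients per class, 256px slides, 64px patches."""
    return synthetic.SyntheticCohortConfig(
        n_patients_per_class=6, slide_height=256, slide_width=256,
        patch_size=64, tissue_blob_count=3, n_genes=300, n_gene_sets=6,
        set_size_range=(10, 30), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.make_cohort(small_config)


@pytest.fixture(scope="session")
def small_bags(small_cohort):
    return tiling.build_bags(small_cohort.slides, small_cohort.labels,
                             patch_size=64, min_tissue=0.9, seed=0,
                             budget_cap=8)


@pytest.fixture(scope="session")
def small_latents(small_cohort):
    defs = genes.definitions_from_tables(small_cohort.gene_sets,
                                         small_cohort.set_padj)
    sig = genes.select_significant(defs, alpha=1.0)
    return genes.compute_gene_latents(
        small_cohort.counts, small_cohort.gene_lengths, sig, latent_dim=16,
        epochs=8, seed=0), sig


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
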