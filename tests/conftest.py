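import pytest

from mircnv.pipeline import PipelineConfig
from mircnv.synthetic import SyntheticConfig, generate_cohort


def small_config(seed: int = 11) -> SyntheticConfig:
    """A three-species cohort small enough for per-test use."""
    return SyntheticConfig(
        n_species=3,
        n_homology_groups=100,
        n_mirnas=15,
        utr_length_mean=250.0,
        utr_length_sd=40.0,
        n_pathways=5,
        pathway_size_range=(5, 8),
        planted_enriched_pathways=[("PW01", "above", 1.0)],
        n_gene_classes=3,
        class_size_range=(8, 15),
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def small_pipeline_config(tmp_path):
    def make(seed: int = 11, subdir: str = "run") -> PipelineConfig:
        return PipelineConfig(out_dir=str(tmp_path / subdir), rng_seed=seed,
                              synthetic=small_config())
    return make
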