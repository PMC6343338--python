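import numpy as np
import pytest

from apacca import ExperimentDesign, PacDataset, SiteRecord, make_design


@pytest.fixture
def toy_design() -> ExperimentDesign:
    """2 experiments x 2 replicates."""
    return make_design(2, 2)


def build_dataset(site_genes, counts, design, quantification="raw") -> PacDataset:
    """site_genes: list of (site_id, gene_id); counts: row per site."""
    sites = [SiteRecord(site_id=s, gene_id=g) for s, g in site_genes]
    return PacDataset(
        sites=sites,
        counts=np.asarray(counts, dtype=float),
        design=design,
        quantification=quantification,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
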