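import numpy as np
import pytest

from m6adyn import pipeline
from m6adyn.models import GeneModel
from m6adyn.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genes=60)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def called(small_study):
    """Peak calling of the small study: stats, enriched windows, peaks, sites."""
    res = pipeline.stage_peakcall(small_study.genes, small_study.tracks,
                                  small_study.design)
    res["sites"] = pipeline.infer_study_sites(
        res["peaks"], small_study.genome, small_study.genes, res["stats_by_sample"]
    )
    return res


@pytest.fixture
def toy_gene_plus():
    """300-nt spliced transcript on + strand: 5'UTR 50, CDS 150, 3'UTR 100."""
    return GeneModel(
        gene_id="toyP", chrom="chrT", strand="+",
        exons=[(100, 220), (300, 480)], cds_start=50, cds_end=200,
    )


@pytest.fixture
def toy_gene_minus():
    return GeneModel(
        gene_id="toyM", chrom="chrT", strand="-",
        exons=[(100, 220), (300, 480)], cds_start=50, cds_end=200,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
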