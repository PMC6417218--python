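import numpy as np
import pandas as pd
import pytest

from promquant import synthetic
from promquant.omics import OmicsDataset
from promquant.promoters import Annotation, OperonTable


@pytest.fixture(scope="session")
def small_truth():
    return synthetic.gen_latent_strength_map(100, seed=11)


@pytest.fixture(scope="session")
def noiseless_suite(small_truth):
    return synthetic.gen_omics_suite(
        small_truth,
        noise_sd={p: 0.0 for p in ("microarray", "rnaseq", "proteomics")},
        platform_offset={p: 0.0 for p in ("microarray", "rnaseq", "proteomics")},
        condition_sd=0.0,
        proteomics_floor=-1e9,  # effectively no censoring
        seed=1)


@pytest.fixture
def toy_annotation():
    """Two + strand genes and one - strand gene on a 2 kb contig."""
    genes = pd.DataFrame([
        {"gene_id": "gA", "contig": "c1", "strand": "+", "start": 101, "end": 400},
        {"gene_id": "gB", "contig": "c1", "strand": "+", "start": 501, "end": 1000},
        {"gene_id": "gC", "contig": "c1", "strand": "-", "start": 1201, "end": 1500},
    ])
    return Annotation(genes)


@pytest.fixture
def toy_operons():
    return OperonTable(pd.DataFrame([
        {"operon_id": "op1", "gene_id": "gA", "position_in_operon": 1, "strand": "+"},
        {"operon_id": "op1", "gene_id": "gB", "position_in_operon": 2, "strand": "+"},
    ]))


def make_dataset(values: dict[str, list[float]], platform: str = "microarray"
                 ) -> OmicsDataset:
    frame = pd.DataFrame(values).T
    frame.columns = [f"c{i+1}" for i in range(frame.shape[1])]
    frame.index.name = "gene_id"
    return OmicsDataset(platform=platform, matrix=frame)
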