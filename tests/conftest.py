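import numpy as np
import pandas as pd
import pytest

import mcam


@pytest.fixture
def tiny_dataset():
    """3 peptides x 4 timepoints, all positive, hand-enterable values."""
    return mcam.QuantDataset(
        peptide_ids=["p1", "p2", "p3"],
        protein_accs=["A1", "A2", "A3"],
        site_labels=["Y100", "Y200", "Y300"],
        conditions=["t0", "t5", "t10", "t30"],
        values=np.array(
            [
                [1.0, 4.0, 2.0, 1.0],
                [1.0, 3.0, 3.5, 3.0],
                [1.0, 1.2, 2.0, 4.0],
            ]
        ),
    )


@pytest.fixture
def tiny_annotations(tiny_dataset):
    df = pd.DataFrame(
        {
            "peptide_id": ["p1", "p2", "p3", "p1", "p2"],
            "category": ["F", "F", "F", "P", "P"],
            "label": ["kinase", "kinase", "adaptor", "signaling", "signaling"],
        }
    )
    return mcam.AnnotationTable(records=df)


@pytest.fixture(scope="session")
def planted():
    """Well-separated 3-group synthetic dataset with strong annotations."""
    spec = mcam.SyntheticSpec(
        n_peptides=60,
        n_groups=3,
        noise_sd=0.05,
        within_prob=0.9,
        background_prob=0.05,
        seed=42,
    )
    dataset, groups = mcam.generate_dataset(spec)
    annotations = mcam.generate_annotations(dataset, groups, spec)
    return spec, dataset, groups, annotations


@pytest.fixture(scope="session")
def planted_mca(planted):
    """A small but diverse ensemble over the planted data, with enrichment."""
    _, dataset, _, annotations = planted
    configs = mcam.expand_grid(
        ["raw", "zscore", "normMax"],
        ["euclidean", "correlation"],
        ["Hierarchical", "Kmeans", "AP", "SOM", "Ncut"],
        [2, 3, 4, 6],
        seed=5,
    )
    mca = mcam.build_mca(dataset, configs)
    enrichment = mcam.enrich_mca(mca, dataset, annotations, dynamics=None)
    return mca, enrichment
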