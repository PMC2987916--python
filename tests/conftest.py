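import numpy as np
import pytest

import covnet
from covnet.synthetic import SyntheticSpec


@pytest.fixture(scope="session")
def atlas():
    return covnet.aal_region_table()


@pytest.fixture(scope="session")
def small_atlas():
    """10-region (5 bilateral pairs) atlas for fast simulation studies."""
    return covnet.reduced_atlas(5)


def small_spec(seed: int, atlas, n_per_group=50, group_effects=None,
               homotopic=0.6, within=0.35, between=0.25, **kwargs):
    groups = {"A": n_per_group, "B": n_per_group}
    return SyntheticSpec(
        n_subjects_per_group=groups,
        homotopic_corr=homotopic,
        within_block_corr=within,
        between_block_corr=between,
        group_effects=group_effects or {},
        seed=seed,
        atlas=atlas,
        **kwargs,
    )


@pytest.fixture
def small_spec_factory(small_atlas):
    def make(seed=0, **kwargs):
        return small_spec(seed, small_atlas, **kwargs)
    return make


@pytest.fixture
def nc_cohort():
    """One moderately sized 90-region cohort from the default preset."""
    spec = covnet.default_three_group_spec(seed=11)
    return covnet.generate_cohort(spec, "NC")


@pytest.fixture
def tiny_net(atlas):
    """Deterministic sparse connected 90-node network for graph-op tests."""
    spec = covnet.default_three_group_spec(seed=5)
    corr = covnet.cohort_correlation(covnet.generate_cohort(spec, "NC"))
    return covnet.threshold_by_sparsity(corr, 0.12)


def make_network(adj):
    """Wrap a raw adjacency (any size) in a label-free BinaryNetwork."""
    return covnet.BinaryNetwork(adjacency=np.asarray(adj, dtype=bool))
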