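import numpy as np
import pytest

from taxrefine import (
    CommunitySpec,
    assemble_features,
    count_tetramers,
    generate_community,
    normalize_abundances,
    project_tnf,
    zscale_columns,
)


def features_from_community(community):
    """Build the feature table for a generated community in memory."""
    counts = np.stack(
        [count_tetramers(seq, cid) for cid, seq in community.sequences]
    )
    tnf_z = zscale_columns(project_tnf(counts))
    abund = normalize_abundances(
        community.depths.to_numpy(dtype=float),
        sample_ids=list(community.depths.columns),
        contig_ids=community.contig_ids,
    )
    return assemble_features(tnf_z, abund, community.contig_ids)


@pytest.fixture(scope="session")
def small_community():
    """4 well-separated species in 2 genera, 25 contigs each: fast to train."""
    spec = CommunitySpec(
        n_species=4,
        species_per_genus=2,
        contigs_per_species=25,
        contig_length_range=(2000, 4000),
        composition_alpha=4.0,
        seed=7,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def small_features(small_community):
    return features_from_community(small_community)


@pytest.fixture(scope="session")
def default_community():
    """The default benchmark community: 8 species, 3 samples, 50 contigs each."""
    return generate_community(CommunitySpec(seed=101))


@pytest.fixture(scope="session")
def default_features(default_community):
    return features_from_community(default_community)
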