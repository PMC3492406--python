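"""Shared fixtures: small seeded synthetic datasets built at test time."""

import numpy as np
import pytest

from lrmotifs.seqcore import DnaSequence, SequenceCluster
from lrmotifs.simulate import (
    PlantConfig,
    generate_planted_dataset,
    random_peaked_pfm,
    sample_iid_background,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_background_cluster(cluster_id, n, length, rng, gc=0.4):
    members = []
    for i in range(n):
        s = sample_iid_background(gc, length, rng)
        s.id = f"{cluster_id}_{i:03d}"
        members.append(s)
    return SequenceCluster(cluster_id, members)


@pytest.fixture
def strong_planted():
    """One 20-member cluster with a sharply peaked width-10 motif, plus a
    motif-free background cluster of the same shape."""
    rng = np.random.default_rng(777)
    pfm = random_peaked_pfm(10, rng, dominance=0.95, name="strong")
    cfg = PlantConfig(
        pfms=[pfm], cluster_sizes=[20], sequence_length=200, gc_fraction=0.4, seed=101
    )
    coll, records, true_pwms = generate_planted_dataset(cfg)
    bg = make_background_cluster("bg", 20, 200, rng)
    return coll.clusters[0], bg, pfm, records


@pytest.fixture(scope="session")
def small_planted_collection():
    """Four planted clusters of 12 sequences each (length 300)."""
    rng = np.random.default_rng(2024)
    pfms = [random_peaked_pfm(10, rng, name=f"pfm{i:02d}") for i in range(4)]
    cfg = PlantConfig(
        pfms=pfms, cluster_sizes=[12] * 4, sequence_length=300, gc_fraction=0.4, seed=55
    )
    return generate_planted_dataset(cfg)
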