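import numpy as np
import pytest

from prophagekit.genome_io import DomainHit, ProphageRegion, Replicon
from prophagekit.synthetic_data import SimConfig, emit_dataset


@pytest.fixture
def small_replicon() -> Replicon:
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    return Replicon("chr_t", seq, topology="circular")


@pytest.fixture
def region_factory():
    def make(region_id="p1", replicon_id="chr_t", start=0, end=100, source="test"):
        return ProphageRegion(region_id, replicon_id, start, end, source)
    return make


@pytest.fixture
def hit_factory():
    def make(region_id="p1", accession="pfam00589", evalue=1e-10, description=""):
        return DomainHit(region_id, accession, description, evalue)
    return make


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact but complete synthetic dataset reused across tests."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(
        seed=11,
        n_chromosomes=4,
        n_plasmids=2,
        host_length_range=(150_000, 400_000),
        plasmid_length_range=(20_000, 60_000),
        prophage_size_range=(4_000, 20_000),
        prophages_per_genome_range=(1, 5),
    )
    return cfg, emit_dataset(cfg, out)
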