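import pytest

from gatafam.domain_scan import scan_zf_motifs
from gatafam.synthetic import SimConfig, make_family


@pytest.fixture(scope="session")
def small_family():
    """A compact 4-species family with every planted feature exercised."""
    cfg = SimConfig(n_species=4, n_clusters=6, mutation_rate=0.02, seed=11)
    return make_family(cfg)


@pytest.fixture(scope="session")
def clean_family():
    """Mutation-free family: planted truth must be recovered exactly."""
    cfg = SimConfig(n_species=4, n_clusters=6, mutation_rate=0.0, seed=7)
    return make_family(cfg)


@pytest.fixture(scope="session")
def family_dir(small_family, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    small_family.write(out)
    return out


def hits_for(fam):
    """Complete-motif hits per isoform of a synthetic family."""
    return {tid: scan_zf_motifs(p, tid) for tid, p in fam.proteins.items()}


@pytest.fixture(scope="session")
def small_hits(small_family):
    return hits_for(small_family)


@pytest.fixture(scope="session")
def clean_hits(clean_family):
    return hits_for(clean_family)
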