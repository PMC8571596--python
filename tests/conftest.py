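import numpy as np
import pytest

from sweepscan.model import GenotypeMatrix, PopulationMap, Site
from sweepscan.synthetic_data import SimulationConfig, simulate_bundle, write_fixture


@pytest.fixture
def popmap_4() -> PopulationMap:
    # matches make_genotypes' default ids s0..s3
    return PopulationMap({"s0": "HG", "s1": "HG", "s2": "CG", "s3": "CG"})


def make_genotypes(dosages, chrom="1", spacing=100, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage list of lists."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_ind = dosages.shape
    if ids is None:
        ids = [f"s{i}" for i in range(n_ind)]
    sites = [Site(chrom, (i + 1) * spacing, "A", "G") for i in range(n_sites)]
    return GenotypeMatrix(sites=sites, dosages=dosages, individual_ids=ids)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small simulated dataset written to disk once per session."""
    cfg = SimulationConfig(seed=1, chrom_length=2_000_000,
                           sweep_spans=(), n_cnv_regions=20, diff_cnv_indices=(5,))
    out = tmp_path_factory.mktemp("fixture")
    bundle = simulate_bundle(cfg)
    paths = write_fixture(bundle, str(out), force=True)
    return paths


@pytest.fixture(scope="session")
def default_bundle():
    """The full default-scale simulation (10 Mb, 5 sweeps, 200 CNVs)."""
    return simulate_bundle(SimulationConfig(seed=1))
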