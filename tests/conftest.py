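import pytest

import introscan as I
from introscan.simulate import polarized_tables


@pytest.fixture(scope="session")
def quartet():
    return I.QuartetConfig("P1", "P2", "P3", "O")


@pytest.fixture(scope="session")
def default_sim():
    """The reference simulation: 1 Mb, ten planted 5-kb P3→P2 tracts, seed 1."""
    return I.simulate(I.default_config(seed=1))


@pytest.fixture(scope="session")
def default_tables(default_sim):
    return polarized_tables(default_sim)


@pytest.fixture(scope="session")
def default_scan(default_tables):
    return I.run_scan(default_tables, I.WindowSpec(5_000))


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A small simulation written to disk (FASTA/VCF/BED/GFF/manifest)."""
    out = tmp_path_factory.mktemp("smallsim")
    cfg = I.SimConfig(
        scaffold_lengths={"sc_1": 20_000},
        tracts=[I.Tract("sc_1", 5_000, 8_000)],
        seed=7,
    )
    result = I.simulate(cfg, out_dir=out)
    return out, result


def intervals_overlap(a, b):
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


@pytest.fixture(scope="session")
def overlap():
    return intervals_overlap
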