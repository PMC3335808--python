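import pytest

import dgetag as d


@pytest.fixture(scope="session")
def ref50():
    return d.generate_reference(50, (200, 600), seed=11)


@pytest.fixture(scope="session")
def truth50(ref50):
    return d.simulate_expression_profiles(ref50, de_fraction=0.3, fold=4.0,
                                          base_mean=100.0, seed=12)


@pytest.fixture(scope="session")
def sim_clean_0h(ref50, truth50):
    """Error- and contamination-free library at t-0."""
    cfg = d.ReadSimConfig(depth=30_000, seed=5)
    return d.simulate_tag_library(ref50, truth50, cfg, library="0h")


@pytest.fixture(scope="session")
def clean_lib_0h(sim_clean_0h):
    return d.clean_reads(sim_clean_0h.reads, d.ADAPTOR_3P, label="0h")


@pytest.fixture(scope="session")
def db50(ref50):
    return d.build_virtual_tag_db(ref50)


@pytest.fixture(scope="session")
def gene_stubs():
    """Cheap sequence-free genes for count-level simulations."""
    return [d.ReferenceGene(gene_id=f"g{i:04d}", sequence="") for i in range(2000)]
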