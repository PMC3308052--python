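import pytest

from panelseeker import SimulationConfig


@pytest.fixture
def small_cfg():
    """A scaled-down study configuration used where runtime matters.

    The cohort structure (11 probands, variant rates, depth model) matches the
    defaults; only the panel is smaller.
    """
    return SimulationConfig(
        seed=1,
        n_genes=12,
        exons_per_gene=(4, 10),
        exon_length=(80, 250),
    )
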