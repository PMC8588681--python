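import pytest

from mitoscreen.simulate import (SimConfig, build_recipient_genome,
                                 simulate_reference_set)


@pytest.fixture(scope="session")
def small_panel_bundle():
    """A modest recipient with one direct repeat pair, shared across tests."""
    cfg = SimConfig(seed=11, genome_length_bp=14000, n_genes=6,
                    repeat_spec=[(800, 95.0, 2)],
                    recomb_fraction=0.30, spanning_reads_per_repeat=200,
                    n_long_reads=0)
    panel = simulate_reference_set(cfg)
    genome, truth = build_recipient_genome(cfg, panel)
    return cfg, panel, genome, truth


@pytest.fixture(scope="session")
def structured_bundle():
    """A recipient with MTPT, HGT tract, missing gene, split gene and edits."""
    cfg = SimConfig(seed=5, genome_length_bp=16000, n_genes=8,
                    repeat_spec=[(600, 92.0, 2, "inverted")],
                    mtpt_spec=[("self_plastome", 300)],
                    hgt_spec=[("Order_3", 800, False)],
                    missing_genes=["cox2"],
                    nuclear_copy_spec=[("cox2", 72.0, True),
                                       ("cox2", 0.0, False)][:1],
                    transsplice_gene="ccmFc", n_edit_sites=8,
                    transcript_depth=40)
    panel = simulate_reference_set(cfg)
    genome, truth = build_recipient_genome(cfg, panel)
    return cfg, panel, genome, truth
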