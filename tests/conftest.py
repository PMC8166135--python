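import pytest

from nlrmap.simulate import MutationConfig, PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def clean_panel():
    """Small 3-accession panel with zero mutation (identity panel)."""
    cfg = PanelConfig(n_accessions=3, n_chromosomes=1,
                      chromosome_length=260_000, n_clusters=3,
                      genes_per_cluster=(3, 4),
                      subgroup_labels=("G1", "G2", "G8"), seed=11)
    null = MutationConfig(snv_rate=0.0, small_indel_rate=0.0)
    return simulate_panel(cfg, null, seed=11)


@pytest.fixture(scope="session")
def mutated_panel():
    """Panel with planted gene-level events but no background noise."""
    cfg = PanelConfig(n_accessions=3, n_chromosomes=1,
                      chromosome_length=300_000, n_clusters=3,
                      genes_per_cluster=(4, 5),
                      subgroup_labels=("G1", "G2"), seed=23)
    mcfg = MutationConfig(snv_rate=0.0, small_indel_rate=0.0,
                          gene_deletion_prob=0.15,
                          gene_duplication_prob=0.2,
                          large_insertion_prob=0.15,
                          premature_stop_prob=0.25)
    return simulate_panel(cfg, mcfg, seed=23)
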