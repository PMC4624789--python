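"""mitofounder: maternal-lineage phylogeography from mtDNA haplotypes.

From control-region (HVS-I) or complete-mitogenome haplotypes to
median-joining networks, haplogroup frequency and diversity summaries,
rho-statistic coalescence dating, and source-sink founder analysis with
probabilistic migration-time allocation — plus a ground-truth simulator
so every stage can be validated end to end.
"""

from importlib.resources import files as _files

from .haplotype_io import (
    BUNDLED_MOTIF_TABLE,
    DEFAULT_ASSAY_TABLE,
    FULL_RANGE,
    HVS1_RANGE,
    FilterPolicy,
    HaploFreqTable,
    Haplotype,
    HaplotypeError,
    VariantCall,
    VariantKind,
    assign_haplogroup_motif,
    classify_diagnostic_snp,
    filter_positions,
    format_variant_string,
    haplotype_from_sequence,
    parse_variant_string,
    read_freq_table,
    read_haplotype_table,
    synthetic_reference,
    write_haplotype_table,
)
from .popstats import (
    DiversitySummary,
    diversity_summary,
    frequency_table,
    fst_permutation,
    mnpd,
    pairwise_differences,
)
from .mj_network import (
    HaploNetwork,
    NetworkNode,
    build_mj_network,
    condense,
    write_edge_list,
    write_graphml,
)
from .rho_dating import (
    CLOCKS,
    ClockSpec,
    ClusterTree,
    parse_newick_counts,
    rho,
    rho_sigma,
    rho_to_age,
    site_class_filter,
    tree_from_paths,
)
from .founder_analysis import (
    DEFAULT_EPOCHS,
    EpochModel,
    FounderCluster,
    MigrationScan,
    compare_sink_allocations,
    default_grid,
    identify_founders,
    partition_epochs,
    reciprocal_fa,
    scan_migration_times,
)
from .synthetic_data import (
    SimConfig,
    SimResult,
    founders_from_truth,
    simulate_source_genealogy,
    simulate_source_sink,
    sprinkle_mutations,
)

__version__ = "0.1.0"


def load_andalusia_berber_counts() -> HaploFreqTable:
    """The bundled African-lineage haplogroup count table for the two
    Andalusian provinces (Huelva, Granada) and three Moroccan Berber
    populations (Asni, Bouhria, Figuig)."""
    path = _files("mitofounder").joinpath("data/andalusia_berber_counts.tsv")
    return read_freq_table(str(path))
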