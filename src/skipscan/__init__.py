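"""skipscan: de novo exon-skipping detection from splicing-aware RNA-seq
alignments via a splice-site link graph, with two-isoform Bayesian ψ
estimation, maximum-entropy splice-site strength/competition scoring, and
splice-site-flanking signal/motif profiling."""

from .io_alignments import (
    Junction,
    CoverageTrack,
    ReadFilterConfig,
    load_alignments,
    write_junction_bed,
)
from .splice_graph import (
    SpliceSite,
    IntronEdge,
    ExonEdge,
    SpliceGraph,
    GraphConfig,
    build_nodes,
    orient_junction,
    orient_junctions,
    add_intron_edges,
    add_exon_edges,
    build_graph,
)
from .event_scanner import (
    SkippingEvent,
    scan_skipping_events,
    deduplicate_events,
    events_to_table,
)
from .psi_model import (
    IsoformCounts,
    PsiEstimate,
    count_isoform_reads,
    effective_positions,
    estimate_psi,
    classify_event,
    classify_psi,
    estimate_events,
)
from .splice_strength import (
    SiteSequence,
    MaxEntModel,
    CompetitionScore,
    extract_site_sequences,
    train_maxent,
    score_site,
    score_event,
    competition_score,
    compare_site_strengths,
    mann_whitney,
)
from .region_profiles import (
    BoundarySegment,
    DensityProfile,
    event_segments,
    tag_density,
    zscore_heat,
    motif_enrichment,
)
from .synthetic_data import (
    LocusSpec,
    SimulatedDataset,
    simulate_locus,
    simulate_dataset,
    sample_training_sites,
    sample_decoys,
)

__version__ = "0.1.0"


def detect_events(alignment_path, genome=None, filter_cfg=None, graph_cfg=None):
    """One-call pipeline: alignments → splice graph → skipping events.

    Returns (events, junctions, graph).  ``genome`` is any mapping
    chrom → sequence (pyfaidx.Fasta or dict); without it, junction strands
    stay 'unknown'.
    """
    junctions, coverage, _stats = load_alignments(alignment_path, filter_cfg)
    cfg = graph_cfg or GraphConfig()
    if genome is not None:
        cfg.genome = genome
    graph = build_graph(junctions, coverage, cfg)
    events = scan_skipping_events(graph)
    return events, junctions, graph
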