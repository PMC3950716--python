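"""Splice-site link graph.

Nodes are splice sites (exon/intron boundaries) inferred from junction
evidence.  Two edge classes connect them:

* intron ("dotted") edges — supported by spliced reads; kept only when the
  junction support reaches ``min_junction_support`` (default 8);
* exon ("solid") edges — spans between adjacent splice sites whose mean
  constitutive-read depth is at least ``min_exon_signal_ratio`` (default 3.0)
  times the larger of the two flanking segments' mean depths.

Junction orientation uses the GT–AG consensus rule: an intron whose genomic
sequence starts ``GT`` and ends ``AG`` is on the '+' strand; the
reverse-complement pattern (``CT .. AC`` on the forward strand) marks '−'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_alignments import CoverageTrack, Junction

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class SpliceSite:
    """A splice boundary node.

    ``pos`` is the 0-based genomic coordinate of the boundary: for a donor,
    the first intronic base; for an acceptor, the first exonic base after the
    intron (both in genomic coordinates, regardless of strand).
    """

    chrom: str
    pos: int
    kind: str  # donor | acceptor
    strand: str  # + | - | unknown

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("splice-site pos must be >= 0")
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"invalid kind {self.kind!r}")


@dataclass(frozen=True)
class IntronEdge:
    """Dotted edge: an intron gap with junction-read support."""

    donor: SpliceSite
    acceptor: SpliceSite
    support: int
    canonical: bool

    @property
    def left_pos(self) -> int:
        return min(self.donor.pos, self.acceptor.pos)

    @property
    def right_pos(self) -> int:
        return max(self.donor.pos, self.acceptor.pos)

    @property
    def chrom(self) -> str:
        return self.donor.chrom

    @property
    def strand(self) -> str:
        return self.donor.strand


@dataclass(frozen=True)
class ExonEdge:
    """Solid edge: a putative exon between two adjacent splice sites."""

    left: SpliceSite
    right: SpliceSite
    mean_depth: float
    flank_ratio: float

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def left_pos(self) -> int:
        return self.left.pos

    @property
    def right_pos(self) -> int:
        return self.right.pos


@dataclass
class GraphConfig:
    min_junction_support: int = 8
    min_exon_signal_ratio: float = 3.0
    max_exon_length: int = 5000
    genome: object | None = None  # mapping chrom -> sequence (e.g. pyfaidx.Fasta)

    def __post_init__(self) -> None:
        if self.min_junction_support < 1:
            raise ValueError("min_junction_support must be >= 1")
        if self.min_exon_signal_ratio <= 1:
            raise ValueError("min_exon_signal_ratio must be > 1")


@dataclass
class SpliceGraph:
    nodes: set[SpliceSite] = field(default_factory=set)
    intron_edges: list[IntronEdge] = field(default_factory=list)
    exon_edges: list[ExonEdge] = field(default_factory=list)

    def node_positions(self, chrom: str) -> list[int]:
        return sorted({n.pos for n in self.nodes if n.chrom == chrom})

    def chroms(self) -> list[str]:
        return sorted({n.chrom for n in self.nodes})


def _genome_slice(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[start:end) as an upper-case string from mapping-like
    genome handles (pyfaidx.Fasta, dict of str)."""
    seq = genome[chrom]
    sub = seq[start:end]
    return str(sub).upper()


def orient_junction(j: Junction, genome) -> str:
    """Strand call from the GT–AG consensus.

    '+' when the intron reads GT..AG on the forward strand, '−' when it reads
    CT..AC (the reverse-complement pattern), 'unknown' otherwise or when no
    genome is supplied.
    """
    if genome is None:
        return "unknown"
    if j.intron_end - j.intron_start < 4:
        return "unknown"
    chrom_len = len(genome[j.chrom])
    if j.intron_start < 0 or j.intron_end > chrom_len:
        raise IndexError(
            f"junction {j.chrom}:{j.intron_start}-{j.intron_end} outside "
            f"genome bounds (chrom length {chrom_len})"
        )
    head = _genome_slice(genome, j.chrom, j.intron_start, j.intron_start + 2)
    tail = _genome_slice(genome, j.chrom, j.intron_end - 2, j.intron_end)
    fwd = head == "GT" and tail == "AG"
    rev = head == "CT" and tail == "AC"
    if fwd and not rev:
        return "+"
    if rev and not fwd:
        return "-"
    return "unknown"


def orient_junctions(junctions: list[Junction], genome) -> list[Junction]:
    return [j.with_strand(orient_junction(j, genome)) for j in junctions]


def _junction_sites(j: Junction) -> tuple[SpliceSite, SpliceSite]:
    """Donor and acceptor nodes of a junction.

    On '+' the donor is at the intron start and the acceptor at the intron
    end; on '−' the roles are swapped.  'unknown' strand is laid out as '+'.
    """
    left_kind, right_kind = (
        ("acceptor", "donor") if j.strand == "-" else ("donor", "acceptor")
    )
    left = SpliceSite(j.chrom, j.intron_start, left_kind, j.strand)
    right = SpliceSite(j.chrom, j.intron_end, right_kind, j.strand)
    if j.strand == "-":
        return right, left  # donor first
    return left, right


def build_nodes(junctions: list[Junction], cfg: GraphConfig | None = None) -> set[SpliceSite]:
    """One node per distinct (chrom, pos, kind, strand) among junction ends."""
    nodes: set[SpliceSite] = set()
    for j in junctions:
        donor, acceptor = _junction_sites(j)
        nodes.add(donor)
        nodes.add(acceptor)
    return nodes


def add_intron_edges(
    nodes: set[SpliceSite], junctions: list[Junction], cfg: GraphConfig
) -> list[IntronEdge]:
    """Dotted edges for junctions whose support meets the threshold.

    The threshold is met at exactly ``min_junction_support`` (support >= 8
    under the default), keeping the printed default meaningful.
    """
    edges = []
    for j in sorted(junctions):
        if j.support < cfg.min_junction_support:
            continue
        donor, acceptor = _junction_sites(j)
        if donor not in nodes or acceptor not in nodes:
            continue
        canonical = j.strand in ("+", "-")
        edges.append(IntronEdge(donor, acceptor, j.support, canonical))
    return edges


def _sites_by_pos(nodes: set[SpliceSite]) -> dict[tuple[str, int], list[SpliceSite]]:
    index: dict[tuple[str, int], list[SpliceSite]] = {}
    for n in nodes:
        index.setdefault((n.chrom, n.pos), []).append(n)
    for v in index.values():
        v.sort()
    return index


def add_exon_edges(
    nodes: set[SpliceSite], coverage: CoverageTrack, cfg: GraphConfig
) -> list[ExonEdge]:
    """Solid edges between adjacent splice-site coordinates.

    For each segment between adjacent node positions the mean constitutive
    depth is compared against the larger of the two flanking segments' means
    (terminal segments use the single available flank).  A segment with zero
    background and positive signal has ratio +inf and is accepted.  Segments
    longer than ``max_exon_length`` are never called exons.  Plausibility of
    donor/acceptor roles at the segment ends is deliberately not enforced
    here — the event scan is the strict phase.
    """
    edges: list[ExonEdge] = []
    site_index = _sites_by_pos(nodes)
    chroms = sorted({n.chrom for n in nodes})
    for chrom in chroms:
        positions = sorted({n.pos for n in nodes if n.chrom == chrom})
        if len(positions) < 2:
            continue
        seg_bounds = list(zip(positions[:-1], positions[1:]))
        means = [coverage.mean_depth(chrom, s, e) for s, e in seg_bounds]
        for i, (s, e) in enumerate(seg_bounds):
            if e - s > cfg.max_exon_length:
                continue
            flanks = []
            if i > 0:
                flanks.append(means[i - 1])
            if i < len(seg_bounds) - 1:
                flanks.append(means[i + 1])
            background = max(flanks) if flanks else 0.0
            signal = means[i]
            if signal <= 0:
                continue
            ratio = signal / background if background > 0 else math.inf
            if ratio < cfg.min_exon_signal_ratio:
                continue
            for left in site_index[(chrom, s)]:
                for right in site_index[(chrom, e)]:
                    if (
                        left.strand != right.strand
                        and "unknown" not in (left.strand, right.strand)
                    ):
                        continue  # mixed-strand loci never share exon edges
                    edges.append(ExonEdge(left, right, signal, ratio))
    return edges


def build_graph(
    junctions: list[Junction],
    coverage: CoverageTrack,
    cfg: GraphConfig | None = None,
) -> SpliceGraph:
    """Full graph construction: orient, build nodes, add both edge classes."""
    cfg = cfg or GraphConfig()
    if cfg.genome is not None:
        junctions = orient_junctions(junctions, cfg.genome)
    nodes = build_nodes(junctions, cfg)
    intron_edges = add_intron_edges(nodes, junctions, cfg)
    exon_edges = add_exon_edges(nodes, coverage, cfg)
    return SpliceGraph(nodes=nodes, intron_edges=intron_edges, exon_edges=exon_edges)
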