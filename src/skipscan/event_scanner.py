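"""Enumerate exon-skipping events from the splice graph.

An exon-skipping event is a six-node sub-graph p1 < p2 < ... < p6 on one
chromosome with

* solid (exon) edges  (p1,p2), (p3,p4), (p5,p6)  — the tri-exon pattern,
* dotted (intron) edges (p2,p3) and (p4,p5)      — the two flanking introns,
* a dotted skip edge (p2,p5)                     — upstream and downstream
  exons joined directly, excluding the middle exon.

Sub-graphs missing any required edge are ignored.  Other alternative-splicing
modes (intron retention, alternative 5'/3' sites) never match this pattern
and are not emitted.  Only single-middle-exon patterns are reported; loci
where two consecutive exons are skipped together surface as separate
single-exon candidates at best.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

from .splice_graph import SpliceGraph, SpliceSite


@dataclass(frozen=True)
class SkippingEvent:
    """A tri-exon skipping site.

    Exons are genomic 0-based half-open intervals in *transcription* order:
    ``up_exon`` is the first exon transcribed, so on '−' strand events it is
    the genomically rightmost of the three.  The four named splice sites
    follow the upstream/downstream-intron nomenclature: upI_ss5/upI_ss3 are
    the donor/acceptor of the intron between the upstream and middle exon,
    dnI_ss5/dnI_ss3 of the intron between the middle and downstream exon.
    """

    chrom: str
    strand: str
    up_exon: tuple[int, int]
    mid_exon: tuple[int, int]
    dn_exon: tuple[int, int]
    upI_ss5: SpliceSite
    upI_ss3: SpliceSite
    dnI_ss5: SpliceSite
    dnI_ss3: SpliceSite
    inclusion_junction_support: tuple[int, int]
    skip_junction_support: int

    @property
    def exons_genomic(self) -> tuple[tuple[int, int], ...]:
        """The three exons in genomic (left-to-right) order."""
        return tuple(sorted((self.up_exon, self.mid_exon, self.dn_exon)))

    @property
    def boundaries(self) -> tuple[int, ...]:
        """The six node coordinates p1..p6 in genomic order."""
        return tuple(p for exon in self.exons_genomic for p in exon)

    @property
    def upstream_intron(self) -> tuple[int, int]:
        """Genomic interval of the intron between up and mid exon."""
        a, b = sorted((self.up_exon, self.mid_exon))
        return (a[1], b[0])

    @property
    def downstream_intron(self) -> tuple[int, int]:
        a, b = sorted((self.mid_exon, self.dn_exon))
        return (a[1], b[0])

    @property
    def skip_intron(self) -> tuple[int, int]:
        a, b = sorted((self.up_exon, self.dn_exon))
        return (a[1], b[0])

    @property
    def event_id(self) -> str:
        p = self.boundaries
        return f"{self.chrom}:{p[0]}-{p[5]}:{self.strand}:mid{p[2]}-{p[3]}"


def _combine_strands(strands: list[str]) -> str | None:
    """Consensus strand over edges; None when '+' and '−' conflict."""
    seen = {s for s in strands if s != "unknown"}
    if len(seen) > 1:
        return None
    return seen.pop() if seen else "unknown"


def _make_event(
    chrom: str,
    p: tuple[int, int, int, int, int, int],
    strand: str,
    sup_left: int,
    sup_right: int,
    sup_skip: int,
) -> SkippingEvent:
    p1, p2, p3, p4, p5, p6 = p
    # Genomic-left intron is (p2,p3), right is (p4,p5).  In transcription
    # order, '+' reads left-to-right; '−' is mirrored.  'unknown' strand
    # events use the '+' layout, flagged by their strand field.
    if strand == "-":
        up, mid, dn = (p5, p6), (p3, p4), (p1, p2)
        upI_ss5 = SpliceSite(chrom, p5, "donor", strand)
        upI_ss3 = SpliceSite(chrom, p4, "acceptor", strand)
        dnI_ss5 = SpliceSite(chrom, p3, "donor", strand)
        dnI_ss3 = SpliceSite(chrom, p2, "acceptor", strand)
        inc_support = (sup_right, sup_left)
    else:
        up, mid, dn = (p1, p2), (p3, p4), (p5, p6)
        upI_ss5 = SpliceSite(chrom, p2, "donor", strand)
        upI_ss3 = SpliceSite(chrom, p3, "acceptor", strand)
        dnI_ss5 = SpliceSite(chrom, p4, "donor", strand)
        dnI_ss3 = SpliceSite(chrom, p5, "acceptor", strand)
        inc_support = (sup_left, sup_right)
    return SkippingEvent(
        chrom=chrom,
        strand=strand,
        up_exon=up,
        mid_exon=mid,
        dn_exon=dn,
        upI_ss5=upI_ss5,
        upI_ss3=upI_ss3,
        dnI_ss5=dnI_ss5,
        dnI_ss3=dnI_ss3,
        inclusion_junction_support=inc_support,
        skip_junction_support=sup_skip,
    )


def scan_skipping_events(g: SpliceGraph) -> list[SkippingEvent]:
    """Find all tri-exon + skip-link patterns in the graph.

    Enumeration is seeded from candidate skip edges rather than all node
    sextets: for each intron edge (a, b) we look for intron edges (a, c)
    with c < b and (d, b) with c < d < b, then require the three exon edges.
    This is equivalent to exhaustive C(n, 6) enumeration (a tested property),
    just cheaper.  When several solid edges reach the outer boundaries the
    shortest flanking exon is reported.
    """
    by_chrom_intron: dict[str, dict[tuple[int, int], object]] = defaultdict(dict)
    for e in g.intron_edges:
        by_chrom_intron[e.chrom][(e.left_pos, e.right_pos)] = e
    # exon edges keyed by right and by left position
    exon_by_right: dict[str, dict[int, list]] = defaultdict(lambda: defaultdict(list))
    exon_by_left: dict[str, dict[int, list]] = defaultdict(lambda: defaultdict(list))
    for e in g.exon_edges:
        exon_by_right[e.chrom][e.right_pos].append(e)
        exon_by_left[e.chrom][e.left_pos].append(e)

    events: list[SkippingEvent] = []
    for chrom, introns in sorted(by_chrom_intron.items()):
        keys = sorted(introns)
        by_left = defaultdict(list)
        by_right = defaultdict(list)
        for a, b in keys:
            by_left[a].append(b)
            by_right[b].append(a)
        for a, b in keys:  # candidate skip edge
            skip_edge = introns[(a, b)]
            for c in by_left[a]:
                if not (a < c < b):
                    continue
                left_edge = introns[(a, c)]
                for d in by_right[b]:
                    if not (c < d < b):
                        continue
                    right_edge = introns[(d, b)]
                    strand = _combine_strands(
                        [left_edge.strand, right_edge.strand, skip_edge.strand]
                    )
                    if strand is None:
                        continue
                    # tri-exon solid edges: (p1,a), (c,d), (b,p6)
                    mids = [
                        e
                        for e in exon_by_left[chrom][c]
                        if e.right_pos == d and _strand_ok(e, strand)
                    ]
                    ups = [
                        e
                        for e in exon_by_right[chrom][a]
                        if e.left_pos < a and _strand_ok(e, strand)
                    ]
                    dns = [
                        e
                        for e in exon_by_left[chrom][b]
                        if e.right_pos > b and _strand_ok(e, strand)
                    ]
                    if not (mids and ups and dns):
                        continue
                    p1 = max(e.left_pos for e in ups)  # shortest upstream exon
                    p6 = min(e.right_pos for e in dns)  # shortest downstream exon
                    events.append(
                        _make_event(
                            chrom,
                            (p1, a, c, d, b, p6),
                            strand,
                            left_edge.support,
                            right_edge.support,
                            skip_edge.support,
                        )
                    )
    return deduplicate_events(events)


def _strand_ok(edge, strand: str) -> bool:
    s = {edge.left.strand, edge.right.strand} - {"unknown"}
    return not s or (strand in s) or strand == "unknown"


def deduplicate_events(events: list[SkippingEvent]) -> list[SkippingEvent]:
    """Collapse events identical in all six boundary coordinates; sort by
    (chrom, leftmost exon start)."""
    seen: dict[tuple, SkippingEvent] = {}
    for ev in events:
        key = (ev.chrom, ev.strand, ev.boundaries)
        if key not in seen:
            seen[key] = ev
    return sorted(
        seen.values(), key=lambda e: (e.chrom, e.boundaries, e.strand)
    )


# ---------------------------------------------------------------------------
# export


def events_to_table(events: list[SkippingEvent]):
    """Event list as a pandas DataFrame (one row per event)."""
    import pandas as pd

    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "up_exon_start": ev.up_exon[0],
                "up_exon_end": ev.up_exon[1],
                "mid_exon_start": ev.mid_exon[0],
                "mid_exon_end": ev.mid_exon[1],
                "dn_exon_start": ev.dn_exon[0],
                "dn_exon_end": ev.dn_exon[1],
                "up_mid_support": ev.inclusion_junction_support[0],
                "mid_dn_support": ev.inclusion_junction_support[1],
                "skip_support": ev.skip_junction_support,
            }
        )
    cols = [
        "event_id", "chrom", "strand",
        "up_exon_start", "up_exon_end", "mid_exon_start", "mid_exon_end",
        "dn_exon_start", "dn_exon_end",
        "up_mid_support", "mid_dn_support", "skip_support",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_events_bed12(events: list[SkippingEvent], path) -> None:
    """Two BED12 lines per event: the inclusion and the skipping isoform."""
    with open(path, "w") as fh:
        for ev in events:
            exons = ev.exons_genomic
            strand = ev.strand if ev.strand in "+-" else "."
            start, end = exons[0][0], exons[-1][1]
            for label, blocks in (
                ("inclusion", exons),
                ("skipping", (exons[0], exons[2])),
            ):
                sizes = ",".join(str(e - s) for s, e in blocks)
                starts = ",".join(str(s - start) for s, e in blocks)
                fh.write(
                    f"{ev.chrom}\t{start}\t{end}\t{ev.event_id}:{label}\t0\t"
                    f"{strand}\t{start}\t{end}\t0\t{len(blocks)}\t{sizes},\t{starts},\n"
                )


def write_events_gff3(events: list[SkippingEvent], path) -> None:
    """Gene/mRNA/exon GFF3 triple per event (two mRNAs per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            exons = ev.exons_genomic
            strand = ev.strand if ev.strand in "+-" else "."
            start, end = exons[0][0] + 1, exons[-1][1]  # GFF is 1-based
            gid = ev.event_id
            fh.write(
                f"{ev.chrom}\tskipscan\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid};Name={gid}\n"
            )
            for iso, blocks in (
                ("A", exons),
                ("B", (exons[0], exons[2])),
            ):
                mid = f"{gid}.{iso}"
                fh.write(
                    f"{ev.chrom}\tskipscan\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={mid};Parent={gid}\n"
                )
                for k, (s, e) in enumerate(blocks, 1):
                    fh.write(
                        f"{ev.chrom}\tskipscan\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f"ID={mid}.e{k};Parent={mid}\n"
                    )
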