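"""Synthetic tri-exon loci with planted skipping events at known true ψ.

Each locus is a five-exon gene: two flanking constitutive exons, then the
tri-exon skipping site (upstream, middle ["cassette"], downstream exon).
Two isoforms are mixed at a known true ψ: the inclusion isoform carries all
five exons, the skipping isoform lacks the middle one.  The two flanking
introns are constitutive (present in both isoforms), which guarantees the
outer boundaries of the tri-exon site appear as splice-site nodes in the
graph, exactly as in real multi-exon genes.

Reads are sampled uniformly over positions of the chosen isoform (a read's
isoform is drawn with probability proportional to ψ × its start-position
count, the standard uniform-fragment generative model) and emitted as SAM
records with N-operator CIGARs mapped back to genomic coordinates.  All
randomness flows from a single seed; identical seeds give byte-identical
output files.

Splice-site windows carry planted consensus sequences: ``strong`` sites use
a high-consensus motif, ``weak`` sites keep the GT/AG core but degrade the
remaining consensus positions.  Sequencing errors are off by default (the
detector consumes alignments, not raw reads); an error-rate knob exists for
robustness experiments.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .splice_graph import revcomp

CHROM = "chrSIM"

# planted splice-site motifs (transcription orientation)
STRONG_DONOR = "CAGGTAAGT"  # 3 exonic + GT + 4 intronic consensus
WEAK_DONOR = "TATGTCGCA"
STRONG_ACCEPTOR = "TTTTCTTTTCTTTCTTACAG" + "GTT"  # 20 intronic (pyrimidine tract + AG) + 3 exonic
WEAK_ACCEPTOR = "GAAGAAGGAAGGAAGAGAAG" + "TAA"

# positional sampling profiles for training-site generation: probability of
# the consensus base at each position (consensus bases from the motifs above)
_DONOR_CONS_P = np.array([0.35, 0.6, 0.8, 0.99, 0.99, 0.7, 0.7, 0.8, 0.5])
_ACCEPTOR_CONS_P = np.concatenate(
    [np.full(18, 0.55), [0.99, 0.99], [0.5, 0.3, 0.3]]
)

SITE_NAMES = ("upI_ss5", "upI_ss3", "dnI_ss5", "dnI_ss3")


@dataclass
class LocusSpec:
    """One planted locus.  Lengths are bases; depth is mean read coverage."""

    exons: tuple[int, int, int] = (150, 120, 150)  # up, mid, dn
    introns: tuple[int, int] = (300, 300)  # up, dn
    true_psi: float = 0.5
    depth: float = 50.0
    read_length: int = 100
    strand: str = "+"
    site_quality: dict = field(
        default_factory=lambda: {s: "strong" for s in SITE_NAMES}
    )
    flank_exon: int = 200
    flank_intron: int = 300
    error_rate: float = 0.0
    is_control: bool = False  # control loci are pure-inclusion (ψ = 1)

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_psi <= 1.0:
            raise ValueError("true_psi must be in [0, 1]")
        if self.exons[1] < 1:
            raise ValueError("middle exon must be >= 1 base")
        if min(self.introns) < 30 or self.flank_intron < 30:
            raise ValueError("introns must be >= 30 bases (site windows need room)")
        if min(self.exons[0], self.exons[2], self.flank_exon) < 23:
            raise ValueError("outer exons must be >= 23 bases")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.is_control:
            self.true_psi = 1.0


@dataclass
class SamRead:
    qname: str
    flag: int
    pos: int  # 0-based genomic start
    cigar: str
    seq: str

    def to_sam(self, chrom: str = CHROM) -> str:
        return (
            f"{self.qname}\t{self.flag}\t{chrom}\t{self.pos + 1}\t60\t"
            f"{self.cigar}\t*\t0\t0\t{self.seq}\t{'I' * len(self.seq)}\tNH:i:1"
        )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _spacer_seq(rng: np.random.Generator, n: int) -> str:
    """Spacer sequence with no GT or AG dinucleotide anywhere, so spacers can
    never fake a canonical intron boundary."""
    s = list(_random_seq(rng, n))
    for i in range(1, len(s)):
        if (s[i - 1] == "G" and s[i] == "T") or (s[i - 1] == "A" and s[i] == "G"):
            s[i] = "C"  # C never completes GT or AG with any neighbour
    return "".join(s)


def _plant(seq: list[str], start: int, motif: str) -> None:
    seq[start : start + len(motif)] = list(motif)


def _locus_layout(spec: LocusSpec) -> dict:
    """Genomic offsets (relative to locus start) of the five exons."""
    e0 = (0, spec.flank_exon)
    i0 = (e0[1], e0[1] + spec.flank_intron)
    e1 = (i0[1], i0[1] + spec.exons[0])
    i1 = (e1[1], e1[1] + spec.introns[0])
    e2 = (i1[1], i1[1] + spec.exons[1])
    i2 = (e2[1], e2[1] + spec.introns[1])
    e3 = (i2[1], i2[1] + spec.exons[2])
    i3 = (e3[1], e3[1] + spec.flank_intron)
    e4 = (i3[1], i3[1] + spec.flank_exon)
    return {"exons": [e0, e1, e2, e3, e4], "introns": [i0, i1, i2, i3], "length": e4[1]}


def _site_motifs(spec: LocusSpec) -> dict[str, str]:
    def donor(q):
        return STRONG_DONOR if q == "strong" else WEAK_DONOR

    def acceptor(q):
        return STRONG_ACCEPTOR if q == "strong" else WEAK_ACCEPTOR

    q = spec.site_quality
    return {
        "upI_ss5": donor(q.get("upI_ss5", "strong")),
        "upI_ss3": acceptor(q.get("upI_ss3", "strong")),
        "dnI_ss5": donor(q.get("dnI_ss5", "strong")),
        "dnI_ss3": acceptor(q.get("dnI_ss3", "strong")),
    }


def _build_genome(spec: LocusSpec, rng: np.random.Generator) -> tuple[str, dict]:
    layout = _locus_layout(spec)
    seq = list(_random_seq(rng, layout["length"]))
    introns = layout["introns"]
    motifs = _site_motifs(spec)
    # constitutive flanking introns always carry strong sites; the named
    # tri-exon sites follow the spec's quality flags
    if spec.strand == "+":
        plan = [
            (introns[0], STRONG_DONOR, STRONG_ACCEPTOR),
            (introns[1], motifs["upI_ss5"], motifs["upI_ss3"]),
            (introns[2], motifs["dnI_ss5"], motifs["dnI_ss3"]),
            (introns[3], STRONG_DONOR, STRONG_ACCEPTOR),
        ]
        for (s, e), dn, ac in plan:
            _plant(seq, s - 3, dn)  # donor window genome[s-3 : s+6]
            _plant(seq, e - 20, ac)  # acceptor window genome[e-20 : e+3]
    else:
        # '-' strand: transcription right-to-left; the genomic-right boundary
        # of each intron is the donor.  Plant reverse-complemented motifs.
        plan = [
            (introns[0], STRONG_DONOR, STRONG_ACCEPTOR),
            (introns[1], motifs["dnI_ss5"], motifs["dnI_ss3"]),
            (introns[2], motifs["upI_ss5"], motifs["upI_ss3"]),
            (introns[3], STRONG_DONOR, STRONG_ACCEPTOR),
        ]
        for (s, e), dn, ac in plan:
            _plant(seq, e - 6, revcomp(dn))  # donor window genome[e-6 : e+3]
            _plant(seq, s - 3, revcomp(ac))  # acceptor window genome[s-3 : s+20]
    return "".join(seq), layout


def _isoform_chain(layout: dict, inclusion: bool) -> list[tuple[int, int]]:
    e = layout["exons"]
    return [e[0], e[1], e[2], e[3], e[4]] if inclusion else [e[0], e[1], e[3], e[4]]


def _read_blocks(chain: list[tuple[int, int]], start: int, read_length: int):
    """Genomic blocks covered by a read starting at transcript offset
    ``start``; blocks are (genomic_start, genomic_end) per exon touched."""
    blocks = []
    remaining = read_length
    offset = start
    for s, e in chain:
        span = e - s
        if offset >= span:
            offset -= span
            continue
        take = min(span - offset, remaining)
        blocks.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past isoform end")
    return blocks


def _blocks_to_cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def simulate_locus(
    spec: LocusSpec,
    rng: np.random.Generator | None = None,
    offset: int = 0,
    locus_id: str = "locus0",
) -> tuple[str, list[SamRead], dict]:
    """Build one locus: genome segment, reads, and the truth-table row.

    ``offset`` shifts all genomic coordinates (for embedding into a larger
    chromosome).  Reads carry NH:i:1 and map with N-CIGARs across introns.
    """
    rng = rng or np.random.default_rng(0)
    genome, layout = _build_genome(spec, rng)
    R = spec.read_length
    inc_chain = _isoform_chain(layout, True)
    skip_chain = _isoform_chain(layout, False)
    inc_len = sum(e - s for s, e in inc_chain)
    skip_len = sum(e - s for s, e in skip_chain)
    p_inc_positions = inc_len - R + 1
    p_skip_positions = skip_len - R + 1
    if min(p_inc_positions, p_skip_positions) < 1:
        raise ValueError("read_length longer than an isoform")
    psi = spec.true_psi
    w_inc = psi * p_inc_positions
    w_skip = (1.0 - psi) * p_skip_positions
    p_choose_inc = 1.0 if w_inc + w_skip == 0 else w_inc / (w_inc + w_skip)

    n_reads = int(round(spec.depth * inc_len / R))
    reads: list[SamRead] = []
    flag = 16 if spec.strand == "-" else 0
    for k in range(n_reads):
        inclusion = bool(rng.random() < p_choose_inc)
        chain = inc_chain if inclusion else skip_chain
        n_pos = p_inc_positions if inclusion else p_skip_positions
        x = int(rng.integers(0, n_pos))
        blocks = _read_blocks(chain, x, R)
        seq = "".join(genome[s:e] for s, e in blocks)
        if spec.error_rate > 0:
            seq = _mutate(seq, spec.error_rate, rng)
        reads.append(
            SamRead(
                qname=f"{locus_id}_r{k:06d}",
                flag=flag,
                pos=blocks[0][0] + offset,
                cigar=_blocks_to_cigar(blocks),
                seq=seq,
            )
        )

    e = layout["exons"]
    motifs = _site_motifs(spec)
    truth = {
        "locus_id": locus_id,
        "chrom": CHROM,
        "strand": spec.strand,
        "up_exon_start": e[1][0] + offset,
        "up_exon_end": e[1][1] + offset,
        "mid_exon_start": e[2][0] + offset,
        "mid_exon_end": e[2][1] + offset,
        "dn_exon_start": e[3][0] + offset,
        "dn_exon_end": e[3][1] + offset,
        "true_psi": spec.true_psi,
        "expected_group": (
            "IIDG" if spec.true_psi >= 0.7 else "SIDG" if spec.true_psi <= 0.3 else "intermediate"
        ),
        "is_control": spec.is_control,
        "n_reads": n_reads,
        **{f"seq_{k}": v for k, v in motifs.items()},
    }
    # on '-' strand the up/dn exons swap genomic sides (transcription order)
    if spec.strand == "-":
        truth.update(
            up_exon_start=e[3][0] + offset,
            up_exon_end=e[3][1] + offset,
            dn_exon_start=e[1][0] + offset,
            dn_exon_end=e[1][1] + offset,
        )
    return genome, reads, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        out[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(out)


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    reads: list[SamRead]
    truth: pd.DataFrame
    signal: list[tuple[str, int, int]] | None = None
    signal_library_size: int | None = None
    control_signal: list[tuple[str, int, int]] | None = None
    motif_hits: pd.DataFrame | None = None
    seed: int | None = None

    def write(self, out_dir) -> dict:
        """Write FASTA + SAM + truth TSV (+ optional BED/TSV) and a manifest."""
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        fasta = os.path.join(out_dir, "genome.fa")
        with open(fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths["genome"] = fasta
        sam = os.path.join(out_dir, "reads.sam")
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for chrom, seq in self.genome.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
            for r in self.reads:
                fh.write(r.to_sam() + "\n")
        paths["reads"] = sam
        truth_path = os.path.join(out_dir, "truth.tsv")
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        if self.signal is not None:
            bed = os.path.join(out_dir, "signal.bed")
            with open(bed, "w") as fh:
                for chrom, s, e in self.signal:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
            paths["signal"] = bed
        if self.motif_hits is not None:
            mh = os.path.join(out_dir, "motif_hits.tsv")
            self.motif_hits.to_csv(mh, sep="\t", index=False)
            paths["motif_hits"] = mh
        manifest = {
            "seed": self.seed,
            "n_loci": int(len(self.truth)),
            "paths": {k: os.path.basename(v) for k, v in paths.items()},
            "sha256": {
                k: hashlib.sha256(open(v, "rb").read()).hexdigest() for k, v in paths.items()
            },
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return paths


def simulate_dataset(
    n_events: int,
    true_psi=0.5,
    depth: float = 50.0,
    read_length: int = 100,
    seed: int = 0,
    n_controls: int = 0,
    spacer: int = 1200,
    weak_sites_in_low_psi: bool = False,
    motif_hit_effect: float | None = None,
    signal_effect: tuple[str, str, float] | None = None,
    strand: str = "+",
    locus_kwargs: dict | None = None,
) -> SimulatedDataset:
    """Concatenate ``n_events`` skipping loci (plus pure-inclusion controls)
    on one synthetic chromosome.

    ``true_psi`` may be a scalar, a sequence of length n_events, or a
    callable rng → ψ.  ``weak_sites_in_low_psi`` plants weak middle-flanking
    sites (dnI_ss5, upI_ss3) in loci with ψ ≤ 0.3.  ``motif_hit_effect``
    generates a motif-hit table with that multiplicative excess in SIDG
    dnI_ss5-intronic segments; ``signal_effect`` = (site:side, group, fold)
    generates a signal BED enriched in the given segment of the given group.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    locus_kwargs = dict(locus_kwargs or {})
    psis = []
    for i in range(n_events):
        if callable(true_psi):
            psis.append(float(true_psi(rng)))
        elif np.isscalar(true_psi):
            psis.append(float(true_psi))
        else:
            psis.append(float(true_psi[i]))

    chunks: list[str] = []
    reads: list[SamRead] = []
    truth_rows: list[dict] = []
    cursor = 0
    for i in range(n_events + n_controls):
        spacer_seq = _spacer_seq(rng, spacer)
        chunks.append(spacer_seq)
        cursor += len(spacer_seq)
        if i < n_events:
            psi = psis[i]
            quality = {s: "strong" for s in SITE_NAMES}
            if weak_sites_in_low_psi and psi <= 0.3:
                quality["dnI_ss5"] = "weak"
                quality["upI_ss3"] = "weak"
            spec = LocusSpec(
                true_psi=psi,
                depth=depth,
                read_length=read_length,
                strand=strand,
                site_quality=quality,
                **locus_kwargs,
            )
        else:
            spec = LocusSpec(
                depth=depth,
                read_length=read_length,
                strand=strand,
                is_control=True,
                **locus_kwargs,
            )
        locus_id = f"locus{i:04d}"
        genome_seg, locus_reads, truth = simulate_locus(
            spec, rng, offset=cursor, locus_id=locus_id
        )
        chunks.append(genome_seg)
        cursor += len(genome_seg)
        reads.extend(locus_reads)
        truth_rows.append(truth)
    chunks.append(_spacer_seq(rng, spacer))
    genome = {CHROM: "".join(chunks)}
    truth_df = pd.DataFrame(truth_rows)

    ds = SimulatedDataset(
        genome=genome, reads=reads, truth=truth_df, seed=seed
    )
    if motif_hit_effect is not None:
        ds.motif_hits = _planted_motif_hits(truth_df, rng, motif_hit_effect)
    if signal_effect is not None:
        sig, lib = _planted_signal(truth_df, rng, signal_effect)
        ds.signal = sig
        ds.signal_library_size = lib
    return ds


def _event_id_from_truth(row) -> str:
    p = sorted(
        [
            row["up_exon_start"], row["up_exon_end"],
            row["mid_exon_start"], row["mid_exon_end"],
            row["dn_exon_start"], row["dn_exon_end"],
        ]
    )
    return (
        f"{row['chrom']}:{p[0]}-{p[5]}:{row['strand']}:mid{p[2]}-{p[3]}"
    )


def _planted_motif_hits(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    effect: float,
    factors=("SF_A", "SF_B", "SF_C"),
    base_rate: float = 3.0,
) -> pd.DataFrame:
    """Poisson motif-hit counts per event × segment × factor; factor SF_A is
    boosted ``effect``-fold in SIDG dnI_ss5-intronic segments."""
    from .region_profiles import SEGMENT_NAMES

    rows = []
    for _, row in truth.iterrows():
        if row.get("is_control", False):
            continue
        eid = _event_id_from_truth(row)
        group = row["expected_group"]
        for factor in factors:
            for seg in SEGMENT_NAMES:
                lam = base_rate
                if factor == "SF_A" and seg == "dnI_ss5:intronic" and group == "SIDG":
                    lam *= effect
                rows.append(
                    {
                        "event_id": eid,
                        "factor": factor,
                        "segment": seg,
                        "count": int(rng.poisson(lam)),
                    }
                )
    return pd.DataFrame(rows)


def _planted_signal(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    effect: tuple[str, str, float],
    base_reads: int = 20,
    read_len: int = 36,
) -> tuple[list[tuple[str, int, int]], int]:
    """Synthetic ChIP-style interval reads: uniform background over each
    event span plus a fold-enrichment in one segment of one group."""
    from .region_profiles import event_segments

    seg_name, boosted_group, fold = effect
    intervals = []
    for _, row in truth.iterrows():
        if row.get("is_control", False):
            continue
        ev = truth_row_to_event(row)
        for seg in event_segments(ev):
            n = base_reads
            if seg.name == seg_name and row["expected_group"] == boosted_group:
                n = int(round(base_reads * fold))
            span = max(seg.length - read_len, 1)
            for _ in range(n):
                s = seg.start + int(rng.integers(0, span))
                intervals.append((row["chrom"], s, s + read_len))
    return intervals, len(intervals)


def truth_row_to_event(row):
    """Reconstruct a SkippingEvent from a truth-table row (exact planted
    coordinates; junction supports are not part of the truth)."""
    from .event_scanner import SkippingEvent
    from .splice_graph import SpliceSite

    chrom, strand = row["chrom"], row["strand"]
    up = (int(row["up_exon_start"]), int(row["up_exon_end"]))
    mid = (int(row["mid_exon_start"]), int(row["mid_exon_end"]))
    dn = (int(row["dn_exon_start"]), int(row["dn_exon_end"]))
    if strand == "-":
        sites = {
            "upI_ss5": SpliceSite(chrom, up[0], "donor", strand),
            "upI_ss3": SpliceSite(chrom, mid[1], "acceptor", strand),
            "dnI_ss5": SpliceSite(chrom, mid[0], "donor", strand),
            "dnI_ss3": SpliceSite(chrom, dn[1], "acceptor", strand),
        }
    else:
        sites = {
            "upI_ss5": SpliceSite(chrom, up[1], "donor", strand),
            "upI_ss3": SpliceSite(chrom, mid[0], "acceptor", strand),
            "dnI_ss5": SpliceSite(chrom, mid[1], "donor", strand),
            "dnI_ss3": SpliceSite(chrom, dn[0], "acceptor", strand),
        }
    return SkippingEvent(
        chrom=chrom,
        strand=strand,
        up_exon=up,
        mid_exon=mid,
        dn_exon=dn,
        inclusion_junction_support=(0, 0),
        skip_junction_support=0,
        **sites,
    )


def sample_training_sites(
    kind: str, n: int, rng: np.random.Generator
) -> list[str]:
    """Sample site sequences from a consensus-frequency profile — a stand-in
    training set (synthetic) for fitting splice-site models without any
    published parameter files."""
    if kind == "donor5":
        consensus, cons_p = STRONG_DONOR, _DONOR_CONS_P
    elif kind == "acceptor3":
        consensus, cons_p = STRONG_ACCEPTOR, _ACCEPTOR_CONS_P
    else:
        raise ValueError(f"unknown site kind {kind!r}")
    alphabet = "ACGT"
    out = []
    for _ in range(n):
        chars = []
        for j, c in enumerate(consensus):
            if rng.random() < cons_p[j]:
                chars.append(c)
            else:
                others = [x for x in alphabet if x != c]
                chars.append(others[int(rng.integers(0, 3))])
        out.append("".join(chars))
    return out


def sample_decoys(kind: str, n: int, rng: np.random.Generator) -> list[str]:
    length = 9 if kind == "donor5" else 23
    return [_random_seq(rng, length) for _ in range(n)]
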