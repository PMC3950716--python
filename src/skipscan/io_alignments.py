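"""Read splicing-aware alignments and split them into junction and coverage evidence.

Splicing-aware aligners encode introns as ``N`` operators in the CIGAR
string.  A record with one or more ``N`` operators is a *spliced read* and
contributes junction evidence; a record without one is a *constitutive read*
and contributes per-base coverage evidence.  Reads failing quality filters
(low mapping quality, too many ambiguous bases, multi-mapped) contribute to
neither.

All coordinates in this package are 0-based, half-open; the SAM 1-based
convention is converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

logger = logging.getLogger(__name__)

# CIGAR operator codes (pysam numeric convention)
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_N, _CIGAR_S, _CIGAR_H = 0, 1, 2, 3, 4, 5
_CIGAR_P, _CIGAR_EQ, _CIGAR_X = 6, 7, 8
_REF_CONSUMING = {_CIGAR_M, _CIGAR_D, _CIGAR_EQ, _CIGAR_X}
_QUERY_CONSUMING = {_CIGAR_M, _CIGAR_I, _CIGAR_S, _CIGAR_EQ, _CIGAR_X}
_SUPPORTED = _REF_CONSUMING | _QUERY_CONSUMING | {_CIGAR_N, _CIGAR_H}


@dataclass(frozen=True, order=True)
class Junction:
    """An intron gap observed in spliced reads.

    ``intron_start`` is the 0-based first intronic base; ``intron_end`` is the
    0-based exclusive end (the first base of the next exon).
    """

    chrom: str
    intron_start: int
    intron_end: int
    support: int = 1
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.intron_start < self.intron_end:
            raise ValueError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                "intron_start must be < intron_end"
            )
        if self.support < 1:
            raise ValueError("junction support must be >= 1")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def with_strand(self, strand: str) -> "Junction":
        return replace(self, strand=strand)


class CoverageTrack:
    """Sparse per-base depth of constitutive (non-spliced) alignments.

    Stored as per-chromosome difference maps; depth arrays are materialised
    on demand.  All depths are non-negative by construction.
    """

    def __init__(self) -> None:
        self._diffs: dict[str, defaultdict[int, int]] = {}
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.n_reads = 0

    def add_interval(self, chrom: str, start: int, end: int) -> None:
        if end <= start or start < 0:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        d = self._diffs.setdefault(chrom, defaultdict(int))
        d[start] += 1
        d[end] -= 1
        self._cache.pop(chrom, None)

    def chroms(self) -> list[str]:
        return sorted(self._diffs)

    def _steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted breakpoints and cumulative depth from each breakpoint on."""
        if chrom not in self._cache:
            d = self._diffs.get(chrom, {})
            positions = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
            deltas = np.fromiter(d.values(), dtype=np.int64, count=len(d))
            order = np.argsort(positions, kind="stable")
            self._cache[chrom] = (positions[order], np.cumsum(deltas[order]))
        return self._cache[chrom]

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end)."""
        if end < start:
            raise ValueError("end < start")
        positions, cum = self._steps(chrom)
        if len(positions) == 0:
            return np.zeros(end - start, dtype=np.int64)
        idx = np.searchsorted(positions, np.arange(start, end), side="right") - 1
        return np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0)

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        """Mean depth over [start, end), via step-function integration."""
        if end <= start:
            return 0.0
        positions, cum = self._steps(chrom)
        if len(positions) == 0:
            return 0.0
        lo = int(np.searchsorted(positions, start, side="right"))
        hi = int(np.searchsorted(positions, end, side="left"))
        pts = np.concatenate([[start], positions[lo:hi], [end]])
        depths = np.concatenate(
            [[cum[lo - 1] if lo > 0 else 0], cum[lo:hi]]
        )
        return float(np.dot(depths, np.diff(pts)) / (end - start))

    def is_empty(self) -> bool:
        return not any(self._diffs.values())


@dataclass
class ReadFilterConfig:
    """Filters applied before a read contributes evidence.

    ``min_junction_overhang`` is the number of aligned bases a spliced read
    must anchor on each side of every intron gap it reports; 1–2 bp anchors
    are a classic source of spurious junctions, hence the default of 6.
    """

    min_mapping_quality: int = 0
    max_ambiguous_bases: int = 2
    discard_multimapped: bool = True
    min_junction_overhang: int = 6

    def __post_init__(self) -> None:
        if self.min_junction_overhang < 1:
            raise ValueError("min_junction_overhang must be >= 1")


@dataclass
class AlignmentStats:
    """Accounting of where each input record went."""

    n_records: int = 0
    n_spliced: int = 0
    n_constitutive: int = 0
    n_discarded: int = 0
    n_unsupported_cigar: int = 0
    discard_reasons: dict = field(default_factory=lambda: defaultdict(int))


def _is_multimapped(rec: pysam.AlignedSegment) -> bool:
    # Union of the two common conventions: NH tag > 1, or secondary flag.
    if rec.is_secondary or rec.is_supplementary:
        return True
    try:
        return int(rec.get_tag("NH")) > 1
    except KeyError:
        return False


def _record_gaps_and_blocks(
    rec: pysam.AlignedSegment,
) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int]]]:
    """Walk the CIGAR; return intron gaps with flanking anchor sizes, and
    aligned (reference-consuming, matched) blocks.

    Gaps are (start, end, left_anchor, right_anchor) where anchors are the
    aligned base counts between this gap and the adjacent gap/read end.
    """
    ref = rec.reference_start
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    anchor_runs: list[int] = [0]  # aligned bases between consecutive N gaps
    for op, length in rec.cigartuples:
        if op in (_CIGAR_M, _CIGAR_EQ, _CIGAR_X):
            blocks.append((ref, ref + length))
            anchor_runs[-1] += length
            ref += length
        elif op == _CIGAR_D:
            ref += length
        elif op == _CIGAR_N:
            gaps.append((ref, ref + length))
            anchor_runs.append(0)
            ref += length
        # I, S, H, P consume no reference
    out = []
    for i, (s, e) in enumerate(gaps):
        out.append((s, e, anchor_runs[i], anchor_runs[i + 1]))
    return out, blocks


def load_alignments(
    path: str | os.PathLike,
    cfg: ReadFilterConfig | None = None,
) -> tuple[list[Junction], CoverageTrack, AlignmentStats]:
    """Parse a SAM/BAM file into junctions and a coverage track.

    Every mapped record passing the filters contributes either its intron
    gap(s) (spliced read) or its aligned span (constitutive read).  Returns
    the junction list (one per distinct (chrom, start, end), sorted), the
    coverage track, and per-record accounting.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    input that is not parseable SAM/BAM or lacks sequence information in the
    header.
    """
    cfg = cfg or ReadFilterConfig()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except ValueError as exc:
        raise ValueError(f"not a parseable SAM/BAM file: {path}: {exc}") from exc

    stats = AlignmentStats()
    support: dict[tuple[str, int, int], int] = defaultdict(int)
    track = CoverageTrack()
    with af:
        if not af.header.get("SQ"):
            raise ValueError(f"alignment file {path} has no @SQ header lines")
        for rec in af:
            stats.n_records += 1
            if rec.is_unmapped:
                stats.n_discarded += 1
                stats.discard_reasons["unmapped"] += 1
                continue
            if cfg.discard_multimapped and _is_multimapped(rec):
                stats.n_discarded += 1
                stats.discard_reasons["multimapped"] += 1
                continue
            if rec.mapping_quality < cfg.min_mapping_quality:
                stats.n_discarded += 1
                stats.discard_reasons["low_mapq"] += 1
                continue
            seq = rec.query_sequence
            if seq and seq.upper().count("N") > cfg.max_ambiguous_bases:
                stats.n_discarded += 1
                stats.discard_reasons["ambiguous_bases"] += 1
                continue
            if rec.cigartuples is None:
                stats.n_discarded += 1
                stats.discard_reasons["no_cigar"] += 1
                continue
            if any(op not in _SUPPORTED for op, _ in rec.cigartuples):
                stats.n_discarded += 1
                stats.n_unsupported_cigar += 1
                stats.discard_reasons["unsupported_cigar"] += 1
                continue
            gaps, blocks = _record_gaps_and_blocks(rec)
            chrom = rec.reference_name
            if gaps:
                stats.n_spliced += 1
                for s, e, left, right in gaps:
                    if (
                        left >= cfg.min_junction_overhang
                        and right >= cfg.min_junction_overhang
                    ):
                        support[(chrom, s, e)] += 1
            else:
                stats.n_constitutive += 1
                for s, e in blocks:
                    track.add_interval(chrom, s, e)
                track.n_reads += 1
    if stats.n_unsupported_cigar:
        logger.warning(
            "skipped %d records with unsupported CIGAR operators",
            stats.n_unsupported_cigar,
        )
    junctions = [
        Junction(chrom, s, e, support=n)
        for (chrom, s, e), n in sorted(support.items())
    ]
    return junctions, track, stats


def write_junction_bed(junctions: list[Junction], path: str | os.PathLike) -> None:
    """Write junctions as 6-column BED (score column carries read support)."""
    with open(path, "w") as fh:
        for i, j in enumerate(sorted(junctions)):
            strand = j.strand if j.strand in "+-" else "."
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\tJUNC{i:06d}\t"
                f"{j.support}\t{strand}\n"
            )
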