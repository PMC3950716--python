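"""Signal and motif profiling of splice-site-flanking segments.

Each skipping event defines eight boundary segments: from each of its four
splice sites, one segment extending 50 bp into the adjacent exon and one
extending 100 bp into the adjacent intron (in transcription orientation).
Segments are truncated where the exon or intron is shorter than the
extension, splitting shared exons/introns at the midpoint so segments never
overlap.

Over these segments the module computes:

* tag densities of interval data (ChIP-style reads), normalized per
  ten-million library reads per base, with optional input-control
  subtraction;
* per-factor Z-score profiles of the group-mean densities and the Pearson
  correlation of the SIDG and IIDG profiles (factors with near-identical
  profiles in both groups have |r| near 1);
* Mann–Whitney enrichment of externally supplied motif-hit counts between
  the SIDG and IIDG groups, reported as signed −log10 p heat values
  (positive = enriched in SIDG, negative = enriched in IIDG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .event_scanner import SkippingEvent
from .splice_strength import mann_whitney

logger = logging.getLogger(__name__)

SEGMENT_SITES = ("upI_ss5", "upI_ss3", "dnI_ss5", "dnI_ss3")
SEGMENT_NAMES = tuple(
    f"{site}:{side}" for site in SEGMENT_SITES for side in ("exonic", "intronic")
)
LIBRARY_NORM = 1e7  # densities reported per ten-million library reads per base


@dataclass(frozen=True)
class BoundarySegment:
    event_id: str
    site: str
    side: str  # exonic | intronic
    chrom: str
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.site}:{self.side}"

    @property
    def length(self) -> int:
        return self.end - self.start


def _clip(lo: int, hi: int, start: int, end: int) -> tuple[int, int]:
    return max(lo, start), min(hi, end)


def event_segments(
    ev: SkippingEvent, exon_ext: int = 50, intron_ext: int = 100
) -> list[BoundarySegment]:
    """The (up to) eight boundary segments of one event.

    Exonic segments never cross the exon midpoint when two sites share an
    exon (the middle exon) and never extend past the exon's far boundary;
    intronic segments likewise split shared introns at their midpoint.
    Zero-length segments (degenerate exons/introns) are omitted with a
    warning.
    """
    if exon_ext < 1 or intron_ext < 1:
        raise ValueError("exon_ext and intron_ext must be >= 1")
    (l1, l2), (m1, m2), (r1, r2) = ev.exons_genomic
    up_intron = (l2, m1)
    dn_intron = (m2, r1)
    mid_split = (m1 + m2) // 2
    up_intron_split = (up_intron[0] + up_intron[1]) // 2
    dn_intron_split = (dn_intron[0] + dn_intron[1]) // 2

    # genomic windows per (genomic site position, side); the genomic-left
    # intron boundary has its exonic window on the left, intronic on the right
    windows: dict[tuple[str, str], tuple[int, int]] = {}
    # site at l2 (end of left exon): exon to the left, upstream intron right
    windows[("L2", "exonic")] = _clip(l1, l2, l2 - exon_ext, l2)
    windows[("L2", "intronic")] = _clip(up_intron[0], up_intron_split, l2, l2 + intron_ext)
    # site at m1: upstream intron left, middle exon right
    windows[("M1", "intronic")] = _clip(up_intron_split, up_intron[1], m1 - intron_ext, m1)
    windows[("M1", "exonic")] = _clip(m1, mid_split, m1, m1 + exon_ext)
    # site at m2: middle exon left, downstream intron right
    windows[("M2", "exonic")] = _clip(mid_split, m2, m2 - exon_ext, m2)
    windows[("M2", "intronic")] = _clip(dn_intron[0], dn_intron_split, m2, m2 + intron_ext)
    # site at r1: downstream intron left, right exon right
    windows[("R1", "intronic")] = _clip(dn_intron_split, dn_intron[1], r1 - intron_ext, r1)
    windows[("R1", "exonic")] = _clip(r1, r2, r1, r1 + exon_ext)

    if ev.strand == "-":
        site_of = {"R1": "upI_ss5", "M2": "upI_ss3", "M1": "dnI_ss5", "L2": "dnI_ss3"}
    else:
        site_of = {"L2": "upI_ss5", "M1": "upI_ss3", "M2": "dnI_ss5", "R1": "dnI_ss3"}

    out = []
    for (pos_key, side), (s, e) in windows.items():
        if e <= s:
            logger.warning(
                "event %s: degenerate %s %s segment omitted",
                ev.event_id, site_of[pos_key], side,
            )
            continue
        out.append(
            BoundarySegment(ev.event_id, site_of[pos_key], side, ev.chrom, s, e)
        )
    order = {name: i for i, name in enumerate(SEGMENT_NAMES)}
    return sorted(out, key=lambda seg: order[seg.name])


def segments_to_bed(segments: list[BoundarySegment], path) -> None:
    """6-column BED, name = eventID:site:side."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t"
                f"{seg.event_id}:{seg.site}:{seg.side}\t0\t.\n"
            )


# ---------------------------------------------------------------------------
# tag densities


class _IntervalIndex:
    """Per-chromosome sorted interval arrays for overlap counting.

    A read overlaps a segment when at least one aligned base intersects it.
    """

    def __init__(self, intervals):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        self.n = 0
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
            self.n += 1
        self._starts = {}
        self._ends = {}
        for chrom, ivs in by_chrom.items():
            arr = np.array(ivs, dtype=np.int64)
            self._starts[chrom] = np.sort(arr[:, 0])
            self._ends[chrom] = np.sort(arr[:, 1])

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._starts:
            return 0
        starts, ends = self._starts[chrom], self._ends[chrom]
        n = len(starts)
        # overlap iff interval.start < end and interval.end > start
        not_left = np.searchsorted(ends, start, side="right")  # end <= start
        not_right = n - np.searchsorted(starts, end, side="left")  # start >= end
        return int(n - not_left - not_right)


def read_bed_intervals(path):
    """Minimal BED reader: (chrom, start, end) triples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


@dataclass
class DensityProfile:
    """events × 8-segment matrix of normalized signal densities."""

    matrix: pd.DataFrame  # index event_id, columns SEGMENT_NAMES
    library_size: int
    control_subtracted: bool

    def segment_means(self) -> pd.Series:
        return self.matrix.mean(axis=0)


def tag_density(
    segments: list[BoundarySegment],
    intervals,
    library_size: int,
    control: tuple | None = None,
) -> DensityProfile:
    """Normalized per-segment tag density, one row per event.

    density = (overlapping reads / segment length) × (1e7 / library size);
    with a ``control`` pair (intervals, library_size), the identically
    normalized control density is subtracted (values may go negative).
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    index = _IntervalIndex(intervals)
    ctrl_index = ctrl_lib = None
    if control is not None:
        ctrl_intervals, ctrl_lib = control
        if ctrl_lib <= 0:
            raise ValueError("control library size must be positive")
        ctrl_index = _IntervalIndex(ctrl_intervals)

    values: dict[str, dict[str, float]] = {}
    for seg in segments:
        d = (
            index.count_overlaps(seg.chrom, seg.start, seg.end)
            / seg.length
            * (LIBRARY_NORM / library_size)
        )
        if ctrl_index is not None:
            d -= (
                ctrl_index.count_overlaps(seg.chrom, seg.start, seg.end)
                / seg.length
                * (LIBRARY_NORM / ctrl_lib)
            )
        values.setdefault(seg.event_id, {})[seg.name] = d
    matrix = pd.DataFrame.from_dict(values, orient="index").reindex(
        columns=list(SEGMENT_NAMES)
    )
    matrix.index.name = "event_id"
    return DensityProfile(
        matrix=matrix.sort_index(),
        library_size=library_size,
        control_subtracted=control is not None,
    )


# ---------------------------------------------------------------------------
# Z-score heat table and group similarity


def zscore_heat(
    profiles_by_group: dict[str, dict[str, DensityProfile]],
) -> tuple[pd.DataFrame, pd.Series]:
    """Z-score profiles and SIDG/IIDG similarity per factor.

    ``profiles_by_group`` maps group name ('SIDG', 'IIDG') → factor →
    DensityProfile.  For each factor and group, the 8 per-group segment-mean
    densities are standardized to mean 0, sd 1; r is the Pearson correlation
    of the two groups' Z-score 8-vectors.  Zero-variance factors are flagged
    (r = NaN).  The returned r series is sorted by |r| ascending.
    """
    rows = {}
    undefined = []
    for group, factors in profiles_by_group.items():
        for factor, profile in factors.items():
            means = profile.segment_means().to_numpy(dtype=float)
            sd = means.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                undefined.append((group, factor))
                z = np.full_like(means, np.nan)
            else:
                z = (means - means.mean()) / sd
            rows[(factor, group)] = z
    heat = pd.DataFrame.from_dict(rows, orient="index", columns=list(SEGMENT_NAMES))
    heat.index = pd.MultiIndex.from_tuples(heat.index, names=["factor", "group"])
    heat = heat.sort_index()

    groups = sorted(profiles_by_group)
    r_values = {}
    if len(groups) == 2:
        g1, g2 = groups
        factors = sorted(
            set(profiles_by_group[g1]) & set(profiles_by_group[g2])
        )
        for factor in factors:
            z1 = heat.loc[(factor, g1)].to_numpy(dtype=float)
            z2 = heat.loc[(factor, g2)].to_numpy(dtype=float)
            if np.isnan(z1).any() or np.isnan(z2).any():
                r_values[factor] = np.nan
                logger.warning("factor %s: zero-variance profile, r undefined", factor)
            else:
                r_values[factor] = float(np.corrcoef(z1, z2)[0, 1])
    r = pd.Series(r_values, name="pearson_r")
    r = r.iloc[np.argsort(r.abs().to_numpy(), kind="stable")]
    return heat, r


# ---------------------------------------------------------------------------
# motif enrichment


def motif_enrichment(
    hit_counts: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    adjust: bool = False,
) -> pd.DataFrame:
    """Signed −log10 Mann–Whitney heat values for motif-hit enrichment.

    ``hit_counts``: long-format DataFrame with columns event_id, factor,
    segment, count (counts already normalized per segment length, or raw —
    the test is rank-based so any per-event monotone normalization works).
    ``groups``: event_id → 'SIDG' | 'IIDG'.  Positive heat = enriched in
    SIDG, negative = enriched in IIDG; optional Benjamini–Hochberg
    adjustment across the factor × segment grid.
    """
    required = {"event_id", "factor", "segment", "count"}
    if not required <= set(hit_counts.columns):
        missing = sorted(required - set(hit_counts.columns))
        raise ValueError(f"hit_counts missing columns: {missing}")
    groups = pd.Series(groups)
    rows = []
    for (factor, segment), sub in hit_counts.groupby(["factor", "segment"], sort=True):
        g = groups.reindex(sub["event_id"]).to_numpy()
        counts = sub["count"].to_numpy(dtype=float)
        sidg = counts[g == "SIDG"]
        iidg = counts[g == "IIDG"]
        if len(sidg) == 0 or len(iidg) == 0:
            logger.warning("factor %s segment %s: a group is empty, skipped", factor, segment)
            continue
        flagged = not (np.any(sidg) or np.any(iidg))
        if flagged:
            p = 1.0
        else:
            _, p = mann_whitney(sidg, iidg)
        sign = 1.0 if sidg.mean() >= iidg.mean() else -1.0
        rows.append(
            {
                "factor": factor,
                "segment": segment,
                "p_value": p,
                "sign": sign,
                "heat": 0.0 if p >= 1.0 else sign * float(-np.log10(p)),
                "all_zero": flagged,
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
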