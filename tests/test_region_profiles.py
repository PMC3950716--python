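"""Boundary segments, tag densities, Z-score profiles, motif enrichment."""

import numpy as np
import pandas as pd
import pytest

from skipscan.region_profiles import (
    SEGMENT_NAMES,
    DensityProfile,
    event_segments,
    motif_enrichment,
    tag_density,
    zscore_heat,
)
from skipscan.synthetic_data import truth_row_to_event


def event_at(up=(1000, 1300), mid=(2300, 2600), dn=(3600, 3900), strand="+"):
    return truth_row_to_event(
        {
            "chrom": "chr1", "strand": strand,
            "up_exon_start": up[0], "up_exon_end": up[1],
            "mid_exon_start": mid[0], "mid_exon_end": mid[1],
            "dn_exon_start": dn[0], "dn_exon_end": dn[1],
        }
    )


def brute_force_overlap_count(intervals, chrom, start, end):
    return sum(1 for c, s, e in intervals if c == chrom and s < end and e > start)


class TestSegments:
    def test_full_length_segments_on_roomy_event(self):
        segs = event_segments(event_at())
        assert len(segs) == 8
        lengths = {seg.name: seg.length for seg in segs}
        for site in ("upI_ss5", "upI_ss3", "dnI_ss5", "dnI_ss3"):
            assert lengths[f"{site}:exonic"] == 50
            assert lengths[f"{site}:intronic"] == 100

    def test_exonic_segments_lie_in_exons(self):
        ev = event_at()
        exons = set()
        for s, e in ev.exons_genomic:
            exons.update(range(s, e))
        for seg in event_segments(ev):
            covered = set(range(seg.start, seg.end))
            if seg.side == "exonic":
                assert covered <= exons
            else:
                assert not (covered & exons)

    def test_short_middle_exon_split_at_midpoint(self):
        ev = event_at(mid=(2300, 2360))  # 60 bp middle exon
        segs = {seg.name: seg for seg in event_segments(ev)}
        a = segs["upI_ss3:exonic"]
        b = segs["dnI_ss5:exonic"]
        assert a.length == 30 and b.length == 30
        assert a.end == b.start  # non-overlapping split

    def test_short_intron_split_at_midpoint(self):
        ev = event_at(up=(1000, 1300), mid=(1450, 1750), dn=(2700, 3000))  # 150 bp up intron
        segs = {seg.name: seg for seg in event_segments(ev)}
        assert segs["upI_ss5:intronic"].end <= segs["upI_ss3:intronic"].start

    def test_minus_strand_mirrors_sites(self):
        plus = {s.name: (s.start, s.end) for s in event_segments(event_at())}
        ev_m = event_at(up=(3600, 3900), mid=(2300, 2600), dn=(1000, 1300), strand="-")
        minus = {s.name: (s.start, s.end) for s in event_segments(ev_m)}
        # genomically the window set is identical; labels swap up/dn sides
        assert minus["upI_ss5:exonic"] == plus["dnI_ss3:exonic"]
        assert minus["dnI_ss5:intronic"] == plus["upI_ss3:intronic"]

    def test_segments_pairwise_disjoint_and_bounded(self):
        for mid in [(2300, 2600), (2300, 2330), (1400, 1460)]:
            ev = event_at(mid=mid)
            segs = event_segments(ev)
            for i, a in enumerate(segs):
                for b in segs[i + 1 :]:
                    assert a.end <= b.start or b.end <= a.start
            lo = min(s.start for s in segs)
            hi = max(s.end for s in segs)
            assert lo >= ev.exons_genomic[0][0] - 100
            assert hi <= ev.exons_genomic[2][1] + 100

    def test_zero_extension_rejected(self):
        with pytest.raises(ValueError):
            event_segments(event_at(), exon_ext=0)


class TestTagDensity:
    def test_no_reads_zero_density(self):
        profile = tag_density(event_segments(event_at()), [], 1_000_000)
        assert (profile.matrix.fillna(0.0) == 0.0).all().all()

    def test_density_arithmetic(self):
        # density = (reads / length) × (1e7 / library): 10 reads fully inside
        # a 100 bp segment at library 1e7 → (10/100) × 1 = 0.1
        segs = [s for s in event_segments(event_at()) if s.name == "upI_ss5:intronic"]
        seg = segs[0]
        reads = [("chr1", seg.start + 5, seg.start + 41)] * 10
        profile = tag_density(segs, reads, 10_000_000)
        assert profile.matrix.iloc[0][seg.name] == pytest.approx(0.1)
        # the normalization constant is linear: a 1e6 library scales ×10
        profile10 = tag_density(segs, reads, 1_000_000)
        assert profile10.matrix.iloc[0][seg.name] == pytest.approx(1.0)

    def test_signal_equal_control_cancels(self):
        segs = event_segments(event_at())
        reads = [("chr1", 1200, 1236), ("chr1", 2290, 2326)] * 5
        profile = tag_density(segs, reads, 1000, control=(reads, 1000))
        assert np.allclose(profile.matrix.fillna(0.0).to_numpy(), 0.0)
        assert profile.control_subtracted

    def test_overlap_counting_matches_brute_force(self, rng):
        segs = event_segments(event_at())
        reads = []
        for _ in range(500):
            s = int(rng.integers(900, 4000))
            reads.append(("chr1", s, s + int(rng.integers(1, 80))))
        profile = tag_density(segs, reads, 10_000_000)
        for seg in segs:
            expected = (
                brute_force_overlap_count(reads, "chr1", seg.start, seg.end)
                / seg.length
            )
            assert profile.matrix.iloc[0][seg.name] == pytest.approx(expected)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError):
            tag_density(event_segments(event_at()), [], 0)


def profile_from_means(means):
    m = pd.DataFrame([means], columns=list(SEGMENT_NAMES), index=["ev1"])
    return DensityProfile(matrix=m, library_size=1, control_subtracted=False)


class TestZScores:
    def test_identical_profiles_r_one(self):
        means = [1, 2, 3, 4, 5, 6, 7, 8]
        heat, r = zscore_heat(
            {"SIDG": {"f": profile_from_means(means)},
             "IIDG": {"f": profile_from_means(means)}}
        )
        assert r["f"] == pytest.approx(1.0)

    def test_reversed_profile_r_minus_one(self):
        heat, r = zscore_heat(
            {"SIDG": {"f": profile_from_means([1, 2, 3, 4, 5, 6, 7, 8])},
             "IIDG": {"f": profile_from_means([8, 7, 6, 5, 4, 3, 2, 1])}}
        )
        assert r["f"] == pytest.approx(-1.0)

    def test_rows_standardized(self):
        heat, _ = zscore_heat(
            {"SIDG": {"f": profile_from_means([1, 5, 2, 8, 3, 9, 4, 7])},
             "IIDG": {"f": profile_from_means([2, 2, 2, 9, 1, 1, 4, 4])}}
        )
        for _, row in heat.iterrows():
            v = row.to_numpy(dtype=float)
            assert abs(v.mean()) < 1e-10
            assert abs(v.std(ddof=1) - 1.0) < 1e-10

    def test_hand_computed_pearson(self):
        a = np.array([1.0, 5, 2, 8, 3, 9, 4, 7])
        b = np.array([2.0, 6, 1, 9, 2, 8, 5, 6])
        za = (a - a.mean()) / a.std(ddof=1)
        zb = (b - b.mean()) / b.std(ddof=1)
        expected = float(np.dot(za - za.mean(), zb - zb.mean()) / (
            np.linalg.norm(za - za.mean()) * np.linalg.norm(zb - zb.mean())
        ))
        _, r = zscore_heat(
            {"SIDG": {"f": profile_from_means(a)}, "IIDG": {"f": profile_from_means(b)}}
        )
        assert r["f"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_missing(self):
        _, r = zscore_heat(
            {"SIDG": {"f": profile_from_means([3] * 8)},
             "IIDG": {"f": profile_from_means([1, 2, 3, 4, 5, 6, 7, 8])}}
        )
        assert np.isnan(r["f"])

    def test_sorted_by_absolute_r_ascending(self):
        profiles = {
            "SIDG": {
                "near": profile_from_means([1, 2, 3, 4, 5, 6, 7, 8]),
                "far": profile_from_means([1, 2, 3, 4, 5, 6, 7, 8]),
            },
            "IIDG": {
                "near": profile_from_means([1.1, 2, 3.2, 4, 5, 6.1, 7, 8]),
                "far": profile_from_means([5, 1, 8, 2, 7, 3, 9, 1]),
            },
        }
        _, r = zscore_heat(profiles)
        assert list(r.index) == sorted(r.index, key=lambda f: abs(r[f]))


class TestMotifEnrichment:
    def _table(self, sidg_counts, iidg_counts, factor="F", segment="dnI_ss5:intronic"):
        rows = []
        groups = {}
        for i, c in enumerate(sidg_counts):
            eid = f"s{i}"
            rows.append({"event_id": eid, "factor": factor, "segment": segment, "count": c})
            groups[eid] = "SIDG"
        for i, c in enumerate(iidg_counts):
            eid = f"i{i}"
            rows.append({"event_id": eid, "factor": factor, "segment": segment, "count": c})
            groups[eid] = "IIDG"
        return pd.DataFrame(rows), groups

    def test_identical_groups_heat_zero(self):
        table, groups = self._table([1, 2, 3], [1, 2, 3])
        out = motif_enrichment(table, groups)
        assert out.iloc[0]["heat"] == 0.0

    def test_sidg_excess_positive_sign_exact_minimum_p(self):
        table, groups = self._table([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
        out = motif_enrichment(table, groups)
        row = out.iloc[0]
        assert row["sign"] == 1.0
        # complete separation at n=5 vs 5: exact two-sided minimum 2/C(10,5)
        assert row["p_value"] == pytest.approx(2 / 252)
        assert row["heat"] == pytest.approx(-np.log10(2 / 252))

    def test_iidg_excess_negative_sign(self):
        table, groups = self._table([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        out = motif_enrichment(table, groups)
        assert out.iloc[0]["heat"] < 0

    def test_all_zero_counts_flagged(self):
        table, groups = self._table([0, 0, 0], [0, 0, 0])
        out = motif_enrichment(table, groups)
        assert out.iloc[0]["all_zero"]
        assert out.iloc[0]["heat"] == 0.0

    def test_bh_adjustment_column_present_when_requested(self):
        table, groups = self._table([5, 6, 7], [1, 2, 3])
        out = motif_enrichment(table, groups, adjust=True)
        assert "q_value" in out.columns

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="factor"):
            motif_enrichment(pd.DataFrame({"event_id": [], "segment": [], "count": []}), {})
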