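"""Maximum-entropy site model, competition score, Mann–Whitney statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import skipscan as sk
from skipscan.splice_strength import (
    CompetitionScore,
    SiteSequence,
    _mann_whitney_exact,
    compare_site_strengths,
    competition_score,
    extract_site_sequences,
    load_model,
    mann_whitney,
    save_model,
    score_site,
    train_maxent,
)
from skipscan.splice_graph import revcomp
from skipscan.synthetic_data import (
    STRONG_ACCEPTOR,
    STRONG_DONOR,
    WEAK_ACCEPTOR,
    WEAK_DONOR,
    sample_decoys,
    sample_training_sites,
    truth_row_to_event,
)


def brute_force_maxent(seqs, length, alphabet, smoothing=1e-6, iters=4000):
    """Oracle: iterative proportional fitting on the full sequence table —
    converges to the maximum-entropy distribution matching the mono and
    adjacent-pair marginals."""
    A = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    space = list(itertools.product(range(A), repeat=length))
    m1 = np.zeros((length, A))
    m2 = np.zeros((length - 1, A, A))
    for s in seqs:
        ii = [idx[c] for c in s]
        for i, a in enumerate(ii):
            m1[i, a] += 1
        for i in range(length - 1):
            m2[i, ii[i], ii[i + 1]] += 1
    n = len(seqs)
    m1 = (1 - smoothing) * (m1 / n) + smoothing / A
    m2 = (1 - smoothing) * (m2 / n) + smoothing / (A * A)
    p = np.full(len(space), 1.0 / len(space))
    for _ in range(iters):
        for i in range(length):
            cur = np.zeros(A)
            for k, s in enumerate(space):
                cur[s[i]] += p[k]
            for k, s in enumerate(space):
                p[k] *= m1[i, s[i]] / cur[s[i]]
        for i in range(length - 1):
            cur = np.zeros((A, A))
            for k, s in enumerate(space):
                cur[s[i], s[i + 1]] += p[k]
            for k, s in enumerate(space):
                p[k] *= m2[i, s[i], s[i + 1]] / cur[s[i], s[i + 1]]
        err = 0.0
        for i in range(length):
            cur = np.zeros(A)
            for k, s in enumerate(space):
                cur[s[i]] += p[k]
            err = max(err, abs(cur - m1[i]).max())
        if err < 1e-13:
            break
    return {
        "".join(alphabet[c] for c in s): p[k] for k, s in enumerate(space)
    }


class TestSiteSequences:
    def test_length_validation(self):
        with pytest.raises(ValueError):
            SiteSequence("donor5", "ACGT")
        with pytest.raises(ValueError):
            SiteSequence("acceptor3", "ACGT" * 3)
        assert SiteSequence("donor5", "CAGGTAAGT").seq == "CAGGTAAGT"

    def test_extraction_is_definitional_slice(self, detected):
        ds, _, events, _, _ = detected
        ev = events[0]
        seqs = extract_site_sequences(ev, ds.genome)
        genome = ds.genome[ev.chrom]
        p = ev.upI_ss5.pos
        assert seqs["upI_ss5"].seq == genome[p - 3 : p + 6]
        q = ev.upI_ss3.pos
        assert seqs["upI_ss3"].seq == genome[q - 20 : q + 3]

    def test_canonical_dinucleotides_in_reading_orientation(self, detected):
        ds, _, events, _, _ = detected
        for ev in events:
            seqs = extract_site_sequences(ev, ds.genome)
            for name, site in seqs.items():
                if site.kind == "donor5":
                    assert site.seq[3:5] == "GT", name
                else:
                    assert site.seq[18:20] == "AG", name

    def test_minus_strand_extraction_is_reverse_complement(self):
        # a '-' event over a genome built as the reverse complement of a '+'
        # locus must extract identical site sequences
        ds_plus = sk.simulate_dataset(n_events=1, true_psi=0.5, depth=20, seed=7, strand="+")
        ds_minus = sk.simulate_dataset(n_events=1, true_psi=0.5, depth=20, seed=7, strand="-")
        ev_p = truth_row_to_event(ds_plus.truth.iloc[0])
        ev_m = truth_row_to_event(ds_minus.truth.iloc[0])
        sp = extract_site_sequences(ev_p, ds_plus.genome)
        sm = extract_site_sequences(ev_m, ds_minus.genome)
        for name in sp:
            assert sp[name].kind == sm[name].kind
            assert sm[name].seq[3:5] == "GT" if sp[name].kind == "donor5" else sm[name].seq[18:20] == "AG"
        # double reverse complement is identity
        assert revcomp(revcomp(sp["upI_ss5"].seq)) == sp["upI_ss5"].seq

    def test_out_of_bounds_raises(self):
        ev = truth_row_to_event(
            {
                "chrom": "c", "strand": "+",
                "up_exon_start": 0, "up_exon_end": 5,
                "mid_exon_start": 10, "mid_exon_end": 15,
                "dn_exon_start": 20, "dn_exon_end": 25,
            }
        )
        with pytest.raises(IndexError):
            extract_site_sequences(ev, {"c": "ACGT" * 10})


class TestMaxEntTraining:
    def test_order1_equals_pwm_exactly(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(120)]
        decoys = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(120)]
        m = train_maxent(seqs, decoys, kind="toy5", constraint_order={1})
        # PWM probability: product of smoothed positional marginals
        counts = np.zeros((5, 4))
        idx = {c: i for i, c in enumerate("ACGT")}
        for s in seqs:
            for i, c in enumerate(s):
                counts[i, idx[c]] += 1
        marg = (1 - 1e-6) * counts / len(seqs) + 1e-6 / 4
        for probe in ("ACGTA", "TTTTT", "CAGGT"):
            pwm = float(np.prod([marg[i, idx[c]] for i, c in enumerate(probe)]))
            assert m.signal_dist.prob(probe) == pytest.approx(pwm, rel=1e-9)

    def test_uniform_training_set_gives_uniform_model(self):
        seqs = ["".join(t) for t in itertools.product("AC", repeat=3)] * 10
        m = train_maxent(seqs, seqs, kind="toy", constraint_order={1, 2}, alphabet="AC")
        for s in set(seqs):
            assert m.signal_dist.prob(s) == pytest.approx(1 / 8, abs=1e-6)

    @pytest.mark.parametrize("alphabet,length", [("AC", 3), ("ACG", 3), ("ACGT", 4)])
    def test_matches_brute_force_maxent(self, alphabet, length, rng):
        seqs = ["".join(rng.choice(list(alphabet), length)) for _ in range(300)]
        decoys = ["".join(rng.choice(list(alphabet), length)) for _ in range(100)]
        m = train_maxent(
            seqs, decoys, kind="toy", constraint_order={1, 2}, alphabet=alphabet
        )
        oracle = brute_force_maxent(seqs, length, alphabet)
        tv = 0.5 * sum(
            abs(m.signal_dist.prob(s) - p) for s, p in oracle.items()
        )
        assert tv <= 1e-5

    def test_insufficient_training_set_rejected(self):
        with pytest.raises(ValueError, match="signal sequences"):
            train_maxent(["ACGTACGTA"] * 5, ["ACGTACGTA"], kind="donor5")

    def test_wrong_length_and_non_acgt_rejected_with_count(self, rng, caplog):
        good = sample_training_sites("donor5", 60, rng)
        bad = ["ACGT", "NNNNNNNNN"]
        m = train_maxent(good + bad, sample_decoys("donor5", 50, rng), kind="donor5")
        assert m.length == 9


class TestScoring:
    def test_identical_signal_and_background_scores_zero(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 3)) for _ in range(100)]
        m = train_maxent(seqs, seqs, kind="toy", constraint_order={1}, alphabet="AC")
        for probe in ("AAA", "CAC", "CCC"):
            assert score_site(m, probe) == pytest.approx(0.0, abs=1e-9)

    def test_log2_definition_on_toy_model(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 3, p=[0.8, 0.2])) for _ in range(400)]
        decoys = ["".join(rng.choice(list("AC"), 3)) for _ in range(400)]
        m = train_maxent(seqs, decoys, kind="toy", constraint_order={1, 2}, alphabet="AC")
        for probe in ("AAA", "ACA", "CCC"):
            expected = math.log2(
                max(m.signal_dist.prob(probe), 1e-12)
                / max(m.background_dist.prob(probe), 1e-12)
            )
            assert score_site(m, probe) == pytest.approx(expected, abs=1e-6)

    def test_scores_finite_for_any_input(self, rng):
        m = train_maxent(
            sample_training_sites("donor5", 100, rng),
            sample_decoys("donor5", 100, rng),
            kind="donor5",
        )
        assert math.isfinite(score_site(m, "TTTTTTTTT"))

    def test_strong_consensus_outscores_weak(self, rng):
        dm = train_maxent(
            sample_training_sites("donor5", 300, rng),
            sample_decoys("donor5", 300, rng),
            kind="donor5",
        )
        am = train_maxent(
            sample_training_sites("acceptor3", 300, rng),
            sample_decoys("acceptor3", 300, rng),
            kind="acceptor3",
        )
        assert score_site(dm, STRONG_DONOR) > score_site(dm, WEAK_DONOR)
        assert score_site(am, STRONG_ACCEPTOR) > score_site(am, WEAK_ACCEPTOR)

    def test_kind_mismatch_rejected(self, rng):
        m = train_maxent(
            sample_training_sites("donor5", 60, rng),
            sample_decoys("donor5", 60, rng),
            kind="donor5",
        )
        with pytest.raises(ValueError):
            score_site(m, SiteSequence("acceptor3", "A" * 23))

    def test_model_round_trips_through_text_file(self, rng, tmp_path):
        m = train_maxent(
            sample_training_sites("donor5", 80, rng),
            sample_decoys("donor5", 80, rng),
            kind="donor5",
        )
        path = tmp_path / "donor.tsv"
        save_model(m, path)
        m2 = load_model(path)
        for probe in ("CAGGTAAGT", "TTTGTCGCA", "ACGTACGTA"):
            assert score_site(m2, probe) == pytest.approx(score_site(m, probe), abs=1e-9)


class TestCompetitionScore:
    def test_equal_scores_give_zero(self):
        assert competition_score((5.0, 5.0, 5.0, 5.0)).S == 0.0

    def test_stated_convention_example(self):
        cs = competition_score(
            {"upI_ss5": 9.0, "upI_ss3": 5.0, "dnI_ss5": 5.0, "dnI_ss3": 9.0}
        )
        assert cs.delta_ss5 == 4.0 and cs.delta_ss3 == 4.0 and cs.S == 8.0

    def test_weakening_middle_flanking_donor_raises_S_linearly(self):
        base = competition_score((9.0, 5.0, 5.0, 9.0)).S
        assert competition_score((9.0, 5.0, 4.0, 9.0)).S == base + 1.0

    def test_invariant_to_constant_shift(self):
        a = competition_score((9.0, 5.0, 7.0, 8.0))
        b = competition_score((12.0, 8.0, 10.0, 11.0))
        assert a.S == pytest.approx(b.S)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            competition_score((math.nan, 0.0, 0.0, 0.0))


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_groups_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (6, 6), (8, 5), (8, 8), (1, 8)])
    def test_matches_scipy_exact_without_ties(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(0.8, 1.0, size=n2)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_data_enumeration(self):
        # with ties scipy's exact method is unavailable; enumeration handles
        # midranks directly and stays a valid permutation p-value
        u, p = _mann_whitney_exact(np.array([1.0, 2.0, 2.0]), np.array([2.0, 3.0, 4.0]))
        assert 0.0 < p <= 1.0

    def test_large_samples_use_tie_corrected_normal(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(1.0, 1.0, size=45)
        _, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGroupComparison:
    def _scores(self, rng, n, donor_shift=0.0):
        out = []
        for _ in range(n):
            out.append(
                CompetitionScore(
                    s_upI_ss5=rng.normal(8, 1),
                    s_upI_ss3=rng.normal(8, 1) - donor_shift,
                    s_dnI_ss5=rng.normal(8, 1) - donor_shift,
                    s_dnI_ss3=rng.normal(8, 1),
                )
            )
        return out

    def test_table_layout_and_direction(self, rng):
        sidg = self._scores(rng, 30, donor_shift=2.0)
        iidg = self._scores(rng, 30)
        table = compare_site_strengths(sidg, iidg)
        assert list(table.index) == ["upI_ss5", "upI_ss3", "dnI_ss5", "dnI_ss3", "S"]
        assert {"mean_SIDG", "sd_SIDG", "mean_IIDG", "sd_IIDG", "p_value"} <= set(table.columns)
        assert table.loc["dnI_ss5", "mean_SIDG"] < table.loc["dnI_ss5", "mean_IIDG"]
        assert table.loc["S", "mean_SIDG"] > table.loc["S", "mean_IIDG"]
        assert table.loc["S", "p_value"] < 0.01

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_site_strengths([], self._scores(rng, 3))
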