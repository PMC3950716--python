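# skipscan

De novo detection of exon-skipping events from splicing-aware RNA-seq
alignments — no gene annotation required — with Bayesian estimation of the
inclusion fraction ψ, maximum-entropy splice-site strength and competition
scoring, and signal/motif profiling of splice-site-flanking regions.

## Who this is for

Transcriptomics analysts who have spliced alignments (TopHat/HISAT-style SAM
with `N`-operator CIGARs) and want to find cassette exons directly from the
read evidence, quantify which isoform dominates at each site, and ask *why*
— are the splice sites flanking the skipped exon weaker, and what binds
around them?

## The method

**Detection.** Spliced reads define splice-site nodes; a pair of nodes is
joined by an *intron* ("dotted") edge when at least 8 reads (default) span
the same gap, oriented by the GT–AG consensus rule. Constitutive reads
define *exon* ("solid") edges: a segment between two adjacent splice sites
becomes an exon when its mean coverage is ≥ 3.0× (default) the larger of
its flanking segments'. A skipping event is a six-node sub-graph with three
exon edges (the tri-exon pattern), two flanking intron edges, and a direct
intron edge joining the outer exons — the skip junction. Other
alternative-splicing modes (intron retention, alternative 5′/3′ sites)
never match the pattern.

**ψ estimation.** Junction-spanning reads are unambiguous: reads over the
up–mid or mid–dn junctions support the inclusion isoform, reads over the
up–dn junction support skipping. Because the inclusion isoform offers more
junction-spanning start positions (c₁) than the skipping isoform (c₂), a
read is inclusion-type with probability

  p(ψ) = ψ·c₁ / (ψ·c₁ + (1−ψ)·c₂)

The posterior over ψ under a Beta(α, β) prior with a Binomial likelihood is
computed by deterministic grid quadrature; with c₁ = c₂ it reduces exactly
to Beta(α + inc, β + exc). Events with posterior mean ψ ≥ 0.7 are
inclusion-isoform-dominated (IIDG), ψ ≤ 0.3 skipping-isoform-dominated
(SIDG).

**Splice-site strength and competition.** Donor 9-mers (3 exonic + 6
intronic bases) and acceptor 23-mers (20 intronic + 3 exonic) are scored as
log₂ odds under a maximum-entropy model matching the mono- and
adjacent-pair marginals of a training set versus a positional background —
trained from user-supplied sites, not bundled parameter files. Per event,

  S = Δ₅ + Δ₃,  Δ₅ = s(upI_ss5) − s(dnI_ss5),  Δ₃ = s(dnI_ss3) − s(upI_ss3)

larger S means the outer site pair outcompetes the middle-exon-flanking
sites, favouring skipping. Group comparisons use the two-sided Mann–Whitney
U test (exhaustive enumeration when both groups ≤ 8, tie-corrected normal
approximation otherwise).

**Region profiles.** Each event defines eight segments (50 bp into the
exon, 100 bp into the intron from each of its four splice sites) over which
the package computes normalized tag densities, per-factor Z-score profiles
with the Pearson r between the SIDG and IIDG profiles, and signed
−log₁₀(p) Mann–Whitney enrichment of externally supplied motif-hit counts.

A seeded simulator generates complete toy datasets — genome FASTA, SAM
reads sampled from two isoforms mixed at a known true ψ, and a truth table
— so the whole pipeline is testable offline.

## Worked example

```sh
skipscan simulate --n-events 6 --true-psi 0.3 --depth 200 --seed 42 --out-dir sim
skipscan detect sim/reads.sam --genome sim/genome.fa --out-dir det
skipscan psi det/events.tsv sim/reads.sam --out-dir psi
```

`detect` logs its accounting and writes `events.tsv` (plus BED12 and GFF3):

```
INFO records=9840 spliced=4958 constitutive=4882 discarded=0
INFO graph: 48 nodes, 30 intron edges (0 junctions below support threshold), 23 exon edges
INFO detected 6 skipping events
```

and `psi/psi.tsv` holds one row per event (first three shown):

```
event_id                         inclusion_reads  exclusion_reads  c_inclusion  c_skipping  psi_mean  ci_low  ci_high  group
chrSIM:1700-2720:+:mid2150-2270  132              167              178          89          0.285     0.240   0.333    SIDG
chrSIM:4920-5940:+:mid5370-5490  139              155              178          89          0.311     0.264   0.361    intermediate
chrSIM:8140-9160:+:mid8590-8710  124              161              178          89          0.280     0.234   0.328    SIDG
```

Reading the first row: 132 junction reads supported inclusion and 167
supported skipping; after rescaling by the 178 vs 89 junction-spanning
start positions the posterior mean ψ is 0.285 with a 95% credible interval
(0.240, 0.333) — close to the simulated truth of 0.3, straddling the 0.3
SIDG threshold, which is why at this depth some of the six events land in
SIDG and others in `intermediate`.

Downstream, `skipscan strength` scores the four splice sites of each event
and compares SIDG vs IIDG distributions, and `skipscan profile` computes
the eight-segment density/enrichment tables.

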