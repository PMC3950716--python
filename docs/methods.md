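# Methods

This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and input handling

All internal coordinates are 0-based, half-open; the SAM 1-based convention
is converted once at the parsing boundary. A splice junction is keyed by
(chromosome, first intronic base, exclusive intron end).

Read filters: records are discarded when unmapped, multi-mapped (NH tag > 1
*or* secondary/supplementary flag — the union of the two common mapper
conventions), below the mapping-quality floor (default 0, i.e. off), or
carrying more than `max_ambiguous_bases` N bases (default 2). A spliced
read supports a junction only when it anchors at least
`min_junction_overhang` aligned bases on each side of the gap. Default 6:
1–2 bp anchors are the classic source of spurious junctions, while 6 bp
costs little sensitivity at ≥ 50× depth. Paired-end mates are treated as
independent evidence reads (counts are read-level, not fragment-level).
Reads with several N operators contribute each intron gap independently.

## The splice-site link graph

* **Intron ("dotted") edges** require junction support ≥
  `min_junction_support` (default 8). The threshold is *met at exactly 8*
  (≥, not >): 8 is the parameter value, and the inclusive reading keeps the
  printed default meaningful.
* **Orientation** uses the GT–AG consensus: GT..AG on the forward strand →
  '+', CT..AC → '−', anything else (including GC–AG introns) → 'unknown'.
  Without a reference genome all strands are 'unknown'; events are still
  reported, laid out as '+' and flagged.
* **Exon ("solid") edges** are called on segments between *adjacent*
  splice-site coordinates. The segment's mean constitutive depth must be ≥
  `min_exon_signal_ratio` (default 3.0, inclusive) times the larger of the
  two flanking segments' means — the maximum is the conservative choice of
  background. Terminal segments use their single flank. A segment with
  positive signal over zero background has ratio +∞ and is accepted; a
  zero-signal segment never becomes an exon. Mean depth (not summed tags)
  is used so the criterion is length-invariant. Segments longer than
  `max_exon_length` (default 5000 bp) are never called exons, preventing
  whole-intron coverage blobs from becoming solid edges.
* Donor/acceptor plausibility is *not* enforced at graph construction;
  the graph stays permissive and the event scan is the strict phase.
  Nodes of opposite known strands never share an exon edge.

## Event scanning

A skipping event is a six-position pattern p1 < … < p6 on one chromosome:
exon edges (p1,p2), (p3,p4), (p5,p6); intron edges (p2,p3), (p4,p5); and
the skip edge (p2,p5). Enumeration is seeded from candidate skip edges
rather than all C(n,6) sextets; equivalence with exhaustive enumeration is
a tested property, not an assumption. When several solid edges reach an
outer boundary the shortest flanking exon is reported (the unit of interest
is the tri-exon site, not the transcript). Events identical in all six
boundaries are deduplicated; overlapping events are all reported. Only
single-middle-exon patterns are emitted — a multi-exon skip surfaces, at
best, as separate single-exon candidates. Event strands come from the
consensus of the three intron edges; conflicts ('+' and '−' evidence in
one sextet) reject the sextet.

## Two-isoform ψ model

Only junction-spanning reads enter the likelihood. Middle-exon body reads
are excluded: junction reads identify the isoform unambiguously, while
body reads would require a model of constitutive coverage with further
assumptions.

The rescaling constants are effective junction-spanning start-position
counts, computed by exact enumeration over isoform positions: a read spans
a junction when it has at least max(overhang, 1) aligned bases on each
side, and a read spanning both junctions of a short middle exon counts
once. For read length 100 and overhang 6 on a long middle exon,
c_inclusion = 178 and c_skipping = 89.

The posterior over ψ ∈ [0,1] under a Beta(α, β) prior (default uniform,
α = β = 1) is evaluated by midpoint-rule quadrature on a 65 536-point grid
— deterministic and testable, unlike a sampler, and the grid is fine
enough that the conjugate equal-constant case matches the Beta closed form
to well below 1e−6 in mean and 95% bounds (interval endpoints come from
linear interpolation of the grid CDF). With zero junction reads the prior
is returned and the estimate is flagged low-confidence, as are events with
fewer than 10 junction reads (no hard floor is imposed).

Group thresholds are inclusive: ψ ≥ 0.7 → IIDG, ψ ≤ 0.3 → SIDG. Where the
two conventions (inclusive vs strict) differ in the literature, the
inclusive form is used and documented here.

## Maximum-entropy splice-site model

Site windows: donor 9-mer = 3 exon-terminal + 6 intron-initial bases
(GT at offsets 3–4 when canonical); acceptor 23-mer = 20 intron-terminal +
3 exon-initial bases (AG at offsets 18–19). '−'-strand windows are
reverse-complemented into reading orientation. GT/AG are *not* hard
requirements for scoring — non-canonical sites simply score low.

The signal model is the maximum-entropy distribution matching the
empirical positional marginals and (by default) all adjacent-pair
marginals of the training set. With these constraints the distribution
factorizes on the position chain, so marginals and the partition function
are computed exactly by forward–backward message passing — the 4²³
acceptor space is never enumerated. Fitting uses generalized iterative
scaling with step damping C = (number of feature groups per sequence);
convergence to max marginal error 1e−6 typically takes a few hundred
iterations. Empirical marginals are smoothed by mixing with the uniform
distribution at weight 1e−6 so unseen symbols keep positive probability.
With order-1 constraints only, the fit is exactly the PWM product of
positional marginals. The background model is the positional composition
of a decoy set. Scores are log₂(P_signal/P_background) with both
probabilities floored at 1e−12, so every input scores finitely; for
23-mers the floor dominates the background term, which shifts all acceptor
scores by a constant and leaves every comparison (Δ, S, group tests)
unchanged. Models are trained from user-supplied site sets and serialized
as versioned text tables; no published parameter files are bundled, so the
framework is licence- and version-independent. Richer constraint sets
(non-adjacent pairs and higher orders, as used by some published acceptor
models) are a known divergence and are not implemented.

The competition score is S = Δ₅ + Δ₃ with Δ₅ = s(upI_ss5) − s(dnI_ss5) and
Δ₃ = s(dnI_ss3) − s(upI_ss3). The sign convention — larger S favours
pairing upI_ss5 with dnI_ss3, i.e. skipping — is recorded here as the
package's convention. S is invariant to adding a constant to all four
scores.

Group summary tables report the mean and the sample standard deviation
(ddof = 1) per site class; where a parenthesized dispersion is needed for
comparison with external tables, note that SD = SE·√n.

## Mann–Whitney U

When both groups have ≤ 8 observations the two-sided p-value is computed
by exhaustive enumeration over all C(n1+n2, n1) labelings using midranks,
so it is exact even under ties; the tail criterion is
min(U, n1·n2 − U) ≤ observed. Larger groups use the tie-corrected normal
approximation with continuity correction.

## Boundary segments and profiling

Eight segments per event: from each of the four splice sites, 50 bp into
the adjacent exon and 100 bp into the adjacent intron, in transcription
orientation. A shared exon or intron (the middle exon; each intron, whose
two segments approach from both ends) is split at its midpoint so segments
never overlap; segments truncate at exon/intron boundaries and degenerate
segments are omitted with a warning.

Tag density = (overlapping reads / segment length) × (1e7 / library size);
a read overlaps when ≥ 1 aligned base intersects the segment (simple and
oracle-checkable, rather than midpoint anchoring). The 1e7 constant is
arbitrary and cancels in every group comparison. Control subtraction
applies the identical normalization to the control track first; values may
go negative.

Z-score profiles standardize each factor's 8 per-group segment-mean
densities to mean 0, sd 1 (per factor over segments, matching a profile-
similarity reading; a per-event alternative would answer a different
question). The Pearson r of the two groups' Z-vectors measures pattern
similarity; factors sort by |r| ascending. Zero-variance profiles yield an
undefined r, reported as missing.

Motif enrichment consumes an externally produced hit-count table
(event × segment × factor) — motif discovery/scanning itself is out of
scope — and reports signed −log₁₀ Mann–Whitney p per factor and segment:
positive when enriched in SIDG, negative in IIDG. Raw p-values are always
reported; Benjamini–Hochberg q-values are an optional flag.

## Synthetic data

Each simulated locus is a five-exon gene: two constitutive flanking exons
(200 bp) and introns (300 bp) guarantee that the tri-exon site's outer
boundaries appear as graph nodes, exactly as in real multi-exon genes;
then upstream (150 bp), middle (120 bp) and downstream (150 bp) exons with
300 bp introns. Two isoforms mix at the specified true ψ: a read picks the
inclusion isoform with probability ψ·(its start positions) against
(1−ψ)·(skipping positions), then a uniform start — the same generative
model the ψ estimator inverts, which is what makes parameter recovery a
meaningful test. Reads are emitted as SAM with exact N-CIGARs; sequencing
errors are off by default (the detector consumes alignments, not raw
reads) with an error-rate knob for robustness experiments. Splice sites
carry planted motifs: strong sites a high-consensus sequence, weak sites
the GT/AG core with degraded consensus elsewhere. Spacer sequence between
loci contains no GT or AG dinucleotide at all, so spacers can never fake a
canonical boundary. All randomness flows from one seed; identical seeds
give byte-identical files.

Training sites for the maximum-entropy models are sampled from a
consensus-frequency profile (a synthetic stand-in training set); decoys
are uniform random sequences.

What the simulator does *not* emulate: expression-level heterogeneity, GC
and fragment-length bias, alignment errors, overlapping genes, non-GT–AG
introns, and multi-isoform loci beyond the two-isoform mixture. Passing
tests therefore demonstrate correctness of the algorithms under the
stated generative model, not performance on real libraries, where anchor
artifacts, mismapping and annotation complexity add error modes.

## Problem sizes used in the acceptance checks

Recovery runs use 200 skipping loci (plus 50 pure-inclusion controls) at
50× depth and read length 100 — at ψ = 0.5 every junction clears the
support-8 threshold comfortably. ψ-recovery runs 40 events per true ψ in
{0.1, 0.3, 0.5, 0.7, 0.9} at 500×, giving ≥ 500 junction reads per event
so that posterior means resolve the 0.3/0.7 thresholds. The competition
check plants weak dnI_ss5/upI_ss3 sites in 100 low-ψ loci against 100
high-ψ loci at 150×, the depth at which ψ = 0.1 events still clear
detection thresholds. Oracle checks (conjugacy, maximum entropy,
event-scan enumeration, Mann–Whitney) use exact independent computations
at sizes where exhaustive enumeration is feasible.

## Known limitations

* Exon edges exist only between adjacent splice-site coordinates, so two
  overlapping middle-exon candidates cannot both be called; disjoint
  alternatives can.
* 'unknown'-strand events are reported in '+' layout; downstream site
  windows for such events may be reverse-complemented relative to truth.
* The ψ model is two-isoform and single-sample; multi-isoform inference
  and differential ψ across samples are out of scope.
* The acceptor maximum-entropy model uses adjacent-pair constraints only,
  weaker than published acceptor models with long-range constraints.
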