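# Methods

This note documents the models behind each stage of `egvscan`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Translated homology search

The discovery stage compares amino-acid queries against all six conceptual
reading frames of nucleotide contigs. Stops are rendered `*`, codons
containing N become `X`, and trailing partial codons are dropped.

*Scoring.* NCBI BLOSUM62 (which scores `*` at −4 against every residue and
+1 against itself, letting alignments run through the premature stops of
degraded elements), gap open 11, gap extend 1 (a gap of length k costs
11 + k). Raw scores are converted to bits and E-values with the standard
published gapped constants λ = 0.267 nats, K = 0.041:
bit = (λS − ln K)/ln 2, E = m·n·2^(−bit). The search space is the raw
product of query length and total translated letters — no edge-effect
correction — so thresholds are directly interpretable; the default
threshold is E ≤ 10⁻⁵.

*Seeding.* Frames up to 2,000 aa are aligned exhaustively (the reported
score is then exactly the Smith–Waterman optimum, which the test suite
verifies against an independent quadratic DP). Longer frames use exact
3-mer word matches with a two-hit trigger: two word hits on one diagonal
separated by 3–40 aa. Because seed positions on a diagonal are strictly
increasing, checking lags 1–3 in the (diagonal, position)-sorted seed list
finds every qualifying pair. Windows of ± (query length + 20) aa around
anchor clusters are then aligned with the same gapped local DP. Single-seed
X-drop extension was not needed at these scales; the two-hit heuristic
alone reduces random seeds to near zero while exact and mildly degraded
matches always carry long identical stretches.

*Coordinates.* Hits are reported in 0-based half-open nucleotide
coordinates on the forward strand; frame −f at reverse-complement offset
o maps aa span [a,b) to [L − (o + 3b), L − (o + 3a)).

## Loci

Hits merge when they share ≥ 1 base on the same contig and strand;
half-open adjacency does not merge. Gap-merging (`max_gap`) exists but
defaults to 0 — a Rep gene lives on one strand, and opposite-strand hits
are distinct loci. Merged cores are extended by ≤ 1 kb per side, clamped
to the contig.

Protein reconstruction evaluates (a) the best single-segment local
alignment of the guide query against all six frames of the locus and (b)
the best two-segment model on one strand, collinear on query and genome,
separated by a GT..AG gap of ≥ 40 nt (one canonical intron; geminivirus
*rep* genes carry at most one). To surface a second collinear exon within
one frame, the best-scoring region is masked with `*` and the frame is
realigned once. Frameshifted elements are recovered as two loci rather than
one — frameshift-restoring alignment is out of scope by design.

Classification is reciprocal-best-hit: each predicted protein is locally
aligned against a mixed reference library (geminivirus + genomovirus +
phytoplasma-plasmid Reps); the label of the highest-bitscore reference at
E ≤ 10⁻⁵ wins (ties: lower E-value, then lexicographic id — determinism).
Proteins shorter than 90 aa are excluded. A protein whose best hit is an
outgroup is excluded from the EGV set but retained in the report with its
label and reason.

## Clustering

Percent identity comes from a global alignment with free terminal gaps;
the denominator is alignment columns excluding terminal-gap columns. The
pair is canonicalized (lexicographically smaller sequence first) before
aligning because co-optimal alignments could otherwise give marginally
different identities in the two orders, breaking symmetry exactly at a
threshold. Greedy clustering processes sequences in decreasing length
(ties: id) and joins the first centroid at identity ≥ threshold (0.8
within species, 0.7 across representatives); the representative is the
longest member. Similarity groups are connected components of the
all-vs-all local-alignment graph at E ≤ 10⁻²⁰ — the published grouping
semantics of all-against-all BLAST clustering without its stochastic 2-D
layout, which is out of scope.

## Hotspots

Contigs are concatenated in lexicographic id order (bin membership depends
on the order, so determinism wins) and loci are counted in 100-kb windows
by their core start; the final partial window is retained with its true
width. The reported statistic is the exact binomial upper tail of the
fullest window, P(X ≥ max count) with X ~ Binomial(n, width/genome), plus
the Bonferroni-adjusted value min(1, n_bins · p). The test suite
cross-checks the tail against a 100,000-replicate uniform multinomial
null.

## Domain profiles

Profiles are L×20 log-odds PSSMs (log2, pseudocount 1 against a uniform
background) built from small seed alignments generated by the simulator
(Rep/AL1, CP-like, MP-like, HSP70-like, NAD-GH-like, three host controls) —
shipping no external profile database, same mechanics. Scanning is
ungapped: per window offset, Kadane's maximal-scoring segment over the
per-column scores (overhangs allowed, contributing zero; non-standard
residues score −1). Significance uses a per-profile Karlin λ solved from
the pooled per-column score distribution under the background
(Σ p_a e^{λs}/L = 1) with K fixed at 0.1 — deliberately conservative; the
null-calibration test shows ≤ 0.02 hits per 500-aa random scan at
E ≤ 0.001 across the whole profile set. Insert/delete profile states
(full profile HMMs) are out of scope.

Locus context: host-category hit in the ±5-kb flanks → `host_flanked`;
else a non-Rep viral hit → `multi_viral`; else `rep_only`. A transcript
with both a Rep hit and a host hit is flagged a co-transcript. The
AL1 filter retains sequences whose best AL1 segment covers ≥ 150 nt
(aa span × 3, boundary inclusive).

## Integron reassembly

Extended loci (± 5 kb) are cut into canonical k-mers (odd k ∈ {21, 33, 55,
77, 99, 127}; odd k has no reverse-complement palindromes). K-mers below
the coverage threshold (default mean multiplicity ≥ 5, exposed as a flag)
are dropped *before* graph construction: host flanks are unique while the
shared viral circle recurs across loci, so the filter is what isolates the
circle. The remaining graph is compacted into unitigs; isolated simple
cycles become circular candidates; reverse-complement twins are
deduplicated. Candidates within 2.5–5 kb are reported, the per-k set
maximizing (circularity, coverage, length) first. No error correction or
bubble popping — inputs are assembly slices, not reads.

Circular candidates are rotated so the virion-strand origin nonanucleotide
`TAATATTAC` starts at position 0 (both strands searched junction-aware;
absent motif → `no-origin` flag; multiple → lowest position,
`multi-origin`). ORFs are ATG→stop on both strands, strictly longer than
75 aa, junction-aware via internal doubling; the doubling approach is
verified against explicit rotation enumeration in the tests.

## Selection

Codon alignments are threaded from gapped protein rows and in-frame CDS
(translation must match exactly; one trailing stop is trimmed; mismatches
are rejected with the offending id and position).

The per-site test is a deterministic counting (SLAC-style) substitute for
Bayesian site-model machinery: it answers the same question — is site
dN/dS below or above 1 — without MCMC, and therefore cannot reproduce
posterior-probability site counts, only the sign and significance of
per-site selection. Synonymous/nonsynonymous opportunities per codon count
each position's three alternatives, excluding changes to stops from both
numerator and denominator (matching the mutation process the simulator
uses). Differences between codon pairs average over all shortest mutational
paths, equally weighted, discarding paths through stops. Without a tree,
counts accumulate over all sequence pairs; with a tree, over edges using a
deterministic minimal Fitch assignment of ancestral codons.

Because all-pairs counting replicates each variant ≈ n/2 times, the
binomial site test scales its counts by (n−1)/n_pairs — the effective
number of independent comparisons — before testing the nonsynonymous
proportion against the neutral expectation N/(N+S). Sites are called
purifying/positive at p ≤ 0.1 with dN/dS below/above 1. Under neutral
simulation the realized false-call rate is ~3–5% of sites; omega = 0.2
simulations (500 codons, 8 sequences) are recovered within ±0.05 with no
positive calls. Gapped or ambiguous codons are dropped at that site;
codons are dropped pairwise, not sitewise.

## Methylation

Feature methylation is the sum of per-site levels within [start, end)
divided by feature length — per-nt normalization; mean-over-covered-
cytosines is available behind a flag since either reading of
length-normalization is defensible. Site levels are taken as given (no
coverage weighting). Category pairs are compared per context with
two-sided Wilcoxon rank-sum tests: exact enumeration when both groups have
≤ 25 untied observations, tie-corrected normal approximation otherwise
(the two agree to |Δp| ≤ 0.01 at n = 15–25). A fixed-step WIG reader is
provided for convenience, but the contract format is the 5-column TSV
(contig, start, end, context, level).

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions.

*Protein families.* All sequences derive from one fixed set of ancestral
proteins (internal family seed, independent of user seeds): a 350-aa Rep
(first 120 aa = AL1-like region), CP (220 aa), MP (110 aa), HSP70 (300
aa), NAD-GH (200 aa) and three host-control ancestors. Outgroup Rep
ancestors sit at 45% (genomovirus) and 55% (phytoplasma plasmid)
divergence from the geminivirus Rep; reference libraries mutate each
ancestor by 12%. This anchoring makes independently generated viral
genomes, libraries and profiles mutually consistent — an implant really is
closer to the geminivirus references than to the outgroups.

*Host genomes.* I.i.d. background at the stated GC plus three repeat
families (consensus 400–800 nt, copies at 80–95% identity) written over
the background until the requested density is covered; every copy is
recorded in a BED-like truth table.

*Viral genomes.* `TAATATTAC` at position 0, then CP, MP and Rep ORFs on
the forward strand separated by random spacers, each ORF preceded by an
in-frame TAA so ORF calling recovers the designed starts. Genomes are
regenerated (bounded retry) until the nonanucleotide occurs exactly once
forward and never on the reverse strand. Real geminiviruses transcribe
bidirectionally from the intergenic region; single-strand layout loses
nothing the pipeline measures and keeps truth coordinates simple.

*Implants.* Random arcs of the circle (or caller-specified arcs; the
`rep` arc mode spans the whole Rep gene with jittered ends and is the
condition for recall measurement), random strand, degraded by per-base
substitution, Poisson 1-nt indels, optional forced in-frame stops, and
uniform end truncation — the spectrum of truncated/frameshifted Reps seen
in real surveys. A chosen fraction co-locates in one 100-kb window
(tandem hotspot). Insertions apply left-to-right with cumulative offsets,
so truth coordinates are exact in the final genome; extracting any truth
interval (reverse-complemented per strand) reproduces the stored degraded
fragment byte-for-byte.

*Co-transcripts.* Each species' transcript carries an HSP70-like CDS and a
Rep CDS in fixed orientation with constant UTRs/spacer. Coding regions
evolve independently from the ancestor (star tree) by attempt/accept:
per-branch mutation attempts ~ Poisson(depth × length), synonymous
changes always accepted, nonsynonymous accepted with probability omega,
stop-creating and stop-destroying changes rejected. This matches the
counting estimator's conventions, so recovered omega is comparable to the
simulated value. Defaults: 6 species, omega 0.2, depth 0.1
attempts/site.

*Methylation.* Every forward-strand cytosine inside a feature gets a level
drawn from N(category × context mean, sd), clipped to [0,1]; context
(CG/CHG/CHH) is read from the actual sequence. Defaults: EGV 0.8/0.7/0.5,
repeat 0.75/0.65/0.45, gene 0.2/0.1/0.05 for CG/CHG/CHH, sd 0.1 — the
qualitative ordering reported for silenced viral insertions vs genes.

*What passing tests do and do not show.* The generator has no codon-usage
bias, no phylogeographic structure, no sequencing error (assemblies are
the unit of analysis), i.i.d. background rather than isochore structure,
and protein families drawn from uniform amino-acid frequencies. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the statistics under known truth — not field performance on real plant
genomes, where repeat complexity and deeper divergence will lower recall.

## Problem sizes and determinism

The shipped end-to-end checks run a 2-Mb genome with 50 implants plus
twenty 2-Mb implant-free controls, 100-instance search-vs-DP comparisons,
100,000-replicate Monte-Carlo hotspot nulls, and 20-seed selection nulls —
sizes chosen so the whole suite completes on a single CPU in minutes while
keeping every estimate's Monte-Carlo error well below the asserted
margins. Every random draw flows from an explicit seed through
`numpy.random.default_rng`; a fixed-seed pipeline run is byte-identical
across executions, and the acceptance script derives all sub-seeds from
its `--seed`.

## Known limitations

- Frameshifted implants surface as split loci (by design); counts of
  "proteins" vs "loci" can therefore differ, and both are reported.
- The two-segment intron model requires its exons to be found as separate
  alignments; two same-frame exons separated by an intron of length
  divisible by 3 can be bridged by the single-segment model instead.
- The PSSM scan is ungapped; indel-riddled domains score lower than a
  profile HMM would.
- E-values use raw m·n search space; at very short query lengths this is
  conservative relative to edge-corrected formulas.
- The per-site selection test is a counting approximation; its effective-
  comparison correction is a pragmatic fix for pairwise pseudo-replication,
  not an exact variance model.
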