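# Methods

This note records the models, algorithms, parameter choices and known
limitations of coralign, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Given a reference genome and short reads (36–300 bp, Phred-scaled base
qualities), report for each read its most likely origin and alignment, with
a mapping quality that honestly reflects ambiguity. The regime of interest
is reads whose alignments are hardest: many substitutions (polymorphic
regions), indels, and reads spanning structural-variant breakpoints, where
seed-and-extend methods tend to misplace reads or let mate-pair priors
overrule the sequence evidence.

## Cost-ordered seed search

A read's 5′ 75 bp (the whole read below 75 bp; ⌊len/75⌋ consecutive
segments for reads ≥ 150 bp) is used as a *long, high-edit-distance seed*:
up to `mm_max = 5` mismatches and at most one gap run of length
`d_seed ≤ 10` bp are allowed inside it. Placements are enumerated in
increasing *cost steps* — all (mismatches, gap length) combinations sorted
by penalty (`mismatch = 4`, `gap open = 6`, `gap extend = 1` per extra
base; these unit costs order the search only). Ties order deterministically:
fewer gaps, fewer mismatches, shorter gap.

Each genomic position is assigned its minimum-penalty signature (ties:
no-gap first, then deletion before insertion, then leftmost split) and
reported exactly once, at that signature's step. Completeness is by
pigeonhole: the seed is cut into `mm_max + 3` chunks of ≥ 9 bp; any
placement within budget leaves ≥ 1 chunk exact (each mismatch breaks one
chunk; a gap run of length ≤ chunk+1 breaks at most two), and exact chunk
hits from a hashed 8-mer index, expanded by the ±`d_seed` shift a gap can
introduce, generate the candidate set at which every signature is then
evaluated exactly (vectorized cumulative-mismatch scan over both strands).
Genomic N matches nothing; read N counts as a mismatch at quality 0. The
test suite checks the per-step hit sets against an independent full-matrix
scan on hundreds of random genomes.

**Deep scan.** If the least-cost step yields multiple hits they are all
reported. If it is unique, enumeration continues until `depth = 1` further
step containing hits at *new* loci; gap-shifted re-descriptions of the
first locus (same chromosome and strand within `d_seed`) are not counted —
they extend to the same alignment and would otherwise both stall the scan
and masquerade as a runner-up. A step with more than `repeat_cap = 64`
hits marks the read as repeat-ambiguous (mapQ forced to 0). If a seed
segment has *no* placement within budget at all (typical for a segment
straddling an SV breakpoint, where half the bases are foreign), each half
of the segment is re-seeded with a proportionally scaled budget; a read
with ≥ 25 bp on either side of a junction always has one clean half to
anchor on. Budgets for short seeds are scaled as ⌊5·len/75⌋ mismatches and
constrained so the pigeonhole construction stays valid.

## Quality-aware scoring

With `P[i] = 1 − 10^(−Q[i]/10)` the correct-call probability (and
`(1 − P[i])/3` the probability of any one specific wrong base under an
unbiased miscall model), aligned columns are scored by Phred-informed step
functions: match bonus 2 for Q ≥ 10 else 1; mismatch penalty
`max(2, min(Q, 40)/5)` (range 2–8). A gap run of length L costs
`12 + 2·(L−1)`. Soft clips score 0. The exact constants are a package
choice — any monotone quality-aware scheme serves the design intent — and
are config-exposed and echoed into the SAM `@PG` line.

**Mapping quality** comes from the two best full-read candidate scores:
`mapQ = min(60, round(2·(S₁ − S₂)))`; with no runner-up the margin is
measured against `0.5 ×` the read's all-match score; ties and
repeat-flagged reads get 0. The constants (scale 2, floor fraction 0.5,
cap 60) are package choices with the contract fixed: two-best-hit based,
0 on ambiguity, capped.

## Extension

Every candidate locus is extended over a window of the read length plus
`d = 30` bp of slack on each side.

**One-gap semi-global pass.** The default extension aligns the whole read
(no clipping) with at most one gap run of length ≤ d: conceptually the read
is split into two halves, the gap is assumed in one of them, the other must
then align mismatch-only, and the displaced part is tried 1…d bases away.
Implemented as an exact vectorized maximization over (window placement,
gap length, gap side, split); the single insertion run may touch the read
boundary (the unconstrained DP optimum can leave edge bases gapped), while
deletions are strictly internal (an edge deletion is dominated by an
ungapped placement at a shifted start). Gap lengths are scanned in
ascending order with a provable early stop: a length-g gap can never beat
all-match minus its gap cost. The result is exactly the optimum of the
one-gap class: the tests compare it against a full affine DP with
traceback-based gap-run counting.

**Affine-SW fallback.** When the semi-global score drops below 90 % of the
read's all-match score, a full local affine alignment runs instead: a
score-only Gotoh pass (vectorized per row; the horizontal gap state is
resolved by a running-maximum scan, exact because gap-open ≥ gap-extend)
finds the best cell, then a banded traceback around the end-cell diagonal
recovers the CIGAR, doubling the band (16 → 256) until the banded score
reproduces the score-only value. Unaligned read prefix/suffix become soft
clips. Per read, SW work is rationed: at most `sw_budget = 32` score
passes, early stop after `stall_limit = 8` attempts without improving the
running best, and the traceback is skipped for candidates scoring strictly
below the running best (an equal score is a genuine tie and keeps its
traceback, so the two-best-hit mapQ sees it). When the fallback is skipped
or rationed away, the candidate keeps its semi-global result, whose score
is a lower bound — ranking is unaffected; in rare cases the runner-up
score is underestimated and mapQ correspondingly conservative.

**Long reads (≥ 150 bp).** Segments are seeded independently; if every
segment's best hit is unique and the hits are mutually local (same
chromosome/strand, positional deltas within read length + d), the whole
read is extended once over that locus; otherwise it is extended at every
segment's candidate loci and the best score wins.

## Supplementary alignment at breakpoints

A primary alignment clipping more than 20 bp triggers realignment of the
clipped tail: a 0-mismatch scan of 20 bp of the tail — by default the
20 bp furthest from the primary alignment, with the junction-side 20-mer
as a fallback probe (sequencing errors concentrate at the 3′ end, where
the outermost probe lives) — proposes candidate loci on both strands. The
*tail alone* is then SW-aligned at each locus (realigning the whole read
would merely rediscover the primary when the partner locus is nearby, as
at tandem-duplication junctions), and the best complementary placement is
emitted as a supplementary record (FLAG 2048) whose soft clips are the
complement of the primary's, so the two records jointly represent the full
read. The supplementary's mapQ is computed against the tail's all-match
score and capped at the primary's.

## Paired-end mapping

Both ends are aligned independently first; *alignment scores precede
mate-pair information*:

* both ends confident (mapQ ≥ 20): reported as-is, concordant
  (same chromosome, FR, |fragment − mean| ≤ 4σ) or not — a confident
  discordant pair is the SV signal and is never displaced;
* otherwise the cross-product of the two candidate lists is scored
  (`S₁ + S₂` + one gap-open unit of bonus for a concordant combination,
  small so sequence evidence dominates) and the pair mapQ is recomputed
  from the two best combination scores;
* an unmapped or weak mate next to a confident anchor is rescued by local
  SW over `mean + 4σ + mate length` in the FR direction, accepted only if
  it reaches 75 % of the mate's all-match score *and* beats the mate's own
  placement on score; a rescued alignment's mapQ never exceeds the
  anchor's.

The insert model (mean, σ, FR) is estimated as median and 1.4826 × MAD of
fragments from uniquely mapped same-chromosome pairs (σ floored at 10 bp;
≥ 100 qualifying pairs required, else nominal CLI values are used).

## Simulators

`make_genome` draws i.i.d. bases at GC 0.41 and, for a requested repeat
fraction, copies 200–2000 bp segments to random positions — enough repeat
structure to exercise multi-hit seeding, the deep scan and mapQ-0
discards. `simulate_reads` places reads uniformly on both strands with a
parametric quality-by-cycle curve (Q ≈ 38 decaying to ≈ 25, logistic
noise); substitution probability per base is the Phred error probability
rescaled so the dataset mean hits the requested rate (low-Q cycles err
more), and per-read errors are capped at 7 % of the read length.
`spike_indels` injects geometric(0.5)-length indels (1–10 bp, insert-only /
delete-only / mixed) at a per-base rate, preserving read length by
re-extending or trimming the 3′ end against the reference — which is why it
takes the genome as an argument — and updating truth positions exactly.
`simulate_pairs` draws FR pairs with Normal(mean, σ) fragments (rejecting
fragments shorter than twice the read length: overlapping ends are
disallowed) or, in discordant mode, ends independently from two different
chromosomes. `rearrange_genome` plans non-overlapping deletions,
insertions, tandem duplications, inversions and translocations (uniform
type mix by default, 100–2000 bp) on a block decomposition that retains
reference provenance, so the event list replays exactly and every junction
(breakpoint) is known in rearranged coordinates;
`reads_spanning_breakpoints` samples reads crossing those junctions with a
minimum flank.

What the simulators do *not* emulate: empirical sequencer error profiles
(miscall identity biases, homopolymer indels), PCR duplicates, coverage
bias, heterozygosity, and real genome repeat taxonomy (the repeat model is
exact duplication). Passing tests therefore demonstrate the method's
internal correctness and its behaviour under controlled error/repeat/SV
regimes, not performance on any particular instrument's data.

## Verification harness and problem sizes

The acceptance layer of the test suite (and `scripts/acceptance.py`, which
recomputes the same figures from scratch and writes them as JSON) runs:
seed-search equivalence against a brute-force position×signature oracle on
200 random genomes (0.6–6 kb, with planted repeats, Ns and indels, both
strands); DP-kernel equivalence against plain-Python Gotoh oracles on 500
random read/window pairs; parameter recovery on a 100-kb two-chromosome
genome (repeat fraction 0.1) with 5,000 × 100-bp reads at 1 % substitution
and 0.1 % indel rate; 50 engineered high-mismatch/decoy fixtures checked
against an all-locus scoring oracle; 1,000 concordant + 1,000
cross-chromosome discordant pairs with a zero-relocation check and the
concordant-vs-discordant F-measure gap; 500 breakpoint-spanning reads
(≥ 25 bp flanks) from a 24-event rearranged genome scored for
primary+supplementary read coverage; closed-form checks; and SAM/FASTQ
format integrity. Problem sizes were chosen so the whole harness completes
in a few minutes on one CPU while every code path is exercised at
realistic parameter values.

## Numerical and degenerate-input choices

Scores are floats; score comparisons in tie-breaks use a 1e-12 guard.
Ranking ties break deterministically by (chromosome, position, strand).
Candidate loci within `d` of each other collapse before extension (they
share the extension window), and identical placements found through
different seeds are merged keeping the best score, so a locus never
competes with itself for mapQ. All-N reads are emitted unmapped (FLAG 4);
an all-N genome refuses to index. Reads shorter than 12 bp are rejected as
unseedable. The 0-based/1-based coordinate conversion happens exactly once,
in the SAM writer.

## Known limitations

* The one-gap seed budget means a seed with two or more widely separated
  indels is found only via the half-seed fallback or SW rescue.
* mapQ is calibrated by contract (two-best-hit, tie ⇒ 0, cap 60), not
  against an error model; absolute values are not comparable across
  aligners.
* The index is rebuilt per `align` invocation in the CLI for simplicity
  (`index` subcommand serialization exists for reuse); genomes are assumed
  to fit in memory (megabase scale).
* Paired-end states cover FR libraries only; RF/long-insert mate-pair
  libraries and insert-size mixtures are out of scope.
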