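# Methods

This note documents the models, error assumptions, numerical choices and
limitations behind `nphp1sv`.

## Locus model

The reference (H1) architecture is a coordinate table over hg19 chr2:
three 45 kb LCR copies (45PROX 110,688,765–110,733,137; 45MID
110,983,704–111,031,088; 45DIST 111,153,516–111,197,896), two 358 kb copies
(358PROX 110,494,431–110,852,754; 358DIST 111,033,787–111,392,192), the
gene (110,880,913–110,962,639) and the locus span
110,080,914–111,762,639. Coordinates are treated as 0-based half-open
(browser convention), so length(45PROX) = 44,372 bp. Orientation is a sign
per copy relative to the family consensus (45PROX +, 45MID +, 45DIST −;
358PROX +, 358DIST −), making every pairwise relative orientation the
product of signs. Published sources disagree by one base on the 45PROX
start (110,688,765 vs 110,688,766); the table value is used — at 44 kb
scale nothing downstream depends on it.

Haplotypes carry two parallel descriptions kept consistent by every
transform: an annotated element list in haplotype-frame coordinates, and a
*segment path* mapping the haplotype back onto the reference (a list of
reference intervals with strand, plus unmapped stuffer segments). Deleting
a 45 kb copy removes its full interval, inserts a 5,936 bp stuffer at the
junction (net −38,436 bp for 45PROX) and shrinks the containing 358 copy;
the inversion reverses the segment strictly between 358PROX.end and
358DIST.start, negating orientations. Placing the breakpoints exactly at
the inner 358 boundaries is a simplification — real breakpoints fall
somewhere inside the 358 homology — but element order and orientation
logic, which is all downstream callers consume, is unaffected. The
inversion is an involution and conserves length and copy counts (property
tested).

NAHR susceptibility is purely geometric: a haplotype is *susceptible* iff
some pair of 45 kb copies flanks the gene (one proximal, one distal) with
equal orientation signs — the configuration required for intra-chromosomal
deletion-forming NAHR. No minimum-homology-length term is included because
none is established for this locus. This classifies {H1, H2, H3}
susceptible and {H4, H5, H6, H7} protected; note that H2/H3 remaining
susceptible after inversion (via the 45MID–45DIST pair brought into direct
orientation) is an inference of the geometric rule, and reports should be
read with that in mind.

## Synthetic data

The generators produce data with the statistical structure the callers
assume; every generator is a pure function of its inputs and
`SimParams.seed` (per-generator salts keep streams independent).

*Sequences.* One random master sequence per LCR family is mutated
independently per copy at the paralog-divergence rate δ (default 0.0025
per bp, giving pairwise paralog identity ≈ 0.995, the magnitude observed
between the real copies) and planted into a uniform random background.
The 45 kb consensus is embedded inside the 358 kb consensus at the real
containment offset, so 358-family homology runs continuously through the
embedded 45 kb copies. Haplotype sequences are assembled from the segment
path (reverse-complementing inverted segments; a shared random 5,936 bp
stuffer fills loss junctions). Uniform base composition and
substitution-only divergence are deliberate simplifications: no repeat
landscape, indels, GC structure or gene conversion, so detector
performance on real genomes will be somewhat worse than on these tests.

*SwaI sites.* Restriction sites are planted on an irregular grid
(spacing uniform on 9–21 kb, ~113 sites) drawn once from a fixed layout
constant — the layout plays the role of the genome's fixed site positions
and deliberately does not vary with the simulation seed. Site positions
project through the segment path, so deletions remove sites and the
inversion reorders them.

*Fosmids.* Clones sample a genotype component (fraction-weighted), insert
length ~ Normal(40 kb, 2.5 kb) truncated positive (fosmid cloning selects
~40 kb inserts; no published insert statistics exist for these libraries,
so the spread is a conventional choice), start uniform. Ends project
through the segment path into the reference frame, which makes discordance
emerge rather than being labelled: spans grow by copy−stuffer length
across a loss, strands equalize across an inversion breakpoint. Ends
landing inside a stuffer are unmappable (the real stuffer has no unique
reference position) and the clone is resampled, as are clones off the
locus. Chimeric clones and mapping errors are not modelled; `mapq` is
constant and exists so quality filtering is exercised.

*Rmaps.* Per molecule: each true cut is missed with p_miss = 0.10,
false cuts arrive as Poisson(1/500 kb), fragment sizes are scaled by
Normal(1, CV = 0.05), and fragments under 0.8 kb merge into a neighbor
(surface desorption of small fragments). These magnitudes are
conventional optical-mapping figures, configurable; published fragment-level
data for this locus do not exist, so simulation truth uses the
construction-implied values (38,436 bp loss, 5,936 bp stuffer).

*aCGH.* The design tiles one copy per LCR family (as the real 8×60K design
did), so a probe's signal sums over paralogs: per probe,
LR = log2(test dosage × identity / ref dosage) + Normal(0, σ = 0.10). The
reference genotype is a four-copy genome (H2/H2), mirroring the universal
reference sample. A single multiplicative identity factor models
cross-species hybridization attenuation; at equal dosage, identity 0.63
reproduces the chimpanzee-like ratio ≈ −0.67. This one-parameter model
reproduces the "between 0 and −1" band of diverged single-copy orthologs
but not probe-specific divergence variation.

*Read depth.* Windows of 500 bp tile the locus; each window's value is the
true family dosage plus Normal(0, σ_cn = 0.2) — the scatter a ~25×
whole-genome-sequencing windowed copy-number estimate typically shows.

*Populations.* Diploid individuals are drawn by random union of haplotypes
at per-population frequencies (Hardy–Weinberg; no inbreeding or linkage
structure).

## LCR detection

Exact 31-mer self-matches (both orientations, trivial diagonal excluded,
k-mer occurrence capped at 10) are clustered in two passes: first on the
diagonal (direct) or anti-diagonal (inverted) within a ±100 bp band — so
slightly offset sub-diagonals, such as an embedded copy displaced a few
bases, stay in one chain — then split at positional gaps over 2 kb.
Blocks ≥ 10 kb on both sides are verified by alignment and reported with
identities; families are connected components of the copy graph, where two
blocks are the same copy when they overlap reciprocally by ≥ 50%
(reciprocal overlap keeps a 45 kb copy nested inside a 358 kb copy from
collapsing the families). The chainer assumes substitution-dominated
divergence; large indels between copies would fragment chains (the band
parameter absorbs only small offsets).

Pairwise identity comes from a minimum-edit global alignment (edlib) —
`identity` is matches over ungapped aligned columns, `identity_gapped`
charges internal gap columns too (hence ≤ identity, matching the ordering
of the two published identity columns). The pair is aligned in canonical
order so the measure is exactly symmetric. Identity profiles score
non-overlapping 100-column alignment windows.

The PRDM9 hotspot motif (5'-CCNCCNTNNCCNC-3') has 8 informative positions;
with a uniform background the published "> 85% of maximum PWM score"
criterion reduces to "at most one informative mismatch", which is adopted
for determinism (score = matched informative positions / 8, hit iff
> 0.85). Both strands are scanned; overlapping opposite-strand hits count
separately. Counts on real sequence may differ slightly from a
full-PWM scan with a non-uniform background.

## Fosmid calling

An ESP is unusable below mapq 20; opposite-strand convergent pairs with
span in [32, 48] kb (≈ insert mean ± 3.2 sd — the original filtering was
manual, so the thresholds are explicit configuration here) are concordant;
longer opposite-strand spans are deletions, shorter are insertions,
equal-strand pairs are inversions; divergent opposite-strand pairs in
range are unusable. Sides (proximal/distal/spanning) come from the span
midpoint relative to the gene. Per-individual evidence requires
`min_support` agreeing clones (default 1). Because the insert distribution
has tails beyond any fixed thresholds, a small false-discordance rate is
intrinsic at defaults; it is exactly zero only when the thresholds cover
the sampled insert support.

## Rmap alignment and calling

The aligner minimizes, by dynamic programming, the total cost of pairing
query fragment runs (length a ≤ Δ) with reference runs (b ≤ Δ):
`(S_q − S_r)²/(2 (σ_rel S_r)²) + c_cut (a−1+b−1)` — a Gaussian relative
sizing-error term plus a fixed penalty per merged cut. Defaults Δ = 3,
c_cut = 3.0, σ_rel = 0.05, margin 5.0; fragments under 0.8 kb are merged
before alignment. The DP is verified against an exhaustive brute-force
enumeration on all maps up to six fragments; when a map pair cannot be
globally aligned under the block cap the aligner raises rather than
returning a cost (both routes agree on infeasibility). Cost is invariant
under simultaneous reversal of both maps.

Consensus construction is deliberately simple (full Bayesian map assembly
is the province of dedicated optical-mapping pipelines): molecules
pre-clustered by origin are aligned to a backbone molecule (modal fragment
count) and each block's query mass is distributed over backbone fragments
proportionally to size, then averaged. Calling assigns each consensus the
minimum-cost candidate among the in-silico H1–H7 digests; a runner-up
within the margin flags ambiguity, and the set of distinct best labels
across consensus maps is the allele-type set (> 2 types ⇒ mosaicism). At
default error parameters, ≥ 95% of seeded simulations per candidate
recover the planted haplotype (tested at 100 simulations per candidate
with 10 molecules per consensus).

## Dosage rules

Mean LR is the arithmetic probe mean; DLRS is the sample standard
deviation of successive differences divided by √2 (plain, not robust,
standard deviation — chosen for determinism and testability; it needs at
least three values). The intra-species rule picks the integer
c ∈ 1..cn_max minimizing |LR − log2(c/cn_ref)| (ties toward smaller c;
below log2(0.5/cn_ref), i.e. under half a copy's signal, the call is 0).
Applied to the published per-sample ratios it reproduces 18 of 20 human
calls and all 3 gorilla calls; the two exceptions (−0.18 called 3, −0.65
called 2 in the source, where orthogonal evidence informed the call) are
asserted as known discordances rather than fitted around. The
inter-species rule is three-way: LR ≤ −1 absent (0 copies), −1 < LR ≤
−0.25 reduced (cn_ref/2), above −0.25 equal (cn_ref). The −1 and 0
boundaries follow the published segment-content convention; −0.25 is this
package's boundary separating the gorilla cluster (≥ −0.18, equal) from
the chimp/orangutan cluster (≤ −0.51, reduced), placed midway on the log2
scale between the clusters it must separate. It reproduces all 14
published nonhuman calls. Content classes use closed upper boundaries
((−∞,−1], (−1,0], (0,∞)), with probe spans taken from midpoints between
adjacent probes.

## Statistics

Kruskal–Wallis uses average ranks, the standard tie correction and the
χ²(k−1) tail; an exact permutation p-value (enumeration of all group
assignments) is available for total n ≤ 10, a limit keeping enumeration
≤ a few thousand assignments. Welch's t uses the Welch–Satterthwaite df
and the t tail. Both statistics are computed from their formulas and
cross-checked in tests against independent implementations; calibration
tests confirm null p-value uniformity (Kruskal–Wallis) and type-I error
within [0.03, 0.07] at α = 0.05 under unequal variances (Welch). Whether
the original population comparison used integer copy-number classes or
raw intensities is not recorded; this package takes integer classes.

## Evidence integration

Rmap allele types outrank fosmid evidence on conflict (the single-molecule
assay is structurally definitive); conflicts are flagged, never dropped.
The dosage call fixes total45, and consistent diploid genotypes are the
pairs from the observed allele types whose copy counts sum to it. With
exactly two observed types in a non-mosaic sample the genotype must carry
both (each consensus map is a real allele); with three or more, the
mosaic interpretation enumerates all dosage-consistent pairs — for allele
types {H5, H6, H7} at total 3 this preserves the H5/H7-vs-H6/H7 ambiguity
exactly, as it cannot be resolved without per-cell data. Mosaic fractions
are not estimated. Without dosage, a single allele type yields a
haploid-style report.

## Problem sizes

Default simulation sizes — 1.68 Mb locus, ~113 restriction sites, 10–12
molecules per consensus, 200–500 clones per library, ~960 probes, 100–200
replicates per recovery experiment — were chosen so each recovery
experiment has enough replicates for a stable ≥ 95% criterion while a full
test run completes on a laptop in minutes.

## Known limitations

Real-data adapters (FASTA/BED/TSV readers) accept external inputs, but no
claims are made beyond the synthetic conditions above: no read-level
simulation, no chimeric clones, no assembly gaps, no gene conversion, no
probe-level hybridization variation, and breakpoints idealized at LCR
boundaries. The detector's anchor-and-chain design assumes high-identity
(> ~97%) duplications; older, diverged repeats need smaller k and looser
chaining.
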