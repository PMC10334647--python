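# Methods

This note documents the models and procedures implemented in `hicphase`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the simulated benchmarks do and do not show.

## Pipeline model

### Input styles and the merge stage

Three contig-input styles are supported. *Paired-haplotype* input carries
explicit bubble pairs; pairing and coverage travel in a sidecar TSV
(`contig_id, partner_id, coverage`) rather than in assembler-specific
header syntax, because header conventions vary by assembler and version.
*Pseudo-haplotype* (primary + alternative files) and *haplotype-ignorant*
(flat) inputs are first converted: the contig set is self-aligned with
minimap2 (`-c -D --secondary=no`), alignments under 80% identity
(`identity_min`) or shorter than 1 kb (`min_align_len`) are discarded, and
colinear same-strand chunks between one contig pair are chained before
ranking — minimap2 splits homologous relationships around heterozygous
inversions, and the chain hull is the quantity the opposite-assignment
step needs.

Each contig's *opposite* is the partner of its longest retained chain.
Candidates commit greedily in decreasing aligned length; a claim that
overlaps (≥ 1 bp) an already committed claim on the same opposite removes
the claimant as a repeat, while a disjoint claim pairs with the opposite's
unclaimed region. Contigs are then minced at claim boundaries; cut points
closer than 200 bp (`min_piece_len`) to a neighbour are dropped so indel
drift at piece ends does not create unusable slivers. Associated pieces
receive coverage C (`C_consensus`, default 40), unassociated pieces 2C.

Non-bubble contigs are heterozygous iff coverage < `C_hetero ×
r_upper_threshold` (strict inequality; default threshold 1.75). `C_hetero`
is defined here as the mean coverage of contigs in committed bubble pairs,
falling back to half the main coverage-histogram peak when no bubbles
exist — a self-contained stand-in for the coverage estimate an assembler
would provide.

The merge output is the array T (entries `[u,v]`, `[u,-]`, `[u,u]`); the
consensus sequence is the primary member's sequence verbatim (no
polishing between members, by design). Every member records provenance
(source contig, offset) so read evidence and truth coordinates can always
be lifted through later splits.

### Read evidence

All evidence stays in *source-contig* coordinates and is lifted on demand
through two piecewise-affine maps (source → consensus contig; consensus
contig → scaffold). Secondary members lift through a linear scaling onto
the primary's coordinates, with strand from the pairing alignment; this is
exact to within the indel drift between haplotypes (tens of bp at 0.5%
heterozygosity), far below the 5–100 kb scales the scaffolder works at.

Long-read PAF alignments are selected per read greedily by decreasing
sequence identity (#match-sites / alignment length), skipping read-interval
overlaps; candidates shorter than 500 bp are noise-floored away. Accepted
alignments are split at consensus-segment boundaries, so links appear
between every pair of consecutive consensus contigs a read crosses. Link
endpoints carry a *pointing direction* (towards the high or low coordinate
side) instead of a hard 5'/3' label; the direction composes with segment
and placement orientations during lifting.

Short reads map by 32-mer exact unique match. A k-mer hitting exactly the
two members of one consensus contig still maps (to the primary member,
deterministically) with the record tagged `consensus`; such records serve
consensus scaffolding but are excluded from phasing, where they would be
uninformative. Hi-C pairs use the same mapping contract with insert length
and orientation ignored; the pipeline equally accepts pre-mapped pair
records as TSV.

### Contact-map statistics

Matrices bin contacts at `bin_size` (100 kb at genome scale; 5 kb in the
desk profile). Trailing partial bins are dropped — a partial bin would bias
band means. Junction geometry, with the junction between bins b−1 and b:
at each diagonal distance k = 1..`k_max` (default 10, matching the
misassembly score's explicit sum), the *outer* pixels are the distance-k
band crossing the junction and the *inner* pixels of each side are the
distance-k band immediately adjacent to it. Matching distance on both
sides is essential: Hi-C counts decay steeply with distance, so comparing
distance-k outer pixels against a mean pooled over distances ≤ k would
flag every junction. N_in,k and μ_in,k refer to the same pixel set, which
keeps S a true per-band between-class variance; terms with
N_in,k + N_out,k = 0 contribute nothing, and an empty band leaves μ = 0.

The erroneous-edge rule is the conjunction of the normalised-S and R
criteria (`s_threshold` = 1.0, `r_threshold` = 1.6). A zero normaliser
S_side,0 (degenerate sparse map) contributes a ratio of 0, and a junction
where either side is shorter than one bin is untestable — the edge then
stands or falls on its weight and long-read support alone.

The misassembly score uses band means within a triangular motif of
`motif_halfwidth` = 10 bins around each bin b, against the pooled
per-distance means μ_all,k of all scaffolds ≥ `min_matrix_scaffold`
(300 kb genome scale / 15 kb desk; if none qualify, all scaffolds with at
least k_max+1 bins, with a warning). Zero local means are floored at half
a count (0.5) before dividing. Peaks are strict local maxima over ±2 bins
(`peak_window`); plateaus keep their leftmost bin and bins whose window
leaves the profile are excluded, making peak sets deterministic. The
threshold P is swept over {0} ∪ {peak heights}; each trial splits the
scaffold at every peak above P and scores each cut by S_upper + S_lower;
the P with the largest mean wins, ties resolved towards larger P (fewer
splits). Flagged bins must additionally pass the erroneous-edge rule at
their boundary before the scaffold is split — at the minimum-coverage
position within the bin (plateau minima take their midpoint; without a
coverage track, the bin midpoint).

### Scaffolding

Stage one joins non-branching chains of the long-read link graph: an edge
is used only when it is the sole incident edge above `minLink` (default 0,
i.e. any support) at both sequence ends, and the Hi-C erroneous-edge test
accepts the tentative junction. Cycles resolve by construction — the
weakest edge of a cycle is processed last and skipped. Gap sizes are the
median link gap, floored at one N.

Stage two iterates the Hi-C end graph. Edge weights count pairs with both
ends within L of the respective scaffold ends (an end position inside both
windows of a short scaffold is assigned to the nearer end); edges below
the weight threshold (50 for L < 100 kb, 100 above, at genome scale) are
removed. The maximum-weight edge (ties: lexicographically smallest node
pair) is tested with Hi-C and — in the first pass — with long-read links:
direct support confirms it; support for an alternative end pairing
redirects the join (after the alternative passes the Hi-C test); failing
both, misassembly candidates in the two end windows (link endpoints whose
mate maps to a third scaffold; for paired libraries the region extent is
the insert tolerance a + 3d) are split at minimum coverage and the round
continues, else the edge is discarded. Joins consume both ends: all other
edges at those ends disappear when the weights are recomputed. L grows
10 kb → 100 kb in 10 kb steps, then to 1 Mb in 100 kb steps, with
misassembly correction re-run before every round; the whole schedule then
repeats once without the long-read check, so that repeats longer than the
reads can still be bridged — the Hi-C test remains active in that pass.

### Phasing

Scaffold members expand into haplotype blocks via T. Links between members
of two blocks within one scaffold count as parallel (same slot) or cross
(opposite slots); links touching homozygous blocks, intra-block links and
consensus-tagged records are ignored. Blocks connect greedily in
decreasing |parallel − cross| (ties: smaller block-index pair) through a
parity union-find; cross-majority connections flip one component. Pairs
with parallel = cross never connect, and candidate pairs are restricted to
blocks of the same scaffold, since division is per scaffold. Scaffolds
divide between adjacent haplotype blocks of different components, except
that an unphased singleton strictly inside one component's span receives a
seeded random phase (recorded as `random` in the report) and no division.
Homozygous blocks attach to the preceding piece and are copied into both
outputs; `[u,-]` blocks emit an equal-length N placeholder on the
alternative side. Hi-C and long-read links are pooled with equal weight —
the simplest faithful reading of using both evidence types together.

## The simulator and what the benchmarks show

`diploid_sim` generates haplotype 0 uniformly at random, derives haplotype
1 by seeded point mutations (SNV:indel 10:1, indels 1–10 bp) at the
requested per-base heterozygosity, plus inversions (1–10 kb) at a separate
`sv_rate` (default 10⁻⁶/bp, about one per megabase — a rate at which
inversions exercise the code without dominating the genome). The liftover
between haplotype coordinate systems is the cumulative indel shift map;
inversions preserve length, so positions inside one are mapped affinely.

Hi-C pairs follow a power law P(d) ∝ d^(−1) on [1 kb, chromosome length]
for intra-chromosomal separations, with 5% uniform inter-chromosomal
background (`inter_frac`) — the canonical distance-decay shape of Hi-C
libraries with TAD-level structure deliberately absent. With probability
`trans_hap_frac` (default 0.5) the haplotype of a pair's second end is
re-drawn uniformly, modelling haplotype-nonspecific mapping; at the
default this leaves a 3:1 parallel:cross phasing signal, and at 1.0
phasing becomes information-free (a property the tests check). Long reads
(gamma lengths, mean 15 kb) are emitted with their truth alignments as
PAF, so the pipeline runs without an external aligner; an identity derived
from the configured error rate is recorded. Fragmentation cuts haplotype 0
at random points (mean 50 kb) and haplotype 1 at their liftover images;
fragments below the variant-density threshold `collapse_threshold`
(10⁻³/bp) collapse to a single copy. Contig orientations are randomised
(jointly for bubble pairs, independently otherwise), and pseudo-haplotype
alternatives are split in two, so the mincing and secondary-association
paths run in every end-to-end test.

The desk profile — 2 chromosomes × 500 kb, 0.5% heterozygosity, 30× Hi-C,
20× long reads, 5 kb bins — was sized to exercise every code path in
seconds per run while keeping ~100 Hi-C pairs per bin pair near the
diagonal, comparable to a real 100 kb-bin map. Length-like parameters
scale with the bin ratio (L schedule 500 bp–50 kb, end windows and matrix
minimum 15 kb); the Hi-C edge-weight thresholds are counts and scale with
coverage instead (25/50 at 30×).

What passing benchmarks show: the score kernels are algebraically correct
(oracle equivalence), the junction tests discriminate cleanly under ideal
power-law contacts, and the full pipeline is consistent end to end —
merge, lifting, orientation handling, splitting and phasing compose
without losing or misplacing bases. What they do not show: robustness to
TADs and other local chromatin structure, to restriction-site and
mappability bias, to chimeric *input* contigs beyond the injected cases,
to collapsed segmental duplications, or to switch errors already inside
the input assembly — the method by design inherits input phasing within
each contig, and polyploid genomes are out of scope.

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; AGP and reports 1-based
  inclusive.
- Hi-C-joined scaffolds receive a fixed 500 N gap (`hic_join_gap`); Hi-C
  carries no gap-size information.
- Secondary-member coordinate lifting rounds to the nearest base and
  clips to the member; splits of a merged pair cut the secondary
  proportionally (at least 1 bp per side).
- Coverage tracks are diff-array depth counts of accepted long-read
  alignment intervals at 100 bp resolution (`coverage_resolution`).
- Empty inputs: an empty contig set merges to an empty T; a zero-contact
  matrix yields no peaks and P = +∞; `n50` of an empty list and a
  non-positive `C_hetero` raise usage errors rather than guessing.
- All randomness (simulator, random phases) flows from explicit seeds;
  two runs with identical inputs and seed are byte-identical, which the
  test-suite asserts on the full FASTA/AGP/report output.
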