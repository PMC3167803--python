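# Methods

## Model and representation

The assembler works on the node set of a bidirected de Bruijn graph whose
nodes are *k-molecules*: the pair {S, S̄} of a k-mer and its reverse
complement, stored once under the canonical (lexicographically smaller)
strand. k is restricted to odd values in [1, 31]: 31 because a k-mer is
packed two bits per base into one 64-bit word, odd because an even k
admits palindromic k-mers that are their own reverse complement, making
the canonical representative of a double-stranded molecule ambiguous.
With the first base in the most significant bits, integer comparison of
packed codes is exactly lexicographic comparison of the strings, so
canonicalization costs one comparison and one reverse-complement.

Partitioning must send a k-mer and its reverse complement to the same
place, so the hash is applied after canonicalization. The hash is a fixed
64-bit linear congruential map h(x) = ((a·x + c) mod 2⁶⁴) >> 33 with
a = 6364136223846793005 and c = 1442695040888963407 (the Knuth MMIX
multiplier). These constants are a documented constant of this
implementation, chosen once for good bit mixing; the only property the
pipeline relies on is near-uniform occupancy, which the test suite checks
(< 10% deviation per bin over 10⁴ random k-mers on 4 partitions).
Partitions are processed sequentially; the contract — and the tested
property — is that every externally visible artifact is byte-identical
across partition counts 1, 2, 4 and 8, so concurrent execution over
partitions is an implementation freedom, not a semantic one.

Each record carries a 16-bit multiplicity, saturating at 65535 (counts
above that carry no assembly information), and an 8-bit adjacency mask:
the low nibble holds right-extensions of the canonical strand indexed by
the 2-bit code of the extension base, the high nibble the
right-extensions of the reverse-complement strand (equivalently, left
extensions indexed by the complement of the left base). The nibble layout
itself is a free choice; correctness is pinned by the edge-symmetry
invariant (if u records an edge toward v, v records the reciprocal edge),
which the tests verify by full scan after every mutating pass.

Records live in per-partition sorted numpy vectors. Lookup is binary
search restricted to the index range of the code's top-r-bit prefix
(r = 24, clamped to 2k so the table is meaningful at small k); the prefix
table is a dict from present prefixes to ranges, which is behaviorally
the full 2^r table with empty ranges omitted. Equivalence of accelerated
lookup with a plain linear scan is tested on random probes. Removal
tombstones records so the sorted order and prefix table remain valid
mid-pass; `compact()` rebuilds both at pass boundaries.

## Graph construction

Edges are recorded only from read adjacency: for the k-mer at read
position i, the extension bases are S[i−1] and S[i+k], complement-swapped
onto the canonical record when the occurrence is non-canonical; at read
boundaries no bit is set. This is deliberately *not* the alternative of
probing all eight possible neighbours for existence, which creates edges
between k-mers that never co-occur in a read. Multiplicities are counted
in the same pass over reads. Reads are sanitized first: any non-ACGT
character becomes 'A' (and input is uppercased); reads are never
discarded for ambiguity.

## Simplification

Three passes, in order:

1. **Low-frequency dead ends.** The multiplicity threshold M is the
   location of the first local minimum of the window-3 moving average of
   the k-mer multiplicity spectrum, scanned between the error mode near
   multiplicity 1 and the spectrum's main peak beyond multiplicity 2;
   when no interior minimum exists (clean data, or no coverage peak) the
   conservative fallback is M = 2. Records that are dead-ended on at
   least one side with multiplicity < M are removed a snapshot-round at
   a time, neighbours repaired, until a round removes nothing — removal
   exposes new dead ends, which is why single rounds do not suffice.
2. **Tips.** From each one-sided dead end the chain is extended away
   from the dead side while extension is unambiguous (current out-degree
   1, next in-degree 1). If the walk ends at another dead end the chain
   is an isolated linear chain — a legitimate short contig, never
   clipped. Otherwise the chain terminates against a branching node
   (which is retained), and is removed iff its sequence length,
   kmer_count + k − 1 bases, is strictly less than 2k. Applied to a
   fixed point. Tip length is measured in bases; the 2k bound with a
   strict comparison makes a 2k−1-base branch removable and a 2k-base
   branch kept, which the tests pin.
3. **Chain extraction.** A directed edge u→v is a *chain edge* iff u has
   out-degree 1 and v in-degree 1 in the walk orientation; chains are the
   maximal paths of chain edges, so the decomposition is structural and
   independent of traversal order and partition count. Walks start from
   dead ends first (one direction); a chain whose both terminals are dead
   ends could be discovered from either end, so it is kept by the walk
   whose starting partition index is the smaller, with ties (both
   terminals in one partition) broken toward the smaller terminal code —
   every chain is emitted exactly once. Remaining k-mers (cycle
   components) are walked in both directions from an arbitrary start;
   a loop is broken at the start point and emitted once as a linear
   chain. A k-molecule may appear twice in one chain in opposite
   orientations — the two raw k-mers of an inverted repeat — so only a
   repeated *oriented* node terminates a walk; this case was isolated by
   the naive-oracle comparison (a 20 bp perfect palindrome in one random
   test genome) and is covered by it.

Chain coverage is the multiplicity sum over the chain divided by its
sequence length; chains below `min_coverage` (default 1.0, a
conservative floor exposed as a flag) are discarded as likely chimeric.
Kept chains are sorted by canonical sequence before emission, making
output byte-stable across runs and partition counts.

## Bubble merging and contigs

Unitigs become nodes with twins; node coverage here is mean k-mer
multiplicity (multiplicity sum / k-mer count) rather than the per-base
chain coverage, because short nodes would otherwise be diluted by the
k−1 overlap and compare unfairly against their flanks. Edges come from
re-threading the original reads: adjacent read k-mers in different nodes
create or re-support an edge; no per-read mapping information is kept.

Bubble detection is a shortest-path sweep from each branching node, nodes
visited in order of cumulative path length in bases measured to the
node's *start* (interior bases from the source), capped at 5k bases — a
simplification of the length/coverage priority some assemblers use, kept
because the merge decision itself is what carries the behavior: a second
arrival at a node exposes two source-rooted paths, and the pair is merged
iff the interior path sequences differ by ≤ 2 bases in length and align
at ≥ 90% identity. Identity is matches / alignment-columns under a global
unit-cost alignment (match +1, mismatch −1, gap −1; Bio.Align). Only
clean arms are merged (interior nodes privately connected along the
path); the lower-coverage arm — a direct edge counts as infinitely
covered — is deleted, its coverage mass folded length-weighted onto the
kept arm and its entry/exit edge support transferred, and the sweep
repeats to a fixed point. A merge log accounts for every discarded base.

Contig emission removes node-level tips (< 2k bases, dead-ended against a
branch) and nodes with coverage below 0.5× the median node coverage (the
cutoff is relative so it adapts to simulated depth, and overridable),
then concatenates maximal unbranched runs with the k−1 overlap collapsed.
Contigs of ≥ 100 bases are reported, canonical strand, sorted.

## Scaffolding

A mate maps to a contig when ≥ 80% of its k-mers vote for one
(contig, strand, offset) triple and no other contig ties; ambiguous and
half-mapped pairs are dropped. Only pair evidence is used to link
contigs — a single read spanning several nodes never creates a link. The
insert size of a same-contig pair is its outer-end-to-outer-end span;
per-library median and standard deviation require ≥ 100 such pairs.
Cross-contig pairs are grouped by (contig pair, relative orientation);
each pair contributes a gap estimate median_insert − tail_a − tail_b,
where tail is the distance from the mate's outer end to the gap-facing
contig end, and a group of ≥ 3 pairs becomes a reliable link. Ordering is
greedy by support: a link is accepted if both contig ends are free and it
does not close a cycle (the closing, lower-support link is rejected and
reported). Paths are emitted as scaffolds with gaps of max(1, round(gap))
'N's — negative estimates clamp to a single N and overlapping contigs are
not merged, which keeps splitting at N-runs an exact inverse of emission.

## Statistics

NGx is computed against the reference genome size: lengths sorted
descending are accumulated until the running total *strictly* exceeds
x% of the genome size, and the crossing length is returned (N50
conventions differ between > and ≥; the strict reading is implemented
and documented). Sequences shorter than 100 bases are excluded before
statistics. Scaffold-to-contig splitting takes maximal N-free runs.

## The read simulator

The generator emulates the target data regime: 36 bp mates (default),
insert sizes rounded from normal(200, 20) and clamped to
[2·read_length, genome_length], fragments uniform over the genome, mates
inward-facing from opposite strands, i.i.d. substitution errors, and an
optional second haplotype differing at planted SNP sites sampled at 50%
allele balance — the source of bubbles. Fragment starts are sampled on an
interval padded by (insert − read_length) on each side with mates clipped
at the genome boundary, so per-base coverage is uniform across the whole
genome including the ends; confining starts to [0, L − insert] leaves the
terminal ~insert bases systematically under-covered and makes exact
end-to-end reconstruction impossible at moderate depth. Read count is
coverage·L/(2·read_length). Everything is reproducible bit-exactly from
the seed, and truth tables (fragment coordinates, SNP positions) are
emitted for downstream assertions.

What the simulator does not model: indels, quality-score structure,
GC-coverage bias, chimeric fragments, adapter contamination, and long or
structured repeats beyond what a uniform random genome contains. Passing
tests on this generator therefore demonstrate the graph algorithms'
correctness under the stated noise model, not end-to-end performance on
real libraries.

## Problem sizes and numerical choices

The verification suite runs at desk scale, chosen so the full test suite
and the acceptance script each complete in minutes on one CPU: 20 kb
repeat-free genomes at 30–40× for reconstruction and error-cleanup
checks, 50 × 2 kb genomes for the oracle comparison (k = 15), 10⁴ pairs
for insert recovery, and an 8 kb two-contig layout for gap recovery. The
gap-recovery fixture uses a 500 ± 25 bp insert library: with 36 bp mates
a pair can only bridge a gap g when its insert exceeds g + 2·36, so a
200 bp library cannot span the fixture's 150-base gap at all — the
longer library exercises the same estimator under geometry where the
estimate is identified. Remaining numerical choices: ties in canonical
ordering cannot occur (odd k); walks and emissions are sorted so all
outputs are deterministic; degenerate inputs (empty read streams, reads
shorter than k, empty graphs) produce empty outputs rather than errors.

## Known limitations

Repeats of length ≥ k−1 fragment the assembly, as for any de Bruijn
assembler at fixed k; no repeat resolution beyond scaffolding is
attempted. The bubble sweep merges one pair per branching node per
iteration and caps search depth at 5k bases, so deeply nested or long
bubbles (e.g. from clustered variants) survive. Scaffolding builds simple
paths only — no multi-library hierarchy, no overlap merging across
negative gaps. Mate mapping is exact-k-mer voting and tolerates at most
~20% of a mate's k-mers being error-corrupted; heavily erroneous mates
simply drop out of the pair database.
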