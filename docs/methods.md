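# Methods

## Gene-order model

A mitochondrial gene order is a circular sequence of oriented elements:
the 13 protein-coding genes, 2 rRNAs, 22 tRNAs (one-letter code, with
L1/L2 and S1/S2 isoacceptors), the Control Region (CoRe) and the
L-strand replication origin (O<sub>L</sub>). Because circular DNA has no
intrinsic start or reading side, one arrangement has 2·n equivalent
readings; canonicalization rotates (and, if needed, mirror-complements)
the order so *cox1* comes first on the H-strand. Copy tags for
duplicated elements (a/b for genes, 1/2 for CoRe) are derived from the
canonical traversal and never stored, so equality is insensitive to how
an input happened to be labeled. O<sub>L</sub> is treated as unsigned:
it participates in order comparison but not in orientation, since it is
a short structural element never reported as inverted. Partial genomes
missing *cox1* canonicalize from a configurable fallback label and are
flagged.

Coordinates are 0-based, half-open and circular throughout;
origin-spanning features carry `end > genome_length` and are read modulo
the length. Converters to and from 1-based closed dialects are provided
and round-trip losslessly.

## Rearrangement events and the search model

Events are inversion (segment reversed, strands flipped), transposition,
inverse transposition, loss of a contiguous segment, standalone partial
random loss (PRL: simultaneous loss of any set of *redundant* copies —
every dropped element must leave an identical survivor), and
duplication-loss events (TD/TDRL/TD-PRL and the triplication variants),
represented as a segment plus one keep-vector per tandem copy. A
completed duplication-plus-loss is one event, matching how rearrangement
mechanisms are counted in the mitogenomics literature.

Two restrictions shape the default search model, and both were design
decisions forced by experiment rather than taken from convention:

1. **Contiguous keep-blocks.** With arbitrary keep-vectors a single
   TDRL can realize *any* interleaving of two subsequences of the
   duplicated block, which collapses most pairwise distances to 1 and
   makes biologically absurd one-step transitions (e.g. regaining a
   precise duplicated tRNA pair inside an otherwise-eroded copy)
   optimal. The default therefore requires each tandem copy to retain
   one contiguous run of the segment — the random-loss phase excises
   runs — which still covers every mechanism used in the mapped
   pathways (block transpositions are a suffix-keep + prefix-keep
   pattern). Single-gene transpositions are carried by the transposition
   event kind. The unrestricted pattern space remains available via
   `EventModel(contiguous_keeps=False)`.
2. **Dollo-leaning weights for the reconstruction scenario.** Under
   strict unit costs, re-*gaining* a Control Region by a fresh
   duplication is as cheap as losing one, and the globally optimal
   history of the 28-taxon scenario then derives shared orders by
   re-duplication instead of descent, contradicting the
   spacer-remnant evidence that corroborates the loss-based pathways.
   The reconstruction preset (`NOTOTHENIOID_MODEL`) therefore weights
   duplication-type events 2 against 1 for losses, PRL, inversions and
   transpositions: structure is easier to lose than to regain. Event
   *counts* remain unweighted; `EventModel()` keeps unit costs for
   plain pairwise inference.

`infer_events` is a breadth-first expansion over enumerated single-event
successors with state deduplication, plus a directed "final hop" test
that recognizes any single event (including duplications longer than
the enumeration cap, and triplications) landing exactly on the target.
All co-minimal paths are reconstructed from the predecessor graph;
triplications are only recognized as a terminal step. Enumeration of
duplication events is capped at segments of `max_dup_len` elements
(default 8) and directed recognition at `max_dup_len_directed`
(default 10); searches run by default on the *nad5*–*trnF* hot-spot
slice, with *nad5*–*trnM* used when the Trematominae inversion (which
crosses into the IQM tRNA cluster) is in play.

## Ancestral reconstruction

Tip orders are mapped by Sankoff dynamic programming over a finite
candidate pool: the distinct observed orders plus the intermediates
discovered on bounded pairwise minimal-path searches between them
(capped per pair, deterministically by notation string). Transition
costs between candidates are completed by shortest paths through this
pool graph, so multi-event transitions price as sums of single-event
steps. This mirrors how a manual parsimony reconstruction posits only
observed orders plus the occasional unsampled intermediate (the
pre-inversion Trematominae arrangement arises automatically as a
pool junction). All co-optimal root states are reported; the primary
assignment used for tabulation breaks ties lexicographically by state
name. A gene order is flagged homoplastic when it is derived
(child ≠ parent) on two or more edges that do not lie on one
root-to-tip path.

The 28-taxon scenario encodes the eight nototheniid gene orders and the
reference topology; RacoGO and GymnGO element lists are transcribed from
figure panels and carry `figure_derived=True` in their metadata. The
reconstruction yields 11 events (one ancestral TD-PRL, five PRLs, one
loss, one inversion, two TDs, one Tri-PRL), a VertGO root anchored by
the three non-Antarctic lineages, and double origins for Noto2GO and
Noto3GO; the result is identical on the alternative topology that moves
*P. antarctica*.

## Spacer scanning

Spacers are inter-feature gaps ≥ 10 nt (wrap-around handled). Each is
locally aligned (Smith–Waterman via Biopython's `PairwiseAligner`;
match +2, mismatch −3, gap open −5, extend −2) against both strands of
every gene of its own genome, CoRe included. A hit passes with
score ≥ 30, ≥ 15 aligned columns and ≥ 70% identity, or a perfect
≥ 15-mer. These cutoffs were calibrated on i.i.d. null spacers against a
whole-mitogenome library: the Karlin–Altschul tail puts chance local
scores near 20, and the measured false-positive rate at the defaults is
below 1% while planted remnants of ≥ 20 nt at ≤ 10% divergence are
always recovered. Any passing hit classifies the spacer GR-ISP. For
protein-coding targets the matched remnant is translated in the donor
gene's frame (vertebrate mitochondrial code) and the longest identical
amino-acid run against the protein is reported.

## Compositional statistics

Skews are AT = (A−T)/(A+T) and GC = (G−C)/(G+C) (N ignored; undefined
flagged on zero denominators). Degenerate-codon classes are computed
from translation table 2 at runtime: NNN4 if all four third-position
variants are synonymous, NNR2/NNY2 if exactly the purine/pyrimidine
pair is (TGA = Trp and ATA = Met make TGR and ATR two-fold; AGA/AGG are
stops and classify "other"). Third positions are pooled per genome
across protein-coding genes, excluding genes encoded on the opposite
strand in the current annotation (automatically excluding *nad6*
everywhere and *nad1* in inverted Trematominae-like genomes), since
their sites mix the two mutational regimes.

Strand symmetry is tested with the binomial normal approximation
z = (nA−nT)/√(nA+nT), two-sided, with a low-power flag under 10 sites;
the exact form of the originally cited equations is not reprinted in the
source literature, so the normal approximation is the documented choice
and its type-I error is verified at nominal α on simulated nulls.
Group comparisons of |skew| use the pooled-variance Student's *t*. A
genome is called a **full** compositional reversal only when, in both
the NNN4 and NNR2+NNY2 pools, the AT and GC skew signs oppose the
uninverted expectation (AT > 0, GC < 0) *and* both symmetry tests reject
at α = 0.05; any partial subset of sign opposition gives **partial**;
rejection with expected signs is the ordinary strand bias and gives
**none**. No multiple-testing correction is applied by default,
mirroring per-gene reporting practice.

## Ka/Ks

Pairwise Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous
site fractions from the code table (changes to stops excluded from the
possibilities), observed differences averaged over all shortest
substitution paths that avoid stops, Jukes–Cantor correction
d = −¾ ln(1 − 4p/3), saturation flagged at p ≥ 0.75, and ratios left
undefined when Ks = 0 (never infinite). Codons with gaps or ambiguity
are dropped pairwise. Inputs are pre-aligned codon alignments; alignment
construction is out of scope. Distributions are summarized per gene as
median/mean/quartiles with 1.5×IQR whiskers, ordered by OXPHOS complex
(I: *nad*; III: *cob*; IV: *cox*; V: *atp*).

## Synthetic-data generator

The simulator builds a ~16.5 kb VertGO ancestor with realistic element
lengths and valid ORFs, then evolves it along a tree. Sites are
independent with transition bias κ = 4 and two deamination multipliers
(A→G, C→T, ×4) on the strand left single-stranded during replication;
with normal polarity this drives the majority-sense third positions
toward positive AT-skew and negative GC-skew, and a scripted
Control-Region inversion can flip the polarity and hence the expected
signs. The ancestor is pre-evolved for 3.0 expected substitutions/site
(burn-in) so tip compositions sit at the process equilibrium rather
than at the arbitrary starting draw; long branches are evolved in ≤ 0.5
rounds so sites can substitute repeatedly. Protein-coding genes accept
nonsynonymous changes with per-gene probability ω (in-frame stops never
accepted) — crude, but sufficient for Ka/Ks rank recovery. Scripted
events act on a label-addressed segment list; material dropped by
duplication-loss events becomes spacer remnants that decay by boosted
substitution plus geometric deletions (rate 0.1/site per unit branch
length, mean chunk 6 nt — mitogenome compaction is fast, so old
remnants disappear). All randomness flows from one seed through named
substreams (per branch, per segment), and a truth log records planted
events, per-node orders, polarity and remnant provenance.

The shipped `synthetic_full` scenario (10 tips) replays the pathway
structure of the study system: one ancestral TD-PRL, convergent PRL
losses in two subclades (the planted homoplasy), a further loss-derived
order, and the polarity-flipping inversion with a long (2.0,
near-equilibrium → full reversal) and an intermediate (0.4, AT channel
flips before GC → partial reversal) post-inversion branch.

What the generator does **not** emulate: rate variation across sites
and lineages, realistic tRNA/rRNA structure, indels in functional
genes, recombination, numts, and concerted evolution of duplicated
Control Regions. Passing tests therefore demonstrate internal
consistency of the methods under the stated model, not performance on
real sequence data.

## Problem sizes and numerical choices

The default test and acceptance runs use: the 28-taxon reconstruction on
the *nad5*–*trnM* window; 200 planted-event trials (pairs whose true
history collapses to a shorter mechanism are excluded from the
denominator — parsimony cannot prefer the longer account); 500 planted
remnants and 1000 nulls for scanner calibration; 10,000 binomial
replicates for the symmetry type-I check; and 100 replicates for Ka/Ks
rank recovery. Ties in the Sankoff top-down pass and in path reporting
are broken lexicographically; search caps raise explicit errors rather
than truncating silently.

## Known limitations

- The candidate-pool Sankoff is exact over its pool, not over the
  unbounded order space; states more than the search depth away from
  every observed order cannot be posited as ancestors.
- All-minimal-path enumeration is bounded by embedding caps on highly
  repetitive duplication patterns and does not enumerate triplications
  in mid-path positions (equal-cost duplication alternatives are always
  found).
- GR-ISP/STD-ISP classification depends on calibrated thresholds; real
  spacer surveys should re-run the null calibration against their own
  genome set.
- With non-unit cost models, `infer_events` returns minimal-event-count
  paths; cost-optimal longer paths are handled through the pool graph in
  the reconstruction, not in plain pairwise inference.
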