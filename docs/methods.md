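# Methods

This note documents the models and procedures implemented in
`duplexatlas`, their assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## Coordinates and reference model

All coordinates are 0-based half-open, everywhere; GTF input (1-based
inclusive) is converted on read and BED output stays 0-based half-open.
The reference is a plus-strand transcriptome: hybrid arms are never
placed on the reverse strand, matching how proximity-ligation libraries
are aligned to transcript sequences. Interval annotation returns the
region kind with the largest overlap, with ties broken by the fixed rank
3′ UTR > CDS > 5′ UTR > noncoding. The preference of the 3′ UTR over the
CDS reflects the strong 3′ UTR binding bias of dsRBPs; the rank below
CDS is this package's choice, as no convention fixes it.

## Read preparation

Linker matching is exact-substring, longest variant first: the full
linker, then the linker missing one, then two 3′ nucleotides (the linker
is a ribonucleotide oligo and degrades from its 3′ end; deeper internal
degradation is not searched). Because the linker's own terminal bases
can be regrown by chance from the downstream arm sequence, a read
emitted with a truncated linker can legitimately be detected as a less
truncated one — the longest match wins by design. Both arms flanking the
linker must be at least `min_flank` = 12 nt or the read is flagged and
skipped. There is no default linker sequence: it is experiment-specific
and must be supplied (`--linker`). The generator uses an arbitrary,
documented 19-mer. UMIs are taken as a 5′ prefix of configurable length
or parsed from the read header.

## Partial alignment

The built-in aligner is an ungapped seed-and-extend search: 11-mers of
the reference sampled every 5 positions are indexed; every read 11-mer
is probed and hits are extended to maximal exact-match segments, which
are reported when they contain at least 15 matches. Any exact segment of
length ≥ tile + step − 1 = 15 necessarily contains an indexed k-mer at a
matching offset, so the search provably finds every reportable segment —
the test suite verifies exact agreement with a full diagonal scan.
Significance is a Karlin–Altschul e-value, e = K·m·n·exp(−λS), with the
ungapped nucleotide parameters for +1/−2 scoring (λ = 1.3327, K = 0.621),
m the read length and n the total reference length. Gapped arms can be
imported from PSL or BLAST-8 files produced by an external aligner; only
ungapped, plus-strand records are usable and others are skipped with a
logged count.

With a ~150 kb reference and 80-nt reads the e ≤ 0.001 cut-off is
reached at segments of roughly 17 matches, so the effective minimum arm
evidence is slightly above the raw score threshold; this scales with
reference size exactly as a practitioner would expect from BLAST-style
statistics.

## Hybrid calling

The cascade applies, in order: e-value filter (≤ 0.001); read drop at
> 100 surviving alignments; best-score-per-read-span selection with ties
retained; non-hybrid call when any single alignment leaves ≤ 15 nt of
the read unaligned (non-hybrid prioritisation controls false positives);
cross-join of ordered alignment pairs filtered on read-space geometry
(gap or overlap ≤ 4 nt), reference-space disjointness for intra-
transcript pairs, and a proximal-arm start within 5 nt of the read 5′
end. The start-offset rule interprets the crosslink position as the read
5′ end (the cDNA truncation convention); it is exposed as
`--max-start-offset` since the alternative (a peak-relative reading) is
not resolvable from first principles. Multi-solution reads are rescued
when both arms of exactly one candidate overlap a uniquely solved read's
solution; remaining ties fall to the greatest total aligned length, and
unresolved reads are ambiguous. The ≤ 15-nt rule is applied after the
e-value filter. Only two-arm solutions are considered; three-segment
chimeras are out of scope.

Deduplication groups hybrids by (proximal transcript, proximal start,
distal transcript, distal start) in reference orientation and collapses
each group with the directional UMI network: UMIs at Hamming distance 1
are connected when the larger count ≥ 2 × the smaller − 1, and each
connected network keeps its highest-count UMI.

## Duplex clustering

Two hybrids are linked when both arm pairs overlap and each arm's
overlap is ≥ 0.5 of the union span of the two arms. Connected components
of this graph are duplexes; arm ends are per-arm medians of the member
starts and ends, using the lower middle value for even counts so
coordinates stay integral. Transitive chaining means end members of a
component may fall below pairwise 0.5 — this is inherent to
component-based clustering and accepted; edge weights do not affect
connectivity and are kept only as annotation. Inter-transcript hybrids
cluster only within the same ordered transcript pair. Atlas merging
re-clusters the union of arm pairs from all sources (linker, direct,
derived) with the same rule and unions the source tags.

## Energy models and duplex folding

Two energy models are provided.

* **simple** — additive per-pair scores (G:C −3, A:U −2, G:U −1
  kcal/mol), +1 kcal/mol per unpaired interior nucleotide, no stacking.
  Fully enumerable; used by all exhaustive oracles and by the partition
  function.
* **nearest-neighbour** (default for folding) — measured Watson–Crick
  stack free energies at 37 °C, a single documented constant (−1.0) for
  wobble-containing stacks, affine loop penalties (2.0 to open, 0.5/nt
  to extend) and a 4.1 kcal/mol duplex initiation term. This gives
  realistic energy scales; exact Turner-2004 replication is not
  attempted because every comparative statement made with these energies
  is rank-based and robust to the model choice. Temperature is fixed at
  37 °C; dangling-end terms are not modelled.

Intermolecular MFE folding considers only arm1–arm2 pairs (Watson–Crick
and G:U), forbids pseudoknots and lonely pairs (every helix ≥ 2 stacked
pairs), and treats unpaired flanks outside the outermost pairs as free.
The recursion is a two-state DP (final helix length 1 vs ≥ 2) with a gap
matrix for the affine interior penalties, O(m·n) time. A duplex is
reported only when the free energy is negative; otherwise the empty
structure with energy 0 is returned. An optional pass-through to the
ViennaRNA `RNAduplex` binary parses its output into the same record for
users who want the full Turner model.

Shuffled controls preserve dinucleotide composition via the Euler-path
(Altschul–Erikson) algorithm, uniform over valid shuffles, with both
arms shuffled independently; the control energy is the mean MFE over a
configurable number of iterations (100 by default in the energy tools;
the derivation workflow uses 20 per UTR to keep the profile stage
proportionate, stated below).

`normalised_energy` divides the duplex energy by the total number of
paired residues on both arms (2 × pairs), allowing comparisons across
duplexes of different lengths.

## Windowed pairing probabilities

Per-nucleotide pairing probabilities come from an exact partition
function over secondary structures with Watson–Crick + G:U pairs,
non-crossing, hairpin loops ≥ 3 nt and no lonely pairs, Boltzmann-
weighted under the simple model at 37 °C. Structures are decomposed
uniquely by maximal helices; inside and outside recursions over this
grammar give exact pair probabilities in O(n³) per window (numba-
compiled). Partition values are held in unscaled doubles, which is ample
for 100-nt windows under this model. A window (default 100 nt) is slid
along the sequence with a configurable step; a base's profile value is
the mean over windows covering it, and the final window is anchored at
the 3′ end so all bases are covered. Per-window exactness is verified
against exhaustive structure enumeration; the per-window mean is a
documented approximation to finer sliding-window averaging schemes. The
derivation pipeline uses step 10 — at window 100 the per-base average
changes negligibly while the profile stage speeds up an order of
magnitude, which is what makes shuffled-control profiles affordable.

## Stem-loop derivation

Peaks are restricted to the 3′ UTR of one representative transcript per
gene — an explicit gene→transcript table if given, otherwise the longest
annotated 3′ UTR (expression-based selection consumes quantification
that is out of scope here). For each UTR a profile and a shuffled-
control profile (mean over 20 dinucleotide shuffles by default) are
computed, and the −100..+100 window around each peak start extracted
(NaN-padded at the sequence ends).

Peaks are clustered by k-means on the +10..+75 region (66 values; NaN
imputed by position mean, lightly smoothed with a width-3 moving
average), with k chosen by mean silhouette over 2..8 in a single stage —
no two-level structure is hard-coded. Clusters are labelled by mean
region probability descending.

The M-shape test smooths the region with a width-5 moving average and
requires two local maxima above the region mean separated by a local
minimum below it, with the dip at least 0.1 (in probability) below the
lower maximum. The prominence requirement is this package's
operationalisation: without it, any gently undulating smooth curve —
including averaged shuffled controls — trivially satisfies the
maxima/minimum condition. Window-edge positions count as maxima when the
profile is monotone into the edge, since a finite region can clip the
first lobe of a genuine stem signature.

Arm delineation works on the +0..+100 metaprofile of each M-shaped
cluster: the maxima pair with the most prominent separating minimum
defines the M; that minimum ends the proximal arm (boundary minima
belong to the proximal arm); the distal arm ends at the next local
minimum or where the profile falls back to the mean; the proximal arm
begins where the profile starts rising into the first maximum. Regions
are padded outward by 5 nt before folding — averaging across a cluster
blurs arm extremities, and unpaired flanks are trimmed after folding, so
the pad only prevents clipping.

Each peak's two arm regions are folded with `duplex_mfe`, unpaired
flanks trimmed to the outermost pair, and the loop length measured
between the trimmed arms. The stem filter requires **≥ 8 contiguously
stacked pairs**: the binding threshold this implements comes from
structural work on the Staufen dsRNA-binding domain, which concerns the
length of a physical stem, and a fragmented set of 8 total pairs spread
over several short helices does not satisfy it (planted-truth
simulations confirm that total-pairs counting admits a substantial rate
of chance structures downstream of unstructured peaks, while every real
stem is contiguous). A permissive total-pairs mode remains available
(`contiguous=False`).

## Metabolism integration

Rates (synthesis, processing, degradation) are log10-transformed,
centred and scaled per rate so the three axes weigh equally, and
clustered with PAM (k-medoids): deterministic greedy BUILD, best-
improvement SWAP, Euclidean distance, lowest-index tie-breaks — the fit
is order-stable and seed-independent. Silhouette widths over k = 2..8
are reported alongside the k = 3 partition; clusters are named A, B, C
by mean degradation descending so labels carry meaning across runs.
Expression matching keeps genes above the 5th percentile (linear
interpolation between order statistics) of copy number among
duplex-bearing genes; the comparison is strict, so the bottom tail of
the duplex-bearing set itself is excluded, as intended.

The compaction score is (duplex extent − introns inside it) / (3′ UTR
length − introns inside it), with the duplex extent measured from the
proximal arm start to the distal arm end; both mean corrected and raw
spans are available. 3′ UTR thirds are equal integer thirds with the
remainder assigned to the last third; a duplex's thirds count is the
number of thirds its extent intersects by ≥ 1 nt.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture
dump. Transcriptomes are rejection-sampled against 13-mer reuse so arm
placements are unique by construction; planted duplexes overwrite the
distal locus with the reverse complement of the proximal arm (perfect
antiparallel helices); arm loci never overlap, but unrelated duplexes
may nest inside another duplex's span. Defaults encode the regime the
method targets: 50 transcripts of 1–3 kb, 500 duplexes, arms 25–35 nt,
reads 75–100 nt, a bimodal span mixture (53% at mean 252 nt sd 80, 47%
at mean 18 nt sd 6, floored at 12 nt so arms stay separable), 10%
inter-transcript duplexes, read-type fractions 0.4/0.4/0.2
(linker/direct/stem-loop), linker truncation probabilities 0.7/0.2/0.1,
6-nt UMIs, 20% PCR duplication with 10% single-base UMI errors on
duplicates. Reads are error-free by default: linker detection and
alignment are exact-match operations, so sequencing-error modelling is
orthogonal to what these fixtures test and sits behind no switch at all
rather than a half-tested one.

The stem-loop study panel emulates AU-rich 3′ UTRs (35% GC background,
the composition regime of mammalian 3′ UTRs) with GC-enriched planted
stems (60% GC, as real UTR stem-loops are relative to their flanks),
loops drawn from A/C so they cannot pair with themselves or extend the
stem, stems of 8–15 bp, loops of 4–10 nt, and the first arm starting
5–9 nt downstream of the peak — crosslinking immediately upstream of a
bound stem. What the panel does **not** emulate: sequencing noise,
coverage-dependent peak calling, isoform ambiguity, or partially
complementary (wobble/bulged) planted stems. Passing tests therefore
demonstrate the correctness and discriminative behaviour of the
computational chain under its stated assumptions, not the sensitivity
that would be obtained on real libraries, where arm uniqueness and
profile contrast are both worse.

Rate tables draw each cluster's log10 rates from Gaussian components;
the default three components are well-separated regimes (high
degradation / low everything / high synthesis with low degradation) for
recovery testing.

## Numerical and degenerate-input choices

EM for the span mixture uses k-means++ initialisation under the caller's
generator, tolerance 1e-6 on the log-likelihood, a 1e-3 floor on
standard deviations, and returns components sorted by mean descending;
all-equal input collapses to a single floored component. k-means for
profiles uses 10 restarts with a seed drawn from the caller's generator.
Identical profiles force k = 1 (silhouette is undefined). Median arm
ends use the lower middle value. Empty atlases, zero peaks, unknown
transcripts and off-UTR peaks all return empty results with logged
counts rather than raising.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
desk scale: 2,000 reads for hybrid-recovery scoring, 1,000 reads for
oracle-equivalence, 500 arm pairs for folding equivalence, 20 sequences
for partition-function equivalence, a 200-UTR panel (160-nt UTRs, 100
planted hairpins, 20-shuffle controls) for derivation, and 100-instance
batches for clustering invariants. These sizes give stable pass/fail
behaviour at comfortable margins; scaling them up changes runtimes, not
conclusions.

## Known limitations

* The aligner is exact-match and ungapped; mismatched or gapped arms
  require importing external alignments. This is a deliberate trade for
  provable completeness against oracles.
* The nearest-neighbour model is a documented subset (wobble stacks as a
  constant, no dangles, simplified loops); absolute energies differ from
  full Turner values though rankings agree in practice.
* The windowed partition function uses the simple energy model, so
  background pairing probabilities are higher than RNAplfold's; all
  downstream logic (M detection, clustering) operates on contrasts, not
  absolute levels.
* Genome-to-transcriptome liftover, repeat masking, overlapping-gene
  collapsing, peak calling and expression quantification are out of
  scope: the reference, peaks and rate tables are inputs.
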