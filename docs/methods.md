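# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, the scope of the synthetic-data generator, and the
known limitations.

## Coordinate and boundary conventions

All genomic intervals are 1-based inclusive (`GenomicInterval`); file
formats keep their native conventions (BED and bedGraph 0-based
half-open, SAM 1-based). An integration site is a pair of boundaries on
the host: the **left boundary** `L` is the last host base before
transgene sequence, the **right boundary** `R` the first host base after
it. The lesion classification is a pure function of the pair:

| relation   | class       | affected host interval |
|------------|-------------|------------------------|
| `R = L+1`  | blunt       | —                      |
| `R > L+1`  | deletion    | `L+1 .. R-1` (length `R−L−1`) |
| `R ≤ L`    | duplication | `R .. L` (length `L−R+1`)     |

The simulator uses the same `(L, R)` semantics to splice payloads, so the
classifier inverts the generator exactly (property-tested over offsets
−50..50). The distance between two sites is the gap between their closest
boundaries, clamped at zero for overlapping or identical sites.

## Simulator

`simulate_host_genome` draws an i.i.d. host chromosome at a target GC
(default 0.40) and overwrites planted motifs. The two-locus scenario
plants, on a toy chromosome of length `n` (default 1 Mb):

- the construct's promoter at its endogenous locus (`0.2 n`), making the
  promoter the one deliberately multi-mapping region;
- insertion loci near `0.6 n`: site 1 with `R1 = L1+12` (11-bp deletion),
  site 2 with `L2 = L1+134`, `R2 = L1+120` (15-bp duplication), closest
  boundaries 108 bp apart;
- junction-flank homology: a 6-bp recognition-site remnant ending at L1,
  the 4-nt `ATAA` overhang directly downstream of R2, and a shared 8-mer
  28 bp upstream of both sites;
- guard bases just inside each lesion (at `L+1` and `R−1`) chosen to
  differ from the construct's terminal bases. Without them a junction
  read can have two equal-scoring placements one base apart and the
  generating coordinate is fundamentally unidentifiable; the planted
  homologies sit in the flanks, never across the cut.

The 8-kb construct (fixed seed, shared by all scenarios) is
`I-SceI site | ~3.9 kb promoter | ~700 bp eGFP | ~3 kb vector backbone |
inverted I-SceI site`. Six copies are inserted 3+3 head-to-tail; the
sister haplotype stays wild-type (hemizygosity).

Read simulation draws `n_pairs = depth · (Σ allele lengths)/2 / (2·read
length)` fragments (`N(350, 35²)` insert, 2×101 bp, substitution errors at
1e-3), uniformly over the two haplotypes in proportion to length. Under
this convention a neutral diploid host base averages `depth`, each
haploid construct copy adds `depth/2`: at 20x, the promoter pileup is
~80x (2 endogenous + 6 transgene copies) and the reporter ~60x. Truth is
tracked per read (haplotype, position, strand) and can be emitted as a
perfect-alignment SAM, with promoter-internal construct reads relocated
to the endogenous copy at MAPQ 0 exactly as a tie-breaking aligner would
place them.

## Aligner

A deliberately small seed-and-verify aligner over the combined reference
(host contigs + construct as an extra contig):

- packed 2-bit k-mer index (k = 21), queried at three read offsets for
  the read and its reverse complement;
- per-candidate ungapped diagonal scoring (+1/−4); **local mode** takes
  the maximum-sum subarray of the diagonal scores (terminal soft clips),
  **end-to-end mode** the full-diagonal sum;
- affine-gap DP rescue (`sw_affine`, gap open −6 / extend −1, glocal:
  free reference start) on the best candidate window when the ungapped
  score fails the threshold or an imperfect local alignment carries a
  clip larger than a substitution can explain (≥ 6 bp). A lone
  substitution clips at most ~5 terminal bases at these scores, so larger
  clips are either indels (the DP wins) or genuine chimeric junctions
  (the DP cannot win and the clip is kept);
- a placement is **unique** if it beats the runner-up by ≥ 2; ties break
  lexicographically (contig, position, strand), so reads internal to the
  promoter repeat land on the endogenous copy as non-unique. Uniqueness
  is encoded as MAPQ 60/0 in SAM output.

The local mode is property-tested for score parity against an exhaustive
affine-gap DP (independent implementation) on multi-kilobase instances.

## Coverage and copy number

Depth counts aligned M bases of unique reads (difference-array
accumulation). Non-unique reads are kept only inside the declared
promoter-homology regions, where multi-mapping is by construction and
dropping them would erase the copy-number signal.

GC bias is corrected with a binned ratio model: 1-kb host bins are
grouped into GC deciles, each decile's mean depth over the global mean
gives a ratio, and each bin's depth is divided by its decile ratio. Bins
overlapping the promoter region or called-site windows (±2 kb) are
masked from the fit — their depth reflects copy number, not GC — and the
construct contig, whose depth *is* the signal, never enters the fit; it
is corrected by the ratio of its mean-GC decile. Background depth is the
median of unmasked host bins.

Copies are estimated as `max(0, round(ploidy · depth/background −
endogenous))` with an exact (Garwood) Poisson interval on the implied
read count. The promoter is measured on the interior of its endogenous
interval (inset by one read length per side): reads crossing the feature
edge align uniquely to the construct and never pile up at the endogenous
locus, so the multi-copy contribution ramps over one read length at each
edge and the full-interval mean would be biased low by ~2%.

## Junction calling

- **Junction pairs**: non-proper pairs with one mate on the construct (or
  inside the promoter-homology region) and the other unique elsewhere on
  the host.
- **Split reads**: local alignments with a terminal clip ≥ 20 bp whose
  clipped tail realigns (locally, smaller k) to the other side; both the
  anchor and the host-side placement must be unique. The anchor/clip
  geometry (which end is clipped, strand of the realignment) determines
  the boundary side, the host position, the adjacent construct
  coordinate, and the construct orientation.
- **Clustering**: breakpoints within 10 bp sharing contig, boundary side,
  construct terminus (start/end/internal, 50-bp tolerance) and
  orientation merge at the leftmost modal position; the observed spread
  is reported as `shift_range`. Junction pairs corroborate the nearest
  boundary within fragment range but never move it. Candidates below the
  support rule (≥ 3 splits, or ≥ 1 split plus ≥ 2 pairs) are written to a
  dropped-candidates table rather than silently discarded.
- **Pairing**: left/right boundaries are matched by optimal assignment
  (minimum total separation ≤ 10 kb) subject to compatibility — same
  orientation joins opposite construct termini, opposite orientation
  joins equal termini; internal termini never close a site. Unmatched
  boundaries are reported as half sites.
- **Concatemer junctions**: construct-internal split reads near the
  termini, clustered by joined-termini signature and relative orientation
  (head-to-tail / head-to-head / tail-to-tail), corroborated by
  discordant construct-internal pairs. Identical tandem junctions between
  indistinguishable copies collapse into one signature cluster, so a
  3-copy head-to-tail array reports one head-to-tail signature, not two
  positional junctions.

`reconstruct_allele` splices the called sites back into the host (used to
round-trip against the simulator), and `in_silico_pcr` extracts exact
primer-delimited products from any template for junction-validation
design.

## Microhomology

The cleavage model cuts the 18-bp recognition site at top-strand offset 9
and bottom-strand offset 5, leaving the 4-nt 3′ overhang `ATAA`. The
scanner enumerates *maximal* exact common substrings (k-mer seeded,
extended both ways, deduplicated; verified against a quadratic oracle)
between each junction flank (both strands) and the adjacent construct
terminus or the recognition site. The per-site-pair report adds
upstream-flank homology between adjacent sites; a duplication lesion
together with flank homology ≥ 4 bp raises a tandem-duplication
signature — the expected footprint of MMEJ insertion followed by local
reamplification.

## Scope and limitations

- The simulator generates substitution errors only (no indel errors, no
  quality model), i.i.d. host sequence (no repeats beyond what is
  planted), and exactly one transgenic + one wild-type haplotype.
- The aligner is exact-k-mer seeded: placements diverging from the
  reference by more than a few edits within every seed window are missed;
  there is no paired-end rescue of an unmapped mate.
- The GC model is a binned ratio, not a fragment-level model; it assumes
  enough copy-neutral host sequence (≥ 50 bins) to fit.
- Copy-number resolution degrades with background noise roughly as
  `ploidy · CV(background)`; at 20x and 1-kb bins, ±1 copy is the
  practical resolution of the rounded estimate.
- Concatemer junctions are reported as signature clusters with split-read
  support; the number of copies comes from coverage, not from counting
  junctions, because identical tandem junctions are unresolvable by
  construction.
- At 20x, a boundary's split support is Poisson with mean ≈ 8; draws
  below the support rule occur (a few percent of runs) and surface as a
  half site plus a dropped-candidates row rather than a wrong call.
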