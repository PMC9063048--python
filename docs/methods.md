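# Methods

This note documents the models, numerical choices and designed behaviour
of `orgpan`: what each stage assumes, which knobs matter, what the
synthetic generator does and does not emulate, and therefore what a green
test suite does and does not demonstrate about real data.

## Circular alignment

Assembled organelle genomes are circles sequenced from an arbitrary start
on an arbitrary strand. `normalize_rotation` votes with sampled k-mers
(default k = 31, stride 8) that are unique in the reference counting both
strands; the (strand, offset) pair with the most votes wins, ties broken
towards '+' and the smallest offset, which makes the operation idempotent.

`align_pair` assumes the two sequences are near-identical (> 90% at the
substitution level, the within-species regime for organelles). Anchors are
k-mers unique in the subject counting both strands, one-to-one on subject
positions; maximal collinear anchor runs become chains. Inter-anchor
intervals up to 5,000 bp on both sides are closed with global edit-distance
alignment (edlib); pure one-sided gaps become insertion/deletion events
directly. Three properties of edit-distance paths required dedicated
handling, all applied symmetrically so called and expected variants stay
comparable:

* co-optimal gap placement scatters one biological indel across the
  interval — raw difference intervals separated by ≤ 5 matched columns are
  merged and shared flanks re-trimmed, restoring the minimal event;
* for very asymmetric intervals the optimal path threads single-base
  matches through the gap to avoid paying for a flank substitution —
  structural events carrying a replaced residue are decomposed by
  assigning the short side to the long side's two ends at minimal Hamming
  cost (flank substitutions plus one pure gap);
* a closure whose smaller side matches poorly (matched fraction < 0.66
  over ≥ 30 bp) splits the chain — this is what separates a rearranged
  segment (picked up again by a minus-strand chain) from an honest gap.

Chain identity is a substitution-level measure: columns of structural
one-sided gaps (> 10 bp) are excluded, so an accession that simply lacks a
fragment is not scored as divergent. Chains below 0.9 identity are
discarded; subject double-coverage from circular wrap is resolved greedily
largest-first; consecutive same-strand chains split by stray anchors (a
duplicated gene matching its source locus) are stitched back; and the two
wrap junctions (subject origin falling mid-query and vice versa) are
closed explicitly, splitting events at the origin. Indel coordinates are
normalized VCF-style (anchored, left-aligned) so equivalent descriptions
of one edit collapse.

The module's oracle is the round trip: for every synthetic pair,
applying the emitted differences to the subject must rebuild the query
byte-exactly (up to rotation/strand). All coordinates are 0-based
half-open internally; VCF/BED/GFF writers convert per convention.

## Pan-genome

The draft reference is the accession with the largest number of
high-quality alignments (identity ≥ 0.9, mutual coverage ≥ 0.975), ties
broken by mean identity then id. The draft is rotated so the first
reference gene starts at position 0 forward — the conventional fixed
origin for organelle assemblies — which also keeps gene models and
variant records from wrapping the origin.

Insertions > 10 bp are clustered across accessions by infix identity
≥ 95% with positional slack of 20 bp plus the length difference (event
boundaries can swallow an adjacent substitution for some carriers); the
majority allele of each cluster is applied right-to-left so earlier edits
do not shift later ones. Unanchored query intervals > 100 bp that align
nowhere on the draft are clustered at ≥ 95% identity (either strand);
clusters supported by ≥ 2 accessions become dispensable scaffolds.
Conflicting dissimilar alleles within 20 bp keep the better-supported one
and log the conflict. Whether a breakpoint fragment surfaces as a
scaffold depends on the reference: if the chosen reference shares the
rearrangement, the fragment anchors and is applied as an ordinary backbone
insertion instead — the truth bookkeeping accounts for this.

## Variant catalog

Only SNPs and small indels (length difference ≤ 10 bp) become records;
larger deletions set the genotype to N for the affected accessions at
overlapping sites (the region is absent, not reference). The
single-sample filter acts per alternate allele in multi-allelic records.
Group summaries count only sites polymorphic within the group; Ts/Tv is
transitions (A↔G, C↔T) over transversions and reported as undefined, not
zero, for SNP-free groups; density divides by the backbone length. The
upstream/downstream flank is 1,000 bp (standard annotator convention);
the genetic code defaults to the standard table, configurable per
organelle; splice sites are the 2 bp at each intron end. Overlapping
features resolve by the priority exonic > splicing > ncRNA_exonic >
intronic.

## Mitotyping and gene PAV

Marker presence requires a local hit covering ≥ 80% of the marker at the
per-marker identity threshold (0.90 MSS4 / 0.85 MSS9 / 0.80 others),
searched on the doubled genome so junction-spanning markers are found.
The 80% coverage requirement is a package choice: truncated assemblies at
marker edges still classify while random hits do not. Classification is
exact-match first; otherwise the "-like" call needs a unique best
agreement ≥ 0.8 (configurable) — a transparent stand-in for manual
structural comparison; ties are unclassified. ORF presence uses the
gene-PAV rule (60% coverage / 85% identity) rather than the marker rule.
Gene hits are seeded by shared 21-mers, extended by semi-global alignment,
deduplicated on the circle (> 50% overlap collapses to the best hit);
identity is over aligned columns with coverage tracked separately, and
copy number counts qualifying non-overlapping loci.

## Diversity

Per-site π is the unordered-pair mismatch fraction over haploid calls
(N excluded; sites with < 2 calls in a group are skipped for it); window
π divides the summed site values by the full 500-bp window length
(vcftools-style denominator) on a 100-bp step, windows wrapping the
circular origin. Only SNP records enter diversity statistics. Fst uses
the Hudson estimator as a ratio of averages — appropriate for haploid
organelle samples where a diploid variance-components estimator would
model heterozygosity that cannot exist; negative estimates are reported,
not clipped. ROD_w = 1 − π_group,w/π_all,w (1 when the group is
monomorphic in a polymorphic window, undefined when π_all,w = 0); windows
at or above the (1 − 0.01) quantile of defined values are selected and
merged when overlapping or abutting; per-region group π is reported as
"na" when the group has no polymorphic site there. Origin-wrapping
windows are excluded from region merging.

## Synthetic populations

The generator's defaults are the study conditions: cp-like genomes of
153,000 bp at 36.3% G+C with an LSC/IRa/SSC/IRb layout, mt-like genomes
of 222,000 bp at 45.2% G+C; mitotype proportions nap/cam/pol/ole =
0.50/0.30/0.15/0.05 with largest-remainder rounding; private SNPs at
2×10⁻⁵ /bp, small indels (1–10 bp) at 2×10⁻⁶ /bp, large novel insertions
(11–1,000 bp) at 0.2 /genome, rare gene deletions/duplications (0.02
/accession each), 150 bp reads at 150× depth. The base sequence *is* the
base-group founder; other founders carry fixed small indels, marker/ORF
insertions or deletions at fixed loci, and — for mitochondria —
segmental inversions (~6% of the genome each), with the designated pair
(*cam*, *pol*) sharing one inversion and hence collinear. The inverted
repeats are 2.4 kb carrying the duplicated rRNA genes — far shorter than
real cp IRs (~25 kb) so that unique-anchor alignment can bridge them;
this is a deliberate down-scaling, and the IR interior is kept
variant-free (mirroring how repeat regions are skipped in read-based
calling).

Population variation is laid out on a site lattice of
focal–partner–focal triplets: each partner site (another group's shared
pair or a group-fixed difference) is flanked within ~70 bp on both sides
by focal-group shared sites, and the triplet span is reserved as one
interval so no structural event can separate them. Consequently every
analysis window that contains any polymorphism also contains focal-group
polymorphism — except the designed low-diversity block (~2–4 kb,
partner sites only), which is the one place the focal group is
monomorphic while the population is not, and is therefore recoverable as
exactly one top-ROD region. The focal group is the *second*-largest
(default *cam*): it carries the shared-site load, so the base group
(*nap*) remains the most homogeneous and is naturally selected as the
reference, as in real panels. Shared sites have two carriers each — the
minimum that survives the singleton filter — which bounds the within-group
π from below at desk scale: with 60 accessions, π_nap lands near 5×10⁻⁵
(the real study's within-group range) while the focal group's π is
inflated to ~10⁻³; population-wide π comes out near 7×10⁻⁴. Mutation
events are placed through an interval registry with margins (20 bp for
SNPs, 40 bp for indels, 60 bp for structural events) so every event is
flanked by clean anchor sequence and truth events map one-to-one onto
called variants. All per-accession mutations are independent (star
phylogeny) — group structure comes entirely from founders and shared
sites, so the NJ tree's within-group branching carries no signal.

Shared novel fragments (300–2,000 bp) are inserted at inversion
breakpoints of a random subset (≥ 2) of a group's accessions; against a
reference lacking the inversion they align nowhere and become scaffolds.
Read placements are error-free and tiled evenly (exactly the target depth
at the default 150 bp/150×); a masked interval removes read *starts* to
create a known structural gap. Emitted genomes are randomly rotated and
flipped so the normalization path is always exercised.

What this does not emulate: sequencing errors and quality scores,
assembly artifacts beyond the masked-gap signature, recombination or
within-group phylogeny, homopolymer/microsatellite indel hotspots, cp IRs
at real length, and realistic allele-frequency spectra (every shared
variant has exactly two carriers). Passing the recovery suite therefore
shows the analysis chain is exact under clean, well-separated variation —
not that it is robust to noisy assemblies or repeat-dense genomes.

## Problem sizes

The recovery suite and the acceptance script run two populations chosen
as this package's reference study conditions: chloroplast-like, 60
accessions × 153 kb, and mitochondrion-like, 24 accessions × 222 kb
(the mt population is smaller because all-vs-all reference selection
dominates runtime and the mt stages — mitotyping, PAV — are exercised
there). Module tests run on 12-accession populations of 60–80 kb.

## Known limitations

* The aligner targets the > 90% identity regime; it is not a
  general-purpose aligner for diverged sequences and offers no affine-gap
  optimality guarantees.
* Reference selection is O(n²) whole-genome alignments; beyond a few
  hundred accessions a sketching pre-filter would be needed.
* Rearranged blocks keep the reference's order on the single linear
  backbone; non-collinear accessions are represented through minus-strand
  chains, not a graph.
* ROD-region extraction assumes the quantile threshold isolates a
  contiguous signal; scattered single-window outliers would merge into
  separate regions (the generator's lattice exists precisely to keep the
  designed block the only such signal).
* A per-site Weir–Cockerham Fst option is noted as future work; the
  Hudson ratio-of-averages is the implemented estimator.
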