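# Methods

`vectorvirome` implements a desk-scale pipeline for discovering and
characterising insect-specific RNA viruses (ISVs) in bulk transcriptomes of
an insect vector that exists as a complex of cryptic species — the motivating
system is the whitefly *Bemisia tabaci*, whose cryptic species are delimited
by divergence of the mitochondrial cytochrome oxidase I (mtCOI) barcode.
This note records the models, parameter choices and numerical conventions,
and what the synthetic data do and do not establish.

## Cryptic-species assignment

Each dataset's assembly is scanned for an mtCOI-like contig by optimal global
alignment (Needleman–Wunsch, linear gap penalty; defaults match +1,
mismatch −1, gap −2; both orientations) against a labelled reference panel.
Divergence is the uncorrected p-distance with pairwise deletion: columns
containing a gap or N in either sequence are excluded from both numerator and
denominator. No substitution-model correction is applied — the 3.5%
species-delimitation convention in the whitefly literature is identity-based.

The dataset is assigned to the species of the nearest reference
(nearest-of-many per label) iff divergence ≤ 0.035, boundary inclusive; the
threshold reads as the limit of a species, so a sample exactly at it still
belongs. All species whose nearest reference falls within threshold are
reported, so mixed-species samples surface rather than being silently
collapsed to one label. Traceback tie-breaking is deterministic (diagonal,
then gap-in-reference, then gap-in-query), and the contig scan breaks score
ties lexicographically by (contig id, reference id), so reruns are identical.

A candidate is rejected as "no credible mtCOI contig" when its best identity
(1 − p-distance) is below 0.75. This cutoff is deliberately far above 50%:
optimal global alignment of unrelated random DNA already yields ~0.6 apparent
identity over compared columns (the optimisation recruits chance matches), so
a 0.5 cutoff rejects nothing. 0.75 sits between that chance ceiling (≤0.68
empirically) and the weakest genuine congeneric barcode match (≥0.8 at the
20% divergence cap of the variant generator). The companion distance tree
over datasets is neighbor joining (via scikit-bio) on the p-distance matrix —
a fast guide tree, not a substitute for model-based phylogenetics.

## Viral contig triage

A contig is called viral only when **all** criteria hold, all boundaries
inclusive ("no less than" reads as ≥):

| criterion | default | notes |
|---|---|---|
| protein-homology E-value | ≤ 1e−20 | best hit per contig |
| contig length | ≥ 500 bp | |
| mean read depth | ≥ 20× | mapped bases / contig length (depth, not breadth) |
| ORF completeness | ≥ 80% of hit span + stop codon | start codon optional |
| cross-assembler confirmation | identity ≥ 0.98 over ≥ 90% of the shorter contig | either orientation |

"Almost complete ORF" is quantified as: the longest stop-free codon run in
the hit's reading frame must cover at least 80% of the hit footprint and end
in a stop codon. The start codon is not required because assembled viral
contigs are frequently 5′-truncated. Note that under this longest-run rule a
single stop near one end of an otherwise intact frame does *not* fail the
contig — the downstream run still covers most of the span; failing requires
the frame to be genuinely fragmented (e.g. a midpoint stop).

Cross-assembler confirmation uses local alignment (Biopython's
PairwiseAligner) and accepts near-identity containment, since independent
assemblers routinely produce contigs that differ only by terminal trimming.
An optional re-check hook accepts a second hit table (mirroring a broad
nucleotide/protein database screen) and drops candidates whose best re-check
subject is non-viral; the default subject test is a "virus"/"viral" token in
the subject id and is pluggable.

Host reads can be subtracted beforehand: a read is dropped when ≥ 80% of its
21-mers (either orientation) occur in the host genome k-mer set.

The built-in translated search is a deliberately small blastx-like tool so
the pipeline is self-contained: six-frame translation, exact 3-aa word
seeding, ungapped X-drop extension under BLOSUM62, and Karlin–Altschul
E-values with fixed ungapped constants (λ = 0.318, K = 0.13; m is the frame's
query length in aa, n the total reference residues). It finds strong
homology reliably; it is not a sensitive remote-homology tool, and external
hit tables (12-column tabular) take precedence when supplied. E-values
decrease monotonically with score within a frame; across frames the m factor
differs by ±1 residue.

## Abundance, composition and association

Reads are mapped to the accepted viral contigs by exact matching on either
strand via a substring index; a fragment counts toward contig *j* only when
it has exactly one occurrence across the whole contig set ("uniquely mapped";
ties are dropped rather than rescued). Relative abundance is TPM:

    a_j = (b_j / c_j) / Σ_{j=1..n} (b_j / c_j) × 10^6

with b_j the unique fragment count, c_j the contig length and n the number
of accepted contigs. Σ a_j = 10^6 per dataset whenever any read maps, and
TPM is invariant to uniform scaling of counts. All-zero counts yield an
all-zero row with a warning rather than NaN.

Composition shares are raw-count fractions (TPM shares are an option; the
two differ when contig lengths differ), and the dominant ("core") virus is
the argmax share with flagged lexicographic tie-breaking. The association
matrix counts, per virus × species, datasets where the virus exceeds a
detection floor (default TPM > 0); a virus present in exactly one species is
species-specific, in two or more shared. PCA runs on log10(TPM + 1) with
column centering and no scaling, by SVD, with the sign convention that each
component's largest-magnitude loading is positive. The qPCR helper returns
2^−ΔΔCt.

## vsiRNA profiling

Cleaned small RNAs (adapter-clipped by exact prefix search, N-free, 18–30 nt
inclusive) are mapped to the viral genomes requiring a perfect match on
either strand. Counting is redundant — every read copy contributes, matching
how vsiRNA size profiles are conventionally drawn. A read matching k
positions contributes weight 1/k to the depth at each matched 5′ start
(depth is recorded at the 5′ start, not as a full-body pileup), and enters
the size×strand and 5′-nt histograms only when all its matches agree on one
strand; strand-ambiguous reads (e.g. reverse-complement palindromes) remain
in the depth track. 5′ bases are reported in RNA alphabet (T → U). Segmented
viruses are profiled per segment and pooled.

Hotspots are maximal runs (gaps ≤ 5 nt allowed) of positions whose depth
exceeds mean + 3 SD, statistics taken over positions with nonzero support.

Classification encodes the standard interpretation of vsiRNA signatures: a
21–22 nt peak with roughly strand-balanced reads is the product of the host
Dicer-2 pathway cleaving a dsRNA replication intermediate
(`canonical_host_RNAi`); a 23 nt peak and/or strong strand bias together
with a strong 5′ U bias points to processing by another organism's silencing
machinery (`non_canonical`), e.g. a fungal associate of the host. The
adjectives are quantified as: balanced strands = plus fraction in
[0.35, 0.65]; strong 5′ U = ≥ 0.5 of reads; fewer than 100 mapped reads =
`insufficient_data`. These cutoffs are configurable; the classifier is
invariant to uniform count scaling and reports the rule trace that fired.

## Synthetic studies and what they show

The generator emulates the statistical structure the analysis assumes, not
sequencing physics. The default study is 3 cryptic species × 2 datasets.
Per dataset: an mtCOI contig at 1% divergence from its species reference
(references are generated ~19% apart), the species' core virus (segment
lengths and counts differ by species: 1200+900, 1500, 1900 nt — the
asymmetry keeps the abundance clusters from projecting onto a single PCA
axis degenerately), a shared minor virus (600 nt), three 800 nt random host
decoys per assembler, 12,000 viral reads (96% core / 4% minor — the
core-dominant regime) plus 600 host reads of 100 nt, and a 5,000-read sRNA
pool in the canonical regime (22 nt peak, balanced strands). The second
assembler's contig set carries the viral contigs trimmed to 99% length and
different decoys. Each genome carries one long clean ORF, and the bundled
"toy" protein reference is that ORF's translation, so triage criteria are
exercised end to end. All generators are pure functions of (parameters,
seed); per-stage seeds are fanned out from one global seed.

The 5′-nt bias is realised by conditioning the start position on the sampled
5′ base — the read starts where the genome already carries that base — which
mirrors the biological mechanism (Dicer/Argonaute loading selects read ends)
and keeps every read perfectly mappable. A substitution mode (overwrite
position 0, flagged in the truth table) exists for studying how 5′-forcing
breaks exact-match mapping, but it is not the default precisely because a
substituted terminal base fails perfect-match mapping 3/4 of the time and
would bias any downstream 5′ recovery.

Passing tests on these data show the *logic* is right: thresholds applied
inclusively, counts conserved, parameters recovered within binomial error,
truth tables reproduced exactly. They do not show robustness to sequencing
error, indels, chimeric contigs, uneven coverage, low-complexity sequence or
remote homology — real data properties the generator deliberately omits.

## Numerical conventions

- Coordinates are 0-based half-open internally; 1-based inclusive only at
  the BLAST-tabular boundary (minus-strand hits have q_start > q_end).
- All randomness flows through numpy Generators seeded from explicit seeds;
  outputs are byte-stable across reruns (fixed sort orders, `%.6g` floats).
- Degenerate inputs are defined, not NaN: all-zero counts → zero TPM with a
  warning; constant matrix → zero-variance PCA with a warning; empty host
  set → all reads kept with a warning; empty depth → no hotspots.
- Duplicate sequence ids are rejected at parse time (they would silently
  corrupt count tables downstream).

## Known limitations

No gapped alignment statistics or composition-adjusted scores in the
translated search; no paired-end fragment model or multi-mapper rescue (EM)
in quantification; no miRNA annotation, phasing or ping-pong signatures in
the sRNA stage; neighbor joining only (no ML phylogenetics or bootstrap);
assembly itself is upstream and out of scope — the pipeline consumes contig
sets.
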