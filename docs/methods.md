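# Methods

## Coordinate model

All internal coordinates are 0-based half-open, the native convention of
UCSC knownGene tables. VCF positions (1-based) are converted exactly
once, at the VCF boundary (`position - 1` for the anchor base).
Chromosome names are normalized to the `chr`-prefixed form on ingest so
gene models and VCFs from either dialect interoperate.

## Feature decomposition

Each transcript tiles the padded interval
`[txStart - upstream_window, txEnd + downstream_window)` with
non-overlapping features. Exons are split at `cdsStart`/`cdsEnd`;
exonic segments 5' of the CDS in transcript orientation are UTR5 and 3'
segments UTR3, which on the minus strand means the genomic-left exonic
segment is the 3' UTR. The upstream window precedes the transcript in
its own orientation (genomically right of `txEnd` for minus-strand
transcripts). A transcript with `cdsStart == cdsEnd` is non-coding; its
exons are labelled `NONCODING_EXON`, a class ranked with the non-coding
tier during prioritization rather than being dropped — non-coding
transcripts are a common source of otherwise-silent annotation gaps.

Each CDS feature stores `cds_offset_before`, the number of coding bases
of its transcript strictly 5' of it in transcript orientation; a coding
position's offset is then `cds_offset_before + (p - start)` on the plus
strand and `cds_offset_before + (end - 1 - p)` on the minus strand.
These offsets are a bijection onto `[0, CDS length)` per transcript, a
property the tests check exhaustively.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `upstreamWindow` | 1,000 bp | promoter-proximal window flagged UPSTREAM |
| `downstreamWindow` | 1,000 bp | window flagged DOWNSTREAM |
| `intronBoundary` | 6 bp | intronic bases within this distance of an exon edge are splice-proximal |

The 1,000 bp windows are a conventional promoter-proximal choice and
are configurable to match any legacy behaviour. The junction distance
of an intronic base counts from 1 at the base adjacent to the exon and
is measured symmetrically at both intron ends, so the default boundary
of 6 flags the canonical ±6 splice window; raising the boundary only
ever grows the splice-proximal set (tested as a monotonicity property),
and 0 disables flagging entirely.

## Coding-effect prediction

The per-transcript CDS file carries the spliced coding sequence already
in coding orientation (reverse-complemented for minus-strand
transcripts), as a plain 3-column TSV (id, strand sign, sequence) — the
only sequence the codon arithmetic needs. For a substitution at coding
offset *c*, codon *c* // 3 is extracted, the alternate allele
(complemented on minus strands) is substituted at *c* mod 3, and both
codons are translated under the standard genetic code (table 1, authored
in-package and cross-checked codon-by-codon against Biopython's table in
the tests).

Effect classes: SYN (same residue), NSN (gain of stop), STL (loss of
the reference stop), NSM (any other residue change). Stop-loss gets its
own class rather than being folded into missense, and ranks with NSN
during prioritization. Degenerate inputs never produce a silent wrong
answer: an N anywhere in the affected codon, a coding offset beyond the
last full codon of a length-not-divisible-by-3 CDS, or a mismatch
between the VCF reference allele and the stored CDS base all yield
UNKNOWN with a warning. Indels receive a region class from their anchor
base only and no codon prediction (variant class NA) — frameshift
consequence calling is out of scope.

The reported "Ref AA chain"/"Alt AA chain" columns carry the full
protein translated up to (not including) the first stop, the alternate
chain truncated at any new stop. For very long proteins these columns
are correspondingly long; users who only need the local change can use
the codon-level column.

## Prioritization

The rank table is a total order over every producible
(hit class, effect class) key; an unrankable key is a configuration bug
and fails fast. The default order places coding above all non-coding
classes and NSN/STL > NSM > SYN within coding — i.e. most damaging
first — with UTR5 ahead of UTR3 and splice-proximal introns ahead of
other non-coding classes. The table is user-overridable
(`PriorityTable.from_order`), so an alternative ordering can be
reproduced without code changes. Ties between equally ranked transcripts
break on the lexicographically smallest transcript id, making selection
a pure, permutation-invariant function of the hit set.

## Synthetic data and what it shows

The generator emulates the study inputs at desk scale: chromosomes of
100 kb (as many as the requested transcripts need), transcripts on both
strands with 1–8 exons, exon lengths 80–300 bp and introns 30–500 bp, a
fraction of non-coding transcripts (12%) and of isoform pairs (35%)
that share an identical CDS while differing in UTR extent — the cases
that exercise multi-transcript prioritization without violating the
one-genome-one-CDS consistency requirement. Planted coding sequences
always start with ATG, end with a stop, contain no internal stop and
have length divisible by 3. Variants are planted per region-class mix
(default: 40% coding, the remainder spread over UTRs, introns, splice
windows, flanks, non-coding exons and intergenic space) by rejection
sampling until the *prioritized* class equals the target, so recovered
cohort proportions equal planted ones exactly. The canonical smoke
bundle is seed 1, 20 transcripts, 80 variants.

Truth comes from a brute-force annotator that shares no interval-index
or codon-arithmetic code with the pipeline: linear scans over transcript
coordinates for region class, and whole-CDS extraction plus Biopython
translation and protein diff for coding effects, with an exhaustive sort
for prioritization. Agreement between pipeline and oracle is therefore a
genuine dual-route check.

What the synthetic data does **not** model: sequencing error and
genotype likelihoods, realistic human gene/intron length distributions,
overlapping genes with conflicting coding sequences on the same bases,
multi-transcript loci beyond two isoforms, and population-scale allele
frequencies. Passing tests show the annotation logic is correct under
the stated conventions, not that any heuristic threshold is tuned for
real genomes — there are no such thresholds; every rule is exact.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline on bundles of
20 transcripts / 80 variants (schema, mode-equivalence and round-trip
checks), 25 transcripts / 800 variants (strand-symmetry under full
bundle mirroring) and 50 transcripts / 5,000 variants (oracle
agreement), sizes at which exhaustive per-base oracles remain practical.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; bundles are byte-stable across runs for a
fixed seed. There is no floating-point tolerance anywhere in the
annotation path — coordinates, offsets and codons are integer/string
exact; summary percentages are the only derived floats.

## Known limitations

- Region classification of indels uses the anchor base only; a deletion
  spanning an exon boundary is classified by its first base.
- Transcripts whose exon list does not reach `txStart`/`txEnd` (absent
  from UCSC dumps, but possible in hand-made files) leave the uncovered
  gap unlabelled rather than guessing a class.
- When `cdsStart` falls inside an intron gap, splitting is strictly by
  coordinate comparison; exotic gene models may label a zero-length UTR
  differently from other tools.
- The sample-ID column reports the first sample of a multi-sample VCF;
  genotype matrices are otherwise ignored.
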