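# Methods

## Scope and model

`exomefunnel` models the downstream half of an exome-based mutation
discovery experiment in the mouse. Everything upstream — probe design,
capture chemistry, read alignment and primary variant calling — is out of
scope; the pipeline consumes a per-sample VCF with allelic depths, gene
models (GFF3), a capture-target design (BED), a reference (FASTA),
known-variant catalogs and uniqueness panels (VCF or 4-column TSV), and
optional linkage intervals. All internal intervals are 0-based half-open
on the forward strand; VCF coordinates are converted on ingest, and
indels are left-aligned against the reference before annotation, since
left-anchored normalization is the de facto standard and exact-key
catalog matching requires one canonical representation.

## Consequence classification

One consequence per variant. When several transcripts overlap a site the
most severe call is kept (severity order: nonsense > frameshift > splice
donor > splice acceptor > in-frame indel > missense > synonymous > UTR >
near-splice > intronic), ties broken by gene symbol.

- Coding SNVs mutate a single codon; both codons are translated
  (standard code, via Biopython) and named `<refAA><codon#><altAA>` with
  `Stop` spelled out, codon numbers 1-based from the annotated CDS start.
  Start-loss and loss of the stop codon are grouped under `nonsense`:
  the funnel only needs "damaging coding", and a finer vocabulary would
  add categories no downstream stage distinguishes.
- Deletions overlapping the CDS are `inframe_del` when the deleted
  length ≡ 0 (mod 3) and the deletion lies wholly in coding sequence
  (named by the first/last affected codons, `H7_Y11del`), otherwise
  `frameshift`. In-frame insertions share the `inframe_del` category —
  a single in-frame-indel class — because no stage treats them
  differently.
- Splice donor/acceptor sites are exactly the two intronic nucleotides
  flanking each exon, oriented by the coding strand (donor on the 3′
  side of the exon). The window is a parameter (`splice_window`, default
  2 bp), as is the near-boundary flag (`near_window`, default 20 bp),
  which exists because a large share of characterized deleterious
  alleles fall within 20 bp of intron/exon boundaries.

## Allele ratio

The ratio is `var_reads / (var_reads + ref_reads)` — the fraction of
read support on the variant allele. A var/ref quotient would diverge for
homozygotes and makes the conventional thresholds (0.95 homozygous, 0.2
heterozygous) meaningless, so the total-support denominator is used
throughout. Thresholds are inclusive (≥): a heterozygous deletion whose
capture/mapping bias puts it exactly at 0.2 must pass the filter it
motivates. Dominant mode applies no upper ratio bound.

## The funnel

Six pure predicates applied in a configurable order (default: in gene →
novel → map overlap → allele ratio → damaging → unique). Because each
stage is a predicate, the final survivor set is order-invariant;
intermediate counts are not, and the default order is the conventional
reporting order. "In gene" uses the full gene span including introns.
"Novel" and "unique" match catalogs allele-exactly (chrom, pos, ref,
alt); position-only matching would mask novel alleles at polymorphic
sites. With no map intervals the map stage passes everything, which is
also how the no-linkage reanalysis mode is expressed. The UTR fallback
(UTR variants passing all non-consequence filters) is computed only when
the funnel empties, mirroring how screens report UTR-only candidates.

## Capture QC

Percentages are rounded half-up to two decimals, matching report-table
presentation; NC80 and 1/NC80 are computed from unrounded intermediates.
NC80 is defined as `d80 / mean_depth`, where `d80` is the largest depth
exceeded-or-met by at least 80 % of targeted bases. An all-zero profile
reports NC80 as missing. On/off-target read classification is consumed
as counts from upstream alignment summaries.

## Synthetic scenarios

The generator emulates the study conditions the pipeline is meant for:

- **Mini-genome**: 2 Mb over 4 chromosomes, ~200 genes of 2–8 exons
  (exons 100–250 bp, introns 150–800 bp), each with an intact ORF
  (ATG…stop, no internal stops) and canonical GT/AG splice
  dinucleotides; UTRs of 30–60 bp at both transcript ends. Targets are
  the exons.
- **Background load**: preset densities scaled by the scenario's
  variant-accessible bases relative to a 54,367,244-base full-exome
  design — `reference_like` ≈ 8,000 calls per full exome with ~half
  INDELs, `divergent` ≈ 200,000 with ~one-third INDELs — preserving
  per-Mb call density at desk scale (~50 and ~1,300 calls on the default
  mini-genome). Variants are placed 80 % in exons, 20 % in intronic
  flanks (100 bp), uniformly; no positional model beyond that is
  attempted.
- **Catalog structure**: true background variants enter the dbSNP-role
  catalog with probability `known_fraction` (0.8) and each uniqueness
  panel independently with `panel_shared_fraction` (0.9). A preset
  fraction of INDELs (half for reference-like backgrounds, where
  reference-guided calling inflates false-positive INDELs; 0.1 for
  divergent) are systematic false positives: absent from dbSNP but
  panel-shared, so the uniqueness stage is what removes them. The
  planted lesion never appears in any catalog or panel.
- **Read support**: depth ~ Poisson(30, floor 8). Background
  homozygotes carry all but Binomial(depth, 0.01) reads on the variant
  allele; background heterozygous SNVs draw Binomial(depth, 0.5) and
  heterozygous INDELs Binomial(depth, 0.5 × `indel_ratio_bias`) variant
  reads, the bias (default 0.4) emulating capture/mapping loss so a het
  INDEL's expected ratio is ≈ 0.2. The *planted lesion* uses
  expectation-valued counts instead of sampling — homozygous: all reads
  variant; heterozygous: `ceil(p × depth)` — so the scenario's ground
  truth sits at the configured ratio by construction and boundary-case
  behaviour (a biased het deletion at exactly 0.2) is reproducible
  rather than a coin flip. Background zygosity is 60 % homozygous, a
  compromise between inbred-background screens (mostly homozygous true
  variants) and exercising the heterozygous ratio stage; no quantitative
  ratio distribution for real heterozygotes is claimed beyond the
  binomial assumption.
- **Map interval**: a fraction of the genome (default 5 %) on the lesion
  chromosome, placed to contain the lesion gene; chromosome-level and
  absent-map configurations are derived from it in the comparison
  drivers.
- **Depth profiles**: per-base negative binomial at equal mean with
  preset size parameter r = 3 (`alpha_like`, dispersed) or r = 15
  (`beta_like`, rebalanced). This emulates only the *direction* of a
  probe-rebalancing redesign — lower dispersion, better 20× coverage —
  not any rebalancing algorithm.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; emitted files embed the seed in their headers
and scenario generation is byte-reproducible.

### What the generator does not emulate

Read-level artifacts (no FASTQ, no mapping), linkage disequilibrium and
real strain haplotype structure, multi-transcript genes, overlapping
genes, indels spanning splice junctions, structural variants, and
mutation-type biases of specific mutagens. Passing tests therefore show
the *analysis* logic is correct under the stated statistical structure,
not that the pipeline is robust to alignment pathologies in real data —
those enter only through the false-positive INDEL and ratio-bias knobs.

## Numerical and design choices

- Coverage thresholds and stage order are configuration, not constants.
- Survivor ranking: category severity, then caller quality descending,
  then genomic position — a total order, so reports are deterministic.
- Funnel ties with several surviving genes are reported as-is; the
  funnel never forces a single winner (two validated genes in one mutant
  is a real outcome).
- Degenerate inputs: empty variant list → all-zero funnel (no error);
  empty depth profile or zero totals → explicit errors; unknown stage
  names and malformed BED/GFF3 lines → named errors with line numbers.
- Scenario sizes in tests and the acceptance script (2 Mb genome,
  100 replicates for recovery rates, 20 for burden comparisons, 10⁴-base
  depth profiles) were chosen as the smallest sizes at which the
  binomial confidence checks and rate thresholds are meaningful.

## Known limitations

- One transcript per gene is assumed by the generator; the classifier
  handles overlapping transcripts (most-severe rule) but this path sees
  little synthetic traffic.
- Deletion names for non-codon-aligned in-frame deletions give the
  affected codon span, not a delins-style rewrite.
- NC80 follows the capture-era convention above; other tools define
  normalized coverage slightly differently, so cross-tool NC80
  comparisons need care.
- The allele-ratio model ignores mapping quality and strand bias;
  `indel_ratio_bias` is a single multiplicative knob.
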