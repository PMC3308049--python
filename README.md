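# exomefunnel

Candidate-mutation nomination for mouse forward genetics by whole-exome
sequencing.

Phenotype-driven mouse screens (spontaneous mutants, ENU mutagenesis)
produce lines whose causative lesion is unknown. Exome capture and
sequencing of a single affected animal yields on the order of 8,000
variant calls for a reference-like (C57BL/6J) background up to more than
200,000 for divergent strain backgrounds — of which exactly one is the
causative mutation. `exomefunnel` implements the analysis layer that
turns that call set into one or two validation candidates, plus the
capture-QC metrics used to judge whether an exome experiment supports
that analysis in the first place.

The package is aimed at people building or evaluating mutation-discovery
pipelines: it runs entirely on self-contained synthetic mutant exomes
with planted lesions, so every stage is testable without any reference
data downloads.

## The method

**Annotation.** Each called variant (VCF with per-sample allelic depths)
is annotated with:

- *allele ratio* `r = v / (v + d)` where `v` and `d` are reads supporting
  the variant and reference alleles (`r ≈ 1` homozygous, `r ≈ 0.5`
  heterozygous; capture/mapping bias depresses `r` for INDELs — a real
  heterozygous 15-bp deletion can sit at `r = 0.2`);
- *functional consequence* against transcript models: coding SNVs are
  translated on the coding strand (`A2P`, `Q5Stop`), deletions are
  in-frame (`H7_Y11del`) when length ≡ 0 (mod 3) else frameshift,
  and the two intronic bases flanking each exon are called splice
  donor/acceptor sites (donor 3′ of the exon on the coding strand);
  intronic variants within 20 bp of a boundary are flagged separately;
- membership in known-variant catalogs (dbSNP-role) and uniqueness panels
  (unrelated exomes / strain-panel data), matched by exact
  (chrom, pos, ref, alt) key after left-alignment.

**The funnel.** Ordered pure-predicate filters, with per-stage survivor
counts:

    variants called → in gene → novel → in map interval
                    → allele ratio (≥0.95 hom / ≥0.2 het)
                    → damaging (coding/splice) → unique → candidates

Thresholds are inclusive, so a boundary heterozygote at exactly 0.2
survives. When no coding/splice candidate remains, UTR variants passing
every other filter are reported as a fallback; the exit-code vocabulary
(0 = candidate, 3 = UTR fallback, 4 = none) encodes the three outcomes a
screen over many mutants needs to triage.

**Capture QC.** From per-target-base depth: percent of target bases at
1/5/10/20×, mean/median depth, on-target read fraction, and NC80 — the
depth exceeded by 80 % of targeted bases divided by mean depth (1.0 is
perfectly uniform capture; 1/NC80 approximates the extra sequencing
needed for uniform 80 % coverage).

**Synthetic scenarios.** A seeded generator emits a 2-Mb mini-genome with
~200 intact gene models, exon targets, background SNV/INDEL loads scaled
from whole-exome practice, catalogs/panels with configurable sharing
fractions, systematic false-positive INDELs, a planted lesion (nonsense,
missense, splice ±2 bp, or 15-bp in-frame deletion) with ground truth,
and negative-binomial depth profiles of configurable uniformity.

## Worked example

```bash
exomefunnel full-run --preset reference_like --seed 7 --out-dir run7
```

prints

```
outcome: candidate; truth gene Gene040 recovered
```

and writes `run7/funnel.tsv` with the per-stage survivor counts,
`run7/survivors.tsv` with the ranked candidates (gene, protein change,
category, allele ratio), and `run7/qc_metrics.tsv` with the coverage
panel. The scenario's ground truth is in `run7/scenario/truth.json`; exit
code 0 confirms a coding/splice candidate was nominated.

The numbered scripts under `analysis/` run the same machinery as a
narrative: `01_simulate_scenarios.py` writes a reference-like and a
divergent scenario; `02_nominate_candidates.py` reproduces the funnel
shape (e.g. divergent: `1285 → 1285 → 314 → 30 → 17 → 10 → 1`, the
planted nonsense lesion being the single survivor);
`03_capture_uniformity.py` shows the rebalanced low-dispersion depth
model beating the high-dispersion one at 20× coverage on every seed;
`04_mapping_burden.py` shows mean validation burden falling as linkage
information is added (no map → chromosome → fine interval); and
`05_published_table_checks.py` recomputes the coverage-percentage
arithmetic below. Outputs land under `results/`.

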