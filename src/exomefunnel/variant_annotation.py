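"""Variant ingest, allele ratios, and functional-consequence classification.

The consequence caller implements the annotation vocabulary used for
candidate-mutation nomination in mouse forward genetics:

* coding SNVs are translated on the coding strand and reported as
  nonsense / missense / synonymous with ``Q5Stop``/``A2P``-style protein names;
* small deletions in coding sequence are in-frame (``H7_Y11del``)
  when their length is a multiple of 3, frameshift otherwise;
* the conserved splice donor / acceptor sites are the two intronic
  nucleotides immediately flanking each exon (donor on the 3' side of an
  exon on the coding strand, acceptor on the 5' side);
* intronic variants within 20 bp of an intron/exon boundary are flagged
  separately (``near_splice_20bp``) because that window carries a large
  share of characterized deleterious alleles.

Allele ratio is computed as var_reads / (var_reads + ref_reads): the
fraction of read support carried by the variant allele (~1 for a
homozygote, ~0.5 for a clean heterozygote, depressed for capture- or
mapping-biased INDELs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .genome_model import GeneModel, GenomicInterval, ReferenceSequence

__all__ = [
    "Variant",
    "Consequence",
    "AnnotatedVariant",
    "read_vcf",
    "read_catalog",
    "allele_ratio",
    "classify_consequence",
    "mark_known",
    "annotate_variants",
    "left_align",
    "parse_region",
    "write_annotated_tsv",
    "SEVERITY_ORDER",
    "CODING_CATEGORIES",
]

log = logging.getLogger(__name__)

# Most to least severe; used to collapse multi-gene overlaps and to rank
# final survivors for reporting.
SEVERITY_ORDER: tuple[str, ...] = (
    "nonsense",
    "frameshift",
    "splice_donor",
    "splice_acceptor",
    "inframe_del",
    "missense",
    "synonymous",
    "utr5",
    "utr3",
    "near_splice_20bp",
    "intronic",
    "intergenic",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

#: categories whose protein_change field is populated
CODING_CATEGORIES = frozenset(
    {"nonsense", "missense", "synonymous", "inframe_del", "frameshift"}
)


@dataclass(frozen=True)
class Variant:
    """One called SNV or small INDEL with its read support.

    ``pos`` is the 1-based VCF position (anchor base for INDELs);
    ``ref_allele``/``alt_allele`` follow VCF conventions.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: float
    var_reads: int
    ref_reads: int
    sample_id: str = ""

    def __post_init__(self):
        if self.var_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.var_reads + self.ref_reads == 0:
            raise ValueError(
                f"{self.chrom}:{self.pos} has zero total read support"
            )

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        if len(self.alt_allele) < len(self.ref_allele):
            return "DEL"
        if len(self.alt_allele) > len(self.ref_allele):
            return "INS"
        return "MNV"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class Consequence:
    """Functional annotation of one variant against the gene set."""

    category: str
    gene_symbol: str = ""
    protein_change: str = ""
    distance_to_exon: int = 0  # 0 exonic; >0 intronic distance; -1 intergenic

    def __post_init__(self):
        if self.category not in _SEVERITY_RANK:
            raise ValueError(f"unknown consequence category {self.category!r}")

    @property
    def severity_rank(self) -> int:
        return _SEVERITY_RANK[self.category]


@dataclass
class AnnotatedVariant:
    variant: Variant
    allele_ratio: float
    consequence: Consequence
    known_in: list[str] = field(default_factory=list)
    in_map_interval: bool = True


def allele_ratio(v: Variant) -> float:
    """Fraction of read support on the variant allele: var/(var+ref)."""
    total = v.var_reads + v.ref_reads
    if total == 0:
        raise ValueError("zero total read support")
    return v.var_reads / total


# ---------------------------------------------------------------------------
# VCF / catalog ingest


def read_vcf(path, sample_id: str | None = None) -> list[Variant]:
    """Read a VCF 4.x into Variants, one per ALT allele.

    Read support is taken from the per-sample AD field when present, else
    from an INFO DP4 tuple (ref fwd, ref rev, alt fwd, alt rev). Records
    with neither raise; non-ACGT alleles are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_id is None:
        sample_id = samples[0] if samples else ""
    sidx = samples.index(sample_id) if sample_id in samples else 0

    out: list[Variant] = []
    for rec in vcf:
        ad = None
        try:
            fmt = rec.format("AD")
            if fmt is not None:
                ad = [int(x) for x in fmt[sidx]]
        except KeyError:
            ad = None
        dp4 = rec.INFO.get("DP4")
        for ai, alt in enumerate(rec.ALT):
            if any(b not in "ACGT" for b in alt.upper()) or alt.startswith("<"):
                log.warning("skipping non-ACGT allele %s at %s:%s", alt, rec.CHROM, rec.POS)
                continue
            if ad is not None and len(ad) > ai + 1:
                ref_reads, var_reads = ad[0], ad[ai + 1]
            elif dp4 is not None:
                d = [int(x) for x in dp4]
                ref_reads, var_reads = d[0] + d[1], d[2] + d[3]
            else:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} lacks AD and DP4 read support"
                )
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF.upper(),
                    alt_allele=alt.upper(),
                    quality=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    var_reads=var_reads,
                    ref_reads=ref_reads,
                    sample_id=sample_id,
                )
            )
    return out


def read_catalog(path) -> set[tuple[str, int, str, str]]:
    """Load a known-variant catalog (VCF or 4-column TSV) as an exact-key set.

    Keys are (chrom, 1-based pos, ref, alt): matching is allele-aware so a
    novel allele at a polymorphic site is not masked.
    """
    path = str(path)
    keys: set[tuple[str, int, str, str]] = set()
    if path.endswith((".vcf", ".vcf.gz")):
        from cyvcf2 import VCF

        for rec in VCF(path):
            for alt in rec.ALT:
                keys.add((rec.CHROM, rec.POS, rec.REF.upper(), alt.upper()))
        return keys
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            keys.add((chrom, int(pos), ref.upper(), alt.upper()))
    return keys


# ---------------------------------------------------------------------------
# Indel normalization


def left_align(v: Variant, ref: ReferenceSequence) -> Variant:
    """Left-align an anchored insertion or deletion against the reference.

    SNVs and already-left-aligned indels are returned unchanged. The
    variant must be in VCF anchored form (shorter allele length 1, shared
    leading base).
    """
    if v.kind not in ("DEL", "INS"):
        return v
    if len(v.ref_allele) > 1 and len(v.alt_allele) > 1:
        return v  # complex substitution: leave as-is
    chrom_seq = ref[v.chrom]
    anchor0 = v.pos - 1
    if v.kind == "DEL":
        seq = v.ref_allele[1:]
    else:
        seq = v.alt_allele[1:]
    moved = False
    while anchor0 > 0 and seq and seq[-1] == chrom_seq[anchor0]:
        seq = chrom_seq[anchor0] + seq[:-1]
        anchor0 -= 1
        moved = True
    if not moved:
        return v
    anchor_base = chrom_seq[anchor0]
    if v.kind == "DEL":
        new_ref, new_alt = anchor_base + seq, anchor_base
    else:
        new_ref, new_alt = anchor_base, anchor_base + seq
    return Variant(
        chrom=v.chrom,
        pos=anchor0 + 1,
        ref_allele=new_ref,
        alt_allele=new_alt,
        quality=v.quality,
        var_reads=v.var_reads,
        ref_reads=v.ref_reads,
        sample_id=v.sample_id,
    )


# ---------------------------------------------------------------------------
# Consequence classification


def _fmt_aa(aa: str) -> str:
    return "Stop" if aa == "*" else aa


def _coding_sequence(gene: GeneModel, ref: ReferenceSequence) -> str:
    """Concatenated CDS in coding (5'->3') orientation."""
    seq = "".join(ref.fetch(iv.chrom, iv.start, iv.end) for iv in gene.cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Coding-orientation offset of genomic position pos0, or None if non-CDS."""
    upstream = 0
    for iv in gene.cds:
        if iv.start <= pos0 < iv.end:
            fwd = upstream + (pos0 - iv.start)
            if gene.strand == "-":
                return gene.cds_length - 1 - fwd
            return fwd
        upstream += len(iv)
    return None


def _snv_coding_consequence(
    gene: GeneModel, ref: ReferenceSequence, pos0: int, alt_base: str
) -> Consequence:
    cds_seq = _coding_sequence(gene, ref)
    off = _cds_offset(gene, pos0)
    assert off is not None
    codon_i, within = divmod(off, 3)
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    base = alt_base if gene.strand == "+" else str(Seq(alt_base).complement())
    mut_codon = codon[:within] + base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    if alt_aa == ref_aa:
        category = "synonymous"
    elif alt_aa == "*" or ref_aa == "*":
        category = "nonsense"  # stop gained, or loss of the stop codon
    elif codon_i == 0 and ref_aa == "M":
        category = "nonsense"  # start-loss: treated as damaging-coding
    else:
        category = "missense"
    change = f"{_fmt_aa(ref_aa)}{codon_i + 1}{_fmt_aa(alt_aa)}"
    return Consequence(category, gene.gene_symbol, change, 0)


def _intron_location(
    gene: GeneModel, pos0: int
) -> tuple[int, str] | None:
    """(distance, side) for an intronic position; side is 'after' the
    upstream exon or 'before' the downstream exon (genomic orientation)."""
    for prev, nxt in zip(gene.exons, gene.exons[1:]):
        if prev.end <= pos0 < nxt.start:
            d_after = pos0 - prev.end + 1
            d_before = nxt.start - pos0
            if d_after <= d_before:
                return d_after, "after"
            return d_before, "before"
    return None


def _noncoding_position_consequence(
    gene: GeneModel, pos0: int, splice_window: int, near_window: int
) -> Consequence:
    """Classify a single genomic position within the gene span, ignoring CDS."""
    in_exon = any(e.start <= pos0 < e.end for e in gene.exons)
    if in_exon:
        if any(iv.start <= pos0 < iv.end for iv in gene.utr5):
            return Consequence("utr5", gene.gene_symbol, "", 0)
        if any(iv.start <= pos0 < iv.end for iv in gene.utr3):
            return Consequence("utr3", gene.gene_symbol, "", 0)
        # exonic, no UTR annotation: orient relative to the CDS
        if gene.cds:
            cds_start, cds_end = gene.cds[0].start, gene.cds[-1].end
            before = pos0 < cds_start
            utr = "utr5" if (before) == (gene.strand == "+") else "utr3"
            return Consequence(utr, gene.gene_symbol, "", 0)
        return Consequence("utr3", gene.gene_symbol, "", 0)
    loc = _intron_location(gene, pos0)
    if loc is None:
        return Consequence("intergenic", "", "", -1)
    dist, side = loc
    if dist <= splice_window:
        # 'after' an exon in genomic coords is the donor side on + strand,
        # the acceptor side on - strand.
        if gene.strand == "+":
            cat = "splice_donor" if side == "after" else "splice_acceptor"
        else:
            cat = "splice_acceptor" if side == "after" else "splice_donor"
        return Consequence(cat, gene.gene_symbol, "", dist)
    if dist <= near_window:
        return Consequence("near_splice_20bp", gene.gene_symbol, "", dist)
    return Consequence("intronic", gene.gene_symbol, "", dist)


def _indel_coding_consequence(
    gene: GeneModel, ref: ReferenceSequence, v: Variant, affected: range
) -> Consequence:
    """Classify an indel whose affected bases overlap the CDS."""
    dlen = abs(len(v.ref_allele) - len(v.alt_allele))
    offsets = [
        off
        for pos0 in affected
        if (off := _cds_offset(gene, pos0)) is not None
    ]
    cds_seq = _coding_sequence(gene, ref)
    protein = str(Seq(cds_seq).translate())
    first = min(offsets) // 3 + 1
    last = max(offsets) // 3 + 1

    def aa(i: int) -> str:
        return _fmt_aa(protein[i - 1]) if i - 1 < len(protein) else "X"

    if v.kind == "DEL":
        fully_in_cds = len(offsets) == dlen
        if dlen % 3 == 0 and fully_in_cds:
            if first == last:
                change = f"{aa(first)}{first}del"
            else:
                change = f"{aa(first)}{first}_{aa(last)}{last}del"
            return Consequence("inframe_del", gene.gene_symbol, change, 0)
        return Consequence("frameshift", gene.gene_symbol, f"{aa(first)}{first}fs", 0)
    # insertion within CDS: in-frame insertions share the inframe_del
    # category (single in-frame-indel class); others shift the frame
    if dlen % 3 == 0:
        return Consequence("inframe_del", gene.gene_symbol, f"{aa(first)}{first}ins", 0)
    return Consequence("frameshift", gene.gene_symbol, f"{aa(first)}{first}fs", 0)


def _classify_against_gene(
    v: Variant,
    gene: GeneModel,
    ref: ReferenceSequence,
    splice_window: int,
    near_window: int,
) -> Consequence | None:
    """Consequence of v against one transcript, or None if outside its span."""
    span = gene.span
    if v.kind == "SNV":
        pos0 = v.pos - 1
        if not span.contains(v.chrom, pos0):
            return None
        if _cds_offset(gene, pos0) is not None:
            return _snv_coding_consequence(gene, ref, pos0, v.alt_allele)
        return _noncoding_position_consequence(gene, pos0, splice_window, near_window)

    if v.kind == "DEL":
        affected = range(v.pos, v.pos - 1 + len(v.ref_allele))  # 0-based deleted bases
    else:  # INS: the insertion sits between anchor and the next base
        affected = range(v.pos, v.pos + 1)
    if v.chrom != span.chrom or not any(span.start <= p < span.end for p in affected):
        return None
    if v.kind == "INS":
        # insertion point is in CDS only if both flanking bases are coding
        in_cds = (
            _cds_offset(gene, v.pos - 1) is not None
            and _cds_offset(gene, v.pos) is not None
        )
    else:
        in_cds = any(_cds_offset(gene, p) is not None for p in affected)
    if in_cds:
        return _indel_coding_consequence(gene, ref, v, affected)
    per_base = [
        _noncoding_position_consequence(gene, p, splice_window, near_window)
        for p in affected
        if span.start <= p < span.end
    ]
    return min(per_base, key=lambda c: (c.severity_rank, c.distance_to_exon))


def classify_consequence(
    v: Variant,
    genes: Sequence[GeneModel],
    ref: ReferenceSequence,
    splice_window: int = 2,
    near_window: int = 20,
) -> Consequence:
    """Classify one variant against the gene set.

    When multiple transcripts overlap the site, the most severe consequence
    is reported; ties break by gene symbol (logged at DEBUG).
    """
    if v.chrom not in ref:
        raise KeyError(f"variant chromosome {v.chrom} absent from reference")
    hits = []
    for gene in genes:
        c = _classify_against_gene(v, gene, ref, splice_window, near_window)
        if c is not None:
            hits.append(c)
    if not hits:
        return Consequence("intergenic", "", "", -1)
    hits.sort(key=lambda c: (c.severity_rank, c.gene_symbol))
    if len(hits) > 1:
        log.debug(
            "%s:%d overlaps %d transcripts; keeping %s (%s)",
            v.chrom, v.pos, len(hits), hits[0].category, hits[0].gene_symbol,
        )
    return hits[0]


# ---------------------------------------------------------------------------
# Catalog marking and the full annotation pass


def mark_known(
    annotated: Sequence[AnnotatedVariant],
    catalogs: Mapping[str, set[tuple[str, int, str, str]]],
) -> Sequence[AnnotatedVariant]:
    """Fill known_in with every catalog holding an exact-allele match."""
    for av in annotated:
        av.known_in = sorted(
            name for name, keys in catalogs.items() if av.variant.key in keys
        )
    return annotated


def parse_region(text: str, ref: ReferenceSequence | None = None) -> GenomicInterval:
    """Parse 'chrom' or 'chrom:start-end' (1-based inclusive) into an interval.

    A bare chromosome name means the whole chromosome (requires ``ref``).
    """
    if ":" in text:
        chrom, rng = text.split(":", 1)
        start, end = rng.replace(",", "").split("-")
        return GenomicInterval(chrom, int(start) - 1, int(end))
    if ref is None:
        raise ValueError(f"whole-chromosome region {text!r} requires a reference")
    return GenomicInterval(text, 0, ref.length(text))


def annotate_variants(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    ref: ReferenceSequence,
    catalogs: Mapping[str, set] | None = None,
    map_intervals: Sequence[GenomicInterval] | None = None,
    splice_window: int = 2,
    near_window: int = 20,
) -> list[AnnotatedVariant]:
    """Normalize, classify and catalog-mark a variant list.

    Indels are left-aligned before annotation. ``map_intervals`` empty or
    None marks every variant as in-interval (no mapping data).
    """
    # index gene spans per chromosome for the common many-variant case
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gi, gene in enumerate(genes):
        span = gene.span
        trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, gi)

    out = []
    for v in variants:
        v = left_align(v, ref)
        lo = v.pos - 1
        hi = v.pos - 1 + max(len(v.ref_allele), 1)
        nearby = (
            [genes[iv.data] for iv in sorted(trees[v.chrom].overlap(lo, hi))]
            if v.chrom in trees
            else []
        )
        cons = classify_consequence(v, nearby, ref, splice_window, near_window)
        in_map = True
        if map_intervals:
            in_map = any(
                iv.chrom == v.chrom and iv.start <= v.pos - 1 < iv.end
                for iv in map_intervals
            )
        out.append(
            AnnotatedVariant(
                variant=v,
                allele_ratio=allele_ratio(v),
                consequence=cons,
                in_map_interval=in_map,
            )
        )
    if catalogs:
        mark_known(out, catalogs)
    return out


def write_annotated_tsv(annotated: Sequence[AnnotatedVariant], path) -> None:
    """One row per annotated variant, with the nomination-relevant columns."""
    import pandas as pd

    rows = [
        {
            "sample": av.variant.sample_id,
            "chrom": av.variant.chrom,
            "pos": av.variant.pos,
            "ref": av.variant.ref_allele,
            "alt": av.variant.alt_allele,
            "kind": av.variant.kind,
            "quality": av.variant.quality,
            "var_reads": av.variant.var_reads,
            "ref_reads": av.variant.ref_reads,
            "allele_ratio": round(av.allele_ratio, 4),
            "gene": av.consequence.gene_symbol,
            "category": av.consequence.category,
            "protein_change": av.consequence.protein_change,
            "distance_to_exon": av.consequence.distance_to_exon,
            "known_in": ",".join(av.known_in),
            "in_map_interval": av.in_map_interval,
        }
        for av in annotated
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
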