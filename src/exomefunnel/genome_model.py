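"""Coordinate-safe genomic interval and gene-model types plus format readers.

All intervals are stored 0-based, half-open, on the forward strand; strand
is carried as metadata and honoured downstream by the consequence caller.
BED input is taken as-is; VCF positions (1-based) are converted on ingest by
:mod:`exomefunnel.variant_annotation`.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TargetSet",
    "ReferenceSequence",
    "interval_overlap",
    "merge_intervals",
    "read_bed",
    "read_gene_models",
    "write_gene_models",
    "read_fasta",
    "BedParseError",
    "GffParseError",
    "GeneModelError",
]


class BedParseError(ValueError):
    """Malformed BED input; message names the offending line number."""


class GffParseError(ValueError):
    """Malformed GFF3 input (missing parents, bad coordinates)."""


class GeneModelError(ValueError):
    """Gene-model invariant violation (CDS outside exons, bad phase)."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into a sorted disjoint list.

    Strand is dropped (merged intervals are unstranded). Idempotent.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class TargetSet:
    """A merged capture-target design: disjoint sorted intervals."""

    intervals: list[GenomicInterval]

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GeneModel:
    """One transcript: ordered exons with CDS and UTR sub-intervals.

    Exons are stored in ascending genomic order regardless of strand; the
    consequence caller orients by ``strand`` when translating.
    """

    gene_symbol: str
    transcript_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        self.utr5 = sorted(self.utr5, key=lambda iv: iv.start)
        self.utr3 = sorted(self.utr3, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise GeneModelError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} / {b.start}-{b.end}"
                )
        for iv in (*self.cds, *self.utr5, *self.utr3):
            if not any(e.start <= iv.start and iv.end <= e.end for e in self.exons):
                raise GeneModelError(
                    f"{self.transcript_id}: feature {iv.start}-{iv.end} "
                    "not contained in any exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        """Gene span from first exon start to last exon end (introns included)."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    def validate_cds_frame(self, strict: bool = True) -> bool:
        """Check concatenated CDS length is a multiple of 3.

        Returns True when in frame; raises (strict) or returns False otherwise.
        """
        ok = self.cds_length % 3 == 0
        if not ok and strict:
            raise GeneModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "is not a multiple of 3"
            )
        return ok


class ReferenceSequence:
    """Per-chromosome nucleotide strings (uppercase A/C/G/T/N)."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {c: s.upper() for c, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise KeyError(
                f"{chrom}:{start}-{end} outside reference (length {len(seq)})"
            )
        return seq[start:end]

    def chroms(self) -> list[str]:
        return list(self.sequences)


def read_bed(path) -> TargetSet:
    """Read a 3+ column BED (0-based half-open) into a merged TargetSet."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return TargetSet(intervals)


def read_fasta(path) -> ReferenceSequence:
    """Read a (possibly gzipped) FASTA into memory."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    return ReferenceSequence(records)


# GFF3 parsing is delegated to gffutils (in-memory sqlite db); the feature
# hierarchy gene -> mRNA -> exon/CDS/UTR is then lifted into GeneModel.

def read_gene_models(path, allow_frame_violation: bool = False) -> list[GeneModel]:
    """Read GFF3 gene/mRNA/exon/CDS/UTR features into GeneModel objects.

    One GeneModel per mRNA. CDS frame (length % 3 == 0) is enforced unless
    ``allow_frame_violation``; then a warning is attached via warnings.warn.
    """
    import warnings

    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise GffParseError(f"{path}: {exc}") from exc

    kinds = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_UTR": "utr5",
        "three_prime_UTR": "utr3",
    }
    models = []
    for mrna in db.features_of_type("mRNA"):
        parts: dict[str, list[GenomicInterval]] = {
            "exons": [],
            "cds": [],
            "utr5": [],
            "utr3": [],
        }
        for child in db.children(mrna.id):
            if child.featuretype in kinds:
                parts[kinds[child.featuretype]].append(
                    GenomicInterval(child.seqid, child.start - 1, child.end, mrna.strand)
                )
        if not parts["exons"]:
            raise GffParseError(f"transcript {mrna.id} has no exons")
        gene_symbol = mrna.id
        parents = list(db.parents(mrna.id, featuretype="gene"))
        if parents:
            gene_symbol = parents[0].attributes.get("Name", [parents[0].id])[0]
        model = GeneModel(
            gene_symbol=gene_symbol,
            transcript_id=mrna.id,
            strand=mrna.strand,
            exons=parts["exons"],
            cds=parts["cds"],
            utr5=parts["utr5"],
            utr3=parts["utr3"],
        )
        if model.cds and not model.validate_cds_frame(strict=False):
            if allow_frame_violation:
                warnings.warn(
                    f"{mrna.id}: CDS length {model.cds_length} not a multiple of 3"
                )
            else:
                raise GeneModelError(
                    f"{mrna.id}: CDS length {model.cds_length} not a multiple of 3"
                )
        models.append(model)
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    """Write GeneModels as GFF3 (inverse of read_gene_models)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gene_id = f"gene:{m.gene_symbol}"
            span = m.span
            fh.write(
                f"{m.chrom}\texomefunnel\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={gene_id};Name={m.gene_symbol}\n"
            )
            fh.write(
                f"{m.chrom}\texomefunnel\tmRNA\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.transcript_id};Parent={gene_id}\n"
            )
            for ftype, ivs in (
                ("exon", m.exons),
                ("CDS", m.cds),
                ("five_prime_UTR", m.utr5),
                ("three_prime_UTR", m.utr3),
            ):
                for iv in ivs:
                    fh.write(
                        f"{m.chrom}\texomefunnel\t{ftype}\t{iv.start + 1}\t{iv.end}"
                        f"\t.\t{m.strand}\t.\tParent={m.transcript_id}\n"
                    )


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_fasta(ref: ReferenceSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in ref.chroms():
            fh.write(f">{chrom}\n")
            seq = ref[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
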