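"""Summary arithmetic over curated allele catalogs and read-mapping geometry.

Two small calculations motivate exome-based mutation discovery in mouse
forward genetics:

* among mutant alleles whose lesion has been characterized, the fraction
  falling in exons or in the conserved splice acceptor/donor dinucleotides
  — the regions an exome design purposefully covers; and
* the fraction of a sequencing read occupied by a deletion gap, which
  sets the mapping penalty and explains why short reads under-recover
  small INDEL alleles (a 15-bp gap spans nearly 38% of a 40-bp read but
  only ~20% of a 76-bp read).
"""

from __future__ import annotations

from dataclasses import dataclass

from .capture_qc import round_half_up

__all__ = ["AlleleClassCounts", "exon_splice_fraction", "read_gap_fraction"]


@dataclass(frozen=True)
class AlleleClassCounts:
    """Allele counts by lesion class from a phenotype-allele catalog."""

    uncharacterized: int
    intron_utr_regulatory: int
    exon: int
    splice: int

    @property
    def total(self) -> int:
        return (
            self.uncharacterized
            + self.intron_utr_regulatory
            + self.exon
            + self.splice
        )

    @property
    def characterized(self) -> int:
        return self.total - self.uncharacterized


def exon_splice_fraction(counts: AlleleClassCounts, ndigits: int = 0) -> float:
    """Percent of *characterized* alleles in exons or conserved splice sites."""
    if counts.characterized == 0:
        raise ValueError("no characterized alleles")
    pct = 100.0 * (counts.exon + counts.splice) / counts.characterized
    return round_half_up(pct, ndigits)


def read_gap_fraction(gap_bp: int, read_bp: int, ndigits: int = 2) -> float:
    """Percent of a read occupied by an alignment gap of ``gap_bp`` bases."""
    if read_bp <= 0 or gap_bp < 0:
        raise ValueError("require read_bp > 0 and gap_bp >= 0")
    return round_half_up(100.0 * gap_bp / read_bp, ndigits)
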