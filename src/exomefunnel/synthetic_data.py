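"""Self-contained synthetic mutant-exome scenarios.

One scenario is a mini-genome (default 2 Mb over 4 chromosomes) carrying
~200 intact protein-coding gene models, an exon capture-target design, a
background of called SNVs/INDELs whose load is scaled from whole-exome
practice (≈8,000 calls for a reference-like strain background up to
≈200,000 for a divergent background, per 54.4 Mb of target), a dbSNP-role
known-variant catalog, uniqueness panels emulating unrelated exomes /
strain-panel data, and one planted causal lesion with a ground-truth
record. Reference-like backgrounds additionally carry an excess of
false-positive INDEL calls that are absent from dbSNP but shared with the
uniqueness panels, emulating systematic mapping artifacts.

Read support is drawn from a simple depth model: background heterozygotes
sample variant reads as Binomial(depth, 0.5), het INDELs as
Binomial(depth, 0.5 x indel_ratio_bias) — the capture/mapping bias that
depresses INDEL allele ratios to ~0.2 — and homozygotes carry (nearly)
all reads on the variant allele. The planted lesion's counts are set at
the model expectation rather than sampled, so the scenario's ground truth
has the configured allele ratio by construction.

All randomness flows from a single seed; generated files embed the seed
in their headers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .capture_qc import DepthProfile
from .genome_model import (
    GeneModel,
    GenomicInterval,
    ReferenceSequence,
    TargetSet,
    merge_intervals,
    write_bed,
    write_fasta,
    write_gene_models,
)
from .variant_annotation import Variant, left_align

__all__ = ["ScenarioConfig", "Scenario", "Truth", "generate", "generate_depth_profile"]

#: whole-exome target size the printed background loads refer to
FULL_EXOME_TARGET_BASES = 54_367_244

#: preset: (total calls per full exome, SNV fraction, FP fraction of INDELs)
PRESETS = {
    "reference_like": (8_000, 0.5, 0.5),
    "divergent": (200_000, 2.0 / 3.0, 0.1),
}

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

LESION_TYPES = (
    "nonsense",
    "missense",
    "splice_donor",
    "splice_acceptor",
    "inframe_del_15bp",
)

_LESION_CATEGORY = {
    "nonsense": "nonsense",
    "missense": "missense",
    "splice_donor": "splice_donor",
    "splice_acceptor": "splice_acceptor",
    "inframe_del_15bp": "inframe_del",
}


@dataclass
class ScenarioConfig:
    """Full parameterization of one synthetic mutant exome."""

    seed: int = 0
    preset: str = "reference_like"
    genome_bases: int = 2_000_000
    n_chroms: int = 4
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 8)
    background_snv_count: int | None = None  # None: derive from preset density
    background_indel_count: int | None = None
    known_fraction: float = 0.8
    panel_shared_fraction: float = 0.9
    n_panels: int = 2
    hom_fraction: float = 0.6  # zygosity mix of background variants
    lesion_type: str = "nonsense"
    lesion_zygosity: str = "hom"
    lesion_gene: str | None = None  # pin to a symbol; None: random compatible gene
    depth_mean: int = 30
    indel_ratio_bias: float = 0.4
    map_fraction: float | None = 0.05  # None: no mapping data
    intron_flank: int = 100  # "nearby intron" width for background placement
    sample_id: str = "mutant"

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.lesion_type!r}")
        if self.lesion_zygosity not in ("hom", "het"):
            raise ValueError("lesion_zygosity must be 'hom' or 'het'")
        for p in (self.known_fraction, self.panel_shared_fraction, self.hom_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class Truth:
    """Ground-truth description of the planted lesion."""

    chrom: str
    pos: int  # 1-based VCF position
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    lesion_type: str
    category: str  # expected consequence category
    zygosity: str
    allele_ratio: float
    n_false_positive_indels: int = 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class Scenario:
    reference: ReferenceSequence
    genes: list[GeneModel]
    targets: TargetSet
    variants: list[Variant]
    catalogs: dict[str, set]
    panels: dict[str, set]
    map_intervals: list[GenomicInterval]
    truth: Truth
    config: ScenarioConfig
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def all_catalogs(self) -> dict[str, set]:
        return {**self.catalogs, **self.panels}


# ---------------------------------------------------------------------------
# genome and gene construction


def _random_genome(rng: np.random.Generator, cfg: ScenarioConfig) -> dict[str, bytearray]:
    per_chrom = cfg.genome_bases // cfg.n_chroms
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": bytearray(lut[rng.integers(0, 4, per_chrom)].tobytes())
        for i in range(cfg.n_chroms)
    }


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + a stop codon."""
    codons: list[str] = []
    need = n_codons - 2
    while len(codons) < need:
        draw = rng.integers(0, 4, (need + 8, 3))
        for row in draw:
            c = _BASES[row[0]] + _BASES[row[1]] + _BASES[row[2]]
            if c not in _STOPS:
                codons.append(c)
                if len(codons) == need:
                    break
    return "ATG" + "".join(codons) + _STOPS[rng.integers(0, 3)]


def _cds_positions_coding_order(gene: GeneModel) -> list[int]:
    pos = [p for iv in gene.cds for p in range(iv.start, iv.end)]
    return pos[::-1] if gene.strand == "-" else pos


def _build_genes(
    rng: np.random.Generator, genome: dict[str, bytearray], cfg: ScenarioConfig
) -> list[GeneModel]:
    chroms = list(genome)
    genes: list[GeneModel] = []
    cursors = {c: int(rng.integers(1_000, 3_000)) for c in chroms}
    for gi in range(cfg.n_genes):
        chrom = chroms[gi % len(chroms)]
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = rng.integers(100, 251, n_exons)
        intron_lens = rng.integers(150, 801, max(n_exons - 1, 0))
        u5 = int(rng.integers(30, 61))
        u3 = int(rng.integers(30, 61))
        cds_len = int(exon_lens.sum()) - u5 - u3
        u3 += cds_len % 3  # keep the reading frame intact
        strand = "+" if rng.integers(0, 2) == 0 else "-"

        start = cursors[chrom]
        exons, pos = [], start
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + int(elen), strand))
            pos += int(elen)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        cursors[chrom] = pos + int(rng.integers(500, 3_000))
        if cursors[chrom] >= len(genome[chrom]) - 5_000:
            raise ValueError(
                "mini-genome too small for the requested gene count; "
                "increase genome_bases or reduce n_genes"
            )

        # carve UTRs and CDS out of the exon chain, honouring strand
        if strand == "+":
            left_trim, right_trim = u5, u3
        else:
            left_trim, right_trim = u3, u5
        first, last = exons[0], exons[-1]
        utr_left = GenomicInterval(chrom, first.start, first.start + left_trim, strand)
        utr_right = GenomicInterval(chrom, last.end - right_trim, last.end, strand)
        cds = []
        for i, e in enumerate(exons):
            s = e.start + left_trim if i == 0 else e.start
            t = e.end - right_trim if i == n_exons - 1 else e.end
            if n_exons == 1:
                s, t = e.start + left_trim, e.end - right_trim
            cds.append(GenomicInterval(chrom, s, t, strand))
        utr5, utr3 = ([utr_left], [utr_right]) if strand == "+" else ([utr_right], [utr_left])

        gene = GeneModel(
            gene_symbol=f"Gene{gi + 1:03d}",
            transcript_id=f"Gene{gi + 1:03d}-T1",
            strand=strand,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
        )
        gene.validate_cds_frame()

        # overwrite the reference so the CDS is an intact ORF
        coding_seq = _random_coding_sequence(rng, gene.cds_length // 3)
        seq = genome[chrom]
        positions = _cds_positions_coding_order(gene)
        for p, base in zip(positions, coding_seq):
            seq[p] = ord(base) if strand == "+" else ord(base.translate(_COMP))
        # canonical splice dinucleotides (coding-strand GT...AG)
        for prev, nxt in zip(exons, exons[1:]):
            if strand == "+":
                seq[prev.end : prev.end + 2] = b"GT"
                seq[nxt.start - 2 : nxt.start] = b"AG"
            else:
                seq[prev.end : prev.end + 2] = b"CT"
                seq[nxt.start - 2 : nxt.start] = b"AC"
        genes.append(gene)
    return genes


def _intron_flank_intervals(genes: Sequence[GeneModel], flank: int) -> list[GenomicInterval]:
    out = []
    for g in genes:
        for prev, nxt in zip(g.exons, g.exons[1:]):
            lo, hi = prev.end, nxt.start
            if hi - lo <= 2 * flank:
                out.append(GenomicInterval(g.chrom, lo, hi))
            else:
                out.append(GenomicInterval(g.chrom, lo, lo + flank))
                out.append(GenomicInterval(g.chrom, hi - flank, hi))
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# lesion planting


def _genomic_of_coding_offset(gene: GeneModel, off: int) -> int:
    return _cds_positions_coding_order(gene)[off]


def _plant_lesion(
    rng: np.random.Generator,
    genome: dict[str, bytearray],
    gene: GeneModel,
    cfg: ScenarioConfig,
) -> tuple[str, int, str, str]:
    """Choose the lesion site; returns (chrom, pos1, ref, alt)."""
    from Bio.Seq import Seq

    chrom = gene.chrom
    seq = genome[chrom]
    positions = _cds_positions_coding_order(gene)
    coding = "".join(
        chr(seq[p]) if gene.strand == "+" else chr(seq[p]).translate(_COMP)
        for p in positions
    )
    n_codons = len(coding) // 3

    def snv_at(off: int, coding_alt: str) -> tuple[str, int, str, str]:
        gpos = positions[off]
        ref_base = chr(seq[gpos])
        alt_base = coding_alt if gene.strand == "+" else coding_alt.translate(_COMP)
        return chrom, gpos + 1, ref_base, alt_base

    if cfg.lesion_type in ("nonsense", "missense"):
        candidates = []
        for ci in range(1, n_codons - 1):  # skip start and stop codons
            codon = coding[ci * 3 : ci * 3 + 3]
            ref_aa = str(Seq(codon).translate())
            for within in range(3):
                for b in _BASES:
                    if b == codon[within]:
                        continue
                    mut = codon[:within] + b + codon[within + 1 :]
                    aa = str(Seq(mut).translate())
                    if cfg.lesion_type == "nonsense" and aa == "*":
                        candidates.append((ci * 3 + within, b))
                    elif cfg.lesion_type == "missense" and aa not in ("*", ref_aa):
                        candidates.append((ci * 3 + within, b))
        off, alt = candidates[rng.integers(0, len(candidates))]
        return snv_at(off, alt)

    if cfg.lesion_type in ("splice_donor", "splice_acceptor"):
        if len(gene.exons) < 2:
            raise ValueError(f"{gene.gene_symbol} has no intron for a splice lesion")
        i = int(rng.integers(0, len(gene.exons) - 1))
        prev, nxt = gene.exons[i], gene.exons[i + 1]
        d = int(rng.integers(1, 3))  # the two conserved intronic bases
        donor_after_prev = gene.strand == "+"
        want_after = (cfg.lesion_type == "splice_donor") == donor_after_prev
        gpos = prev.end + (d - 1) if want_after else nxt.start - d
        ref_base = chr(seq[gpos])
        alt_base = _BASES[(_BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4]
        if alt_base == ref_base:
            alt_base = _BASES[(_BASES.index(ref_base) + 1) % 4]
        return chrom, gpos + 1, ref_base, alt_base

    if cfg.lesion_type == "inframe_del_15bp":
        # codon-aligned 15-bp window fully inside one CDS interval, away
        # from the start and stop codons
        # keep a 9-base intra-exon margin on the genomic-left side so that
        # left-alignment during annotation cannot shift the deletion
        # across the CDS-exon edge
        candidates = []
        for off in range(3, len(coding) - 3 - 15, 3):
            window = positions[off : off + 15]
            lo, hi = min(window), max(window)
            if hi - lo != 14 or lo < 1:
                continue
            host = next((iv for iv in gene.cds if iv.start <= lo < iv.end), None)
            if host is None or lo - host.start < 9 or hi >= host.end:
                continue
            candidates.append(lo)
        if not candidates:
            raise ValueError(f"{gene.gene_symbol}: no room for a 15-bp deletion")
        lo = candidates[int(rng.integers(0, len(candidates)))]
        anchor0 = lo - 1
        ref = "".join(chr(seq[p]) for p in range(anchor0, anchor0 + 16))
        return chrom, anchor0 + 1, ref, ref[0]

    raise AssertionError(cfg.lesion_type)


def _lesion_compatible(gene: GeneModel, lesion_type: str) -> bool:
    if lesion_type in ("splice_donor", "splice_acceptor"):
        return len(gene.exons) >= 2
    if lesion_type == "inframe_del_15bp":
        return any(len(iv) >= 30 for iv in gene.cds)
    return gene.cds_length >= 30


# ---------------------------------------------------------------------------
# read-support model


def _background_reads(
    rng: np.random.Generator, cfg: ScenarioConfig, is_indel: bool, hom: bool
) -> tuple[int, int]:
    depth = max(8, int(rng.poisson(cfg.depth_mean)))
    if hom:
        ref = int(rng.binomial(depth, 0.01))
        return depth - ref, ref
    p = 0.5 * (cfg.indel_ratio_bias if is_indel else 1.0)
    var = int(rng.binomial(depth, p))
    var = min(max(var, 1), depth - 1)  # a called het has support on both alleles
    return var, depth - var


def _lesion_reads(cfg: ScenarioConfig, is_indel: bool) -> tuple[int, int]:
    depth = cfg.depth_mean
    if cfg.lesion_zygosity == "hom":
        return depth, 0
    p = 0.5 * (cfg.indel_ratio_bias if is_indel else 1.0)
    var = math.ceil(p * depth)
    return var, depth - var


# ---------------------------------------------------------------------------
# scenario assembly


def _background_counts(cfg: ScenarioConfig, accessible_bases: int) -> tuple[int, int, int]:
    """(n_snv, n_true_indel, n_fp_indel) scaled to the mini target space."""
    total_full, snv_frac, fp_frac = PRESETS[cfg.preset]
    scale = accessible_bases / FULL_EXOME_TARGET_BASES
    total = total_full * scale
    n_snv = (
        cfg.background_snv_count
        if cfg.background_snv_count is not None
        else int(round(total * snv_frac))
    )
    n_indel_total = (
        cfg.background_indel_count
        if cfg.background_indel_count is not None
        else int(round(total * (1 - snv_frac)))
    )
    n_fp = int(round(n_indel_total * fp_frac))
    return n_snv, n_indel_total - n_fp, n_fp


def _sample_positions(
    rng: np.random.Generator,
    exonic: list[GenomicInterval],
    flanks: list[GenomicInterval],
    n: int,
    occupied: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    """Draw n distinct positions, 80% from exons and 20% from intron flanks."""

    pools = {}
    for key, intervals in (("exon", exonic), ("flank", flanks)):
        sizes = np.array([len(iv) for iv in intervals])
        pools[key] = (intervals, sizes, np.cumsum(sizes))

    def draw(key: str) -> tuple[str, int]:
        intervals, sizes, cum = pools[key]
        r = int(rng.integers(0, cum[-1]))
        i = int(np.searchsorted(cum, r, side="right"))
        iv = intervals[i]
        offset = r - (cum[i] - sizes[i])
        return iv.chrom, iv.start + int(offset)

    out = []
    attempts = 0
    while len(out) < n and attempts < 50 * n + 1000:
        attempts += 1
        chrom, pos = draw("exon" if rng.random() < 0.8 else "flank")
        if (chrom, pos) in occupied:
            continue
        occupied.add((chrom, pos))
        out.append((chrom, pos))
    if len(out) < n:
        raise RuntimeError("could not place the requested background variant load")
    return out


def generate(cfg: ScenarioConfig, out_dir: str | Path | None = None) -> Scenario:
    """Generate one complete scenario; write standard-format files if asked.

    Deterministic under ``cfg.seed``: repeated calls yield identical
    objects and identical file bytes.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = _random_genome(rng, cfg)
    genes = _build_genes(rng, genome, cfg)
    targets = TargetSet([e for g in genes for e in g.exons])
    flanks = _intron_flank_intervals(genes, cfg.intron_flank)
    exon_ivs = list(targets.intervals)

    # lesion gene and map interval
    if cfg.lesion_gene is not None:
        matches = [g for g in genes if g.gene_symbol == cfg.lesion_gene]
        if not matches:
            raise ValueError(f"lesion gene {cfg.lesion_gene!r} not in scenario")
        lesion_gene = matches[0]
        if not _lesion_compatible(lesion_gene, cfg.lesion_type):
            raise ValueError(
                f"pinned gene {cfg.lesion_gene} incompatible with {cfg.lesion_type}"
            )
    else:
        compatible = [g for g in genes if _lesion_compatible(g, cfg.lesion_type)]
        lesion_gene = compatible[int(rng.integers(0, len(compatible)))]

    chrom_len = len(genome[lesion_gene.chrom])
    map_intervals: list[GenomicInterval] = []
    if cfg.map_fraction is not None:
        span = lesion_gene.span
        length = min(int(cfg.map_fraction * cfg.genome_bases), chrom_len)
        lo_min = max(0, span.end - length)
        lo_max = min(span.start, chrom_len - length)
        lo = int(rng.integers(lo_min, lo_max + 1)) if lo_max > lo_min else lo_min
        map_intervals = [GenomicInterval(lesion_gene.chrom, lo, lo + length)]

    reference = ReferenceSequence({c: bytes(s).decode() for c, s in genome.items()})

    chrom, pos1, ref_allele, alt_allele = _plant_lesion(rng, genome, lesion_gene, cfg)
    lesion_is_indel = len(ref_allele) != len(alt_allele)
    lvar, lref = _lesion_reads(cfg, lesion_is_indel)
    # emit in normalized (left-aligned) form so ground-truth, sample and
    # catalog keys agree with what annotation produces
    lesion = left_align(
        Variant(
            chrom=chrom,
            pos=pos1,
            ref_allele=ref_allele,
            alt_allele=alt_allele,
            quality=90.0,
            var_reads=lvar,
            ref_reads=lref,
            sample_id=cfg.sample_id,
        ),
        reference,
    )

    # background variants
    n_snv, n_indel, n_fp = _background_counts(cfg, targets.total_bases + sum(len(iv) for iv in flanks))
    occupied = {(chrom, p) for p in range(lesion.pos - 1, pos1 - 1 + len(ref_allele))}
    variants: list[Variant] = [lesion]
    catalogs: dict[str, set] = {"dbSNP": set()}
    panels: dict[str, set] = {f"panel_{i + 1}": set() for i in range(cfg.n_panels)}
    n_fp_emitted = 0

    specs = [("SNV", False)] * n_snv + [("INDEL", False)] * n_indel + [("INDEL", True)] * n_fp
    sites = _sample_positions(rng, exon_ivs, flanks, len(specs), occupied)
    for (kind, is_fp), (vchrom, vpos0) in zip(specs, sites):
        seq = genome[vchrom]
        if kind == "SNV":
            ref = chr(seq[vpos0])
            alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                alt = _BASES[(_BASES.index(ref) + 1) % 4]
            is_indel = False
        else:
            is_indel = True
            ilen = int(rng.integers(1, 7))
            if rng.random() < 0.5 and vpos0 + ilen + 1 < len(seq):  # deletion
                ref = "".join(chr(b) for b in seq[vpos0 : vpos0 + ilen + 1])
                alt = ref[0]
                for p in range(vpos0 + 1, vpos0 + ilen + 1):
                    occupied.add((vchrom, p))
            else:  # insertion
                ref = chr(seq[vpos0])
                alt = ref + "".join(_BASES[i] for i in rng.integers(0, 4, ilen))
        hom = bool(rng.random() < cfg.hom_fraction)
        var_reads, ref_reads = _background_reads(rng, cfg, is_indel, hom)
        v = left_align(
            Variant(
                chrom=vchrom,
                pos=vpos0 + 1,
                ref_allele=ref,
                alt_allele=alt,
                quality=float(np.round(20 + 60 * rng.random(), 1)),
                var_reads=var_reads,
                ref_reads=ref_reads,
                sample_id=cfg.sample_id,
            ),
            reference,
        )
        variants.append(v)
        if is_fp:
            n_fp_emitted += 1
        elif rng.random() < cfg.known_fraction:
            catalogs["dbSNP"].add(v.key)
        for pname in panels:
            if rng.random() < cfg.panel_shared_fraction:
                panels[pname].add(v.key)

    variants.sort(key=lambda v: (v.chrom, v.pos, v.alt_allele))

    truth = Truth(
        chrom=lesion.chrom,
        pos=lesion.pos,
        ref_allele=lesion.ref_allele,
        alt_allele=lesion.alt_allele,
        gene_symbol=lesion_gene.gene_symbol,
        lesion_type=cfg.lesion_type,
        category=_LESION_CATEGORY[cfg.lesion_type],
        zygosity=cfg.lesion_zygosity,
        allele_ratio=lvar / (lvar + lref),
        n_false_positive_indels=n_fp_emitted,
    )

    scenario = Scenario(
        reference=reference,
        genes=genes,
        targets=targets,
        variants=variants,
        catalogs=catalogs,
        panels=panels,
        map_intervals=map_intervals,
        truth=truth,
        config=cfg,
    )
    if out_dir is not None:
        _write_scenario(scenario, Path(out_dir))
    return scenario


# ---------------------------------------------------------------------------
# depth profiles


def generate_depth_profile(
    cfg: ScenarioConfig,
    uniformity: str = "beta_like",
    mean_depth: float = 30.0,
    n_bases: int | None = None,
    on_target_rate: float = 0.59,
    read_length: int = 100,
    size_parameter: float | None = None,
) -> DepthProfile:
    """Negative-binomial per-base depths over the target space.

    ``alpha_like`` uses a high-dispersion profile, ``beta_like`` a
    rebalanced low-dispersion one (same mean), emulating the direction of
    a probe-rebalancing redesign: more uniform coverage, higher fraction
    of bases at >= 20x. ``size_parameter`` overrides the preset NB size r
    (variance = mean + mean^2/r, so r -> inf approaches uniform depth).
    Deterministic under ``cfg.seed``.
    """
    dispersion = {"alpha_like": 3.0, "beta_like": 15.0}
    if uniformity not in dispersion:
        raise ValueError("uniformity must be 'alpha_like' or 'beta_like'")
    if size_parameter is not None:
        dispersion = {uniformity: float(size_parameter)}
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    if n_bases is None:
        scenario_rng = np.random.default_rng(cfg.seed)
        genome = _random_genome(scenario_rng, cfg)
        genes = _build_genes(scenario_rng, genome, cfg)
        n_bases = TargetSet([e for g in genes for e in g.exons]).total_bases
    r = dispersion[uniformity]
    p = r / (r + mean_depth)
    depths = rng.negative_binomial(r, p, n_bases)
    on_target = int(depths.sum() // read_length)
    total = int(on_target / on_target_rate)
    return DepthProfile(
        depths=depths.astype(np.int64),
        target_set=None,
        total_reads=total,
        on_target_reads=on_target,
    )


# ---------------------------------------------------------------------------
# file emission


def _write_vcf(
    path: Path,
    variants: Sequence[tuple[str, int, str, str] | Variant],
    reference: ReferenceSequence,
    seed: int,
    sample_id: str | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=exomefunnel-synthetic\n")
        fh.write(f"##exomefunnel_seed={seed}\n")
        for chrom in reference.chroms():
            fh.write(f"##contig=<ID={chrom},length={reference.length(chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER"
        if sample_id is not None:
            cols += f"\tINFO\tFORMAT\t{sample_id}"
        else:
            cols += "\tINFO"
        fh.write(cols + "\n")
        for v in variants:
            if isinstance(v, Variant):
                gt = "1/1" if v.ref_reads == 0 else "0/1"
                fh.write(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
                    f"{v.quality:.1f}\tPASS\t.\tGT:AD\t{gt}:{v.ref_reads},{v.var_reads}\n"
                )
            else:
                chrom, pos, ref, alt = v
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def _write_scenario(s: Scenario, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = s.config.seed
    paths = {
        "reference": out_dir / "reference.fa",
        "genes": out_dir / "genes.gff3",
        "targets": out_dir / "targets.bed",
        "sample_vcf": out_dir / "sample.vcf",
        "map_bed": out_dir / "map_interval.bed",
        "truth": out_dir / "truth.json",
        "manifest": out_dir / "manifest.tsv",
    }
    write_fasta(s.reference, paths["reference"])
    write_gene_models(s.genes, paths["genes"])
    write_bed(s.targets.intervals, paths["targets"])
    _write_vcf(paths["sample_vcf"], s.variants, s.reference, seed, s.config.sample_id)
    for name, keys in s.all_catalogs.items():
        p = out_dir / f"{name}.vcf"
        paths[name] = p
        _write_vcf(p, sorted(keys), s.reference, seed)
    if s.map_intervals:
        write_bed(s.map_intervals, paths["map_bed"])
    else:
        paths.pop("map_bed")
    with open(paths["truth"], "w") as fh:
        json.dump({**s.truth.__dict__, "seed": seed}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["manifest"], "w") as fh:
        fh.write("key\tpath\n")
        fh.write(f"seed\t{seed}\n")
        for key, p in paths.items():
            if key != "manifest":
                fh.write(f"{key}\t{p.name}\n")  # relative: manifest sits beside files
    s.paths = {k: str(v) for k, v in paths.items()}
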