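"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's incremental code paths: coding
consequences are derived by rebuilding the *entire* mutant coding
sequence and translating both proteins; interval math by enumerating
position sets; QC metrics by sorting and counting.
"""

from __future__ import annotations

import re

from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate())


def extract_cds(gene, chrom_seq: str, deleted: frozenset = frozenset()) -> str:
    """CDS in coding orientation, optionally skipping deleted genomic positions."""
    bases = []
    for iv in gene.cds:
        for p in range(iv.start, iv.end):
            if p not in deleted:
                bases.append(chrom_seq[p])
    s = "".join(bases)
    return revcomp(s) if gene.strand == "-" else s


def oracle_snv_coding(gene, chrom_seq: str, pos0: int, alt: str):
    """(category, p_ref, p_mut) for a coding SNV by full-CDS rebuild."""
    p_ref = translate(extract_cds(gene, chrom_seq))
    mut_seq = chrom_seq[:pos0] + alt + chrom_seq[pos0 + 1 :]
    p_mut = translate(extract_cds(gene, mut_seq))
    if p_ref == p_mut:
        return "synonymous", p_ref, p_mut
    i = next(k for k in range(len(p_ref)) if p_ref[k] != p_mut[k])
    if p_mut[i] == "*" or p_ref[i] == "*" or (i == 0 and p_ref[i] == "M"):
        return "nonsense", p_ref, p_mut
    return "missense", p_ref, p_mut


def oracle_del_coding(gene, chrom_seq: str, deleted_positions: range):
    """(category, p_ref, p_mut) for a deletion overlapping the CDS."""
    cds_positions = {p for iv in gene.cds for p in range(iv.start, iv.end)}
    in_cds = [p for p in deleted_positions if p in cds_positions]
    dlen = len(deleted_positions)
    p_ref = translate(extract_cds(gene, chrom_seq))
    p_mut = translate(extract_cds(gene, chrom_seq, frozenset(deleted_positions)))
    if dlen % 3 == 0 and len(in_cds) == dlen:
        return "inframe_del", p_ref, p_mut
    return "frameshift", p_ref, p_mut


_SNV_NAME = re.compile(r"^(Stop|[A-Z*])(\d+)(Stop|[A-Z*])$")
_DEL_NAME = re.compile(r"^(Stop|[A-Z])(\d+)(?:_(Stop|[A-Z])(\d+))?del$")


def _aa(token: str) -> str:
    return "*" if token == "Stop" else token


def verify_snv_name(change: str, p_ref: str, p_mut: str) -> bool:
    """Check an SNV protein name structurally against the two proteins."""
    m = _SNV_NAME.match(change)
    if not m:
        return False
    ref_aa, n, alt_aa = _aa(m.group(1)), int(m.group(2)), _aa(m.group(3))
    if not (1 <= n <= len(p_ref)):
        return False
    if p_ref[n - 1] != ref_aa:
        return False
    if p_ref == p_mut:
        return ref_aa == alt_aa
    return p_mut[n - 1] == alt_aa and p_ref[: n - 1] == p_mut[: n - 1]


def verify_del_name(change: str, p_ref: str, p_mut: str) -> bool:
    """Check an in-frame deletion name: removing those codons gives p_mut."""
    m = _DEL_NAME.match(change)
    if not m:
        return False
    first = int(m.group(2))
    last = int(m.group(4)) if m.group(4) else first
    if not (1 <= first <= last <= len(p_ref)):
        return False
    if _aa(m.group(1)) != p_ref[first - 1]:
        return False
    if m.group(3) and _aa(m.group(3)) != p_ref[last - 1]:
        return False
    if last - first + 1 != len(p_ref) - len(p_mut):
        return False
    return p_ref[: first - 1] + p_ref[last:] == p_mut


def oracle_noncoding_category(gene, pos0: int, splice_window=2, near_window=20):
    """Straight-line positional classification ignoring CDS translation."""
    span_lo, span_hi = gene.exons[0].start, gene.exons[-1].end
    if not (span_lo <= pos0 < span_hi):
        return "intergenic"
    for e in gene.exons:
        if e.start <= pos0 < e.end:
            if any(iv.start <= pos0 < iv.end for iv in gene.cds):
                return "cds"
            if any(iv.start <= pos0 < iv.end for iv in gene.utr5):
                return "utr5"
            return "utr3"
    # intronic: distance to the closest exon edge and which edge it is
    best = None
    for e in gene.exons:
        for edge, side in ((e.end - 1, "right"), (e.start, "left")):
            d = pos0 - edge if side == "right" else edge - pos0
            if d > 0 and (best is None or d < best[0]):
                best = (d, side)
    d, side = best
    if d <= splice_window:
        donor = (side == "right") == (gene.strand == "+")
        return "splice_donor" if donor else "splice_acceptor"
    if d <= near_window:
        return "near_splice_20bp"
    return "intronic"


def brute_force_funnel(annotated, cfg, panels):
    """Independent straight-line re-filter: cumulative stage counts + final set."""
    novelty = set(cfg.novelty_catalogs)
    panel_sets = [panels[n] for n in cfg.uniqueness_panels if n in panels]
    ratio_min = cfg.hom_ratio_min if cfg.inheritance == "recessive_homozygous" else cfg.het_ratio_min

    def passes(av, stage):
        if stage == "in_gene":
            return av.consequence.category != "intergenic"
        if stage == "novel":
            return not (set(av.known_in) & novelty)
        if stage == "map_overlap":
            if not cfg.map_intervals:
                return True
            p = av.variant.pos - 1
            return any(
                iv.chrom == av.variant.chrom and iv.start <= p < iv.end
                for iv in cfg.map_intervals
            )
        if stage == "allele_ratio":
            return av.allele_ratio >= ratio_min
        if stage == "damaging":
            return av.consequence.category in cfg.damaging_categories
        if stage == "unique":
            if panel_sets:
                return all(av.variant.key not in s for s in panel_sets)
            return not (set(av.known_in) & set(cfg.uniqueness_panels))
        raise ValueError(stage)

    counts = {}
    kept = list(annotated)
    for stage in cfg.stage_order:
        kept = [av for av in kept if passes(av, stage)]
        counts[stage] = len(kept)
    return counts, {av.variant.key for av in kept}


def sort_and_count_metrics(depths):
    """QC metric panel recomputed by explicit sorting and counting."""
    xs = sorted(int(x) for x in depths)
    n = len(xs)
    mean = sum(xs) / n

    def pct_at_least(t):
        from decimal import Decimal, ROUND_HALF_UP

        c = sum(1 for x in xs if x >= t)
        return float(
            (Decimal(100 * c) / Decimal(n)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )

    # d80: largest depth with >= 80% of bases at or above it
    candidates = sorted(set(xs), reverse=True)
    depth80 = 0
    for d in candidates:
        if sum(1 for x in xs if x >= d) / n >= 0.8:
            depth80 = d
            break
    if n % 2:
        median = float(xs[n // 2])
    else:
        median = (xs[n // 2 - 1] + xs[n // 2]) / 2
    return {
        "pct_covered_1x": pct_at_least(1),
        "pct_covered_5x": pct_at_least(5),
        "pct_covered_10x": pct_at_least(10),
        "pct_covered_20x": pct_at_least(20),
        "bases_covered": sum(1 for x in xs if x >= 1),
        "bases_not_covered": sum(1 for x in xs if x == 0),
        "mean_depth": mean,
        "median_depth": median,
        "nc80": depth80 / mean if mean > 0 else None,
        "inv_nc80": mean / depth80 if depth80 > 0 else None,
    }
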