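import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomefunnel.genome_model import GeneModel, GenomicInterval, ReferenceSequence
from exomefunnel.variant_annotation import (
    Variant,
    allele_ratio,
    classify_consequence,
    left_align,
    mark_known,
    parse_region,
    read_vcf,
    annotate_variants,
)

from oracles import (
    oracle_del_coding,
    oracle_noncoding_category,
    oracle_snv_coding,
    revcomp,
    verify_del_name,
    verify_snv_name,
)

# 20-codon ORF used by the hand-built toy genes; codon 5 is CAA (Q), so a
# C->T at its first base creates a premature TAA stop.
CODING = (
    "ATGGCTGAATTCCAAGGTCATAAACTGTGGTACGTCGATCCAAGA"  # codons 1-15 (exon A)
    "AGCTTTGTGCGATAA"  # codons 16-20 (exon B)
)


def _toy(strand):
    """Two-exon toy gene: exons [20,80)+[140,200), CDS split 45+15 nt."""
    seq = list("ACGT" * 100)
    if strand == "+":
        seq[35:80] = CODING[:45]
        seq[140:155] = CODING[45:]
        utr5, utr3 = [GenomicInterval("chrT", 20, 35)], [GenomicInterval("chrT", 155, 200)]
    else:
        genomic_cds = revcomp(CODING)
        seq[35:80] = genomic_cds[:45]
        seq[140:155] = genomic_cds[45:]
        utr5, utr3 = [GenomicInterval("chrT", 155, 200)], [GenomicInterval("chrT", 20, 35)]
    ref = ReferenceSequence({"chrT": "".join(seq)})
    gene = GeneModel(
        "Toy1", "Toy1-T1", strand,
        exons=[GenomicInterval("chrT", 20, 80), GenomicInterval("chrT", 140, 200)],
        cds=[GenomicInterval("chrT", 35, 80), GenomicInterval("chrT", 140, 155)],
        utr5=utr5, utr3=utr3,
    )
    return gene, ref


def snv(pos0, alt, ref_base="N", **kw):
    kw.setdefault("quality", 50.0)
    kw.setdefault("var_reads", 15)
    kw.setdefault("ref_reads", 15)
    return Variant("chrT", pos0 + 1, ref_base, alt, **kw)


class TestAlleleRatio:
    def test_depressed_heterozygous_indel_ratio(self):
        v = Variant("chr1", 10, "CTTTTT", "C", 50, var_reads=5, ref_reads=20)
        assert allele_ratio(v) == pytest.approx(0.2)

    def test_pure_homozygote_and_ideal_het(self):
        assert allele_ratio(Variant("c", 1, "A", "T", 1, 10, 0)) == 1.0
        assert allele_ratio(Variant("c", 1, "A", "T", 1, 7, 7)) == 0.5

    def test_zero_support_rejected(self):
        with pytest.raises(ValueError):
            Variant("c", 1, "A", "T", 1, 0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(1, 20))
    def test_invariant_under_read_count_scaling(self, var, ref, k):
        if var + ref == 0:
            return
        a = Variant("c", 1, "A", "T", 1, var, ref)
        b = Variant("c", 1, "A", "T", 1, var * k, ref * k)
        assert allele_ratio(a) == pytest.approx(allele_ratio(b))


class TestToyGeneConsequences:
    """Named worked examples on a hand-built two-exon gene, both strands."""

    def test_nonsense_q5stop_plus_strand(self):
        gene, ref = _toy("+")
        c = classify_consequence(snv(47, "T", "C"), [gene], ref)
        assert c.category == "nonsense"
        assert c.protein_change == "Q5Stop"

    def test_nonsense_q5stop_minus_strand(self):
        gene, ref = _toy("-")
        # codon 5 first base sits at genomic 154-12=142; genome carries the
        # complement so the stop-making change is G->A on the forward strand
        c = classify_consequence(snv(142, "A", "G"), [gene], ref)
        assert c.category == "nonsense"
        assert c.protein_change == "Q5Stop"

    def test_missense_and_synonymous(self):
        gene, ref = _toy("+")
        mis = classify_consequence(snv(38, "C", "G"), [gene], ref)
        assert (mis.category, mis.protein_change) == ("missense", "A2P")
        syn = classify_consequence(snv(52, "C", "T"), [gene], ref)
        assert (syn.category, syn.protein_change) == ("synonymous", "G6G")

    @pytest.mark.parametrize(
        "strand,pos0,expected,dist",
        [
            ("+", 80, "splice_donor", 1),
            ("+", 81, "splice_donor", 2),
            ("+", 138, "splice_acceptor", 2),
            ("+", 139, "splice_acceptor", 1),
            ("-", 139, "splice_donor", 1),
            ("-", 80, "splice_acceptor", 1),
            ("+", 95, "near_splice_20bp", 16),
            ("+", 110, "intronic", 30),
        ],
    )
    def test_splice_windows_respect_strand(self, strand, pos0, expected, dist):
        """The conserved sites are the two intronic bases flanking each exon."""
        gene, ref = _toy(strand)
        c = classify_consequence(snv(pos0, "A", ref.fetch("chrT", pos0, pos0 + 1)), [gene], ref)
        if c.category == expected == "splice_donor" or True:
            assert c.category == expected
            assert c.distance_to_exon == dist

    def test_utr_and_intergenic(self):
        gene, ref = _toy("+")
        assert classify_consequence(snv(25, "A", "C"), [gene], ref).category == "utr5"
        assert classify_consequence(snv(160, "A", "C"), [gene], ref).category == "utr3"
        assert classify_consequence(snv(5, "A", "C"), [gene], ref).category == "intergenic"
        assert classify_consequence(snv(250, "A", "C"), [gene], ref).category == "intergenic"

    def test_inframe_deletion_named_by_flanking_codons(self):
        gene, ref = _toy("+")
        # delete codons 7-11 (genomic 53..68); anchor base at 52
        anchor0 = 52
        seq = ref["chrT"]
        v = Variant("chrT", anchor0 + 1, seq[anchor0 : anchor0 + 16], seq[anchor0], 50, 15, 15)
        c = classify_consequence(v, [gene], ref)
        assert c.category == "inframe_del"
        assert c.protein_change == "H7_Y11del"

    def test_frameshift_deletion(self):
        gene, ref = _toy("+")
        seq = ref["chrT"]
        v = Variant("chrT", 53, seq[52:55], seq[52], 50, 15, 15)
        assert classify_consequence(v, [gene], ref).category == "frameshift"


class TestOracleAgreement:
    """Random variants over generated genes vs the full-translation oracle."""

    def test_random_snvs_match_full_translation_oracle(self, small_scenario, rng):
        s = small_scenario
        n_checked = 0
        while n_checked < 150:
            gene = s.genes[rng.integers(0, len(s.genes))]
            chrom_seq = s.reference[gene.chrom]
            span = gene.span
            pos0 = int(rng.integers(span.start - 10, span.end + 10))
            ref_base = chrom_seq[pos0]
            alt = "ACGT"[(("ACGT".index(ref_base)) + 1 + int(rng.integers(0, 3))) % 4]
            v = Variant(gene.chrom, pos0 + 1, ref_base, alt, 50, 15, 15)
            got = classify_consequence(v, [gene], s.reference)
            in_cds = any(iv.start <= pos0 < iv.end for iv in gene.cds)
            if in_cds:
                cat, p_ref, p_mut = oracle_snv_coding(gene, chrom_seq, pos0, alt)
                assert got.category == cat
                assert verify_snv_name(got.protein_change, p_ref, p_mut)
            else:
                assert got.category == oracle_noncoding_category(gene, pos0)
            n_checked += 1

    def test_random_cds_deletions_match_oracle_category(self, small_scenario, rng):
        s = small_scenario
        n_checked = 0
        while n_checked < 60:
            gene = s.genes[rng.integers(0, len(s.genes))]
            host = gene.cds[int(rng.integers(0, len(gene.cds)))]
            dlen = int(rng.choice([1, 2, 3, 4, 6, 9, 15]))
            if len(host) < dlen + 12 or host.start < 1:
                continue
            lo = int(rng.integers(host.start + 9, host.end - dlen - 3))
            chrom_seq = s.reference[gene.chrom]
            v = Variant(
                gene.chrom, lo, chrom_seq[lo - 1 : lo + dlen], chrom_seq[lo - 1], 50, 15, 15
            )
            got = classify_consequence(v, [gene], s.reference)
            cat, _, _ = oracle_del_coding(gene, chrom_seq, range(v.pos, v.pos + dlen))
            assert got.category == cat
            n_checked += 1

    def test_codon_aligned_deletion_names_verified_against_oracle(self, small_scenario, rng):
        """In-frame, codon-aligned deletions carry X<i>_Y<j>del names that
        remove exactly those codons from the reference protein."""
        s = small_scenario
        n_checked = 0
        while n_checked < 40:
            gene = s.genes[rng.integers(0, len(s.genes))]
            chrom_seq = s.reference[gene.chrom]
            # genomic CDS positions in coding order, independent of the package
            positions = [p for iv in gene.cds for p in range(iv.start, iv.end)]
            if gene.strand == "-":
                positions = positions[::-1]
            dlen = int(rng.choice([3, 6, 15]))
            off = int(rng.integers(1, (len(positions) - dlen) // 3 - 1)) * 3
            window = positions[off : off + dlen]
            lo, hi = min(window), max(window)
            if hi - lo != dlen - 1 or lo < 1:
                continue
            if chrom_seq[lo - 1] == chrom_seq[hi]:
                continue  # would left-shift, breaking codon alignment
            v = Variant(gene.chrom, lo, chrom_seq[lo - 1 : hi + 1], chrom_seq[lo - 1], 50, 15, 15)
            got = classify_consequence(v, [gene], s.reference)
            cat, p_ref, p_mut = oracle_del_coding(gene, chrom_seq, range(lo, hi + 1))
            assert got.category == cat == "inframe_del"
            assert verify_del_name(got.protein_change, p_ref, p_mut)
            n_checked += 1


class TestVcfIngest:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=1000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tm1\n"
    )

    def write(self, tmp_path, body):
        p = tmp_path / "x.vcf"
        p.write_text(self.HEADER + body)
        return p

    def test_ad_fields_and_indel_kinds(self, tmp_path):
        p = self.write(
            tmp_path,
            "chr1\t10\t.\tA\tG\t60\tPASS\t.\tGT:AD\t0/1:10,10\n"
            "chr1\t20\t.\tCTTTTT\tC\t60\tPASS\t.\tGT:AD\t0/1:20,5\n",
        )
        vs = read_vcf(p, "m1")
        assert vs[0].var_reads == 10 and vs[0].ref_reads == 10 and vs[0].kind == "SNV"
        assert vs[1].kind == "DEL"
        assert len(vs[1].ref_allele) - len(vs[1].alt_allele) == 5
        assert allele_ratio(vs[1]) == pytest.approx(0.2)

    def test_multiallelic_records_split_per_alt(self, tmp_path):
        p = self.write(
            tmp_path,
            "chr1\t10\t.\tA\tC,T\t60\tPASS\t.\tGT:AD\t1/2:10,6,4\n"
            "chr1\t30\t.\tG\tGA\t60\tPASS\t.\tGT:AD\t0/1:12,9\n",
        )
        vs = read_vcf(p, "m1")
        assert len(vs) == 3
        assert (vs[0].alt_allele, vs[0].var_reads) == ("C", 6)
        assert (vs[1].alt_allele, vs[1].var_reads) == ("T", 4)
        assert vs[2].kind == "INS"

    def test_missing_read_support_raises(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t10\t.\tA\tG\t60\tPASS\t.\n"
        )
        with pytest.raises(ValueError, match="chr1:10"):
            read_vcf(p)


class TestNormalizationAndCatalogs:
    def test_left_align_shifts_through_homopolymer(self):
        ref = ReferenceSequence({"c": "GGATTTTTCAA"})
        v = Variant("c", 7, "TT", "T", 50, 10, 10)  # right-anchored form
        n = left_align(v, ref)
        assert (n.pos, n.ref_allele, n.alt_allele) == (3, "AT", "A")

    def test_snv_untouched_by_left_align(self):
        ref = ReferenceSequence({"c": "GGATTTTTCAA"})
        v = Variant("c", 5, "T", "G", 50, 10, 10)
        assert left_align(v, ref) is v

    def test_known_matching_is_allele_aware(self):
        gene_ref = ReferenceSequence({"c": "A" * 100})
        av = annotate_variants(
            [Variant("c", 10, "A", "T", 50, 10, 10)], [], gene_ref,
            catalogs={"dbSNP": {("c", 10, "A", "G")}, "panel": {("c", 10, "A", "T")}},
        )[0]
        assert av.known_in == ["panel"]

    def test_parse_region_forms(self):
        ref = ReferenceSequence({"chr2": "A" * 500})
        iv = parse_region("chr2:101-200", ref)
        assert (iv.start, iv.end) == (100, 200)
        whole = parse_region("chr2", ref)
        assert (whole.start, whole.end) == (0, 500)
        with pytest.raises(ValueError):
            parse_region("chr2")
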