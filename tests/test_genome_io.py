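"""Genome containers, readers, sequence extraction, and gene-order comparison."""

import random

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitocomp.genome_io import (
    ALPHA,
    ANCESTRAL_INSECT_ORDER,
    BETA,
    LEPIDOPTERA_ORDER,
    NEUROPTERA_ORDER,
    AnnotatedGenome,
    AnnotationError,
    GeneFeature,
    canonical_name,
    compare_gene_orders,
    extract_gene_sequence,
    gene_order_signature,
    read_feature_table,
    read_genbank,
    write_feature_table,
)


@pytest.mark.parametrize("label,expected", [
    ("ND4L", "nad4L"),
    ("COI", "cox1"),
    ("cox1", "cox1"),
    ("16S rRNA", "rrnL"),
    ("tRNA-Leu(UUR)", "trnL2"),
    ("tRNA-Ser (AGN)", "trnS1"),
    ("A+T-rich region", "control_region"),
    ("cytochrome b", "cob"),
])
def test_canonical_name_synonyms(label, expected):
    assert canonical_name(label) == expected


def test_unknown_label_is_an_error_with_the_offending_label():
    with pytest.raises(AnnotationError, match="mystery"):
        canonical_name("mystery gene 7")


def test_duplicate_feature_names_rejected():
    feats = [GeneFeature("cox1", 1, 30, ALPHA), GeneFeature("cox1", 40, 60, ALPHA)]
    with pytest.raises(AnnotationError, match="duplicate"):
        AnnotatedGenome("x", "A" * 100, True, feats)


def test_read_genbank_minimal_record(tmp_path):
    rec = SeqRecord(Seq("ATGAAATTTCCCGGGTAA" + "ACGT" * 20), id="T1", name="T1",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    rec.features = [
        SeqFeature(SimpleLocation(0, 18, strand=1), type="CDS",
                   qualifiers={"gene": ["ND4L"]}),
        SeqFeature(SimpleLocation(20, 86, strand=-1), type="tRNA",
                   qualifiers={"product": ["tRNA-Leu(UUR)"]}),
    ]
    path = tmp_path / "t.gb"
    SeqIO.write(rec, str(path), "genbank")
    g = read_genbank(path)
    assert len(g) == 98
    assert g.feature("nad4L") == GeneFeature("nad4L", 1, 18, ALPHA, "PCG")
    assert g.feature("trnL2").strand == BETA


def test_feature_table_round_trip(tmp_path, genome7):
    write_feature_table(genome7, tmp_path / "g.fa", tmp_path / "g.tsv")
    back = read_feature_table(tmp_path / "g.fa", tmp_path / "g.tsv")
    assert back.sequence == genome7.sequence
    assert sorted(back.features, key=lambda f: f.start) == sorted(
        genome7.features, key=lambda f: f.start)


def test_feature_table_plus_minus_strands(tmp_path):
    (tmp_path / "g.fa").write_text(">g\n" + "ACGT" * 30 + "\n")
    (tmp_path / "g.tsv").write_text(
        "name\tstart\tend\tstrand\tcategory\n"
        "cox1\t1\t30\t+\tPCG\n"
        "trnV\t31\t60\t-\ttRNA\n")
    g = read_feature_table(tmp_path / "g.fa", tmp_path / "g.tsv")
    assert g.feature("cox1").strand == ALPHA
    assert g.feature("trnV").strand == BETA


def test_empty_feature_table_warns_not_raises(tmp_path, caplog):
    (tmp_path / "g.fa").write_text(">g\nACGTACGT\n")
    (tmp_path / "g.tsv").write_text("name\tstart\tend\tstrand\tcategory\n")
    with caplog.at_level("WARNING"):
        g = read_feature_table(tmp_path / "g.fa", tmp_path / "g.tsv")
    assert g.features == []
    assert "empty" in caplog.text


class TestExtractGeneSequence:
    def test_alpha_slice(self):
        g = AnnotatedGenome("x", "ATGAAACCC", True, [GeneFeature("cox1", 1, 6, ALPHA)])
        assert extract_gene_sequence(g, "cox1") == "ATGAAA"

    def test_beta_reverse_complement(self):
        g = AnnotatedGenome("x", "ATGAAACCC", True, [GeneFeature("cox1", 1, 6, BETA)])
        assert extract_gene_sequence(g, "cox1") == "TTTCAT"

    def test_wraparound_concatenates_across_origin(self):
        seq = "AAAATTTTGGGGCCCCAGCT"  # 20 bp toy circle
        g = AnnotatedGenome("x", seq, True, [GeneFeature("cox1", 17, 4, ALPHA)])
        assert extract_gene_sequence(g, "cox1") == seq[16:] + seq[:4]

    def test_beta_matches_character_oracle_on_random_toys(self):
        rng = random.Random(1)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(25):
            seq = "".join(rng.choice("ACGT") for _ in range(50))
            a, b = sorted(rng.sample(range(1, 51), 2))
            g = AnnotatedGenome("x", seq, True, [GeneFeature("cox1", a, b, BETA)])
            oracle = "".join(comp[c] for c in reversed(seq[a - 1 : b]))
            assert extract_gene_sequence(g, "cox1") == oracle

    def test_unknown_gene(self, genome7):
        with pytest.raises(KeyError):
            extract_gene_sequence(genome7, "nad7")


class TestGeneOrder:
    def test_builtin_orders_are_permutations_of_37(self):
        for sig in (ANCESTRAL_INSECT_ORDER, NEUROPTERA_ORDER, LEPIDOPTERA_ORDER):
            assert len(set(sig.genes())) == 37

    def test_ancestral_has_trnW_before_trnC(self):
        genes = ANCESTRAL_INSECT_ORDER.genes()
        assert genes.index("trnW") + 1 == genes.index("trnC")

    def test_neuroptera_has_trnC_immediately_before_trnW(self, neuroptera_genome):
        sig = gene_order_signature(neuroptera_genome)
        genes = sig.genes()
        assert genes.index("trnC") + 1 == genes.index("trnW")

    def test_signature_invariant_under_rotation(self, genome7):
        from mitocomp.genome_io import slice_circular

        # rotate the circular coordinate system by 5000 positions
        L = len(genome7)
        shift = 5000
        seq = slice_circular(genome7.sequence, shift + 1, shift)
        feats = []
        for f in genome7.features:
            s = (f.start - shift - 1) % L + 1
            e = (f.end - shift - 1) % L + 1
            feats.append(GeneFeature(f.name, s, e, f.strand))
        rotated = AnnotatedGenome("rot", seq, True, feats)
        assert gene_order_signature(rotated) == gene_order_signature(genome7)

    def test_identical_signatures_have_no_differences(self):
        rep = compare_gene_orders(ANCESTRAL_INSECT_ORDER, ANCESTRAL_INSECT_ORDER)
        assert rep.breakpoints == 0
        assert rep.repositioned == ()
        assert rep.strand_changes == ()

    def test_trnC_translocation_detected_with_explicit_adjacency_count(self):
        rep = compare_gene_orders(NEUROPTERA_ORDER, ANCESTRAL_INSECT_ORDER)
        assert rep.repositioned == ("trnC",)
        # brute-force adjacency sets: moving one gene breaks 3 adjacencies
        a, b = NEUROPTERA_ORDER.genes(), ANCESTRAL_INSECT_ORDER.genes()
        adj = lambda g: {(g[i], g[(i + 1) % len(g)]) for i in range(len(g))}
        assert rep.breakpoints == len(adj(a) - adj(b)) == 3

    def test_lepidopteran_trnM_translocation_detected(self):
        rep = compare_gene_orders(LEPIDOPTERA_ORDER, ANCESTRAL_INSECT_ORDER)
        assert rep.repositioned == ("trnM",)

    def test_disjoint_orders_raise(self):
        from mitocomp.genome_io import GeneOrderSignature
        s1 = GeneOrderSignature((("cox1", ALPHA), ("cox2", ALPHA)))
        s2 = GeneOrderSignature((("nad1", BETA), ("nad2", ALPHA)))
        with pytest.raises(ValueError):
            compare_gene_orders(s1, s2)
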