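"""Start/stop inference, feature accounting, and spacer detection."""

import pytest

from mitocomp.annotate import (
    feature_account,
    find_spacers,
    infer_start,
    infer_stop,
    render_stop,
    startstop_report,
)
from mitocomp.genome_io import ALPHA, BETA, AnnotatedGenome, GeneFeature


def toy(seq, feats):
    return AnnotatedGenome("toy", seq, True, feats)


class TestInferStart:
    def test_first_legitimate_start_after_upstream_gene(self):
        # upstream gene ends at 2; ATT at position 3 is the first ATN in frame
        seq = "CCATTATGAAATTTTAAGGG" + "A" * 40
        g = toy(seq, [
            GeneFeature("trnI", 1, 2, ALPHA),
            GeneFeature("cox1", 3, 18, ALPHA),
        ])
        call = infer_start(g, "cox1", rough_start=3, search_window=12)
        assert (call.position, call.codon, call.canonical) == (3, "ATT", True)

    def test_exact_gtg_start_is_canonical(self):
        seq = "GTGAAATTTTAA" + "C" * 48
        g = toy(seq, [GeneFeature("cox1", 1, 12, ALPHA),
                      GeneFeature("trnV", 41, 58, ALPHA)])
        call = infer_start(g, "cox1", rough_start=1, search_window=9)
        assert (call.codon, call.canonical) == ("GTG", True)

    def test_non_canonical_start_retained_and_flagged(self):
        # ACG start; upstream codons are sanitized non-starts (middle C)
        seq = "CCCCCCACGAAATTTTAA" + "G" * 42
        g = toy(seq, [GeneFeature("trnI", 1, 3, ALPHA),
                      GeneFeature("cox1", 7, 18, ALPHA)])
        call = infer_start(g, "cox1", rough_start=7, search_window=9)
        assert (call.codon, call.canonical) == ("ACG", False)

    def test_window_larger_than_genome_rejected(self):
        g = toy("ATGTAA" + "C" * 24, [GeneFeature("cox1", 1, 6, ALPHA)])
        with pytest.raises(ValueError, match="window"):
            infer_start(g, "cox1", rough_start=1, search_window=100)


class TestInferStop:
    def test_full_stop(self):
        seq = "ATGAAATAA" + "C" * 51
        g = toy(seq, [GeneFeature("cox1", 1, 9, ALPHA)])
        call = infer_stop(g, "cox1")
        assert (call.end, call.codon, call.truncated) == (9, "TAA", False)

    def test_truncated_stop_abutting_downstream_gene(self):
        # 2 in-frame nt (TA) before the downstream gene, no earlier stop
        seq = "ATGAAATTTTA" + "GGGCCCGGGCCC" + "C" * 37
        g = toy(seq, [GeneFeature("cox1", 1, 11, ALPHA),
                      GeneFeature("trnG", 12, 23, ALPHA)])
        call = infer_stop(g, "cox1")
        assert (call.end, call.codon, call.truncated) == (11, "TA", True)

    def test_stop_exactly_at_downstream_boundary_kept_complete(self):
        seq = "ATGAAATAA" + "GGGCCC" + "C" * 45
        g = toy(seq, [GeneFeature("cox1", 1, 9, ALPHA),
                      GeneFeature("trnG", 10, 15, ALPHA)])
        call = infer_stop(g, "cox1")
        assert (call.end, call.codon, call.truncated) == (9, "TAA", False)

    def test_no_stop_no_downstream_gene_raises(self):
        g = toy("ATG" + "AAA" * 19, [GeneFeature("cox1", 1, 60, ALPHA)])
        with pytest.raises(ValueError, match="no stop"):
            infer_stop(g, "cox1")

    def test_never_reaches_into_downstream_gene(self, genome7):
        """Truncation guarantee on every synthetic PCG."""
        for f in genome7.gene_features():
            if f.category != "PCG":
                continue
            call = infer_stop(genome7, f.name)
            expected_end = f.end if f.strand == ALPHA else f.start
            assert call.end == expected_end

    def test_start_inference_idempotent_on_refined_annotation(self, genome7):
        for f in genome7.gene_features():
            if f.category != "PCG":
                continue
            anchor = f.start if f.strand == ALPHA else f.end
            call = infer_start(genome7, f.name, rough_start=anchor)
            assert call.position == anchor and call.canonical


class TestFeatureAccount:
    def test_adjacent_features_have_zero_inc(self):
        g = toy("A" * 30, [GeneFeature("trnI", 1, 10, ALPHA),
                           GeneFeature("trnQ", 11, 20, BETA)])
        acct = feature_account(g)
        assert acct.loc[acct.name == "trnI", "inc"].item() == 0

    def test_overlap_yields_negative_inc(self):
        g = toy("A" * 30, [GeneFeature("trnI", 1, 10, ALPHA),
                           GeneFeature("trnQ", 8, 20, BETA)])
        acct = feature_account(g)
        assert acct.loc[acct.name == "trnI", "inc"].item() == -3

    def test_truncated_stop_rendering(self):
        assert render_stop("TAA") == "TAA"
        assert render_stop("TA") == "TAa"
        assert render_stop("T") == "Taa"

    def test_account_reports_truncated_stop_of_generated_gene(self):
        from mitocomp.synthetic import GenomeSpec, generate_genome
        g = generate_genome(GenomeSpec(seed=11, truncated_stops={"cox2": "TA"}))
        acct = feature_account(g)
        assert acct.loc[acct.name == "cox2", "scd"].item() == "TAa"

    def test_empty_genome_yields_empty_account(self):
        assert feature_account(toy("ACGT", [])).empty

    def test_coverage_conservation(self, genome7):
        """Σ sizes + Σ ncp lengths − Σ overlaps = genome length."""
        L = len(genome7)
        acct = feature_account(genome7)
        gene_sizes = acct.loc[acct.name != "control_region", "size"].sum()
        ncps = find_spacers(genome7).ncps
        overlaps = -acct.loc[acct.inc < 0, "inc"].sum()
        assert gene_sizes + sum(p.length for p in ncps) - overlaps == L


class TestSpacers:
    def test_fully_covered_toy_has_no_ncps(self):
        g = toy("A" * 20, [GeneFeature("trnI", 1, 10, ALPHA),
                           GeneFeature("trnQ", 11, 20, BETA)])
        assert find_spacers(g).ncps == ()

    def test_single_gap_labeled_s1(self):
        g = toy("A" * 50, [GeneFeature("trnI", 1, 10, ALPHA),
                           GeneFeature("trnQ", 31, 50, BETA)])
        sp = find_spacers(g)
        assert len(sp.ncps) == 1
        p = sp.ncps[0]
        assert (p.start, p.end, p.length, p.label) == (11, 30, 20, "s1")

    def test_short_gap_not_labeled(self):
        g = toy("A" * 50, [GeneFeature("trnI", 1, 10, ALPHA),
                           GeneFeature("trnQ", 21, 50, BETA)])
        sp = find_spacers(g)
        assert len(sp.ncps) == 1 and sp.ncps[0].label == ""

    def test_synthetic_genome_spacers_in_genome_order(self, genome7):
        sp = find_spacers(genome7)
        labels = [(p.label, p.length) for p in sp.spacers]
        assert labels == [("s1", 55), ("s2", 20), ("s3", 1049)]


def test_startstop_report_all_atg_starts(genome7):
    df = startstop_report([genome7])
    st_cols = [c for c in df.columns if c.endswith("_ST")]
    assert len(st_cols) == 13
    assert all(df[c].item() == "ATG" for c in st_cols)
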