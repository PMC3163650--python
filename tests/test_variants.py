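"""Variant discovery, coordinates, tallies, clusters, coding consequences."""

import numpy as np
import pandas as pd
import pytest

from divergene import ctsb_gene_model, ctsb_variant_table, synth
from divergene.variants import (GeneModel, annotate, cluster_scan,
                                coding_consequence, diff_alleles,
                                tally_variants)


class TestDiffAlleles:
    def test_single_snp(self):
        df = diff_alleles("ACGTACGT", "ACGAACGT", anchor=1)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["type"], row.rel_position, row.HAB, row.LAB) == \
            ("SNP", 4, "T", "A")

    def test_anchor_offsets_positions(self):
        df = diff_alleles("ACGTACGT", "ACGAACGT", anchor=101)
        assert df.rel_position[0] == 104

    def test_insertion_anchored_at_preceding_base(self):
        # LAB has extra TT after HAB position 3
        df = diff_alleles("ACGATC", "ACGTTATC")
        assert len(df) == 1
        row = df.iloc[0]
        assert row["type"] == "insertion"
        assert row.rel_position == 3
        assert row.HAB == "-" and row.LAB == "TT"

    def test_deletion_single_event_for_gap_run(self):
        df = diff_alleles("ACGTTATC", "ACGATC")
        assert len(df) == 1
        row = df.iloc[0]
        assert row["type"] == "deletion"
        assert row.rel_position == 3
        assert row.HAB == "TT" and row.LAB == "-"

    def test_n_columns_skipped(self):
        df = diff_alleles("ACNTA", "ACGTA")
        assert len(df) == 0

    def test_identical_sequences(self):
        assert len(diff_alleles("ACGTACGT", "ACGTACGT")) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            diff_alleles("", "ACGT")
        with pytest.raises(ValueError):
            diff_alleles("ACGU", "ACGT")

    def test_roundtrip_with_generator(self):
        planted = pd.DataFrame({
            "type": ["SNP", "insertion", "SNP", "deletion", "SNP"],
            "rel_position": [40, 120, 260, 410, 700],
            "HAB": ["A", "-", "G", "CA", "T"],
            "LAB": ["G", "TG", "T", "-", "C"],
        })
        hab, lab, hab_pos = synth.make_allele_pair(planted, length=800, seed=6)
        found = diff_alleles(hab, lab)
        assert len(found) == 5
        assert list(found["type"]) == list(planted["type"])
        # positions come back in the HAB (reference) frame
        np.testing.assert_array_equal(found.rel_position, hab_pos)
        ins = found[found["type"] == "insertion"].iloc[0]
        assert ins.LAB == "TG"
        dele = found[found["type"] == "deletion"].iloc[0]
        assert dele.HAB == "CA"


class TestGeneModelCoordinates:
    def test_spans(self, toy_model):
        assert toy_model.promoter_span == (-500, -1)
        assert toy_model.gene_end == 300
        assert toy_model.der_span == (301, 600)
        assert toy_model.intron_span(1) == (101, 200)
        assert toy_model.span_of("exon-2") == (201, 300)

    def test_rel_genomic_roundtrip_no_zero(self, toy_model):
        assert toy_model.rel_to_genomic(1) == 1000
        assert toy_model.rel_to_genomic(-1) == 999
        assert toy_model.genomic_to_rel(1000) == 1
        assert toy_model.genomic_to_rel(999) == -1
        for rel in (-500, -1, 1, 42, 150, 300, 600):
            assert toy_model.genomic_to_rel(toy_model.rel_to_genomic(rel)) == rel
        with pytest.raises(ValueError):
            toy_model.rel_to_genomic(0)

    def test_minus_strand(self):
        m = GeneModel(name="m", chromosome="1", strand="-", tss_genomic=5000,
                      exons=[(1, 50)])
        assert m.rel_to_genomic(1) == 5000
        assert m.rel_to_genomic(10) == 4991
        assert m.rel_to_genomic(-3) == 5003
        assert m.genomic_to_rel(4991) == 10

    def test_mrna_position_skips_intron(self, toy_model):
        assert toy_model.mrna_position(1) == 1
        assert toy_model.mrna_position(100) == 100
        assert toy_model.mrna_position(150) is None
        assert toy_model.mrna_position(201) == 101
        assert toy_model.mrna_length == 200

    def test_region_of_with_utrs(self, toy_model):
        # CDS mRNA 11..190: first 10 mRNA bases are 5'UTR, last 10 3'UTR
        assert toy_model.region_of(-10) == "promoter"
        assert toy_model.region_of(5) == "5'UTR"
        assert toy_model.region_of(11) == "exon-1"
        assert toy_model.region_of(150) == "intron-1"
        assert toy_model.region_of(250) == "exon-2"
        assert toy_model.region_of(295) == "3'UTR"
        assert toy_model.region_of(400) == "DER"
        assert toy_model.region_of(-501) == "flanking"
        assert toy_model.region_of(601) == "flanking"

    def test_model_validation(self):
        with pytest.raises(ValueError):
            GeneModel(name="x", chromosome="1", strand="?", exons=[(1, 10)])
        with pytest.raises(ValueError):
            GeneModel(name="x", chromosome="1", exons=[(1, 10), (5, 20)])
        with pytest.raises(ValueError):
            GeneModel(name="x", chromosome="1", exons=[(2, 10)])

    def test_yaml_roundtrip(self, toy_model, tmp_path):
        p = tmp_path / "m.yaml"
        toy_model.to_yaml(p)
        back = GeneModel.from_yaml(p)
        assert back == toy_model


class TestAnnotate:
    def test_fills_all_columns(self, toy_model):
        df = pd.DataFrame({"type": ["SNP", "SNP"], "rel_position": [-10, 250],
                           "HAB": ["A", "C"], "LAB": ["G", "T"]})
        out = annotate(df, toy_model)
        assert list(out.location) == ["promoter", "exon-2"]
        assert list(out.genomic_position) == [990, 1249]
        assert pd.isna(out.mrna_position[0]) and out.mrna_position[1] == 150

    def test_from_genomic(self, toy_model):
        df = pd.DataFrame({"type": ["SNP"], "genomic_position": [1249],
                           "HAB": ["C"], "LAB": ["T"]})
        out = annotate(df, toy_model)
        assert out.rel_position[0] == 250

    def test_idempotent_and_order_invariant(self, toy_model):
        df = pd.DataFrame({"type": ["SNP"] * 3,
                           "rel_position": [250, -10, 400],
                           "HAB": list("ACG"), "LAB": list("GTA")})
        once = annotate(df, toy_model)
        pd.testing.assert_frame_equal(annotate(once, toy_model), once)
        shuffled = annotate(df.iloc[::-1].reset_index(drop=True), toy_model)
        merged = once.set_index("rel_position")
        for _, r in shuffled.iterrows():
            assert merged.loc[r.rel_position, "location"] == r.location


class TestTallyAndScan:
    def test_tally_margins(self):
        df = pd.DataFrame({
            "type": ["SNP", "SNP", "insertion", "deletion"],
            "location": ["promoter", "intron-1", "promoter", "DER"],
        })
        tab = tally_variants(df)
        assert tab.loc["total", "total"] == 4
        assert tab.loc["SNP", "total"] == 2
        assert tab.loc["total", "promoter"] == 2

    def test_cluster_scan_hand_example(self):
        df = pd.DataFrame({"rel_position": [10, 15, 18, 50, 52, 54, 56, 200]})
        best = cluster_scan(df, window_bp=10)
        assert best["count"].iloc[0] == 4
        assert best.start.iloc[0] == 50 and best.end.iloc[0] == 59

    def test_window_is_half_open(self):
        df = pd.DataFrame({"rel_position": [1, 10]})
        assert cluster_scan(df, 10)["count"].iloc[0] == 2
        assert cluster_scan(df, 9)["count"].iloc[0] == 1

    def test_monotone_in_window(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"rel_position": rng.integers(1, 2000, 80)})
        prev = 0
        for w in (10, 50, 100, 500):
            c = cluster_scan(df, w)["count"].iloc[0]
            assert c >= prev
            prev = c

    def test_region_filter(self):
        df = pd.DataFrame({
            "rel_position": [10, 12, 14, 310, 312],
            "location": ["intron-1", "intron-1", "5'UTR", "DER", "DER"],
        })
        assert cluster_scan(df, 20, "introns")["count"].iloc[0] == 2
        assert cluster_scan(df, 20, "exons")["count"].iloc[0] == 1
        assert cluster_scan(df, 20, "DER")["count"].iloc[0] == 2
        assert len(cluster_scan(df, 20, "promoter")) == 0

    def test_scan_validation(self):
        df = pd.DataFrame({"rel_position": [1]})
        with pytest.raises(ValueError):
            cluster_scan(df, 0)
        with pytest.raises(ValueError):
            cluster_scan(df, 10, "introns")  # no location column


class TestCodingConsequence:
    # toy CDS: ATG then (TCT GAA GGC) repeating: codon 2 = TCT (Ser),
    # codon 3 = GAA (Glu).  CDS occupies mRNA 11..190.
    def snp(self, rel, hab, lab):
        return {"type": "SNP", "rel_position": rel, "HAB": hab, "LAB": lab}

    def test_missense(self, toy_model):
        # mRNA 14 = CDS offset 4 -> codon 2 pos 1: TCT -> CCT, Ser -> Pro
        out = coding_consequence(self.snp(14, "T", "C"), toy_model)
        assert out == "missense Ser->Pro"

    def test_synonymous(self, toy_model):
        # mRNA 19 = CDS offset 9 -> codon 4 wobble: GAA -> GAG, both Glu
        out = coding_consequence(self.snp(19, "A", "G"), toy_model)
        assert out == "synonymous (Glu)"

    def test_missense_first_base(self, toy_model):
        # codon GAA -> AAA: Glu -> Lys at its first base (mRNA 17)
        out = coding_consequence(self.snp(17, "G", "A"), toy_model)
        assert out == "missense Glu->Lys"

    def test_utr_is_non_coding(self, toy_model):
        assert coding_consequence(self.snp(5, "A", "G"), toy_model) == "non-coding"
        assert coding_consequence(self.snp(150, "A", "G"), toy_model) == "non-coding"

    def test_cds_indel_frame_affecting(self, toy_model):
        v = {"type": "deletion", "rel_position": 20, "HAB": "AA", "LAB": "-"}
        assert coding_consequence(v, toy_model) == "frame-affecting"

    def test_allele_mismatch_rejected(self, toy_model):
        with pytest.raises(ValueError, match="neither allele"):
            coding_consequence(self.snp(14, "G", "C"), toy_model)

    def test_missing_cds_rejected(self):
        m = GeneModel(name="x", chromosome="1", exons=[(1, 30)])
        with pytest.raises(ValueError, match="CDS"):
            coding_consequence(self.snp(5, "A", "G"), m)


class TestCtsbFixture:
    """The packaged synthetic Ctsb catalogue must be self-consistent."""

    def test_totals(self):
        tab = tally_variants(ctsb_variant_table())
        assert tab.loc["SNP", "total"] == 76
        assert tab.loc["insertion", "total"] == 8
        assert tab.loc["deletion", "total"] == 9
        assert tab.loc["total", "total"] == 93

    def test_annotation_consistency(self):
        df = ctsb_variant_table()
        model = ctsb_gene_model()
        re_annot = annotate(df.drop(columns=["location", "mrna_position"]),
                            model)
        assert list(re_annot.location) == list(df.location)
        np.testing.assert_array_equal(
            re_annot.genomic_position, df.genomic_position)

    def test_positions_unique(self):
        assert ctsb_variant_table()["rel_position"].is_unique
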