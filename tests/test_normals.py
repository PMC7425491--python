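"""Normal-junction DB, reference proteome extraction, normal-peptide index."""

import pandas as pd
import pytest

from spliceneo.genome import GenomeSequence
from spliceneo.models import TranscriptModel
from spliceneo.normals import (
    JunctionKey,
    NormalJunctionDB,
    build_normal_junction_db,
    build_normal_peptide_index,
    extract_reference_proteome,
)


def _panel(rows, n_samples=100):
    recs = []
    for (chrom, strand, s, e), counts in rows:
        padded = list(counts) + [0] * (n_samples - len(counts))
        recs.append([chrom, strand, s, e] + padded)
    cols = ["chrom", "strand", "intron_start", "intron_end"] + [
        f"N{i}" for i in range(n_samples)
    ]
    return pd.DataFrame(recs, columns=cols)


MODEL = TranscriptModel(
    "T1", "G1", "chr1", "+", ((0, 10), (20, 30), (40, 50)), 0, 50
)


class TestNormalJunctionDB:
    def test_one_qualifying_sample_meets_the_one_percent_ceiling(self):
        # ceil(0.01 * 100) = 1: a junction with >=2 reads in exactly one
        # sample is already "normal"
        panel = _panel([(("chr1", "+", 100, 200), [2])])
        db = build_normal_junction_db(panel, [MODEL])
        assert JunctionKey("chr1", "+", 100, 200) in db

    def test_below_min_reads_everywhere_is_excluded(self):
        panel = _panel([(("chr1", "+", 100, 200), [1] * 100)])
        db = build_normal_junction_db(panel, [MODEL])
        assert JunctionKey("chr1", "+", 100, 200) not in db

    def test_annotation_junctions_always_included(self):
        db = build_normal_junction_db(_panel([]), [MODEL])
        assert JunctionKey("chr1", "+", 10, 20) in db
        assert JunctionKey("chr1", "+", 30, 40) in db
        assert db.provenance(JunctionKey("chr1", "+", 10, 20)) == {"annotation"}

    def test_empty_panel_warns_and_keeps_annotation(self, caplog):
        with caplog.at_level("WARNING"):
            db = build_normal_junction_db(None, [MODEL])
        assert len(db) == 2 and "annotation" in caplog.text.lower() or "panel" in caplog.text

    def test_adding_samples_never_removes_keys(self):
        base_rows = [(("chr1", "+", 100, 200), [2] * 5)]
        small = build_normal_junction_db(_panel(base_rows, 50), [MODEL])
        # grow the panel: same junction counts plus extra all-zero samples
        # and a second qualifying junction
        grown = build_normal_junction_db(
            _panel(base_rows + [(("chr1", "+", 300, 400), [3] * 50)], 100), [MODEL]
        )
        assert set(small.keys()) <= set(grown.keys())

    def test_strand_unknown_query_matches_either_strand(self):
        db = NormalJunctionDB()
        db.add(JunctionKey("chr1", "-", 5, 9), "panel")
        assert JunctionKey("chr1", ".", 5, 9) in db
        assert JunctionKey("chr1", "+", 5, 9) not in db

    def test_tsv_round_trip(self, tmp_path):
        db = build_normal_junction_db(
            _panel([(("chr1", "+", 100, 200), [2] * 10)]), [MODEL]
        )
        p = tmp_path / "db.tsv"
        db.write_tsv(p)
        back = NormalJunctionDB.read_tsv(p)
        assert back.keys() == db.keys()
        for k in db.keys():
            assert back.provenance(k) == db.provenance(k)


class TestReferenceProteome:
    def test_toy_cds_translates_to_mk(self):
        genome = GenomeSequence.from_dict({"chr1": "ATGAAATAG" + "C" * 10})
        model = TranscriptModel("T", "G", "chr1", "+", ((0, 19),), 0, 9)
        assert extract_reference_proteome([model], genome) == [("T", "MK")]

    def test_minus_strand_two_exon_cds_matches_hand_translation(self):
        # forward genome "CTAT" + intron "GG" + "TTCAT"; on '-' the
        # transcript reads revcomp("TTCAT") + revcomp("CTAT") =
        # ATGAA + ATAG = ATGAAATAG -> "MK"
        genome = GenomeSequence.from_dict({"chr1": "CTATGGTTCAT"})
        model = TranscriptModel(
            "T", "G", "chr1", "-", ((0, 4), (6, 11)), 0, 11
        )
        assert extract_reference_proteome([model], genome) == [("T", "MK")]

    def test_internal_stop_truncates(self):
        genome = GenomeSequence.from_dict({"chr1": "ATGAAATAGAAAGGG"})
        model = TranscriptModel("T", "G", "chr1", "+", ((0, 15),), 0, 15)
        assert extract_reference_proteome([model], genome) == [("T", "MK")]

    def test_cds_not_multiple_of_three_warns_and_translates_floor(self, caplog):
        genome = GenomeSequence.from_dict({"chr1": "ATGAAAGGGC"})
        model = TranscriptModel("T", "G", "chr1", "+", ((0, 10),), 0, 10)
        with caplog.at_level("WARNING"):
            out = extract_reference_proteome([model], genome)
        assert out == [("T", "MKG")]
        assert "divisible by 3" in caplog.text

    def test_agrees_with_naive_string_translator(self, fixture_dir, manifest):
        from spliceneo.models import load_annotation
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        table = unambiguous_dna_by_id[1].forward_table
        comp = str.maketrans("ACGT", "TGCA")
        genome = GenomeSequence(str(fixture_dir / "genome.fa"))
        models = load_annotation(fixture_dir / "annotation.refgene.txt")
        got = dict(extract_reference_proteome(models, genome))
        for m in models:
            cds = "".join(
                genome.fetch(m.chrom, max(s, m.cds_start), min(e, m.cds_end))
                for s, e in m.exons
                if min(e, m.cds_end) > max(s, m.cds_start)
            )
            if m.strand == "-":
                cds = cds.translate(comp)[::-1]
            prot = []
            for i in range(0, len(cds) - 2, 3):
                aa = table.get(cds[i : i + 3])
                if aa is None:  # stop codon
                    break
                prot.append(aa)
            assert got[m.transcript_id] == "".join(prot)


class TestNormalPeptideIndex:
    def test_known_nine_mer_membership(self):
        index = build_normal_peptide_index(["MKANPALTMQ"], ks=(8, 9, 10))
        assert index.contains("MKANPALTM")
        assert not index.contains("AAAAAAAAA")

    def test_every_indexed_kmer_is_reported_present(self):
        proteins = ["MKANPALTMQWERTYIP", "HACKSLVDE"]
        index = build_normal_peptide_index(proteins)
        for p in proteins:
            for k in (8, 9, 10, 11):
                for i in range(len(p) - k + 1):
                    assert index.contains(p[i : i + k])

    def test_nearest_single_mismatch(self):
        index = build_normal_peptide_index(["MKANPALTMQ"], ks=(9,))
        pep, m = index.nearest("MKANPALTW")
        assert (pep, m) == ("MKANPALTM", 1)

    def test_nearest_is_order_invariant_with_lexicographic_ties(self):
        # two windows both at distance 1 from the query; the smaller wins
        a = build_normal_peptide_index(["AAAAAAAAC", "AAAAAAAAD"], ks=(9,))
        b = build_normal_peptide_index(["AAAAAAAAD", "AAAAAAAAC"], ks=(9,))
        q = "AAAAAAAAE"
        assert a.nearest(q) == b.nearest(q) == ("AAAAAAAAC", 1)

    def test_empty_protein_list_rejected(self):
        with pytest.raises(ValueError):
            build_normal_peptide_index([])

    def test_reference_nine_mers_all_present_in_index(self, fixture_dir):
        from spliceneo.models import load_annotation

        genome = GenomeSequence(str(fixture_dir / "genome.fa"))
        models = load_annotation(fixture_dir / "annotation.refgene.txt")
        proteome = [s for _, s in extract_reference_proteome(models, genome)]
        index = build_normal_peptide_index(proteome, ks=(9,))
        for prot in proteome:
            for i in range(len(prot) - 8):
                assert index.contains(prot[i : i + 9])
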