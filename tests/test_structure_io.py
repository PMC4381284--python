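import pytest

from sirna_access.structure_io import (
    MrnaRecord,
    SecondaryStructure,
    SirnaRecord,
    classify_efficacy,
    read_ct,
    read_dotbracket,
    read_fasta,
    read_feature_table,
    read_sirna_table,
    read_ss_count,
    reverse_complement,
    write_ct,
    write_feature_table,
    write_ss_count,
)


class TestFasta:
    def test_t_normalized_to_u(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == "ACGU" and rec.length == 4

    def test_multiline_multirecord(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\nGU\n>b\nGGG\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert [r.length for r in recs] == [4, 3]

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\n")
        with pytest.raises(ValueError, match="empty"):
            read_fasta(p)

    def test_ambiguous_base_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGN\n")
        with pytest.raises(ValueError, match="N"):
            read_fasta(p)

    def test_header_id_up_to_whitespace(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">NM_0001 some description\nAAAA\n")
        (rec,) = read_fasta(p)
        assert rec.id == "NM_0001"


class TestCt:
    def _write_ct(self, tmp_path, text):
        p = tmp_path / "s.ct"
        p.write_text(text)
        return p

    def test_open_chain(self, tmp_path):
        text = "4 test\n1 G 0 2 0 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n4 C 3 0 0 4\n"
        s = read_ct(self._write_ct(tmp_path, text))
        assert s.pairs == (0, 0, 0, 0, 0)

    def test_hairpin_pairs_hand_checked(self, tmp_path):
        rows = []
        seq = "GGGAAACCC"
        partner = {1: 9, 2: 8, 3: 7, 7: 3, 8: 2, 9: 1}
        for i, base in enumerate(seq, 1):
            rows.append(f"{i} {base} {i-1} {i+1 if i<9 else 0} {partner.get(i,0)} {i}")
        text = "9 dG = -9.0 test\n" + "\n".join(rows) + "\n"
        s = read_ct(self._write_ct(tmp_path, text))
        assert s.pairs[1:] == (9, 8, 7, 0, 0, 0, 3, 2, 1)
        assert s.energy == -9.0

    def test_involution_violation_names_rows(self, tmp_path):
        text = (
            "5 test\n1 G 0 2 5 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n4 A 3 5 0 4\n"
            "5 C 4 0 0 5\n"
        )
        with pytest.raises(ValueError, match="1.*5|involution"):
            read_ct(self._write_ct(tmp_path, text))

    def test_roundtrip_preserves_pair_table(self, tmp_path):
        s = read_dotbracket("GGGAAACCCAAGGGAAACCC", "(((...)))..(((...)))", energy=-18.0)
        p = tmp_path / "rt.ct"
        write_ct(s, p)
        s2 = read_ct(p)
        assert s2.pairs == s.pairs
        assert s2.sequence == s.sequence
        assert s2.energy == s.energy


class TestDotBracket:
    def test_direct_matching(self):
        s = read_dotbracket("GGGAAACCC", "(((...)))")
        assert s.pairs[1:] == (9, 8, 7, 0, 0, 0, 3, 2, 1)

    def test_open_chain(self):
        s = read_dotbracket("ACGU", "....")
        assert all(p == 0 for p in s.pairs)

    def test_short_hairpin_rejected(self):
        with pytest.raises(ValueError, match="hairpin"):
            read_dotbracket("GGGAACCC", "(((..)))")

    def test_illegal_pair_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            read_dotbracket("AAAAAGA", "(.....)")

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            read_dotbracket("GGGAAACCC", "(((...).)")

    def test_pseudoknot_rejected_via_pairs(self):
        with pytest.raises(ValueError, match="pseudoknot"):
            SecondaryStructure(
                sequence="GGGGAAAACCCC",
                pairs=(0, 9, 10, 0, 0, 0, 0, 0, 0, 1, 2, 0, 0),
            )

    def test_agrees_with_ct(self, tmp_path):
        db = read_dotbracket("GGGAAACCC", "(((...)))")
        p = tmp_path / "x.ct"
        write_ct(db, p)
        assert read_ct(p).pairs == db.pairs


class TestSsCount:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "x.sscount"
        p.write_text("2\n1 2\n2 0\n3 1\n")
        ss = read_ss_count(p)
        assert ss.counts == (0, 2, 0, 1)
        assert ss.n_structures == 2

    def test_count_above_n_rejected(self, tmp_path):
        p = tmp_path / "x.sscount"
        p.write_text("2\n1 5\n")
        with pytest.raises(ValueError, match="exceeds"):
            read_ss_count(p)

    def test_missing_position_rejected(self, tmp_path):
        p = tmp_path / "x.sscount"
        p.write_text("2\n1 1\n3 1\n")
        with pytest.raises(ValueError, match="missing position 2"):
            read_ss_count(p)

    def test_roundtrip(self, tmp_path):
        from sirna_access.structure_io import SsCountVector

        ss = SsCountVector(counts=(0, 3, 1, 0, 2), n_structures=3)
        p = tmp_path / "rt.sscount"
        write_ss_count(ss, p, sequence="GAUC")
        assert read_ss_count(p) == ss


class TestSirnaTable:
    def test_efficacy_class_boundaries(self):
        assert classify_efficacy(95) == "VH"
        assert classify_efficacy(90) == "VH"
        assert classify_efficacy(89.9) == "H"
        assert classify_efficacy(70) == "H"
        assert classify_efficacy(50) == "M"
        assert classify_efficacy(49.9) == "L"
        assert classify_efficacy(0) == "L"

    def test_percent_rows_classified(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "id\tguide\ttarget_id\tefficacy\n"
            "s1\tACGUACGUACGUACGUACG\tm1\t95\n"
            "s2\tACGUACGUACGUACGUACG\tm1\t50\n"
        )
        r1, r2 = read_sirna_table(p)
        assert r1.efficacy_class == "VH"
        assert r2.efficacy_class == "M"

    def test_csv_autodetected_and_class_tokens(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("id,guide,target_id,efficacy\ns1,acguacguacguacguacgu,m1,VH\n")
        (rec,) = read_sirna_table(p)
        assert rec.guide == "ACGUACGUACGUACGUACGU"
        assert rec.efficacy_class == "VH"

    def test_guide_length_bound(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tguide\ttarget_id\tefficacy\ns1\tACGUACGUACGUACGUAC\tm1\t95\n")
        with pytest.raises(ValueError, match="guide length"):
            read_sirna_table(p)

    def test_unknown_token_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tguide\ttarget_id\tefficacy\ns1\tACGUACGUACGUACGUACG\tm1\tgreat\n")
        with pytest.raises(ValueError, match="unknown efficacy token"):
            read_sirna_table(p)

    def test_inconsistent_class_and_percent_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SirnaRecord(
                id="s", guide="ACGUACGUACGUACGUACG", target_id="m",
                efficacy_percent=95.0, efficacy_class="L",
            )


class TestFeatureTable:
    def test_empty_list_gives_header_only(self, tmp_path):
        p = tmp_path / "f.tsv"
        write_feature_table([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("sirna_id\t")

    def test_roundtrip(self, tmp_path):
        from sirna_access.synthetic_data import fixture_study

        rows = fixture_study().features
        p = tmp_path / "f.tsv"
        write_feature_table(rows, p)
        back = read_feature_table(p)
        assert len(back) == len(rows)
        for a, b in zip(rows, back):
            assert a.sirna_id == b.sirna_id
            assert a.runs == b.runs
            assert a.stem == b.stem
            assert abs(a.hb_index - b.hb_index) < 1e-4
            assert abs(a.dg_overall - b.dg_overall) < 1e-4


def test_reverse_complement():
    assert reverse_complement("GAUC") == "GAUC"
    assert reverse_complement("AAGG") == "CCUU"
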