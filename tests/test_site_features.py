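import logging
import math

import pytest

from sirna_access.fold_engine import (
    FoldParams,
    enumerate_structures,
    representative_ensemble,
    ss_count,
    write_ensemble,
)
from sirna_access.loop_annotation import annotate, element_counts_in_site
from sirna_access.site_features import (
    build_feature_vector,
    classify_accessibility,
    compute_site_features,
    hb_index,
    locate_site,
    unpaired_stats,
)
from sirna_access.structure_io import (
    MrnaRecord,
    SirnaRecord,
    SsCountVector,
    read_dotbracket,
    read_ss_count,
    reverse_complement,
)

from conftest import random_rna


def _sirna(guide, target="m1", sid="s1", percent=95.0):
    return SirnaRecord(id=sid, guide=guide, target_id=target, efficacy_percent=percent)


class TestLocateSite:
    def test_single_exact_hit(self):
        mrna = MrnaRecord(id="m1", sequence="AAAA" + "GCCCAAAUUUGGGCCCAAA" + "GGGG")
        guide = reverse_complement("GCCCAAAUUUGGGCCCAAA")
        site = locate_site(_sirna(guide), mrna)
        assert (site.start, site.end) == (5, 23)

    def test_absent_target_raises(self):
        mrna = MrnaRecord(id="m1", sequence="A" * 40)
        with pytest.raises(ValueError, match="target site not found"):
            locate_site(_sirna("G" * 19), mrna)

    def test_multiple_hits_take_5prime_most_and_warn(self, caplog):
        block = "GCCCAAAUUUGGGCCCAAA"
        mrna = MrnaRecord(id="m1", sequence=block + "AAAA" + block)
        guide = reverse_complement(block)
        with caplog.at_level(logging.WARNING):
            site = locate_site(_sirna(guide), mrna)
        assert site.start == 1
        assert "multiple positions" in caplog.text
        assert "[1, 24]" in caplog.text


class TestUnpairedStats:
    def test_fully_paired_site(self):
        s = read_dotbracket("GGGGGAAAAACCCCC", "(((((.....)))))")
        assert unpaired_stats(s, (1, 5)) == (0, (), 0)

    def test_fully_unpaired_site(self):
        s = read_dotbracket("A" * 19, "." * 19)
        assert unpaired_stats(s, (1, 19)) == (19, (19,), 19)

    def test_runs_follow_pattern(self):
        #              123456789
        s = read_dotbracket("GGAAACACC", "((...).).")
        # pairs: 1-8, 2-6; unpaired 3,4,5,7,9
        assert unpaired_stats(s, (1, 9)) == (5, (3, 1, 1), 3)

    def test_run_truncated_at_site_boundary(self):
        s = read_dotbracket("GGAAACACC", "((...).).")
        n, runs, mx = unpaired_stats(s, (4, 7))
        assert (n, runs, mx) == (3, (2, 1), 2)


class TestHbIndex:
    def test_fully_accessible_site_is_zero(self):
        ss = SsCountVector(counts=(0, 2, 2, 2), n_structures=2)
        assert hb_index(ss, "GAU", (1, 3)) == 0.0

    def test_fully_paired_gc_site(self):
        ss = SsCountVector(counts=(0,) + (0,) * 19, n_structures=4)
        assert hb_index(ss, "G" * 19, (1, 19)) == 57.0

    def test_hand_example(self):
        ss = SsCountVector(counts=(0, 1, 0, 2), n_structures=2)
        assert hb_index(ss, "GAU", (1, 3)) == pytest.approx(3.5)

    def test_monotone_in_pairing(self):
        seq = "GAUCG"
        base = SsCountVector(counts=(0, 2, 1, 3, 0, 2), n_structures=3)
        hb0 = hb_index(base, seq, (1, 5))
        for i in range(1, 6):
            if base.counts[i] == 0:
                continue
            counts = list(base.counts)
            counts[i] -= 1  # one more structure pairs position i
            more = SsCountVector(counts=tuple(counts), n_structures=3)
            assert hb_index(more, seq, (1, 5)) > hb0

    def test_site_outside_vector_rejected(self):
        ss = SsCountVector(counts=(0, 1, 1), n_structures=2)
        with pytest.raises(ValueError, match="outside"):
            hb_index(ss, "GAU", (1, 3))

    def test_internal_and_serialized_sscount_agree(self, tmp_path):
        seq = "GGCGAAAGCGCCAAGGGAAACCC"
        ens = representative_ensemble(seq, n_windows=3)
        write_ensemble(ens, tmp_path, "m")
        direct = hb_index(ss_count(ens), seq, (3, 21))
        reread = hb_index(read_ss_count(tmp_path / "m.sscount"), seq, (3, 21))
        assert direct == pytest.approx(reread)


class TestClassifyAccessibility:
    @pytest.mark.parametrize(
        "hb,expected",
        [(24.9, "accessible"), (25.0, "inaccessible"), (0.0, "accessible")],
    )
    def test_cutpoint_is_strict(self, hb, expected):
        assert classify_accessibility(hb) == expected


class TestBuildFeatureVector:
    def _study_row(self, seq, start=1, glen=19, percent=95.0):
        mrna = MrnaRecord(id="m1", sequence=seq)
        guide = reverse_complement(seq[start - 1 : start - 1 + glen])
        sirna = _sirna(guide, percent=percent)
        ens = representative_ensemble(seq, n_windows=4)
        return build_feature_vector(sirna, mrna, ens)

    def test_invariants_hold(self, rng):
        for _ in range(10):
            seq = random_rna(rng, int(rng.integers(30, 60)))
            start = int(rng.integers(1, len(seq) - 19 + 2))
            fv = self._study_row(seq, start=start)
            assert fv.site_length == 19
            assert fv.n_unpaired == sum(fv.runs)
            assert 0 <= fv.hb_index <= 3 * 19

    def test_unstructured_mrna_gives_null_features(self):
        fv = self._study_row("A" * 30)
        assert fv.n_unpaired == 19
        assert fv.hb_index == 0.0
        assert fv.dg_break_target == 0.0
        assert fv.stem == 0

    def test_cross_feature_consistency(self, rng):
        # unpaired count equals site length minus stem count, and matches a
        # recount through the annotation
        seq = random_rna(rng, 50)
        start = 10
        fv = self._study_row(seq, start=start)
        ens = representative_ensemble(seq, n_windows=4)
        ann = annotate(ens.optimal)
        counts = element_counts_in_site(ann, (start, start + 18))
        assert fv.n_unpaired == 19 - counts["STEM"]

    def test_non_extreme_class_rejected(self):
        seq = "A" * 30
        mrna = MrnaRecord(id="m1", sequence=seq)
        guide = reverse_complement(seq[:19])
        sirna = _sirna(guide, percent=60.0)  # class M
        ens = representative_ensemble(seq)
        with pytest.raises(ValueError, match="only VH and L"):
            build_feature_vector(sirna, mrna, ens)

    def test_hand_built_fixture_row(self):
        # 25-nt hairpin mRNA with a fully known fold:
        # AAA GGGG AAAA CCCC AAA then padding to fit a 19-nt site
        seq = "AAAGGGGAAAACCCCAAAAAAAAAA"
        mrna = MrnaRecord(id="m1", sequence=seq)
        ens = representative_ensemble(seq, n_windows=0)  # optimal fold only
        assert ens.optimal.dotbracket() == "...((((....)))).........."
        guide = reverse_complement(seq[0:19])
        fv = build_feature_vector(_sirna(guide), mrna, ens)
        assert fv.loop5 == 3
        assert fv.stem == 8
        assert fv.h_loop == 4
        assert fv.loop3 == 4
        assert fv.n_unpaired == 11
        assert fv.runs == (3, 4, 4)
        # single-structure ensemble: the 8 paired site positions are all
        # G/C -> H-b = 8 * 3 = 24
        assert fv.hb_index == pytest.approx(24.0)
        assert fv.dg_break_target == -12.0  # opening the site unfolds all 4 GC pairs
        assert fv.gc_percent == pytest.approx(100 * 8 / 19)
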