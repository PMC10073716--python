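"""Sequence windows, BLOSUM62 consensus, domains, and categories."""

import math

import numpy as np
import pytest

from upmprofiler.io_formats import DomainAnnotation
from upmprofiler.motif_analysis import (BLOSUM62, GAP, align_windows,
                                        category_summary, consensus,
                                        conservation_score, domain_overlap,
                                        extract_window, has_consensus)
from upmprofiler.synthetic_data import default_config, simulate


class TestExtractWindow:
    def test_full_window_centers_the_arginine(self):
        seq = "A" * 244 + "R" + "C" * 60
        w = extract_window(seq, 245)
        assert len(w.window) == 21
        assert w.window[10] == "R"
        assert not w.truncated

    def test_left_truncation(self):
        seq = "AAAAR" + "C" * 30
        w = extract_window(seq, 5)
        assert w.flank_left == 4 and len(w.window) == 15 and w.truncated

    def test_non_arginine_center_rejected(self):
        with pytest.raises(ValueError, match="not R"):
            extract_window("AAKAA", 3)

    def test_out_of_range_center(self):
        with pytest.raises(ValueError):
            extract_window("AAR", 9)

    def test_roster_windows_recenter(self):
        """Every Cit site of the synthetic roster yields a window whose
        center index holds the R at the recorded protein position."""
        data = simulate(default_config(0))
        for (acc, pos), truth in data.ground_truth.site_stoichiometry.items():
            seq = data.sequences[acc]
            if seq[pos - 1] != "R":
                continue
            w = extract_window(seq, pos, accession=acc)
            assert w.window[w.flank_left] == "R"
            # relocate: the window is a verbatim substring around the center
            start = pos - w.flank_left
            assert seq[start - 1:start - 1 + len(w.window)] == w.window


class TestAlignment:
    def test_identical_windows_score_diagonal(self):
        seq = "MKTAYIAKQRLDFGHWEVLNV"  # 21-mer with R at index 9? use real R
        seq = "MKTAYIAKQWRDFGHWEVLNV"  # R at 0-based index 10
        w = extract_window(seq, 11)
        a = align_windows([w, w])
        expected = sum(BLOSUM62[c, c] for c in seq)
        assert a.total_score == pytest.approx(expected)
        assert a.column_scores[10] == BLOSUM62["R", "R"] == 5.0

    def test_center_column_is_pure_arginine(self):
        s1 = "A" * 10 + "R" + "C" * 10
        s2 = "W" * 10 + "R" + "Y" * 10
        a = align_windows([extract_window(s1, 11), extract_window(s2, 11)])
        assert a.column_scores[10] == BLOSUM62["R", "R"]
        cols = consensus(a)
        center = cols[10]
        assert center.offset == 0 and center.modal_residue == "R"
        assert center.agreement == 100.0

    def test_truncated_window_pads_with_zero_scoring_gaps(self):
        full = extract_window("A" * 10 + "R" + "A" * 10, 11)
        short = extract_window("AAAAR" + "A" * 10, 5)  # 6 left columns padded
        a = align_windows([full, short])
        assert a.rows[1][:6] == GAP * 6
        # a single non-gap char cannot form a pair: score 0 in padded columns
        assert all(s == 0 for s in a.column_scores[:6])

    def test_window_order_symmetry_and_column_additivity(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQSTVWY")
        seqs = ["".join(rng.choice(aas, 10)) + "R" + "".join(rng.choice(aas, 10))
                for _ in range(4)]
        ws = [extract_window(s, 11) for s in seqs]
        fwd = align_windows(ws)
        rev = align_windows(list(reversed(ws)))
        assert fwd.total_score == pytest.approx(rev.total_score)
        assert fwd.total_score == pytest.approx(sum(fwd.column_scores))

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            align_windows([extract_window("A" * 10 + "R" + "A" * 10, 11)])


class TestConsensus:
    def _alignment(self, columns):
        """Build an alignment whose i-th column holds the given residues."""
        n = len(columns[0])
        width = len(columns)
        rows = ["".join(columns[j][i] for j in range(width)) for i in range(n)]
        # wrap rows as a fake alignment with matching width
        from upmprofiler.motif_analysis import WindowAlignment
        flank = (width - 1) // 2
        return WindowAlignment(rows=tuple(rows), column_scores=(0,) * width,
                               flank=flank)

    def test_absolute_center_conservation(self):
        a = self._alignment([list("RRRRRRRRRRR")])
        col = consensus(a)[0]
        assert col.agreement == 100.0 and col.conservation_score == 11
        assert col.shade == "mid"

    def test_light_shade_between_40_and_60(self):
        # 5 of 11 = 45.45 %
        a = self._alignment([list("AAAAACDEFGH")])
        col = consensus(a)[0]
        assert col.agreement == pytest.approx(45.4545, abs=1e-3)
        assert col.shade == "light"

    def test_no_shade_and_plus_mark_below_40(self):
        # 4 of 11 = 36.36 %
        a = self._alignment([list("AAAACDEFGHI")])
        col = consensus(a)[0]
        assert col.shade == "none" and col.mark == "+"

    def test_gaps_excluded_from_denominator(self):
        a = self._alignment([["A", "A", GAP, GAP]])
        col = consensus(a)[0]
        assert col.agreement == 100.0

    def test_all_gap_column_reported_empty(self):
        a = self._alignment([[GAP, GAP]])
        col = consensus(a)[0]
        assert col.modal_residue is None and math.isnan(col.agreement)

    def test_has_consensus_ignores_center(self):
        # three windows with pairwise-distinct flank residues: every flank
        # column sits at 33.3 % agreement, below the >40 % bar, while the
        # center R stays at 100 %
        s1 = "A" * 10 + "R" + "C" * 10
        s2 = "W" * 10 + "R" + "Y" * 10
        s3 = "L" * 10 + "R" + "S" * 10
        ws = [extract_window(s, 11) for s in (s1, s2, s3)]
        cols = consensus(align_windows(ws))
        assert not has_consensus(cols)
        # two identical windows agree fully on the flanks
        cols2 = consensus(align_windows([ws[0], extract_window(s1, 11)]))
        assert has_consensus(cols2)


class TestConservationScore:
    def test_identity_scores_eleven(self):
        assert conservation_score(list("WWWW")) == 11

    def test_non_identical_capped_at_ten(self):
        assert conservation_score(list("ILV")) <= 10
        assert conservation_score(list("ILV")) >= 5  # aliphatic/hydrophobic/...

    def test_opposed_charges_score_low(self):
        assert conservation_score(list("DK")) < conservation_score(list("DE"))

    def test_gap_only_scores_zero(self):
        assert conservation_score([GAP, GAP]) == 0


class TestDomains:
    DOMS = [DomainAnnotation("SEMG2_HUMAN", "IDR", 228, 248),
            DomainAnnotation("DPP4_HUMAN", "Prolyl endopeptidase", 605, 635)]

    def test_inside_interval(self):
        assert domain_overlap("SEMG2_HUMAN", 245, self.DOMS) == [("IDR", True)]

    def test_boundary_exclusive_outside(self):
        assert domain_overlap("SEMG2_HUMAN", 227, self.DOMS) == [("IDR", False)]

    def test_other_protein_interval(self):
        assert domain_overlap("DPP4_HUMAN", 611, self.DOMS) == \
            [("Prolyl endopeptidase", True)]


class TestCategories:
    def _map(self, sizes):
        out = {}
        i = 0
        for cat, n in sizes.items():
            for _ in range(n):
                out[f"P{i}"] = cat
                i += 1
        return out

    def test_single_member_among_eleven_is_nine_percent(self):
        df = category_summary(self._map(
            {"motility": 3, "eppin": 2, "a": 1, "b": 1, "c": 1, "d": 1,
             "others": 2}))
        row = df.set_index("category")
        assert row.loc["a", "percent"] == 9
        assert row.loc["motility", "percent"] == 27
        assert row.loc["eppin", "percent"] == 18

    def test_single_category_is_everything(self):
        df = category_summary(self._map({"only": 5}))
        assert df["percent"].tolist() == [100]

    def test_exact_percentages_sum_to_hundred(self):
        df = category_summary(self._map({"a": 3, "b": 2, "c": 2}))
        assert df["percent_exact"].sum() == pytest.approx(100.0)

    def test_half_rounds_away_from_zero(self):
        # 1 of 8 = 12.5 -> 13
        df = category_summary(self._map({"a": 7, "b": 1}))
        assert df.set_index("category").loc["b", "percent"] == 13

    def test_unassigned_protein_listed_in_error(self):
        with pytest.raises(ValueError, match="P0"):
            category_summary({"P0": "", "P1": "x"})
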