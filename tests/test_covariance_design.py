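"""Covariance scoring, contact validation, covariant design selection."""

import numpy as np
import pandas as pd
import pytest

from memstab import (
    build_contact_map,
    filter_alignment,
    gen_msa,
    read_score_table,
    score_covariance,
    select_covariant_design,
    validate_pairs,
)
from memstab.covariance_design import CovarianceScoreTable, write_score_table
from memstab.msa_consensus import ConsensusCall

TARGET = "MLIVKEDAQSWFTRNGHYCP" + "MLIVKEDAQS"  # 30 residues


def make_alignment(rows, ids):
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    return MultipleSeqAlignment(
        [SeqRecord(Seq(r), id=i, description="") for r, i in zip(rows, ids)]
    )


def planted_alignment(n=1500, seed=3):
    profiles = {
        c: {TARGET[c - 1]: 0.7, ("A" if TARGET[c - 1] != "A" else "G"): 0.3}
        for c in range(1, 31)
    }
    joint = {("A", "C"): 0.5, ("C", "A"): 0.5}
    return gen_msa(n, 30, profiles, coupled_pairs=[(5, 25, joint)],
                   target_seq=TARGET, seed=seed)[0]


def make_call(position):
    return ConsensusCall(position=position, target_aa="K", consensus_aa="R",
                         f_consensus=0.5, f_target=0.2, f_min=0.2, delta=0.1)


class TestFilterAlignment:
    def test_full_coverage_row_kept(self):
        aln, _ = gen_msa(20, 10, {}, target_seq="MKVLNQRSTW", seed=0)
        kept, removed = filter_alignment(aln, "TARGET", 0.7)
        assert removed == 0 and len(kept) == 20

    def test_sparse_row_removed(self):
        aln = make_alignment(
            ["MKVLNQRSTW", "MKVL------", "MKVLNQRST-"], ids=["T", "gappy", "ok"]
        )
        kept, removed = filter_alignment(aln, "T", 0.7)
        assert removed == 1
        assert [r.id for r in kept] == ["T", "ok"]

    def test_target_row_never_removed(self):
        aln = make_alignment(["M---------", "MKVLNQRSTW"], ids=["T", "s1"])
        kept, _ = filter_alignment(aln, "T", 0.7)
        assert "T" in [r.id for r in kept]


class TestScoreCovariance:
    def test_planted_pair_ranks_first_and_background_near_zero(self):
        aln = planted_alignment()
        table = score_covariance(aln, "TARGET")
        top = table.top(1).iloc[0]
        assert (top.i, top.j) == (5, 25)
        background = table.pairs[~((table.pairs.i == 5) & (table.pairs.j == 25))]
        # APC zero-centers independent columns: background scores are tiny
        assert np.abs(background.score).max() < 0.2 * top.score
        assert abs(background.score.mean()) < 0.01

    def test_apc_preserves_dominant_pair_ranking(self):
        aln = planted_alignment(seed=11)
        table = score_covariance(aln, "TARGET")
        ranked = table.pairs.sort_values("score", ascending=False)
        assert (ranked.iloc[0].i, ranked.iloc[0].j) == (5, 25)

    def test_minimum_separation_excludes_neighbors(self):
        aln = planted_alignment()
        table = score_covariance(aln, "TARGET", min_separation=5)
        assert (table.pairs.j - table.pairs.i).min() >= 5

    def test_single_row_alignment_rejected(self):
        aln, _ = gen_msa(1, 10, {}, target_seq="MKVLNQRSTW", seed=0)
        with pytest.raises(ValueError, match="single-row"):
            score_covariance(aln, "TARGET")

    def test_mean_field_dca_also_ranks_planted_pair_first(self):
        aln = planted_alignment(n=800)
        table = score_covariance(aln, "TARGET", method="mf_dca")
        top = table.top(1).iloc[0]
        assert (top.i, top.j) == (5, 25)

    def test_score_table_csv_roundtrip(self, tmp_path):
        table = CovarianceScoreTable(
            method="mi_apc",
            pairs=pd.DataFrame({"i": [1, 2], "j": [7, 9], "score": [0.5, 0.1]}),
        )
        path = tmp_path / "scores.csv"
        write_score_table(table, path, target_sequence=TARGET)
        loaded = read_score_table(path)
        pd.testing.assert_frame_equal(
            loaded.pairs[["i", "j", "score"]], table.pairs, check_dtype=False
        )


class TestContactMap:
    def test_toy_structure_distances_match_hand_euclidean(self, toy_pdb):
        cmap = build_contact_map(toy_pdb, target_mapping={"A": 0})
        assert cmap.distance(1, 2) == pytest.approx(4.0, abs=1e-6)
        assert cmap.distance(2, 3) == pytest.approx(5.0, abs=1e-6)
        assert cmap.distance(1, 3) == pytest.approx(9.0, abs=1e-6)
        assert cmap.distance(3, 1) == cmap.distance(1, 3)  # symmetric

    def test_offset_mapping_shifts_positions(self, toy_pdb):
        cmap = build_contact_map(toy_pdb, target_mapping={"A": 100})
        assert cmap.distance(101, 102) == pytest.approx(4.0, abs=1e-6)

    def test_alignment_fallback_mapping(self, toy_pdb):
        cmap = build_contact_map(toy_pdb, target_mapping="align",
                                 target_sequence="AGL")
        assert cmap.distance(1, 2) == pytest.approx(4.0, abs=1e-6)

    def test_unmapped_chain_reported(self, toy_pdb):
        with pytest.warns(UserWarning, match="could not be mapped"):
            with pytest.raises(ValueError, match="no mappable atoms"):
                build_contact_map(toy_pdb, target_mapping={"B": 0})


class TestValidatePairs:
    def _scores(self, pairs):
        return CovarianceScoreTable(
            method="imported",
            pairs=pd.DataFrame(
                {
                    "i": [p[0] for p in pairs],
                    "j": [p[1] for p in pairs],
                    "score": np.linspace(1.0, 0.5, len(pairs)),
                }
            ),
        )

    def _toy_map(self, contacts, far, cap=12.0):
        from memstab.covariance_design import ContactMap

        distances = {p: 4.0 for p in contacts} | {p: 9.0 for p in far}
        mapped = {x for p in list(contacts) + list(far) for x in p}
        return ContactMap(source="toy", distances=distances,
                          mapped_positions=mapped, distance_cap=cap)

    def test_all_contacts_give_unit_precision(self):
        contacts = [(1, 7), (2, 9), (3, 11)]
        report = validate_pairs(self._scores(contacts), self._toy_map(contacts, []),
                                cutoff_A=6.0, top_k=3)
        assert report["precision"] == 1.0
        assert report["removal_list"] == []

    def test_half_planted_contacts_give_half_precision(self):
        pairs = [(i, i + 10) for i in range(1, 11)]
        report = validate_pairs(
            self._scores(pairs), self._toy_map(pairs[:5], pairs[5:]),
            cutoff_A=6.0, top_k=10,
        )
        assert report["precision"] == 0.5
        assert len(report["removal_list"]) == 5

    def test_unmapped_pairs_excluded_from_denominator(self):
        pairs = [(1, 7), (2, 9), (90, 99)]
        report = validate_pairs(
            self._scores(pairs), self._toy_map([(1, 7), (2, 9)], []),
            cutoff_A=6.0, top_k=3,
        )
        assert report["n_unmapped"] == 1
        assert report["precision"] == 1.0

    def test_top_k_larger_than_table_rejected(self):
        with pytest.raises(ValueError, match="top_k"):
            validate_pairs(self._scores([(1, 7)]), self._toy_map([(1, 7)], []),
                           top_k=5)

    def test_high_coupling_alignment_reaches_high_precision(self):
        # planted covarying pairs that are also "in contact" in a toy map
        rng = np.random.default_rng(5)
        target = "".join(rng.choice(list("MLIVKEDAQSWFTRNGHY"), size=40))
        pairs = [(2, 12), (5, 25), (8, 30), (15, 33), (20, 38)]
        joints = [{("A", "C"): 0.5, ("C", "A"): 0.5},
                  {("L", "V"): 0.5, ("V", "L"): 0.5},
                  {("K", "E"): 0.5, ("E", "K"): 0.5},
                  {("F", "W"): 0.5, ("W", "F"): 0.5},
                  {("S", "T"): 0.5, ("T", "S"): 0.5}]
        aln, _ = gen_msa(
            2000, 40, {}, coupled_pairs=[(i, j, jt) for (i, j), jt in zip(pairs, joints)],
            target_seq=target, seed=17,
        )
        table = score_covariance(aln, "TARGET")
        cmap = self._toy_map(pairs, [])
        cmap.mapped_positions = set(range(1, 41))
        report = validate_pairs(table, cmap, cutoff_A=6.0, top_k=5)
        assert report["precision"] >= 0.9


class TestSelectCovariantDesign:
    def _scores(self):
        return CovarianceScoreTable(
            method="imported",
            pairs=pd.DataFrame(
                {"i": [5, 40], "j": [9, 50], "score": [0.9, 0.8]}
            ),
        )

    def test_intersection_by_hand(self):
        calls = [make_call(p) for p in (5, 10, 20)]
        design = select_covariant_design(calls, self._scores(), top_pairs=2)
        assert [c.position for c in design] == [5]

    def test_no_overlap_gives_empty_design(self):
        calls = [make_call(p) for p in (100, 200)]
        assert select_covariant_design(calls, self._scores(), top_pairs=2) == []

    def test_output_is_subset_with_identical_calls(self):
        calls = [make_call(p) for p in (5, 9, 40, 77)]
        design = select_covariant_design(calls, self._scores(), top_pairs=2)
        assert set(design) <= set(calls)  # frozen dataclasses: identity-preserving subset

    def test_false_negative_removal_before_cut_promotes_next_pair(self):
        calls = [make_call(p) for p in (5, 40)]
        # removing (5, 9) before the top-1 cut lets (40, 50) in
        design = select_covariant_design(
            calls, self._scores(), top_pairs=1, contact_filter=[(5, 9)],
            remove_before_cut=True,
        )
        assert [c.position for c in design] == [40]
        # removing after the cut leaves nothing
        design = select_covariant_design(
            calls, self._scores(), top_pairs=1, contact_filter=[(5, 9)],
            remove_before_cut=False,
        )
        assert design == []
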