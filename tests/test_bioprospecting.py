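"""Sequence mining: FASTA I/O, alignment, identity, clustering, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indolekit import bioprospecting as bp
from conftest import brute_force_align_score


def make_record(rid, seq, species=None, **annotations):
    return bp.SequenceRecord(id=rid, species=species or f"Species {rid}",
                             sequence=seq, annotations=annotations)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestFasta:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert bp.read_fasta(path) == []

    def test_round_trip_preserves_everything(self, tmp_path):
        records = [
            make_record("tnaA_1", "MKWFACDE", species="Escherichia coli",
                        pfam_pf01212_present=True, pathogenic_host=False,
                        theoretical_mass_kda=51.2),
            make_record("tnaA_2", "MKYLACDE", species="Providencia rettgeri"),
        ]
        path = tmp_path / "two.fasta"
        bp.write_fasta(records, path)
        again = bp.read_fasta(path)
        assert [r.id for r in again] == ["tnaA_1", "tnaA_2"]
        assert [r.length for r in again] == [8, 8]
        assert again[0].species == "Escherichia coli"
        assert again[0].annotations["pfam_pf01212_present"] is True
        assert again[0].annotations["pathogenic_host"] is False
        assert again[0].annotations["theoretical_mass_kda"] == pytest.approx(51.2)
        assert again[1].sequence == "MKYLACDE"

    def test_missing_species_reports_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">seq1 nothing=here\nMKWL\n")
        with pytest.raises(ValueError, match="seq1.*missing species"):
            bp.read_fasta(path)

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            make_record("bad", "MK1L")

    def test_generator_round_trip_counts(self, tmp_path):
        from indolekit.synthetic_data import FamilySpec, generate_sequence_families
        spec = FamilySpec(n_families=2, members_per_family=3,
                          seed_length_mean=30, seed_length_sd=2, rng_seed=5)
        records, _ = generate_sequence_families(spec)
        path = tmp_path / "syn.fasta"
        bp.write_fasta(records, path)
        again = bp.read_fasta(path)
        assert len(again) == 6
        assert [r.length for r in again] == [r.length for r in records]


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------

class TestDedupe:
    def test_all_distinct_species_unchanged(self):
        records = [make_record(f"r{i}", "MKWL") for i in range(4)]
        assert bp.dedupe_by_species(records) == records

    def test_longest_then_lexicographic(self):
        records = [
            make_record("c", "M" * 400, species="Same sp."),
            make_record("b", "M" * 450, species="Same sp."),
            make_record("a", "K" * 450, species="Same sp."),
        ]
        kept = bp.dedupe_by_species(records)
        assert [r.id for r in kept] == ["a"]

    def test_count_equals_distinct_species(self):
        records = [make_record(f"r{i}", "MKWL", species=f"sp{i % 3}")
                   for i in range(9)]
        assert len(bp.dedupe_by_species(records)) == 3

    def test_missing_species_lists_offenders(self):
        records = [make_record("ok", "MKWL"),
                   bp.SequenceRecord(id="anon", species="", sequence="MKWL")]
        with pytest.raises(ValueError, match="anon"):
            bp.dedupe_by_species(records)


# ---------------------------------------------------------------------------
# alignment and identity
# ---------------------------------------------------------------------------

class TestGlobalAlign:
    def test_self_alignment_perfect(self):
        aln = bp.global_align("MKWLACDE", "MKWLACDE")
        assert aln.score == 8.0
        assert bp.percent_identity(aln) == 1.0

    def test_internal_gap_example(self):
        # any alignment of these two has exactly one gap and <= 3 matches,
        # so the brute-force optimum is 3*1 - 1 = 2
        aln = bp.global_align("ACDE", "ACE")
        assert aln.score == brute_force_align_score("ACDE", "ACE") == 2.0
        assert aln.aligned_b == "AC-E"

    @given(st.text(alphabet="ACDE", min_size=1, max_size=6),
           st.text(alphabet="ACDE", min_size=1, max_size=6))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_oracle(self, a, b):
        assert bp.global_align(a, b).score == brute_force_align_score(a, b)

    @given(st.text(alphabet="ACDEFGHIK", min_size=1, max_size=6),
           st.text(alphabet="ACDEFGHIK", min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_with_alternate_scoring(self, a, b):
        scoring = bp.Scoring(match=2.0, mismatch=-3.0, gap=-2.0)
        assert bp.global_align(a, b, scoring).score == brute_force_align_score(
            a, b, scoring)

    def test_alignment_is_consistent_with_score(self):
        scoring = bp.Scoring()
        aln = bp.global_align("MKWACDEF", "MKYACDF", scoring)
        score = 0.0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if "-" in (x, y):
                score += scoring.gap
            else:
                score += scoring.match if x == y else scoring.mismatch
        assert score == aln.score

    def test_illegal_characters_error(self):
        with pytest.raises(ValueError, match="illegal"):
            bp.global_align("MKZ1", "MK")


class TestPercentIdentity:
    def test_gap_columns_count_in_denominator(self):
        aln = bp.Alignment("AC-E", "ACDE", 0.0)
        assert bp.percent_identity(aln) == 0.75

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bp.percent_identity(bp.Alignment("AC", "ACD", 0.0))


class TestIdentityMatrix:
    def test_identical_records_give_ones(self):
        records = [make_record("a", "MKWL"), make_record("b", "MKWL")]
        m = bp.identity_matrix(records)
        assert np.allclose(m.identity, 1.0)

    def test_matches_per_pair_alignment(self):
        records = [make_record("a", "MKWLACDE"), make_record("b", "MKYLACD"),
                   make_record("c", "MKWWWCDE")]
        m = bp.identity_matrix(records)
        for i in range(3):
            for j in range(i + 1, 3):
                aln = bp.global_align(records[i].sequence, records[j].sequence)
                assert m.identity[i, j] == pytest.approx(bp.percent_identity(aln))

    def test_symmetric_unit_diagonal(self, planted_identity_matrix):
        m = planted_identity_matrix.identity
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(np.diag(1.0 - m), 0.0)

    def test_permutation_equivariance(self):
        records = [make_record("a", "MKWLACDE"), make_record("b", "MKYLACD"),
                   make_record("c", "MKWWWCDE")]
        m1 = bp.identity_matrix(records).identity
        perm = [2, 0, 1]
        m2 = bp.identity_matrix([records[i] for i in perm]).identity
        assert np.allclose(m2, m1[np.ix_(perm, perm)])

    def test_within_family_exceeds_between(self, planted_families,
                                           planted_identity_matrix):
        _, _, labels = planted_families
        labels = np.array(labels)
        m = planted_identity_matrix.identity
        iu = np.triu_indices(len(labels), k=1)
        same = labels[iu[0]] == labels[iu[1]]
        assert m[iu][same].mean() > m[iu][~same].mean()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestHierarchicalCluster:
    def test_two_items_single_merge(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        tree = bp.hierarchical_cluster(D)
        assert tree.merges == [(0, 1, 0.3, 2)]

    def test_four_item_hand_agglomeration(self):
        # complete linkage by hand: merge (0,1)@0.1 -> cluster 4;
        # d(4,2)=max(.5,.6)=.6, d(4,3)=max(.9,.8)=.9, d(2,3)=0.4 ->
        # merge (2,3)@0.4 -> cluster 5; d(4,5)=max(.6,.9)=.9 -> merge @0.9
        D = np.array([
            [0.0, 0.1, 0.5, 0.9],
            [0.1, 0.0, 0.6, 0.8],
            [0.5, 0.6, 0.0, 0.4],
            [0.9, 0.8, 0.4, 0.0],
        ])
        tree = bp.hierarchical_cluster(D, linkage="complete")
        assert tree.merges == [(0, 1, 0.1, 2), (2, 3, 0.4, 2), (4, 5, 0.9, 4)]

    def test_single_linkage_differs_as_expected(self):
        D = np.array([
            [0.0, 0.1, 0.5, 0.9],
            [0.1, 0.0, 0.6, 0.8],
            [0.5, 0.6, 0.0, 0.4],
            [0.9, 0.8, 0.4, 0.0],
        ])
        tree = bp.hierarchical_cluster(D, linkage="single")
        # after (0,1)@0.1 and (2,3)@0.4, single linkage joins at min = 0.5
        assert tree.merges[-1] == (4, 5, 0.5, 4)

    def test_zero_distances_merge_at_zero(self):
        D = np.zeros((5, 5))
        tree = bp.hierarchical_cluster(D)
        assert all(h == 0.0 for _, _, h, _ in tree.merges)

    def test_complete_heights_nondecreasing(self, planted_identity_matrix):
        tree = bp.hierarchical_cluster(planted_identity_matrix.distance())
        heights = [h for _, _, h, _ in tree.merges]
        assert heights == sorted(heights)

    def test_merge_heights_agree_with_scipy(self):
        """Independent cross-check against scipy's complete linkage."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = bp.hierarchical_cluster(D, linkage="complete")
        theirs = linkage(squareform(D, checks=False), method="complete")
        assert np.allclose(sorted(h for _, _, h, _ in ours.merges),
                           sorted(theirs[:, 2]))

    def test_nan_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            bp.hierarchical_cluster(D)


class TestCutTree:
    @pytest.fixture
    def small_tree(self, planted_identity_matrix):
        return (bp.hierarchical_cluster(planted_identity_matrix.distance()),
                planted_identity_matrix.ids)

    def test_k_equals_n_all_singletons(self, small_tree):
        tree, ids = small_tree
        cut = bp.cut_tree(tree, ids, k=len(ids))
        assert cut.k == len(ids)
        assert sorted(cut.labels.values()) == list(range(1, len(ids) + 1))

    def test_k_one_single_cluster(self, small_tree):
        tree, ids = small_tree
        cut = bp.cut_tree(tree, ids, k=1)
        assert set(cut.labels.values()) == {1}

    def test_k_out_of_range(self, small_tree):
        tree, ids = small_tree
        with pytest.raises(ValueError, match="out of range"):
            bp.cut_tree(tree, ids, k=0)

    def test_cut_by_height_agrees_with_cut_by_k(self, small_tree):
        tree, ids = small_tree
        heights = [h for _, _, h, _ in tree.merges]
        n = tree.n_leaves
        checked = 0
        for k in range(2, n):
            # the equivalence requires a strict gap between the two heights
            if heights[n - k - 1] >= heights[n - k]:
                continue
            h_mid = (heights[n - k - 1] + heights[n - k]) / 2.0
            by_k = bp.cut_tree(tree, ids, k=k)
            by_h = bp.cut_tree(tree, ids, height=h_mid)
            assert by_k.labels == by_h.labels
            checked += 1
        assert checked >= 2

    def test_planted_families_recovered(self, planted_families,
                                        planted_identity_matrix):
        from sklearn.metrics import adjusted_rand_score
        spec, records, truth = planted_families
        tree = bp.hierarchical_cluster(planted_identity_matrix.distance())
        cut = bp.cut_tree(tree, planted_identity_matrix.ids, k=spec.n_families)
        found = [cut.labels[r.id] for r in records]
        assert adjusted_rand_score(truth, found) == 1.0


# ---------------------------------------------------------------------------
# filtering, selection, summary
# ---------------------------------------------------------------------------

class TestFilter:
    def test_short_sequence_discarded_for_length(self):
        records = [make_record("short", "M" * 209), make_record("ok", "M" * 471)]
        kept, discarded = bp.filter_candidates(
            records, bp.FilterRules(min_length=300))
        assert [r.id for r in kept] == ["ok"]
        assert discarded[0][0].id == "short"
        assert "length" in discarded[0][1]

    def test_pathogen_flag_excluded(self):
        records = [make_record("p", "MKWL" * 100, pathogenic_host=True),
                   make_record("s", "MKWL" * 100, pathogenic_host=False)]
        kept, discarded = bp.filter_candidates(
            records, bp.FilterRules(exclude_flags=("pathogenic_host",)))
        assert [r.id for r in kept] == ["s"]
        assert "pathogenic_host" in discarded[0][1]

    def test_empty_rules_keep_all(self):
        records = [make_record("a", "MK"), make_record("b", "MKW")]
        kept, discarded = bp.filter_candidates(records, None)
        assert kept == records and discarded == []

    def test_mass_window(self):
        # ~50 kDa corresponds to roughly 450 residues of average mass ~110 Da
        records = [make_record("big", "W" * 600), make_record("mid", "A" * 650)]
        # tryptophan-only 600-mer is ~112 kDa; alanine 650-mer is ~46 kDa
        kept, discarded = bp.filter_candidates(
            records, bp.FilterRules(mass_window_kda=(40.0, 60.0)))
        assert [r.id for r in kept] == ["mid"]
        assert "mass" in discarded[0][1]

    def test_mass_matches_biopython(self):
        from Bio.SeqUtils import molecular_weight
        seq = "MKWLACDEFGHIKLMNPQRSTVWY" * 3
        rec = make_record("m", seq)
        expected = molecular_weight(seq, seq_type="protein") / 1000.0
        assert rec.theoretical_mass_kda() == pytest.approx(expected, rel=1e-6)


class TestSelectRepresentatives:
    def _setup(self):
        records = [
            make_record("a1", "MKWLACDEMKWLACDE"),
            make_record("a2", "MKWLACDEMKWLACDD"),
            make_record("b1", "GGGGPPPPGGGGPPPP"),
            make_record("c1", "YYYYTTTTYYYYTTTT", pathogenic_host=True),
            make_record("c2", "YYYYTTTTYYYYTTTC"),
        ]
        matrix = bp.identity_matrix(records)
        labels = {"a1": 1, "a2": 1, "b1": 2, "c1": 3, "c2": 3}
        return records, matrix, bp.ClusterAssignment(labels=labels, k=3)

    def test_one_per_cluster_all_admissible(self):
        records, matrix, assignment = self._setup()
        selected, empty = bp.select_representatives(assignment, records, matrix)
        assert len(selected) == 3
        assert empty == []
        assert len({assignment.labels[r.id] for r in selected}) == 3

    def test_filters_respected(self):
        records, matrix, assignment = self._setup()
        rules = bp.FilterRules(exclude_flags=("pathogenic_host",))
        selected, _ = bp.select_representatives(assignment, records, matrix, rules)
        chosen_in_3 = [r for r in selected if assignment.labels[r.id] == 3]
        assert [r.id for r in chosen_in_3] == ["c2"]

    def test_fully_inadmissible_cluster_reported(self):
        records, matrix, assignment = self._setup()
        rules = bp.FilterRules(max_length=15)  # kills nobody except... all are 16
        selected, empty = bp.select_representatives(assignment, records, matrix,
                                                    rules)
        assert selected == []
        assert empty == [1, 2, 3]

    def test_single_admissible_record(self):
        records = [make_record("only", "MKWLACDE"), make_record("pad", "MKYLACDE")]
        matrix = bp.identity_matrix(records)
        assignment = bp.ClusterAssignment(labels={"only": 1, "pad": 2}, k=2)
        selected, _ = bp.select_representatives(assignment, records, matrix)
        assert selected[0].id == "only"


class TestClusterSummary:
    def test_single_record(self):
        s = bp.cluster_summary([make_record("x", "M" * 471)])
        assert (s.n, s.mean, s.sd, s.min, s.max) == (1, 471.0, 0.0, 471, 471)

    def test_range_endpoints(self):
        s = bp.cluster_summary([make_record("a", "M" * 209),
                                make_record("b", "M" * 568)])
        assert (s.min, s.max) == (209, 568)

    def test_matches_numpy_recomputation(self, planted_families):
        _, records, _ = planted_families
        s = bp.cluster_summary(records)
        lengths = np.array([r.length for r in records])
        assert s.mean == pytest.approx(lengths.mean())
        assert s.sd == pytest.approx(lengths.std(ddof=1))
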