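import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from ugtfam.motif_mining import PSPGBox
from ugtfam.phylogeny import (
    NOVEL_CANDIDATE,
    Alignment,
    TreeSizeError,
    UndefinedDistanceError,
    assign_groups,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    p_distance,
    robinson_foulds,
)
from ugtfam.synthetic_data import FamilySpec, make_family, random_additive_tree

from conftest import random_protein


def _random_alignment(rng, n_rows=6, n_cols=44, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    rows = tuple(random_protein(rng, n_cols, alphabet) for _ in range(n_rows))
    return Alignment(tuple(f"s{i}" for i in range(n_rows)), rows)


class TestPDistance:
    def test_identical_rows_are_zero(self):
        row = "W" * 44
        assert p_distance(row, row) == 0.0

    def test_quarter_difference(self):
        a = "A" * 44
        b = "C" * 11 + "A" * 33
        assert p_distance(a, b) == pytest.approx(11 / 44)

    def test_pairwise_deletion_of_gaps_and_x(self):
        # 2 comparable sites, 1 differing
        assert p_distance("AC-X", "AG-A") == pytest.approx(0.5)

    def test_no_comparable_sites_is_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("XX--", "AAXX")

    def test_matches_sitewise_counting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = random_protein(rng, 44, "ACDGX-")
            b = random_protein(rng, 44, "ACDGX-")
            comparable = [
                (x, y)
                for x, y in zip(a, b)
                if x not in "-X" and y not in "-X"
            ]
            if not comparable:
                continue
            expected = sum(x != y for x, y in comparable) / len(comparable)
            assert p_distance(a, b) == pytest.approx(expected)


class TestDistanceMatrix:
    def test_identical_pair_has_zero_off_diagonal(self):
        aln = Alignment(("a", "b", "c"), ("WWWW", "WWWW", "WWAA"))
        dm = distance_matrix(aln)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == pytest.approx(0.5)

    def test_matches_scalar_p_distance_per_pair(self):
        rng = np.random.default_rng(11)
        aln = _random_alignment(rng, n_rows=8, alphabet="ACDGX-W")
        dm = distance_matrix(aln)
        for i, la in enumerate(aln.labels):
            for lb in aln.labels[i + 1:]:
                ra = aln.rows[aln.labels.index(la)]
                rb = aln.rows[aln.labels.index(lb)]
                assert dm[la, lb] == pytest.approx(p_distance(ra, rb))

    def test_alignment_validation(self):
        with pytest.raises(ValueError):
            Alignment(("a",), ("WW",))
        with pytest.raises(ValueError):
            Alignment(("a", "b"), ("WW", "WWW"))
        with pytest.raises(ValueError):
            Alignment(("a", "a"), ("WW", "WW"))


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_solve_path_equations(self):
        dm = DistanceMatrix(
            [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]], ids=["A", "B", "C"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_four_taxon_additive_matrix_recovered(self):
        ids = ["A", "B", "C", "D"]
        data = np.array(
            [
                [0, 0.3, 0.45, 0.55],
                [0.3, 0, 0.55, 0.65],
                [0.45, 0.55, 0, 0.7],
                [0.55, 0.65, 0.7, 0],
            ]
        )
        dm = DistanceMatrix(data, ids=ids)
        tree = neighbor_joining(dm)
        assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})
        paths = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert abs(paths[a, b] - dm[a, b]) < 1e-9

    def test_fewer_than_three_labels_rejected(self):
        dm = DistanceMatrix([[0, 0.1], [0.1, 0]], ids=["A", "B"])
        with pytest.raises(TreeSizeError):
            neighbor_joining(dm)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(3)
        tree = random_additive_tree(8, seed=3)
        dm = tree.tip_tip_distances()
        base = neighbor_joining(dm)
        perm = list(dm.ids)
        rng.shuffle(perm)
        permuted = DistanceMatrix(
            [[dm[a, b] for b in perm] for a in perm], ids=perm
        )
        assert bipartitions(neighbor_joining(permuted)) == bipartitions(base)

    def test_recovers_random_additive_trees(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 13))
            truth = random_additive_tree(n, seed=rng)
            dm = truth.tip_tip_distances()
            tree = neighbor_joining(dm)
            assert robinson_foulds(tree, truth) == 0
            paths = tree.tip_tip_distances()
            for i, a in enumerate(dm.ids):
                for b in dm.ids[i + 1:]:
                    assert abs(paths[a, b] - dm[a, b]) < 1e-9

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check topology against scikit-bio's own NJ."""
        for seed in (1, 2, 3):
            truth = random_additive_tree(7, seed=seed)
            dm = truth.tip_tip_distances()
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm)
            assert bipartitions(ours) == bipartitions(theirs)

    def test_negative_estimates_clamped_to_zero(self):
        # non-additive matrix known to produce a negative NJ estimate
        data = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.05],
                [0.6, 0.6, 0.05, 0.0],
            ]
        )
        dm = DistanceMatrix(data, ids=["A", "B", "C", "D"])
        tree = neighbor_joining(dm)
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0


class TestBootstrap:
    def _congruent_alignment(self):
        # every column carries the same AB|CD split
        return Alignment(
            ("A", "B", "C", "D"),
            ("AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"),
        )

    def test_fully_congruent_alignment_gives_support_100(self):
        tree = bootstrap_support(self._congruent_alignment(), n_replicates=25, seed=0)
        supports = [
            node.support for node in tree.non_tips(include_self=False)
        ]
        assert supports == [100.0]

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(13)
        aln = _random_alignment(rng, n_rows=10)
        t1 = bootstrap_support(aln, n_replicates=100, seed=5)
        t2 = bootstrap_support(aln, n_replicates=100, seed=5)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            aln = _random_alignment(rng, n_rows=6)
            tree = bootstrap_support(aln, n_replicates=1, seed=int(rng.integers(1000)))
            for node in tree.non_tips(include_self=False):
                assert node.support in (0.0, 100.0)

    def test_supports_bounded_on_random_alignments(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            aln = _random_alignment(rng, n_rows=7)
            tree = bootstrap_support(aln, n_replicates=20, seed=int(rng.integers(1000)))
            for node in tree.non_tips(include_self=False):
                assert 0.0 <= node.support <= 100.0

    def test_supports_serialise_as_internal_newick_labels(self, tmp_path):
        tree = bootstrap_support(self._congruent_alignment(), n_replicates=10, seed=1)
        path = tmp_path / "t.nwk"
        tree.write(str(path), format="newick")
        parsed = dendropy.Tree.get(path=str(path), schema="newick",
                                   suppress_internal_node_taxa=False)
        internal_labels = {
            n.label or (n.taxon.label if n.taxon else None)
            for n in parsed.preorder_internal_node_iter()
        }
        assert "100" in internal_labels


class TestAssignGroups:
    def _supported_tree(self, alignment, seed=0):
        return bootstrap_support(alignment, n_replicates=50, seed=seed)

    def test_query_assigned_to_nearest_reference(self):
        aln = Alignment(
            ("refL", "q1", "refE", "q2"),
            ("AAAAAAAAAA", "AAAAAAAAAC", "GGGGGGGGGG", "GGGGGGGGGC"),
        )
        tree = self._supported_tree(aln)
        assignments = {
            a.label: a for a in assign_groups(tree, {"refL": "L", "refE": "E"})
        }
        assert assignments["q1"].group == "L"
        assert assignments["q1"].nearest_reference == "refL"
        assert assignments["q2"].group == "E"

    def test_references_self_assign(self):
        aln = Alignment(
            ("r1", "r2", "q"),
            ("AAAA", "CCCC", "AAAC"),
        )
        tree = self._supported_tree(aln)
        assignments = {a.label: a for a in assign_groups(tree, {"r1": "A", "r2": "B"})}
        assert assignments["r1"].group == "A" and assignments["r1"].is_reference
        assert assignments["r2"].group == "B" and assignments["r2"].is_reference

    def test_supported_reference_free_clade_flagged_novel(self):
        # three tight queries far from both references
        aln = Alignment(
            ("refA", "refB", "n1", "n2", "n3"),
            (
                "AAAAAAAAAAAAAAAAAAAA",
                "AAAAAAAAACCCCCCCCCCC",
                "GGGGGGGGGGGGGGGGGGGG",
                "GGGGGGGGGGGGGGGGGGGT",
                "GGGGGGGGGGGGGGGGGGTT",
            ),
        )
        tree = self._supported_tree(aln, seed=2)
        assignments = {
            a.label: a for a in assign_groups(tree, {"refA": "A", "refB": "B"})
        }
        for q in ("n1", "n2", "n3"):
            assert assignments[q].group == NOVEL_CANDIDATE
            assert assignments[q].clade_support >= 60.0

    def test_novel_override_requires_min_size(self):
        aln = Alignment(
            ("refA", "refB", "n1", "n2", "n3"),
            (
                "AAAAAAAAAAAAAAAAAAAA",
                "AAAAAAAAACCCCCCCCCCC",
                "GGGGGGGGGGGGGGGGGGGG",
                "GGGGGGGGGGGGGGGGGGGT",
                "GGGGGGGGGGGGGGGGGGTT",
            ),
        )
        tree = self._supported_tree(aln, seed=2)
        assignments = assign_groups(
            tree, {"refA": "A", "refB": "B"}, novel_min_size=4
        )
        assert all(a.group != NOVEL_CANDIDATE for a in assignments)

    def test_assignment_is_total(self):
        aln = Alignment(
            ("r", "q1", "q2", "q3"),
            ("AAAA", "AAAC", "AACC", "ACCC"),
        )
        tree = self._supported_tree(aln)
        assignments = assign_groups(tree, {"r": "D"})
        assert sorted(a.label for a in assignments) == ["q1", "q2", "q3", "r"]

    def test_missing_reference_label_raises(self):
        aln = Alignment(("a", "b", "c"), ("AAAA", "AACC", "CCCC"))
        tree = self._supported_tree(aln)
        with pytest.raises(KeyError):
            assign_groups(tree, {"zz": "A"})

    def test_group_recovery_on_synthetic_families(self):
        """>= 95% of queries get their generating group back when groups
        are 3x more divergent between than within (50 replicates)."""
        correct = total = 0
        for seed in range(50):
            spec = FamilySpec(
                n_groups=4, members_per_group=6, seed=seed,
            )
            records, truth = make_family(spec)
            boxes = [
                PSPGBox(r.id, r.sequence[truth[r.id].box_start:][:44])
                for r in records
            ]
            aln = Alignment.from_boxes(boxes)
            tree = neighbor_joining(distance_matrix(aln))
            refs = {f"G{g}_M01": f"G{g}" for g in range(1, 5)}
            for a in assign_groups(tree, refs):
                if a.is_reference:
                    continue
                total += 1
                correct += a.group == truth[a.label].group
        assert correct / total >= 0.95
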