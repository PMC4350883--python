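"""Distances, Poisson correction, coverage filtering, NJ, bootstrap, monophyly."""

import itertools
import math

import numpy as np
import pytest
import skbio

import wrkykit as w
from wrkykit import phylo
from wrkykit.errors import DegenerateDistance, DomainError, PreconditionError


def aln(*rows):
    return [w.SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]


class TestPDistance:
    def test_identical_rows_are_zero(self):
        dm = w.p_distance(aln("ACDEF", "ACDEF", "ACDEF"))
        assert np.allclose(dm.d, 0)

    def test_single_difference(self):
        dm = w.p_distance(aln("AAAA", "AAAT"))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_drops_gap_columns_per_pair(self):
        dm = w.p_distance(aln("A-AA", "AGAT"), deletion="pairwise")
        assert dm.comparable_sites[0, 1] == 3
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion_drops_columns_globally(self):
        rows = aln("A-AA", "AGAT", "AGAA")
        pw = w.p_distance(rows, deletion="pairwise")
        comp = w.p_distance(rows, deletion="complete")
        # the gap column is dropped for every pair in complete mode
        assert comp.comparable_sites[1, 2] == 3 < pw.comparable_sites[1, 2]
        assert (pw.comparable_sites >= comp.comparable_sites).all()

    def test_no_comparable_sites_raises_named_pair(self):
        with pytest.raises(DegenerateDistance) as err:
            w.p_distance(aln("A--", "-AA", "AAA"))
        assert err.value.pair == ("s0", "s1")

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(5)
        rows = aln(*(
            "".join(rng.choice(list("ACDEFG-"), size=40)) for _ in range(6)
        ))
        dm = w.p_distance(rows)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)


class TestPoissonCorrection:
    def test_zero_maps_to_zero(self):
        assert w.poisson_correct(0.0) == 0.0

    def test_closed_form_value(self):
        assert w.poisson_correct(0.25) == pytest.approx(0.2876821, abs=1e-7)

    def test_matches_closed_form_on_grid_and_dominates_p(self):
        for p in np.linspace(0.0, 0.99, 100):
            d = w.poisson_correct(p)
            assert d == pytest.approx(-math.log(1 - p))
            assert d >= p

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 0.99, 50)
        values = [w.poisson_correct(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_p_of_one_rejected(self):
        with pytest.raises(DomainError):
            w.poisson_correct(1.0)


class TestSiteCoverageFilter:
    def test_gapless_alignment_unchanged(self):
        rows = aln("ACDE", "ACDF")
        out = w.site_coverage_filter(rows, 0.95)
        assert [r.residues for r in out] == ["ACDE", "ACDF"]

    def test_boundary_coverage_retained(self):
        # 20 rows, one column with exactly one gap: coverage 0.95 is kept
        # under the strict "< threshold is eliminated" rule
        rows = [w.SequenceRecord(f"s{i}", "A" + ("-" if i == 0 else "C"))
                for i in range(20)]
        out = w.site_coverage_filter(rows, 0.95)
        assert all(len(r.residues) == 2 for r in out)

    def test_below_threshold_removed(self):
        # 10 rows, one column with two gaps: coverage 0.8 < 0.95
        rows = [w.SequenceRecord(f"s{i}", "A" + ("-" if i < 2 else "C"))
                for i in range(10)]
        out = w.site_coverage_filter(rows, 0.95)
        assert all(r.residues == "A" for r in out)

    def test_x_counts_as_missing(self):
        rows = [w.SequenceRecord(f"s{i}", "A" + ("X" if i < 2 else "C"))
                for i in range(10)]
        out = w.site_coverage_filter(rows, 0.95)
        assert all(r.residues == "A" for r in out)

    def test_all_columns_removed_warns(self):
        rows = aln("A-", "-A")
        with pytest.warns(UserWarning):
            w.site_coverage_filter(rows, 0.95)

    def test_study_scale_filter_matches_independent_column_count(self):
        """On a large gappy alignment the retained set equals an independent
        per-column coverage computation."""
        rng = np.random.default_rng(6)
        n_rows, n_cols = 300, 120
        mat = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=(n_rows, n_cols))
        gap_prob = rng.uniform(0, 0.15, size=n_cols)
        gaps = rng.random((n_rows, n_cols)) < gap_prob
        mat[gaps] = "-"
        rows = [w.SequenceRecord(f"s{i}", "".join(mat[i])) for i in range(n_rows)]
        out = w.site_coverage_filter(rows, 0.95)
        expected_cols = [
            j for j in range(n_cols)
            if (mat[:, j] != "-").sum() / n_rows >= 0.95
        ]
        assert len(out) == n_rows
        assert len(out[0].residues) == len(expected_cols)
        assert out[0].residues == "".join(mat[0, expected_cols])


def random_binary_tree(rng, n_leaves):
    names = [f"t{i}" for i in range(n_leaves)]
    nodes = [skbio.TreeNode(name=n, length=float(rng.uniform(0.1, 1.0))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = skbio.TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.append(nodes[j])
        parent.append(nodes[i])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode()
    for n in nodes:
        root.append(n)
    return root, names


def path_distance_matrix(root, names):
    n = len(names)
    d = np.zeros((n, n))
    tips = {t.name: t for t in root.tips()}
    for a, b in itertools.combinations(range(n), 2):
        d[a, b] = d[b, a] = tips[names[a]].distance(tips[names[b]])
    return phylo.DistanceMatrix(names, d, np.ones((n, n), dtype=int))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = w.nj_tree(phylo.DistanceMatrix(["a", "b", "c"], d, np.ones((3, 3), int)))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_recovers_topology_from_additive_distances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            root, names = random_binary_tree(rng, n)
            tree = w.nj_tree(path_distance_matrix(root, names))
            assert phylo.bipartitions(tree) == phylo.bipartitions(root)

    def test_agrees_with_scikit_bio_on_random_matrices(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(8)
        for _ in range(10):
            n = 6
            m = rng.uniform(0.1, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            names = [f"x{i}" for i in range(n)]
            ours = w.nj_tree(phylo.DistanceMatrix(names, m, np.ones((n, n), int)))
            theirs = sknj(SkDM(m, names))
            assert phylo.bipartitions(ours) == phylo.bipartitions(theirs)

    def test_equal_distances_resolve_deterministically(self):
        n = 5
        m = np.full((n, n), 0.5)
        np.fill_diagonal(m, 0)
        names = [f"x{i}" for i in range(n)]
        dm = phylo.DistanceMatrix(names, m, np.ones((n, n), int))
        t1 = w.write_newick(w.nj_tree(dm))
        t2 = w.write_newick(w.nj_tree(dm))
        assert t1 == t2

    def test_fewer_than_three_taxa_rejected(self):
        m = np.array([[0.0, 0.1], [0.1, 0.0]])
        with pytest.raises(PreconditionError):
            w.nj_tree(phylo.DistanceMatrix(["a", "b"], m, np.ones((2, 2), int)))


class TestMonophyly:
    def test_single_taxon_and_full_set_trivially_monophyletic(self):
        tree = w.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert w.is_monophyletic(tree, {"a"})
        assert w.is_monophyletic(tree, {"a", "b", "c", "d"})

    def test_clade_versus_mixed_set(self):
        tree = w.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert w.is_monophyletic(tree, {"a", "b"})
        assert not w.is_monophyletic(tree, {"a", "c"})

    def test_unknown_taxon_rejected(self):
        tree = w.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(PreconditionError):
            w.is_monophyletic(tree, {"a", "zzz"})


def two_clade_alignment(seed=3, n_per_clade=5, length=120):
    """Two well-separated clades: within-clade p ~ 0.02, between ~ 0.5."""
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGIKLMNPQRSTVY")
    anc_a = rng.choice(aa, size=length)
    anc_b = anc_a.copy()
    flip = rng.random(length) < 0.5
    for i in np.where(flip)[0]:
        anc_b[i] = rng.choice([c for c in aa if c != anc_b[i]])
    rows = []
    for label, anc in (("A", anc_a), ("B", anc_b)):
        for k in range(n_per_clade):
            seq = anc.copy()
            mut = rng.random(length) < 0.02
            for i in np.where(mut)[0]:
                seq[i] = rng.choice([c for c in aa if c != seq[i]])
            rows.append(w.SequenceRecord(f"{label}{k}", "".join(seq)))
    return rows


class TestBootstrap:
    def test_planted_clade_separation_has_full_support(self):
        rows = two_clade_alignment(seed=3)
        tree, support = w.bootstrap_support(rows, n_replicates=200, seed=3)
        clade_a = frozenset(r.id for r in rows if r.id.startswith("A"))
        leaves = frozenset(t.name for t in tree.tips())
        canon = clade_a if min(leaves) not in clade_a else leaves - clade_a
        assert w.is_monophyletic(tree, clade_a)
        assert support[canon] == pytest.approx(1.0)

    def test_same_seed_reproduces_supports(self):
        rows = two_clade_alignment(seed=4, n_per_clade=4, length=60)
        _, s1 = w.bootstrap_support(rows, n_replicates=50, seed=11)
        _, s2 = w.bootstrap_support(rows, n_replicates=50, seed=11)
        assert s1 == s2

    def test_single_replicate_supports_are_binary(self):
        rows = two_clade_alignment(seed=5, n_per_clade=4, length=60)
        _, support = w.bootstrap_support(rows, n_replicates=1, seed=1)
        assert set(support.values()) <= {0.0, 1.0}

    def test_clade_support_invariant_to_taxon_order(self):
        """The support of the planted clade split does not depend on row order.

        (Weakly supported within-clade bipartitions are not order-stable:
        identical within-clade distances tie, and NJ breaks ties by index.)
        """
        rows = two_clade_alignment(seed=6, n_per_clade=4, length=60)
        clade_a = frozenset(r.id for r in rows if r.id.startswith("A"))
        leaves = frozenset(r.id for r in rows)
        canon = clade_a if min(leaves) not in clade_a else leaves - clade_a
        _, s1 = w.bootstrap_support(rows, n_replicates=50, seed=2)
        _, s2 = w.bootstrap_support(list(reversed(rows)), n_replicates=50, seed=2)
        assert s1[canon] == s2[canon] == pytest.approx(1.0)

    def test_zero_replicates_rejected(self):
        rows = two_clade_alignment(seed=7, n_per_clade=4, length=60)
        with pytest.raises(PreconditionError):
            w.bootstrap_support(rows, n_replicates=0, seed=0)
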