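"""TN93 distances, neighbor joining, bootstrap, rooting, breakpoint scan."""

import subprocess
import textwrap

import dendropy
import numpy as np
import pytest

from kirhaplo.diversity import Alignment
from kirhaplo.phylo import (
    DistanceMatrix,
    DomainPartition,
    bootstrap_support,
    breakpoint_scan,
    clade_by_label_check,
    leaf_path_lengths,
    midpoint_root,
    nj_tree,
    p_distance,
    partition_by_domains,
    tn93_distance,
)
from kirhaplo.simulate import make_mosaic, simulate_two_clade_alignment


def tn93_closed_form(seq_x, seq_y):
    """Independent evaluation of the published TN93 closed form."""
    pairs = [(a, b) for a, b in zip(seq_x, seq_y) if a in "ACGT" and b in "ACGT"]
    L = len(pairs)
    pooled = [c for p in pairs for c in p]
    pA, pC, pG, pT = (pooled.count(b) / (2 * L) for b in "ACGT")
    pR, pY = pA + pG, pC + pT
    P1 = sum(1 for a, b in pairs if {a, b} == {"A", "G"}) / L
    P2 = sum(1 for a, b in pairs if {a, b} == {"C", "T"}) / L
    Q = sum(1 for a, b in pairs if a != b and ({a, b} not in ({"A", "G"}, {"C", "T"}))) / L
    k1 = 2 * pA * pG / pR
    k2 = 2 * pT * pC / pY
    k3 = 2 * (pR * pY - pA * pG * pY / pR - pT * pC * pR / pY)
    return (
        -k1 * np.log(1 - P1 / k1 - Q / (2 * pR))
        - k2 * np.log(1 - P2 / k2 - Q / (2 * pY))
        - k3 * np.log(1 - Q / (2 * pR * pY))
    )


from _oracles import random_additive_newick


class TestTN93:
    def test_identical_sequences_zero(self):
        aln = Alignment(("a", "b"), ("ACGTACGT", "ACGTACGT"))
        assert tn93_distance(aln).values[0, 1] == 0.0

    def test_matches_published_closed_form(self):
        """Constructed pair with P1=0.05, P2=0.03, Q=0.02."""
        L = 10_000
        quarter = L // 4
        x = "A" * quarter + "G" * quarter + "C" * quarter + "T" * quarter
        y = list(x)
        for k in range(0, 500):  # A->G transitions
            y[k] = "G"
        for k in range(5000, 5300):  # C->T transitions
            y[k] = "T"
        for k in range(2500, 2700):  # G->C transversions
            y[k] = "C"
        y = "".join(y)
        aln = Alignment(("x", "y"), (x, y))
        mine = tn93_distance(aln).values[0, 1]
        assert mine == pytest.approx(tn93_closed_form(x, y), rel=1e-12)

    def test_collapses_to_jc_under_equal_rates(self):
        """With equal base composition and P1=P2, TN93 nears the JC value."""
        rng = np.random.default_rng(0)
        aln, _, _ = simulate_two_clade_alignment(
            n_per_clade=1, inter_divergence=0.1, intra_divergence=0,
            length=50_000, kappa=1.0, seed=3,
        )
        d = tn93_distance(aln).values[0, 1]
        p = p_distance(aln).values[0, 1]
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, rel=0.02)

    def test_matches_ape_reference_implementation(self, tmp_path):
        """Cross-check against the R ape package's dist.dna TN93."""
        aln, _, _ = simulate_two_clade_alignment(
            n_per_clade=1, inter_divergence=0.1, intra_divergence=0,
            length=5000, seed=42,
        )
        fasta = tmp_path / "pair.fasta"
        with open(fasta, "w") as fh:
            for sid, row in zip(aln.ids, aln.rows):
                fh.write(f">{sid}\n{row}\n")
        script = tmp_path / "tn93.R"
        script.write_text(textwrap.dedent(f"""
            library(ape)
            seqs <- read.dna("{fasta}", format="fasta")
            d <- dist.dna(seqs, model="TN93", pairwise.deletion=TRUE)
            cat(sprintf("%.12f", as.numeric(d)))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        assert tn93_distance(aln).values[0, 1] == pytest.approx(
            float(out.stdout.strip()), abs=1e-10
        )

    def test_at_least_p_distance(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            aln, _, _ = simulate_two_clade_alignment(
                n_per_clade=2, inter_divergence=0.15, intra_divergence=0.02,
                length=2000, seed=seed,
            )
            d = tn93_distance(aln).values
            p = p_distance(aln).values
            assert (d >= p - 1e-12).all()

    def test_saturated_pair_hits_ceiling(self):
        x = "A" * 300 + "C" * 300
        y = "C" * 300 + "A" * 300
        with pytest.warns(UserWarning, match="saturated"):
            d = tn93_distance(Alignment(("x", "y"), (x, y)))
        assert d.values[0, 1] == 5.0


class TestNJ:
    def test_four_taxon_additive_example(self):
        D = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array([
                [0.0, 0.2, 0.4, 0.4],
                [0.2, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.3],
                [0.4, 0.4, 0.3, 0.0],
            ]),
        )
        tree = nj_tree(D)
        paths = leaf_path_lengths(tree)
        assert paths[("A", "B")] == pytest.approx(0.2)
        assert paths[("C", "D")] == pytest.approx(0.3)
        assert paths[("A", "C")] == pytest.approx(0.4)
        ok, _ = clade_by_label_check(midpoint_root(tree), {"A", "B"})
        assert ok

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]]),
        )
        tree = nj_tree(D)
        paths = leaf_path_lengths(tree)
        for pair, expected in ((("A", "B"), 0.3), (("A", "C"), 0.5), (("B", "C"), 0.6)):
            assert paths[pair] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_reconstructs_random_additive_trees(self, seed):
        """Path-length equivalence on random additive matrices (4-12 taxa)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = [f"T{k}" for k in range(n)]
        true = dendropy.Tree.get(data=random_additive_newick(rng, labels), schema="newick")
        truth = leaf_path_lengths(true)
        order = tuple(sorted(labels))
        mat = np.zeros((n, n))
        for (a, b), d in truth.items():
            i, j = order.index(a), order.index(b)
            mat[i, j] = mat[j, i] = d
        rec = nj_tree(DistanceMatrix(order, mat))
        paths = leaf_path_lengths(rec)
        for pair, d in truth.items():
            assert paths[pair] == pytest.approx(d, abs=1e-9)

    def test_agrees_with_dendropy_nj(self):
        """Independent oracle: dendropy's NJ on the same distance matrix."""
        aln, _, _ = simulate_two_clade_alignment(
            n_per_clade=3, inter_divergence=0.1, intra_divergence=0.02,
            length=3000, seed=5,
        )
        D = tn93_distance(aln)
        mine = leaf_path_lengths(nj_tree(D))

        pdm_csv = "," + ",".join(D.labels) + "\n"
        for i, lab in enumerate(D.labels):
            pdm_csv += lab + "," + ",".join(str(x) for x in D.values[i]) + "\n"
        import io as _io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            _io.StringIO(pdm_csv), delimiter=","
        )
        theirs = pdm.nj_tree()
        theirs_paths = {}
        their_pdm = theirs.phylogenetic_distance_matrix()
        taxa = sorted(theirs.taxon_namespace, key=lambda t: t.label)
        import itertools

        for t1, t2 in itertools.combinations(taxa, 2):
            theirs_paths[(t1.label, t2.label)] = their_pdm.patristic_distance(t1, t2)
        for pair in mine:
            assert mine[pair] == pytest.approx(theirs_paths[pair], abs=1e-9)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]))


class TestBootstrapAndRooting:
    def test_deep_clades_get_high_support(self):
        aln, g1, g2 = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.2, intra_divergence=0.01,
            length=2000, seed=7,
        )
        tree = midpoint_root(bootstrap_support(aln, B=100, seed=1))
        ok, support = clade_by_label_check(tree, g1)
        assert ok and support >= 99
        ok, support = clade_by_label_check(tree, g2)
        assert ok and support >= 99

    def test_single_replicate_support_binary(self):
        aln, _, _ = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.1, intra_divergence=0.01,
            length=500, seed=9,
        )
        tree = bootstrap_support(aln, B=1, seed=2)
        supports = [
            node.support
            for node in tree.preorder_node_iter()
            if getattr(node, "support", None) is not None
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_seeded_determinism(self):
        aln, _, _ = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.1, intra_divergence=0.01,
            length=500, seed=9,
        )
        t1 = bootstrap_support(aln, B=25, seed=3)
        t2 = bootstrap_support(aln, B=25, seed=3)
        s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
        assert s1 == s2

    def test_midpoint_two_leaves(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.3);", schema="newick")
        rooted = midpoint_root(tree)
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in rooted.leaf_node_iter()
        }
        assert depths["A"] == pytest.approx(0.2)
        assert depths["B"] == pytest.approx(0.2)

    def test_midpoint_on_internal_edge(self):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.1):0.15,(C:0.15,D:0.15):0.0);", schema="newick"
        )
        rooted = midpoint_root(tree)
        # longest path C-D? no: A-C = 0.4, C-D=0.3, A-B=0.2 -> A-C or A-D (ties on labels)
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in rooted.leaf_node_iter()
        }
        assert max(depths.values()) == pytest.approx(0.2)

    def test_rerooting_preserves_path_lengths(self):
        rng = np.random.default_rng(11)
        nwk = random_additive_newick(rng, [f"T{k}" for k in range(8)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        before = leaf_path_lengths(tree)
        after = leaf_path_lengths(midpoint_root(tree))
        for pair in before:
            assert after[pair] == pytest.approx(before[pair], abs=1e-9)


class TestDomains:
    def test_partition_slices_and_lengths(self):
        aln = Alignment(("a", "b"), ("ACGTACGTAC", "ACGTACGTAC"))
        part = DomainPartition((("five_prime", 0, 6), ("three_prime", 6, 10)))
        domains = partition_by_domains(aln, part)
        assert [(name, sub.length) for name, sub in domains] == [
            ("five_prime", 6),
            ("three_prime", 4),
        ]
        assert sum(sub.length for _, sub in domains) == 10

    def test_empty_partition(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
        assert partition_by_domains(aln, DomainPartition(())) == []

    def test_overlap_rejected(self):
        aln = Alignment(("a", "b"), ("ACGTACGT", "ACGTACGT"))
        with pytest.raises(ValueError, match="overlap"):
            partition_by_domains(aln, DomainPartition((("x", 0, 5), ("y", 4, 8))))

    def test_clade_query_on_known_topology(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        assert clade_by_label_check(tree, {"A", "B"})[0] is True
        assert clade_by_label_check(tree, {"A", "C"})[0] is False
        with pytest.raises(ValueError, match="unknown"):
            clade_by_label_check(tree, {"A", "Z"})

    def test_mosaic_regions_give_conflicting_clades(self):
        """Two-region mosaic: each region clusters by a different grouping."""
        a1, g1a, g1b = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.15, intra_divergence=0.01,
            length=1500, seed=13, labels=("W", "X"),
        )
        # second region groups (W1,X1) vs (W2,X2): swap rows to re-pair
        a2, _, _ = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.15, intra_divergence=0.01,
            length=1500, seed=14, labels=("W", "X"),
        )
        rows2 = dict(zip(a2.ids, a2.rows))
        merged = Alignment(
            a1.ids,
            tuple(
                a1.rows[k] + rows2[other]
                for k, other in enumerate(["W1", "X1", "W2", "X2"])
            ),
        )
        part = DomainPartition((("left", 0, 1500), ("right", 1500, 3000)))
        trees = {
            name: midpoint_root(nj_tree(tn93_distance(sub)))
            for name, sub in partition_by_domains(merged, part)
        }
        assert clade_by_label_check(trees["left"], {"W1", "W2"})[0] is True
        assert clade_by_label_check(trees["right"], {"W1", "W2"})[0] is False
        assert clade_by_label_check(trees["right"], {"W1", "X1"})[0] is True


class TestBreakpointScan:
    def _mosaic_fixture(self, seed, bp=500, inter=0.05, length=1000):
        aln, ga, gb = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=inter, intra_divergence=0.0,
            length=length, seed=seed,
        )
        mosaic = make_mosaic(aln.rows[0], aln.rows[2], [bp])
        full = Alignment(aln.ids + ("M",), aln.rows + (mosaic,))
        return full, ga | {"M"}, gb | {"M"}

    def test_localizes_known_breakpoint(self):
        full, g1, g2 = self._mosaic_fixture(seed=21)
        res = breakpoint_scan(full, g1, g2, n_permutations=199, seed=1)
        assert res.breakpoint is not None
        assert abs(res.breakpoint - 500) <= 25
        assert res.p_value < 0.05

    def test_homogeneous_alignment_not_significant(self):
        """Permutation null calibration: no mosaic -> high p-value."""
        aln, ga, gb = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.05, intra_divergence=0.01,
            length=1000, seed=23,
        )
        # non-mosaic sequence: grouping2 pairs one leaf from each clade
        res = breakpoint_scan(
            aln, ga, {"A1", "B1"}, n_permutations=499, seed=2
        )
        assert res.p_value > 0.05

    def test_one_sided_support_no_breakpoint(self):
        aln, ga, gb = simulate_two_clade_alignment(
            n_per_clade=2, inter_divergence=0.05, intra_divergence=0.0,
            length=1000, seed=25,
        )
        res = breakpoint_scan(aln, ga, {"A1", "B1"}, n_permutations=99, seed=3)
        assert set(res.categories) == {1}
        assert res.breakpoint is None

    def test_no_informative_columns_rejected(self):
        aln = Alignment(("a", "b", "c", "d"), ("ACGT",) * 4)
        with pytest.raises(ValueError, match="informative"):
            breakpoint_scan(aln, {"a", "b"}, {"a", "c"})
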