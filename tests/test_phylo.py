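"""Ortholog clustering, center-star supermatrices, NJ exactness on additive
matrices, and bootstrap supports."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from oracles import gotoh_score, optimal_sp_cost_3, sp_cost_msa
from taxodelim.align import AA_SCHEME, SchemeSpec
from taxodelim.errors import InputError, UndefinedMetricError
from taxodelim.metrics import AaiParams
from taxodelim.phylo import (
    Supermatrix,
    align_and_concatenate,
    bipartitions,
    bootstrap,
    center_star_align,
    distance_matrix,
    nj_tree,
    rbh_pairs,
    single_copy_clusters,
    to_newick,
)
from taxodelim.records import SeqRecord
from taxodelim.simulate import make_additive_tree_matrix, make_proteome_pair

from conftest import random_protein


def _clone(prots, prefix):
    return [SeqRecord(f"{prefix}_{p.id.split('_', 1)[1]}", p.residues) for p in prots]


class TestRbh:
    def test_identical_proteomes_pair_every_protein(self):
        prots = [SeqRecord(f"A_p{i}", random_protein(np.random.default_rng(i), 100)) for i in range(5)]
        other = _clone(prots, "B")
        pairs = rbh_pairs(prots, other)
        assert sorted(pairs) == [(f"A_p{i}", f"B_p{i}") for i in range(5)]

    def test_disjoint_proteomes_no_pairs(self):
        pa = [SeqRecord(f"a{i}", random_protein(np.random.default_rng(900 + i), 90)) for i in range(3)]
        pb = [SeqRecord(f"b{i}", random_protein(np.random.default_rng(990 + i), 90)) for i in range(3)]
        assert rbh_pairs(pa, pb) == []

    def test_matches_exhaustive_mutual_best_oracle(self):
        proteomes, _ = make_proteome_pair(4, 1.0, 75.0, seed=17, length=40)
        pa, pb = proteomes["A"], proteomes["B"]

        def sub(x, y):
            return AA_SCHEME.substitution_score(x, y)

        def best(queries, subjects):
            out = {}
            for q in queries:
                scored = sorted(
                    (
                        (-gotoh_score(q.residues, s.residues, sub, 11, 1, local=True), s.id)
                        for s in subjects
                    )
                )
                out[q.id] = scored[0][1]
            return out

        fwd, rev = best(pa, pb), best(pb, pa)
        oracle = sorted(
            (a, b) for a, b in fwd.items() if rev.get(b) == a
        )
        got = sorted(rbh_pairs(pa, pb, AaiParams(min_alignment_length=10, min_coverage=0.5)))
        assert got == oracle


class TestClusters:
    def _proteomes(self, n_strains=3, n_families=4, seed=0):
        strains = [f"S{i}" for i in range(n_strains)]
        proteomes = {s: [] for s in strains}
        for fam in range(n_families):
            ancestor = random_protein(np.random.default_rng(seed * 100 + fam), 120)
            for k, s in enumerate(strains):
                rng = np.random.default_rng(seed * 1000 + fam * 10 + k)
                mut = list(ancestor)
                for pos in rng.choice(len(mut), size=12, replace=False):
                    mut[pos] = "W" if mut[pos] != "W" else "Y"
                proteomes[s].append(SeqRecord(f"{s}_f{fam}", "".join(mut)))
        return proteomes

    def test_identical_proteomes_give_one_cluster_per_protein(self):
        prots = [SeqRecord(f"A_p{i}", random_protein(np.random.default_rng(40 + i), 110)) for i in range(4)]
        proteomes = {"A": prots, "B": _clone(prots, "B"), "C": _clone(prots, "C")}
        clusters = single_copy_clusters(proteomes)
        assert len(clusters) == 4
        for c in clusters:
            assert len(c.members) == 3

    def test_planted_universal_families_recovered_among_decoys(self):
        proteomes = self._proteomes(n_strains=4, n_families=5, seed=3)
        # decoys: strain-unique proteins plus an in-strain paralog pair
        for s in proteomes:
            rng = np.random.default_rng(hash(s) % 2**32)
            proteomes[s].append(SeqRecord(f"{s}_unique", random_protein(rng, 120)))
        clusters = single_copy_clusters(proteomes)
        assert len(clusters) == 5

    def test_family_missing_in_one_strain_is_excluded(self):
        proteomes = self._proteomes(n_strains=3, n_families=4, seed=5)
        proteomes["S0"] = proteomes["S0"][:-1]  # drop one family from S0
        clusters = single_copy_clusters(proteomes)
        assert len(clusters) == 3

    def test_cluster_count_invariant_to_strain_order(self):
        proteomes = self._proteomes(n_strains=3, n_families=4, seed=7)
        a = single_copy_clusters(proteomes)
        reordered = {k: proteomes[k] for k in reversed(list(proteomes))}
        b = single_copy_clusters(reordered)
        assert [c.members for c in a] == [c.members for c in b]

    def test_requires_three_strains(self):
        with pytest.raises(InputError):
            single_copy_clusters({"A": [], "B": []})


class TestCenterStar:
    def test_identical_sequences_align_gap_free(self):
        seqs = [("a", "MKVLAW"), ("b", "MKVLAW"), ("c", "MKVLAW")]
        msa = center_star_align(seqs)
        assert all(row == "MKVLAW" for row in msa.values())

    def test_concatenated_width_is_sum_of_cluster_widths(self):
        prots = {
            "A": [SeqRecord("A_x", "MKVLAWQERT"), SeqRecord("A_y", "M" * 20)],
            "B": [SeqRecord("B_x", "MKVLAWQERT"), SeqRecord("B_y", "M" * 20)],
            "C": [SeqRecord("C_x", "MKVLAWQERT"), SeqRecord("C_y", "M" * 20)],
        }
        toy = AaiParams(min_alignment_length=5, min_coverage=0.5)
        clusters = single_copy_clusters(prots, toy)
        sm = align_and_concatenate(clusters, prots)
        assert sm.width == 30
        assert [(c, s, e) for c, s, e in sm.partitions] == [("OG0001", 0, 10), ("OG0002", 10, 30)]
        assert all("-" not in row for row in sm.rows.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_center_star_cost_within_twice_optimal(self, seed):
        # unit-cost scheme: score = -cost, so center selection minimises cost
        rng = np.random.default_rng(3100 + seed)
        unit = SchemeSpec("protein", match=0.0, mismatch=-1.0, gap_open=0.0, gap_extend=1.0)
        seqs = [("s%d" % i, random_protein(rng, int(rng.integers(4, 9)))) for i in range(3)]
        msa = center_star_align(seqs, unit)
        cost = sp_cost_msa(list(msa.values()))
        optimal = optimal_sp_cost_3(seqs[0][1], seqs[1][1], seqs[2][1])
        assert cost <= 2 * optimal


class TestDistance:
    def _sm(self, rows):
        return Supermatrix(rows=rows, partitions=())

    def test_identical_rows_zero(self):
        sm = self._sm({"A": "MKVL", "B": "MKVL", "C": "MKVL"})
        dm = distance_matrix(sm)
        assert np.allclose(dm.data, 0.0)

    def test_quarter_p_distance(self):
        sm = self._sm({"A": "AAAA", "B": "AAAT", "C": "AAAA"})
        dm = distance_matrix(sm)
        assert dm["A", "B"] == pytest.approx(0.25)

    def test_gapped_columns_excluded(self):
        sm = self._sm({"A": "MK-L", "B": "MKVL", "C": "MKVL"})
        assert distance_matrix(sm)["A", "B"] == 0.0

    def test_poisson_undefined_at_saturation(self):
        sm = self._sm({"A": "AAAA", "B": "TTTT", "C": "AAAA"})
        with pytest.raises(UndefinedMetricError):
            distance_matrix(sm, model="poisson")

    def test_poisson_transform(self):
        sm = self._sm({"A": "AAAA", "B": "AAAT", "C": "AAAA"})
        dm = distance_matrix(sm, model="poisson")
        assert dm["A", "B"] == pytest.approx(-np.log(0.75))


class TestNj:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_recovered_exactly(self, seed):
        n = 4 + seed % 5
        dm, truth = make_additive_tree_matrix(n, 4200 + seed)
        tree = nj_tree(dm)
        got, want = bipartitions(tree), bipartitions(truth)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9)
        tl_got = {t.name: t.length for t in tree.tips()}
        tl_want = {t.name: t.length for t in truth.tips()}
        assert tl_got == pytest.approx(tl_want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_topology_agrees_with_reference_nj(self, seed):
        dm, _ = make_additive_tree_matrix(6, 5200 + seed)
        mine = bipartitions(nj_tree(dm))
        reference = bipartitions(skbio_nj(dm))
        assert set(mine) == set(reference)

    def test_taxon_permutation_leaves_topology_invariant(self):
        dm, _ = make_additive_tree_matrix(6, 77)
        perm = list(dm.ids)[::-1]
        assert set(bipartitions(nj_tree(dm))) == set(bipartitions(nj_tree(dm.filter(perm))))

    def test_outgroup_rooting(self):
        dm, _ = make_additive_tree_matrix(5, 88)
        tree = nj_tree(dm, outgroup="T00")
        root_children = tree.children
        assert len(root_children) == 2
        assert any(c.name == "T00" for c in root_children)

    def test_missing_outgroup_rejected(self):
        dm, _ = make_additive_tree_matrix(4, 89)
        with pytest.raises(InputError):
            nj_tree(dm, outgroup="nope")

    def test_clone_pair_gets_zero_terminal_branches(self):
        dm = DistanceMatrix(
            [[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], ["A", "B", "C", "D"]
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.0, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.0, abs=1e-12)


class TestBootstrap:
    def _separated_sm(self):
        # two clearly separated clades (AB | CD) over 60 columns
        left = "A" * 30 + "C" * 30
        right = "G" * 30 + "T" * 30
        rows = {
            "A": left,
            "B": left[:29] + "G" + left[30:],
            "C": right,
            "D": right[:29] + "A" + right[30:],
        }
        return Supermatrix(rows=rows, partitions=())

    def test_planted_bipartition_gets_full_support(self):
        res = bootstrap(self._separated_sm(), n_reps=50, seed=1)
        supports = [n.support for n in res.tree.non_tips(include_self=False) if getattr(n, "support", None) is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_reproducible_for_fixed_seed(self):
        r1 = bootstrap(self._separated_sm(), n_reps=20, seed=9)
        r2 = bootstrap(self._separated_sm(), n_reps=20, seed=9)
        assert to_newick(r1.tree) == to_newick(r2.tree)

    def test_identical_rows_flagged_degenerate(self):
        sm = Supermatrix(rows={"A": "MKVL", "B": "MKVL", "C": "MKVL"}, partitions=())
        res = bootstrap(sm, n_reps=5, seed=0)
        assert res.degenerate

    def test_newick_round_trips_leaf_set(self):
        res = bootstrap(self._separated_sm(), n_reps=10, seed=3)
        from skbio import TreeNode
        from io import StringIO

        back = TreeNode.read(StringIO(to_newick(res.tree)))
        assert {t.name for t in back.tips()} == {"A", "B", "C", "D"}
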