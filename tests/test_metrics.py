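"""ANI/AAI/POCP behaviour: self-identity, parameter recovery against the
mutation-log oracle, formula arithmetic, and matrix layout."""

import numpy as np
import pytest

from taxodelim.errors import InputError, UndefinedMetricError
from taxodelim.metrics import (
    AniParams,
    PocpResult,
    aai,
    ani,
    ani_one_way,
    fragment_genome,
    genome_stats,
    metric_matrix,
    pocp,
    pocp_table,
)
from taxodelim.records import SeqRecord
from taxodelim.simulate import make_genome, make_proteome_pair, mutate_genome

from conftest import random_protein


class TestAni:
    def test_self_identity_is_exactly_100(self):
        g = make_genome(12_000, 50, 1)
        res = ani(g, g)
        assert res.value == 100.0
        assert res.fragments_used == res.fragments_total

    def test_two_way_is_mean_of_one_ways(self):
        g = make_genome(10_000, 50, 2)
        m, _ = mutate_genome(g, 0.04, 2)
        fwd, rev = ani_one_way(g, m), ani_one_way(m, g)
        assert ani(g, m).value == pytest.approx((fwd.value + rev.value) / 2)

    @pytest.mark.parametrize("rate", [0.01, 0.05])
    def test_recovers_logged_substitution_rate(self, rate):
        g = make_genome(25_000, 50, 3)
        m, log = mutate_genome(g, rate, 5)
        expected = 100.0 * (1.0 - len(log.mutated_positions) / len(g))
        assert ani(g, m).value == pytest.approx(expected, abs=0.5)

    def test_monotone_decreasing_in_substitution_rate(self):
        g = make_genome(15_000, 50, 4)
        values = []
        for rate in (0.0, 0.02, 0.05, 0.10):
            m, _ = mutate_genome(g, rate, 9)
            values.append(ani(g, m).value)
        assert values == sorted(values, reverse=True)
        assert values[0] == 100.0

    def test_unrelated_genomes_under_strict_filters_undefined(self):
        a = make_genome(5_000, 50, 6)
        b = make_genome(5_000, 50, 7)
        with pytest.raises(UndefinedMetricError):
            ani(a, b, AniParams(min_identity=95.0))

    def test_fragmentation_keeps_long_tail_only(self):
        g = SeqRecord("g", "A" * (1020 * 2 + 800))
        assert [len(f) for f in fragment_genome(g, AniParams())] == [1020, 1020, 800]
        g2 = SeqRecord("g", "A" * (1020 * 2 + 300))
        assert [len(f) for f in fragment_genome(g2, AniParams())] == [1020, 1020]


class TestAai:
    def test_identical_proteomes_100(self, rng):
        prots = [SeqRecord(f"x{i}", random_protein(np.random.default_rng(50 + i), 120)) for i in range(6)]
        other = [SeqRecord(f"y{i}", p.residues) for i, p in enumerate(prots)]
        res = aai(prots, other)
        assert res.value == pytest.approx(100.0)
        assert res.rbh_count == 6

    def test_disjoint_proteomes_undefined(self):
        pa = [SeqRecord(f"a{i}", random_protein(np.random.default_rng(70 + i), 100)) for i in range(4)]
        pb = [SeqRecord(f"b{i}", random_protein(np.random.default_rng(170 + i), 100)) for i in range(4)]
        with pytest.raises(UndefinedMetricError):
            aai(pa, pb)

    @pytest.mark.parametrize("identity", [70.0, 85.0])
    def test_recovers_generator_logged_identities(self, identity):
        proteomes, log = make_proteome_pair(8, 1.0, identity, seed=int(identity))
        res = aai(proteomes["A"], proteomes["B"])
        expected = float(np.mean(list(log.pair_identities.values())))
        assert res.value == pytest.approx(expected, abs=0.5)
        assert res.rbh_count == 8


class TestPocp:
    def test_formula_on_planted_counts(self):
        res = PocpResult(c1=2, c2=3, t1=4, t2=5)
        assert res.value == pytest.approx(100.0 * 5 / 9)
        assert round(res.value, 1) == 55.6

    def test_identical_proteomes_100(self):
        prots = [SeqRecord(f"x{i}", random_protein(np.random.default_rng(90 + i), 120)) for i in range(5)]
        res = pocp(prots, prots)
        assert res.value == 100.0
        assert (res.c1, res.c2, res.t1, res.t2) == (5, 5, 5, 5)

    def test_disjoint_proteomes_zero(self):
        pa = [SeqRecord(f"a{i}", random_protein(np.random.default_rng(200 + i), 100)) for i in range(4)]
        pb = [SeqRecord(f"b{i}", random_protein(np.random.default_rng(300 + i), 100)) for i in range(4)]
        assert pocp(pa, pb).value == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry(self, seed):
        proteomes, _ = make_proteome_pair(8, 0.5, 75.0, seed=600 + seed)
        ab = pocp(proteomes["A"], proteomes["B"])
        ba = pocp(proteomes["B"], proteomes["A"])
        assert ab.value == pytest.approx(ba.value)
        assert (ab.c1, ab.c2) == (ba.c2, ba.c1)

    def test_counts_cannot_exceed_sizes(self):
        with pytest.raises(InputError):
            PocpResult(c1=5, c2=0, t1=4, t2=4)

    def test_empty_proteome_rejected(self):
        with pytest.raises(InputError):
            pocp([], [SeqRecord("a", "MKVLAW")])


class TestGenomeStats:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", (4, 100.0)), ("ATAT", (4, 0.0)), ("GGCCNN", (6, 100.0)), ("ACGT", (4, 50.0))],
    )
    def test_length_and_gc(self, seq, expected):
        assert genome_stats(SeqRecord("g", seq)) == expected


class TestMetricMatrix:
    def test_two_identical_strains_all_100(self):
        g = make_genome(6_000, 50, 30)
        prots = [SeqRecord(f"q{i}", random_protein(np.random.default_rng(400 + i), 120)) for i in range(4)]
        genomes = {"A": SeqRecord("A", g.residues), "B": SeqRecord("B", g.residues)}
        proteomes = {"A": prots, "B": [SeqRecord(f"r{i}", p.residues) for i, p in enumerate(prots)]}
        table, _ = metric_matrix(genomes, proteomes)
        assert float(table.loc["A", "A"]) == 100.0
        assert float(table.loc["B", "A"]) == pytest.approx(100.0)  # ANI below diagonal
        assert float(table.loc["A", "B"]) == pytest.approx(100.0)  # AAI above diagonal

    def test_three_strains_match_per_pair_calls(self):
        base = make_genome(8_000, 50, 31)
        m1, _ = mutate_genome(base, 0.03, 1)
        m2, _ = mutate_genome(base, 0.08, 2)
        genomes = {"A": SeqRecord("A", base.residues), "B": SeqRecord("B", m1.residues), "C": SeqRecord("C", m2.residues)}
        prot_ab, _ = make_proteome_pair(5, 1.0, 85.0, 7, prefix_a="A", prefix_b="B")
        prot_c = [SeqRecord(f"C_p{i:03d}", p.residues) for i, p in enumerate(prot_ab["A"])]
        proteomes = {"A": prot_ab["A"], "B": prot_ab["B"], "C": prot_c}
        table, detail = metric_matrix(genomes, proteomes)
        assert float(table.loc["B", "A"]) == pytest.approx(ani(genomes["A"], genomes["B"]).value)
        assert float(table.loc["A", "C"]) == pytest.approx(aai(proteomes["A"], proteomes["C"]).value)
        assert "A|B" in detail and "ani_one_way" in detail["A|B"]

    def test_pocp_table_against_reference(self):
        proteomes, _ = make_proteome_pair(6, 0.5, 80.0, 8)
        table = pocp_table(proteomes, reference="A")
        assert list(table.index) == ["B"]
        assert float(table.iloc[0, 0]) == pytest.approx(pocp(proteomes["B"], proteomes["A"]).value)
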