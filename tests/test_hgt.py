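"""The top-five out-of-family HGT rule: planted recovery, threshold pinning,
verdict monotonicity, and summary arithmetic."""

import pytest

from taxodelim.align import HitRecord
from taxodelim.errors import LineageError
from taxodelim.hgt import (
    CANDIDATE,
    INSUFFICIENT,
    NOT_CANDIDATE,
    HgtParams,
    screen,
    summarize,
)
from taxodelim.io import read_hits, write_hits
from taxodelim.records import SeqRecord
from taxodelim.simulate import make_hgt_fixture

FAMILY = "Leptolyngbyaceae"


def mk_hit(qid, sid, rank, coverage=0.95, similarity=60.0, family="Nostocaceae"):
    return HitRecord(
        query_id=qid,
        subject_id=sid,
        percent_identity=min(similarity, 50.0),
        percent_similarity=similarity,
        alignment_length=100,
        query_coverage=coverage,
        evalue=1e-30 * (rank + 1),
        bitscore=150.0 - rank,
        subject_lineage=("Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales", family, "G", "G sp"),
    )


@pytest.fixture
def protein():
    return SeqRecord("E412_0001", "M" * 100)


class TestScreen:
    @pytest.mark.parametrize("seed", range(4))
    def test_planted_foreign_set_recovered_exactly(self, seed):
        proteome, hits, log = make_hgt_fixture(n_proteins=12, n_foreign=4, seed=seed, n_sparse=1)
        calls = screen(proteome, hits, self_family=FAMILY, self_strain="E412")
        candidates = tuple(sorted(c.protein_id for c in calls if c.verdict == CANDIDATE))
        assert candidates == log.foreign_ids
        non = [c.protein_id for c in calls if c.verdict == NOT_CANDIDATE]
        assert not set(non) & set(log.foreign_ids)

    def test_all_in_family_top_five_is_not_candidate(self, protein):
        hits = [mk_hit(protein.id, f"s{r}", r, family=FAMILY) for r in range(5)]
        calls = screen([protein], hits, self_family=FAMILY)
        assert calls[0].verdict == NOT_CANDIDATE

    def test_all_foreign_top_five_is_candidate(self, protein):
        hits = [mk_hit(protein.id, f"s{r}", r) for r in range(5)]
        calls = screen([protein], hits, self_family=FAMILY)
        assert calls[0].verdict == CANDIDATE

    def test_coverage_below_90_percent_never_enters_top_five(self, protein):
        # the in-family hit at coverage 0.85 ranks first but must be filtered
        hits = [mk_hit(protein.id, "infam", 0, coverage=0.85, family=FAMILY)]
        hits += [mk_hit(protein.id, f"s{r}", r) for r in range(1, 6)]
        calls = screen([protein], hits, self_family=FAMILY)
        assert calls[0].verdict == CANDIDATE
        assert all(h.subject_id != "infam" for h in calls[0].retained_hits)

    def test_similarity_and_coverage_thresholds_inclusive(self, protein):
        hits = [mk_hit(protein.id, "edge", 0, coverage=0.90, similarity=40.0, family=FAMILY)]
        hits += [mk_hit(protein.id, f"s{r}", r) for r in range(1, 6)]
        calls = screen([protein], hits, self_family=FAMILY)
        # the exactly-at-threshold in-family hit is retained -> not a candidate
        assert calls[0].verdict == NOT_CANDIDATE
        just_below = [mk_hit(protein.id, "edge", 0, coverage=0.8999, similarity=39.9, family=FAMILY)]
        just_below += [mk_hit(protein.id, f"s{r}", r) for r in range(1, 6)]
        calls = screen([protein], just_below, self_family=FAMILY)
        assert calls[0].verdict == CANDIDATE

    def test_fewer_than_five_retained_is_insufficient(self, protein):
        hits = [mk_hit(protein.id, f"s{r}", r) for r in range(3)]
        calls = screen([protein], hits, self_family=FAMILY)
        assert calls[0].verdict == INSUFFICIENT

    def test_self_strain_hits_excluded_before_ranking(self, protein):
        hits = [mk_hit(protein.id, "E412_best_self_record", 0, similarity=99.0, family=FAMILY)]
        hits += [mk_hit(protein.id, f"s{r}", r) for r in range(1, 6)]
        calls = screen([protein], hits, self_family=FAMILY, self_strain="E412")
        assert calls[0].verdict == CANDIDATE

    def test_monotonicity_adding_deep_in_family_hit_keeps_verdict(self, protein):
        base = [mk_hit(protein.id, f"s{r}", r) for r in range(5)]
        deep = base + [mk_hit(protein.id, "infam_deep", 9, family=FAMILY)]
        v1 = screen([protein], base, self_family=FAMILY)[0].verdict
        v2 = screen([protein], deep, self_family=FAMILY)[0].verdict
        assert v1 == v2 == CANDIDATE
        # inserting an in-family hit into the top five flips the verdict
        intop = base + [mk_hit(protein.id, "infam_top", 2, family=FAMILY)]
        assert screen([protein], intop, self_family=FAMILY)[0].verdict == NOT_CANDIDATE

    def test_strict_mode_rejects_missing_lineage(self, protein):
        hit = mk_hit(protein.id, "s0", 0)
        hit.subject_lineage = ()
        hits = [hit] + [mk_hit(protein.id, f"s{r}", r) for r in range(1, 6)]
        with pytest.raises(LineageError):
            screen([protein], hits, self_family=FAMILY, params=HgtParams(strict_lineage=True))
        # lenient mode counts it as non-self-family
        calls = screen([protein], hits, self_family=FAMILY)
        assert calls[0].verdict == CANDIDATE

    def test_rank_before_filter_switch_changes_pool(self, protein):
        # excluded border hit occupies a top-five slot when ranking first
        hits = [mk_hit(protein.id, f"cov{r}", r, coverage=0.85) for r in range(4)]
        hits += [mk_hit(protein.id, f"s{r}", r + 4) for r in range(5)]
        default = screen([protein], hits, self_family=FAMILY)[0]
        assert default.verdict == CANDIDATE
        ranked_first = screen(
            [protein], hits, self_family=FAMILY, params=HgtParams(rank_before_filter=True)
        )[0]
        assert ranked_first.verdict == INSUFFICIENT


class TestSummarize:
    def test_fraction_arithmetic(self):
        proteome, hits, log = make_hgt_fixture(n_proteins=10, n_foreign=3, seed=5)
        calls = screen(proteome, hits, self_family=FAMILY, self_strain="E412")
        s = summarize(calls)
        assert s.n_candidates == 3 and s.n_proteins == 10
        assert s.fraction_candidates == pytest.approx(0.3)
        assert s.candidate_ids == sorted(log.foreign_ids)

    def test_zero_and_all_candidate_extremes(self, protein):
        none = screen([protein], [mk_hit(protein.id, f"s{r}", r, family=FAMILY) for r in range(5)], self_family=FAMILY)
        assert summarize(none).fraction_candidates == 0.0
        all_f = screen([protein], [mk_hit(protein.id, f"s{r}", r) for r in range(5)], self_family=FAMILY)
        assert summarize(all_f).fraction_candidates == 1.0


class TestTabularRoundTrip:
    def test_screen_results_survive_tsv_round_trip(self, tmp_path):
        proteome, hits, log = make_hgt_fixture(n_proteins=8, n_foreign=2, seed=6)
        path = tmp_path / "hits.tsv"
        write_hits(hits, path)
        back = read_hits(path, {p.id: len(p) for p in proteome})
        v1 = [c.verdict for c in screen(proteome, hits, self_family=FAMILY, self_strain="E412")]
        v2 = [c.verdict for c in screen(proteome, back, self_family=FAMILY, self_strain="E412")]
        assert v1 == v2
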