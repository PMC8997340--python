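"""Horizontal-gene-transfer candidate screen over per-protein hit tables.

A protein is called an HGT candidate when, after dropping hits to the
strain's own records and keeping only hits covering >= 90% of the query
with >= 40% amino-acid similarity, all of its top five retained hits lie
outside the focal family. Proteins with fewer than five retained hits are
reported as a separate, auditable class rather than silently called
non-candidates.

Hit tables may come from :func:`taxodelim.align.search` or from any
external search engine via the extended tabular format
(:mod:`taxodelim.io`), as long as hits carry a subject lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import HitRecord
from .errors import InputError, LineageError
from .records import SeqRecord

CANDIDATE = "candidate"
NOT_CANDIDATE = "not_candidate"
INSUFFICIENT = "insufficient_hits"

SIMILARITY = "similarity"  # positives; the default reading of the screen
IDENTITY = "identity"


@dataclass(frozen=True)
class HgtParams:
    min_coverage: float = 0.90
    min_similarity: float = 40.0
    top_n: int = 5
    similarity_mode: str = SIMILARITY  # or IDENTITY
    rank_before_filter: bool = False  # filter-then-rank by default
    strict_lineage: bool = False


@dataclass
class HgtCall:
    protein_id: str
    retained_hits: list[HitRecord]
    verdict: str
    donor_summary: dict[str, int] = field(default_factory=dict)


def _is_self_strain(hit: HitRecord, self_strain: str) -> bool:
    return bool(self_strain) and self_strain.lower() in hit.subject_id.lower()


def _in_family(hit: HitRecord, family: str, strict: bool) -> bool:
    if not hit.subject_lineage:
        if strict:
            raise LineageError(f"hit {hit.query_id}->{hit.subject_id} lacks a lineage")
        return False
    return any(rank.lower() == family.lower() for rank in hit.subject_lineage)


def _family_of(hit: HitRecord) -> str:
    # Lineage convention: (domain, phylum, class, order, family, genus, species).
    if len(hit.subject_lineage) >= 5:
        return hit.subject_lineage[4]
    return hit.subject_lineage[-1] if hit.subject_lineage else "unknown"


def screen(
    proteome: list[SeqRecord],
    hits: list[HitRecord],
    self_family: str,
    self_strain: str = "",
    params: HgtParams | None = None,
) -> list[HgtCall]:
    """Apply the top-five out-of-family rule to every protein of the proteome."""
    params = params or HgtParams()
    by_query: dict[str, list[HitRecord]] = {p.id: [] for p in proteome}
    for hit in hits:
        if hit.query_id in by_query:
            by_query[hit.query_id].append(hit)

    def passes(hit: HitRecord) -> bool:
        sim = hit.percent_similarity if params.similarity_mode == SIMILARITY else hit.percent_identity
        return hit.query_coverage >= params.min_coverage and sim >= params.min_similarity

    calls = []
    for protein in proteome:
        pool = [h for h in by_query[protein.id] if not _is_self_strain(h, self_strain)]
        pool.sort(key=HitRecord.sort_key)
        if params.rank_before_filter:
            top = [h for h in pool[: params.top_n] if passes(h)]
        else:
            retained = [h for h in pool if passes(h)]
            top = retained[: params.top_n]
        if len(top) < params.top_n:
            verdict = INSUFFICIENT
        elif any(_in_family(h, self_family, params.strict_lineage) for h in top):
            verdict = NOT_CANDIDATE
        else:
            verdict = CANDIDATE
        donors: dict[str, int] = {}
        for h in top:
            fam = _family_of(h)
            donors[fam] = donors.get(fam, 0) + 1
        calls.append(HgtCall(protein.id, top, verdict, donors))
    return calls


@dataclass
class HgtSummary:
    n_proteins: int
    n_candidates: int
    n_not_candidates: int
    n_insufficient: int
    fraction_candidates: float  # candidates / all screened proteins
    donor_families: dict[str, int]
    candidate_ids: list[str]


def summarize(calls: list[HgtCall]) -> HgtSummary:
    if not calls:
        raise InputError("summarize requires at least one call")
    candidates = [c for c in calls if c.verdict == CANDIDATE]
    donors: dict[str, int] = {}
    for c in candidates:
        for fam, n in c.donor_summary.items():
            donors[fam] = donors.get(fam, 0) + n
    return HgtSummary(
        n_proteins=len(calls),
        n_candidates=len(candidates),
        n_not_candidates=sum(1 for c in calls if c.verdict == NOT_CANDIDATE),
        n_insufficient=sum(1 for c in calls if c.verdict == INSUFFICIENT),
        fraction_candidates=len(candidates) / len(calls),
        donor_families=dict(sorted(donors.items())),
        candidate_ids=sorted(c.protein_id for c in candidates),
    )


def calls_to_tsv(calls: list[HgtCall]) -> str:
    lines = ["protein_id\tverdict\tn_retained\ttop_hit\ttop_family"]
    for c in calls:
        top = c.retained_hits[0] if c.retained_hits else None
        lines.append(
            "\t".join(
                [
                    c.protein_id,
                    c.verdict,
                    str(len(c.retained_hits)),
                    top.subject_id if top else "-",
                    _family_of(top) if top else "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"
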