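"""Whole-genome and proteome divergence indices: ANI, AAI, POCP, genome stats.

ANI follows the classical fragment-based convention: the query genome is cut
into consecutive 1,020-bp fragments, each is aligned at its best location in
the subject genome, and fragments are retained when the best alignment shows
>= 30% identity over >= 70% of the fragment. The reported two-way value is
the mean of the two one-way means, so a genome against itself is exactly
100.00. Fragment placement uses edlib's exact infix (semi-global) alignment.

AAI is the mean identity over reciprocal-best-hit protein pairs (selection
by seeded local search with identity >= 30%, coverage >= 0.7, alignment
>= 50 aa; identity then recomputed over a global alignment of each pair).
POCP is 100*(C1+C2)/(T1+T2) with a protein counted as conserved when it has
a hit in the other proteome with e-value < 1e-5, identity > 40% and an
alignable region > 50% of the query length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import (
    AA_SCHEME,
    HitRecord,
    SearchParams,
    global_align,
    percent_identity,
    reciprocal_best_hits,
    search,
)
from .errors import InputError, UndefinedMetricError
from .records import NUCLEOTIDE, SeqRecord

ONE_WAY = "one_way"
TWO_WAY = "two_way"


@dataclass(frozen=True)
class AniParams:
    fragment_length: int = 1020
    min_tail: int = 700  # final partial fragment kept if at least this long
    min_identity: float = 30.0
    min_aligned_fraction: float = 0.7


@dataclass(frozen=True)
class AaiParams:
    min_identity: float = 30.0
    min_coverage: float = 0.7
    min_alignment_length: int = 50
    search: SearchParams = field(default_factory=SearchParams)


@dataclass(frozen=True)
class PocpParams:
    max_evalue: float = 1e-5
    min_identity: float = 40.0  # strict: identity must exceed this
    min_alignable_fraction: float = 0.5  # of the query protein's length
    search: SearchParams = field(default_factory=SearchParams)


@dataclass
class AniResult:
    value: float
    fragments_total: int
    fragments_used: int
    direction: str


@dataclass
class AaiResult:
    value: float
    rbh_count: int


@dataclass
class PocpResult:
    """Conserved-protein counts in both directions and the derived percentage."""

    c1: int
    c2: int
    t1: int
    t2: int

    def __post_init__(self) -> None:
        if not (0 <= self.c1 <= self.t1 and 0 <= self.c2 <= self.t2):
            raise InputError("conserved counts exceed proteome sizes")

    @property
    def value(self) -> float:
        return 100.0 * (self.c1 + self.c2) / (self.t1 + self.t2)


def fragment_genome(genome: SeqRecord, params: AniParams) -> list[str]:
    seq = genome.residues
    frags = [seq[i : i + params.fragment_length] for i in range(0, len(seq), params.fragment_length)]
    if frags and len(frags[-1]) < params.fragment_length and len(frags[-1]) < params.min_tail:
        frags.pop()
    return frags


def _fragment_identity(fragment: str, subject: str) -> float:
    """Identity (%) of the fragment at its best infix placement in the subject."""
    res = edlib.align(fragment, subject, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, fragment, subject)
    matched = nice["matched_aligned"]
    return 100.0 * matched.count("|") / len(matched)


def ani_one_way(ga: SeqRecord, gb: SeqRecord, params: AniParams | None = None) -> AniResult:
    params = params or AniParams()
    if ga.alphabet != NUCLEOTIDE or gb.alphabet != NUCLEOTIDE:
        raise InputError("ANI requires nucleotide genomes")
    frags = fragment_genome(ga, params)
    identities = []
    for frag in frags:
        ident = _fragment_identity(frag, gb.residues)
        # infix placement aligns the full fragment, so aligned fraction is 1
        if ident >= params.min_identity and 1.0 >= params.min_aligned_fraction:
            identities.append(ident)
    if not identities:
        raise UndefinedMetricError(
            f"ANI({ga.id}, {gb.id}) undefined: no fragment passed the retention filters"
        )
    return AniResult(
        value=float(np.mean(identities)),
        fragments_total=len(frags),
        fragments_used=len(identities),
        direction=ONE_WAY,
    )


def ani(ga: SeqRecord, gb: SeqRecord, params: AniParams | None = None) -> AniResult:
    """Two-way ANI: the mean of the two one-way values."""
    fwd = ani_one_way(ga, gb, params)
    rev = ani_one_way(gb, ga, params)
    return AniResult(
        value=(fwd.value + rev.value) / 2.0,
        fragments_total=fwd.fragments_total + rev.fragments_total,
        fragments_used=fwd.fragments_used + rev.fragments_used,
        direction=TWO_WAY,
    )


def _aai_filter(params: AaiParams):
    def accept(hit: HitRecord) -> bool:
        return (
            hit.percent_identity >= params.min_identity
            and hit.query_coverage >= params.min_coverage
            and hit.alignment_length >= params.min_alignment_length
        )

    return accept


def aai(pa: list[SeqRecord], pb: list[SeqRecord], params: AaiParams | None = None) -> AaiResult:
    """Mean identity over reciprocal best hits between two proteomes."""
    params = params or AaiParams()
    if not pa or not pb:
        raise InputError("AAI requires two non-empty proteomes")
    by_id_a = {p.id: p for p in pa}
    by_id_b = {p.id: p for p in pb}
    pairs = reciprocal_best_hits(pa, pb, params.search, hit_filter=_aai_filter(params))
    if not pairs:
        raise UndefinedMetricError("AAI undefined: no reciprocal best hits passed the filters")
    identities = []
    for fwd, _ in pairs:
        aln = global_align(by_id_a[fwd.query_id], by_id_b[fwd.subject_id], AA_SCHEME)
        identities.append(percent_identity(aln))
    return AaiResult(value=float(np.mean(identities)), rbh_count=len(pairs))


def _conserved_count(queries: list[SeqRecord], subjects: list[SeqRecord], params: PocpParams) -> int:
    count = 0
    for q in queries:
        for hit in search(q, subjects, params.search):
            if (
                hit.evalue < params.max_evalue
                and hit.percent_identity > params.min_identity
                and hit.query_coverage > params.min_alignable_fraction
            ):
                count += 1
                break
    return count


def pocp(pa: list[SeqRecord], pb: list[SeqRecord], params: PocpParams | None = None) -> PocpResult:
    """Percentage of conserved proteins, symmetric by construction."""
    params = params or PocpParams()
    if not pa or not pb:
        raise InputError("POCP requires two non-empty proteomes")
    return PocpResult(
        c1=_conserved_count(pa, pb, params),
        c2=_conserved_count(pb, pa, params),
        t1=len(pa),
        t2=len(pb),
    )


def genome_stats(g: SeqRecord) -> tuple[int, float]:
    """(length in bp, GC% over unambiguous bases)."""
    if g.alphabet != NUCLEOTIDE:
        raise InputError("genome_stats requires a nucleotide sequence")
    seq = g.residues
    counts = {c: seq.count(c) for c in "ACGT"}
    unambiguous = sum(counts.values())
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous if unambiguous else 0.0
    return len(seq), gc


def metric_matrix(
    genomes: dict[str, SeqRecord],
    proteomes: dict[str, list[SeqRecord]],
    ani_params: AniParams | None = None,
    aai_params: AaiParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Square strain table: AAI above the diagonal, two-way ANI below,
    100.00 on the diagonal; undefined cells rendered NA. Also returns a
    per-pair detail dict (one-way ANI values, RBH counts)."""
    strains = sorted(genomes)
    if len(strains) < 2:
        raise InputError("metric_matrix requires at least 2 strains")
    table = pd.DataFrame(np.nan, index=strains, columns=strains, dtype=float)
    detail: dict = {}
    for s in strains:
        table.loc[s, s] = 100.00
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            key = f"{a}|{b}"
            detail[key] = {}
            try:
                fwd = ani_one_way(genomes[a], genomes[b], ani_params)
                rev = ani_one_way(genomes[b], genomes[a], ani_params)
                table.loc[b, a] = (fwd.value + rev.value) / 2.0
                detail[key]["ani_one_way"] = {f"{a}->{b}": fwd.value, f"{b}->{a}": rev.value}
            except UndefinedMetricError:
                detail[key]["ani_one_way"] = None
            try:
                res = aai(proteomes[a], proteomes[b], aai_params)
                table.loc[a, b] = res.value
                detail[key]["aai_rbh_count"] = res.rbh_count
            except UndefinedMetricError:
                detail[key]["aai_rbh_count"] = 0
    return table, detail


def pocp_table(
    proteomes: dict[str, list[SeqRecord]],
    reference: str,
    params: PocpParams | None = None,
) -> pd.DataFrame:
    """One-column POCP table of every strain against a reference strain."""
    if reference not in proteomes:
        raise InputError(f"reference strain {reference!r} not in proteome set")
    rows = []
    for strain in sorted(proteomes):
        if strain == reference:
            continue
        res = pocp(proteomes[strain], proteomes[reference], params)
        rows.append({"Species": strain, reference: res.value})
    return pd.DataFrame(rows).set_index("Species")
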