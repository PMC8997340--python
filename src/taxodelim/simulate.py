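"""Synthetic fixtures with known ground truth for every pipeline stage.

Every generator is a pure function of (parameters, seed) and returns a
:class:`GeneratorLog` carrying exactly the information needed to compute
oracle values independently of the code under test: mutated site lists for
ANI, region boundary tables for ITS dissection, per-pair identities for
AAI/POCP, planted foreign-protein sets for the HGT screen, and generating
trees for NJ.

Simplifications worth knowing (see also docs/methods.md): the mutation
model is substitution-only (keeps site-count oracles exact); ITS variable
regions use reduced alphabets (A/C for V2, poly-A interiors for boxB/V3)
so the basal helix motifs and the landmark motifs can never be shadowed by
chance, which also makes their fold element content unrealistically simple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import HitRecord
from .errors import InputError
from .its import EXPECTED_TRNA_LENGTHS, Motif, Region, load_motifs, load_trna_refs, load_anchors
from .records import SeqRecord

_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class GeneratorLog:
    """Ground truth recorded by a generator run."""

    seed: int
    mutated_positions: tuple[int, ...] = ()
    regions: tuple[Region, ...] = ()
    target_identities: dict = field(default_factory=dict)
    pair_identities: dict = field(default_factory=dict)
    foreign_ids: tuple[str, ...] = ()
    shared_family_ids: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)


def make_genome(length_bp: int, gc_percent: float, seed: int) -> SeqRecord:
    """i.i.d. bases at the requested GC content."""
    if length_bp < 1:
        raise InputError("length_bp must be >= 1")
    if not (0 <= gc_percent <= 100):
        raise InputError("gc_percent must be in [0, 100]")
    rng = np.random.default_rng(seed)
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    bases = rng.choice(_NT, size=length_bp, p=[a, g, g, a])
    return SeqRecord(id=f"synth_genome_{seed}", residues="".join(bases))


def mutate_genome(g: SeqRecord, sub_rate: float, seed: int) -> tuple[SeqRecord, GeneratorLog]:
    """Per-site substitution to a uniformly chosen different base."""
    if not (0 <= sub_rate < 1):
        raise InputError("sub_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = np.array(list(g.residues))
    hit = rng.random(len(seq)) < sub_rate
    positions = np.flatnonzero(hit)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    mutant = SeqRecord(id=f"{g.id}_mut{seed}", residues="".join(seq))
    return mutant, GeneratorLog(seed=seed, mutated_positions=tuple(int(p) for p in positions))


def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray = _NT) -> str:
    if length == 0:
        return ""
    return "".join(rng.choice(alphabet, size=length))


def _rejection_seq(rng, length: int, forbidden: list[Motif], alphabet=_NT, max_tries: int = 200) -> str:
    """Random sequence containing no (approximate) occurrence of any motif."""
    from .its import find_motif

    for _ in range(max_tries):
        cand = _random_seq(rng, length, alphabet)
        if all(find_motif(cand, m) is None for m in forbidden):
            return cand
    raise InputError(f"could not sample a {length}-nt region avoiding landmark motifs")


_AC = np.array(list("AC"))


def make_its(
    variable_lengths: tuple[int, int, int, int] = (121, 76, 45, 98),
    include_trnas: tuple[bool, bool] = (True, True),
    seed: int = 0,
    spacer: str = "AATT",
    motifs: dict[str, Motif] | None = None,
) -> tuple[SeqRecord, list[Region]]:
    """Assemble an ITS from domain templates in canonical region order.

    ``variable_lengths`` = (D1-D1', V2, boxB, V3); the default values mirror
    the longest observed configuration (380 bp with tRNAs removed). Returns
    the sequence and the ground-truth boundary table (including spacers).
    """
    d1_len, v2_len, boxb_len, v3_len = variable_lengths
    if boxb_len < 8 or v3_len < 6:
        raise InputError("boxB needs >= 8 bp (basal AGCA/TGCT), V3 >= 6 bp (basal GTC/GAC)")
    if d1_len < 1 or v2_len < 0:
        raise InputError("D1-D1' must be positive, V2 non-negative")
    motifs = motifs or load_motifs()
    rng = np.random.default_rng(seed)
    include_ile, include_ala = include_trnas
    trnas = {r.id: r.residues for r in load_trna_refs()}

    d1 = _rejection_seq(rng, d1_len, [motifs["d2"]])
    pieces: list[tuple[str, str]] = [("D1-D1'", d1), ("D2", motifs["d2"].sequence), ("D3", motifs["d3"].sequence)]
    if spacer:
        pieces.append(("spacer", spacer))
    if include_ile:
        pieces.append(("tRNA-Ile", trnas["tRNA-Ile"]))
    pieces.append(("boxA", motifs["boxa"].sequence))
    pieces.append(("D4", motifs["d4"].sequence))
    pieces.append(("V2", _random_seq(rng, v2_len, _AC)))
    if include_ala:
        pieces.append(("tRNA-Ala", trnas["tRNA-Ala"]))
    # boxB/V3 interiors are poly-A: with no interior pairing partners the
    # weighted-maximum-pairing fold is forced onto the basal helix motifs
    # (AGCA..UGCU, GUC..GAC), mirroring the basal stems shared across strains
    boxb = motifs["boxb_start"].sequence + "A" * (boxb_len - 8) + motifs["boxb_end"].sequence
    pieces.append(("boxB", boxb))
    v3 = motifs["v3_start"].sequence + "A" * (v3_len - 6) + motifs["v3_end"].sequence
    pieces.append(("V3", v3))

    regions, chunks, pos = [], [], 0
    for name, res in pieces:
        regions.append(Region(name, pos, pos + len(res)))
        chunks.append(res)
        pos += len(res)
    record = SeqRecord(id=f"synth_its_{seed}", residues="".join(chunks))
    return record, regions


def plant_operons(
    its_records: list[SeqRecord],
    flank: int = 2000,
    seed: int = 0,
    gc_percent: float = 50.0,
) -> SeqRecord:
    """A genome carrying one rrn-like operon (16S-anchor | ITS | 23S-anchor)
    per provided ITS, separated by random flanks."""
    ssu, lsu = load_anchors()
    rng = np.random.default_rng(seed)
    parts = [_random_seq(rng, flank)]
    for its in its_records:
        parts.extend([ssu.residues, its.residues, lsu.residues, _random_seq(rng, flank)])
    return SeqRecord(id=f"synth_operon_genome_{seed}", residues="".join(parts))


def _mutate_protein(rng, residues: str, identity_percent: float) -> tuple[str, float]:
    """Substitute interior residues to reach the target identity exactly."""
    L = len(residues)
    n_sub = int(round(L * (1.0 - identity_percent / 100.0)))
    interior = np.arange(2, L - 2)
    n_sub = min(n_sub, len(interior))
    sites = rng.choice(interior, size=n_sub, replace=False)
    seq = list(residues)
    for pos in sites:
        choices = [a for a in _AA if a != seq[pos]]
        seq[pos] = choices[rng.integers(0, len(choices))]
    return "".join(seq), 100.0 * (L - n_sub) / L


def make_proteome_pair(
    n: int,
    shared_fraction: float,
    identity_level: float,
    seed: int,
    length: int = 150,
    prefix_a: str = "A",
    prefix_b: str = "B",
) -> tuple[dict[str, list[SeqRecord]], GeneratorLog]:
    """Two proteomes of n proteins each sharing ``shared_fraction`` of
    families mutated to ``identity_level`` %; the rest are unrelated."""
    if not (0 <= shared_fraction <= 1):
        raise InputError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(n * shared_fraction))
    pa, pb = [], []
    pair_identities = {}
    shared_ids = []
    for i in range(n_shared):
        base = _random_seq(rng, length, _AA)
        mutated, realized = _mutate_protein(rng, base, identity_level)
        ida, idb = f"{prefix_a}_p{i:03d}", f"{prefix_b}_p{i:03d}"
        pa.append(SeqRecord(ida, base))
        pb.append(SeqRecord(idb, mutated))
        pair_identities[(ida, idb)] = realized
        shared_ids.append(ida)
    for i in range(n_shared, n):
        pa.append(SeqRecord(f"{prefix_a}_p{i:03d}", _random_seq(rng, length, _AA)))
        pb.append(SeqRecord(f"{prefix_b}_p{i:03d}", _random_seq(rng, length, _AA)))
    log = GeneratorLog(
        seed=seed,
        target_identities={"shared": identity_level},
        pair_identities=pair_identities,
        shared_family_ids=tuple(shared_ids),
    )
    return {prefix_a: pa, prefix_b: pb}, log


_FOREIGN_FAMILIES = (
    "Nostocaceae",
    "Chroococcaceae",
    "Oscillatoriaceae",
    "Microcystaceae",
    "Rivulariaceae",
    "Aphanizomenonaceae",
)


def _lineage(family: str, genus: str, species: str) -> tuple[str, ...]:
    return ("Bacteria", "Cyanobacteria", "Cyanophyceae", "Synechococcales", family, genus, species)


def make_hgt_fixture(
    n_proteins: int = 10,
    n_foreign: int = 3,
    depth: int = 8,
    self_family: str = "Leptolyngbyaceae",
    seed: int = 0,
    self_strain: str = "E412",
    n_sparse: int = 0,
) -> tuple[list[SeqRecord], list[HitRecord], GeneratorLog]:
    """Proteome plus hit table with planted foreign proteins.

    Every protein gets a self-strain hit (must be excluded), and
    threshold-straddling hits are planted at coverage 0.89 vs 0.90 and
    similarity 39.9 vs 40.0 so that the filters are pinned exactly: if the
    failing border hits were (wrongly) retained they would displace or
    introduce in-family hits in the top five.
    """
    if n_foreign + n_sparse > n_proteins:
        raise InputError("n_foreign + n_sparse cannot exceed n_proteins")
    if depth < 6:
        raise InputError("depth must be >= 6 so the top-five rule is decidable")
    rng = np.random.default_rng(seed)
    proteome = [SeqRecord(f"{self_strain}_{i:04d}", _random_seq(rng, 120, _AA)) for i in range(n_proteins)]
    order = rng.permutation(n_proteins)
    foreign = sorted(proteome[i].id for i in order[:n_foreign])
    sparse = sorted(proteome[i].id for i in order[n_foreign : n_foreign + n_sparse])
    hits: list[HitRecord] = []

    def add(qid, sid, rank, coverage, similarity, family, genus="Genus"):
        span = int(round(coverage * 120))
        hits.append(
            HitRecord(
                query_id=qid,
                subject_id=sid,
                percent_identity=min(similarity, 35.0 + rank),
                percent_similarity=similarity,
                alignment_length=span,
                query_coverage=coverage,
                evalue=1e-40 * (rank + 1),
                bitscore=200.0 - rank,
                subject_lineage=_lineage(family, genus, f"{genus} sp{rank}"),
                query_start=0,
                query_end=span,
                subject_start=0,
                subject_end=span,
            )
        )

    for p in proteome:
        fams = [str(f) for f in rng.permutation(_FOREIGN_FAMILIES)]
        # subject ids must not contain the self-strain token (except the
        # planted self hit), or the exclusion step would eat them
        q = p.id.split("_")[-1]
        # a self-strain hit that must be dropped before ranking
        add(p.id, f"{self_strain}_{q}_self", 0, 1.0, 95.0, self_family)
        if p.id in sparse:
            for r in range(1, 4):
                add(p.id, f"{fams[r % len(fams)]}_q{q}_r{r}", r, 0.95, 60.0, fams[r % len(fams)])
            continue
        if p.id in foreign:
            # would-be in-family top hits, excluded by the border filters
            add(p.id, f"border_cov_q{q}", 1, 0.89, 80.0, self_family)
            add(p.id, f"border_sim_q{q}", 2, 0.95, 39.9, self_family)
            # five retained out-of-family hits; one sits exactly on both
            # inclusive thresholds
            add(p.id, f"{fams[0]}_q{q}_t", 3, 0.90, 40.0, fams[0])
            for r in range(4, 8):
                cov = float(rng.uniform(0.92, 1.0))
                sim = float(rng.uniform(45.0, 90.0))
                add(p.id, f"{fams[r % len(fams)]}_q{q}_r{r}", r, cov, sim, fams[r % len(fams)])
            # an in-family hit below rank five: must not flip the verdict
            add(p.id, f"infam_q{q}_deep", 9, 0.95, 70.0, self_family)
        else:
            # native: excluded out-of-family border hit ranks best; if it
            # were retained the in-family fifth hit would drop out of the
            # top five and the verdict would flip
            add(p.id, f"border_cov_q{q}", 1, 0.89, 85.0, fams[0])
            for r in range(2, 6):
                cov = float(rng.uniform(0.92, 1.0))
                sim = float(rng.uniform(45.0, 90.0))
                add(p.id, f"{fams[r % len(fams)]}_q{q}_r{r}", r, cov, sim, fams[r % len(fams)])
            add(p.id, f"infam_q{q}", 6, 0.96, 75.0, self_family)
            for r in range(7, depth + 1):
                add(p.id, f"{fams[r % len(fams)]}_q{q}_r{r}", r, 0.93, 55.0, fams[r % len(fams)])
    log = GeneratorLog(seed=seed, foreign_ids=tuple(foreign), extra={"sparse_ids": tuple(sparse)})
    return proteome, hits, log


def make_additive_tree_matrix(n_taxa: int, seed: int) -> tuple[DistanceMatrix, TreeNode]:
    """A random additive (tree-metric) distance matrix and its generating
    unrooted tree (trifurcating root, positive branch lengths)."""
    if n_taxa < 3:
        raise InputError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"T{i:02d}" for i in range(n_taxa)]

    def blen():
        return float(rng.uniform(0.1, 1.0))

    tree = TreeNode(children=[TreeNode(name=l, length=blen()) for l in labels[:3]])
    for label in labels[3:]:
        attachable = [n for n in tree.traverse(include_self=False)]
        target = attachable[rng.integers(0, len(attachable))]
        parent = target.parent
        frac = float(rng.uniform(0.2, 0.8))
        old_len = target.length
        parent.remove(target)
        target.length = old_len * (1.0 - frac)
        joint = TreeNode(length=old_len * frac, children=[target, TreeNode(name=label, length=blen())])
        parent.append(joint)
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    return dm.filter(order), tree


@dataclass
class StudyBundle:
    """A miniature multi-strain study: genomes with planted rrn operons,
    16S sequences, proteomes with universal single-copy families, an HGT hit
    table for the focal strain, and the ground-truth logs."""

    focal: str
    strains: list[str]
    outgroup: str
    genomes: dict[str, SeqRecord]
    s16: dict[str, SeqRecord]
    proteomes: dict[str, list[SeqRecord]]
    its_truth: dict[str, list[Region]]
    hgt_proteome: list[SeqRecord]
    hgt_hits: list[HitRecord]
    self_family: str
    logs: dict[str, GeneratorLog]


def make_study_bundle(
    seed: int = 0,
    genome_length: int = 30_000,
    n_universal: int = 12,
    n_unique: int = 14,
) -> StudyBundle:
    """Strains built to straddle the published genus thresholds: the focal
    strain is genus-level divergent from every neighbor (ANI < 83, AAI <= 70,
    POCP < 50, nearest 16S identity ~96%)."""
    rng = np.random.default_rng(seed)
    strains = ["SP1", "SP2", "SP3", "OUT"]
    focal = "SP1"
    base = make_genome(genome_length, 48.0, seed)
    genome_rates = {"SP2": 0.18, "SP3": 0.22, "OUT": 0.30}
    s16_rates = {"SP2": 0.04, "SP3": 0.06, "OUT": 0.09}
    prot_rates = {"SP2": 0.35, "SP3": 0.36, "OUT": 0.40}

    logs: dict[str, GeneratorLog] = {}
    its_truth: dict[str, list[Region]] = {}
    genomes: dict[str, SeqRecord] = {}
    s16: dict[str, SeqRecord] = {}
    base16 = SeqRecord("base16S", _random_seq(rng, 1000))
    v2_lengths = {"SP1": 76, "SP2": 24, "SP3": 90, "OUT": 11}
    for idx, strain in enumerate(strains):
        if strain == focal:
            core = base
            seq16 = base16.residues
        else:
            core, log = mutate_genome(base, genome_rates[strain], seed + 11 + idx)
            logs[f"genome_{strain}"] = log
            mut16, log16 = mutate_genome(base16, s16_rates[strain], seed + 41 + idx)
            seq16 = mut16.residues
            logs[f"s16_{strain}"] = log16
        its, regions = make_its(
            variable_lengths=(121, v2_lengths[strain], 45, 98),
            include_trnas=(True, strain != "OUT"),
            seed=seed + 71 + idx,
        )
        its_truth[strain] = regions
        operon = plant_operons([its], flank=500, seed=seed + 101 + idx)
        genomes[strain] = SeqRecord(strain, core.residues + operon.residues)
        s16[strain] = SeqRecord(f"{strain}_16S", seq16)

    # universal single-copy protein families plus strain-unique proteins
    proteomes: dict[str, list[SeqRecord]] = {s: [] for s in strains}
    for fam in range(n_universal):
        ancestor = _random_seq(rng, 140, _AA)
        for strain in strains:
            if strain == focal:
                residues, realized = ancestor, 100.0
            else:
                residues, realized = _mutate_protein(
                    np.random.default_rng(seed + 1000 + fam * 10 + strains.index(strain)),
                    ancestor,
                    100.0 * (1.0 - prot_rates[strain]),
                )
            proteomes[strain].append(SeqRecord(f"{strain}_og{fam:03d}", residues))
    for strain in strains:
        srng = np.random.default_rng(seed + 5000 + strains.index(strain))
        for u in range(n_unique):
            proteomes[strain].append(SeqRecord(f"{strain}_u{u:03d}", _random_seq(srng, 140, _AA)))

    hgt_proteome, hgt_hits, hgt_log = make_hgt_fixture(
        n_proteins=10, n_foreign=3, seed=seed + 9000, self_strain=focal
    )
    logs["hgt"] = hgt_log
    return StudyBundle(
        focal=focal,
        strains=strains,
        outgroup="OUT",
        genomes=genomes,
        s16=s16,
        proteomes=proteomes,
        its_truth=its_truth,
        hgt_proteome=hgt_proteome,
        hgt_hits=hgt_hits,
        self_family="Leptolyngbyaceae",
        logs=logs,
    )
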