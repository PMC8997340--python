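"""Single-copy ortholog extraction, supermatrix construction, and
distance-based phylogenomics.

Orthology is approximated by reciprocal best hits (RBH) under AAI-style
filters; single-copy clusters are the connected components of the RBH graph
that contain exactly one protein from every strain. Per-cluster alignments
use a center-star progressive strategy (center = the member minimising the
summed alignment distance to the others; its pairwise alignments are merged
column-wise, "once a gap, always a gap"), concatenated in sorted cluster
order into a supermatrix with a partition map.

Tree inference is neighbor joining on p- or Poisson-corrected distances with
deterministic lexicographic tie-breaking, optional outgroup rooting, and
classical bootstrap (column resampling) supports. NJ is exact on additive
distance matrices. This distance pipeline is a self-contained stand-in for
maximum-likelihood inference and is labelled as such in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skbio import DistanceMatrix, TreeNode

from .align import AA_SCHEME, SchemeSpec, SearchParams, global_align, reciprocal_best_hits
from .errors import InputError, UndefinedMetricError
from .metrics import AaiParams, _aai_filter
from .records import SeqRecord

P_DISTANCE = "p_distance"
POISSON = "poisson"


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: tuple[tuple[str, str], ...]  # (strain_id, protein_id), sorted by strain

    def protein_of(self, strain: str) -> str:
        for s, p in self.members:
            if s == strain:
                return p
        raise KeyError(strain)


def rbh_pairs(
    pa: list[SeqRecord],
    pb: list[SeqRecord],
    params: AaiParams | None = None,
) -> list[tuple[str, str]]:
    """Mutual best hits between two proteomes, as (id_a, id_b) pairs."""
    params = params or AaiParams()
    pairs = reciprocal_best_hits(pa, pb, params.search, hit_filter=_aai_filter(params))
    return [(fwd.query_id, fwd.subject_id) for fwd, _ in pairs]


def single_copy_clusters(
    proteomes: dict[str, list[SeqRecord]],
    params: AaiParams | None = None,
) -> list[OrthologCluster]:
    """Transitive closure of pairwise RBH; keep clusters with exactly one
    member per strain across all strains."""
    strains = sorted(proteomes)
    if len(strains) < 3:
        raise InputError("single-copy clustering requires at least 3 strains")
    graph = nx.Graph()
    for strain in strains:
        for p in proteomes[strain]:
            graph.add_node((strain, p.id))
    for i, a in enumerate(strains):
        for b in strains[i + 1 :]:
            for pid_a, pid_b in rbh_pairs(proteomes[a], proteomes[b], params):
                graph.add_edge((a, pid_a), (b, pid_b))
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        per_strain: dict[str, int] = {}
        for strain, _ in members:
            per_strain[strain] = per_strain.get(strain, 0) + 1
        if len(per_strain) == len(strains) and all(n == 1 for n in per_strain.values()):
            clusters.append(tuple(members))
    clusters.sort()
    return [
        OrthologCluster(cluster_id=f"OG{i:04d}", members=members)
        for i, members in enumerate(clusters, start=1)
    ]


def _merge_center_star(center: str, alns: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments into one MSA.

    Returns rows [center, other_1, ...]; gap columns inserted into the center
    by one alignment are propagated to all rows.
    """
    L = len(center)
    gap_counts = []
    split_rows = []
    for c_row, s_row in alns:
        gaps = [0] * (L + 1)
        chunks: list[list[str]] = [[] for _ in range(L + 1)]
        idx = 0
        for c_char, s_char in zip(c_row, s_row):
            if c_char == "-":
                gaps[idx] += 1
                chunks[idx].append(s_char)
            else:
                chunks[idx].append(s_char)
                idx += 1
        gap_counts.append(gaps)
        split_rows.append(chunks)
    master = [max((g[k] for g in gap_counts), default=0) for k in range(L + 1)]
    center_row = "".join(
        "-" * master[k] + (center[k] if k < L else "") for k in range(L + 1)
    )
    rows = [center_row]
    for gaps, chunks in zip(gap_counts, split_rows):
        parts = []
        for k in range(L + 1):
            chunk = "".join(chunks[k])
            parts.append("-" * (master[k] - gaps[k]) + chunk)
        rows.append("".join(parts))
    return rows


def center_star_align(
    seqs: list[tuple[str, str]],
    scheme: SchemeSpec | None = None,
) -> dict[str, str]:
    """Center-star multiple alignment; returns label -> aligned row."""
    if not seqs:
        raise InputError("nothing to align")
    if len(seqs) == 1:
        return {seqs[0][0]: seqs[0][1]}
    records = [SeqRecord(label, res) for label, res in seqs]
    scheme = scheme or AA_SCHEME
    n = len(records)
    scores = np.zeros((n, n))
    alns = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], scheme)
            scores[i, j] = scores[j, i] = aln.score
            alns[(i, j)] = aln
    center = int(np.argmax(scores.sum(axis=1)))  # ties -> lowest index
    pairwise = []
    order = [center]
    for j in range(n):
        if j == center:
            continue
        order.append(j)
        if (center, j) in alns:
            aln = alns[(center, j)]
            pairwise.append((aln.aligned_query, aln.aligned_subject))
        else:
            aln = alns[(j, center)]
            pairwise.append((aln.aligned_subject, aln.aligned_query))
    rows = _merge_center_star(records[center].residues, pairwise)
    return {records[idx].id: rows[k] for k, idx in enumerate(order)}


@dataclass
class Supermatrix:
    rows: dict[str, str]  # strain -> concatenated aligned residues
    partitions: tuple[tuple[str, int, int], ...]  # (cluster_id, start, end), 0-based half-open

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_phylip(self) -> str:
        lines = [f" {len(self.rows)} {self.width}"]
        for strain in sorted(self.rows):
            lines.append(f"{strain}  {self.rows[strain]}")
        return "\n".join(lines) + "\n"

    def partition_tsv(self) -> str:
        lines = ["cluster_id\tstart\tend"]
        for cid, s, e in self.partitions:
            lines.append(f"{cid}\t{s}\t{e}")
        return "\n".join(lines) + "\n"


def align_and_concatenate(
    clusters: list[OrthologCluster],
    proteomes: dict[str, list[SeqRecord]],
    scheme: SchemeSpec | None = None,
) -> Supermatrix:
    """Per-cluster center-star MSAs concatenated in sorted cluster order."""
    if not clusters:
        raise InputError("no single-copy clusters to concatenate")
    by_id = {strain: {p.id: p for p in prots} for strain, prots in proteomes.items()}
    strains = sorted({s for c in clusters for s, _ in c.members})
    parts: dict[str, list[str]] = {s: [] for s in strains}
    partitions = []
    offset = 0
    for cluster in sorted(clusters, key=lambda c: c.cluster_id):
        seqs = [(strain, by_id[strain][pid].residues) for strain, pid in cluster.members]
        msa = center_star_align(seqs, scheme)
        width = len(next(iter(msa.values())))
        for strain in strains:
            parts[strain].append(msa[strain])
        partitions.append((cluster.cluster_id, offset, offset + width))
        offset += width
    return Supermatrix(
        rows={s: "".join(chunks) for s, chunks in parts.items()},
        partitions=tuple(partitions),
    )


def distance_matrix(sm: Supermatrix, model: str = P_DISTANCE) -> DistanceMatrix:
    """Pairwise p-distance (or Poisson-corrected -ln(1-p)) over shared
    non-gap columns of the supermatrix."""
    ids = sorted(sm.rows)
    if len(ids) < 3:
        raise InputError("distance matrix requires at least 3 rows")
    n = len(ids)
    mat = np.zeros((n, n))
    arr = {s: np.frombuffer(sm.rows[s].encode(), dtype="S1") for s in ids}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[ids[i]], arr[ids[j]]
            shared = (a != b"-") & (b != b"-")
            total = int(shared.sum())
            if total == 0:
                raise UndefinedMetricError(f"no shared columns between {ids[i]} and {ids[j]}")
            p = float((a[shared] != b[shared]).sum()) / total
            if model == P_DISTANCE:
                d = p
            elif model == POISSON:
                if p >= 1.0:
                    raise UndefinedMetricError(f"Poisson distance undefined at p={p}")
                d = -math.log(1.0 - p)
            else:
                raise InputError(f"unknown distance model {model!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> TreeNode:
    """Neighbor joining with deterministic lexicographic tie-breaking.

    Exact (topology and branch lengths) on additive matrices. When an
    outgroup is given the tree is rooted on the outgroup's terminal edge
    (split at its midpoint).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise InputError("NJ requires at least 3 taxa")
    if outgroup is not None and outgroup not in ids:
        raise InputError(f"outgroup {outgroup!r} not among taxa")
    # working structures: label -> TreeNode; distances in a dict-of-dicts
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    dist: dict[frozenset, float] = {}
    for i in ids:
        for j in ids:
            if i < j:
                dist[frozenset((i, j))] = float(dm[i, j])

    def d(i: str, j: str) -> float:
        return 0.0 if i == j else dist[frozenset((i, j))]

    active = sorted(ids)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (n - 2) * d(i, j) - r[i] - r[j]
                key = (q, i, j)  # lexicographic pair choice on ties
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = d(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d(i, j) - li
        new_label = f"@{counter:04d}"
        counter += 1
        ni, nj_ = nodes.pop(i), nodes.pop(j)
        ni.length, nj_.length = li, lj
        nodes[new_label] = TreeNode(children=[ni, nj_])
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((new_label, k))] = (d(i, k) + d(j, k) - d(i, j)) / 2.0
        active = sorted([a for a in active if a not in (i, j)] + [new_label])
    # closed-form star for the last three nodes
    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = d(a, b) - la
    lc = d(a, c) - la
    for label, length in ((a, la), (b, lb), (c, lc)):
        nodes[label].length = length
    tree = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    if outgroup is not None:
        og = tree.find(outgroup)
        tree = tree.root_at(og, above=True, branch_attrs=[])
    return tree


def bipartitions(tree: TreeNode) -> dict[frozenset, float]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each internal edge maps the canonical side (the one not containing the
    lexicographically smallest leaf) to its branch length; for edges that
    meet at a rooted tree's root the two half-lengths are summed.
    """
    leaves = frozenset(l.name for l in tree.tips())
    anchor = min(leaves)
    parts: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = leaves - side
        length = node.length or 0.0
        # a root with two children is an artifact of rooting: its two child
        # edges are one unrooted edge
        parent = node.parent
        if parent is not None and parent.is_root() and len(parent.children) == 2:
            sibling = [c for c in parent.children if c is not node][0]
            length += sibling.length or 0.0
            parts[side] = max(parts.get(side, 0.0), length)
            continue
        parts[side] = parts.get(side, 0.0) + length if side in parts else length
    return parts


def terminal_lengths(tree: TreeNode) -> dict[str, float]:
    out = {}
    for tip in tree.tips():
        length = tip.length or 0.0
        parent = tip.parent
        if parent is not None and parent.is_root() and len(parent.children) == 2:
            # rooted on this tip's edge: the unrooted terminal edge is split
            sibling = [c for c in parent.children if c is not tip][0]
            length += 0.0  # half retained; callers compare unrooted trees pre-rooting
        out[tip.name] = length
    return out


@dataclass
class BootstrapResult:
    tree: TreeNode  # the full-data tree, internal nodes carry .support (%)
    n_replicates: int
    degenerate: bool  # all pairwise distances zero; supports meaningless


def bootstrap(
    sm: Supermatrix,
    n_reps: int,
    seed: int,
    model: str = P_DISTANCE,
    outgroup: str | None = None,
) -> BootstrapResult:
    """Column resampling with replacement; supports are the percentage of
    replicate NJ trees containing each internal bipartition."""
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    dm = distance_matrix(sm, model)
    degenerate = bool(np.allclose(dm.data, 0.0))
    tree = nj_tree(dm, outgroup)
    rng = np.random.default_rng(seed)
    width = sm.width
    ids = sorted(sm.rows)
    arrs = {s: np.frombuffer(sm.rows[s].encode(), dtype="S1") for s in ids}
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep = Supermatrix(
            rows={s: arrs[s][cols].tobytes().decode() for s in ids},
            partitions=(),
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except UndefinedMetricError:
            continue
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    leaves = frozenset(ids)
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(l.name for l in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            node.support = None
            continue
        if anchor in side:
            side = leaves - side
        node.support = None if degenerate else 100.0 * counts.get(side, 0) / n_reps
    return BootstrapResult(tree=tree, n_replicates=n_reps, degenerate=degenerate)


def to_newick(tree: TreeNode, with_support: bool = True) -> str:
    """Newick text; integer supports written as internal node labels."""
    copy = tree.copy()
    if with_support:
        for node in copy.non_tips(include_self=True):
            support = getattr(node, "support", None)
            node.name = str(int(round(support))) if support is not None else None
    out = str(copy).strip()
    return out + "\n" if not out.endswith("\n") else out
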