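"""Helix secondary-structure prediction by weighted maximum pairing.

The ITS helices (D1-D1', V2, boxB, V3) are folded with a Nussinov-style
dynamic program that maximises the summed weight of nested base pairs
(GC = 3, AU = 2, GU = 1 by default) under a minimum hairpin loop of 3
unpaired residues. This is a deliberately self-contained combinatorial
model — not a thermodynamic nearest-neighbour energy model — so element
counts on real helices are a soft, model-dependent comparison surface,
while pair-weight optimality is exactly testable by exhaustive enumeration.

Structures are annotated into the classical elements: stems (maximal
stacks of consecutive pairs), hairpin loops, left/right bulges,
symmetric/asymmetric internal loops, multiloops and exterior residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import AlphabetError, InputError
from .records import SeqRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

STEM = "stem"
HAIRPIN = "hairpin-loop"
BULGE_LEFT = "bulge-left"
BULGE_RIGHT = "bulge-right"
INTERNAL_SYM = "internal-loop-symmetric"
INTERNAL_ASYM = "internal-loop-asymmetric"
MULTILOOP = "multiloop"
EXTERIOR = "exterior"


@dataclass(frozen=True)
class FoldParams:
    """Pair weights and the minimum hairpin-loop length."""

    gc_weight: int = 3
    au_weight: int = 2
    gu_weight: int = 1
    min_loop: int = 3

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((5, 5), dtype=np.int32)
        w[1, 2] = w[2, 1] = self.gc_weight
        w[0, 3] = w[3, 0] = self.au_weight
        w[2, 3] = w[3, 2] = self.gu_weight
        return w


DEFAULT_FOLD_PARAMS = FoldParams()


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"non-nucleotide character {exc.args[0]!r} in fold input") from exc


@njit(cache=True)
def _fill(codes, w, min_loop):  # pragma: no cover - exercised via wrappers
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for jp in range(i + min_loop + 1, j + 1):
                pw = w[codes[i], codes[jp]]
                if pw > 0:
                    inner = dp[i + 1, jp - 1] if jp - 1 > i + 1 else 0
                    right = dp[jp + 1, j] if jp + 1 <= j else 0
                    cand = pw + inner + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


@njit(cache=True)
def _batch_scores(code_matrix, w, min_loop):  # pragma: no cover
    m = code_matrix.shape[0]
    out = np.empty(m, dtype=np.int32)
    for s in range(m):
        dp = _fill(code_matrix[s], w, min_loop)
        n = code_matrix.shape[1]
        out[s] = dp[0, n - 1] if n > 1 else 0
    return out


def optimal_pair_weight(seq: str | SeqRecord, params: FoldParams = DEFAULT_FOLD_PARAMS) -> int:
    """Maximum total pair weight over all nested structures of the sequence."""
    residues = seq.residues if isinstance(seq, SeqRecord) else seq
    if not residues:
        raise InputError("cannot fold an empty sequence")
    codes = encode(residues)
    if len(codes) < 2:
        return 0
    dp = _fill(codes, params.weight_matrix(), params.min_loop)
    return int(dp[0, len(codes) - 1])


def batch_pair_weights(code_matrix: np.ndarray, params: FoldParams = DEFAULT_FOLD_PARAMS) -> np.ndarray:
    """Optimal pair weights for many equal-length sequences (coded rows)."""
    if code_matrix.shape[1] < 2:
        return np.zeros(code_matrix.shape[0], dtype=np.int32)
    return _batch_scores(np.ascontiguousarray(code_matrix, dtype=np.int8),
                         params.weight_matrix(), params.min_loop)


@dataclass(frozen=True)
class Element:
    kind: str
    # residue counts: stems count base pairs; loops/bulges count unpaired
    # residues (internal loops carry (left, right)).
    size: tuple[int, ...]
    position: int


@dataclass
class SecondaryStructure:
    """A nested base-pair set with structure-element annotation."""

    sequence: str
    pairs: frozenset[tuple[int, int]]
    elements: tuple[Element, ...] = ()
    total_weight: int = 0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        ordered = sorted(self.pairs)
        for i, j in ordered:
            if not (0 <= i < j < n):
                raise InputError(f"pair ({i}, {j}) out of range")
            if i in seen or j in seen:
                raise InputError("a residue participates in more than one pair")
            seen.update((i, j))
        for a, (i, j) in enumerate(ordered):
            for k, l in ordered[a + 1 :]:
                if i < k < j < l:
                    raise InputError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    def partner_array(self) -> list[int]:
        partner = [-1] * len(self.sequence)
        for i, j in self.pairs:
            partner[i], partner[j] = j, i
        return partner

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el.kind] = counts.get(el.kind, 0) + 1
        return counts


def fold(seq: str | SeqRecord, params: FoldParams = DEFAULT_FOLD_PARAMS) -> SecondaryStructure:
    """Optimal weighted-maximum-pairing structure with deterministic traceback.

    Ties are broken by preferring to pair the leftmost residue with the
    smallest admissible partner, scanning pairing options before leaving the
    residue unpaired.
    """
    residues = (seq.residues if isinstance(seq, SeqRecord) else seq).upper()
    if not residues:
        raise InputError("cannot fold an empty sequence")
    codes = encode(residues)
    n = len(codes)
    w = params.weight_matrix()
    pairs: set[tuple[int, int]] = set()
    if n >= 2:
        dp = _fill(codes, w, params.min_loop)
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i <= params.min_loop:
                continue
            target = dp[i, j]
            if target == 0:
                continue
            chosen = False
            for jp in range(i + params.min_loop + 1, j + 1):
                pw = int(w[codes[i], codes[jp]])
                if pw <= 0:
                    continue
                inner = int(dp[i + 1, jp - 1]) if jp - 1 > i + 1 else 0
                right = int(dp[jp + 1, j]) if jp + 1 <= j else 0
                if pw + inner + right == target:
                    pairs.add((i, jp))
                    stack.append((i + 1, jp - 1))
                    if jp + 1 <= j:
                        stack.append((jp + 1, j))
                    chosen = True
                    break
            if not chosen:
                stack.append((i + 1, j))
        total = int(dp[0, n - 1])
    else:
        total = 0
    structure = SecondaryStructure(sequence=residues, pairs=frozenset(pairs), total_weight=total)
    return annotate_elements(structure)


def annotate_elements(s: SecondaryStructure) -> SecondaryStructure:
    """Derive structure elements purely from the pair set.

    A bulge is a one-sided unpaired run between stacked pairs; an internal
    loop is two-sided (symmetric iff both sides are equal); a stem is a
    maximal stack of consecutive pairs; unpaired residues outside every pair
    form the exterior.
    """
    n = len(s.sequence)
    partner = s.partner_array()
    elements: list[Element] = []

    ordered = sorted(s.pairs)
    pairset = s.pairs
    # stems: maximal runs of stacked pairs
    for i, j in ordered:
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its stack
        length = 1
        while (i + length, j - length) in pairset:
            length += 1
        elements.append(Element(STEM, (length,), i))

    def children_and_unpaired(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, i
        while k <= j:
            if partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                if partner[k] == -1:
                    unpaired += 1
                k += 1
        return kids, unpaired

    for i, j in ordered:
        kids, _ = children_and_unpaired(i + 1, j - 1)
        if not kids:
            elements.append(Element(HAIRPIN, (j - i - 1,), i + 1))
        elif len(kids) == 1:
            (k, l) = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                continue  # stacked pair, part of a stem
            if right == 0:
                elements.append(Element(BULGE_LEFT, (left,), i + 1))
            elif left == 0:
                elements.append(Element(BULGE_RIGHT, (right,), l + 1))
            elif left == right:
                elements.append(Element(INTERNAL_SYM, (left, right), i + 1))
            else:
                elements.append(Element(INTERNAL_ASYM, (left, right), i + 1))
        else:
            _, unpaired = children_and_unpaired(i + 1, j - 1)
            elements.append(Element(MULTILOOP, (unpaired,), i + 1))

    _, ext_unpaired = children_and_unpaired(0, n - 1)
    if ext_unpaired or not s.pairs:
        elements.append(Element(EXTERIOR, (n if not s.pairs else ext_unpaired,), 0))
    elements.sort(key=lambda e: (e.position, e.kind))
    return SecondaryStructure(
        sequence=s.sequence,
        pairs=s.pairs,
        elements=tuple(elements),
        total_weight=s.total_weight,
    )


def structure_distance(
    s1: SecondaryStructure, s2: SecondaryStructure
) -> tuple[int, dict[str, int]]:
    """(base-pair symmetric difference, per-kind signed element-count delta).

    Sequences are compared left-aligned; the delta is count(s2) - count(s1).
    """
    bp = len(s1.pairs ^ s2.pairs)
    c1, c2 = s1.element_counts(), s2.element_counts()
    delta = {kind: c2.get(kind, 0) - c1.get(kind, 0) for kind in sorted(set(c1) | set(c2))}
    return bp, delta


def to_dotbracket(s: SecondaryStructure) -> str:
    out = ["."] * len(s.sequence)
    for i, j in s.pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def parse_dotbracket(sequence: str, dotbracket: str) -> SecondaryStructure:
    if len(sequence) != len(dotbracket):
        raise InputError("sequence and dot-bracket lengths differ")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, c in enumerate(dotbracket):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise InputError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
        elif c != ".":
            raise InputError(f"unexpected dot-bracket character {c!r}")
    if stack:
        raise InputError("unbalanced '(' in dot-bracket")
    return annotate_elements(SecondaryStructure(sequence=sequence.upper(), pairs=frozenset(pairs)))


def element_report(s: SecondaryStructure) -> str:
    """Per-element TSV (kind, sizes, position)."""
    lines = ["kind\tsizes\tposition"]
    for el in s.elements:
        lines.append(f"{el.kind}\t{','.join(map(str, el.size))}\t{el.position}")
    return "\n".join(lines) + "\n"
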