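"""Sequence records and alphabets.

A :class:`SeqRecord` is the unit every analysis consumes: an identified
nucleotide or protein sequence. The class is deliberately small — file I/O
goes through Biopython (see :mod:`taxodelim.io`); this type only pins down
the invariants the pipeline relies on (non-empty residues, a consistent
alphabet, stable identifiers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlphabetError, InputError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_CHARS = set("ACGTUN")
# 20 standard amino acids plus X (unknown); B/Z/* are not accepted.
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def infer_alphabet(residues: str) -> str:
    """Guess the alphabet from residue content (nucleotide wins on ties)."""
    chars = set(residues)
    if chars <= _NT_CHARS:
        return NUCLEOTIDE
    if chars <= _AA_CHARS:
        return PROTEIN
    raise AlphabetError(f"residues contain characters outside both alphabets: {sorted(chars - _AA_CHARS - _NT_CHARS)}")


@dataclass
class SeqRecord:
    """An identified sequence.

    Residues are stored uppercase. ``alphabet`` is inferred when omitted.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} has empty residues")
        self.residues = self.residues.upper()
        if self.alphabet is None:
            self.alphabet = infer_alphabet(self.residues)
        else:
            allowed = _NT_CHARS if self.alphabet == NUCLEOTIDE else _AA_CHARS
            if self.alphabet not in (NUCLEOTIDE, PROTEIN):
                raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
            bad = set(self.residues) - allowed
            if bad:
                raise AlphabetError(
                    f"sequence {self.id!r}: characters {sorted(bad)} not in {self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != NUCLEOTIDE:
            raise AlphabetError("reverse_complement requires a nucleotide sequence")
        return SeqRecord(
            id=self.id,
            residues=self.residues.translate(_COMPLEMENT)[::-1],
            description=self.description,
            alphabet=NUCLEOTIDE,
        )

    def slice(self, start: int, end: int, suffix: str = "") -> "SeqRecord":
        """0-based half-open subsequence, with an optional id suffix."""
        if not (0 <= start < end <= len(self.residues)):
            raise InputError(f"invalid slice [{start}, {end}) on {self.id!r} (length {len(self)})")
        return SeqRecord(
            id=self.id + suffix,
            residues=self.residues[start:end],
            description=self.description,
            alphabet=self.alphabet,
        )


def check_unique_ids(records: list[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise InputError(f"duplicate sequence id {r.id!r} in collection")
        seen.add(r.id)


def normalize_rna(residues: str) -> str:
    """Map U to T so RNA and DNA spellings compare as equal."""
    return residues.replace("U", "T")
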