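"""16S-23S internal transcribed spacer extraction and dissection.

The ITS between the 16S and 23S rRNA genes of an rrn operon is cut into
its canonical regions: the conserved domains D1-D1', D2, D3, boxA and D4
(constant lengths 12/5/12/7 bp for the motif-delimited ones), the variable
regions V2, boxB and V3, and the two spacer tRNAs (tRNA-Ile, 74 nt;
tRNA-Ala, 73 nt) when present. Region boundaries are anchored on short
conserved motifs (editable, see ``data/motifs.yaml``) plus the basal helix
motifs of boxB (AGCA...UGCU) and V3 (GUC...GAC); unnamed gaps between
landmarks are kept as explicit spacer regions so lengths always sum to the
ITS length.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import edlib
import pandas as pd
import yaml

from .errors import InputError, OrientationError
from .records import SeqRecord, normalize_rna

CANONICAL_ORDER = (
    "D1-D1'",
    "D2",
    "D3",
    "tRNA-Ile",
    "boxA",
    "D4",
    "V2",
    "tRNA-Ala",
    "boxB",
    "V3",
)

TABLE1_COLUMNS = (
    "ITS length (tRNA removed)",
    "D1-D1'",
    "D2",
    "D3",
    "tRNA-Ile",
    "boxA",
    "D4",
    "V2",
    "tRNA-Ala",
    "boxB",
    "V3",
)

_TRNA_LENGTH_TOLERANCE = 2
EXPECTED_TRNA_LENGTHS = {"tRNA-Ile": 74, "tRNA-Ala": 73}


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Motif:
    sequence: str
    max_mismatches: int = 1


def _data_text(name: str) -> str:
    return resources.files("taxodelim.data").joinpath(name).read_text()


def load_motifs(path: str | None = None) -> dict[str, Motif]:
    """Load landmark motif definitions (bundled defaults unless ``path`` given)."""
    text = open(path).read() if path else _data_text("motifs.yaml")
    raw = yaml.safe_load(text)
    return {
        name: Motif(d["sequence"].upper(), int(d.get("max_mismatches", 1)))
        for name, d in raw.items()
    }


def _read_bundled_fasta(name: str) -> list[SeqRecord]:
    records = []
    rid, desc, chunks = None, "", []
    for line in _data_text(name).splitlines():
        if line.startswith(">"):
            if rid is not None:
                records.append(SeqRecord(rid, "".join(chunks), desc))
            head = line[1:].split(None, 1)
            rid, desc = head[0], head[1] if len(head) > 1 else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        records.append(SeqRecord(rid, "".join(chunks), desc))
    return records


def load_trna_refs() -> list[SeqRecord]:
    return _read_bundled_fasta("synthetic_trnas.fasta")


def load_anchors() -> tuple[SeqRecord, SeqRecord]:
    ssu, lsu = _read_bundled_fasta("synthetic_anchors.fasta")
    return ssu, lsu


def _find_exact_all(text: str, pattern: str) -> list[int]:
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _find_anchor(genome: str, anchor: str, max_edit: int) -> list[tuple[int, int]]:
    """All exact occurrences, else the best approximate one (edit distance <= max_edit)."""
    exact = _find_exact_all(genome, anchor)
    if exact:
        return [(i, i + len(anchor)) for i in exact]
    res = edlib.align(anchor, genome, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_edit:
        return []
    s, e = res["locations"][0]
    return [(s, e + 1)]


def extract_its(
    genome: SeqRecord,
    ssu_anchor: SeqRecord | None = None,
    lsu_anchor: SeqRecord | None = None,
    max_edit_fraction: float = 0.1,
) -> list[SeqRecord]:
    """One ITS record per rrn operon: the span strictly between the 16S end
    and the 23S start anchor matches. Both strands are searched; reverse-strand
    operons are returned in sense orientation."""
    if ssu_anchor is None or lsu_anchor is None:
        default_ssu, default_lsu = load_anchors()
        ssu_anchor = ssu_anchor or default_ssu
        lsu_anchor = lsu_anchor or default_lsu

    def scan(seq: str) -> list[tuple[int, int]]:
        ssu = _find_anchor(seq, ssu_anchor.residues, int(max_edit_fraction * len(ssu_anchor)))
        lsu = _find_anchor(seq, lsu_anchor.residues, int(max_edit_fraction * len(lsu_anchor)))
        spans = []
        for _, ssu_end in ssu:
            following = [ls for ls, _ in lsu if ls > ssu_end]
            if following:
                spans.append((ssu_end, min(following)))
        return spans, bool(ssu), bool(lsu)

    fwd_spans, fwd_ssu, fwd_lsu = scan(genome.residues)
    rc = genome.reverse_complement()
    rev_spans, rev_ssu, rev_lsu = scan(rc.residues)
    if not fwd_spans and not rev_spans:
        if (fwd_ssu and rev_lsu and not fwd_lsu and not rev_ssu) or (
            rev_ssu and fwd_lsu and not rev_lsu and not fwd_ssu
        ):
            raise OrientationError(
                f"{genome.id}: 16S and 23S anchors matched on opposite strands"
            )
        warnings.warn(f"{genome.id}: no rrn anchor pair found; no ITS extracted")
        return []
    records = []
    for n, (s, e) in enumerate(fwd_spans + rev_spans, start=1):
        src = genome if n <= len(fwd_spans) else rc
        strand = "+" if n <= len(fwd_spans) else "-"
        records.append(
            SeqRecord(
                id=f"{genome.id}_ITS{n}",
                residues=src.residues[s:e],
                description=f"16S-23S ITS, operon {n}, strand {strand}",
            )
        )
    return records


def locate_trnas(
    its: SeqRecord,
    trna_refs: list[SeqRecord] | None = None,
    max_edit_fraction: float = 0.1,
) -> list[tuple[str, int, int]]:
    """Locate spacer tRNAs by alignment against the bundled references.

    Returns (name, start, end) sorted by start; overlapping calls keep the
    better-scoring tRNA with a warning.
    """
    if not its.residues:
        raise InputError("empty ITS")
    refs = trna_refs if trna_refs is not None else load_trna_refs()
    calls = []
    for ref in refs:
        res = edlib.align(ref.residues, normalize_rna(its.residues), mode="HW", task="locations")
        max_edit = int(max_edit_fraction * len(ref))
        if res["editDistance"] < 0 or res["editDistance"] > max_edit:
            continue
        s, e = res["locations"][0]
        calls.append((res["editDistance"], ref.id, s, e + 1))
    kept: list[tuple[str, int, int]] = []
    for dist, name, s, e in sorted(calls):
        if any(s < ke and ks < e for _, ks, ke in kept):
            warnings.warn(f"{its.id}: overlapping tRNA call {name} dropped")
            continue
        kept.append((name, s, e))
    kept.sort(key=lambda c: c[1])
    return kept


def find_motif(
    text: str,
    motif: Motif,
    start: int = 0,
    end: int | None = None,
) -> tuple[int, int] | None:
    """Leftmost lowest-mismatch ungapped occurrence of the motif in [start, end).

    Returns (position, mismatches) or None.
    """
    end = len(text) if end is None else end
    m = motif.sequence
    best: tuple[int, int] | None = None
    for i in range(start, end - len(m) + 1):
        mm = sum(1 for a, b in zip(text[i : i + len(m)], m) if a != b)
        if mm <= motif.max_mismatches and (best is None or mm < best[1]):
            best = (i, mm)
            if mm == 0:
                break
    return best


def dissect(
    its: SeqRecord,
    motifs: dict[str, Motif] | None = None,
    trna_refs: list[SeqRecord] | None = None,
) -> "ItsDissection":
    """Assign all canonical ITS regions (or flag them absent).

    Landmarks are located in canonical order, each searched downstream of the
    previous found landmark; variable regions fill the intervals between
    landmarks, and residual gaps become explicit spacer regions.
    """
    if not its.residues:
        raise InputError("empty ITS")
    motifs = motifs or load_motifs()
    seq = normalize_rna(its.residues)
    n = len(seq)
    trnas = {name: (s, e) for name, s, e in locate_trnas(its, trna_refs)}
    found: dict[str, tuple[int, int]] = {}
    absent: list[str] = []

    ile = trnas.get("tRNA-Ile")
    ala = trnas.get("tRNA-Ala")
    if ile:
        found["tRNA-Ile"] = ile
    else:
        absent.append("tRNA-Ile")
    if ala:
        found["tRNA-Ala"] = ala
    else:
        absent.append("tRNA-Ala")

    cursor = 0
    # D2 bounds D1-D1' on the right; search it before the first tRNA.
    d2_window_end = ile[0] if ile else (ala[0] if ala else n)
    hit = find_motif(seq, motifs["d2"], 0, d2_window_end)
    if hit:
        d2_start = hit[0]
        found["D2"] = (d2_start, d2_start + len(motifs["d2"].sequence))
        found["D1-D1'"] = (0, d2_start)
        cursor = found["D2"][1]
    else:
        absent.extend(["D1-D1'", "D2"])

    hit = find_motif(seq, motifs["d3"], cursor, d2_window_end)
    if hit:
        found["D3"] = (hit[0], hit[0] + len(motifs["d3"].sequence))
        cursor = found["D3"][1]
    else:
        absent.append("D3")

    boxa_from = ile[1] if ile else cursor
    hit = find_motif(seq, motifs["boxa"], boxa_from, ala[0] if ala else n)
    if hit:
        found["boxA"] = (hit[0], hit[0] + len(motifs["boxa"].sequence))
        cursor = found["boxA"][1]
    else:
        absent.append("boxA")

    hit = find_motif(seq, motifs["d4"], cursor, ala[0] if ala else n)
    if hit:
        found["D4"] = (hit[0], hit[0] + len(motifs["d4"].sequence))
        cursor = found["D4"][1]
    else:
        absent.append("D4")

    # boxB: basal AGCA ... UGCU, searched after tRNA-Ala (or after D4).
    boxb_from = ala[1] if ala else cursor
    boxb = None
    bstart = find_motif(seq, motifs["boxb_start"], boxb_from, n)
    if bstart:
        bend = find_motif(seq, motifs["boxb_end"], bstart[0] + len(motifs["boxb_start"].sequence), n)
        if bend:
            boxb = (bstart[0], bend[0] + len(motifs["boxb_end"].sequence))
            found["boxB"] = boxb
    if boxb is None:
        absent.append("boxB")

    # V2 fills from D4 to the next landmark (tRNA-Ala, else boxB).
    if "D4" in found:
        v2_end = ala[0] if ala else (boxb[0] if boxb else None)
        if v2_end is not None and v2_end >= found["D4"][1]:
            found["V2"] = (found["D4"][1], v2_end)
        else:
            absent.append("V2")
    else:
        absent.append("V2")

    # V3: from the basal GUC after boxB through the ITS end (closing GAC).
    v3_from = boxb[1] if boxb else (ala[1] if ala else cursor)
    vstart = find_motif(seq, motifs["v3_start"], v3_from, n)
    if vstart:
        found["V3"] = (vstart[0], n)
        if not seq.endswith(motifs["v3_end"].sequence):
            warnings.warn(f"{its.id}: V3 does not close with {motifs['v3_end'].sequence}")
    else:
        absent.append("V3")

    regions = [Region(name, s, e) for name, (s, e) in found.items()]
    regions.sort(key=lambda r: (r.start, r.end))
    # Fill unassigned gaps with explicit spacers.
    full: list[Region] = []
    pos = 0
    for r in regions:
        if r.start > pos:
            full.append(Region("spacer", pos, r.start))
        full.append(r)
        pos = max(pos, r.end)
    if pos < n:
        full.append(Region("spacer", pos, n))
    trna_total = sum(e - s for s, e in trnas.values())
    return ItsDissection(
        source_id=its.id,
        regions=full,
        absent=tuple(absent),
        its_length=n,
        total_length_trna_removed=n - trna_total,
    )


@dataclass
class ItsDissection:
    """Coordinate-anchored ITS regions for one operon (one summary-table row)."""

    source_id: str
    regions: list[Region]
    absent: tuple[str, ...]
    its_length: int
    total_length_trna_removed: int

    def __post_init__(self) -> None:
        prev_end = 0
        for r in self.regions:
            if r.start < prev_end:
                raise InputError(f"{self.source_id}: overlapping regions at {r.name}")
            prev_end = r.end

    def region(self, name: str) -> Region | None:
        for r in self.regions:
            if r.name == name:
                return r
        return None

    def length_of(self, name: str) -> int | None:
        r = self.region(name)
        return None if r is None else r.length

    @property
    def zero_length_regions(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions if r.length == 0)

    def non_spacer_regions(self) -> list[Region]:
        return [r for r in self.regions if r.name != "spacer"]


def length_table(dissections: list[ItsDissection]) -> pd.DataFrame:
    """Region-length summary table, one row per dissected ITS.

    Absent regions are rendered as '-'.
    """
    if not dissections:
        raise InputError("length_table requires at least one dissection")
    rows = []
    for d in dissections:
        row: dict[str, object] = {"Strain": d.source_id, TABLE1_COLUMNS[0]: d.total_length_trna_removed}
        for name in CANONICAL_ORDER:
            length = d.length_of(name)
            row[name] = length if length is not None else "-"
        rows.append(row)
    return pd.DataFrame(rows, columns=("Strain",) + TABLE1_COLUMNS).set_index("Strain")


def regions_to_bed(d: ItsDissection) -> str:
    """BED-like text (0-based half-open) for one dissection."""
    lines = [f"{d.source_id}\t{r.start}\t{r.end}\t{r.name}" for r in d.regions]
    return "\n".join(lines) + "\n"
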