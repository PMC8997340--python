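"""File formats: FASTA, GenBank-lite, extended tabular hits, Newick helpers.

FASTA goes through Biopython (wrapped at 60 columns on output). Hit tables
use the familiar 12-column tabular search dialect (qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore) extended
with two columns: percent_similarity and a semicolon-joined subject
lineage. Coordinates are 1-based inclusive in the tabular dialect and
0-based half-open in memory.
"""

from __future__ import annotations

import warnings
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .align import HitRecord
from .errors import ParseError
from .records import SeqRecord


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (possibly multi-record, CRLF-tolerant) FASTA file."""
    records = []
    text = Path(path).read_text().replace("\r\n", "\n").replace("\r", "\n")
    # reject headers that are not headers before handing to Biopython
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line and not line.startswith((">", ";")) and records == [] and lineno == 1:
            raise ParseError("FASTA must start with a '>' header", line=lineno)
        break
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        if not rec.id:
            raise ParseError(f"FASTA record with empty id in {path}")
        records.append(SeqRecord(id=rec.id, residues=str(rec.seq), description=rec.description[len(rec.id) :].strip()))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def read_genbank_lite(path: str | Path) -> SeqRecord:
    """Parse only the LOCUS line and the ORIGIN sequence block.

    Deliberately lenient: everything between LOCUS and ORIGIN is ignored, so
    records trimmed down to those two blocks parse fine. A LOCUS length that
    disagrees with the ORIGIN sequence raises a warning, not an error.
    """
    name, stated_len, seq_chunks = None, None, []
    in_origin = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("LOCUS"):
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError("LOCUS line lacks a record name", line=lineno)
                name = fields[1]
                for i, f in enumerate(fields):
                    if f == "bp" and i > 0 and fields[i - 1].isdigit():
                        stated_len = int(fields[i - 1])
            elif line.startswith("ORIGIN"):
                in_origin = True
            elif line.startswith("//"):
                in_origin = False
            elif in_origin:
                seq_chunks.append("".join(c for c in line if c.isalpha()))
    if not seq_chunks:
        raise ParseError(f"no ORIGIN sequence block found in {path}")
    residues = "".join(seq_chunks).upper()
    if name is None:
        raise ParseError(f"no LOCUS line found in {path}")
    if stated_len is not None and stated_len != len(residues):
        warnings.warn(
            f"{path}: LOCUS length {stated_len} != ORIGIN length {len(residues)}"
        )
    return SeqRecord(id=name, residues=residues)


HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore psim lineage"
).split()


def write_hits(hits: list[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_start + 1),
                        str(h.query_end),
                        str(h.subject_start + 1),
                        str(h.subject_end),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                        f"{h.percent_similarity:.2f}",
                        ";".join(h.subject_lineage),
                    ]
                )
                + "\n"
            )


def read_hits(path: str | Path, query_lengths: dict[str, int] | None = None) -> list[HitRecord]:
    """Read the extended tabular hit format.

    ``query_lengths`` (id -> residues) is needed to reconstruct query
    coverage; without it coverage falls back to the aligned span over the
    span end (an upper-bound-free guess) — pass lengths whenever the
    downstream screen filters on coverage.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ParseError(f"expected >= 13 tab-separated columns, got {len(fields)}", line=lineno)
            (qid, sid, pident, length, mism, gapo, qs, qe, ss, se, ev, bs, psim) = fields[:13]
            lineage = tuple(x for x in (fields[13] if len(fields) > 13 else "").split(";") if x)
            qstart, qend = int(qs) - 1, int(qe)
            span = qend - qstart
            if query_lengths and qid in query_lengths:
                coverage = span / query_lengths[qid]
            else:
                coverage = 1.0
            try:
                hits.append(
                    HitRecord(
                        query_id=qid,
                        subject_id=sid,
                        percent_identity=float(pident),
                        percent_similarity=float(psim),
                        alignment_length=int(length),
                        query_coverage=min(coverage, 1.0),
                        evalue=float(ev),
                        bitscore=float(bs),
                        subject_lineage=lineage,
                        mismatches=int(mism),
                        gap_opens=int(gapo),
                        query_start=qstart,
                        query_end=qend,
                        subject_start=int(ss) - 1,
                        subject_end=int(se),
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return hits


def write_text(text: str, path: str | Path) -> None:
    Path(path).write_text(text)
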