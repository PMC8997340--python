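#!/usr/bin/env python
"""Optional helper: download the deposited reference chromosome (GenBank
accession CP072600) and report its basic statistics and ITS dissection.

Requires network access; nothing in the test suite or the acceptance
script depends on this helper. The bundled dissection motifs are synthetic
stand-ins, so on the real chromosome the genome statistics (length, GC%)
are the reliable outputs while the ITS dissection requires organism-specific
motif definitions (see --motifs).

Usage:
    python scripts/fetch_reference_genome.py --out scratch/CP072600.fasta
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id=CP072600&rettype=fasta&retmode=text"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--motifs", type=Path, default=None, help="Organism-specific motif YAML.")
    args = parser.parse_args()

    args.out.parent.mkdir(parents=True, exist_ok=True)
    print(f"fetching CP072600 -> {args.out}", file=sys.stderr)
    with urllib.request.urlopen(EUTILS, timeout=120) as resp:
        args.out.write_bytes(resp.read())

    from taxodelim.io import read_fasta
    from taxodelim.its import dissect, extract_its, length_table, load_motifs
    from taxodelim.metrics import genome_stats

    genome = read_fasta(args.out)[0]
    length, gc = genome_stats(genome)
    print(f"{genome.id}\tlength={length:,} bp\tGC={gc:.1f}%")

    motifs = load_motifs(str(args.motifs)) if args.motifs else None
    its_records = extract_its(genome)
    if not its_records:
        print("no ITS found with the bundled synthetic anchors (expected on real data;", file=sys.stderr)
        print("supply organism-specific anchors/motifs for a real dissection)", file=sys.stderr)
        return
    dissections = [dissect(its, motifs=motifs) for its in its_records]
    print(length_table(dissections).to_string())


if __name__ == "__main__":
    main()
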