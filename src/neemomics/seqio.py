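"""Small sequence/format helpers shared across the package.

FASTA is read and written through Biopython; GFF3 gene models use a minimal
reader/writer restricted to the gene/mRNA/exon/CDS features this package
produces and consumes (1-based inclusive coordinates throughout).
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, contigs: Dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(path: str | os.PathLike, rows: Iterable[Tuple]) -> None:
    """Write GFF3 rows given as (contig, source, type, start, end, score,
    strand, phase, attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gff3(path: str | os.PathLike):
    """Yield (contig, type, start, end, strand, phase, attrs-dict) tuples."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = {}
            for kv in f[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            phase = None if f[7] == "." else int(f[7])
            yield f[0], f[2], int(f[3]), int(f[4]), f[6], phase, attrs
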