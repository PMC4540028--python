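"""Truth-alignment read simulator.

Reads are drawn from a genotype's assembly; because the panel generator
retains an exact reference/query alignment map, every read is emitted as a
SAM record placed at its true reference origin with the correct gapped
alignment (insertions and deletions from the planted edits; leading or
trailing bases that fall inside an inserted segment are soft-clipped). No
external aligner is involved, so alignment truth is exact by construction.

Sequencing is idealized: error-free bases, constant Q40 qualities, single
fixed read length, no GC or insert-size modelling.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .panel import AlignmentOp, Panel, PanelConfig


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    contig: str
    ref_start: int  # 0-based leftmost aligned reference position
    cigar: str
    sequence: str


def _identity_map(length: int) -> List[AlignmentOp]:
    return [("M", 0, 0, length)]


def _cigar_for(
    ops: Sequence[AlignmentOp], qs: int, qe: int
) -> Optional[Tuple[int, str]]:
    """Reference start and CIGAR for the query interval [qs, qe)."""
    pieces: List[Tuple[str, int]] = []
    ref_start = None
    q_starts = [op[2] for op in ops]
    i = max(0, bisect_right(q_starts, qs) - 1)
    for kind, rstart, qstart, ln in ops[i:]:
        if kind == "D":
            # zero query extent; internal only
            if qs < qstart < qe and pieces:
                pieces.append(("D", ln))
            continue
        if qstart >= qe:
            break
        ov_s = max(qstart, qs)
        ov_e = min(qstart + ln, qe)
        if ov_e <= ov_s:
            continue
        if kind == "M":
            if ref_start is None:
                ref_start = rstart + (ov_s - qstart)
            pieces.append(("M", ov_e - ov_s))
        else:  # insertion relative to the reference
            pieces.append(("I", ov_e - ov_s))
    if ref_start is None:
        return None  # read lies entirely within an inserted segment
    # leading/trailing I become soft clips; strip dangling D
    while pieces and pieces[0][0] in ("I", "D"):
        op, ln = pieces.pop(0)
        if op == "I":
            pieces.insert(0, ("S", ln))
            break
    while pieces and pieces[-1][0] in ("I", "D"):
        op, ln = pieces.pop()
        if op == "I":
            pieces.append(("S", ln))
            break
    merged: List[Tuple[str, int]] = []
    for op, ln in pieces:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    cigar = "".join(f"{ln}{op}" for op, ln in merged)
    return ref_start, cigar


def simulate_reads(
    assembly: Dict[str, str],
    config: PanelConfig,
    alignment_maps: Optional[Dict[str, List[AlignmentOp]]] = None,
    genotype: str = "G1",
    seed: Optional[int] = None,
) -> List[SimulatedRead]:
    """Sample reads to the configured coverage and derive truth alignments.

    ``alignment_maps`` maps contig name to the reference/query alignment
    ops for this genotype; omitted contigs are assumed identical to the
    reference. Read starts are uniform with overhanging starts clipped to
    the contig, which keeps mean depth equal to the nominal coverage.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(1)[0]
    )
    L = config.read_length
    reads: List[SimulatedRead] = []
    for contig in sorted(assembly):
        seq = assembly[contig]
        G = len(seq)
        if G < L:
            continue
        ops = (alignment_maps or {}).get(contig) or _identity_map(G)
        n = math.ceil(config.coverage * G / L)
        raw = rng.integers(-(L - 1), G, size=n)
        starts = np.clip(raw, 0, G - L)
        starts.sort()
        for i, s in enumerate(starts):
            s = int(s)
            placed = _cigar_for(ops, s, s + L)
            if placed is None:
                continue
            ref_start, cigar = placed
            reads.append(
                SimulatedRead(
                    name=f"{genotype}_{contig}_{i:06d}",
                    contig=contig,
                    ref_start=ref_start,
                    cigar=cigar,
                    sequence=seq[s : s + L],
                )
            )
    return reads


def simulate_genotype_reads(panel: Panel, genotype: str, seed: Optional[int] = None) -> List[SimulatedRead]:
    """Convenience wrapper pulling assembly and alignment maps off a panel."""
    maps = {
        contig: ops
        for (g, contig), ops in panel.alignment_maps.items()
        if g == genotype
    }
    base = panel.config.seed if seed is None else seed
    # distinct per-genotype stream
    offset = {"G1": 101, "G2": 202, "G3": 303}.get(genotype, 404)
    return simulate_reads(
        panel.assemblies[genotype], panel.config, maps, genotype, seed=base + offset
    )


def write_sam(
    reads: Iterable[SimulatedRead],
    reference: Dict[str, str],
    path,
    mapq: int = 60,
) -> None:
    """Write truth alignments as a text SAM file (coordinate-sorted)."""
    reads = sorted(reads, key=lambda r: (r.contig, r.ref_start))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig, seq in reference.items():
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(seq)}\n")
        for r in reads:
            qual = "I" * len(r.sequence)
            fh.write(
                f"{r.name}\t0\t{r.contig}\t{r.ref_start + 1}\t{mapq}\t{r.cigar}"
                f"\t*\t0\t0\t{r.sequence}\t{qual}\n"
            )


def write_fastq(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def mean_depth(reads: Sequence[SimulatedRead], contig: str, contig_length: int) -> float:
    """Mean aligned-base depth over one contig (M ops only)."""
    total = 0
    for r in reads:
        if r.contig != contig:
            continue
        num = ""
        for ch in r.cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch == "M":
                    total += int(num)
                num = ""
    return total / contig_length
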