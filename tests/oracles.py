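"""Independent oracles used by the test suite.

These deliberately re-derive results through a different computational path
than the library (exhaustive enumeration, whole-protein translation), so
agreement is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

from typing import Dict, Set, Tuple

from Bio.Seq import Seq

_VALID = set("ACGT")


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n)
    )


def brute_force_ssrs(
    sequence: str, min_repeats: Dict[int, int]
) -> Set[Tuple[int, int, str, int]]:
    """Exhaustive tandem-repeat enumeration: every start position is tested
    as the leftmost point of a maximal period-k run, counting full motif
    copies directly. Returns {(start_1based, end_1based, motif, count)}."""
    seq = sequence.upper()
    n = len(seq)
    found: Set[Tuple[int, int, str, int]] = set()
    for k, minrep in min_repeats.items():
        for i in range(n - k * minrep + 1):
            motif = seq[i : i + k]
            if not set(motif) <= _VALID:
                continue
            if not _primitive(motif):
                continue
            # leftmost: the period-k run must not extend to i-1
            if i > 0 and seq[i - 1] in _VALID and seq[i - 1] == seq[i - 1 + k]:
                continue
            c = 1
            while seq[i + c * k : i + (c + 1) * k] == motif:
                c += 1
            if c >= minrep:
                found.add((i + 1, i + c * k, motif, c))
    return found


def whole_protein_effect(
    gene, contig_seq: str, position: int, alt_base: str
) -> str:
    """Classify a CDS SNP by translating the full reference and mutant
    proteins and diffing them (independent of any codon arithmetic)."""
    mutant = contig_seq[: position - 1] + alt_base + contig_seq[position:]

    def protein(seq: str) -> str:
        spliced = "".join(seq[s - 1 : e] for s, e, _ in gene.cds)
        if gene.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return str(Seq(spliced).translate())

    ref_prot, alt_prot = protein(contig_seq), protein(mutant)
    if ref_prot == alt_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    i = diffs[0]
    if i == 0 and ref_prot[0] == "M":
        return "start_lost"
    if alt_prot[i] == "*":
        return "stop_gained"
    if ref_prot[i] == "*":
        return "stop_lost"
    return "nonsynonymous"
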