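"""Microsatellite (SSR) detection and canonical motif classification.

A simple sequence repeat is a tandem run of a primitive 1-6 bp motif. The
scanner reports, for every unit length, each maximal perfect tandem region
whose number of full motif copies meets a per-unit-length minimum (defaults
follow the MISA tool's shipped configuration: mono >=10, di >=6, tri through
hexa >=5 copies). Runs whose motif is itself a repetition of a shorter unit
(e.g. "ATAT") are reported only under the shorter, primitive unit.

Motif classes group a motif with all cyclic rotations of itself and of its
reverse complement, labelled "X/revcomp(X)" with X the lexicographically
smallest rotation — e.g. CTT runs belong to class AAG/CTT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..seqio import revcomp

#: MISA default minimum copy numbers per unit length.
MISA_MIN_REPEATS: Dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: MISA default maximum interruption (bp) between SSRs merged as compound.
MISA_MAX_INTERRUPTION = 100

_VALID_BASES = frozenset(b"ACGT")


@dataclass(frozen=True)
class SSRThresholds:
    """Detection thresholds: minimum full-copy counts keyed by unit length."""

    min_repeats: Dict[int, int] = field(default_factory=lambda: dict(MISA_MIN_REPEATS))
    max_interruption: int = MISA_MAX_INTERRUPTION

    def __post_init__(self):
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")

    @classmethod
    def relaxed(cls, min_repeats: int = 2) -> "SSRThresholds":
        """Uniform low threshold, used when re-counting a known locus."""
        return cls(min_repeats={k: min_repeats for k in range(1, 7)})


@dataclass(frozen=True)
class SSRLocus:
    """One detected microsatellite (coordinates 1-based inclusive)."""

    contig: str
    start: int
    end: int
    motif: str
    repeat_count: int
    compound: bool = False
    interruption: int = 0

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.motif)


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical strand-invariant class label "X/revcomp(X)" for a motif.

    X is the lexicographic minimum over all cyclic rotations of the motif
    and of its reverse complement, so the label is invariant under rotation
    and strand flip.
    """
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    x = min(rotations)
    return f"{x}/{revcomp(x)}"


def scan_ssrs(
    sequence: str,
    thresholds: SSRThresholds | None = None,
    contig: str = "seq",
) -> List[SSRLocus]:
    """Find all maximal primitive-motif tandem repeats meeting thresholds.

    Runs containing N (or any non-ACGT character once validated) are split at
    the offending base; reported spans never overlap an N. Loci are returned
    sorted by start position then unit length.
    """
    thresholds = thresholds or SSRThresholds()
    if not sequence:
        return []
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    bad = ~valid & (arr != ord("N"))
    if bad.any():
        pos = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"invalid character {sequence[pos]!r} at position {pos + 1} of {contig}"
        )
    seq = sequence.upper()
    loci: List[SSRLocus] = []
    n = len(seq)
    for k, min_rep in sorted(thresholds.min_repeats.items()):
        if n < k * min_rep:
            continue
        eq = (arr[k:] == arr[:-k]) & valid[k:] & valid[:-k]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.view(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for a, b in zip(starts.tolist(), ends.tolist()):
            # eq indices [a, b) correspond to sequence region [a, b + k)
            region_len = (b - a) + k
            count = region_len // k
            if count < min_rep:
                continue
            motif = seq[a : a + k]
            if not is_primitive(motif):
                continue
            loci.append(
                SSRLocus(
                    contig=contig,
                    start=a + 1,
                    end=a + count * k,
                    motif=motif,
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def find_compound(
    loci: Sequence[SSRLocus], max_interruption: int = MISA_MAX_INTERRUPTION
) -> List[SSRLocus]:
    """Merge SSRs on the same contig lying within ``max_interruption`` bases
    into compound loci.

    Returns one locus per merged group: singleton groups come back unchanged;
    merged groups carry the outer span, the first member's motif, the summed
    repeat count, ``compound=True`` and the largest gap as ``interruption``.
    Repeat-count comparison across genotypes is ill-defined for compound
    structures, so polymorphism calling excludes them.
    """
    out: List[SSRLocus] = []
    by_contig: Dict[str, List[SSRLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig, []).append(locus)
    for contig in by_contig:
        group: List[SSRLocus] = []
        for locus in sorted(by_contig[contig], key=lambda l: (l.start, l.end)):
            if group and locus.start - group[-1].end - 1 <= max_interruption:
                group.append(locus)
            else:
                if group:
                    out.append(_emit_group(group))
                group = [locus]
        if group:
            out.append(_emit_group(group))
    out.sort(key=lambda l: (l.contig, l.start))
    return out


def _emit_group(group: List[SSRLocus]) -> SSRLocus:
    if len(group) == 1:
        return group[0]
    gaps = [b.start - a.end - 1 for a, b in zip(group, group[1:])]
    first = group[0]
    return SSRLocus(
        contig=first.contig,
        start=first.start,
        end=max(l.end for l in group),
        motif=first.motif,
        repeat_count=sum(l.repeat_count for l in group),
        compound=True,
        interruption=max(gaps),
    )


def scan_assembly(
    contigs: Dict[str, str], thresholds: SSRThresholds | None = None
) -> List[SSRLocus]:
    """Run :func:`scan_ssrs` over every contig of an assembly."""
    loci: List[SSRLocus] = []
    for name, seq in contigs.items():
        loci.extend(scan_ssrs(seq, thresholds, contig=name))
    return loci


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Tabulate loci (one row each) in the package's SSR TSV layout."""
    rows = [
        {
            "contig": l.contig,
            "start": l.start,
            "end": l.end,
            "motif": l.motif,
            "class": l.canonical_class,
            "unit_length": l.unit_length,
            "repeat_count": l.repeat_count,
            "compound": l.compound,
            "interruption": l.interruption,
        }
        for l in loci
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "start",
            "end",
            "motif",
            "class",
            "unit_length",
            "repeat_count",
            "compound",
            "interruption",
        ],
    )


def summarize_ssrs(
    loci: Sequence[SSRLocus],
    gene_spans: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Dict[str, pd.Series]:
    """Count loci per canonical class and per unit length, with an optional
    genic/non-genic split (a locus is genic if it overlaps any gene span by
    at least one base).
    """
    classes = pd.Series([l.canonical_class for l in loci], dtype=object)
    units = pd.Series([l.unit_length for l in loci], dtype=int)
    summary = {
        "by_class": classes.value_counts().sort_index(),
        "by_unit_length": units.value_counts().sort_index(),
        "total": pd.Series({"n_loci": len(loci)}),
    }
    if gene_spans is not None:
        spans_by_contig: Dict[str, List[Tuple[int, int]]] = {}
        for contig, s, e in gene_spans:
            spans_by_contig.setdefault(contig, []).append((s, e))
        genic = 0
        for l in loci:
            for s, e in spans_by_contig.get(l.contig, ()):
                if l.start <= e and l.end >= s:
                    genic += 1
                    break
        summary["genic"] = pd.Series({"genic": genic, "non_genic": len(loci) - genic})
    return summary
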