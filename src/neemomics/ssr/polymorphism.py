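"""Cross-genotype SSR polymorphism calling by flank anchoring.

Each reference SSR locus is carried with 100 bp of immediately adjacent
sequence on both sides. The two flanks are located in a query assembly by
exact 31-mer seeding followed by full-flank verification allowing up to two
mismatches per flank; a locus is matched only when both flanks place
uniquely, on one contig, in consistent orientation and order, and the span
between them has not inflated beyond the locus length plus a fixed slack.
The inter-flank query sequence is then re-scanned for the repeat (with a
relaxed two-copy minimum so shrunken runs are still countable) and the
locus is classified polymorphic, monomorphic, class_changed or unresolved.
A locus concordantly polymorphic against every query genotype joins the
marker shortlist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from ..seqio import revcomp
from .detect import SSRLocus, SSRThresholds, scan_ssrs

log = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 100
SEED_K = 31
MAX_MISMATCH_PER_FLANK = 2
SPAN_SLACK = 200


@dataclass(frozen=True)
class SSRRegion:
    locus: SSRLocus
    left_flank: str
    right_flank: str
    flank_truncated: bool


@dataclass(frozen=True)
class FlankHit:
    contig: str
    start: int  # 1-based
    end: int
    strand: str  # '+' | '-'
    mismatches: int


@dataclass(frozen=True)
class LocusMatch:
    region: SSRRegion
    query_contig: str
    left_hit: FlankHit
    right_hit: FlankHit
    orientation: str  # forward | reverse
    inter_flank_span: int
    unique: bool


@dataclass(frozen=True)
class PolymorphicSSR:
    match: LocusMatch
    ref_repeat_count: int
    query_repeat_count: int
    query_class: str  # canonical class or "absent"
    status: str  # polymorphic | monomorphic | class_changed | unresolved

    @property
    def locus(self) -> SSRLocus:
        return self.match.region.locus


def extract_regions(
    assembly: Dict[str, str],
    loci: Sequence[SSRLocus],
    flank_len: int = DEFAULT_FLANK_LEN,
) -> List[SSRRegion]:
    """Cut each locus's immediate flanks out of its contig.

    ``flank_truncated`` marks loci closer than ``flank_len`` to a contig
    end; such regions are excluded from anchoring downstream.
    """
    regions = []
    for locus in loci:
        seq = assembly.get(locus.contig)
        if seq is None:
            raise ValueError(f"locus contig {locus.contig!r} absent from assembly")
        if locus.start < 1 or locus.end > len(seq):
            raise ValueError(
                f"locus {locus.contig}:{locus.start}-{locus.end} out of contig bounds"
            )
        left_start = max(0, locus.start - 1 - flank_len)
        left = seq[left_start : locus.start - 1]
        right = seq[locus.end : locus.end + flank_len]
        truncated = len(left) < flank_len or len(right) < flank_len
        regions.append(SSRRegion(locus, left, right, truncated))
    return regions


class KmerIndex:
    """Exact k-mer location index over the forward strands of an assembly."""

    def __init__(self, assembly: Dict[str, str], k: int = SEED_K):
        self.k = k
        self.assembly = assembly
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for contig, seq in assembly.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                self.index.setdefault(kmer, []).append((contig, i))

    def locate_flank(self, flank: str, max_mismatch: int) -> List[FlankHit]:
        """All placements of ``flank`` (either strand) with <= max_mismatch
        mismatches, found by multi-seed lookup and verification. Seeds are
        spread so that ``max_mismatch`` mismatches cannot hide every seed."""
        hits: Dict[Tuple[str, int, str], int] = {}
        for strand, query in (("+", flank), ("-", revcomp(flank))):
            n = len(query)
            if n < self.k:
                continue
            offsets = self._seed_offsets(n, max_mismatch + 1)
            candidates = set()
            for off in offsets:
                for contig, pos in self.index.get(query[off : off + self.k], ()):
                    candidates.add((contig, pos - off))
            for contig, start in candidates:
                seq = self.assembly[contig]
                if start < 0 or start + n > len(seq):
                    continue
                window = seq[start : start + n]
                mm = sum(a != b for a, b in zip(window, query))
                if mm <= max_mismatch:
                    key = (contig, start, strand)
                    prev = hits.get(key)
                    if prev is None or mm < prev:
                        hits[key] = mm
        return [
            FlankHit(contig, start + 1, start + len(flank), strand, mm)
            for (contig, start, strand), mm in sorted(hits.items())
        ]

    def _seed_offsets(self, flank_len: int, n_seeds: int) -> List[int]:
        span = flank_len - self.k
        if span <= 0:
            return [0]
        n = min(n_seeds, span + 1)
        return sorted({round(i * span / (n - 1)) for i in range(n)}) if n > 1 else [0]


def match_locus(
    region: SSRRegion,
    index: KmerIndex,
    max_mismatch_per_flank: int = MAX_MISMATCH_PER_FLANK,
    span_slack: int = SPAN_SLACK,
) -> Optional[LocusMatch]:
    """Anchor both flanks of a region in a query assembly.

    Returns None when either flank is missing or ambiguous, flanks land on
    different contigs/strands, are mis-ordered, or the inter-flank span
    exceeds the reference locus length plus ``span_slack``.
    """
    if region.flank_truncated or not region.left_flank or not region.right_flank:
        log.debug("skipping %s: truncated flank", region.locus)
        return None
    left_hits = index.locate_flank(region.left_flank, max_mismatch_per_flank)
    right_hits = index.locate_flank(region.right_flank, max_mismatch_per_flank)
    if len(left_hits) != 1 or len(right_hits) != 1:
        if left_hits and right_hits:
            lh, rh = left_hits[0], right_hits[0]
            return LocusMatch(region, lh.contig, lh, rh, "ambiguous", 0, unique=False)
        return None
    lh, rh = left_hits[0], right_hits[0]
    if lh.contig != rh.contig or lh.strand != rh.strand:
        return None
    if lh.strand == "+":
        span = rh.start - lh.end - 1
        ordered = rh.start > lh.end
        orientation = "forward"
    else:
        # on the minus strand the right flank precedes the left one
        span = lh.start - rh.end - 1
        ordered = lh.start > rh.end
        orientation = "reverse"
    if not ordered or span < 0:
        return None
    if span > region.locus.length + span_slack:
        return None
    return LocusMatch(region, lh.contig, lh, rh, orientation, span, unique=True)


def _inter_flank_sequence(match: LocusMatch, query_assembly: Dict[str, str]) -> str:
    seq = query_assembly[match.query_contig]
    if match.orientation == "forward":
        return seq[match.left_hit.end : match.right_hit.start - 1]
    return revcomp(seq[match.right_hit.end : match.left_hit.start - 1])


def call_polymorphism(
    region: SSRRegion,
    match: LocusMatch,
    query_assembly: Dict[str, str],
    count_thresholds: Optional[SSRThresholds] = None,
) -> PolymorphicSSR:
    """Classify a uniquely matched locus against the query repeat structure.

    The inter-flank query sequence is re-scanned with a relaxed two-copy
    minimum; the longest run of the reference canonical class provides the
    query repeat count. Absence of the class (including total deletion of
    the locus) is called polymorphic with query_class "absent"; a different
    class present is class_changed; N in the inter-flank sequence makes the
    locus unresolved.
    """
    if not match.unique:
        raise ValueError("polymorphism requires a unique locus match")
    count_thresholds = count_thresholds or SSRThresholds.relaxed(2)
    inter = _inter_flank_sequence(match, query_assembly)
    ref_locus = region.locus
    ref_class = ref_locus.canonical_class
    if "N" in inter:
        return PolymorphicSSR(match, ref_locus.repeat_count, 0, "unresolved", "unresolved")
    runs = scan_ssrs(inter, count_thresholds, contig=match.query_contig) if inter else []
    same_class = [r for r in runs if r.canonical_class == ref_class]
    if same_class:
        best = max(same_class, key=lambda r: r.length)
        status = "monomorphic" if best.repeat_count == ref_locus.repeat_count else "polymorphic"
        return PolymorphicSSR(match, ref_locus.repeat_count, best.repeat_count, ref_class, status)
    other = [r for r in runs if r.unit_length >= 2 or r.repeat_count >= 4]
    if other:
        best = max(other, key=lambda r: r.length)
        return PolymorphicSSR(
            match, ref_locus.repeat_count, best.repeat_count, best.canonical_class, "class_changed"
        )
    return PolymorphicSSR(match, ref_locus.repeat_count, 0, "absent", "polymorphic")


def call_pair(
    reference: Dict[str, str],
    loci: Sequence[SSRLocus],
    query_assembly: Dict[str, str],
    flank_len: int = DEFAULT_FLANK_LEN,
    max_mismatch_per_flank: int = MAX_MISMATCH_PER_FLANK,
) -> List[PolymorphicSSR]:
    """Full reference-vs-query pipeline: extract regions, anchor, classify.

    Compound and truncated-flank loci are excluded; ambiguous matches yield
    no call.
    """
    regions = extract_regions(reference, [l for l in loci if not l.compound], flank_len)
    index = KmerIndex(query_assembly)
    calls: List[PolymorphicSSR] = []
    for region in regions:
        if region.flank_truncated:
            continue
        match = match_locus(region, index, max_mismatch_per_flank)
        if match is None or not match.unique:
            continue
        calls.append(call_polymorphism(region, match, query_assembly))
    return calls


def concordant_polymorphic(
    *call_sets: Sequence[PolymorphicSSR],
) -> List[SSRLocus]:
    """Reference loci called polymorphic in every pairwise comparison.

    Call sets must derive from the same reference locus list (loci are keyed
    by contig/span/motif). Output is sorted by contig then start.
    """
    if not call_sets:
        raise ValueError("at least one call set required")

    def key(c: PolymorphicSSR):
        l = c.locus
        return (l.contig, l.start, l.end, l.motif)

    poly_keys = None
    loci_by_key = {}
    for calls in call_sets:
        keys = set()
        for c in calls:
            loci_by_key[key(c)] = c.locus
            if c.status == "polymorphic":
                keys.add(key(c))
        poly_keys = keys if poly_keys is None else (poly_keys & keys)
    shortlist = [loci_by_key[k] for k in poly_keys]
    shortlist.sort(key=lambda l: (l.contig, l.start))
    return shortlist
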