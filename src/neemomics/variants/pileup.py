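"""Pileup-based SNP and small-InDel calling from text SAM alignments.

The caller builds per-site base and gap columns from the gapped alignment
(CIGAR) of every read, then emits a haploid-style call wherever a single
alternate allele reaches a high fraction of the column (default 0.8 —
genotype-to-genotype assembly differences, not heterozygous sites). Variant
confidence is a Phred-scaled binomial tail probability of observing the
alternate count from sequencing error alone (fixed per-base error rate
0.01). Calls are filtered on a minimum column depth of 10 reads and variant
quality above 30; input records below a mapping-quality floor of 20 are
ignored. InDels are left-aligned against the reference before reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pysam
from scipy.stats import binom

log = logging.getLogger(__name__)

#: fixed per-base sequencing error rate used in the quality model
ERROR_RATE = 0.01

_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_CODE_BASE = "ACGT"


@dataclass
class EffectAnnotation:
    region_class: str = "intergenic"  # upstream|downstream|exonic|intronic|intergenic
    coding_effect: str = "none"  # synonymous|nonsynonymous|start_lost|stop_gained|stop_lost|none
    gene_id: Optional[str] = None


@dataclass
class VariantCall:
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    type: str  # SNP | insertion | deletion
    depth: int
    alt_count: int
    qual: float
    filter: str = "pass"  # pass | low_depth | low_qual
    effect: Optional[EffectAnnotation] = None

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


def phred_quality(alt_count: int, depth: int, error_rate: float = ERROR_RATE) -> float:
    """Phred-scaled probability of >= alt_count errors among depth draws."""
    if alt_count <= 0:
        return 0.0
    logsf = binom.logsf(alt_count - 1, depth, error_rate)
    return float(-10.0 * logsf / np.log(10.0))


def normalize_indel(contig_seq: str, pos: int, ref: str, alt: str) -> Tuple[int, str, str]:
    """Left-align an anchored indel against its contig (1-based ``pos``).

    Implements the standard normalization: repeatedly trim a shared trailing
    base, extending alleles leftward with the previous reference base when
    one empties; finally trim shared leading bases. Pure substitutions pass
    through unchanged.
    """
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 1:
            pos -= 1
            b = contig_seq[pos - 1]
            ref, alt = b + ref, b + alt
            changed = True
        if not changed:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


class _ContigColumns:
    """Per-contig accumulator of base counts and gap events."""

    __slots__ = ("length", "base_counts", "del_cover", "insertions", "deletions")

    def __init__(self, length: int):
        self.length = length
        self.base_counts = np.zeros((4, length), dtype=np.int32)
        self.del_cover = np.zeros(length, dtype=np.int32)
        self.insertions: Dict[Tuple[int, str], int] = {}
        self.deletions: Dict[Tuple[int, int], int] = {}


def pileup_call(
    alignments,
    reference: Dict[str, str],
    min_depth: int = 10,
    min_qual: float = 30.0,
    min_alt_fraction: float = 0.8,
    min_mapq: int = 20,
) -> List[VariantCall]:
    """Call SNPs and InDels from SAM alignments against a reference.

    ``alignments`` may be a path to a SAM file or an open
    :class:`pysam.AlignmentFile`. Calls are emitted whenever an alternate
    allele reaches ``min_alt_fraction`` of its column; the ``filter`` field
    records ``low_depth`` (depth < min_depth), ``low_qual`` (qual <=
    min_qual) or ``pass``.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), "r")
    columns: Dict[str, _ContigColumns] = {}
    for read in alignments:
        if read.is_unmapped:
            continue
        contig = read.reference_name
        if contig not in reference:
            raise ValueError(f"alignment references unknown contig {contig!r}")
        if read.mapping_quality < min_mapq:
            continue
        if contig not in columns:
            columns[contig] = _ContigColumns(len(reference[contig]))
        col = columns[contig]
        try:
            _accumulate(col, read)
        except Exception as exc:  # malformed CIGAR / record
            log.warning("skipping malformed record %s: %s", read.query_name, exc)
    calls: List[VariantCall] = []
    for contig in sorted(columns):
        calls.extend(
            _call_contig(
                contig,
                reference[contig],
                columns[contig],
                min_depth,
                min_qual,
                min_alt_fraction,
            )
        )
    return calls


def _accumulate(col: _ContigColumns, read) -> None:
    seq = read.query_sequence
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ref_pos = read.reference_start
    q = 0
    for op, ln in read.cigartuples:
        if op == 0 or op == 7 or op == 8:  # M/=/X
            block = codes[q : q + ln]
            idx = np.arange(ref_pos, ref_pos + ln)
            base_idx = np.searchsorted([65, 67, 71, 84], block)
            # map ASCII to 0..3; non-ACGT would misindex, guard:
            valid = np.isin(block, (65, 67, 71, 84))
            np.add.at(col.base_counts, (base_idx[valid], idx[valid]), 1)
            ref_pos += ln
            q += ln
        elif op == 1:  # I
            if ref_pos > 0:
                key = (ref_pos - 1, seq[q : q + ln])
                col.insertions[key] = col.insertions.get(key, 0) + 1
            q += ln
        elif op == 2:  # D
            if ref_pos > 0:
                key = (ref_pos - 1, ln)
                col.deletions[key] = col.deletions.get(key, 0) + 1
            col.del_cover[ref_pos : ref_pos + ln] += 1
            ref_pos += ln
        elif op == 4:  # S
            q += ln
        elif op == 5 or op == 6:  # H/P
            pass
        else:
            raise ValueError(f"unsupported CIGAR op {op}")


def _filter_label(depth: int, qual: float, min_depth: int, min_qual: float) -> str:
    if depth < min_depth:
        return "low_depth"
    if qual <= min_qual:
        return "low_qual"
    return "pass"


def _call_contig(
    contig: str,
    ref_seq: str,
    col: _ContigColumns,
    min_depth: int,
    min_qual: float,
    min_alt_fraction: float,
) -> List[VariantCall]:
    ref_codes = np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)
    ref_idx = np.searchsorted([65, 67, 71, 84], np.where(np.isin(ref_codes, (65, 67, 71, 84)), ref_codes, 65))
    base_depth = col.base_counts.sum(axis=0)
    depth = base_depth + col.del_cover
    counts = col.base_counts.copy()
    # mask the reference base so the max over rows is the top alternate
    counts[ref_idx, np.arange(col.length)] = 0
    alt_counts = counts.max(axis=0)
    alt_rows = counts.argmax(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
    snp_sites = np.nonzero((alt_counts > 0) & (frac >= min_alt_fraction))[0]

    calls: List[VariantCall] = []
    for p in snp_sites:
        ref_base = ref_seq[p]
        if ref_base not in "ACGT":
            continue
        alt_base = _CODE_BASE[alt_rows[p]]
        d = int(depth[p])
        ac = int(alt_counts[p])
        qual = phred_quality(ac, d)
        calls.append(
            VariantCall(
                contig=contig,
                position=int(p) + 1,
                ref_allele=ref_base,
                alt_allele=alt_base,
                type="SNP",
                depth=d,
                alt_count=ac,
                qual=qual,
                filter=_filter_label(d, qual, min_depth, min_qual),
            )
        )
    for (anchor, ins_seq), support in col.insertions.items():
        d = int(depth[anchor])
        if d == 0 or support / d < min_alt_fraction:
            continue
        ref = ref_seq[anchor]
        pos, nref, nalt = normalize_indel(ref_seq, anchor + 1, ref, ref + ins_seq)
        qual = phred_quality(support, d)
        calls.append(
            VariantCall(
                contig=contig,
                position=pos,
                ref_allele=nref,
                alt_allele=nalt,
                type="insertion",
                depth=d,
                alt_count=int(support),
                qual=qual,
                filter=_filter_label(d, qual, min_depth, min_qual),
            )
        )
    for (anchor, dlen), support in col.deletions.items():
        d = int(depth[anchor])
        if d == 0 or support / d < min_alt_fraction:
            continue
        ref = ref_seq[anchor : anchor + 1 + dlen]
        pos, nref, nalt = normalize_indel(ref_seq, anchor + 1, ref, ref_seq[anchor])
        qual = phred_quality(support, d)
        calls.append(
            VariantCall(
                contig=contig,
                position=pos,
                ref_allele=nref,
                alt_allele=nalt,
                type="deletion",
                depth=d,
                alt_count=int(support),
                qual=qual,
                filter=_filter_label(d, qual, min_depth, min_qual),
            )
        )
    calls.sort(key=lambda c: (c.contig, c.position, c.ref_allele, c.alt_allele))
    return calls
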