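"""Miniature variant-effect annotation against gene models.

Region classes follow the usual precedence: exonic > intronic >
upstream/downstream (within a 5 kb window of the nearest gene, by strand) >
intergenic. For SNPs falling in a CDS, the affected codon is rebuilt on the
coding strand and translated with the standard genetic code to classify
synonymous / nonsynonymous / start_lost / stop_gained / stop_lost changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from ..seqio import read_gff3, revcomp
from .pileup import EffectAnnotation, VariantCall

DEFAULT_FLANK_WINDOW = 5000


@dataclass
class GeneModel:
    """A protein-coding gene model (1-based inclusive spans).

    ``exons`` and ``cds`` are kept in genomic (left-to-right) order; for
    minus-strand genes transcription order is the reverse. Phases follow
    GFF3 semantics: bases to skip at the 5' end of each CDS piece to reach
    a codon boundary.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int, int]]  # (start, end, phase)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        total = sum(e - s + 1 for s, e, _ in self.cds)
        if total % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: CDS length {total} not divisible by 3")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_in_transcription_order(self) -> List[Tuple[int, int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def spliced_cds(self, contig_seq: str) -> str:
        """Coding-strand CDS sequence spliced across pieces."""
        parts = [contig_seq[s - 1 : e] for s, e, _ in self.cds]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def cds_offset_of(self, position: int) -> Optional[int]:
        """0-based offset of a genomic position within the spliced CDS,
        counted in the direction of transcription; None if not in the CDS."""
        offset = 0
        for s, e, _ in self.cds_in_transcription_order():
            if s <= position <= e:
                if self.strand == "+":
                    return offset + (position - s)
                return offset + (e - position)
            offset += e - s + 1
        return None


def load_gene_models(gff_path) -> List[GeneModel]:
    """Load gene models from a GFF3 file (gene/mRNA/exon/CDS features)."""
    genes: Dict[str, dict] = {}
    for contig, ftype, start, end, strand, phase, attrs in read_gff3(gff_path):
        if ftype == "gene":
            gid = attrs["ID"]
            genes[gid] = {"contig": contig, "strand": strand, "exons": [], "cds": []}
        elif ftype in ("exon", "CDS"):
            parent = attrs.get("Parent", "")
            gid = parent.split(".")[0]
            if gid not in genes:
                genes[gid] = {"contig": contig, "strand": strand, "exons": [], "cds": []}
            if ftype == "exon":
                genes[gid]["exons"].append((start, end))
            else:
                genes[gid]["cds"].append((start, end, phase or 0))
    models = []
    for gid, g in genes.items():
        exons = g["exons"] or [(s, e) for s, e, _ in g["cds"]]
        models.append(
            GeneModel(gene_id=gid, contig=g["contig"], strand=g["strand"], exons=exons, cds=g["cds"])
        )
    models.sort(key=lambda m: (m.contig, m.start))
    return models


def _classify_codon_change(ref_codon: str, alt_codon: str, codon_index: int) -> str:
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if codon_index == 0 and ref_codon == "ATG":
        return "start_lost"
    if ref_aa == "*":
        return "stop_lost"
    if alt_aa == "*":
        return "stop_gained"
    return "nonsynonymous"


def annotate_variant(
    call: VariantCall,
    models: Sequence[GeneModel],
    reference: Dict[str, str],
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> EffectAnnotation:
    """Classify one variant's genomic context and, for CDS SNPs, its
    coding effect. ``models`` should contain the genes of the variant's
    contig (others are ignored)."""
    pos = call.position
    contig_models = [m for m in models if m.contig == call.contig]

    # exonic (CDS classification has priority among overlapping genes)
    exonic_gene = None
    for m in contig_models:
        if any(s <= pos <= e for s, e in m.exons):
            if exonic_gene is None:
                exonic_gene = m
            if m.cds_offset_of(pos) is not None:
                exonic_gene = m
                break
    if exonic_gene is not None:
        effect = "none"
        if call.type == "SNP":
            offset = exonic_gene.cds_offset_of(pos)
            if offset is not None:
                contig_seq = reference[call.contig]
                cds_seq = exonic_gene.spliced_cds(contig_seq)
                codon_index = offset // 3
                within = offset % 3
                codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
                alt_base = (
                    call.alt_allele if exonic_gene.strand == "+" else revcomp(call.alt_allele)
                )
                alt_codon = codon[:within] + alt_base + codon[within + 1 :]
                effect = _classify_codon_change(codon, alt_codon, codon_index)
        return EffectAnnotation("exonic", effect, exonic_gene.gene_id)

    for m in contig_models:
        if m.start <= pos <= m.end:
            return EffectAnnotation("intronic", "none", m.gene_id)

    # nearest gene within the flank window
    best: Tuple[int, GeneModel] | None = None
    for m in contig_models:
        if pos < m.start:
            dist = m.start - pos
        elif pos > m.end:
            dist = pos - m.end
        else:  # pragma: no cover - handled above
            dist = 0
        if dist <= flank_window and (best is None or dist < best[0]):
            best = (dist, m)
    if best is not None:
        _, m = best
        before = pos < m.start
        upstream = (before and m.strand == "+") or (not before and m.strand == "-")
        return EffectAnnotation("upstream" if upstream else "downstream", "none", m.gene_id)
    return EffectAnnotation("intergenic", "none", None)


def annotate_calls(
    calls: Sequence[VariantCall],
    models: Sequence[GeneModel],
    reference: Dict[str, str],
    flank_window: int = DEFAULT_FLANK_WINDOW,
) -> None:
    """Annotate calls in place, with a per-contig model index."""
    by_contig: Dict[str, List[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    for call in calls:
        call.effect = annotate_variant(
            call, by_contig.get(call.contig, []), reference, flank_window
        )
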