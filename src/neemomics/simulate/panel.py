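"""Multi-genotype genome panel simulator with machine-readable truth.

Emulates a three-genotype design: one reference assembly carrying planted
microsatellites and protein-coding gene models, plus query genotype
assemblies derived from the reference by planted SSR repeat-number changes,
SNPs and small InDels. Every engineered difference is recorded in truth
tables, and an exact reference/query alignment map is retained so the read
simulator can emit ground-truth SAM records without an external aligner.

Layout per contig: non-repetitive spacers (rejection-sampled to contain no
SSR at detection thresholds) alternate with planted SSR runs and gene
bodies, so detector precision and recall are measurable against a clean
truth set. Gene bodies are valid ORFs (ATG ... stop, no internal stop) with
zero or one intron; with the defaults genes cover roughly 40% of each
contig, in line with a gene-dense plant draft assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..seqio import revcomp, write_fasta, write_gff3
from ..ssr.detect import SSRLocus, SSRThresholds, is_primitive, scan_ssrs
from ..variants.annotate import GeneModel
from ..variants.pileup import normalize_indel

DEFAULT_TISSUES = (
    "developing_endosperm",
    "mature_leaf",
    "mature_fruit",
    "seedling_root",
    "fruit_coat_and_pulp",
    "seedling_shoot",
    "flower",
)

#: per-tissue concentration pattern (pg per ug dry tissue) used as the
#: planted metabolite vector: a factor-two gradient from developing
#: endosperm (maximal) down to mature leaf (64-fold lower), following the
#: azadirachtin tissue ordering (endosperm > shoot > root > fruit > pulp >
#: flower > leaf).
METABOLITE_PROFILE = {
    "developing_endosperm": 2000.0,
    "seedling_shoot": 1000.0,
    "seedling_root": 500.0,
    "mature_fruit": 250.0,
    "fruit_coat_and_pulp": 125.0,
    "flower": 62.5,
    "mature_leaf": 31.25,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_UNIT_LENGTH_P = (0.20, 0.25, 0.35, 0.10, 0.05, 0.05)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
_MIN_SPACER = 250


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters of the simulated genotype panel."""

    seed: int = 0
    n_contigs: int = 5
    contig_length: int = 120_000
    n_genes: int = 400
    n_ssr_planted: int = 550
    n_ssr_polymorphic: int = 60
    snp_rate: float = 0.0029
    indel_rate: float = 0.00022
    read_length: int = 100
    coverage: float = 30.0
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    n_corr_genes: int = 50
    expression_noise_cv: float = 0.1
    calib_noise_cv: float = 0.01
    n_query_genotypes: int = 2
    flank_len: int = 100
    ssr_deletion_prob: float = 0.05

    def __post_init__(self):
        if self.n_ssr_polymorphic > self.n_ssr_planted:
            raise ValueError("n_ssr_polymorphic cannot exceed n_ssr_planted")
        for name in ("snp_rate", "indel_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not self.tissues or len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue list must be non-empty and unique")
        if self.n_corr_genes > self.n_genes:
            raise ValueError("n_corr_genes cannot exceed n_genes")

    @property
    def genotypes(self) -> List[str]:
        return ["G1"] + [f"G{i + 2}" for i in range(self.n_query_genotypes)]


@dataclass
class TruthTables:
    """Machine-readable record of every planted feature and difference."""

    ssr_truth: pd.DataFrame  # contig,start,end,motif,class,unit_length,repeat_count_<genotype>...
    variant_truth: pd.DataFrame  # genotype,contig,position,ref,alt,type
    ssr_indel_truth: pd.DataFrame  # SSR repeat changes expressed as indel records
    corr_gene_truth: List[str]
    planted_metabolite: pd.Series  # per-tissue concentration

    def polymorphic_loci(self, genotype: str, reference: str = "G1") -> pd.DataFrame:
        t = self.ssr_truth
        return t[t[f"repeat_count_{genotype}"] != t[f"repeat_count_{reference}"]]


# Alignment map op: (kind 'M'|'I'|'D', ref_start0, query_start0, length)
AlignmentOp = Tuple[str, int, int, int]


@dataclass
class Panel:
    config: PanelConfig
    assemblies: Dict[str, Dict[str, str]]  # genotype -> contig -> sequence
    gene_models: List[GeneModel]
    truth: TruthTables
    alignment_maps: Dict[Tuple[str, str], List[AlignmentOp]]  # (genotype, contig)

    @property
    def reference(self) -> Dict[str, str]:
        return self.assemblies["G1"]

    @property
    def gene_ids(self) -> List[str]:
        return [m.gene_id for m in self.gene_models]

    def gene_lengths(self) -> pd.Series:
        return pd.Series(
            {m.gene_id: sum(e - s + 1 for s, e in m.exons) for m in self.gene_models}
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _ssr_free_seq(
    rng: np.random.Generator,
    length: int,
    thresholds: SSRThresholds,
    forbid_first: str = "",
    forbid_last: str = "",
    max_tries: int = 200,
) -> str:
    """Random sequence containing no SSR at detection thresholds, optionally
    constrained at its boundary characters so it cannot extend an adjacent
    planted repeat run."""
    if length == 0:
        return ""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if forbid_first and seq[0] in forbid_first:
            continue
        if forbid_last and seq[-1] in forbid_last:
            continue
        if not scan_ssrs(seq, thresholds):
            return seq
    raise RuntimeError("failed to sample an SSR-free spacer (length %d)" % length)


def _random_motif(rng: np.random.Generator) -> str:
    unit = int(rng.choice(np.arange(1, 7), p=_UNIT_LENGTH_P))
    while True:
        motif = _random_seq(rng, unit)
        if is_primitive(motif):
            return motif


def _random_repeat_count(rng: np.random.Generator, unit: int) -> int:
    if unit == 1:
        return int(rng.integers(10, 19))
    if unit == 2:
        return int(rng.integers(6, 15))
    return int(rng.integers(5, 12))


def _random_gene_segment(
    rng: np.random.Generator, thresholds: SSRThresholds, max_tries: int = 50
) -> Tuple[str, str, List[int], int]:
    """Return (genomic segment, strand, exon piece lengths in genomic order,
    intron length). Pieces concatenated in transcription order form a valid
    ORF free of SSRs."""
    for _ in range(max_tries):
        n_aa = int(rng.integers(80, 201))
        codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_aa)
        body = "".join(_SENSE_CODONS[i] for i in codon_idx)
        cds = "ATG" + body + _STOP_CODONS[rng.integers(0, 3)]
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.6:
            cut = int(rng.integers(30, len(cds) - 30))
            intron_len = int(rng.integers(60, 121))
            intron = _random_seq(rng, intron_len)
            plus_segment = cds[:cut] + intron + cds[cut:]
            piece_lens_tx = [cut, len(cds) - cut]
        else:
            intron_len = 0
            plus_segment = cds
            piece_lens_tx = [len(cds)]
        segment = plus_segment if strand == "+" else revcomp(plus_segment)
        if scan_ssrs(segment, thresholds):
            continue
        if strand == "+":
            piece_lens_genomic = piece_lens_tx
        else:
            piece_lens_genomic = list(reversed(piece_lens_tx))
        return segment, strand, piece_lens_genomic, intron_len
    raise RuntimeError("failed to sample an SSR-free gene segment")


def _build_contig(
    rng: np.random.Generator,
    contig_name: str,
    length: int,
    n_ssr: int,
    n_genes: int,
    thresholds: SSRThresholds,
    gene_counter_start: int,
) -> Tuple[str, List[SSRLocus], List[GeneModel]]:
    """Assemble one reference contig from spacers, SSR runs and gene bodies."""
    items: List[Tuple[str, object]] = []
    for _ in range(n_ssr):
        motif = _random_motif(rng)
        count = _random_repeat_count(rng, len(motif))
        items.append(("ssr", (motif, count)))
    for j in range(n_genes):
        items.append(("gene", _random_gene_segment(rng, thresholds)))
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    item_lens = [
        len(payload[0]) * payload[1] if kind == "ssr" else len(payload[0])
        for kind, payload in items
    ]
    n_spacers = len(items) + 1
    required = sum(item_lens) + n_spacers * _MIN_SPACER
    if required > length:
        raise ValueError(
            f"contig_length={length} too short: {n_ssr} SSRs + {n_genes} genes "
            f"with {_MIN_SPACER} bp minimum spacers require >= {required} bases"
        )
    extra = length - required
    spacer_lens = (np.full(n_spacers, _MIN_SPACER) + rng.multinomial(extra, np.full(n_spacers, 1.0 / n_spacers))).tolist()

    pieces: List[str] = []
    loci: List[SSRLocus] = []
    models: List[GeneModel] = []
    pos = 0  # 0-based cursor
    gene_no = gene_counter_start
    for idx, (kind, payload) in enumerate(items):
        prev_forbid = ""
        next_forbid = ""
        if idx > 0 and items[idx - 1][0] == "ssr":
            prev_forbid = items[idx - 1][1][0][0]  # motif first base
        if items[idx][0] == "ssr":
            motif = payload[0]
            next_forbid = motif[-1]
        spacer = _ssr_free_seq(
            rng, int(spacer_lens[idx]), thresholds,
            forbid_first=prev_forbid, forbid_last=next_forbid,
        )
        pieces.append(spacer)
        pos += len(spacer)
        if kind == "ssr":
            motif, count = payload
            run = motif * count
            loci.append(
                SSRLocus(contig=contig_name, start=pos + 1, end=pos + len(run),
                         motif=motif, repeat_count=count)
            )
            pieces.append(run)
            pos += len(run)
        else:
            segment, strand, piece_lens, intron_len = payload
            gene_no += 1
            gid = f"Ai{gene_no:05d}"
            spans: List[Tuple[int, int]] = []
            cursor = pos
            for j, pl in enumerate(piece_lens):
                spans.append((cursor + 1, cursor + pl))
                cursor += pl
                if j < len(piece_lens) - 1:
                    cursor += intron_len  # single intron between the two pieces
            # phases in transcription order
            tx_spans = spans if strand == "+" else list(reversed(spans))
            phases = []
            cum = 0
            for s, e in tx_spans:
                phases.append((3 - cum % 3) % 3)
                cum += e - s + 1
            phase_by_span = dict(zip(tx_spans, phases))
            cds = [(s, e, phase_by_span[(s, e)]) for s, e in spans]
            models.append(
                GeneModel(gene_id=gid, contig=contig_name, strand=strand,
                          exons=list(spans), cds=cds)
            )
            pieces.append(segment)
            pos += len(segment)
    last_forbid = items[-1][1][0][0] if items and items[-1][0] == "ssr" else ""
    pieces.append(
        _ssr_free_seq(rng, int(spacer_lens[-1]), thresholds, forbid_first=last_forbid)
    )
    seq = "".join(pieces)
    assert len(seq) == length
    return seq, loci, models


def _distribute(total: int, bins: int) -> List[int]:
    base, rem = divmod(total, bins)
    return [base + (1 if i < rem else 0) for i in range(bins)]


# Edit: (ref_start0, ref_end0, replacement, kind) with kind snp|ins|del|ssr
Edit = Tuple[int, int, str, str]


def _apply_edits(ref_seq: str, edits: Sequence[Edit]) -> Tuple[str, List[AlignmentOp]]:
    """Build the query sequence and a reference/query alignment map from
    sorted, non-overlapping edits."""
    pieces: List[str] = []
    ops: List[AlignmentOp] = []
    rpos = 0
    qpos = 0

    def emit_match(length: int):
        nonlocal rpos, qpos
        if length <= 0:
            return
        if ops and ops[-1][0] == "M" and ops[-1][1] + ops[-1][3] == rpos and ops[-1][2] + ops[-1][3] == qpos:
            ops[-1] = ("M", ops[-1][1], ops[-1][2], ops[-1][3] + length)
        else:
            ops.append(("M", rpos, qpos, length))
        rpos += length
        qpos += length

    for start, end, rep, kind in sorted(edits):
        if start > rpos:
            pieces.append(ref_seq[rpos:start])
            emit_match(start - rpos)
        rl = end - start
        ql = len(rep)
        pieces.append(rep)
        aligned = min(rl, ql)
        emit_match(aligned)
        if ql > rl:
            ops.append(("I", rpos, qpos, ql - rl))
            qpos += ql - rl
        elif rl > ql:
            ops.append(("D", rpos, qpos, rl - ql))
            rpos = end
    if rpos < len(ref_seq):
        pieces.append(ref_seq[rpos:])
        emit_match(len(ref_seq) - rpos)
    return "".join(pieces), ops


def generate_panel(config: PanelConfig) -> Panel:
    """Generate the reference assembly, query genotypes and truth tables.

    Deterministic for a given config (including seed): all randomness flows
    from one seed sequence with fixed child streams.
    """
    root = np.random.SeedSequence(config.seed)
    contig_ss, variant_ss, expr_ss = root.spawn(3)
    thresholds = SSRThresholds()

    # --- reference assembly -------------------------------------------------
    ssr_per_contig = _distribute(config.n_ssr_planted, config.n_contigs)
    genes_per_contig = _distribute(config.n_genes, config.n_contigs)
    reference: Dict[str, str] = {}
    all_loci: List[SSRLocus] = []
    gene_models: List[GeneModel] = []
    contig_children = contig_ss.spawn(config.n_contigs)
    gene_counter = 0
    for i in range(config.n_contigs):
        name = f"contig{i + 1:02d}"
        for attempt in range(5):
            rng = np.random.default_rng(contig_children[i].spawn(1)[0] if attempt else contig_children[i])
            seq, loci, models = _build_contig(
                rng, name, config.contig_length,
                ssr_per_contig[i], genes_per_contig[i], thresholds, gene_counter,
            )
            detected = scan_ssrs(seq, thresholds, contig=name)
            planted_set = {(l.start, l.end, l.motif, l.repeat_count) for l in loci}
            detected_set = {(l.start, l.end, l.motif, l.repeat_count) for l in detected}
            if planted_set == detected_set:
                break
        else:
            raise RuntimeError(f"could not assemble a clean contig {name}")
        reference[name] = seq
        all_loci.extend(loci)
        gene_models.extend(models)
        gene_counter += len(models)

    # --- query genotypes ----------------------------------------------------
    genotypes = config.genotypes
    queries = genotypes[1:]
    vr = np.random.default_rng(variant_ss)
    n_loci = len(all_loci)
    shared_core = min(config.n_ssr_polymorphic // 3, n_loci)
    core = set(vr.choice(n_loci, size=shared_core, replace=False)) if shared_core else set()
    poly_sets: Dict[str, set] = {}
    for g in queries:
        remaining = [i for i in range(n_loci) if i not in core]
        n_extra = max(0, config.n_ssr_polymorphic - len(core))
        extra = set(vr.choice(len(remaining), size=min(n_extra, len(remaining)), replace=False))
        poly_sets[g] = core | {remaining[i] for i in extra}

    ssr_counts: Dict[str, List[int]] = {g: [l.repeat_count for l in all_loci] for g in genotypes}
    assemblies: Dict[str, Dict[str, str]] = {"G1": reference}
    alignment_maps: Dict[Tuple[str, str], List[AlignmentOp]] = {}
    variant_rows: List[dict] = []
    ssr_indel_rows: List[dict] = []

    loci_by_contig: Dict[str, List[Tuple[int, SSRLocus]]] = {}
    for idx, locus in enumerate(all_loci):
        loci_by_contig.setdefault(locus.contig, []).append((idx, locus))

    genotype_children = variant_ss.spawn(len(queries))
    for g, g_child in zip(queries, genotype_children):
        grng = np.random.default_rng(g_child)
        query_contigs: Dict[str, str] = {}
        for contig, ref_seq in reference.items():
            L = len(ref_seq)
            edits: List[Edit] = []
            occupied = np.zeros(L, dtype=bool)

            # SSR repeat-number changes
            for idx, locus in loci_by_contig.get(contig, ()):
                s0, e0 = locus.start - 1, locus.end
                if idx in poly_sets[g]:
                    k = locus.unit_length
                    if grng.random() < config.ssr_deletion_prob:
                        new_count = 0
                    else:
                        delta = int(grng.integers(1, 5)) * (1 if grng.random() < 0.5 else -1)
                        new_count = locus.repeat_count + delta
                        if new_count < 2:
                            new_count = locus.repeat_count + abs(delta)
                    ssr_counts[g][idx] = new_count
                    edits.append((s0, e0, locus.motif * new_count, "ssr"))
                    # truth record, expressed as a left-aligned indel
                    if new_count > locus.repeat_count:
                        anchor = e0 - 1
                        ins = locus.motif * (new_count - locus.repeat_count)
                        pos, ref_a, alt_a = normalize_indel(
                            ref_seq, anchor + 1, ref_seq[anchor], ref_seq[anchor] + ins
                        )
                    else:
                        anchor = s0 + new_count * k - 1
                        pos, ref_a, alt_a = normalize_indel(
                            ref_seq, anchor + 1,
                            ref_seq[anchor:e0], ref_seq[anchor],
                        )
                    ssr_indel_rows.append(
                        dict(genotype=g, contig=contig, position=pos,
                             ref=ref_a, alt=alt_a,
                             type="insertion" if new_count > locus.repeat_count else "deletion")
                    )
                # SSR run and flanks are off-limits for planted indels;
                # the run itself is off-limits for SNPs
                occupied[s0:e0] = True

            indel_excluded = occupied.copy()
            for idx, locus in loci_by_contig.get(contig, ()):
                s0, e0 = locus.start - 1, locus.end
                lo = max(0, s0 - config.flank_len - 12)
                hi = min(L, e0 + config.flank_len + 12)
                indel_excluded[lo:hi] = True
            indel_excluded[:2] = True
            indel_excluded[-12:] = True

            taken = occupied.copy()  # positions already consumed by edits

            # planted InDels (length 1-10, uniform), kept clear of SSR flanks
            elig = np.nonzero(~indel_excluded)[0]
            n_indel = grng.binomial(len(elig), config.indel_rate) if config.indel_rate else 0
            indel_pos = grng.choice(elig, size=n_indel, replace=False) if n_indel else []
            for p in sorted(int(x) for x in indel_pos):
                ln = int(grng.integers(1, 11))
                if grng.random() < 0.5 and p + ln + 2 < L:  # deletion
                    span = slice(p, p + ln)
                    if taken[max(0, p - 15) : p + ln + 15].any():
                        continue
                    edits.append((p, p + ln, "", "del"))
                    taken[max(0, p - 15) : p + ln + 15] = True
                    pos, ref_a, alt_a = normalize_indel(
                        ref_seq, p, ref_seq[p - 1 : p + ln], ref_seq[p - 1]
                    )
                    variant_rows.append(
                        dict(genotype=g, contig=contig, position=pos,
                             ref=ref_a, alt=alt_a, type="deletion")
                    )
                else:  # insertion before ref position p
                    if taken[max(0, p - 15) : p + 15].any():
                        continue
                    ins = _random_seq(grng, ln)
                    edits.append((p, p, ins, "ins"))
                    taken[max(0, p - 15) : p + 15] = True
                    pos, ref_a, alt_a = normalize_indel(
                        ref_seq, p, ref_seq[p - 1], ref_seq[p - 1] + ins
                    )
                    variant_rows.append(
                        dict(genotype=g, contig=contig, position=pos,
                             ref=ref_a, alt=alt_a, type="insertion")
                    )

            # planted SNPs (anywhere except SSR runs and already-edited bases)
            snp_elig = np.nonzero(~taken)[0]
            n_snp = grng.binomial(len(snp_elig), config.snp_rate) if config.snp_rate else 0
            snp_pos = grng.choice(snp_elig, size=n_snp, replace=False) if n_snp else []
            for p in sorted(int(x) for x in snp_pos):
                ref_base = ref_seq[p]
                alt_base = "ACGT".replace(ref_base, "")[grng.integers(0, 3)]
                edits.append((p, p + 1, alt_base, "snp"))
                variant_rows.append(
                    dict(genotype=g, contig=contig, position=p + 1,
                         ref=ref_base, alt=alt_base, type="SNP")
                )

            qseq, ops = _apply_edits(ref_seq, edits)
            query_contigs[contig] = qseq
            alignment_maps[(g, contig)] = ops
        assemblies[g] = query_contigs

    for contig in reference:
        alignment_maps[("G1", contig)] = [("M", 0, 0, len(reference[contig]))]

    # --- truth tables -------------------------------------------------------
    ssr_truth = pd.DataFrame(
        [
            {
                "contig": l.contig, "start": l.start, "end": l.end,
                "motif": l.motif, "class": l.canonical_class,
                "unit_length": l.unit_length,
                **{f"repeat_count_{g}": ssr_counts[g][i] for g in genotypes},
            }
            for i, l in enumerate(all_loci)
        ]
    )
    variant_truth = pd.DataFrame(
        variant_rows, columns=["genotype", "contig", "position", "ref", "alt", "type"]
    ).sort_values(["genotype", "contig", "position"]).reset_index(drop=True)
    ssr_indel_truth = pd.DataFrame(
        ssr_indel_rows, columns=["genotype", "contig", "position", "ref", "alt", "type"]
    ).sort_values(["genotype", "contig", "position"]).reset_index(drop=True)

    er = np.random.default_rng(expr_ss)
    gene_ids = [m.gene_id for m in gene_models]
    corr_genes = sorted(
        er.choice(gene_ids, size=min(config.n_corr_genes, len(gene_ids)), replace=False)
    )
    metabolite = pd.Series(
        {t: METABOLITE_PROFILE.get(t, 100.0) for t in config.tissues}, name="azadirachtin"
    )

    truth = TruthTables(
        ssr_truth=ssr_truth,
        variant_truth=variant_truth,
        ssr_indel_truth=ssr_indel_truth,
        corr_gene_truth=list(corr_genes),
        planted_metabolite=metabolite,
    )
    return Panel(
        config=config,
        assemblies=assemblies,
        gene_models=gene_models,
        truth=truth,
        alignment_maps=alignment_maps,
    )


def panel_loci(panel: Panel) -> List[SSRLocus]:
    """Reference SSR loci reconstructed from the truth table."""
    return [
        SSRLocus(contig=r.contig, start=int(r.start), end=int(r.end),
                 motif=r.motif, repeat_count=int(r.repeat_count_G1))
        for r in panel.truth.ssr_truth.itertuples()
    ]


def write_panel(panel: Panel, outdir) -> None:
    """Write assemblies (FASTA), gene models (GFF3) and truth tables (TSV)."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for g, contigs in panel.assemblies.items():
        write_fasta(os.path.join(outdir, f"{g}.fa"), contigs)
    rows = []
    for m in panel.gene_models:
        attrs = f"ID={m.gene_id}"
        rows.append((m.contig, "neemomics", "gene", m.start, m.end, ".", m.strand, ".", attrs))
        rows.append((m.contig, "neemomics", "mRNA", m.start, m.end, ".", m.strand, ".",
                     f"ID={m.gene_id}.t1;Parent={m.gene_id}"))
        for s, e in m.exons:
            rows.append((m.contig, "neemomics", "exon", s, e, ".", m.strand, ".",
                         f"Parent={m.gene_id}.t1"))
        for s, e, ph in m.cds:
            rows.append((m.contig, "neemomics", "CDS", s, e, ".", m.strand, ph,
                         f"Parent={m.gene_id}.t1"))
    write_gff3(os.path.join(outdir, "genes.gff3"), rows)
    panel.truth.ssr_truth.to_csv(os.path.join(outdir, "ssr_truth.tsv"), sep="\t", index=False)
    panel.truth.variant_truth.to_csv(os.path.join(outdir, "variant_truth.tsv"), sep="\t", index=False)
    panel.truth.ssr_indel_truth.to_csv(os.path.join(outdir, "ssr_indel_truth.tsv"), sep="\t", index=False)
    pd.Series(panel.truth.corr_gene_truth, name="gene_id").to_csv(
        os.path.join(outdir, "corr_gene_truth.tsv"), sep="\t", index=False
    )
    panel.truth.planted_metabolite.rename_axis("tissue").to_csv(
        os.path.join(outdir, "planted_metabolite.tsv"), sep="\t"
    )
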