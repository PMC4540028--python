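"""Gene-set sharing arithmetic used in comparative summaries."""

from __future__ import annotations


def genes_without_orthologs(total_genes: int, genes_with_orthologs: int) -> int:
    """Number of genes lacking any ortholog in the compared species."""
    if genes_with_orthologs > total_genes:
        raise ValueError("genes_with_orthologs cannot exceed total_genes")
    return total_genes - genes_with_orthologs


def shared_gene_percent(shared_genes: int, total_genes: int, ndigits: int = 2) -> float:
    """Percentage of the gene complement shared with another species."""
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    return round(shared_genes / total_genes * 100.0, ndigits)
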