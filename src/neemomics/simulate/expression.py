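"""Multi-tissue expression and metabolite simulator.

Emits a genes x tissues read-count table in which a planted subset of genes
has expected RPKM exactly proportional to a planted per-tissue metabolite
concentration vector (before noise), while all remaining genes carry
profiles independent of the metabolite. Column sums are solved so that
computing RPKM with per-tissue mapped-read totals equal to the column sums
reproduces the proportionality exactly in the noiseless case. Noise is
mean-one multiplicative lognormal with a configurable coefficient of
variation; counts are therefore continuous (expected read mass, not
integer draws).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Panel, PanelConfig

#: nominal per-tissue library size used to scale background counts
NOMINAL_LIBRARY = 5_000_000.0


@dataclass
class ExpressionData:
    counts: pd.DataFrame  # genes x tissues
    gene_lengths: pd.Series  # bases
    library_sizes: pd.Series  # per-tissue column sums of counts
    expected_rpkm: pd.DataFrame  # pre-noise truth
    metabolite: pd.Series  # per-tissue planted concentration


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_expression(
    config: PanelConfig,
    gene_ids: Sequence[str],
    gene_lengths: pd.Series,
    corr_genes: Sequence[str],
    metabolite: pd.Series,
    seed: Optional[int] = None,
    background_tissue_sigma: float = 0.3,
    planted_peak_rpkm: float = 200.0,
    tissue_specific_fraction: float = 0.08,
    silent_fraction: float = 0.04,
) -> ExpressionData:
    """Simulate per-tissue counts for the panel's gene set.

    Planted ``corr_genes`` track ``metabolite`` across tissues. The
    background mixes three realistic gene kinds: broadly expressed genes
    with a lognormal baseline and independent lognormal per-tissue
    variation (``background_tissue_sigma`` on the log scale); a
    ``tissue_specific_fraction`` expressed in exactly one random tissue;
    and a ``silent_fraction`` with no reads in any tissue (annotated but
    unexpressed gene models).
    """
    if len(corr_genes) > len(gene_ids):
        raise ValueError("more correlated genes than genes in the panel")
    missing = set(corr_genes) - set(gene_ids)
    if missing:
        raise ValueError(f"correlated genes absent from panel: {sorted(missing)[:3]}")
    tissues = list(config.tissues)
    if list(metabolite.index) != tissues:
        metabolite = metabolite.reindex(tissues)
    m = metabolite.to_numpy(dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    genes = list(gene_ids)
    lengths = gene_lengths.reindex(genes).to_numpy(dtype=float)
    if np.isnan(lengths).any():
        raise ValueError("gene length missing for some genes")
    planted_mask = np.isin(genes, list(corr_genes))
    n_genes, n_tissues = len(genes), len(tissues)

    base = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n_genes)
    tissue_factor = rng.lognormal(mean=0.0, sigma=background_tissue_sigma, size=(n_genes, n_tissues))
    bg_rpkm = base[:, None] * tissue_factor
    # carve tissue-specific and silent genes out of the background
    kind_draw = rng.random(n_genes)
    ts_mask = (kind_draw < tissue_specific_fraction) & ~planted_mask
    silent_mask = (
        (kind_draw >= tissue_specific_fraction)
        & (kind_draw < tissue_specific_fraction + silent_fraction)
        & ~planted_mask
    )
    ts_tissue = rng.integers(0, n_tissues, size=n_genes)
    ts_level = rng.lognormal(np.log(30.0), 0.7, size=n_genes)
    bg_rpkm[ts_mask, :] = 0.0
    bg_rpkm[ts_mask, ts_tissue[ts_mask]] = ts_level[ts_mask]
    bg_rpkm[silent_mask, :] = 0.0  # silent: no reads in any tissue
    bg_rpkm[planted_mask, :] = 0.0

    # planted genes: RPKM = c_g * m_t exactly (before noise)
    peak = rng.lognormal(mean=np.log(planted_peak_rpkm), sigma=0.5, size=int(planted_mask.sum()))
    c = np.zeros(n_genes)
    m_max = m.max() if m.max() > 0 else 1.0
    c[planted_mask] = peak / m_max

    bg_counts = bg_rpkm * lengths[:, None] * NOMINAL_LIBRARY / 1e9
    B = bg_counts.sum(axis=0)
    alpha = float((c * lengths).sum()) / 1e9
    if np.any(alpha * m >= 0.9):
        raise ValueError("planted genes would dominate the library; lower peak RPKM")
    S = B / (1.0 - alpha * m)  # solved so column sums equal library sizes
    planted_counts = (c[:, None] * m[None, :]) * lengths[:, None] * S[None, :] / 1e9
    counts = bg_counts + planted_counts

    expected_rpkm = counts * 1e9 / (lengths[:, None] * S[None, :])
    noise = _lognormal_factor(rng, config.expression_noise_cv, counts.shape)
    counts = counts * noise

    counts_df = pd.DataFrame(counts, index=genes, columns=tissues)
    expected_df = pd.DataFrame(expected_rpkm, index=genes, columns=tissues)
    return ExpressionData(
        counts=counts_df,
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
        library_sizes=counts_df.sum(axis=0).rename("mapped_reads"),
        expected_rpkm=expected_df,
        metabolite=pd.Series(m, index=tissues, name=metabolite.name or "metabolite"),
    )


def simulate_panel_expression(panel: Panel, seed: Optional[int] = None) -> ExpressionData:
    """Expression matrix for a generated panel's gene set and truth."""
    base = panel.config.seed if seed is None else seed
    return simulate_expression(
        panel.config,
        panel.gene_ids,
        panel.gene_lengths(),
        panel.truth.corr_gene_truth,
        panel.truth.planted_metabolite,
        seed=base + 9001,
    )
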