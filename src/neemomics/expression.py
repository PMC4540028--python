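"""RPKM expression profiling and the metabolite-correlation screen.

RPKM (reads per kilobase of gene model per million mapped reads) is
``count * 1e9 / (gene_length * total_mapped)`` with the per-tissue total
taken as reads mapped to the gene set. Candidate biosynthesis genes are
nominated by Pearson correlation of a gene's tissue profile with a
metabolite concentration vector, tiered at r >= 0.8 and r >= 0.9
(inclusive, configurable), with a contrasting-tissue requirement that the
high-metabolite tissue out-expresses the low-metabolite tissue. A ddCt
helper converts qPCR Ct values to fold changes against a reference gene
and calibrator sample.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

EXPRESSED_MIN_RPKM = 1.0
SUMMARY_THRESHOLDS = (1.0, 5.0, 10.0)


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """RPKM matrix from a genes x tissues count table.

    ``totals`` defaults to the per-tissue column sums (reads mapped to the
    gene set), making the matrix self-contained.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"gene length missing for {list(missing[:3])} ...")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns).astype(float)
    if (totals <= 0).any():
        raise ValueError("per-tissue totals must be positive")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def expression_summary(
    matrix: pd.DataFrame, thresholds: Sequence[float] = SUMMARY_THRESHOLDS
) -> pd.DataFrame:
    """Per-tissue counts of genes expressed above each RPKM threshold."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    return pd.DataFrame(
        {f"rpkm_gt_{t:g}": (matrix > t).sum(axis=0) for t in thresholds}
    )


def tissue_partition(
    matrix: pd.DataFrame, min_rpkm: float = EXPRESSED_MIN_RPKM
) -> Dict[str, pd.Index]:
    """Split genes into ubiquitous (expressed in all tissues), tissue-specific
    (exactly one tissue) and other, using RPKM >= min_rpkm as expressed."""
    if matrix.shape[1] < 2:
        raise ValueError("tissue partition requires at least two tissues")
    expressed = matrix >= min_rpkm
    n = expressed.sum(axis=1)
    ubiquitous = matrix.index[n == matrix.shape[1]]
    specific = matrix.index[n == 1]
    other = matrix.index[(n != matrix.shape[1]) & (n != 1)]
    return {"ubiquitous": ubiquitous, "tissue_specific": specific, "other": other}


def metabolite_correlation(
    matrix: pd.DataFrame, profile: pd.Series
) -> pd.DataFrame:
    """Per-gene Pearson correlation with a metabolite concentration vector.

    Tissue sets must match; genes with zero expression variance (or a
    constant metabolite profile) get ``defined=False`` and NaN rather than
    a silent zero, and are excluded from downstream ranking.
    """
    diff = set(matrix.columns) ^ set(profile.index)
    if diff:
        raise ValueError(f"tissue sets differ: {sorted(diff)}")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 shared tissues")
    m = profile.reindex(matrix.columns).to_numpy(dtype=float)
    X = matrix.to_numpy(dtype=float)
    mc = m - m.mean()
    m_ss = float(mc @ mc)
    Xc = X - X.mean(axis=1, keepdims=True)
    x_ss = (Xc**2).sum(axis=1)
    denom = np.sqrt(x_ss * m_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ mc / np.where(denom > 0, denom, 1.0), np.nan)
    defined = denom > 0
    r = np.clip(r, -1.0, 1.0, out=r) if defined.any() else r
    return pd.DataFrame({"r": r, "defined": defined}, index=matrix.index)


def candidate_screen(
    matrix: pd.DataFrame,
    profile: pd.Series,
    r_min: float = 0.8,
    r_strict: float = 0.9,
    contrast: Tuple[str, str] = ("developing_endosperm", "mature_leaf"),
) -> pd.DataFrame:
    """Rank genes by metabolite correlation and tier the candidates.

    tier r08: r >= r_min and RPKM(high tissue) > RPKM(low tissue);
    tier r09: additionally r >= r_strict. Sorted by r descending, ties by
    gene id. Genes with undefined correlation are excluded.
    """
    high, low = contrast
    for t in contrast:
        if t not in matrix.columns:
            raise ValueError(f"contrast tissue {t!r} absent from matrix")
    if matrix.empty:
        return pd.DataFrame(
            columns=["r", "rpkm_high", "rpkm_low", "contrast_pass", "tier",
                     "n_tissues_rpkm1", "n_tissues_rpkm5", "n_tissues_rpkm10"]
        )
    corr = metabolite_correlation(matrix, profile)
    out = pd.DataFrame(index=matrix.index)
    out["r"] = corr["r"]
    out["rpkm_high"] = matrix[high]
    out["rpkm_low"] = matrix[low]
    out["contrast_pass"] = matrix[high] > matrix[low]
    for t in (1, 5, 10):
        out[f"n_tissues_rpkm{t}"] = (matrix >= t).sum(axis=1)
    out = out[corr["defined"]]
    tier = np.full(len(out), "none", dtype=object)
    r08 = (out["r"] >= r_min) & out["contrast_pass"]
    r09 = r08 & (out["r"] >= r_strict)
    tier[r08.to_numpy()] = "r08"
    tier[r09.to_numpy()] = "r09"
    out["tier"] = tier
    # stable sort: ties in r break by gene id
    out = out.sort_index().sort_values("r", ascending=False, kind="mergesort")
    return out


def permutation_null(
    matrix: pd.DataFrame,
    profile: pd.Series,
    r_threshold: float = 0.9,
    n_permutations: int = 100,
    seed: int = 0,
    contrast: Optional[Tuple[str, str]] = None,
) -> np.ndarray:
    """Tier sizes after shuffling the metabolite vector's tissue labels.

    Returns the number of genes reaching ``r_threshold`` (and passing the
    contrast, if given) under each of ``n_permutations`` label shuffles —
    the permutation null for the observed tier size.
    """
    rng = np.random.default_rng(seed)
    values = profile.reindex(matrix.columns).to_numpy(dtype=float)
    counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = pd.Series(rng.permutation(values), index=matrix.columns)
        corr = metabolite_correlation(matrix, perm)
        ok = corr["defined"] & (corr["r"] >= r_threshold)
        if contrast is not None:
            high, low = contrast
            ok &= matrix[high] > matrix[low]
        counts[i] = int(ok.sum())
    return counts


def cluster_tissues(
    matrix: pd.DataFrame, method: str = "average", metric: str = "correlation"
) -> Tuple[np.ndarray, list]:
    """Hierarchical clustering of tissues on log-scale expression.

    Returns the scipy linkage matrix and the tissue labels in dendrogram
    leaf order (the tissue-relationship view of the expression data).
    """
    X = np.log1p(matrix.to_numpy(dtype=float)).T
    Z = linkage(X, method=method, metric=metric)
    order = leaves_list(Z)
    return Z, [matrix.columns[i] for i in order]


def ddct_fold_change(
    ct_target: pd.Series, ct_reference: pd.Series, calibrator: str
) -> pd.Series:
    """Relative qPCR quantification: fold = 2^(-ddCt) per sample.

    dCt = Ct_target - Ct_reference per sample; ddCt is taken against the
    calibrator sample, whose fold change is therefore exactly 1.
    """
    if calibrator not in ct_target.index:
        raise ValueError(f"calibrator sample {calibrator!r} not among samples")
    missing = ct_target.index.difference(ct_reference.index)
    if len(missing):
        raise ValueError(f"reference Ct missing for samples {list(missing)}")
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference.reindex(ct_target.index)).all()):
        raise ValueError("Ct values must be finite")
    dct = ct_target - ct_reference.reindex(ct_target.index)
    ddct = dct - dct[calibrator]
    return np.power(2.0, -ddct).rename("fold_change")
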