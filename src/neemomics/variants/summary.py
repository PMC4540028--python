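"""Marker-density arithmetic and variant-effect summaries."""

from __future__ import annotations

import math
from typing import Dict, Sequence

import pandas as pd

from .pileup import VariantCall


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def marker_density(
    counts_per_genotype: Sequence[int], genome_size: int, sig: int = 2
) -> Dict[str, object]:
    """Marker density per 1,000 bases, per genotype and averaged.

    ``density = count / genome_size * 1000``; the mean across genotypes is
    reported rounded to two significant figures (full precision retained
    under ``mean``).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    counts = list(counts_per_genotype)
    if not counts:
        raise ValueError("counts_per_genotype must be non-empty")
    per = [c / genome_size * 1000.0 for c in counts]
    mean = sum(per) / len(per)
    return {
        "per_genotype": per,
        "mean": mean,
        "mean_rounded": round_sig(mean, sig),
    }


def summarize_effects(calls: Sequence[VariantCall]) -> Dict[str, pd.DataFrame]:
    """Counts and fractions per region class and per coding effect, for all
    calls and for the pass-filter subset."""

    def _table(subset: Sequence[VariantCall]) -> pd.DataFrame:
        regions = pd.Series(
            [c.effect.region_class if c.effect else "unannotated" for c in subset],
            dtype=object,
        )
        effects = pd.Series(
            [c.effect.coding_effect if c.effect else "none" for c in subset],
            dtype=object,
        )
        rows = []
        for axis, series in (("region_class", regions), ("coding_effect", effects)):
            counts = series.value_counts()
            total = counts.sum()
            for label, n in counts.items():
                rows.append(
                    {"axis": axis, "label": label, "count": int(n),
                     "fraction": n / total if total else 0.0}
                )
        return pd.DataFrame(rows, columns=["axis", "label", "count", "fraction"])

    return {
        "all": _table(calls),
        "pass": _table([c for c in calls if c.filter == "pass"]),
    }
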