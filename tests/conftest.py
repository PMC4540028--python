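import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make oracles importable

from neemomics.simulate import (
    PanelConfig,
    generate_panel,
    simulate_genotype_reads,
    simulate_panel_expression,
    write_sam,
)
from neemomics.variants import annotate_calls, pileup_call

SMALL_CONFIG = PanelConfig(
    seed=1,
    n_contigs=2,
    contig_length=30_000,
    n_genes=30,
    n_ssr_planted=40,
    n_ssr_polymorphic=10,
    n_corr_genes=10,
)

DEFAULT_CONFIG = PanelConfig(seed=7)


@pytest.fixture(scope="session")
def small_panel():
    """A compact two-contig panel for fast unit-level checks."""
    return generate_panel(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_panel():
    """The full default study panel (5 x 120 kb, 3 genotypes)."""
    return generate_panel(DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def default_variant_calls(default_panel, tmp_path_factory):
    """Pass-filter and raw pileup calls for both query genotypes at 30x."""
    outdir = tmp_path_factory.mktemp("sam")
    calls = {}
    for g in ("G2", "G3"):
        reads = simulate_genotype_reads(default_panel, g)
        sam = outdir / f"{g}.sam"
        write_sam(reads, default_panel.reference, sam)
        calls[g] = pileup_call(sam, default_panel.reference)
    return calls


@pytest.fixture(scope="session")
def default_expression(default_panel):
    return simulate_panel_expression(default_panel)
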