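#!/usr/bin/env python
"""Survey microsatellites in the panel assemblies.

Scans each genotype assembly with MISA-default thresholds, classifies loci
into canonical motif classes, splits them by gene overlap, and writes
per-genotype SSR tables plus a class/unit-length summary under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from neemomics.seqio import read_fasta
from neemomics.ssr import loci_to_frame, scan_assembly, summarize_ssrs
from neemomics.variants import load_gene_models


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    models = load_gene_models(args.panel / "genes.gff3")
    gene_spans = [(m.contig, m.start, m.end) for m in models]
    summary_rows = []
    for fasta in sorted(args.panel.glob("G*.fa")):
        genotype = fasta.stem
        assembly = read_fasta(fasta)
        loci = scan_assembly(assembly)
        frame = loci_to_frame(loci)
        frame.to_csv(args.out / f"{genotype}.ssr.tsv", sep="\t", index=False)
        s = summarize_ssrs(loci, gene_spans if genotype == "G1" else None)
        top = s["by_class"].sort_values(ascending=False).head(3)
        print(f"{genotype}: {len(loci)} SSRs; top classes: "
              + ", ".join(f"{c} ({n})" for c, n in top.items()))
        row = {"genotype": genotype, "n_ssrs": len(loci)}
        row.update({f"unit_{k}": v for k, v in s["by_unit_length"].items()})
        if "genic" in s:
            row.update(s["genic"].to_dict())
            print(f"    genic: {s['genic']['genic']}, "
                  f"non-genic: {s['genic']['non_genic']}")
        summary_rows.append(row)
    pd.DataFrame(summary_rows).to_csv(args.out / "ssr_summary.tsv", sep="\t", index=False)
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
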