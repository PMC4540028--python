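#!/usr/bin/env python
"""Calibration curves and absolute metabolite quantification.

Simulates internal-standard dilution series at the published endpoints
(azadirachtin 15.6 pg-1 ng, salanin 7.8 pg-0.5 ng, nimbin 3.4 pg-0.25 ng)
with 1% multiplicative noise, fits response-ratio calibration lines,
reports fold spans and correlation coefficients, then quantifies forward-
simulated tissue samples through the 2 mg / 1 mL / 5-into-50 uL / 10 uL
preparation chain and checks recovery.
"""

import argparse
from pathlib import Path

import pandas as pd

from neemomics.quantify import SamplePrep, fit_calibration, quantify
from neemomics.simulate import simulate_calibration, simulate_sample_responses

ENDPOINTS = {"azadirachtin": (15.6, 1000.0), "salanin": (7.8, 500.0), "nimbin": (3.4, 250.0)}
# endosperm-like and leaf-like test concentrations, pg per ug dry tissue
TEST_SAMPLES = {"developing_endosperm": 950.0, "seedling_root": 120.0, "mature_leaf": 8.0}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    prep = SamplePrep()
    curve_rows, quant_rows = [], []
    for i, (met, (low, high)) in enumerate(ENDPOINTS.items()):
        levels = 7
        factor = (high / low) ** (1 / (levels - 1))
        std = simulate_calibration(low, levels, factor, true_slope=0.002,
                                   true_intercept=0.01, noise_cv=0.01,
                                   seed=args.seed + i)
        curve = fit_calibration(std, met)
        curve_rows.append({
            "metabolite": met, "slope": curve.slope, "intercept": curve.intercept,
            "r": round(curve.r, 4), "range_low_pg": curve.range_low,
            "range_high_pg": curve.range_high, "fold_span": curve.fold_span,
        })
        print(f"{met}: r={curve.r:.4f}, range {curve.range_low:g}-{round(curve.range_high, 6):g} pg "
              f"({curve.fold_span}-fold)")
        for tissue, conc in TEST_SAMPLES.items():
            analyte, is_r = simulate_sample_responses(conc, prep, 0.002, 0.01)
            q = quantify(curve, analyte, is_r, prep)
            quant_rows.append({
                "metabolite": met, "tissue": tissue, "planted_pg_per_ug": conc,
                "measured_pg_per_ug": round(q.pg_per_ug, 4),
                "flags": ";".join(q.flags) or ".",
            })
    pd.DataFrame(curve_rows).to_csv(args.out / "calibration_curves.tsv", sep="\t", index=False)
    qdf = pd.DataFrame(quant_rows)
    qdf.to_csv(args.out / "quantification.tsv", sep="\t", index=False)
    err = (qdf.measured_pg_per_ug / qdf.planted_pg_per_ug - 1).abs().max()
    print(f"max relative recovery error over {len(qdf)} samples: {err:.2%} "
          "(responses noise-free; curves carry 1% calibration noise)")


if __name__ == "__main__":
    main()
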