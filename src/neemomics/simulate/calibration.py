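"""Dilution-series calibration-standard simulator.

Standards form a geometric (serial-dilution) amount series; the analyte /
internal-standard response ratio follows a straight line in amount with
mean-one multiplicative lognormal noise, emulating the response of a
triple-quadrupole SRM assay near its linear range.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_IS_RESPONSE = 1.0e5


def simulate_calibration(
    low_amount: float,
    n_levels: int = 7,
    dilution_factor: float = 2.0,
    true_slope: float = 0.002,
    true_intercept: float = 0.01,
    noise_cv: float = 0.01,
    seed: Optional[int] = 0,
    is_response: float = DEFAULT_IS_RESPONSE,
) -> pd.DataFrame:
    """Simulate an internal-standard calibration table.

    Returns a DataFrame with columns ``amount_pg``, ``analyte_response``,
    ``is_response`` for ``n_levels`` standards rising from ``low_amount``
    by ``dilution_factor`` per level (e.g. 15.6 pg doubling over 7 levels
    tops out at 998.4 pg, a 64-fold span).
    """
    if low_amount <= 0:
        raise ValueError("low_amount must be positive")
    if n_levels < 3:
        raise ValueError("need at least 3 calibration levels")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    rng = np.random.default_rng(seed)
    amounts = low_amount * dilution_factor ** np.arange(n_levels)
    ratio = true_slope * amounts + true_intercept
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        ratio = ratio * rng.lognormal(-sigma**2 / 2.0, sigma, size=n_levels)
    return pd.DataFrame(
        {
            "amount_pg": amounts,
            "analyte_response": ratio * is_response,
            "is_response": np.full(n_levels, is_response),
        }
    )


def simulate_sample_responses(
    concentration_pg_per_ug: float,
    prep,
    slope: float,
    intercept: float,
    is_response: float = DEFAULT_IS_RESPONSE,
) -> tuple[float, float]:
    """Forward-simulate the SRM responses of a tissue sample of known
    concentration carried through the preparation chain (noise-free).

    Inverse of the quantification arithmetic: amount on column =
    concentration x tissue mass x (aliquot/extract) x (injection/final).
    """
    mass_ug = prep.tissue_mass_mg * 1000.0
    amount = (
        concentration_pg_per_ug
        * mass_ug
        * (prep.aliquot_volume_ul / prep.extract_volume_ul)
        * (prep.injection_volume_ul / prep.final_volume_ul)
    )
    ratio = slope * amount + intercept
    return ratio * is_response, is_response
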