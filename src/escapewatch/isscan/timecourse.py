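"""Aggregation of per-sample frequencies into time courses and
log-linear enrichment slopes.

Escape modes enrich approximately exponentially while rare (frequency
~ e^{(c + k_total) g}), so the per-generation enrichment of a feature is
estimated as the slope of ln(frequency) on generation over a user-selected
window — reported, as in the percent-wise convention, as
100 * (e^slope - 1) percent per generation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["timecourse_table", "enrichment_slopes"]


def timecourse_table(samples: dict, generations: dict | None = None) -> pd.DataFrame:
    """Tidy long-format table of feature frequencies over time points.

    Parameters
    ----------
    samples
        Mapping of time-point label -> mapping of feature name ->
        frequency (rows of one sample's quantification output).
    generations
        Optional mapping of time-point label -> generation number;
        defaults to interpreting labels as numbers.
    """
    if not samples:
        raise ValueError("at least one sample is required")
    rows = []
    for label, feats in samples.items():
        g = generations[label] if generations else float(label)
        for feature, freq in feats.items():
            rows.append({"time_point": label, "generation": g, "feature": feature, "frequency": freq})
    return pd.DataFrame(rows).sort_values(["feature", "generation"], ignore_index=True)


def enrichment_slopes(
    table: pd.DataFrame, window: tuple[float, float] = (30.0, 53.0)
) -> pd.DataFrame:
    """Per-feature log-linear enrichment over a generation window.

    Returns columns (feature, slope_per_generation, percent_per_generation,
    n_points, defined); features with fewer than two positive-frequency
    points inside the window are flagged undefined.
    """
    out = []
    for feature, grp in table.groupby("feature"):
        sel = grp[
            (grp["generation"] >= window[0])
            & (grp["generation"] <= window[1])
            & (grp["frequency"] > 0)
        ]
        if len(sel) < 2:
            out.append(
                {
                    "feature": feature,
                    "slope_per_generation": math.nan,
                    "percent_per_generation": math.nan,
                    "n_points": len(sel),
                    "defined": False,
                }
            )
            continue
        slope = np.polyfit(sel["generation"], np.log(sel["frequency"]), 1)[0]
        out.append(
            {
                "feature": feature,
                "slope_per_generation": float(slope),
                "percent_per_generation": 100.0 * math.expm1(slope),
                "n_points": len(sel),
                "defined": True,
            }
        )
    return pd.DataFrame(out)
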