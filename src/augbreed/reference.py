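"""Published genetic-parameter estimates for the strawberry trial.

This module carries the printed per-trait panel from the original
augmented-block strawberry study this pipeline models (five blocks,
13 checks, ~870 test genotypes from five 'Camino Real' crosses): variance
components, broad-sense heritability, genotypic coefficients of
variation, reference/selected means and selection gains, to two printed
decimals.

Column anchoring: the published table's column *headers* show drift (the
second column is headed AFM although AFM was excluded as non-significant),
so columns here are anchored to the internally consistent numeric block —
the per-trait GS% values restated in the article text identify the
columns as TFM, CFM, CFN, ACFM, TSS, F, L, Hue, C.  The grand-mean and CV
rows of the printed table are not columnwise consistent with this block
and are not carried here.

The identity helpers recompute derived rows (GG, GS%, h2, CVg/CVe) from
the printed inputs.  Printed values are rounded to two decimals, so each
helper also reports the *attainable interval* of the derived quantity
when every input varies within its half-ulp (+-0.005) rounding envelope;
all the recomputation formulas are monotone in each input, so evaluating
the corners of the rounding box gives the exact interval.
"""
from __future__ import annotations

import itertools
from typing import Callable

import numpy as np
import pandas as pd

PANEL_TRAITS = ("TFM", "CFM", "CFN", "ACFM", "TSS", "F", "L", "Hue", "C")

#: Columns whose printed (sigma_g2, sigma_p2, h2) triple is internally
#: consistent; the h2 identity is asserted only here.
SELF_CONSISTENT_H2 = ("TFM", "CFN", "ACFM", "L", "Hue")

PUBLISHED_PANEL = pd.DataFrame(
    {
        #        TFM        CFM        CFN     ACFM   TSS    F     L       Hue     C
        "sigma_p2": [29096.89, 24564.06, 160.38, 7.63, 0.31, 0.98, 114.72, 344.01, 80.25],
        "sigma_e2": [12997.73, 11262.51, 64.69, 1.90, 0.14, 0.32, 0.81, 30.83, 5.05],
        "sigma_g2": [16098.97, 13301.55, 95.69, 5.73, 0.17, 0.66, 113.91, 313.17, 75.70],
        "h2_pct": [55.32, 54.15, 59.66, 75.09, 54.02, 67.49, 99.29, 91.03, 93.70],
        "CVg_pct": [12.99, 14.68, 19.45, 12.51, 6.19, 8.45, 26.73, 32.31, 26.64],
        "CVg_over_CVe": [1.11, 1.08, 1.21, 1.73, 1.08, 1.44, 11.84, 3.19, 3.86],
        "Xo": [976.67, 785.21, 50.19, 19.12, 6.66, 9.66, 39.91, 54.84, 32.55],
        "Xs": [1219.45, 1047.56, 65.68, 20.07, 6.68, 9.94, 52.98, 71.66, 37.65],
        "GG": [134.33, 142.06, 9.24, 0.71, 0.01, 0.19, 12.98, 15.31, 4.78],
        "GS_pct": [13.75, 18.09, 18.42, 3.72, 0.16, 1.98, 32.52, 27.91, 14.68],
    },
    index=list(PANEL_TRAITS),
).T
PUBLISHED_PANEL.index.name = "parameter"

#: Units of the trait scale, for report labelling only.
TRAIT_UNITS = {
    "TFM": "g", "CFM": "g", "CFN": "fruits", "ACFM": "g/fruit",
    "TSS": "degrees Brix", "F": "N", "L": "", "Hue": "degrees", "C": "",
}

HALF_ULP = 0.005  # all panel values are printed to two decimals


def attainable_interval(
    fn: Callable[..., float], *printed: float, half: float = HALF_ULP,
) -> tuple[float, float]:
    """Range of ``fn`` over the rounding box of its printed inputs.

    Evaluates ``fn`` at every corner of the box ``printed_i +- half``;
    exact for functions monotone in each argument (all identity formulas
    used here are).
    """
    corners = itertools.product(*[(p - half, p + half) for p in printed])
    values = [fn(*c) for c in corners]
    return min(values), max(values)


def interval_gap(printed_value: float, lo: float, hi: float) -> float:
    """Distance from a printed value to an attainable interval (0 inside)."""
    if lo <= printed_value <= hi:
        return 0.0
    return min(abs(printed_value - lo), abs(printed_value - hi))


# -- identity formulas (all inputs on the printed scale) --------------------

def gg_from_printed(xs: float, xo: float, h2_pct: float) -> float:
    """GG = (Xs - Xo) * h2, with h2 printed in percent."""
    return (xs - xo) * h2_pct / 100.0


def gs_from_printed(xs: float, xo: float, h2_pct: float) -> float:
    """GS% = 100 (Xs - Xo) h2 / Xo, with h2 printed in percent."""
    return (xs - xo) * h2_pct / xo


def h2_from_printed(sigma_g2: float, sigma_p2: float) -> float:
    """h2 (%) = 100 sigma_g2 / sigma_p2."""
    return 100.0 * sigma_g2 / sigma_p2


def ratio_from_printed(sigma_g2: float, sigma_e2: float) -> float:
    """CVg/CVe = sqrt(sigma_g2 / sigma_e2)."""
    return float(np.sqrt(sigma_g2 / sigma_e2))


def identity_report() -> pd.DataFrame:
    """Recompute every derived panel row from the printed inputs.

    One row per (trait, quantity) with the recomputed point value, the
    attainable interval under 2-dp input rounding, the printed value and
    the gap between printed value and interval.
    """
    rows = []
    p = PUBLISHED_PANEL
    for trait in PANEL_TRAITS:
        col = p[trait]
        specs = [
            ("GG", gg_from_printed, (col["Xs"], col["Xo"], col["h2_pct"])),
            ("GS_pct", gs_from_printed, (col["Xs"], col["Xo"], col["h2_pct"])),
            ("h2_pct", h2_from_printed, (col["sigma_g2"], col["sigma_p2"])),
            ("CVg_over_CVe", ratio_from_printed,
             (col["sigma_g2"], col["sigma_e2"])),
        ]
        for name, fn, args in specs:
            lo, hi = attainable_interval(fn, *args)
            point = fn(*args)
            printed = col[name]
            rows.append({
                "trait": trait, "quantity": name, "recomputed": point,
                "interval_lo": lo, "interval_hi": hi, "printed": printed,
                "gap": interval_gap(printed, lo, hi),
            })
        rows.append({
            "trait": trait, "quantity": "sigma_p2_additivity",
            "recomputed": col["sigma_g2"] + col["sigma_e2"],
            "interval_lo": col["sigma_g2"] + col["sigma_e2"] - 2 * HALF_ULP,
            "interval_hi": col["sigma_g2"] + col["sigma_e2"] + 2 * HALF_ULP,
            "printed": col["sigma_p2"],
            "gap": interval_gap(
                col["sigma_p2"],
                col["sigma_g2"] + col["sigma_e2"] - 2 * HALF_ULP,
                col["sigma_g2"] + col["sigma_e2"] + 2 * HALF_ULP),
        })
    return pd.DataFrame(rows)
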