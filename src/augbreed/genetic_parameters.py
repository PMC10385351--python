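"""Per-trait genetic parameters of an augmented trial.

For each trait the panel reports: the phenotypic variance of adjusted
test-genotype values (sigma_p2), the check-derived environmental variance
(sigma_e2), their difference as genotypic variance (sigma_g2, truncated
at zero), broad-sense heritability h2 = sigma_g2 / sigma_p2, the
genotypic and environmental coefficients of variation and their ratio,
the reference mean Xo, the selected-set mean Xs, and the expected
response to selection GG = (Xs - Xo) * h2 with GS% = 100 * GG / Xo.

Because test genotypes are unreplicated, sigma_p2 is the sample variance
(n-1 denominator) of the adjusted values: the genotypes are treated as a
sample from the population of crosses.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .augmented_design import AdjustedValues, adjust, anova_augmented, cv_rows
from .traits_io import TrialTable

logger = logging.getLogger(__name__)

#: Panel row order (mirrors the conventional genetic-parameter report).
PANEL_ROWS = (
    "mu", "mu_F",
    "CV_checks_pct", "CV_tests_pct", "CV_all_pct",
    "sigma_p2", "sigma_e2", "sigma_g2",
    "h2_pct", "CVg_pct", "CVe_pct", "CVg_over_CVe",
    "Xo", "Xs", "GG", "GS_pct",
)


@dataclass
class GeneticParams:
    """All per-trait genetic parameters; variances in squared trait units."""

    trait: str
    mu: float
    mu_F: float
    CV_checks_pct: float
    CV_tests_pct: float
    CV_all_pct: float
    sigma_p2: float
    sigma_e2: float
    sigma_g2: float
    h2: float               # proportion; rendered as % in the panel
    CVg_pct: float
    CVe_pct: float
    CVg_over_CVe: float
    Xo: float
    Xs: float
    GG: float
    GS_pct: float
    truncated: bool = False

    def as_row(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("trait")
        d.pop("truncated")
        d.pop("h2")
        d["h2_pct"] = 100.0 * self.h2
        return d


def variance_components(adjusted: AdjustedValues) -> tuple[float, float, bool]:
    """(sigma_p2, sigma_g2, truncated) from adjusted test values.

    sigma_p2 is the n-1 sample variance of the adjusted test-genotype
    values; sigma_g2 = sigma_p2 - sigma_e2, truncated at zero (with a
    logged warning) since a variance cannot be negative.
    """
    values = adjusted.adjusted.dropna().to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(
            f"trait {adjusted.trait!r}: need >= 2 adjusted test values, "
            f"got {values.size}")
    sigma_p2 = float(np.var(values, ddof=1))
    sigma_g2 = sigma_p2 - adjusted.error_ms
    truncated = sigma_g2 < 0
    if truncated:
        logger.warning(
            "trait %s: sigma_p2 (%.4g) < sigma_e2 (%.4g); genotypic "
            "variance truncated to 0", adjusted.trait, sigma_p2,
            adjusted.error_ms)
        sigma_g2 = 0.0
    return sigma_p2, sigma_g2, truncated


def heritability(vg: float, vf: float) -> float:
    """Broad-sense heritability h2 = Vg / Vf (a proportion in [0, 1])."""
    if vf <= 0:
        raise ValueError(f"phenotypic variance must be positive, got {vf}")
    if vg < 0 or vg > vf:
        raise ValueError(
            f"genotypic variance must satisfy 0 <= Vg <= Vf, got "
            f"Vg={vg}, Vf={vf}")
    return vg / vf


def coefficients_of_variation(
    sigma_g2: float, sigma_e2: float, mean: float,
) -> tuple[float, float, float]:
    """(CVg%, CVe%, CVg/CVe) for given variance components and mean.

    The ratio equals sqrt(sigma_g2 / sigma_e2) and is NaN (flagged) when
    the environmental variance is zero.
    """
    if not mean > 0:
        raise ValueError(f"CV requires a positive mean, got {mean}")
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be non-negative")
    cvg = 100.0 * math.sqrt(sigma_g2) / mean
    cve = 100.0 * math.sqrt(sigma_e2) / mean
    if sigma_e2 == 0:
        logger.warning("sigma_e2 = 0: CVg/CVe undefined")
        return cvg, cve, math.nan
    return cvg, cve, math.sqrt(sigma_g2 / sigma_e2)


def selection_gain(xs: float, xo: float, h2: float) -> tuple[float, float]:
    """Expected response to selection: GG = (Xs - Xo) h2; GS% = 100 GG/Xo."""
    if not xo > 0:
        raise ValueError(f"reference mean Xo must be positive, got {xo}")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be a proportion in [0, 1], got {h2}")
    gg = (xs - xo) * h2
    return gg, 100.0 * gg / xo


def trait_params(
    adjusted: AdjustedValues,
    selection: set[str] | None = None,
    xo_reference: str = "tests",
) -> GeneticParams:
    """Assemble the genetic-parameter panel entries for one trait.

    ``xo_reference`` selects the reference mean Xo: ``"tests"`` (default)
    uses the mean of all adjusted test values — the operative choice for
    the gain formula — while ``"checks"`` uses the mean of check means.
    With no selection the gain entries are NaN.
    """
    sigma_p2, sigma_g2, truncated = variance_components(adjusted)
    h2 = heritability(sigma_g2, sigma_p2) if sigma_p2 > 0 else 0.0

    if xo_reference == "tests":
        xo = adjusted.test_mean
    elif xo_reference == "checks":
        xo = adjusted.check_mean
    else:
        raise ValueError(
            f"xo_reference must be 'tests' or 'checks', got {xo_reference!r}")
    cvg, cve, ratio = coefficients_of_variation(
        sigma_g2, adjusted.error_ms, xo)

    xs = gg = gs = math.nan
    if selection:
        sel = adjusted.adjusted.reindex(sorted(selection)).dropna()
        if sel.empty:
            logger.warning("trait %s: selected set has no adjusted values",
                           adjusted.trait)
        else:
            xs = float(sel.mean())
            gg, gs = selection_gain(xs, xo, h2)

    cvs = cv_rows(adjusted)
    return GeneticParams(
        trait=adjusted.trait,
        mu=adjusted.grand_mean,
        mu_F=adjusted.federer_mean,
        CV_checks_pct=cvs["CV_checks_pct"],
        CV_tests_pct=cvs["CV_tests_pct"],
        CV_all_pct=cvs["CV_all_pct"],
        sigma_p2=sigma_p2,
        sigma_e2=adjusted.error_ms,
        sigma_g2=sigma_g2,
        h2=h2,
        CVg_pct=cvg,
        CVe_pct=cve,
        CVg_over_CVe=ratio,
        Xo=xo,
        Xs=xs,
        GG=gg,
        GS_pct=gs,
        truncated=truncated,
    )


def parameter_panel(
    table: TrialTable,
    selection: set[str] | None = None,
    traits: list[str] | None = None,
    xo_reference: str = "tests",
) -> tuple[pd.DataFrame, dict[str, GeneticParams]]:
    """Genetic-parameter panel for every (or the given) trait.

    Returns ``(panel, params)``: the panel is a DataFrame with parameter
    rows and one column per trait, mirroring the standard report layout;
    ``params`` maps trait name to :class:`GeneticParams`.
    """
    traits = traits if traits is not None else table.trait_names
    params: dict[str, GeneticParams] = {}
    for trait in traits:
        adjusted = adjust(table, trait)
        params[trait] = trait_params(adjusted, selection, xo_reference)
    panel = pd.DataFrame(
        {t: p.as_row() for t, p in params.items()}).reindex(list(PANEL_ROWS))
    panel.index.name = "parameter"
    return panel, params


def anova_panel(table: TrialTable, alpha: float = 0.01,
                traits: list[str] | None = None) -> pd.DataFrame:
    """Stacked ANOVA tables for all traits (long format, one row/source)."""
    traits = traits if traits is not None else table.trait_names
    frames = []
    for trait in traits:
        frame = anova_augmented(table, trait, alpha=alpha).frame.reset_index()
        frame.insert(0, "trait", trait)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
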