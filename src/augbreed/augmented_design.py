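"""Augmented block design: adjustment and analysis of variance.

The model is the classical fixed-effect augmented block model

    Y_ij = mu + tau_i + B_j + e_ij,

where tau_i splits into check effects (replicated once per block) and
test-genotype effects (one plot each).  Because only the checks are
replicated, block effects and the error variance are estimated from the
check plots alone — a two-way RCBD ANOVA on the checks — and each test
genotype's value is adjusted by subtracting its block's estimated effect.
This reproduces the least-squares solution of the full model: with one
plot per test genotype those plots are fitted exactly, so the residual
sum of squares (and hence the block-effect estimates) is driven entirely
by the checks.

The treatment sum of squares of the augmented ANOVA is decomposed into
checks, adjusted test genotypes, and the 1-df checks-vs-genotypes
contrast; all F ratios use the check-derived error mean square.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits_io import TrialTable, TrialValidationError

logger = logging.getLogger(__name__)

ANOVA_SOURCES = (
    "blocks",
    "treatments_adj",
    "checks",
    "genotypes_adj",
    "checks_vs_genotypes",
    "error",
    "total",
)


@dataclass(frozen=True)
class CheckAnova:
    """Two-way checks x blocks ANOVA on the replicated check plots."""

    error_ms: float
    error_df: int
    block_ss: float
    check_ss: float
    error_ss: float
    block_df: int
    check_df: int
    check_grand_mean: float


@dataclass
class AdjustedValues:
    """Per-trait output of the augmented-block adjustment.

    ``adjusted`` maps each test genotype to Y_gj - B_hat_j (NaN when the
    plot is missing); ``check_means`` are raw means over the replicated
    check plots; ``error_ms`` is the check-derived residual mean square.
    ``grand_mean`` is the arithmetic mean of all plots and
    ``federer_mean`` the replication-weighted mean of entry means.
    """

    trait: str
    block_effects: pd.Series
    adjusted: pd.Series
    check_means: pd.Series
    error_ms: float
    error_df: int
    grand_mean: float
    federer_mean: float

    @property
    def test_mean(self) -> float:
        return float(self.adjusted.dropna().mean())

    @property
    def check_mean(self) -> float:
        return float(self.check_means.mean())


class AnovaTable:
    """ANOVA of an augmented block trial for one trait.

    ``frame`` has one row per source (blocks, treatments_adj, checks,
    genotypes_adj, checks_vs_genotypes, error, total) with columns
    ``df, ss, ms, F, p``.
    """

    def __init__(self, frame: pd.DataFrame, trait: str, alpha: float = 0.01):
        self.frame = frame
        self.trait = trait
        self.alpha = alpha

    @property
    def error_ms(self) -> float:
        return float(self.frame.at["error", "ms"])

    def p_value(self, source: str = "genotypes_adj") -> float:
        return float(self.frame.at[source, "p"])

    def is_significant(self, source: str = "genotypes_adj",
                       alpha: float | None = None) -> bool:
        p = self.p_value(source)
        if np.isnan(p):
            return False
        return p <= (self.alpha if alpha is None else alpha)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnovaTable(trait={self.trait!r})\n{self.frame}"


def check_anova(table: TrialTable, trait: str) -> CheckAnova:
    """RCBD ANOVA of the check plots; the error estimate of the trial.

    Returns the residual mean square with (b-1)(c-1) degrees of freedom
    plus the block and check sums of squares.  A missing check plot is an
    error — the decomposition requires the complete c x b layout.
    """
    m = table.check_matrix(trait)  # checks x blocks, complete
    values = m.to_numpy(dtype=float)
    c, b = values.shape
    if b < 2 or c < 2:
        raise TrialValidationError(
            f"trait {trait!r}: need >= 2 blocks and >= 2 checks, "
            f"got {b} x {c}")
    grand = values.mean()
    block_means = values.mean(axis=0)
    check_means = values.mean(axis=1)
    block_ss = float(c * np.sum((block_means - grand) ** 2))
    check_ss = float(b * np.sum((check_means - grand) ** 2))
    total_ss = float(np.sum((values - grand) ** 2))
    error_ss = max(total_ss - block_ss - check_ss, 0.0)
    error_df = (b - 1) * (c - 1)
    return CheckAnova(
        error_ms=error_ss / error_df,
        error_df=error_df,
        block_ss=block_ss,
        check_ss=check_ss,
        error_ss=error_ss,
        block_df=b - 1,
        check_df=c - 1,
        check_grand_mean=float(grand),
    )


def block_effects(table: TrialTable, trait: str) -> pd.Series:
    """Estimated block effects B_hat_j from the check plots.

    B_hat_j = (mean of checks in block j) - (grand mean of all check
    plots); the estimates sum to zero.
    """
    m = table.check_matrix(trait)
    effects = m.mean(axis=0) - m.to_numpy(dtype=float).mean()
    effects.name = trait
    return effects.astype(float)


def federer_weighted_mean(table: TrialTable, trait: str,
                          effects: pd.Series | None = None) -> float:
    """Replication-weighted grand mean of entry means.

    Check means (replicated b times) and adjusted test values (one plot
    each) are combined with weights proportional to replication; with all
    entries equally replicated this reduces to the arithmetic mean.
    """
    if effects is None:
        effects = block_effects(table, trait)
    m = table.check_matrix(trait)
    b = m.shape[1]
    check_means = m.mean(axis=1)
    tests = table.test_values(trait)
    adjusted = tests[trait].to_numpy(dtype=float) - effects.reindex(
        tests["block"]).to_numpy(dtype=float)
    total = b * check_means.sum() + adjusted.sum()
    n_plots = b * len(check_means) + len(adjusted)
    return float(total / n_plots)


def adjust(table: TrialTable, trait: str,
           effects: pd.Series | None = None) -> AdjustedValues:
    """Adjusted test-genotype values Y_gj - B_hat_j for one trait.

    Test genotypes with no (or missing) observation are carried as NaN
    and logged; check means come from the raw replicated plots.
    """
    if effects is None:
        effects = block_effects(table, trait)
    ca = check_anova(table, trait)
    m = table.check_matrix(trait)

    tests = table.tests[["genotype_id", "block", trait]]
    adjusted = pd.Series(
        tests[trait].to_numpy(dtype=float)
        - effects.reindex(tests["block"]).to_numpy(dtype=float),
        index=pd.Index(tests["genotype_id"], name="genotype_id"),
        name=trait,
    )
    n_missing = int(adjusted.isna().sum())
    if n_missing:
        logger.warning("trait %s: %d test plots missing; excluded from this "
                       "trait's analysis", trait, n_missing)

    all_values = pd.concat(
        [table.checks[trait], table.tests[trait]]).astype(float).dropna()
    grand_mean = float(all_values.mean())
    return AdjustedValues(
        trait=trait,
        block_effects=effects,
        adjusted=adjusted,
        check_means=m.mean(axis=1),
        error_ms=ca.error_ms,
        error_df=ca.error_df,
        grand_mean=grand_mean,
        federer_mean=federer_weighted_mean(table, trait, effects),
    )


def anova_augmented(table: TrialTable, trait: str,
                    alpha: float = 0.01) -> AnovaTable:
    """Augmented-block ANOVA with the treatment SS decomposition.

    Sources: blocks (ignoring treatments), treatments adjusted for
    blocks, split into checks / adjusted genotypes / checks-vs-genotypes,
    and the check-derived error.  F ratios are against the error mean
    square; with zero error degrees of freedom no tests are performed and
    F and p are NaN.
    """
    ca = check_anova(table, trait)
    effects = block_effects(table, trait)

    checks = table.checks[["block", trait]].dropna(subset=[trait])
    tests = table.test_values(trait)
    y_all = pd.concat([checks[trait], tests[trait]]).to_numpy(dtype=float)
    blocks_all = pd.concat([checks["block"], tests["block"]])
    n = y_all.size
    grand = y_all.mean()
    total_ss = float(np.sum((y_all - grand) ** 2))

    # blocks ignoring treatments: between-block SS over all plots
    block_groups = pd.Series(y_all, index=blocks_all.values).groupby(level=0)
    block_ss = float(sum(
        len(g) * (g.mean() - grand) ** 2 for _, g in block_groups))
    b = len(table.blocks)

    # treatments eliminating blocks: full-model RSS equals the check RCBD
    # residual SS (test plots are fitted exactly), so
    # SS_treat(adj) = SS_total - SS_blocks(ignoring) - SS_error.
    error_ss = ca.error_ss
    treat_ss = max(total_ss - block_ss - error_ss, 0.0)

    m = table.check_matrix(trait)
    c = m.shape[0]
    check_means = m.mean(axis=1).to_numpy(dtype=float)
    checks_ss = float(m.shape[1] * np.sum(
        (check_means - check_means.mean()) ** 2))

    adjusted = (tests[trait].to_numpy(dtype=float)
                - effects.reindex(tests["block"]).to_numpy(dtype=float))
    v = adjusted.size
    genotypes_ss = float(np.sum((adjusted - adjusted.mean()) ** 2))
    # 1-df contrast between the check plots (bc of them) and the adjusted
    # genotype values (v of them); the three components are the classical
    # ones and are not forced to add up to the adjusted treatment SS.
    n_checks_plots = c * m.shape[1]
    cvg_ss = float(
        n_checks_plots * v / (n_checks_plots + v)
        * (ca.check_grand_mean - adjusted.mean()) ** 2)

    rows = {
        "blocks": (b - 1, block_ss),
        "treatments_adj": (c + v - 1, treat_ss),
        "checks": (c - 1, checks_ss),
        "genotypes_adj": (v - 1, genotypes_ss),
        "checks_vs_genotypes": (1, cvg_ss),
        "error": (ca.error_df, error_ss),
        "total": (n - 1, total_ss),
    }
    frame = pd.DataFrame(
        [(src, df, ss) for src, (df, ss) in rows.items()],
        columns=["source", "df", "ss"]).set_index("source")
    frame["ms"] = frame["ss"] / frame["df"].replace(0, np.nan)
    frame.at["total", "ms"] = np.nan

    if ca.error_df > 0 and ca.error_ms > 0:
        frame["F"] = frame["ms"] / ca.error_ms
        frame["p"] = stats.f.sf(frame["F"], frame["df"], ca.error_df)
    else:
        if ca.error_df == 0:
            logger.warning(
                "trait %s: zero error degrees of freedom; no F tests", trait)
        frame["F"] = np.nan
        frame["p"] = np.nan
    frame.loc[["error", "total"], ["F", "p"]] = np.nan
    return AnovaTable(frame, trait=trait, alpha=alpha)


def cv_percent(ms_error: float, mean: float) -> float:
    """Coefficient of variation, %: 100 * sqrt(error MS) / mean."""
    if not mean > 0:
        raise ValueError(f"CV requires a positive mean, got {mean}")
    if ms_error < 0:
        raise ValueError(f"error mean square must be >= 0, got {ms_error}")
    return 100.0 * float(np.sqrt(ms_error)) / float(mean)


def cv_rows(adj: AdjustedValues) -> dict[str, float]:
    """The three CV presentations: vs check, test and combined means.

    The combined row uses the replication-weighted (Federer) mean.
    """
    return {
        "CV_checks_pct": cv_percent(adj.error_ms, adj.check_mean),
        "CV_tests_pct": cv_percent(adj.error_ms, adj.test_mean),
        "CV_all_pct": cv_percent(adj.error_ms, adj.federer_mean),
    }
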