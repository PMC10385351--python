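"""Synthetic augmented-block trials with known genetic architecture.

The generator draws data from the same additive model the analysis
assumes:

    Y_ijt = mu_t + g_it + B_jt + e_ijt,

with genotypic effects g_i multivariate normal across traits (a
configured genetic correlation matrix and per-trait genotypic variances),
fixed block effects drawn once per trial, and residuals independent
normals.  Checks are replicated once per block; test genotypes are
assigned to blocks round-robin within their populations.  Everything is
reproducible from a single seed.

``table1_preset`` returns the study-scale configuration: 5 blocks, 13
checks (8 commercial cultivars + 5 first-generation parents), 870 test
genotypes from five populations, and nine traits whose means and
variance components equal the published panel (see
:mod:`augbreed.reference`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import augmented_design, genetic_parameters, selection_index
from .reference import PUBLISHED_PANEL, PANEL_TRAITS, TRAIT_UNITS
from .traits_io import ROLE_CHECK, ROLE_TEST, TraitSpec, TrialTable

logger = logging.getLogger(__name__)

#: The 13 replicated checks: 8 commercial cultivars + 5 parents.
DEFAULT_CHECK_IDS = (
    "Camarosa", "CaminoReal", "Monterrey", "Albion", "Festival",
    "Dover", "Aromas", "SanAndreas",
    "RVFS06", "RVCA16", "RVCS44", "RVFS07", "RVDA11",
)

#: Test-genotype populations (cross families) and their sizes; 870 total.
DEFAULT_POPULATIONS = {
    "RVFS07CR": 194,
    "RVFS06CR": 171,
    "RVCA16CR": 163,
    "RVCS44CR": 152,
    "RVDA11CR": 190,
}

DEFAULT_SEED = 20230714


@dataclass(frozen=True)
class TraitSim:
    """Generative parameters of one trait."""

    name: str
    mean: float
    sigma_g2: float
    sigma_e2: float
    block_sd: float = 0.0
    direction: int = +1
    units: str = ""

    @property
    def h2(self) -> float:
        """True broad-sense heritability implied by the components."""
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else 0.0


@dataclass
class SimulationConfig:
    """Full specification of a synthetic augmented-block trial."""

    traits: list[TraitSim]
    genetic_corr: np.ndarray | None = None  # identity when None
    n_blocks: int = 5
    check_ids: tuple[str, ...] = DEFAULT_CHECK_IDS
    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATIONS))
    seed: int = DEFAULT_SEED

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def n_tests(self) -> int:
        return sum(self.populations.values())

    def corr_matrix(self) -> np.ndarray:
        t = len(self.traits)
        if self.genetic_corr is None:
            return np.eye(t)
        return np.asarray(self.genetic_corr, dtype=float)

    def validate(self) -> None:
        if self.n_blocks < 2 or len(self.check_ids) < 2:
            raise ValueError("need >= 2 blocks and >= 2 checks")
        for t in self.traits:
            if t.sigma_g2 < 0 or t.sigma_e2 < 0 or t.block_sd < 0:
                raise ValueError(
                    f"trait {t.name!r}: variances/SDs must be >= 0")
        corr = self.corr_matrix()
        k = len(self.traits)
        if corr.shape != (k, k):
            raise ValueError(
                f"genetic correlation matrix must be {k} x {k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("genetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("genetic correlation matrix needs unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError(
                "genetic correlation matrix is not positive semi-definite")

    def trait_specs(self) -> list[TraitSpec]:
        return [TraitSpec(name=t.name, direction=t.direction, units=t.units)
                for t in self.traits]


@dataclass
class TruthRecord:
    """The latent quantities behind one simulated trial."""

    genotype_effects: pd.DataFrame   # genotype x trait (deviations from mu)
    block_effects: pd.DataFrame      # block x trait
    residuals: pd.DataFrame          # plot rows x trait

    def true_h2(self, config: SimulationConfig) -> dict[str, float]:
        return {t.name: t.h2 for t in config.traits}


def _corr_sqrt(corr: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (handles singular correlation matrices)."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def simulate_trial(
    config: SimulationConfig, seed: int | np.random.SeedSequence | None = None,
) -> tuple[TrialTable, TruthRecord]:
    """Draw one augmented-block trial from the configured model.

    Returns the plot-level :class:`TrialTable` together with the
    :class:`TruthRecord` of genotype effects, block effects and realized
    residuals.  The same seed yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    traits = config.traits
    names = config.trait_names
    t = len(traits)
    blocks = [f"B{j + 1}" for j in range(config.n_blocks)]

    test_ids, test_pops = [], []
    for pop, size in config.populations.items():
        for i in range(size):
            test_ids.append(f"{pop}{i + 1:03d}")
            test_pops.append(pop)
    genotype_ids = list(config.check_ids) + test_ids
    n_geno = len(genotype_ids)

    # genotype effects: z @ sqrt(R) scaled by per-trait genetic SDs
    sd_g = np.array([np.sqrt(tr.sigma_g2) for tr in traits])
    g = rng.standard_normal((n_geno, t)) @ _corr_sqrt(config.corr_matrix())
    g *= sd_g[None, :]

    # fixed block effects, one draw per trial, centered to sum to zero
    # across blocks (the fixed-effect model convention; the block mean is
    # not identifiable separately from the grand mean)
    sd_b = np.array([tr.block_sd for tr in traits])
    b_eff = rng.standard_normal((config.n_blocks, t)) * sd_b[None, :]
    b_eff -= b_eff.mean(axis=0, keepdims=True)

    # plot layout: checks once per block, tests round-robin across blocks
    rows_geno, rows_pop, rows_role, rows_block = [], [], [], []
    for check in config.check_ids:
        for blk in blocks:
            rows_geno.append(check)
            rows_pop.append("check")
            rows_role.append(ROLE_CHECK)
            rows_block.append(blk)
    for i, (gid, pop) in enumerate(zip(test_ids, test_pops)):
        rows_geno.append(gid)
        rows_pop.append(pop)
        rows_role.append(ROLE_TEST)
        rows_block.append(blocks[i % config.n_blocks])

    n_plots = len(rows_geno)
    sd_e = np.array([np.sqrt(tr.sigma_e2) for tr in traits])
    residuals = rng.standard_normal((n_plots, t)) * sd_e[None, :]

    geno_index = {gid: i for i, gid in enumerate(genotype_ids)}
    block_index = {blk: j for j, blk in enumerate(blocks)}
    gi = np.array([geno_index[x] for x in rows_geno])
    bi = np.array([block_index[x] for x in rows_block])
    mu = np.array([tr.mean for tr in traits])
    values = mu[None, :] + g[gi] + b_eff[bi] + residuals

    data = pd.DataFrame({
        "genotype_id": rows_geno,
        "population_id": rows_pop,
        "role": rows_role,
        "block": rows_block,
    })
    for k, name in enumerate(names):
        data[name] = values[:, k]

    table = TrialTable(data, config.trait_specs())
    truth = TruthRecord(
        genotype_effects=pd.DataFrame(
            g, index=pd.Index(genotype_ids, name="genotype_id"),
            columns=names),
        block_effects=pd.DataFrame(
            b_eff, index=pd.Index(blocks, name="block"), columns=names),
        residuals=pd.DataFrame(residuals, columns=names).assign(
            genotype_id=rows_geno, block=rows_block),
    )
    return table, truth


def table1_preset(seed: int = DEFAULT_SEED) -> SimulationConfig:
    """Study-scale configuration with the published variance components.

    Per-trait means use the published reference means (Xo row) and the
    genotypic/environmental variances the published panel values.  The
    genetic correlation matrix carries a positive production block
    (TFM/CFM/CFN r = 0.7) and a negative hue-yield association
    (TFM-Hue r = -0.4), the qualitative pattern of the published
    correlation network.  Block-effect SDs are set to half the residual
    SD — moderate field heterogeneity.  Directions are all +1: for every
    trait, including lightness and hue, the published selected-set means
    exceeded the reference means.
    """
    traits = []
    for name in PANEL_TRAITS:
        col = PUBLISHED_PANEL[name]
        traits.append(TraitSim(
            name=name,
            mean=float(col["Xo"]),
            sigma_g2=float(col["sigma_g2"]),
            sigma_e2=float(col["sigma_e2"]),
            block_sd=0.5 * float(np.sqrt(col["sigma_e2"])),
            direction=+1,
            units=TRAIT_UNITS.get(name, ""),
        ))
    corr = np.eye(len(PANEL_TRAITS))
    idx = {n: i for i, n in enumerate(PANEL_TRAITS)}
    for a, b, r in (("TFM", "CFM", 0.7), ("TFM", "CFN", 0.7),
                    ("CFM", "CFN", 0.7), ("TFM", "Hue", -0.4)):
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return SimulationConfig(traits=traits, genetic_corr=corr, seed=seed)


# ---------------------------------------------------------------------------
# Monte-Carlo recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoverySummary:
    """Bias/RMSE of the estimated genetic parameters over replicates.

    ``estimates`` is a per-trait frame with true values, mean estimates,
    bias and RMSE for h2, sigma_g2 and GS%; ``response`` compares the
    expected gain GG with the realized response (mean true genotypic
    value of the selected set minus the population mean) per trait, and
    ``phenotypic_differential`` is the mean realized Xs - Xo vector.
    """

    estimates: pd.DataFrame
    response: pd.DataFrame
    phenotypic_differential: pd.Series
    n_reps: int


def _analyze_replicate(
    table: TrialTable, truth: TruthRecord, intensity: float,
    weights_mode: str,
) -> tuple[dict, dict]:
    """One pipeline pass: adjust, estimate, select, measure response."""
    est: dict[str, dict[str, float]] = {}
    adjusted_cols = {}
    for trait in table.trait_names:
        adj = augmented_design.adjust(table, trait)
        p = genetic_parameters.trait_params(adj)
        est[trait] = {"h2": p.h2, "sigma_g2": p.sigma_g2, "Xo": p.Xo,
                      "CVg_pct": p.CVg_pct}
        adjusted_cols[trait] = adj.adjusted

    values = pd.DataFrame(adjusted_cols)
    weights = None
    if weights_mode == "cvg":
        weights = selection_index.weights_from_cvg(
            {t: est[t]["CVg_pct"] for t in table.trait_names})
    result = selection_index.run_selection(
        values, table.traits, intensity=intensity, weights=weights)
    selected = result.selected_ids

    response: dict[str, dict[str, float]] = {}
    g = truth.genotype_effects
    g_tests = g.loc[values.index]
    for trait in table.trait_names:
        xs = float(values.loc[selected, trait].mean())
        xo = est[trait]["Xo"]
        gg, gs = genetic_parameters.selection_gain(
            xs, xo, est[trait]["h2"])
        realized = float(g_tests.loc[selected, trait].mean()
                         - g_tests[trait].mean())
        response[trait] = {"expected_GG": gg, "realized": realized,
                           "GS_pct": gs, "diff_pheno": xs - xo}
    return est, response


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    intensity: float = 0.05,
    weights: str = "cvg",
    seed: int | None = None,
) -> RecoverySummary:
    """Run the full estimate-and-select pipeline on ``n_reps`` simulated
    trials and summarize parameter recovery.

    Per-replicate sub-streams are spawned deterministically from the
    master seed (``config.seed`` unless overridden).
    """
    if n_reps < 2:
        raise ValueError("recovery experiment needs n_reps >= 2")
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = master.spawn(n_reps)

    names = config.trait_names
    h2_true = {t.name: t.h2 for t in config.traits}
    sg2_true = {t.name: t.sigma_g2 for t in config.traits}

    h2_est = {n: [] for n in names}
    sg2_est = {n: [] for n in names}
    gs_est = {n: [] for n in names}
    exp_gg = {n: [] for n in names}
    realized = {n: [] for n in names}
    dpheno = {n: [] for n in names}

    for r, stream in enumerate(streams):
        try:
            table, truth = simulate_trial(config, seed=stream)
            est, resp = _analyze_replicate(table, truth, intensity, weights)
        except Exception as exc:  # noqa: BLE001 - annotate replicate
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        for n in names:
            h2_est[n].append(est[n]["h2"])
            sg2_est[n].append(est[n]["sigma_g2"])
            gs_est[n].append(resp[n]["GS_pct"])
            exp_gg[n].append(resp[n]["expected_GG"])
            realized[n].append(resp[n]["realized"])
            dpheno[n].append(resp[n]["diff_pheno"])

    # paired per-replicate exact-theory prediction: G P^{-1} dp_r
    dp_matrix = np.column_stack([dpheno[n] for n in names])
    sd_g = np.array([np.sqrt(t.sigma_g2) for t in config.traits])
    G = config.corr_matrix() * np.outer(sd_g, sd_g)
    resid = np.array([t.sigma_e2 * (1.0 + 1.0 / len(config.check_ids))
                      for t in config.traits])
    # pred_r' = dp_r' P^{-1} G  (P, G symmetric)
    theory = dp_matrix @ np.linalg.solve(G + np.diag(resid), G)

    rows = []
    for n in names:
        h2 = np.array(h2_est[n])
        sg2 = np.array(sg2_est[n])
        rows.append({
            "trait": n,
            "h2_true": h2_true[n],
            "h2_mean": h2.mean(),
            "h2_bias": h2.mean() - h2_true[n],
            "h2_rmse": float(np.sqrt(np.mean((h2 - h2_true[n]) ** 2))),
            "sigma_g2_true": sg2_true[n],
            "sigma_g2_mean": sg2.mean(),
            "sigma_g2_bias": sg2.mean() - sg2_true[n],
            "sigma_g2_rmse": float(
                np.sqrt(np.mean((sg2 - sg2_true[n]) ** 2))),
            "GS_pct_mean": float(np.mean(gs_est[n])),
        })
    estimates = pd.DataFrame(rows).set_index("trait")

    resp_rows = []
    for i, n in enumerate(names):
        e = np.array(exp_gg[n])
        rl = np.array(realized[n])
        diff = rl - e
        tdiff = rl - theory[:, i]
        resp_rows.append({
            "trait": n,
            "expected_GG_mean": e.mean(),
            "realized_mean": rl.mean(),
            "theory_mean": float(theory[:, i].mean()),
            "diff_mean": diff.mean(),
            "diff_se": float(diff.std(ddof=1) / np.sqrt(n_reps)),
            "theory_diff_mean": float(tdiff.mean()),
            "theory_diff_se": float(tdiff.std(ddof=1) / np.sqrt(n_reps)),
            "realized_se": float(rl.std(ddof=1) / np.sqrt(n_reps)),
        })
    response = pd.DataFrame(resp_rows).set_index("trait")
    phen = pd.Series({n: float(np.mean(dpheno[n])) for n in names},
                     name="phenotypic_differential")
    return RecoverySummary(estimates=estimates, response=response,
                           phenotypic_differential=phen, n_reps=n_reps)


def theoretical_response(
    config: SimulationConfig, phenotypic_differential: pd.Series,
) -> pd.Series:
    """Exact expected genetic response given a phenotypic differential.

    Under the generative model the regression of the genotypic values on
    the adjusted phenotypes is linear, so for *any* selection rule the
    expected per-trait genetic response is ``G P^{-1} dp``, where G is
    the genetic covariance matrix, P the covariance of adjusted
    phenotypes (G plus residual variance inflated by the block-effect
    estimation term sigma_e2 / c), and dp the realized per-trait
    phenotypic selection differential.  The univariate gain
    GG = h2 (Xs - Xo) is the diagonal approximation of this vector and
    understates/overstates the response when traits are genetically
    correlated and selection is multi-trait.
    """
    names = config.trait_names
    sd_g = np.array([np.sqrt(t.sigma_g2) for t in config.traits])
    G = config.corr_matrix() * np.outer(sd_g, sd_g)
    c = len(config.check_ids)
    resid = np.array([t.sigma_e2 * (1.0 + 1.0 / c) for t in config.traits])
    P = G + np.diag(resid)
    dp = phenotypic_differential.reindex(names).to_numpy(dtype=float)
    pred = G @ np.linalg.solve(P, dp)
    return pd.Series(pred, index=names, name="theoretical_response")
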