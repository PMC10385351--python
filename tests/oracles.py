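"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — direct least squares on dummy
matrices, exhaustive enumeration, textbook agglomeration — and shares no
code with the package implementation it checks.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def ls_fit_augmented(table, trait: str):
    """Direct least-squares fit of y = mu + treatment + block.

    Dummy-codes every treatment (checks and tests alike) and every block
    and solves the rank-deficient normal equations with the
    pseudoinverse.  Returns the treatment-effect estimates (identifiable
    only up to contrasts), the residual mean square on (b-1)(c-1)
    degrees of freedom, and the genotype order.
    """
    checks = table.checks[["genotype_id", "block", trait]].dropna()
    tests = table.tests[["genotype_id", "block", trait]].dropna()
    plots = pd.concat([checks, tests], ignore_index=True)

    genotypes = sorted(plots["genotype_id"].unique())
    blocks = sorted(plots["block"].unique())
    g_idx = {g: i for i, g in enumerate(genotypes)}
    b_idx = {b: i for i, b in enumerate(blocks)}

    n = len(plots)
    X = np.zeros((n, 1 + len(genotypes) + len(blocks)))
    X[:, 0] = 1.0
    for row, (_, r) in enumerate(plots.iterrows()):
        X[row, 1 + g_idx[r["genotype_id"]]] = 1.0
        X[row, 1 + len(genotypes) + b_idx[r["block"]]] = 1.0
    y = plots[trait].to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    b = len(blocks)
    c = table.checks["genotype_id"].nunique()
    error_df = (b - 1) * (c - 1)
    effects = pd.Series(
        beta[1:1 + len(genotypes)], index=genotypes, name="effect")
    return effects, rss / error_df, genotypes


def exhaustive_rank_sum(values: pd.DataFrame, directions: dict[str, int],
                        weights: dict[str, float] | None = None):
    """Sum-of-ranks index by explicit comparison counting.

    Rank of genotype i within a trait = 1 + number of strictly better
    genotypes + half the number of equal ones (average-tie rule), with
    "better" defined by the trait's direction.
    """
    index = {}
    for g in values.index:
        total = 0.0
        for trait in values.columns:
            x = values.at[g, trait]
            better = equal = 0
            for h in values.index:
                if h == g:
                    continue
                yv = values.at[h, trait]
                if (yv - x) * directions[trait] > 0:
                    better += 1
                elif yv == x:
                    equal += 1
            rank = 1.0 + better + equal / 2.0
            w = 1.0 if weights is None else weights[trait]
            total += w * rank
        index[g] = total
    return pd.Series(index)


def brute_force_upgma(dist: np.ndarray):
    """Textbook UPGMA agglomeration; returns the cophenetic matrix.

    Cluster distances are the unweighted means of the original pairwise
    distances; the closest pair (ties: lexicographically first) merges at
    each step, and every cross-pair of the merged clusters gets the merge
    height as its cophenetic distance.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a]
                         for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def rcbd_residual_ms(values: np.ndarray) -> float:
    """Residual mean square of a two-way layout via direct least squares."""
    c, b = values.shape
    rows = []
    y = []
    for i in range(c):
        for j in range(b):
            x = np.zeros(1 + c + b)
            x[0] = 1.0
            x[1 + i] = 1.0
            x[1 + c + j] = 1.0
            rows.append(x)
            y.append(values[i, j])
    X = np.array(rows)
    y = np.array(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return rss / ((b - 1) * (c - 1))
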