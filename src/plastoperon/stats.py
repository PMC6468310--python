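"""Resampling and enrichment statistics used by the operon pipeline.

Group comparisons between operon-pair and non-operon-pair feature values
are assessed distribution-free: a permutation test on the absolute
difference of group means, and a complementary "empiric P-value" that
repeatedly subsamples both groups and scores how often one sample mean
exceeds the other.  Gene-class enrichment among operon genes is quantified
by a normalised enrichment index together with a hypergeometric tail
P-value, with Benjamini-Hochberg control across multiple classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("plastoperon")

CENSOR_BOUND = 1e-5


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one gene class.

    x_i operon genes of class i, among n total operon genes; k_i genes of
    class i among m genes overall.
    """

    x_i: int
    n: int
    k_i: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_i <= min(self.n, self.k_i)):
            raise ValueError("require 0 <= x_i <= min(n, k_i)")
        if self.k_i > self.m or self.n > self.m:
            raise ValueError("class and operon totals cannot exceed the gene total")


@dataclass(frozen=True)
class PermutationResult:
    observed_margin: float
    n_permutations: int
    p_value: float
    censored: bool = False

    def __str__(self) -> str:
        if self.censored:
            return f"P < {self.p_value:g}"
        return f"P = {self.p_value:g}"


def _permuted_margins(
    pooled: np.ndarray, n_a: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Absolute mean differences of ``n_perm`` random splits of the pool."""
    n = len(pooled)
    total = pooled.sum()
    margins = np.empty(n_perm)
    # Vectorised in chunks: random keys -> argsort -> first n_a indices form group A.
    chunk = max(1, int(2e6 // n))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        keys = rng.random((size, n))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        sums_a = pooled[idx].sum(axis=1)
        mean_a = sums_a / n_a
        mean_b = (total - sums_a) / (n - n_a)
        margins[done : done + size] = np.abs(mean_a - mean_b)
        done += size
    return margins


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test on the absolute difference of means.

    Values are pooled and split ``n`` times into two random vectors of the
    original sizes; the P-value is the fraction of permuted margins at
    least as extreme as the observed one.  A fraction of exactly 0 at the
    default n = 10^4 triggers a rerun at 10^5; if still 0, the result is a
    censored bound of 10^-5 (never a P of 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    rng = np.random.default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    margins = _permuted_margins(pooled, len(a), n, rng)
    p = float(np.mean(margins >= observed))
    n_used = n
    if p == 0.0 and n < 100_000:
        n_used = 100_000
        margins = _permuted_margins(pooled, len(a), n_used, rng)
        p = float(np.mean(margins >= observed))
    if p == 0.0:
        return PermutationResult(observed, n_used, CENSOR_BOUND, censored=True)
    return PermutationResult(observed, n_used, p)


def empiric_pvalue(
    group_a: Sequence[float],
    group_b: Sequence[float],
    sample_size: int = 50,
    rounds: int = 1000,
    objective: str = "greater",
    seed: int | None = None,
) -> float:
    """Fraction of subsampling rounds in which mean(a) relates to mean(b).

    Each round draws ``sample_size`` values from each group (without
    replacement when the group is large enough, else with replacement) and
    scores 1 when the objective relation between the sample means holds.
    The result estimates P(relation holds): values near 1 support the
    relation, near 0.5 indicate no difference.
    """
    if objective not in ("greater", "less"):
        raise ValueError("objective must be 'greater' or 'less'")
    if rounds < 100:
        logger.warning("empiric_pvalue with rounds=%d has coarse resolution", rounds)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    rng = np.random.default_rng(seed)

    def draw(x: np.ndarray) -> np.ndarray:
        replace = len(x) < sample_size
        return rng.choice(x, size=sample_size, replace=replace)

    hits = 0
    for _ in range(rounds):
        ma = draw(a).mean()
        mb = draw(b).mean()
        if (objective == "greater" and ma > mb) or (objective == "less" and ma < mb):
            hits += 1
    return hits / rounds


FULLY_DEPLETED = float("-inf")


def enrichment_index(inp: EnrichmentInput) -> float:
    """Normalised over/under-representation of a gene class among operon genes.

    ((x_i/n) - (k_i/m)) / (x_i/n): positive means the class is
    over-represented among operon genes, negative depleted; always <= 1.
    A class with no operon genes at all returns -inf ("fully depleted").
    """
    if inp.n == 0 or inp.m == 0:
        raise ValueError("n and m must be positive")
    if inp.x_i == 0:
        return FULLY_DEPLETED
    observed = inp.x_i / inp.n
    background = inp.k_i / inp.m
    return (observed - background) / observed


def hypergeometric_enrichment(inp: EnrichmentInput) -> float:
    """Hypergeometric tail P-value matching the direction of the index.

    Upper tail P(X >= x_i) when the class is enriched (index >= 0), lower
    tail P(X <= x_i) when depleted, for X ~ Hypergeom(m, k_i, n).
    """
    dist = sps.hypergeom(inp.m, inp.k_i, inp.n)
    enriched = inp.x_i > 0 and enrichment_index(inp) >= 0
    if enriched:
        return float(dist.sf(inp.x_i - 1))
    return float(dist.cdf(inp.x_i))


def bh_fdr(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; returns (adjusted, reject)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted <= alpha


def functional_enrichment_resampling(
    operon_map,
    gene_classes: Mapping[str, str],
    n_samples: int = 10_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Do operons group functionally related genes?

    Each sample draws a random multi-gene operon and scores the fraction
    of its internal adjacent gene pairs whose members share a functional
    class; the same sampling on a class-shuffled gene->class map provides
    the null backdrop.  Returns (observed scores, shuffled scores, z, p)
    where the two score arrays are the ``n_samples``-draw resampling
    distributions (for display), while z and p come from a two-tailed
    rank-sum test on the per-operon scores — one score per operon under
    each map — so the test's sample size is the number of operons, not
    the resampling depth.
    """
    genes = [g for op in operon_map.operons for g in op]
    assigned = sum(1 for g in genes if g in gene_classes)
    if assigned < 0.9 * len(genes):
        raise ValueError("gene classes assigned to fewer than 90% of genes")
    multi = [op for op in operon_map.operons if len(op) >= 2]
    if not multi:
        raise ValueError("no multi-gene operons to sample")
    rng = np.random.default_rng(seed)

    def score(op: Sequence[str], classes: Mapping[str, str]) -> float:
        shared = sum(
            1
            for g5, g3 in zip(op, op[1:])
            if classes.get(g5) is not None and classes.get(g5) == classes.get(g3)
        )
        return shared / (len(op) - 1)

    # Class-shuffled null: permute the class labels over the same genes.
    keys = [g for g in genes if g in gene_classes]
    labels = [gene_classes[g] for g in keys]
    shuffled_labels = list(labels)
    rng.shuffle(shuffled_labels)
    shuffled_map = dict(zip(keys, shuffled_labels))

    per_operon_obs = np.array([score(op, gene_classes) for op in multi])
    per_operon_shuf = np.array([score(op, shuffled_map) for op in multi])
    picks = rng.integers(0, len(multi), size=n_samples)
    observed = per_operon_obs[picks]
    picks_null = rng.integers(0, len(multi), size=n_samples)
    shuffled = per_operon_shuf[picks_null]

    z, p = sps.ranksums(per_operon_obs, per_operon_shuf)
    return observed, shuffled, float(z), float(p)


def stats_report(results: Mapping[str, PermutationResult]) -> "pd.DataFrame":
    """Tabulate named permutation-test results for TSV/JSON export."""
    import pandas as pd

    rows = [
        {
            "test": name,
            "statistic": r.observed_margin,
            "p": r.p_value,
            "n_permutations": r.n_permutations,
            "censored": r.censored,
        }
        for name, r in results.items()
    ]
    return pd.DataFrame(rows)
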