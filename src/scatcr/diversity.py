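"""Per-locus genetic diversity statistics and equilibrium tests.

Diversity follows the usual microsatellite summaries: observed
heterozygosity, unbiased expected heterozygosity ``2n/(2n-1) * (1 - sum
p_i^2)``, and polymorphism information content. Hardy-Weinberg and
linkage-disequilibrium tests are seeded permutation tests; multiple
testing uses the Holm step-down ("sequential Bonferroni") procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LocusDiversity",
    "TestResult",
    "locus_diversity",
    "panel_summary",
    "hwe_test",
    "ld_test",
    "sequential_bonferroni",
]


@dataclass
class LocusDiversity:
    locus: str
    n_alleles: int
    size_min: int
    size_max: int
    h_exp: float
    h_obs: float
    pic: float
    n_typed: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    testable: bool = True


def _genotypes_at(individuals, locus: str) -> list[tuple[int, int]]:
    return [
        ind.consensus[locus]
        for ind in individuals
        if ind.consensus.get(locus) is not None
    ]


def _freqs(genos: list[tuple[int, int]]) -> np.ndarray:
    alleles = np.asarray([a for g in genos for a in g])
    _, counts = np.unique(alleles, return_counts=True)
    return counts / counts.sum()


def expected_heterozygosity(p: np.ndarray, n: int | None = None) -> float:
    """Gene diversity ``1 - sum p^2``; unbiased-corrected when ``n`` given."""
    h = 1.0 - float(np.sum(np.asarray(p, dtype=float) ** 2))
    if n is not None:
        h *= 2 * n / (2 * n - 1)
    return h


def pic_value(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p**2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - a2 - cross


def panel_summary(table: pd.DataFrame) -> pd.Series:
    """Unweighted means over loci of a per-locus summary table.

    Reproduces the arithmetic of a diversity table's "Average" row: every
    numeric column is averaged across loci with equal weight.
    """
    numeric = table.select_dtypes("number")
    if numeric.empty:
        raise ValueError("no numeric per-locus columns to average")
    return numeric.mean(axis=0)


def locus_diversity(
    individuals, unbiased: bool = True
) -> tuple[list[LocusDiversity], pd.Series]:
    """Per-locus diversity plus unweighted panel means.

    Loci typed in fewer than 2 individuals are excluded. Returns the
    per-locus records and a Series of unweighted means over loci
    (``n_alleles``, ``h_exp``, ``h_obs``, ``pic``).
    """
    loci: list[str] = []
    for ind in individuals:
        for locus in ind.consensus:
            if locus not in loci:
                loci.append(locus)
    records = []
    for locus in loci:
        genos = _genotypes_at(individuals, locus)
        if len(genos) < 2:
            continue
        alleles = sorted({a for g in genos for a in g})
        p = _freqs(genos)
        h_obs = float(np.mean([a != b for a, b in genos]))
        records.append(
            LocusDiversity(
                locus=locus,
                n_alleles=len(alleles),
                size_min=min(alleles),
                size_max=max(alleles),
                h_exp=expected_heterozygosity(p, len(genos) if unbiased else None),
                h_obs=h_obs,
                pic=pic_value(p),
                n_typed=len(genos),
            )
        )
    means = pd.Series(
        {
            "n_alleles": float(np.mean([r.n_alleles for r in records])),
            "h_exp": float(np.mean([r.h_exp for r in records])),
            "h_obs": float(np.mean([r.h_obs for r in records])),
            "pic": float(np.mean([r.pic for r in records])),
        }
    )
    return records, means


def hwe_test(
    individuals,
    locus: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Permutation exact test of Hardy-Weinberg proportions at one locus.

    The 2n allele copies are shuffled and re-paired into genotypes; the
    two-sided p-value is the total null probability of heterozygote
    counts no more probable than the observed one (probabilities
    estimated from the permutation distribution). Monomorphic loci are
    not testable and return p = 1.
    """
    genos = _genotypes_at(individuals, locus)
    if len(genos) < 5:
        raise ValueError(f"need >= 5 typed individuals at {locus}, got {len(genos)}")
    alleles = np.asarray([a for g in genos for a in g])
    if len(np.unique(alleles)) < 2:
        return TestResult(statistic=np.nan, p_value=1.0,
                          method="hwe-permutation (not testable)", testable=False)
    n = len(genos)
    h_obs = int(sum(a != b for a, b in genos))
    rng = np.random.default_rng(seed)
    hets = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(alleles)
        hets[i] = int(np.sum(perm[0::2] != perm[1::2]))
    freq = np.bincount(hets, minlength=n + 1).astype(float)
    freq_obs = freq[h_obs]
    # probability-ordering two-sided p, add-one smoothed
    extreme = freq[freq <= freq_obs].sum()
    p = (extreme + 1.0) / (n_permutations + 1.0)
    return TestResult(
        statistic=float(h_obs), p_value=min(p, 1.0), method="hwe-permutation"
    )


def ld_test(
    individuals,
    locus_pair: tuple[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Permutation test of genotypic association between two loci.

    The statistic is the Pearson chi-square of the genotype x genotype
    contingency table; the null distribution comes from shuffling one
    locus's genotypes across individuals. One-sided upper-tail p-value.
    """
    la, lb = locus_pair
    paired = [
        (ind.consensus[la], ind.consensus[lb])
        for ind in individuals
        if ind.consensus.get(la) is not None and ind.consensus.get(lb) is not None
    ]
    if len(paired) < 5:
        raise ValueError("need >= 5 individuals typed at both loci")
    ga = [g[0] for g in paired]
    gb = [g[1] for g in paired]
    if len(set(ga)) < 2 or len(set(gb)) < 2:
        return TestResult(statistic=np.nan, p_value=1.0,
                          method="ld-permutation (not testable)", testable=False)

    cat_a = pd.Categorical(ga).codes
    cat_b = pd.Categorical(gb).codes
    ka, kb = cat_a.max() + 1, cat_b.max() + 1

    def chi2_stat(codes_b: np.ndarray) -> float:
        table = np.zeros((ka, kb))
        np.add.at(table, (cat_a, codes_b), 1.0)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / table.sum()
        mask = expected > 0
        return float(((table - expected)[mask] ** 2 / expected[mask]).sum())

    obs = chi2_stat(cat_b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if chi2_stat(rng.permutation(cat_b)) >= obs - 1e-12:
            count += 1
    p = (count + 1.0) / (n_permutations + 1.0)
    return TestResult(statistic=obs, p_value=min(p, 1.0), method="ld-permutation")


def sequential_bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Holm step-down multiple-testing flags.

    Sort ascending; the i-th smallest (1-based) is compared against
    ``alpha / (m - i + 1)``; testing stops at the first failure. Returns
    significance flags in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            flags[idx] = True
        else:
            break
    return flags.tolist()
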