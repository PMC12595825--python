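"""Haplotype frequencies, Nei diversity with bootstrap CI, and the
distinct-haplogroup permutation test.

Nei's haplotype diversity for a sample of n haploid individuals with
haplotype relative frequencies p_i is

    HD = n/(n-1) * (1 - sum_i p_i^2),

the unbiased probability that two individuals drawn without replacement
carry different haplotypes. Confidence intervals come from a nonparametric
bootstrap over individuals (percentile method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import AnalysisView, MISSING_INT

__all__ = [
    "DiversityEstimate",
    "PermutationTestResult",
    "haplotype_frequencies",
    "nei_hd",
    "bootstrap_hd_ci",
    "distinct_hg_permutation_test",
]


@dataclass
class DiversityEstimate:
    n: int
    k: int
    hd: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    replicates: int = 0

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.hd <= 1 + 1e-12):
            raise ValueError(f"HD {self.hd} outside [0, 1]")
        if self.k > self.n:
            raise ValueError("distinct count exceeds sample size")


@dataclass
class PermutationTestResult:
    observed: int
    null_mean: float
    p_value: float
    permutations: int
    seed: int
    alternative: str = "two-sided"


def _row_keys(view: AnalysisView, indices: Sequence[int]) -> list[tuple]:
    """Haplotype identity keys: full allele vectors; a row containing a
    missing allele matches nothing, i.e. forms its own singleton class."""
    keys = []
    for i in indices:
        row = view.matrix[i]
        if (row == MISSING_INT).any():
            keys.append(("__missing__", view.sample_ids[i]))
        else:
            keys.append(tuple(int(a) for a in row))
    return keys


def haplotype_frequencies(
    view: AnalysisView, population: Optional[str] = None
) -> dict[tuple, int]:
    """Direct-count haplotype frequencies for one population (or all samples)."""
    idx = (
        view.population_indices(population)
        if population is not None
        else list(range(view.n))
    )
    if not idx:
        raise ValueError(f"no samples selected (population={population!r})")
    counts: dict[tuple, int] = {}
    for key in _row_keys(view, idx):
        counts[key] = counts.get(key, 0) + 1
    return counts


def nei_hd(counts: Mapping[tuple, int] | Sequence[int]) -> DiversityEstimate:
    """Nei's haplotype diversity from haplotype counts."""
    vals = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    n = sum(vals)
    if n < 2:
        raise ValueError("HD requires n >= 2")
    p = np.asarray(vals, dtype=float) / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    return DiversityEstimate(n=n, k=len(vals), hd=hd)


def bootstrap_hd_ci(
    view: AnalysisView,
    population: Optional[str] = None,
    replicates: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> DiversityEstimate:
    """Percentile bootstrap CI for HD, resampling individuals with replacement."""
    if replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    idx = (
        view.population_indices(population)
        if population is not None
        else list(range(view.n))
    )
    keys = _row_keys(view, idx)
    codes = np.asarray(
        [{k: c for c, k in enumerate(dict.fromkeys(keys))}[k] for k in keys]
    )
    n = len(codes)
    point = nei_hd(np.bincount(codes).tolist())
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n, size=(replicates, n))
    hds = np.empty(replicates)
    for b in range(replicates):
        counts = np.bincount(codes[draws[b]])
        p = counts[counts > 0] / n
        hds[b] = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    alpha = (1.0 - level) / 2
    lo, hi = np.quantile(hds, [alpha, 1 - alpha])
    return DiversityEstimate(
        n=n, k=point.k, hd=point.hd, ci_low=float(lo), ci_high=float(hi), replicates=replicates
    )


def distinct_hg_permutation_test(
    focal: Sequence[str],
    others: Sequence[str],
    permutations: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test for the number of distinct haplogroups in a focal sample.

    The statistic is the count of distinct labels among the focal
    individuals. The null resamples |focal| labels *without replacement*
    from the pooled focal+other label multiset (a rarefaction-style null
    that respects unequal sample sizes). Two-sided p-value with the (b+1)/(B+1)
    finite-sample correction, capped at 1.
    """
    focal = list(focal)
    others = list(others)
    if not focal:
        raise ValueError("focal sample is empty")
    pool = np.asarray(focal + others, dtype=object)
    if len(focal) > len(pool):
        raise ValueError("focal larger than pooled labels")
    if permutations < 100:
        raise ValueError("need at least 100 permutations")
    obs = len(set(focal))
    rng = np.random.default_rng(seed)
    null = np.empty(permutations, dtype=np.int64)
    for b in range(permutations):
        draw = rng.choice(pool, size=len(focal), replace=False)
        null[b] = len(set(draw.tolist()))
    p_ge = (int((null >= obs).sum()) + 1) / (permutations + 1)
    p_le = (int((null <= obs).sum()) + 1) / (permutations + 1)
    p = min(1.0, 2.0 * min(p_ge, p_le))
    return PermutationTestResult(
        observed=obs,
        null_mean=float(null.mean()),
        p_value=p,
        permutations=permutations,
        seed=seed,
    )
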