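"""Bayesian allele-frequency haplogroup prediction from Y-STR haplotypes.

Y-chromosome haplogroups are SNP-defined clades, but because STR allele
distributions differ between clades, a haplogroup can be predicted from an
STR haplotype alone. The predictor here is the naive-Bayes classifier of
that family: per-haplogroup, per-locus allele frequency tables give the
likelihood of a haplotype as the product of its allele frequencies over the
non-missing loci; combining with a prior yields a posterior over
haplogroups. A call is made only when the winning posterior clears a
probability threshold (0.85 by default, with equal priors).

Frequency tables are trained from labelled reference haplotypes with
additive smoothing, or loaded from TSV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, Dataset, ViewMode, make_view, MISSING_INT, AnalysisView

__all__ = [
    "NO_CALL",
    "AlleleFrequencyTable",
    "PredictionResult",
    "build_frequency_table",
    "predict",
    "predict_dataset",
    "write_frequency_table",
    "read_frequency_table",
]

NO_CALL = "NO_CALL"

#: Default smoothing mass added per allele of the support.
DEFAULT_PSEUDOCOUNT = 5e-4

#: Default posterior-probability threshold for making a call.
DEFAULT_THRESHOLD = 0.85


@dataclass
class AlleleFrequencyTable:
    """Per-(haplogroup, locus) allele frequency distributions.

    ``freq[haplogroup][locus]`` maps integer alleles to probabilities that
    sum to 1 over the smoothed support; every probability is positive after
    smoothing, so no single unseen allele can zero out a likelihood.
    """

    haplogroups: tuple[str, ...]
    loci: tuple[str, ...]
    freq: dict[str, dict[str, dict[int, float]]]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        for hg in self.haplogroups:
            for loc, dist in self.freq[hg].items():
                total = sum(dist.values())
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValueError(
                        f"frequencies for ({hg}, {loc}) sum to {total}, expected 1"
                    )
                if any(p <= 0 for p in dist.values()):
                    raise ValueError(f"non-positive probability in ({hg}, {loc})")

    def frequency(self, haplogroup: str, locus: str, allele: int) -> float:
        """Smoothed frequency; alleles outside the support get the floor mass."""
        dist = self.freq[haplogroup].get(locus)
        if dist is None:
            raise KeyError(f"locus {locus} not in table")
        if allele in dist:
            return dist[allele]
        return min(dist.values())  # off-support allele: smoothing floor


@dataclass
class PredictionResult:
    sample_id: str
    posterior: dict[str, float]
    fitness: dict[str, float]
    call: str
    threshold: float

    def __post_init__(self) -> None:
        total = sum(self.posterior.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"posterior sums to {total}")


def build_frequency_table(
    labelled: Dataset,
    haplogroup_of: Mapping[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> AlleleFrequencyTable:
    """Train an allele-frequency table from haplogroup-labelled references.

    Empirical counts per (haplogroup, locus) are smoothed additively over an
    allele support spanning the observed range at that locus ± 2 repeats:
    ``f(a) = (count(a) + c) / (n + c·|support|)``.
    """
    view = make_view(labelled, ViewMode.PREDICTION)
    hgs = sorted({haplogroup_of[s] for s in view.sample_ids})
    loci = view.effective_loci

    # shared support per locus: observed range across all haplogroups ± 2
    support: dict[str, list[int]] = {}
    for j, loc in enumerate(loci):
        col = view.matrix[:, j]
        obs = col[col != MISSING_INT]
        if obs.size:
            support[loc] = list(range(int(obs.min()) - 2, int(obs.max()) + 3))

    freq: dict[str, dict[str, dict[int, float]]] = {}
    for hg in hgs:
        rows = [i for i, s in enumerate(view.sample_ids) if haplogroup_of[s] == hg]
        per_locus: dict[str, dict[int, float]] = {}
        any_data = False
        for j, loc in enumerate(loci):
            if loc not in support:
                continue
            col = view.matrix[rows, j]
            obs = col[col != MISSING_INT]
            if pseudocount > 0:
                alleles = support[loc]
            else:  # no smoothing mass: support shrinks to observed alleles
                alleles = sorted(set(obs.tolist()))
                if not alleles:
                    continue
            counts = {a: int((obs == a).sum()) for a in alleles}
            n = int(obs.size)
            if n:
                any_data = True
            denom = n + pseudocount * len(counts)
            if denom == 0:
                continue  # no observations and no smoothing mass
            per_locus[loc] = {a: (c + pseudocount) / denom for a, c in counts.items()}
        if not any_data:
            raise ValueError(f"haplogroup {hg}: no non-missing alleles at any locus")
        freq[hg] = per_locus
    return AlleleFrequencyTable(
        haplogroups=tuple(hgs), loci=loci, freq=freq, pseudocount=pseudocount
    )


def predict(
    h: "Haplotype | Mapping[str, Optional[float]]",
    table: AlleleFrequencyTable,
    prior: Optional[Mapping[str, float]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    fitness_floor: float = -math.inf,
    sample_id: Optional[str] = None,
) -> PredictionResult:
    """Posterior haplogroup probabilities for one haplotype.

    ``posterior(g) ∝ prior(g) · Π_l f(allele_l | g, l)`` over the non-missing
    loci shared with the table; missing loci are skipped. ``fitness(g)`` is
    the mean log10 per-locus allele frequency, a goodness-of-fit score; the
    default floor of -inf disables the fitness filter (the reference
    predictor's "fitness 0" setting). A call is made iff the top posterior
    is ≥ ``threshold``, is not exactly tied, and clears the fitness floor.
    """
    alleles: Mapping[str, Optional[float]]
    if hasattr(h, "alleles"):
        alleles = h.alleles  # type: ignore[union-attr]
        sample_id = sample_id or h.sample_id  # type: ignore[union-attr]
    else:
        alleles = h
        sample_id = sample_id or "?"
    if fitness_floor == 0:
        # the reference tool's "fitness score 0" setting disables the filter
        fitness_floor = -math.inf

    hgs = table.haplogroups
    if prior is None:
        prior = {g: 1.0 / len(hgs) for g in hgs}
    if not math.isclose(sum(prior[g] for g in hgs), 1.0, abs_tol=1e-9):
        raise ValueError("prior must sum to 1")

    used_loci = [
        loc
        for loc in table.loci
        if alleles.get(loc) is not MISSING and any(loc in table.freq[g] for g in hgs)
    ]
    if not used_loci:
        warnings.warn(f"sample {sample_id}: no informative loci; returning prior")
        return PredictionResult(
            sample_id=sample_id,
            posterior={g: prior[g] for g in hgs},
            fitness={g: 0.0 for g in hgs},
            call=NO_CALL,
            threshold=threshold,
        )

    loglik = {}
    fitness = {}
    for g in hgs:
        logs = [
            math.log10(table.frequency(g, loc, int(alleles[loc])))
            for loc in used_loci
            if loc in table.freq[g]
        ]
        loglik[g] = sum(logs)
        fitness[g] = sum(logs) / len(logs)

    logpost = {g: math.log10(prior[g]) + loglik[g] if prior[g] > 0 else -math.inf for g in hgs}
    m = max(logpost.values())
    unnorm = {g: 10 ** (lp - m) if lp > -math.inf else 0.0 for g, lp in logpost.items()}
    z = sum(unnorm.values())
    posterior = {g: u / z for g, u in unnorm.items()}

    best = max(posterior, key=posterior.__getitem__)
    top = posterior[best]
    tied = sum(1 for p in posterior.values() if math.isclose(p, top, rel_tol=0, abs_tol=1e-12))
    call = NO_CALL
    if top >= threshold and tied == 1 and fitness[best] >= fitness_floor:
        call = best
    return PredictionResult(
        sample_id=sample_id, posterior=posterior, fitness=fitness, call=call, threshold=threshold
    )


def predict_dataset(
    ds: Dataset,
    table: AlleleFrequencyTable,
    prior: Optional[Mapping[str, float]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    fitness_floor: float = -math.inf,
) -> tuple[list[PredictionResult], pd.DataFrame, float]:
    """Predict every sample; summarise per-population haplogroup frequencies.

    Returns the per-sample results, a population × haplogroup relative-
    frequency table over *called* samples, and the overall NO_CALL rate.
    """
    results = [
        predict(h, table, prior=prior, threshold=threshold, fitness_floor=fitness_floor)
        for h in ds.haplotypes
    ]
    calls = pd.DataFrame(
        {
            "population": [h.population for h in ds.haplotypes],
            "call": [r.call for r in results],
        }
    )
    called = calls[calls["call"] != NO_CALL]
    if len(called):
        freq = (
            called.groupby("population")["call"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
    else:
        freq = pd.DataFrame()
    no_call_rate = 1.0 - len(called) / len(calls) if len(calls) else 0.0
    return results, freq, no_call_rate


def write_frequency_table(table: AlleleFrequencyTable, path: str | Path) -> None:
    rows = [
        (hg, loc, a, p)
        for hg in table.haplogroups
        for loc, dist in table.freq[hg].items()
        for a, p in sorted(dist.items())
    ]
    pd.DataFrame(rows, columns=["haplogroup", "locus", "allele", "frequency"]).to_csv(
        path, sep="\t", index=False
    )


def read_frequency_table(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> AlleleFrequencyTable:
    df = pd.read_csv(path, sep="\t")
    freq: dict[str, dict[str, dict[int, float]]] = {}
    for (hg, loc), grp in df.groupby(["haplogroup", "locus"]):
        freq.setdefault(str(hg), {})[str(loc)] = {
            int(a): float(p) for a, p in zip(grp["allele"], grp["frequency"])
        }
    hgs = tuple(sorted(freq))
    loci = tuple(sorted({loc for d in freq.values() for loc in d}))
    return AlleleFrequencyTable(haplogroups=hgs, loci=loci, freq=freq, pseudocount=pseudocount)
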