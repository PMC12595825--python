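"""Analysis of molecular variance (AMOVA) on squared-step distances.

Under the stepwise mutation model the molecular distance between two STR
haplotypes is the sum of squared repeat differences over loci. AMOVA
decomposes the total distance variance into hierarchical components using
the distance formulation: the sum of squares of a set of individuals is

    SS(set) = (1/|set|) * sum over unordered pairs in set of d_ij,

and variance components follow from the standard moment equations with
unequal-size coefficients. Phi statistics are ratios of variance
components; their null distributions come from label permutations.

The one-level two-population Phi_ST computed here *is* Slatkin's R_ST for
microsatellite data, which is why the pairwise-distance module delegates to
this code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import AnalysisView, MISSING_INT

__all__ = [
    "AmovaTable",
    "RegionalContrast",
    "squared_step_matrix",
    "one_level_components",
    "amova",
    "regional_contrast",
]


def squared_step_matrix(view: AnalysisView) -> np.ndarray:
    """Pairwise squared-step distance matrix with pairwise deletion.

    d_ij = sum over loci non-missing in both i and j of (a_il - a_jl)^2.
    Pairs sharing zero loci get NaN (flagged; callers decide how to handle).
    """
    X = view.matrix.astype(float)
    X[view.matrix == MISSING_INT] = np.nan
    n, L = X.shape
    D = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l in range(L):
        col = X[:, l]
        ok = ~np.isnan(col)
        both = np.outer(ok, ok)
        diff = np.subtract.outer(np.nan_to_num(col), np.nan_to_num(col))
        D += np.where(both, diff**2, 0.0)
        shared += both
    D[shared == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


def _pair_sum(D: np.ndarray, idx: Sequence[int]) -> float:
    sub = D[np.ix_(idx, idx)]
    return float(np.nansum(sub)) / 2.0


def one_level_components(
    D: np.ndarray, labels: Sequence[str]
) -> dict[str, float]:
    """One-level (populations) variance components from a distance matrix.

    Returns df, SS, sigma2 for among/within, Phi_ST, and the n0 coefficient.
    """
    labels = list(labels)
    N = len(labels)
    pops = list(dict.fromkeys(labels))
    P = len(pops)
    if P < 2:
        raise ValueError("need >= 2 populations")
    idx_of = {p: [i for i, l in enumerate(labels) if l == p] for p in pops}
    sizes = np.array([len(idx_of[p]) for p in pops], dtype=float)

    ss_total = _pair_sum(D, range(N)) / N
    ss_within = sum(_pair_sum(D, idx_of[p]) / len(idx_of[p]) for p in pops)
    ss_among = ss_total - ss_within

    df_among = P - 1
    df_within = N - P
    sigma_within = ss_within / df_within if df_within > 0 else np.nan
    n0 = (N - float(np.sum(sizes**2)) / N) / df_among
    ms_among = ss_among / df_among
    sigma_among = (ms_among - sigma_within) / n0
    total = sigma_among + sigma_within
    phi_st = sigma_among / total if total > 0 else np.nan
    return {
        "N": N,
        "P": P,
        "ss_total": ss_total,
        "ss_among": ss_among,
        "ss_within": ss_within,
        "df_among": df_among,
        "df_within": df_within,
        "sigma_among": sigma_among,
        "sigma_within": sigma_within,
        "phi_st": phi_st,
        "n0": n0,
    }


def _two_level_components(
    D: np.ndarray, pop_labels: Sequence[str], group_of: Mapping[str, str]
) -> dict[str, float]:
    """Nested (groups / populations / individuals) variance components."""
    labels = list(pop_labels)
    N = len(labels)
    pops = list(dict.fromkeys(labels))
    P = len(pops)
    groups = list(dict.fromkeys(group_of[p] for p in pops))
    G = len(groups)
    if G < 2:
        raise ValueError("nested design needs >= 2 groups")
    pop_idx = {p: [i for i, l in enumerate(labels) if l == p] for p in pops}
    grp_pops = {g: [p for p in pops if group_of[p] == g] for g in groups}
    for g, ps in grp_pops.items():
        if len(ps) < 2:
            warnings.warn(f"group {g!r} has a single population; Phi_SC weakly informed there")
    grp_idx = {g: [i for p in grp_pops[g] for i in pop_idx[p]] for g in groups}
    n_p = {p: len(pop_idx[p]) for p in pops}
    n_g = {g: len(grp_idx[g]) for g in groups}

    ss_total = _pair_sum(D, range(N)) / N
    ss_wp = sum(_pair_sum(D, pop_idx[p]) / n_p[p] for p in pops)
    ss_wg = sum(_pair_sum(D, grp_idx[g]) / n_g[g] for g in groups)
    ss_ap = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg  # among groups

    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag

    sum_npsq_by_g = {g: sum(n_p[p] ** 2 for p in grp_pops[g]) for g in groups}
    n1 = (N - sum(sum_npsq_by_g[g] / n_g[g] for g in groups)) / df_ap if df_ap > 0 else np.nan
    n2 = (
        sum(sum_npsq_by_g[g] / n_g[g] for g in groups)
        - sum(n_p[p] ** 2 for p in pops) / N
    ) / df_ag
    n3 = (N - sum(n_g[g] ** 2 for g in groups) / N) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1 if df_ap > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    return {
        "N": N,
        "P": P,
        "G": G,
        "ss_total": ss_total,
        "ss_ag": ss_ag,
        "ss_ap": ss_ap,
        "ss_wp": ss_wp,
        "df_ag": df_ag,
        "df_ap": df_ap,
        "df_wp": df_wp,
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "phi_st": (sigma_a + sigma_b) / total if total > 0 else np.nan,
        "phi_ct": sigma_a / total if total > 0 else np.nan,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else np.nan,
    }


def _percentages(components: Sequence[float]) -> list[float]:
    floored = [max(c, 0.0) for c in components]
    total = sum(floored)
    if total <= 0:
        return [float("nan")] * len(components)
    return [100.0 * c / total for c in floored]


@dataclass
class AmovaTable:
    """Hierarchical variance decomposition with Phi statistics and p-values."""

    design: str  # "POPS" or "GROUPS_POPS"
    rows: list[dict]
    phi: dict[str, float]
    pvalues: dict[str, float]
    permutations: int
    seed: int

    def __str__(self) -> str:
        lines = [f"AMOVA ({self.design}; {self.permutations} permutations, seed {self.seed})"]
        lines.append(f"{'source':<34}{'df':>6}{'SS':>12}{'sigma2':>12}{'%':>8}")
        for r in self.rows:
            lines.append(
                f"{r['source']:<34}{r['df']:>6}{r['ss']:>12.4f}{r['sigma2']:>12.4f}{r['percent']:>8.2f}"
            )
        for k, v in self.phi.items():
            p = self.pvalues.get(k)
            lines.append(f"{k} = {v:.4f}" + (f"  (p = {p:.4f})" if p is not None else ""))
        return "\n".join(lines)


def amova(
    view: AnalysisView,
    partition: Optional[Mapping[str, str]] = None,
    groups: Optional[Mapping[str, str]] = None,
    permutations: int = 10_000,
    seed: int = 0,
    D: Optional[np.ndarray] = None,
) -> AmovaTable:
    """AMOVA over populations, optionally nested within groups.

    ``partition`` maps sample_id → population (defaults to the view's
    population labels). With ``groups`` (population → group) the design is
    two-level and Phi_CT / Phi_SC are reported alongside Phi_ST. Negative
    variance components are reported as computed; they are floored at zero
    only when percentages are formed. Permutation schemes: Phi_ST permutes
    individuals among populations; Phi_CT permutes whole populations among
    groups; Phi_SC permutes individuals among populations within groups.
    """
    if partition is None:
        labels = list(view.populations)
    else:
        labels = [partition[s] for s in view.sample_ids]
    if D is None:
        D = squared_step_matrix(view)
    if np.isnan(D).any():
        raise ValueError("distance matrix has pairs with zero shared loci")
    rng = np.random.default_rng(seed)

    if groups is None:
        c = one_level_components(D, labels)
        pct = _percentages([c["sigma_among"], c["sigma_within"]])
        rows = [
            {"source": "Among populations", "df": c["df_among"], "ss": c["ss_among"],
             "sigma2": c["sigma_among"], "percent": pct[0]},
            {"source": "Within populations", "df": c["df_within"], "ss": c["ss_within"],
             "sigma2": c["sigma_within"], "percent": pct[1]},
        ]
        phi = {"Phi_ST": c["phi_st"]}
        pvals: dict[str, float] = {}
        if permutations > 0 and np.isfinite(c["phi_st"]):
            arr = np.asarray(labels, dtype=object)
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(arr)
                if one_level_components(D, perm)["phi_st"] >= c["phi_st"]:
                    count += 1
            pvals["Phi_ST"] = (count + 1) / (permutations + 1)
        return AmovaTable("POPS", rows, phi, pvals, permutations, seed)

    c = _two_level_components(D, labels, groups)
    pct = _percentages([c["sigma_a"], c["sigma_b"], c["sigma_c"]])
    rows = [
        {"source": "Among groups", "df": c["df_ag"], "ss": c["ss_ag"],
         "sigma2": c["sigma_a"], "percent": pct[0]},
        {"source": "Among populations within groups", "df": c["df_ap"], "ss": c["ss_ap"],
         "sigma2": c["sigma_b"], "percent": pct[1]},
        {"source": "Within populations", "df": c["df_wp"], "ss": c["ss_wp"],
         "sigma2": c["sigma_c"], "percent": pct[2]},
    ]
    phi = {"Phi_ST": c["phi_st"], "Phi_CT": c["phi_ct"], "Phi_SC": c["phi_sc"]}
    pvals = {}
    if permutations > 0:
        arr = np.asarray(labels, dtype=object)
        pops = list(dict.fromkeys(labels))
        # Phi_ST: individuals among populations (ignoring groups)
        if np.isfinite(c["phi_st"]):
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(arr)
                if _two_level_components(D, perm, groups)["phi_st"] >= c["phi_st"]:
                    count += 1
            pvals["Phi_ST"] = (count + 1) / (permutations + 1)
        # Phi_CT: whole populations among groups
        if np.isfinite(c["phi_ct"]):
            grp_names = [groups[p] for p in pops]
            count = 0
            for _ in range(permutations):
                shuffled = rng.permutation(np.asarray(grp_names, dtype=object))
                gmap = dict(zip(pops, shuffled))
                try:
                    stat = _two_level_components(D, labels, gmap)["phi_ct"]
                except ValueError:
                    continue
                if stat >= c["phi_ct"]:
                    count += 1
            pvals["Phi_CT"] = (count + 1) / (permutations + 1)
        # Phi_SC: individuals among populations within their group
        if np.isfinite(c["phi_sc"]):
            count = 0
            by_group: dict[str, list[int]] = {}
            for i, l in enumerate(labels):
                by_group.setdefault(groups[l], []).append(i)
            for _ in range(permutations):
                perm = np.asarray(labels, dtype=object).copy()
                for g, members in by_group.items():
                    sub = perm[members]
                    perm[members] = rng.permutation(sub)
                if _two_level_components(D, perm, groups)["phi_sc"] >= c["phi_sc"]:
                    count += 1
            pvals["Phi_SC"] = (count + 1) / (permutations + 1)
    return AmovaTable("GROUPS_POPS", rows, phi, pvals, permutations, seed)


@dataclass
class RegionalContrast:
    cohort_a: AmovaTable
    cohort_b: AmovaTable
    percent_a: float
    percent_b: float
    ratio: float


def regional_contrast(
    view: AnalysisView,
    partition_a: Mapping[str, str],
    partition_b: Mapping[str, str],
    permutations: int = 10_000,
    seed: int = 0,
    min_region_size: int = 2,
) -> RegionalContrast:
    """Contrast among-region differentiation between two cohorts.

    Each partition maps a cohort's sample_ids to regions from the
    five-region vocabulary. Runs a one-level AMOVA by region within each
    cohort and reports the ratio of among-region percentages (a / b).
    Regions with fewer than ``min_region_size`` samples are dropped with a
    warning.
    """
    tables = []
    pcts = []
    for k, part in enumerate((partition_a, partition_b)):
        sizes: dict[str, int] = {}
        for s, r in part.items():
            sizes[r] = sizes.get(r, 0) + 1
        keep_regions = {r for r, c in sizes.items() if c >= min_region_size}
        dropped = set(sizes) - keep_regions
        if dropped:
            warnings.warn(f"cohort {k}: dropping regions with <{min_region_size} samples: {sorted(dropped)}")
        idx = [
            i
            for i, s in enumerate(view.sample_ids)
            if s in part and part[s] in keep_regions
        ]
        if len({part[view.sample_ids[i]] for i in idx}) < 2:
            raise ValueError(f"cohort {k}: fewer than two usable regions")
        sub = view.subset(idx)
        partition = {s: part[s] for s in sub.sample_ids}
        t = amova(sub, partition=partition, permutations=permutations, seed=seed + k)
        tables.append(t)
        pcts.append(t.rows[0]["percent"])
    ratio = pcts[0] / pcts[1] if pcts[1] > 0 else float("inf")
    return RegionalContrast(tables[0], tables[1], pcts[0], pcts[1], ratio)
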