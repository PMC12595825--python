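"""Pairwise population differentiation for Y-STR data.

Slatkin's R_ST is the microsatellite analogue of F_ST: a Phi statistic on
squared repeat-count differences, appropriate under the stepwise mutation
model where allele sizes carry phylogenetic signal. Each population pair is
analysed as a two-population molecular-variance decomposition; significance
comes from permuting individuals between the two populations.

R_ST converts to an equilibrium island-model migrant number with the
haploid estimator M = (1 - R_ST) / (2 R_ST). Matrices embed into two
dimensions with nonmetric MDS (Kruskal stress-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .amova import one_level_components, squared_step_matrix
from .io import AnalysisView, MISSING_INT

__all__ = [
    "PairwiseMatrix",
    "smm_distance",
    "pairwise_rst",
    "migration_rate",
    "nmds_embed",
]


@dataclass
class PairwiseMatrix:
    """Labelled symmetric matrix of R_ST or M values with optional p-values."""

    labels: tuple[str, ...]
    values: np.ndarray
    statistic: str  # "RST" or "M"
    pvalues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("matrix not symmetric")
        if self.statistic == "RST" and not np.allclose(np.diag(v), 0):
            raise ValueError("RST diagonal must be 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if j <= i:
                    continue
                row = {"popA": a, "popB": b, self.statistic: self.values[i, j]}
                if self.pvalues is not None:
                    row["p"] = self.pvalues[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def smm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Squared-step distance between two haplotype rows (pairwise deletion).

    Loci missing in either haplotype are skipped; NaN if no locus is shared.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING_INT) & (b != MISSING_INT)
    if not ok.any():
        warnings.warn("haplotype pair shares no typed locus; distance undefined")
        return float("nan")
    d = a[ok].astype(float) - b[ok].astype(float)
    return float(np.sum(d**2))


def _phi_from_ss(ss_total: np.ndarray, ss_within: np.ndarray, N: int, n1: int, n2: int):
    """Vectorised two-population Phi_ST from sums of squares."""
    df_within = N - 2
    sigma_w = ss_within / df_within
    n0 = (N - (n1**2 + n2**2) / N) / 1.0
    ms_a = (ss_total - ss_within) / 1.0
    sigma_a = (ms_a - sigma_w) / n0
    total = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, sigma_a / total, np.nan)


def pairwise_rst(
    view: AnalysisView,
    populations: Optional[Sequence[str]] = None,
    permutations: int = 10_000,
    seed: int = 0,
    min_size: int = 2,
) -> PairwiseMatrix:
    """Pairwise Slatkin R_ST with permutation p-values.

    Each pair's R_ST is the Phi_ST of the two-population AMOVA on
    squared-step distances (shared code path with the AMOVA module, so the
    two agree exactly). The p-value is the proportion of >= observed values
    over random reassignments of individuals between the two populations,
    with the (b+1)/(B+1) correction. Populations below ``min_size`` are
    skipped with a warning (NaN entries).
    """
    if populations is None:
        populations = list(dict.fromkeys(view.populations))
    populations = list(populations)
    if len(populations) < 2:
        raise ValueError("need >= 2 populations")
    D = squared_step_matrix(view)
    if np.isnan(D).any():
        raise ValueError("distance matrix has pairs with zero shared loci")
    rng = np.random.default_rng(seed)
    k = len(populations)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    idx_of = {p: view.population_indices(p) for p in populations}
    for p in populations:
        if len(idx_of[p]) < min_size:
            warnings.warn(f"population {p!r} has n < {min_size}; its pairs are skipped")
    for i in range(k):
        for j in range(i + 1, k):
            ia, ib = idx_of[populations[i]], idx_of[populations[j]]
            if len(ia) < min_size or len(ib) < min_size:
                vals[i, j] = vals[j, i] = np.nan
                continue
            idx = ia + ib
            sub = D[np.ix_(idx, idx)]
            n1, n2 = len(ia), len(ib)
            N = n1 + n2
            labels = ["A"] * n1 + ["B"] * n2
            comp = one_level_components(sub, labels)
            obs = comp["phi_st"]
            vals[i, j] = vals[j, i] = obs
            if permutations > 0 and np.isfinite(obs):
                # batched permutations: boolean masks with exactly n1 members
                r = rng.random((permutations, N))
                part = np.argpartition(r, n1 - 1, axis=1)[:, :n1]
                mask = np.zeros((permutations, N), dtype=float)
                mask[np.arange(permutations)[:, None], part] = 1.0
                inv = 1.0 - mask
                s1 = np.einsum("bi,ij,bj->b", mask, sub, mask) / 2.0
                s2 = np.einsum("bi,ij,bj->b", inv, sub, inv) / 2.0
                ss_total = sub.sum() / 2.0 / N
                ss_within = s1 / n1 + s2 / n2
                phis = _phi_from_ss(ss_total, ss_within, N, n1, n2)
                count = int(np.sum(phis[np.isfinite(phis)] >= obs))
                p = (count + 1) / (permutations + 1)
                pvals[i, j] = pvals[j, i] = p
    return PairwiseMatrix(
        labels=tuple(populations),
        values=vals,
        statistic="RST",
        pvalues=pvals if permutations > 0 else None,
    )


def migration_rate(rst: PairwiseMatrix) -> PairwiseMatrix:
    """Haploid island-model migrant number M = (1 - R_ST) / (2 R_ST).

    Non-positive R_ST (no detectable differentiation) maps to +inf — kept
    as a sentinel rather than clamped, so "M > 40"-style regimes of near-
    panmictic pairs stay visible. R_ST = 1 maps to M = 0.
    """
    if rst.statistic != "RST":
        raise ValueError("input must be an RST matrix")
    R = rst.values
    M = np.full_like(R, np.nan)
    with np.errstate(divide="ignore"):
        pos = np.isfinite(R) & (R > 0)
        M[pos] = (1.0 - R[pos]) / (2.0 * R[pos])
        M[np.isfinite(R) & (R <= 0)] = np.inf
    np.fill_diagonal(M, np.inf)
    return PairwiseMatrix(labels=rst.labels, values=M, statistic="M")


def _stress1(embedded_d: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 via monotone (isotonic) regression of configuration
    distances on the input dissimilarity order."""
    order = np.argsort(dissim, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(embedded_d)
    dhat[order] = iso.fit_transform(np.arange(len(order)), embedded_d[order])
    denom = float(np.sum(embedded_d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((embedded_d - dhat) ** 2) / denom))


@dataclass
class NmdsResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k+1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def nmds_embed(
    mat: PairwiseMatrix,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> NmdsResult:
    """Nonmetric MDS embedding of a distance matrix (Kruskal stress-1).

    Negative entries are clamped to zero before embedding. The SMACOF
    optimiser runs from ``restarts`` seeded starts and keeps the best; the
    reported stress is Kruskal's stress-1 recomputed from the final
    configuration by isotonic regression, so a perfect rank-preserving
    embedding reports ~0.
    """
    if len(mat.labels) < 3:
        raise ValueError("need >= 3 labels to embed")
    Dm = np.array(mat.values, dtype=float)
    Dm[~np.isfinite(Dm)] = np.nan
    if np.isnan(Dm).any():
        raise ValueError("cannot embed a matrix with undefined entries")
    Dm = np.clip(Dm, 0.0, None)
    np.fill_diagonal(Dm, 0.0)
    if np.allclose(Dm, 0.0):
        return NmdsResult(
            labels=mat.labels,
            coordinates=np.zeros((len(mat.labels), dims)),
            stress=0.0,
            degenerate=True,
        )
    mds = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        n_init=restarts,
        init="random",
        random_state=seed,
        max_iter=max_iter,
        eps=eps,
        normalized_stress=True,
    )
    coords = mds.fit_transform(Dm)
    iu = np.triu_indices(len(mat.labels), k=1)
    emb_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    stress = _stress1(emb_d, Dm[iu])
    return NmdsResult(labels=mat.labels, coordinates=coords, stress=stress)
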