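"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as literal enumeration over pairs/subsets so it
shares no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def squared_step_oracle(a, b):
    """Literal squared-step distance between two complete haplotypes."""
    return sum((x - y) ** 2 for x, y in zip(a, b))


def amova_one_level_oracle(X, labels):
    """One-level AMOVA components from explicitly enumerated pair sums.

    Solves the moment equations directly: E[MS_within] = s_w,
    E[MS_among] = s_w + n0 * s_a.
    """
    X = np.asarray(X)
    n = len(labels)
    pops = sorted(set(labels))

    def pair_sum(indices):
        tot = 0.0
        for i, j in itertools.combinations(indices, 2):
            tot += squared_step_oracle(X[i], X[j])
        return tot

    ss_total = pair_sum(range(n)) / n
    ss_within = 0.0
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        ss_within += pair_sum(idx) / len(idx)
    ss_among = ss_total - ss_within

    sizes = [sum(1 for l in labels if l == p) for p in pops]
    df_a, df_w = len(pops) - 1, n - len(pops)
    s_w = ss_within / df_w
    n0 = (n - sum(s * s for s in sizes) / n) / df_a
    s_a = (ss_among / df_a - s_w) / n0
    phi = s_a / (s_a + s_w) if (s_a + s_w) > 0 else float("nan")
    return {
        "ss_total": ss_total,
        "ss_among": ss_among,
        "ss_within": ss_within,
        "sigma_among": s_a,
        "sigma_within": s_w,
        "phi_st": phi,
    }


def mst_cost_oracle(vectors, weights):
    """Prim's algorithm written out longhand over weighted step distances."""
    vecs = list(vectors)
    if len(vecs) < 2:
        return 0.0
    def d(u, v):
        return sum(w * abs(x - y) for w, x, y in zip(weights, u, v))
    in_tree = {0}
    cost = 0.0
    while len(in_tree) < len(vecs):
        best = None
        for i in in_tree:
            for j in range(len(vecs)):
                if j not in in_tree:
                    dd = d(vecs[i], vecs[j])
                    if best is None or dd < best[0]:
                        best = (dd, j)
        cost += best[0]
        in_tree.add(best[1])
    return cost


def steiner_oracle(observed, weights, max_extra=2):
    """Exhaustive Steiner search: best MST cost over observed plus up to
    ``max_extra`` candidate nodes drawn from the allele bounding box."""
    obs = [tuple(v) for v in observed]
    lo = [min(v[j] for v in obs) for j in range(len(obs[0]))]
    hi = [max(v[j] for v in obs) for j in range(len(obs[0]))]
    box = [tuple(p) for p in itertools.product(*[range(l, h + 1) for l, h in zip(lo, hi)])]
    candidates = [p for p in box if p not in set(obs)]
    best = mst_cost_oracle(obs, weights)
    for r in range(1, max_extra + 1):
        for extra in itertools.combinations(candidates, r):
            c = mst_cost_oracle(obs + list(extra), weights)
            if c < best:
                best = c
    return best


def distinct_count_null_oracle(focal_n, pool):
    """Exact null distribution of the distinct-label count when drawing
    focal_n labels without replacement from the pool, by full enumeration."""
    from collections import Counter

    dist = Counter()
    total = 0
    for combo in itertools.combinations(range(len(pool)), focal_n):
        dist[len({pool[i] for i in combo})] += 1
        total += 1
    return {k: v / total for k, v in dist.items()}
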