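"""Independent reference implementations used only by the tests.

These deliberately avoid the package's code paths: the matcher enumerates all
gated partial matchings recursively, and the count-split test enumerates the
conditional distribution with plain ``math.lgamma`` arithmetic.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_match(pos_a, pos_b, gate: float):
    """Minimize sum(pair distances) + gate * (#unmatched) by full enumeration.

    Links are allowed only within the gate.  Returns (min_cost, cardinality)
    where cardinality is the largest link count among cost-optimal matchings.
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    na = 0 if pos_a.size == 0 else len(pos_a)
    nb = 0 if pos_b.size == 0 else len(pos_b)
    dist = np.array(
        [[math.dist(pos_a[i], pos_b[j]) for j in range(nb)] for i in range(na)]
    ) if na and nb else np.zeros((na, nb))

    best = {"cost": math.inf, "card": 0}

    def rec(i, used_b, cost, links):
        if cost >= best["cost"] + 1e-12:
            return
        if i == na:
            total = cost + gate * (nb - links)
            if total < best["cost"] - 1e-12:
                best["cost"], best["card"] = total, links
            elif abs(total - best["cost"]) <= 1e-12:
                best["card"] = max(best["card"], links)
            return
        rec(i + 1, used_b, cost + gate, links)  # leave a_i unmatched
        for j in range(nb):
            if not used_b & (1 << j) and dist[i, j] <= gate:
                rec(i + 1, used_b | (1 << j), cost + dist[i, j], links + 1)

    rec(0, 0, 0.0, 0)
    return best["cost"], best["card"]


def _log_nb_pmf(k: int, mean: float, dispersion: float) -> float:
    if dispersion == 0:
        return k * math.log(mean) - mean - math.lgamma(k + 1)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log1p(-p)
    )


def exact_test_oracle(
    ya: int, yb: int, dispersion: float, n_a: int = 1, n_b: int = 1
) -> float:
    """Enumerate the conditional split distribution and sum the <=-observed tail."""
    total = ya + yb
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    weights = []
    for y in range(total + 1):
        lw = _log_nb_pmf(y, n_a * mu, dispersion / n_a) + _log_nb_pmf(
            total - y, n_b * mu, dispersion / n_b
        )
        weights.append(math.exp(lw))
    norm = sum(weights)
    obs = weights[ya]
    tail = sum(w for w in weights if w <= obs * (1 + 1e-8))
    return min(1.0, tail / norm)


def bh_oracle(pvals):
    """Step-up BH by the textbook formula, a loop per index."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj
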