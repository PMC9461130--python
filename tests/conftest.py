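"""Shared fixtures and independent brute-force oracles used across the suite."""

from __future__ import annotations

import math
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from mdgnet import simulate as sim


@pytest.fixture(scope="session")
def toy_map():
    """5 chromosomes x 100 cM, markers every 2 cM (the demo genome)."""
    return sim.MapSpec.uniform(5, 100.0, 2.0)


@pytest.fixture(scope="session")
def ril_398(toy_map):
    """One 398-line RIL cohort reused by mapping tests (seeded)."""
    return sim.simulate_ril_population(toy_map, 398, 171, seed=11)


@pytest.fixture(scope="session")
def ril_2000(toy_map):
    return sim.simulate_ril_population(toy_map, 2000, 1000, seed=12)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_cycles(G: nx.Graph, min_len: int = 3, max_len: int = 5) -> set:
    """All simple cycles of bounded length by exhaustive arrangement checking."""
    nodes = list(G.nodes)
    found = set()
    for k in range(min_len, max_len + 1):
        for subset in combinations(nodes, k):
            first = subset[0]
            for rest in permutations(subset[1:]):
                cyc = (first,) + rest
                if all(G.has_edge(cyc[i], cyc[(i + 1) % k]) for i in range(k)):
                    found.add(canonical(cyc))
    return found


def canonical(cycle) -> tuple:
    nodes = list(cycle)
    n = len(nodes)
    best = None
    for seq in (nodes, nodes[::-1]):
        for s in range(n):
            rot = tuple(seq[(s + i) % n] for i in range(n))
            if best is None or rot < best:
                best = rot
    return best


def brute_force_maximal_cliques(G: nx.Graph) -> list:
    """Maximal cliques by subset enumeration (exponential; tiny graphs only)."""
    nodes = list(G.nodes)
    cliques = []
    for k in range(1, len(nodes) + 1):
        for subset in combinations(nodes, k):
            if all(G.has_edge(a, b) for a, b in combinations(subset, 2)):
                cliques.append(set(subset))
    return [c for c in cliques
            if not any(c < d for d in cliques)]


def brute_force_mcc(G: nx.Graph) -> dict:
    scores = {v: 0.0 for v in G.nodes}
    for c in brute_force_maximal_cliques(G):
        if len(c) < 2:
            continue
        for v in c:
            scores[v] += math.factorial(len(c) - 1)
    return scores


def brute_force_interval_closure(intervals: list) -> list:
    """Transitive closure of pairwise interval overlap; returns index groups."""
    n = len(intervals)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            (l1, r1), (l2, r2) = intervals[i], intervals[j]
            if l1 <= r2 and l2 <= r1:
                adj[i].add(j)
                adj[j].add(i)
    seen, groups = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        groups.append(frozenset(comp))
    return groups


def grid_refine_minimize(fun, lo=-6.0, hi=6.0, coarse=4001):
    """1-D minimization: coarse grid then golden-section refinement."""
    from scipy.optimize import minimize_scalar

    xs = np.linspace(lo, hi, coarse)
    vals = [fun(x) for x in xs]
    k = int(np.argmin(vals))
    a, b = xs[max(k - 1, 0)], xs[min(k + 1, coarse - 1)]
    res = minimize_scalar(fun, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
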