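"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for transparency, not speed: exhaustive loops over
pairs, arcs, simple paths and permutations.  None of it shares code with the
package under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Freeman betweenness by exhaustive enumeration of all shortest paths."""
    n = a.shape[0]
    nbrs = [[j for j in range(n) if a[i, j]] for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best: int | None = None
            shortest: list[list[int]] = []
            stack = [(s, [s])]
            while stack:
                node, path = stack.pop()
                if node == t:
                    length = len(path) - 1
                    if best is None or length < best:
                        best, shortest = length, [path]
                    elif length == best:
                        shortest.append(path)
                    continue
                if best is not None and len(path) - 1 >= best:
                    continue
                for nb in nbrs[node]:
                    if nb not in path:
                        stack.append((nb, path + [nb]))
            if not shortest:
                continue
            total = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / total
    return bc


def dyad_census(a: np.ndarray) -> tuple[int, int, int]:
    """(mutual, asymmetric, null) dyad counts by pair scan."""
    n = a.shape[0]
    mutual = asym = null = 0
    for i in range(n):
        for j in range(i + 1, n):
            forward, back = a[i, j], a[j, i]
            if forward and back:
                mutual += 1
            elif forward or back:
                asym += 1
            else:
                null += 1
    return mutual, asym, null


def brute_reciprocity(a: np.ndarray, method: str) -> float:
    mutual, asym, _ = dyad_census(a)
    if method == "dyad":
        return mutual / (mutual + asym)
    arcs = int(a.sum())
    return 2 * mutual / arcs


def brute_total_degree(a: np.ndarray) -> np.ndarray:
    """Union degree: distinct alters with an arc in either direction."""
    n = a.shape[0]
    out = np.zeros(n, dtype=int)
    for i in range(n):
        out[i] = sum(
            1 for j in range(n) if j != i and (a[i, j] or a[j, i])
        )
    return out


def brute_block_density(a: np.ndarray, sectors: list[str], levels) -> np.ndarray:
    """Union-tie density per sector block by exhaustive pair counting."""
    k = len(levels)
    n = a.shape[0]
    values = np.full((k, k), np.nan)
    for gi, g in enumerate(levels):
        ig = [i for i in range(n) if sectors[i] == g]
        for hi, h in enumerate(levels):
            ih = [i for i in range(n) if sectors[i] == h]
            if gi == hi:
                pairs = list(itertools.combinations(ig, 2))
            else:
                pairs = [(i, j) for i in ig for j in ih]
            if not pairs:
                continue
            tied = sum(1 for i, j in pairs if a[i, j] or a[j, i])
            values[gi, hi] = tied / len(pairs)
    return values


def brute_block_reciprocity(
    a: np.ndarray, sectors: list[str], levels
) -> np.ndarray:
    """Reciprocated share of arcs from each reporting block, arc by arc."""
    k = len(levels)
    n = a.shape[0]
    values = np.full((k, k), np.nan)
    for gi, g in enumerate(levels):
        for hi, h in enumerate(levels):
            arcs = recip = 0
            for i in range(n):
                if sectors[i] != g:
                    continue
                for j in range(n):
                    if i == j or sectors[j] != h or not a[i, j]:
                        continue
                    arcs += 1
                    recip += int(a[j, i])
            if arcs:
                values[gi, hi] = recip / arcs
    return values


def brute_member_stats(a: np.ndarray, sectors: list[str]) -> dict[str, np.ndarray]:
    n = a.shape[0]
    inter_out = np.zeros(n, dtype=int)
    intra_out = np.zeros(n, dtype=int)
    inter_rec = np.full(n, np.nan)
    intra_rec = np.full(n, np.nan)
    for i in range(n):
        inter = [j for j in range(n) if j != i and a[i, j] and sectors[j] != sectors[i]]
        intra = [j for j in range(n) if j != i and a[i, j] and sectors[j] == sectors[i]]
        inter_out[i], intra_out[i] = len(inter), len(intra)
        if inter:
            inter_rec[i] = sum(a[j, i] for j in inter) / len(inter)
        if intra:
            intra_rec[i] = sum(a[j, i] for j in intra) / len(intra)
    return {
        "intersectoral_out_degree": inter_out,
        "intrasectoral_out_degree": intra_out,
        "intersectoral_reciprocity": inter_rec,
        "intrasectoral_reciprocity": intra_rec,
    }


def normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients by explicitly solving X'X b = X'y."""
    X = np.asarray(X, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def exact_perm_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p per coefficient over all n! re-orderings of y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    observed = np.abs(normal_equations(X, y))
    count = np.zeros(X.shape[1])
    total = 0
    for perm in itertools.permutations(range(n)):
        beta = normal_equations(X, y[list(perm)])
        count += np.abs(beta) >= observed - 1e-12
        total += 1
    return count / total
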