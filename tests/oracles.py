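"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles with a
different algorithmic formulation than the package code paths it checks:
explicit loops, exhaustive enumeration and direct definitions.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Kabsch-Sander 3-state secondary structure
# ---------------------------------------------------------------------------

Q_FACTOR = 0.084 * 332.0
E_CUT = -0.5


def ks_hbond_set(backbones: list[dict | None], prolines: set[int]) -> set[tuple[int, int]]:
    """(donor, acceptor) pairs with Kabsch-Sander energy < -0.5 kcal/mol.

    `backbones[i]` holds N/CA/C/O coordinates (or None when incomplete);
    the amide H of residue i sits 1 A from N along C(i-1)->O(i-1) reversed.
    """
    bonds = set()
    n = len(backbones)
    for don in range(n):
        if backbones[don] is None or don == 0 or don in prolines:
            continue
        prev = backbones[don - 1]
        if prev is None:
            continue
        co = np.asarray(prev["C"]) - np.asarray(prev["O"])
        norm = np.linalg.norm(co)
        if norm < 1e-9:
            continue
        h = np.asarray(backbones[don]["N"]) + co / norm
        n_at = np.asarray(backbones[don]["N"])
        for acc in range(n):
            if abs(don - acc) < 2 or backbones[acc] is None:
                continue
            c_at = np.asarray(backbones[acc]["C"])
            o_at = np.asarray(backbones[acc]["O"])
            d_on = math.dist(o_at, n_at)
            d_ch = math.dist(c_at, h)
            d_oh = math.dist(o_at, h)
            d_cn = math.dist(c_at, n_at)
            if min(d_on, d_ch, d_oh, d_cn) < 0.5:
                continue
            e = Q_FACTOR * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            if e < E_CUT:
                bonds.add((don, acc))
    return bonds


def ks_assign(backbones: list[dict | None], prolines: set[int] | None = None) -> list[str]:
    """3-state assignment: helix from two consecutive i->i+4 bonds, strand
    from parallel/antiparallel bridges, else coil."""
    n = len(backbones)
    if n < 5:
        return ["C"] * n
    bonds = ks_hbond_set(backbones, prolines or set())

    def hb(d: int, a: int) -> bool:
        return (d, a) in bonds

    labels = ["C"] * n
    for i in range(n):
        for j in range(i + 3, n):
            anti = (hb(i, j) and hb(j, i)) or (hb(j + 1, i - 1) and hb(i + 1, j - 1))
            para = (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i))
            if anti or para:
                labels[i] = "E"
                labels[j] = "E"
    turn = [hb(i + 4, i) for i in range(n)]
    for i in range(n - 1):
        if turn[i] and turn[i + 1]:
            for k in range(i + 1, min(i + 5, n)):
                labels[k] = "H"
    return labels


# ---------------------------------------------------------------------------
# Graph centralities (adjacency-matrix formulations)
# ---------------------------------------------------------------------------

def brute_centralities(n_nodes: int, edges: list[tuple[int, int]]) -> dict[str, np.ndarray]:
    """Degree, clustering, closeness, betweenness by direct definition.

    Shortest paths via Floyd-Warshall; path counts by dynamic programming on
    the distance matrix; betweenness normalized by (n-1)(n-2)/2.
    """
    inf = float("inf")
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for u, v in edges:
        adj[u, v] = adj[v, u] = True
    deg = adj.sum(axis=1).astype(float)

    clustering = np.zeros(n_nodes)
    for v in range(n_nodes):
        nbrs = np.where(adj[v])[0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:])
        clustering[v] = 2.0 * links / (k * (k - 1))

    dist = np.full((n_nodes, n_nodes), inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj] = 1.0
    for k in range(n_nodes):
        for i in range(n_nodes):
            for j in range(n_nodes):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]

    closeness = np.zeros(n_nodes)
    for v in range(n_nodes):
        comp = [u for u in range(n_nodes) if dist[v, u] < inf]
        tot = sum(dist[v, u] for u in comp if u != v)
        if tot > 0:
            closeness[v] = (len(comp) - 1) / tot

    # sigma[s, t]: number of shortest s-t paths, by DP in distance order
    sigma = np.zeros((n_nodes, n_nodes))
    for s in range(n_nodes):
        sigma[s, s] = 1.0
        reachable = [t for t in range(n_nodes) if dist[s, t] < inf]
        for t in sorted(reachable, key=lambda t: dist[s, t]):
            if t == s:
                continue
            sigma[s, t] = sum(sigma[s, p] for p in range(n_nodes)
                              if adj[p, t] and dist[s, p] + 1 == dist[s, t])

    betweenness = np.zeros(n_nodes)
    for v in range(n_nodes):
        acc = 0.0
        for s in range(n_nodes):
            for t in range(s + 1, n_nodes):
                if v in (s, t) or dist[s, t] == inf or sigma[s, t] == 0:
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    acc += sigma[s, v] * sigma[v, t] / sigma[s, t]
        betweenness[v] = acc
    if n_nodes > 2:
        betweenness /= (n_nodes - 1) * (n_nodes - 2) / 2.0
    return {"degree": deg, "clustering": clustering,
            "closeness": closeness, "betweenness": betweenness}


# ---------------------------------------------------------------------------
# Global alignment by exhaustive enumeration (affine gaps)
# ---------------------------------------------------------------------------

def brute_global_alignment_score(a: str, b: str, score: dict[tuple[str, str], float],
                                 gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score by enumerating every alignment.

    A gap run of length L costs gap_open + gap_extend * (L - 1), matching
    the package's convention.  Feasible only for short sequences.
    """
    best = -math.inf

    def rec(i: int, j: int, acc: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, acc)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + score[(a[i], b[j])], "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last == "A" else gap_open
            rec(i + 1, j, acc - cost, "A")
        if j < len(b):  # gap in a
            cost = gap_extend if last == "B" else gap_open
            rec(i, j + 1, acc - cost, "B")

    rec(0, 0, 0.0, "M")
    return best


# ---------------------------------------------------------------------------
# Kendall tau by explicit pair enumeration
# ---------------------------------------------------------------------------

def brute_kendall(x, y) -> float:
    n = len(x)
    cp = dp = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = x[i] - x[j]
            sy = y[i] - y[j]
            if sx * sy > 0:
                cp += 1
            elif sx * sy < 0:
                dp += 1
    return (cp - dp) / (0.5 * n * (n - 1))


# ---------------------------------------------------------------------------
# Accessible surface area by seeded random-direction sampling
# ---------------------------------------------------------------------------

_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


def sampled_asa(coords: np.ndarray, elements: list[str], probe: float = 1.4,
                n_dirs: int = 400, seed: int = 0) -> np.ndarray:
    """Per-atom ASA from uniformly sampled sphere directions (Monte Carlo)."""
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_dirs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.array([_RADII.get(e, 1.7) for e in elements]) + probe
    out = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * dirs
        free = np.ones(n_dirs, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - cj, axis=1) >= rj
        out[i] = 4.0 * math.pi * r * r * free.mean()
    return out
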