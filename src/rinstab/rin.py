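"""Residue interaction networks (RINs) from protein structures.

Nodes are residues; a generic inter-atomic contact (IAC) edge connects any
residue pair whose closest heavy atoms lie within 5 A (sequence separation
>= 2), and additional typed edges fire on standard geometric rules:
hydrogen bond (N/O pairs <= 3.5 A), salt bridge (charged-group atoms of
Arg/Lys/His vs Asp/Glu <= 4.0 A), pi-pi stacking (aromatic ring centroids
<= 6.5 A) and pi-cation (ring centroid to Lys NZ / Arg CZ <= 6.0 A).  A
residue pair may carry several edge types.

Node topology (degree, clustering coefficient, closeness, betweenness) is
evaluated on six subnetworks — one per bond type plus the union — all on
the full node set.  Isolated nodes take closeness and betweenness 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from ._aa import (
    AA_INDEX,
    AROMATIC_RING_ATOMS,
    CATION_ATOMS,
    NEGATIVE_GROUP_ATOMS,
    POSITIVE_GROUP_ATOMS,
)
from .structure_io import Structure

__all__ = [
    "EDGE_TYPES",
    "RINEdge",
    "RIN",
    "build_rin",
    "subnetworks",
    "node_centralities",
    "centralities_by_subnetwork",
    "neighbor_composition",
    "write_tables",
]

EDGE_TYPES = ("HBOND", "IAC", "PIPISTACK", "PICATION", "IONIC")
MEASURES = ("degree", "clustering", "closeness", "betweenness")

NodeKey = tuple[str, str]


@dataclass(frozen=True)
class RINEdge:
    u: NodeKey
    v: NodeKey
    etype: str
    distance: float
    atoms: tuple[str, str]


@dataclass
class RIN:
    nodes: dict[NodeKey, str]  # residue key -> three-letter aa
    edges: list[RINEdge] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.nodes)

    def graph(self) -> nx.Graph:
        """Simple undirected graph on the full node set (multi-typed pairs
        collapse to a single edge)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if not g.has_edge(e.u, e.v):
                g.add_edge(e.u, e.v, etypes=[e.etype], distance=e.distance)
            else:
                g[e.u][e.v]["etypes"].append(e.etype)
        return g


def _group_coords(res, names: tuple[str, ...]) -> np.ndarray | None:
    coords = [a.coord for a in res.atoms if a.name in names]
    return np.array(coords) if coords else None


def _ring_centroid(res) -> np.ndarray | None:
    if res.aa not in AROMATIC_RING_ATOMS:
        return None
    coords = _group_coords(res, AROMATIC_RING_ATOMS[res.aa])
    if coords is None or len(coords) < 3:
        return None
    return coords.mean(axis=0)


def build_rin(
    s: Structure,
    contact_cutoff: float = 5.0,
    min_seq_sep: int = 2,
    hbond_cutoff: float = 3.5,
    ionic_cutoff: float = 4.0,
    pipi_cutoff: float = 6.5,
    pication_cutoff: float = 6.0,
) -> RIN:
    """Build the typed residue interaction network of a single chain."""
    for name, value in (("contact_cutoff", contact_cutoff), ("hbond_cutoff", hbond_cutoff),
                        ("ionic_cutoff", ionic_cutoff), ("pipi_cutoff", pipi_cutoff),
                        ("pication_cutoff", pication_cutoff)):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if s.length < 2:
        raise ValueError("empty structure: need at least 2 residues to build a RIN")

    residues = s.residues
    nodes = {r.key: r.aa for r in residues}
    edges: list[RINEdge] = []

    heavy = [r.heavy_atoms() for r in residues]
    heavy_coords = [np.array([a.coord for a in atoms]) for atoms in heavy]
    centroids = [_ring_centroid(r) for r in residues]
    reach = max(contact_cutoff, hbond_cutoff, ionic_cutoff, pipi_cutoff, pication_cutoff)

    n = len(residues)
    for i in range(n):
        for j in range(i + min_seq_sep, n):
            if j - i < min_seq_sep:
                continue
            ri, rj = residues[i], residues[j]
            # coarse gate on CA (or first atom) distance
            anchor_i = heavy_coords[i].mean(axis=0)
            anchor_j = heavy_coords[j].mean(axis=0)
            if np.linalg.norm(anchor_i - anchor_j) > reach + 12.0:
                continue
            d = cdist(heavy_coords[i], heavy_coords[j])
            ai, aj = np.unravel_index(np.argmin(d), d.shape)
            dmin = float(d[ai, aj])
            if dmin <= contact_cutoff:
                edges.append(RINEdge(ri.key, rj.key, "IAC", dmin,
                                     (heavy[i][ai].name, heavy[j][aj].name)))
            # hydrogen bond: closest N/O pair
            no_i = [a for a in heavy[i] if a.element in ("N", "O")]
            no_j = [a for a in heavy[j] if a.element in ("N", "O")]
            if no_i and no_j and dmin <= hbond_cutoff + 8.0:
                dno = cdist(np.array([a.coord for a in no_i]), np.array([a.coord for a in no_j]))
                bi, bj = np.unravel_index(np.argmin(dno), dno.shape)
                if dno[bi, bj] <= hbond_cutoff:
                    edges.append(RINEdge(ri.key, rj.key, "HBOND", float(dno[bi, bj]),
                                         (no_i[bi].name, no_j[bj].name)))
            # salt bridge between charged groups
            for ra, rb in ((ri, rj), (rj, ri)):
                if ra.aa in POSITIVE_GROUP_ATOMS and rb.aa in NEGATIVE_GROUP_ATOMS:
                    pos = _group_coords(ra, POSITIVE_GROUP_ATOMS[ra.aa])
                    neg = _group_coords(rb, NEGATIVE_GROUP_ATOMS[rb.aa])
                    if pos is not None and neg is not None:
                        dd = cdist(pos, neg)
                        if dd.min() <= ionic_cutoff:
                            edges.append(RINEdge(ri.key, rj.key, "IONIC", float(dd.min()),
                                                 ("charged_group", "charged_group")))
                    break
            # pi-pi stacking between ring centroids
            if centroids[i] is not None and centroids[j] is not None:
                dc = float(np.linalg.norm(centroids[i] - centroids[j]))
                if dc <= pipi_cutoff:
                    edges.append(RINEdge(ri.key, rj.key, "PIPISTACK", dc,
                                         ("ring_centroid", "ring_centroid")))
            # pi-cation: ring centroid vs cationic atom
            for (ra, ca), (rb, cb) in (((ri, centroids[i]), (rj, centroids[j])),
                                       ((rj, centroids[j]), (ri, centroids[i]))):
                if ca is not None and rb.aa in CATION_ATOMS:
                    cat = _group_coords(rb, CATION_ATOMS[rb.aa])
                    if cat is not None:
                        dd = cdist(ca[None, :], cat)
                        if dd.min() <= pication_cutoff:
                            edges.append(RINEdge(ri.key, rj.key, "PICATION", float(dd.min()),
                                                 ("ring_centroid", CATION_ATOMS[rb.aa][0])))

    # de-duplicate (u, v, etype)
    seen: set[tuple] = set()
    unique_edges = []
    for e in edges:
        sig = (e.u, e.v, e.etype)
        if sig not in seen:
            seen.add(sig)
            unique_edges.append(e)
    return RIN(nodes, unique_edges)


def subnetworks(rin: RIN) -> dict[str, RIN]:
    """One RIN per edge type plus the ALL union, all on the full node set."""
    out = {etype: RIN(dict(rin.nodes), [e for e in rin.edges if e.etype == etype])
           for etype in EDGE_TYPES}
    out["ALL"] = RIN(dict(rin.nodes), list(rin.edges))
    return out


def _centrality_dicts(g: nx.Graph) -> dict[str, dict]:
    return {
        "degree": dict(g.degree()),
        "clustering": nx.clustering(g),
        "closeness": nx.closeness_centrality(g, wf_improved=False),
        "betweenness": nx.betweenness_centrality(g, normalized=True),
    }


def node_centralities(g: RIN, node: NodeKey) -> dict[str, float]:
    """Degree, clustering, closeness and betweenness of one node."""
    if node not in g.nodes:
        raise KeyError(f"unknown node {node}")
    tables = _centrality_dicts(g.graph())
    return {m: float(tables[m][node]) for m in MEASURES}


def centralities_by_subnetwork(rin: RIN) -> dict[str, dict[NodeKey, dict[str, float]]]:
    """All-node centralities for all six subnetworks in one pass."""
    out: dict[str, dict[NodeKey, dict[str, float]]] = {}
    for name, sub in subnetworks(rin).items():
        tables = _centrality_dicts(sub.graph())
        out[name] = {node: {m: float(tables[m][node]) for m in MEASURES}
                     for node in sub.nodes}
    return out


def neighbor_composition(rin: RIN, node: NodeKey) -> tuple[np.ndarray, int]:
    """Counts of contacting residues by amino-acid type, plus network size.

    A neighbor is counted once regardless of how many edge types connect it.
    """
    if node not in rin.nodes:
        raise KeyError(f"unknown node {node}")
    neighbors = set()
    for e in rin.edges:
        if e.u == node:
            neighbors.add(e.v)
        elif e.v == node:
            neighbors.add(e.u)
    counts = np.zeros(20)
    for nb in neighbors:
        counts[AA_INDEX[rin.nodes[nb]]] += 1
    return counts, rin.size


def write_tables(s: Structure, rin: RIN, out_dir: str | Path) -> dict[str, Path]:
    """Write nodes.tsv / edges.tsv / residues.tsv for network viewers."""
    import pandas as pd

    from .structure_io import residue_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cents = centralities_by_subnetwork(rin)
    node_rows = []
    for res in s.residues:
        row = {"id": f"{res.chain}:{res.seq_id}", "aa": res.aa, "ss": res.ss, "rsa": res.rsa}
        for sub in list(EDGE_TYPES) + ["ALL"]:
            for m in MEASURES:
                row[f"{sub.lower()}_{m}"] = cents[sub][res.key][m]
        node_rows.append(row)
    paths = {
        "nodes": out_dir / "nodes.tsv",
        "edges": out_dir / "edges.tsv",
        "residues": out_dir / "residues.tsv",
    }
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False)
    pd.DataFrame(
        [{"u": f"{e.u[0]}:{e.u[1]}", "v": f"{e.v[0]}:{e.v[1]}", "etype": e.etype,
          "distance": round(e.distance, 3), "atom_u": e.atoms[0], "atom_v": e.atoms[1]}
         for e in rin.edges]
    ).to_csv(paths["edges"], sep="\t", index=False)
    residue_table(s).to_csv(paths["residues"], sep="\t", index=False)
    return paths
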