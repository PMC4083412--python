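"""Evolutionary features and simplified per-residue statistical potentials.

From a user-supplied multiple sequence alignment the module computes, per
structure position: conservation (1 - normalized Shannon entropy), mutual
information against structural contact partners, and the average cluster
purity (ACP) correction.  When no alignment is available the features fall
back to conservation=1, mi=0, acp=1 with a warning.

The statistical potential is a two-term knowledge-based pseudo-energy:
a pairwise contact term -log(f_obs(a,b)/f_exp(a,b)) summed over RIN
contacts, and a solvation term -log(f_obs(a|burial)/f(a)) on the RSA<=0.25
burial split.  Reference contact/burial frequencies ship with the package
(derived from a seeded synthetic fixture ensemble) and can be replaced by
user-supplied tables, or bypassed entirely with a per-position score file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from ._aa import AA_INDEX, HYDROPHOBIC, STANDARD_AA, THREE_TO_ONE
from .structure_io import Structure

__all__ = [
    "MSA",
    "EvoProfile",
    "PotentialScores",
    "ReferenceStats",
    "read_msa",
    "conservation",
    "mutual_information",
    "acp",
    "evo_profile",
    "default_evo_profile",
    "potential_scores",
    "load_external_scores",
    "build_reference_stats",
    "default_reference_stats",
    "save_reference_stats",
    "load_reference_stats",
]

_LOG2_20 = math.log2(20.0)
_GAP_CHARS = {"-", ".", "X"}


@dataclass
class MSA:
    ids: list[str]
    rows: list[str]
    query_row: int

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def query_columns(self) -> list[int]:
        """Alignment columns carrying the (ungapped) query sequence."""
        return [c for c, ch in enumerate(self.rows[self.query_row]) if ch not in _GAP_CHARS]


def read_msa(path: str | Path, query_id: str) -> MSA:
    """Read a FASTA alignment and locate the query row."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"format error reading alignment: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    if query_id not in ids:
        raise ValueError(f"query {query_id!r} not found in alignment (rows: {ids[:5]}...)")
    return MSA(ids, rows, ids.index(query_id))


def map_msa_to_structure(msa: MSA, s: Structure) -> list[int]:
    """Columns of the alignment for each structure residue, in order.

    Raises when the ungapped query sequence does not match the structure's
    sequence, naming the first mismatching position.
    """
    cols = msa.query_columns()
    query_seq = "".join(msa.rows[msa.query_row][c] for c in cols)
    struct_seq = s.sequence
    if len(query_seq) != len(struct_seq):
        raise ValueError(
            f"query/structure length mismatch: {len(query_seq)} vs {len(struct_seq)}")
    for i, (a, b) in enumerate(zip(query_seq, struct_seq)):
        if a != b:
            raise ValueError(
                f"query/structure sequence mismatch at position {i + 1}: {a!r} vs {b!r}")
    return cols


def _column_freqs(msa: MSA, col: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    for row in msa.rows:
        ch = row[col]
        if ch in _GAP_CHARS:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {ch: c / total for ch, c in counts.items()}


def conservation(msa: MSA, col: int) -> float:
    """1 - H(col)/log2(20); gaps excluded, all-gap columns give 0."""
    freqs = _column_freqs(msa, col)
    if not freqs:
        return 0.0
    h = -sum(p * math.log2(p) for p in freqs.values())
    return max(0.0, 1.0 - h / _LOG2_20)


def mutual_information(msa: MSA, i: int, j: int) -> float:
    """Plug-in mutual information (bits) between columns over co-ungapped rows."""
    pairs = [(r[i], r[j]) for r in msa.rows
             if r[i] not in _GAP_CHARS and r[j] not in _GAP_CHARS]
    if len(pairs) < 2:
        return 0.0
    n = len(pairs)
    p_ab: dict[tuple[str, str], float] = {}
    p_a: dict[str, float] = {}
    p_b: dict[str, float] = {}
    for a, b in pairs:
        p_ab[(a, b)] = p_ab.get((a, b), 0.0) + 1.0 / n
        p_a[a] = p_a.get(a, 0.0) + 1.0 / n
        p_b[b] = p_b.get(b, 0.0) + 1.0 / n
    mi = 0.0
    for (a, b), pab in p_ab.items():
        mi += pab * math.log2(pab / (p_a[a] * p_b[b]))
    return max(0.0, mi)


def acp(msa: MSA, i: int, partners: list[int]) -> float:
    """Average cluster purity of partner columns given the query residue at i.

    For each partner column j, restrict to rows sharing the query's residue
    at column i; the purity is the frequency of the most common (ungapped)
    partner residue among those rows.  Returns the mean over partners, or
    1.0 when no partner yields any eligible row.
    """
    a_star = msa.rows[msa.query_row][i]
    if a_star in _GAP_CHARS:
        return 1.0
    purities = []
    for j in partners:
        counts: dict[str, int] = {}
        for row in msa.rows:
            if row[i] == a_star and row[j] not in _GAP_CHARS:
                counts[row[j]] = counts.get(row[j], 0) + 1
        total = sum(counts.values())
        if total:
            purities.append(max(counts.values()) / total)
    return float(np.mean(purities)) if purities else 1.0


@dataclass
class EvoProfile:
    conservation: np.ndarray
    mi: np.ndarray
    acp: np.ndarray

    def __len__(self) -> int:
        return len(self.conservation)


def default_evo_profile(n_residues: int) -> EvoProfile:
    """Neutral profile used when no alignment is supplied."""
    return EvoProfile(np.ones(n_residues), np.zeros(n_residues), np.ones(n_residues))


def evo_profile(msa: MSA | None, s: Structure, rin=None) -> EvoProfile:
    """Per-residue conservation / MI / ACP aligned to the structure.

    MI and ACP are averaged over each residue's RIN contact partners; when
    no RIN is given, sequence neighbors (i-1, i+1) stand in.
    """
    n = s.length
    if msa is None:
        warnings.warn("no alignment supplied; evolutionary features default to "
                      "conservation=1, mi=0, acp=1")
        return default_evo_profile(n)
    cols = map_msa_to_structure(msa, s)

    # structure-position partners
    if rin is not None:
        adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
        index_of = {res.key: i for i, res in enumerate(s.residues)}
        for e in rin.edges:
            ui, vi = index_of[e.u], index_of[e.v]
            if vi not in adjacency[ui]:
                adjacency[ui].append(vi)
            if ui not in adjacency[vi]:
                adjacency[vi].append(ui)
    else:
        adjacency = {i: [j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)}

    cons = np.array([conservation(msa, c) for c in cols])
    mi = np.zeros(n)
    acps = np.zeros(n)
    for i in range(n):
        partner_cols = [cols[j] for j in adjacency[i]]
        if partner_cols:
            mi[i] = float(np.mean([mutual_information(msa, cols[i], pc) for pc in partner_cols]))
        acps[i] = acp(msa, cols[i], partner_cols)
    return EvoProfile(cons, mi, acps)


# ---------------------------------------------------------------------------
# Simplified statistical potential
# ---------------------------------------------------------------------------

@dataclass
class ReferenceStats:
    """Contact and burial frequencies backing the two-term potential."""

    contact_obs: np.ndarray  # (20, 20) joint contact probabilities
    contact_exp: np.ndarray  # (20, 20) expected from marginals
    burial_given_aa: np.ndarray  # (20,) P(buried | aa)
    aa_freq: np.ndarray  # (20,) background frequencies

    def p_aa_given_state(self, buried: bool) -> np.ndarray:
        joint = self.aa_freq * (self.burial_given_aa if buried else 1.0 - self.burial_given_aa)
        return joint / joint.sum()


@dataclass
class PotentialScores:
    pairwise: np.ndarray
    solvation: np.ndarray

    def __len__(self) -> int:
        return len(self.pairwise)


def build_reference_stats(structures_with_rins: list[tuple[Structure, object]],
                          pseudo: float = 1.0) -> ReferenceStats:
    """Count contact and burial statistics over an ensemble of structures.

    Each structure must carry per-residue RSA; contacts come from its RIN.
    Pseudo-counts keep every frequency strictly positive.
    """
    contact = np.full((20, 20), pseudo)
    buried = np.full(20, pseudo)
    total_state = np.full(20, 2.0 * pseudo)
    aa_counts = np.full(20, pseudo)
    for s, net in structures_with_rins:
        idx = {r.key: AA_INDEX[r.aa] for r in s.residues}
        for e in net.edges:
            if e.etype != "IAC":
                continue
            a, b = idx[e.u], idx[e.v]
            contact[a, b] += 1
            contact[b, a] += 1
        for r in s.residues:
            a = AA_INDEX[r.aa]
            aa_counts[a] += 1
            total_state[a] += 1
            if r.rsa is not None and r.rsa <= 0.25:
                buried[a] += 1
    contact_obs = contact / contact.sum()
    marg = contact_obs.sum(axis=1)
    contact_exp = np.outer(marg, marg) / np.outer(marg, marg).sum()
    return ReferenceStats(
        contact_obs=contact_obs,
        contact_exp=contact_exp,
        burial_given_aa=buried / total_state,
        aa_freq=aa_counts / aa_counts.sum(),
    )


def save_reference_stats(stats: ReferenceStats, path: str | Path) -> None:
    rows = []
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            rows.append(("contact_obs", a, b, stats.contact_obs[i, j]))
            rows.append(("contact_exp", a, b, stats.contact_exp[i, j]))
    for i, a in enumerate(STANDARD_AA):
        rows.append(("burial_given_aa", a, "", stats.burial_given_aa[i]))
        rows.append(("aa_freq", a, "", stats.aa_freq[i]))
    pd.DataFrame(rows, columns=["kind", "aa1", "aa2", "value"]).to_csv(
        path, sep="\t", index=False)


def load_reference_stats(path: str | Path) -> ReferenceStats:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    contact_obs = np.zeros((20, 20))
    contact_exp = np.zeros((20, 20))
    burial = np.zeros(20)
    freq = np.zeros(20)
    for _, row in df.iterrows():
        i = AA_INDEX[row["aa1"]]
        if row["kind"] == "contact_obs":
            contact_obs[i, AA_INDEX[row["aa2"]]] = row["value"]
        elif row["kind"] == "contact_exp":
            contact_exp[i, AA_INDEX[row["aa2"]]] = row["value"]
        elif row["kind"] == "burial_given_aa":
            burial[i] = row["value"]
        elif row["kind"] == "aa_freq":
            freq[i] = row["value"]
    if not (contact_obs > 0).all() or not (freq > 0).all():
        raise ValueError("reference table incomplete; use the shipped defaults "
                         "(profiles.default_reference_stats())")
    return ReferenceStats(contact_obs, contact_exp, burial, freq)


_DEFAULT_STATS: ReferenceStats | None = None


def default_reference_stats() -> ReferenceStats:
    """The packaged reference table (derived from a synthetic fixture ensemble)."""
    global _DEFAULT_STATS
    if _DEFAULT_STATS is None:
        with resources.as_file(resources.files("rinstab") / "data" / "reference_stats.tsv") as p:
            _DEFAULT_STATS = load_reference_stats(p)
    return _DEFAULT_STATS


def potential_scores(s: Structure, rin, reference: ReferenceStats | None = None) -> PotentialScores:
    """Two-term pseudo-energy per residue from the reference statistics.

    pairwise(i) sums -log(f_obs/f_exp) over the residue's IAC contacts;
    solvation(i) is -log(f_obs(aa|burial state)/f(aa)) with buried meaning
    RSA <= 0.25 (requires compute_rsa beforehand).
    """
    if reference is None:
        reference = default_reference_stats()
    n = s.length
    index_of = {r.key: i for i, r in enumerate(s.residues)}
    aa_idx = np.array([AA_INDEX[r.aa] for r in s.residues])
    pairwise = np.zeros(n)
    ratio = reference.contact_obs / reference.contact_exp
    for e in rin.edges:
        if e.etype != "IAC":
            continue
        ui, vi = index_of[e.u], index_of[e.v]
        term = -math.log(ratio[aa_idx[ui], aa_idx[vi]])
        pairwise[ui] += term
        pairwise[vi] += term
    solvation = np.zeros(n)
    p_buried = reference.p_aa_given_state(True)
    p_exposed = reference.p_aa_given_state(False)
    for i, r in enumerate(s.residues):
        if r.rsa is None:
            raise ValueError("solvation potential needs RSA; run compute_rsa first")
        p_state = p_buried if r.rsa <= 0.25 else p_exposed
        solvation[i] = -math.log(p_state[aa_idx[i]] / reference.aa_freq[aa_idx[i]])
    return PotentialScores(pairwise, solvation)


def load_external_scores(path: str | Path, s: Structure) -> PotentialScores:
    """Per-position score override (TSV: position, name, value).

    Lets genuine external potential outputs replace the built-in provider;
    names must be 'pairwise' or 'solvation'. Missing positions default to 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    for col in ("position", "name", "value"):
        if col not in df.columns:
            raise ValueError(f"format error: score file missing column {col!r}")
    pairwise = np.zeros(s.length)
    solvation = np.zeros(s.length)
    for _, row in df.iterrows():
        idx = s.index_of(row["position"])
        if row["name"] == "pairwise":
            pairwise[idx] = float(row["value"])
        elif row["name"] == "solvation":
            solvation[idx] = float(row["value"])
        else:
            raise ValueError(f"unknown score name {row['name']!r}")
    return PotentialScores(pairwise, solvation)
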