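"""Mutation tables, curation filters and synthetic structure fixtures.

The fixture generators build small proteins with ideal internal-coordinate
geometry (alpha helix, antiparallel beta hairpin, fully extended chain) and
an occlusion cage, so the whole pipeline — secondary structure, solvent
accessibility, interaction networks, encoding and training — is exercised
without any external structure downloads.

Curation mirrors the training-set filters used for stability data: no
proline variants, and no mutations destabilizing by more than 5 kcal/mol.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa import ONE_TO_THREE, STANDARD_AA, THREE_TO_ONE
from ._geometry import backbone_from_torsions, cb_position
from .model import MutationRecord
from .structure_io import Atom, Residue, Structure, write_pdb

__all__ = [
    "MutationTable",
    "read_mutation_table",
    "apply_curation_filters",
    "make_fixture_structure",
    "simulate_ddg",
    "make_mutation_dataset",
]

_MANDATORY_COLS = ["pdb_id", "chain", "position", "wt", "mut", "ph", "temp"]


@dataclass
class MutationTable:
    records: list[MutationRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pdb_id": [r.pdb_id for r in self.records],
                "chain": [r.chain for r in self.records],
                "position": [r.position for r in self.records],
                "wt": [r.wt_aa for r in self.records],
                "mut": [r.mut_aa for r in self.records],
                "ph": [r.ph for r in self.records],
                "temp": [r.temperature for r in self.records],
                "ddg": [r.ddg_exp for r in self.records],
            }
        )


def read_mutation_table(path: str | Path, provenance: str = "") -> MutationTable:
    """Read a TSV mutation table into typed records.

    Mandatory columns: pdb_id, chain, position, wt, mut, ph, temp; optional
    ddg.  Rows with wt == mut are rejected with a warning; duplicate keys
    are collapsed by averaging their ddg values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"position": str, "chain": str})
    missing = [c for c in _MANDATORY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"format error: missing mandatory columns {missing}")
    has_ddg = "ddg" in df.columns
    records: dict[tuple, list] = {}
    for _, row in df.iterrows():
        if str(row["wt"]).strip().upper() == str(row["mut"]).strip().upper():
            warnings.warn(f"rejected row {row['pdb_id']}:{row['position']}: wt == mut")
            continue
        rec = MutationRecord(
            pdb_id=str(row["pdb_id"]),
            chain=str(row["chain"]),
            position=str(row["position"]),
            wt_aa=str(row["wt"]),
            mut_aa=str(row["mut"]),
            ph=float(row["ph"]),
            temperature=float(row["temp"]),
            ddg_exp=float(row["ddg"]) if has_ddg and pd.notna(row["ddg"]) else None,
        )
        records.setdefault(rec.key, []).append(rec)
    out: list[MutationRecord] = []
    for key, group in records.items():
        if len(group) > 1:
            ddgs = [r.ddg_exp for r in group if r.ddg_exp is not None]
            mean_ddg = float(np.mean(ddgs)) if ddgs else None
            warnings.warn(f"duplicate mutation key {key}: averaged {len(group)} ddg values")
            rec = group[0]
            rec.ddg_exp = mean_ddg
            out.append(rec)
        else:
            out.append(group[0])
    return MutationTable(out, provenance=provenance or str(path))


def apply_curation_filters(
    t: MutationTable,
    max_destab: float = 5.0,
    exclude_proline: bool = True,
    sign_convention: str = "positive_destabilizing",
) -> tuple[MutationTable, list[tuple[tuple, str]]]:
    """Drop proline variants and strongly destabilizing mutations.

    The ddG bound is one-sided on the destabilizing side of the configured
    sign convention.  Returns the retained table and a rejection log of
    (mutation key, rule) pairs.
    """
    kept: list[MutationRecord] = []
    rejections: list[tuple[tuple, str]] = []
    for rec in t.records:
        if exclude_proline and ("PRO" in (rec.wt_aa, rec.mut_aa)):
            rejections.append((rec.key, "proline"))
            continue
        if rec.ddg_exp is not None:
            destab = rec.ddg_exp if sign_convention == "positive_destabilizing" else -rec.ddg_exp
            if destab > max_destab:
                rejections.append((rec.key, "max_destab"))
                continue
        kept.append(rec)
    return MutationTable(kept, provenance=t.provenance), rejections


# ---------------------------------------------------------------------------
# Synthetic structure fixtures
# ---------------------------------------------------------------------------

def _sequence_list(sequence: str | None, n: int) -> list[str]:
    if sequence is None:
        return ["ALA"] * n
    seq = [ONE_TO_THREE[c] if len(c) == 1 else c for c in sequence]
    if len(seq) != n:
        raise ValueError(f"sequence length {len(seq)} != n_residues {n}")
    return seq


def _residues_from_backbones(backbones: list[dict[str, np.ndarray]], seq3: list[str],
                             chain: str = "A") -> list[Residue]:
    residues = []
    for i, (bb, aa) in enumerate(zip(backbones, seq3)):
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", bb["O"]),
        ]
        if aa != "GLY" and "CB" in bb:
            atoms.append(Atom("CB", "C", bb["CB"]))
        residues.append(Residue(chain, str(i + 1), aa, atoms))
    return residues


def _torsion_fixture(phi: float, psi: float, n: int, seq3: list[str],
                     pdb_id: str) -> Structure:
    backbones = backbone_from_torsions([phi] * n, [psi] * n)
    return Structure(pdb_id, "A", _residues_from_backbones(backbones, seq3))


def _hairpin_fixture(n: int, seq3: list[str], pdb_id: str) -> Structure:
    """Flat idealized antiparallel hairpin: two strands bridged by backbone
    hydrogen bonds plus a two-residue connecting turn."""
    if n < 8:
        raise ValueError("hairpin fixture needs at least 8 residues")
    m = (n - 2) // 2
    if m % 2 == 1:
        m -= 1  # even strand length keeps the bridge register aligned
    n_turn = n - 2 * m
    rise = 3.8
    sep = 4.13  # strand-to-strand backbone separation giving ~2.9 A N..O
    x_b0 = 2.6 + rise * m

    backbones: list[dict[str, np.ndarray]] = []
    # strand A along +x at y=0; carbonyls alternate +/- y
    for i in range(m):
        s_i = 1.0 if i % 2 == 1 else -1.0
        c = np.array([rise * i + 2.6, 0.0, 0.0])
        bb = {
            "N": np.array([rise * i, 0.0, 0.0]),
            "CA": np.array([rise * i + 1.4, 0.0, 0.4 * (-1.0) ** i]),
            "C": c,
            "O": c + np.array([0.0, s_i * 1.231, 0.0]),
        }
        bb["CB"] = cb_position(bb["N"], bb["CA"], bb["C"])
        backbones.append(bb)
    # connecting turn: out-of-plane arc, carbonyls point +z (no spurious bonds)
    start = np.array([rise * (m - 1) + 2.6, 0.0, 0.0])
    end = np.array([x_b0, sep, 0.0])
    for k in range(1, n_turn + 1):
        frac = k / (n_turn + 1)
        center = start + frac * (end - start) + np.array([0.8, 0.0, 2.2])
        bb = {
            "N": center + np.array([-0.8, -0.3, -0.4]),
            "CA": center,
            "C": center + np.array([0.8, 0.3, -0.4]),
            "O": center + np.array([0.8, 0.3, 0.83]),
        }
        bb["CB"] = center + np.array([0.0, -1.0, 1.1])
        backbones.append(bb)
    # strand B along -x at y=sep; carbonyls alternate -/+ y
    for j in range(m):
        t_j = 1.0 if j % 2 == 0 else -1.0
        c = np.array([x_b0 - rise * j - 2.6, sep, 0.0])
        bb = {
            "N": np.array([x_b0 - rise * j, sep, 0.0]),
            "CA": np.array([x_b0 - rise * j - 1.4, sep, 0.4 * (-1.0) ** j]),
            "C": c,
            "O": c + np.array([0.0, t_j * 1.231, 0.0]),
        }
        bb["CB"] = cb_position(bb["N"], bb["CA"], bb["C"])
        backbones.append(bb)
    return Structure(pdb_id, "A", _residues_from_backbones(backbones, seq3))


def _cage_fixture(seq3: list[str], pdb_id: str, cage_radius: float = 4.0,
                  n_cage: int = 240) -> Structure:
    """A single residue enclosed by a spherical cage of carbon atoms."""
    central = _residues_from_backbones(backbone_from_torsions([-57.0], [-47.0]),
                                       seq3[:1])[0]
    centroid = central.coords().mean(axis=0)
    residues = [central]
    # Fibonacci sphere of single-atom glycine "cage" residues
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(n_cage):
        z = 1.0 - 2.0 * (k + 0.5) / n_cage
        r_xy = math.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * k
        direction = np.array([r_xy * math.cos(theta), r_xy * math.sin(theta), z])
        pos = centroid + cage_radius * direction
        residues.append(Residue("A", str(k + 2), "GLY", [Atom("CA", "C", pos)]))
    return Structure(pdb_id, "A", residues)


def make_fixture_structure(kind: str, n_residues: int = 15,
                           sequence: str | None = None, seed: int = 0,
                           pdb_id: str | None = None) -> tuple[Structure, str]:
    """Build a synthetic Structure and its PDB text.

    Kinds: ``helix`` (phi=-57, psi=-47), ``extended`` (phi=psi=180),
    ``hairpin`` (two antiparallel strands + turn), ``cage`` (one residue
    enclosed at `cage` radius 4 A; n_residues ignored beyond the first).
    Deterministic for a given seed (the geometry itself is seed-free; the
    seed is kept in the signature for API symmetry with the simulators).
    """
    if n_residues < 4 and kind != "cage":
        raise ValueError("need at least 4 residues")
    pdb_id = pdb_id or f"{kind[:3]}{n_residues}"
    seq3 = _sequence_list(sequence, n_residues if kind != "cage" else 1)
    if kind == "helix":
        s = _torsion_fixture(-57.0, -47.0, n_residues, seq3, pdb_id)
    elif kind == "extended":
        s = _torsion_fixture(180.0, 180.0, n_residues, seq3, pdb_id)
    elif kind == "hairpin":
        s = _hairpin_fixture(n_residues, seq3, pdb_id)
    elif kind == "cage":
        s = _cage_fixture(seq3, pdb_id)
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    return s, write_pdb(s)


def simulate_ddg(X: np.ndarray, coefficients: np.ndarray, noise_sd: float = 0.3,
                 seed: int = 0) -> np.ndarray:
    """Linear synthetic ddG: y = X @ coefficients + N(0, noise_sd^2)."""
    X = np.asarray(X, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if X.shape[1] != coefficients.shape[0]:
        raise ValueError(f"coefficient length {coefficients.shape[0]} != {X.shape[1]} columns")
    rng = np.random.default_rng(seed)
    y = X @ coefficients
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=X.shape[0])
    return y


def make_mutation_dataset(n_structures: int = 20, per_structure: int = 50,
                          seed: int = 0) -> tuple[list[MutationRecord], dict[str, Structure]]:
    """Random mutations on a panel of random-sequence fixture structures.

    Alternates helix and hairpin folds with lengths 14-24 and random
    non-proline sequences, then draws `per_structure` distinct substitutions
    per structure with pH in [5, 9] and temperature in [15, 45] C.
    """
    rng = np.random.default_rng(seed)
    aa_pool = [a for a in STANDARD_AA if a != "PRO"]
    structures: dict[str, Structure] = {}
    records: list[MutationRecord] = []
    for si in range(n_structures):
        kind = "helix" if si % 2 == 0 else "hairpin"
        length = int(rng.integers(14, 25))
        if kind == "hairpin":
            length = max(10, length - length % 2)
        seq3 = [aa_pool[i] for i in rng.integers(0, len(aa_pool), size=length)]
        seq1 = "".join(THREE_TO_ONE[a] for a in seq3)
        pdb_id = f"fix{si:03d}"
        s, _ = make_fixture_structure(kind, length, sequence=seq1, pdb_id=pdb_id)
        structures[pdb_id] = s
        seen = set()
        while len(seen) < per_structure:
            pos = int(rng.integers(1, length + 1))
            wt = s.residues[pos - 1].aa
            mut = aa_pool[int(rng.integers(0, len(aa_pool)))]
            if mut == wt or (pos, mut) in seen:
                continue
            seen.add((pos, mut))
            records.append(MutationRecord(
                pdb_id=pdb_id, chain="A", position=str(pos), wt_aa=wt, mut_aa=mut,
                ph=float(np.round(rng.uniform(5.0, 9.0), 2)),
                temperature=float(np.round(rng.uniform(15.0, 45.0), 1)),
            ))
    return records, structures
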