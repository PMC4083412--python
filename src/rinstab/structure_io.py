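"""Protein structure input and per-residue annotation.

Reads single-chain PDB structures into a light internal model, assigns
3-state secondary structure with a simplified Kabsch–Sander procedure
(backbone hydrogen-bond electrostatics), and computes relative solvent
accessibility (RSA) by Shrake–Rupley point sampling normalised with the
Rost & Sander (1994) maximum-ASA table.

Residues with RSA <= 0.25 are classified *buried*, above that *exposed*.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from ._aa import MAX_ASA, THREE_TO_ONE, is_standard

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "parse_pdb",
    "write_pdb",
    "assign_secondary_structure",
    "compute_rsa",
    "classify_exposure",
    "assign_from_dssp",
    "residue_table",
]

# Kabsch-Sander H-bond energy: E = q1*q2*(1/dON + 1/dCH - 1/dOH - 1/dCN)*f
# with q1*q2*f = 0.084 * 332 kcal/mol; a bond exists when E < -0.5 kcal/mol.
_KS_COUPLING = 0.084 * 332.0
_KS_CUTOFF = -0.5


class StructureError(ValueError):
    """Raised for unreadable or empty structures and missing chains."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)) or self.coord.shape != (3,):
            raise StructureError(f"atom {self.name}: non-finite or malformed coordinates")


@dataclass
class Residue:
    chain: str
    seq_id: str  # author residue number + insertion code, e.g. "52" or "52A"
    aa: str  # three-letter code, standard residues only
    atoms: list[Atom]
    ss: str | None = None  # one of H / E / C after assignment
    rsa: float | None = None
    asa: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain, self.seq_id)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        return np.array([a.coord for a in atoms], dtype=float)


@dataclass
class Structure:
    pdb_id: str
    chain: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE[r.aa] for r in self.residues)

    def residue_by_seq_id(self, seq_id: str) -> Residue:
        for r in self.residues:
            if r.seq_id == str(seq_id).strip():
                return r
        raise StructureError(f"residue {seq_id} not found in chain {self.chain}")

    def index_of(self, seq_id: str) -> int:
        for i, r in enumerate(self.residues):
            if r.seq_id == str(seq_id).strip():
                return i
        raise StructureError(f"residue {seq_id} not found in chain {self.chain}")


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise StructureError(f"format error at line {lineno}: bad coordinate field")


def parse_pdb(source: str | Path, chain: str = "A", model_index: int = 0) -> Structure:
    """Read one chain of one model from PDB-format text or a file path.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order); HETATM records, waters and non-standard
    residues are excluded; hydrogens are retained when present.
    """
    if isinstance(source, Path) or ("\n" not in str(source) and os.path.exists(str(source))):
        path = Path(source)
        text = path.read_text()
        pdb_id = path.stem
    else:
        text = str(source)
        pdb_id = "struct"
    _validate_pdb_lines(text)

    parser = PDBParser(QUIET=True)
    bio_structure = parser.get_structure(pdb_id, io.StringIO(text))
    models = list(bio_structure.get_models())
    if not models:
        raise StructureError("empty structure: no MODEL/ATOM records")
    if model_index >= len(models):
        raise StructureError(f"model index {model_index} out of range ({len(models)} models)")
    model = models[model_index]

    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise StructureError(f"chain not found: {chain!r} (file has {chain_ids})")

    residues: list[Residue] = []
    for bio_res in model[chain]:
        hetfield, resseq, icode = bio_res.id
        if hetfield.strip():
            continue  # HETATM / water
        resname = bio_res.get_resname().strip()
        if not is_standard(resname):
            warnings.warn(f"dropping non-standard residue {resname} {resseq}{icode.strip()}")
            continue
        atoms: list[Atom] = []
        for bio_atom in bio_res:
            if bio_atom.is_disordered():
                children = list(bio_atom.disordered_get_list())
                best = max(children, key=lambda a: a.get_occupancy() or 0.0)
                occ = best.get_occupancy()
                atoms.append(Atom(best.get_name(), best.element, best.get_coord(),
                                  best.get_altloc().strip(), occ if occ is not None else 1.0))
            else:
                occ = bio_atom.get_occupancy()
                atoms.append(Atom(bio_atom.get_name(), bio_atom.element, bio_atom.get_coord(),
                                  bio_atom.get_altloc().strip(), occ if occ is not None else 1.0))
        if atoms:
            residues.append(Residue(chain, f"{resseq}{icode.strip()}", resname, atoms))
    if not residues:
        raise StructureError("empty structure: no standard residues in chain")
    return Structure(pdb_id, chain, residues)


def write_pdb(s: Structure) -> str:
    """Serialise a Structure back to PDB-format text (single model)."""
    lines = []
    serial = 1
    for res in s.residues:
        # split numeric part and insertion code
        seq = res.seq_id
        icode = " "
        if seq and seq[-1].isalpha():
            icode = seq[-1]
            seq = seq[:-1]
        for a in res.atoms:
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{a.altloc or ' '}{res.aa:>3s} {res.chain}"
                f"{int(seq):4d}{icode}   {a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Secondary structure (simplified Kabsch-Sander, 3 states)
# ---------------------------------------------------------------------------

def _backbone(res: Residue) -> dict[str, np.ndarray] | None:
    out = {}
    for name in ("N", "CA", "C", "O"):
        a = res.atom(name)
        if a is None:
            return None
        out[name] = a.coord
    return out


def _amide_h(bb_i: dict[str, np.ndarray], bb_prev: dict[str, np.ndarray] | None,
             res: Residue) -> np.ndarray | None:
    """Ideal amide hydrogen: 1 A from N along the previous C=O bond direction."""
    h = res.atom("H")
    if h is not None:
        return h.coord
    if bb_prev is None or res.aa == "PRO":
        return None  # chain start cannot donate; proline has no amide H
    d = bb_prev["C"] - bb_prev["O"]
    n = np.linalg.norm(d)
    if n < 1e-9:
        return None
    return bb_i["N"] + d / n


def _hbond_energy(donor_n: np.ndarray, donor_h: np.ndarray,
                  acc_c: np.ndarray, acc_o: np.ndarray) -> float:
    d_on = np.linalg.norm(acc_o - donor_n)
    d_ch = np.linalg.norm(acc_c - donor_h)
    d_oh = np.linalg.norm(acc_o - donor_h)
    d_cn = np.linalg.norm(acc_c - donor_n)
    if min(d_on, d_ch, d_oh, d_cn) < 0.5:  # atoms essentially on top of each other
        return 0.0
    return _KS_COUPLING * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)


def _hbond_matrix(s: Structure) -> np.ndarray:
    """hb[i, j] True when the N-H of residue i hydrogen-bonds the C=O of j."""
    n = s.length
    bbs = [_backbone(r) for r in s.residues]
    hs: list[np.ndarray | None] = []
    for i, r in enumerate(s.residues):
        if bbs[i] is None:
            hs.append(None)
            continue
        hs.append(_amide_h(bbs[i], bbs[i - 1] if i > 0 else None, r))
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if bbs[i] is None or hs[i] is None:
            continue
        for j in range(n):
            if abs(i - j) < 2 or bbs[j] is None:
                continue
            e = _hbond_energy(bbs[i]["N"], hs[i], bbs[j]["C"], bbs[j]["O"])
            if e < _KS_CUTOFF:
                hb[i, j] = True
    return hb


def assign_secondary_structure(s: Structure) -> Structure:
    """Label each residue H (helix), E (strand) or C (coil) in place.

    H requires two consecutive i->i+4 backbone hydrogen bonds; E marks the
    partners of a parallel or antiparallel bridge; everything else is coil.
    Residues lacking backbone atoms are coil. Returns the same Structure.
    """
    n = s.length
    for r in s.residues:
        r.ss = "C"
    if n < 5:
        return s
    hb = _hbond_matrix(s)

    # hbond(a, b): donor N-H of a to acceptor C=O of b
    def hbond(a: int, b: int) -> bool:
        return 0 <= a < n and 0 <= b < n and hb[a, b]

    ss = ["C"] * n
    # bridges -> E
    for i in range(n):
        for j in range(i + 3, n):
            para = (hbond(j, i - 1) and hbond(i + 1, j)) or (hbond(i, j - 1) and hbond(j + 1, i))
            anti = (hbond(i, j) and hbond(j, i)) or (hbond(j + 1, i - 1) and hbond(i + 1, j - 1))
            if para or anti:
                ss[i] = "E"
                ss[j] = "E"
    # two consecutive 4-turns -> helix on i+1..i+4 (overrides strand)
    turn4 = [hbond(i + 4, i) for i in range(n)]
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, i + 5):
                if k < n:
                    ss[k] = "H"
    for r, label in zip(s.residues, ss):
        r.ss = label
    return s


# ---------------------------------------------------------------------------
# Solvent accessibility
# ---------------------------------------------------------------------------

def _as_bio_entity(s: Structure):
    """Build a Bio.PDB model (heavy atoms only) for the SASA machinery."""
    builder = StructureBuilder()
    builder.init_structure(s.pdb_id)
    builder.init_model(0)
    builder.init_chain(s.chain)
    builder.init_seg("    ")
    serial = 1
    for idx, res in enumerate(s.residues):
        builder.init_residue(res.aa, " ", idx + 1, " ")
        for a in res.heavy_atoms():
            builder.init_atom(a.name, a.coord.astype(np.float64), 0.0,
                              a.occupancy, " ", f" {a.name:<3s}"[:4], serial, a.element)
            serial += 1
    return builder.get_structure()[0]


def compute_rsa(s: Structure, probe_radius: float = 1.4, sphere_points: int = 92) -> Structure:
    """Fill per-residue absolute (asa) and relative (rsa) solvent accessibility.

    Shrake-Rupley sampling over heavy atoms; RSA = ASA / maxASA(aa) with the
    Rost & Sander (1994) reference, clipped to [0, 1].
    """
    model = _as_bio_entity(s)
    ShrakeRupley(probe_radius=probe_radius, n_points=sphere_points).compute(
        model, level="R")
    bio_residues = list(model[s.chain])
    for res, bio_res in zip(s.residues, bio_residues):
        asa = float(bio_res.sasa)
        res.asa = asa
        res.rsa = float(np.clip(asa / MAX_ASA[res.aa], 0.0, 1.0))
    return s


def classify_exposure(rsa: float) -> str:
    """Buried when RSA <= 25%, exposed otherwise."""
    return "buried" if rsa <= 0.25 else "exposed"


# ---------------------------------------------------------------------------
# DSSP-file override and annotation output
# ---------------------------------------------------------------------------

_DSSP_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def assign_from_dssp(s: Structure, dssp_path: str | Path) -> Structure:
    """Override internal ss/rsa from a precomputed DSSP output file."""
    lines = Path(dssp_path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE")) + 1
    except StopIteration:
        raise StructureError("format error: not a DSSP output file")
    table: dict[tuple[str, str], tuple[str, float]] = {}
    for ln in lines[start:]:
        if len(ln) < 38 or ln[13] == "!":
            continue
        seq_id = (ln[5:10].strip() + ln[10].strip())
        chain_id = ln[11]
        ss8 = ln[16]
        acc = float(ln[34:38])
        table[(chain_id, seq_id)] = (_DSSP_TO_3.get(ss8, "C"), acc)
    for res in s.residues:
        if res.key in table:
            ss3, acc = table[res.key]
            res.ss = ss3
            res.asa = acc
            res.rsa = float(np.clip(acc / MAX_ASA[res.aa], 0.0, 1.0))
    return s


def residue_table(s: Structure):
    """Per-residue annotation table (chain, seq_id, aa, ss, asa, rsa)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chain": [r.chain for r in s.residues],
            "seq_id": [r.seq_id for r in s.residues],
            "aa": [r.aa for r in s.residues],
            "ss": [r.ss for r in s.residues],
            "asa": [r.asa for r in s.residues],
            "rsa": [r.rsa for r in s.residues],
        }
    )
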