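"""The 184-dimensional mutation descriptor and its ablation subsets.

Slot layout (named, ordered, machine-readable):

    ENV              2   pH, temperature
    SEQ_ONEHOT      80   one-hot wild-type, mutant, left and right neighbor
    LOCAL            4   secondary structure one-hot (H/E/C) + RSA
    EVO              3   conservation, mutual information, ACP
    POTENTIAL        2   pairwise contact + solvation pseudo-energies
    NET_CENTRALITY  72   {site, left, right} x 6 subnetworks x 4 measures
    NET_COMPOSITION 20   amino-acid counts among RIN contacts of the site
    NET_SIZE         1   node count of the RIN
                   ---
                   184

Variants: FULL keeps all 184 slots; NOCC drops all network topology
(NET_CENTRALITY + NET_COMPOSITION + NET_SIZE -> 91 slots); NORING keeps
only ENV, SEQ_ONEHOT, LOCAL, conservation, POTENTIAL and NET_SIZE (90).
Terminal mutation sites leave the missing neighbor's one-hot block and
centralities at zero.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import AA_INDEX, STANDARD_AA
from .model import MutationRecord
from .profiles import EvoProfile, PotentialScores, default_evo_profile
from .rin import EDGE_TYPES, MEASURES, RIN, centralities_by_subnetwork, neighbor_composition
from .structure_io import Structure

__all__ = [
    "FeatureManifest",
    "FeatureVector",
    "default_manifest",
    "one_hot",
    "encode",
    "variant_subset",
    "encode_dataset",
]

GROUPS = ("ENV", "SEQ_ONEHOT", "LOCAL", "EVO", "POTENTIAL",
          "NET_CENTRALITY", "NET_COMPOSITION", "NET_SIZE")
VARIANTS = ("FULL", "NOCC", "NORING")
_SUBNETS = list(EDGE_TYPES) + ["ALL"]
_POSITIONS = ("site", "left", "right")


@dataclass
class FeatureManifest:
    slots: list[tuple[str, str]]  # (slot_name, group)
    variant: str = "FULL"

    def __len__(self) -> int:
        return len(self.slots)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.slots]

    @property
    def groups(self) -> list[str]:
        return [g for _, g in self.slots]

    def group_size(self, group: str) -> int:
        return sum(1 for _, g in self.slots if g == group)

    @property
    def hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": range(len(self.slots)),
                             "slot_name": self.names, "group": self.groups})

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("duplicate slot names in manifest")


@dataclass
class FeatureVector:
    values: np.ndarray
    mutation: MutationRecord
    manifest: FeatureManifest = field(repr=False, default=None)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i]


def default_manifest() -> FeatureManifest:
    """The full, ordered 184-slot manifest."""
    slots: list[tuple[str, str]] = [("ph", "ENV"), ("temperature", "ENV")]
    for pos in ("wt", "mut", "left", "right"):
        slots += [(f"{pos}_{aa}", "SEQ_ONEHOT") for aa in STANDARD_AA]
    slots += [("ss_H", "LOCAL"), ("ss_E", "LOCAL"), ("ss_C", "LOCAL"), ("rsa", "LOCAL")]
    slots += [("conservation", "EVO"), ("mi", "EVO"), ("acp", "EVO")]
    slots += [("pot_pairwise", "POTENTIAL"), ("pot_solvation", "POTENTIAL")]
    for pos in _POSITIONS:
        for sub in _SUBNETS:
            for m in MEASURES:
                slots.append((f"net_{pos}_{sub.lower()}_{m}", "NET_CENTRALITY"))
    slots += [(f"comp_{aa}", "NET_COMPOSITION") for aa in STANDARD_AA]
    slots.append(("network_size", "NET_SIZE"))
    assert len(slots) == 184
    return FeatureManifest(slots)


def one_hot(aa: str) -> np.ndarray:
    """20-vector with a single 1 at the residue's alphabetical index."""
    if aa not in AA_INDEX:
        raise ValueError(f"non-standard residue code: {aa!r}")
    v = np.zeros(20)
    v[AA_INDEX[aa]] = 1.0
    return v


def variant_subset(manifest: FeatureManifest, variant: str) -> FeatureManifest:
    """Restrict the manifest to an ablation variant (FULL / NOCC / NORING)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "FULL":
        return FeatureManifest(list(manifest.slots), "FULL")
    if variant == "NOCC":
        dropped = {"NET_CENTRALITY", "NET_COMPOSITION", "NET_SIZE"}
        return FeatureManifest([(n, g) for n, g in manifest.slots if g not in dropped], "NOCC")
    # NORING: minimal core — env, sequence one-hots, local context,
    # conservation, the potential terms and the network (protein) size
    kept_groups = {"ENV", "SEQ_ONEHOT", "LOCAL", "POTENTIAL", "NET_SIZE"}
    slots = [(n, g) for n, g in manifest.slots
             if g in kept_groups or (g == "EVO" and n == "conservation")]
    return FeatureManifest(slots, "NORING")


def _slot_values(m: MutationRecord, s: Structure, net: RIN, evo: EvoProfile,
                 pot: PotentialScores, centralities: dict | None) -> dict[str, float]:
    site = s.index_of(m.position)
    res = s.residues[site]
    if res.aa != m.wt_aa:
        raise ValueError(
            f"wild-type check failed at {m.position}: expected {m.wt_aa}, found {res.aa}")
    if res.ss is None or res.rsa is None:
        raise ValueError("structure not annotated: run assign_secondary_structure "
                         "and compute_rsa before encoding")
    if centralities is None:
        centralities = centralities_by_subnetwork(net)

    values: dict[str, float] = {"ph": m.ph, "temperature": m.temperature}
    neighbors = {"site": site, "left": site - 1 if site > 0 else None,
                 "right": site + 1 if site < s.length - 1 else None}
    blocks = {"wt": one_hot(m.wt_aa), "mut": one_hot(m.mut_aa),
              "left": one_hot(s.residues[neighbors["left"]].aa) if neighbors["left"] is not None else np.zeros(20),
              "right": one_hot(s.residues[neighbors["right"]].aa) if neighbors["right"] is not None else np.zeros(20)}
    for pos, block in blocks.items():
        for aa, val in zip(STANDARD_AA, block):
            values[f"{pos}_{aa}"] = float(val)
    for label in ("H", "E", "C"):
        values[f"ss_{label}"] = 1.0 if res.ss == label else 0.0
    values["rsa"] = float(res.rsa)
    values["conservation"] = float(evo.conservation[site])
    values["mi"] = float(evo.mi[site])
    values["acp"] = float(evo.acp[site])
    values["pot_pairwise"] = float(pot.pairwise[site])
    values["pot_solvation"] = float(pot.solvation[site])
    for pos in _POSITIONS:
        idx = neighbors[pos]
        for sub in _SUBNETS:
            for meas in MEASURES:
                name = f"net_{pos}_{sub.lower()}_{meas}"
                if idx is None:
                    values[name] = 0.0
                else:
                    values[name] = centralities[sub][s.residues[idx].key][meas]
    comp, size = neighbor_composition(net, res.key)
    for aa, c in zip(STANDARD_AA, comp):
        values[f"comp_{aa}"] = float(c)
    values["network_size"] = float(size)
    return values


def encode(m: MutationRecord, s: Structure, net: RIN, evo: EvoProfile,
           pot: PotentialScores, manifest: FeatureManifest | None = None,
           centralities: dict | None = None) -> FeatureVector:
    """Assemble one mutation's descriptor in manifest order."""
    if manifest is None:
        manifest = default_manifest()
    values = _slot_values(m, s, net, evo, pot, centralities)
    vec = np.array([values[name] for name in manifest.names], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [manifest.names[i] for i in np.where(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite feature values in slots {bad}")
    return FeatureVector(vec, m, manifest)


def encode_dataset(records: list[MutationRecord], structures: dict[str, Structure],
                   manifest: FeatureManifest | None = None,
                   msas: dict | None = None, reference=None) -> np.ndarray:
    """Feature matrix for many mutations, annotating and caching per structure.

    `structures` maps pdb_id to Structure; `msas` optionally maps pdb_id to
    an MSA.  Missing ss/rsa annotations are computed in place.
    """
    from .profiles import evo_profile, potential_scores
    from .rin import build_rin
    from .structure_io import assign_secondary_structure, compute_rsa

    if manifest is None:
        manifest = default_manifest()
    cache: dict[str, tuple] = {}
    rows = []
    for rec in records:
        if rec.pdb_id not in cache:
            s = structures[rec.pdb_id]
            if any(r.ss is None for r in s.residues):
                assign_secondary_structure(s)
            if any(r.rsa is None for r in s.residues):
                compute_rsa(s)
            net = build_rin(s)
            cents = centralities_by_subnetwork(net)
            msa = (msas or {}).get(rec.pdb_id)
            if msa is not None:
                evo = evo_profile(msa, s, net)
            else:
                evo = default_evo_profile(s.length)
            pot = potential_scores(s, net, reference)
            cache[rec.pdb_id] = (s, net, cents, evo, pot)
        s, net, cents, evo, pot = cache[rec.pdb_id]
        rows.append(encode(rec, s, net, evo, pot, manifest, cents).values)
    return np.array(rows)
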