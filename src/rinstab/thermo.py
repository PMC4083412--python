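"""Mesophile/thermophile comparative mutation scanning.

Two homologous structures are aligned globally (Needleman-Wunsch, BLOSUM62,
affine gaps); every aligned, gap-free, substituted column is then predicted
in both directions: mutate the mesophile residue to the thermophile one on
the mesophile structure (MtoT) under mesophile-side pH/temperature, and the
reverse (TtoM) on the thermophile structure.  Each prediction is classified
as a stability increase (ddG < 0 under the positive-destabilizing
convention) or decrease, and tallied by the burial state of the mutated
residue in the structure being mutated.  Columns aligned to a gap are
excluded entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from ._aa import ONE_TO_THREE, THREE_TO_ONE
from .encoding import FeatureManifest, default_manifest, encode
from .model import MutationRecord, TrainedModel, predict
from .structure_io import Structure, classify_exposure

__all__ = [
    "PairAlignment",
    "ScanSummary",
    "needleman_wunsch",
    "bidirectional_scan",
    "hypothesis_report",
]


@dataclass
class PairAlignment:
    seqA: str  # gapped row A
    seqB: str  # gapped row B
    score: float
    identity_count: int
    alignment_length: int
    gap_count: int  # columns containing a gap
    pair_map: list[tuple[int, int]]  # (ungapped posA, ungapped posB), gap-free columns

    @property
    def identity_fraction(self) -> float:
        """Identities over the full alignment length (gap columns included)."""
        return self.identity_count / self.alignment_length


def needleman_wunsch(seq_a: str, seq_b: str, substitution_matrix="BLOSUM62",
                     gap_open: float = 10.0, gap_extend: float = 0.5) -> PairAlignment:
    """Optimal global alignment under affine gap penalties.

    `substitution_matrix` is a matrix name (e.g. "BLOSUM62") or a
    substitution-matrix object.  A gap of length L costs
    gap_open + gap_extend * (L - 1).  The first optimal alignment in the
    aligner's deterministic traversal order is returned.
    """
    for name, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - set(ONE_TO_THREE)
        if bad:
            raise ValueError(f"unknown letters in {name} sequence: {sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution_matrix, str):
        substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.substitution_matrix = substitution_matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    identity = sum(a == b and a != "-" for a, b in zip(row_a, row_b))
    gap_cols = sum(a == "-" or b == "-" for a, b in zip(row_a, row_b))
    pair_map = []
    ia = ib = 0
    for a, b in zip(row_a, row_b):
        if a != "-" and b != "-":
            pair_map.append((ia, ib))
        if a != "-":
            ia += 1
        if b != "-":
            ib += 1
    return PairAlignment(row_a, row_b, float(aln.score), identity, len(row_a),
                         gap_cols, pair_map)


@dataclass
class ScanSummary:
    directions: dict[str, dict] = field(default_factory=dict)  # MtoT / TtoM
    sites: pd.DataFrame | None = None

    def counts(self, direction: str) -> tuple[int, int, float]:
        d = self.directions[direction]
        return d["n_increase"], d["n_decrease"], d["energy_sum"]


def _prepare(s: Structure):
    from .profiles import default_evo_profile, potential_scores
    from .rin import build_rin, centralities_by_subnetwork
    from .structure_io import assign_secondary_structure, compute_rsa

    if any(r.ss is None for r in s.residues):
        assign_secondary_structure(s)
    if any(r.rsa is None for r in s.residues):
        compute_rsa(s)
    net = build_rin(s)
    return net, centralities_by_subnetwork(net), default_evo_profile(s.length), \
        potential_scores(s, net)


def bidirectional_scan(struct_a: Structure, struct_b: Structure, aln: PairAlignment,
                       model: TrainedModel, env_a: tuple[float, float] = (7.0, 25.0),
                       env_b: tuple[float, float] = (7.0, 65.0),
                       manifest: FeatureManifest | None = None) -> ScanSummary:
    """Predict ddG for every substituted aligned column in both directions.

    `struct_a` is the mesophile (direction MtoT mutates it toward B),
    `struct_b` the thermophile (TtoM); env_* are (pH, temperature).
    """
    if manifest is None:
        manifest = default_manifest()
    ungapped_a = aln.seqA.replace("-", "")
    ungapped_b = aln.seqB.replace("-", "")
    for label, ungapped, s in (("A", ungapped_a, struct_a), ("B", ungapped_b, struct_b)):
        if ungapped != s.sequence:
            for i, (x, y) in enumerate(zip(ungapped, s.sequence)):
                if x != y:
                    raise ValueError(f"alignment/sequence mismatch on side {label} "
                                     f"at ungapped position {i + 1}: {x!r} vs {y!r}")
            raise ValueError(f"alignment/sequence length mismatch on side {label}")

    ctx = {"MtoT": (struct_a, env_a, *_prepare(struct_a)),
           "TtoM": (struct_b, env_b, *_prepare(struct_b))}
    rows = []
    for ia, ib in aln.pair_map:
        aa_a, aa_b = ungapped_a[ia], ungapped_b[ib]
        if aa_a == aa_b:
            continue
        for direction, site_idx, target in (("MtoT", ia, aa_b), ("TtoM", ib, aa_a)):
            s, (ph, temp), net, cents, evo, pot = ctx[direction]
            res = s.residues[site_idx]
            rec = MutationRecord(s.pdb_id, s.chain, res.seq_id, res.aa,
                                 ONE_TO_THREE[target], ph=ph, temperature=temp)
            try:
                fv = encode(rec, s, net, evo, pot, manifest, cents)
            except ValueError as exc:
                warnings.warn(f"site {res.seq_id} ({direction}) skipped: {exc}")
                continue
            ddg = float(predict(model, fv.values[None, :])[0])
            rows.append({
                "posA": struct_a.residues[ia].seq_id, "aaA": aa_a,
                "posB": struct_b.residues[ib].seq_id, "aaB": aa_b,
                "direction": direction, "ddg_pred": ddg,
                "exposure": classify_exposure(res.rsa),
            })
    sites = pd.DataFrame(rows, columns=["posA", "aaA", "posB", "aaB",
                                        "direction", "ddg_pred", "exposure"])
    directions = {}
    for direction in ("MtoT", "TtoM"):
        sub = sites[sites["direction"] == direction]
        # positive ddG destabilizes: prediction < 0 is a stability increase
        inc = int((sub["ddg_pred"] < 0).sum())
        directions[direction] = {
            "n_increase": inc,
            "n_decrease": int(len(sub) - inc),
            "energy_sum": float(sub["ddg_pred"].sum()),
            "buried_increase": int(((sub["ddg_pred"] < 0) & (sub["exposure"] == "buried")).sum()),
            "buried_total": int((sub["exposure"] == "buried").sum()),
            "exposed_increase": int(((sub["ddg_pred"] < 0) & (sub["exposure"] == "exposed")).sum()),
            "exposed_total": int((sub["exposure"] == "exposed").sum()),
        }
    return ScanSummary(directions, sites)


def _pct(num: int, den: int) -> float:
    return float("nan") if den == 0 else 100.0 * num / den


def hypothesis_report(summaries: dict[str, ScanSummary]) -> pd.DataFrame:
    """Per-pair and total rows testing the thermostability hypothesis.

    The hypothesis: thermophile-derived variants (MtoT) increase stability
    and mesophile-derived variants (TtoM) decrease it.  Support percentages
    are increase/(increase+decrease) for MtoT and decrease/(...) for TtoM,
    overall and within the exposed/buried classes of the mutated structure;
    empty directions report NaN rather than 0.
    """
    if not summaries:
        raise ValueError("need at least one scan summary")
    rows = []
    tot: dict[str, dict[str, float]] = {d: {k: 0 for k in
                                            ("n_increase", "n_decrease", "energy_sum",
                                             "buried_increase", "buried_total",
                                             "exposed_increase", "exposed_total")}
                                        for d in ("MtoT", "TtoM")}
    for pair, summary in summaries.items():
        row: dict[str, object] = {"pair": pair}
        for d in ("MtoT", "TtoM"):
            vals = summary.directions[d]
            for k in tot[d]:
                tot[d][k] += vals[k]
            row[f"{d}_increase"] = vals["n_increase"]
            row[f"{d}_decrease"] = vals["n_decrease"]
            row[f"{d}_energy"] = round(vals["energy_sum"], 2)
        rows.append(row)
    total_row: dict[str, object] = {"pair": "Total"}
    for d in ("MtoT", "TtoM"):
        total_row[f"{d}_increase"] = tot[d]["n_increase"]
        total_row[f"{d}_decrease"] = tot[d]["n_decrease"]
        total_row[f"{d}_energy"] = round(tot[d]["energy_sum"], 2)
        n = tot[d]["n_increase"] + tot[d]["n_decrease"]
        supporting = tot[d]["n_increase"] if d == "MtoT" else tot[d]["n_decrease"]
        total_row[f"{d}_support_pct"] = round(_pct(supporting, n), 1)
        for cls in ("buried", "exposed"):
            cls_n = tot[d][f"{cls}_total"]
            cls_inc = tot[d][f"{cls}_increase"]
            cls_support = cls_inc if d == "MtoT" else cls_n - cls_inc
            total_row[f"{d}_{cls}_support_pct"] = round(_pct(cls_support, cls_n), 1)
    rows.append(total_row)
    return pd.DataFrame(rows)
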