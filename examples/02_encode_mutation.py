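"""Encode one point mutation as the 184-dimensional descriptor.

Shows the slot-group layout, the ablation variants, and a few informative
slots of a concrete substitution.
"""

from rinstab.datasets import make_fixture_structure
from rinstab.encoding import default_manifest, encode, variant_subset
from rinstab.model import MutationRecord
from rinstab.profiles import default_evo_profile, potential_scores
from rinstab.rin import build_rin
from rinstab.structure_io import assign_secondary_structure, compute_rsa

s, _ = make_fixture_structure("helix", 15, sequence="ACDEFGHIKLMNQRS", pdb_id="h15")
assign_secondary_structure(s)
compute_rsa(s)
net = build_rin(s)
evo = default_evo_profile(s.length)  # neutral: no alignment supplied
pot = potential_scores(s, net)

man = default_manifest()
groups = {}
for _, g in man.slots:
    groups[g] = groups.get(g, 0) + 1
print("manifest groups:", groups, "| total", len(man))
print("ablations: NOCC", len(variant_subset(man, "NOCC")),
      "slots, NORING", len(variant_subset(man, "NORING")), "slots")

rec = MutationRecord("h15", "A", "8", "ILE", "ALA", ph=7.0, temperature=25.0)
fv = encode(rec, s, net, evo, pot, man)
print(f"\nencoded {rec.wt_aa}{rec.position}{rec.mut_aa}: vector length {len(fv)}")
for name in ("ph", "temperature", "ss_H", "rsa", "pot_pairwise", "pot_solvation",
             "net_site_all_degree", "network_size"):
    print(f"  {name:22s} = {fv.values[man.names.index(name)]:.3f}")
# ss_H=1 marks a helical site; rsa is the relative solvent accessibility;
# the potential slots are knowledge-based pseudo-energies of the wild type's
# structural context; network slots summarize the residue's RIN topology.
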