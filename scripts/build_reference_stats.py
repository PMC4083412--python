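"""Regenerate the packaged reference contact/burial statistics.

The shipped table (src/rinstab/data/reference_stats.tsv) is derived from a
fixed, seeded ensemble of synthetic fixture structures; rerunning this
script reproduces it bit-for-bit.
"""

from pathlib import Path

from rinstab.datasets import make_mutation_dataset
from rinstab.profiles import build_reference_stats, save_reference_stats
from rinstab.rin import build_rin
from rinstab.structure_io import compute_rsa

OUT = Path(__file__).resolve().parent.parent / "src" / "rinstab" / "data" / "reference_stats.tsv"
ENSEMBLE_SEED = 20140520  # fixed: defines the shipped reference ensemble


def main() -> None:
    _, structures = make_mutation_dataset(n_structures=40, per_structure=1,
                                          seed=ENSEMBLE_SEED)
    pairs = []
    for s in structures.values():
        compute_rsa(s)
        pairs.append((s, build_rin(s)))
    stats = build_reference_stats(pairs)
    save_reference_stats(stats, OUT)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
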