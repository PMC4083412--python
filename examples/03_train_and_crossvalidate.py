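"""Train the ddG regressor on synthetic mutations and cross-validate.

Generates 400 mutations on fixture structures, simulates a linear ddG
signal with 0.3 kcal/mol experimental noise, runs 10-fold cross-validation
and reports the pooled statistics used for stability benchmarks.
"""

import numpy as np

from rinstab.datasets import make_mutation_dataset, simulate_ddg
from rinstab.encoding import default_manifest, encode_dataset
from rinstab.model import cross_validate, train

records, structures = make_mutation_dataset(n_structures=8, per_structure=50, seed=7)
X = encode_dataset(records, structures)
rng = np.random.default_rng(8)
coef = rng.normal(0, 0.15, X.shape[1]) * (X.std(axis=0) > 0)
coef *= 1.5 / (X @ coef).std()  # ddG spread ~1.5 kcal/mol
y = simulate_ddg(X, coef, noise_sd=0.3, seed=9)

cv = cross_validate(X, y, k=10, seed=10, hidden_units=5)
p = cv["pooled"]
print(f"10-fold CV on {p['n']} synthetic mutations:")
print(f"  Pearson r     = {p['pearson_r']:.3f}")
print(f"  Spearman rho  = {p['spearman_rho']:.3f}")
print(f"  Kendall tau   = {p['kendall_tau']:.3f}")
print(f"  sigma         = {p['sigma']:.3f} kcal/mol")
# r near 1 and sigma near the injected noise (0.3 kcal/mol x model error)
# indicate the 5-hidden-unit network recovers the synthetic signal.

m = train(X, y, hidden_units=5, seed=11, manifest_hash=default_manifest().hash)
print(f"\nfinal model: best epoch {m.best_epoch}, "
      f"validation RMSE {min(m.history['val_rmse']):.3f} kcal/mol "
      f"({len(m.history['val_rmse'])} epochs, early-stopped)")
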