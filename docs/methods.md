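# Methods

This note documents the models, numerical choices and limitations behind
`rinstab`. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external benchmarks.

## Structure model and annotation

PDB input is parsed through Bio.PDB into a light single-chain model: one
selected chain of one selected model (first by default), HETATM records,
waters and non-standard residues excluded, hydrogens retained when
present. Alternate locations resolve to the highest-occupancy conformer,
ties broken by file order. Residue identity follows author numbering
(resSeq + insertion code, as printed in PDB files); coordinates and all
distances are in Å.

**Secondary structure** is a simplified 3-state Kabsch–Sander assignment
implemented in-package rather than by shelling out to an external binary:
the backbone hydrogen-bond energy

    E = 0.084 · 332 · (1/d(O,N) + 1/d(C,H) − 1/d(O,H) − 1/d(C,N))  kcal/mol

uses an ideal amide hydrogen placed 1 Å from N along the previous
residue's C→O direction when no H atom is present (prolines and chain
starts cannot donate); a bond exists when E < −0.5 kcal/mol. Helix (H)
requires two consecutive i→i+4 bonds and labels the four spanned residues;
strand (E) marks both partners of a parallel or antiparallel bridge; helix
takes precedence; everything else — including residues with incomplete
backbones and chains shorter than five residues — is coil. A hook
(`assign_from_dssp`) overrides the internal assignment from a precomputed
DSSP output file, mapping the 8 states onto H/E/C.

**Solvent accessibility** uses Shrake–Rupley sampling (Bio.PDB.SASA; probe
1.4 Å, 92 sphere points, heavy atoms only) summed per residue and
normalized by the Rost & Sander (1994) maximum-ASA table, clipped to
[0, 1]. RSA ≤ 0.25 classifies a residue as buried. The 25% threshold's
sensitivity to the choice of normalization table is a known caveat; the
table is fixed and shipped with the package.

## Residue interaction network

Nodes are residues; edges are typed by geometric rules evaluated on heavy
atoms only (most crystal structures lack hydrogens):

| type | rule | default cutoff |
|---|---|---|
| IAC | closest heavy-atom pair | 5.0 Å |
| HBOND | closest N/O–N/O pair | 3.5 Å |
| IONIC | charged-group atoms, Arg/Lys/His vs Asp/Glu | 4.0 Å |
| PIPISTACK | aromatic ring centroids (Phe/Tyr/Trp/His) | 6.5 Å |
| PICATION | ring centroid to Lys NZ / Arg CZ | 6.0 Å |

The 5 Å closest-atom contact rule is the defining choice; the typed-edge
cutoffs are standard literature values and are configurable, as the
originating network tool's exact per-type geometry (including π-system
angle filters) is not reproduced here. All edges require a chain-order
separation ≥ 2 so covalently adjacent backbones do not dominate the
topology; a residue pair may carry several edge types.

Node topology is computed with networkx on six subnetworks (one per edge
type plus the union, all on the full node set): degree, clustering
coefficient 2·triangles/(deg·(deg−1)), closeness (n_c−1)/Σd within the
node's component, and Brandes betweenness normalized by (n−1)(n−2)/2.
Conventions for degenerate cases are explicit: isolated nodes take
closeness and betweenness 0, clustering is 0 below degree 2. A brute-force
adjacency-matrix implementation (Floyd–Warshall distances, DP path counts,
triangle enumeration) serves as the oracle in tests.

## Evolutionary features and potentials

From a user-supplied FASTA alignment (alignment generation is out of
scope), per structure position: conservation 1 − H/log₂20 with gaps
excluded from the frequencies (all-gap column → 0); plug-in mutual
information in bits over co-ungapped rows, averaged over the position's
network contact partners (sequence neighbors i±1 when no network is
given); and average cluster purity — for each partner column, the modal
frequency of its residues among rows sharing the query's residue at the
site, averaged over partners. These formulas are package definitions,
pinned and unit-tested, behind a provider interface; without an alignment
the features default to conservation 1, MI 0, ACP 1 with a warning, so
prediction degrades gracefully instead of failing.

The statistical potential is a deliberate simplification: two terms
(pairwise contact −log(f_obs(a,b)/f_exp(a,b)) summed over IAC contacts,
and solvation −log(f_obs(a|burial state)/f(a)) on the 25% burial split)
fill the descriptor's potential slots. Full physics-grade reference
potentials are each their own body of work; the slots accept genuine
external per-position scores through a TSV override
(`load_external_scores`). The shipped reference frequencies are counted,
with unit pseudo-counts, over a fixed seeded ensemble of 40 synthetic
fixture structures (`scripts/build_reference_stats.py` reproduces the
table bit-for-bit); they make the scores well-defined and finite, not
physically meaningful — real applications should supply statistics counted
over a structure database.

## The 184-slot descriptor

The manifest is machine-readable (name, group) and hashed; models refuse
to load against a different layout. Group sizes: ENV 2, SEQ_ONEHOT 80
(4 positions × 20, alphabetical three-letter order), LOCAL 4 (H/E/C
one-hot + raw RSA), EVO 3, POTENTIAL 2, NET_CENTRALITY 72 (site/left/right
× 6 subnetworks × 4 measures), NET_COMPOSITION 20, NET_SIZE 1 — total 184.
Terminal sites zero-fill the missing neighbor's one-hot block and
centralities. pH and temperature pass through unnormalized; the model's
input scaling absorbs units. Ablations: NOCC drops all network groups
(91 slots); NORING keeps ENV, one-hots, local context, conservation, the
potential slots and the network size (90 slots) — the network size doubles
as a protein-length feature there.

## Regressor and training

ŷ = w₂ᵀ·tanh(W₁x + b₁) + b₂ with 5 hidden units; an `identity` activation
option exposes the exact linear limit for validation. Inputs and target
are range-scaled to [−1, 1] by training-split min/max (the convention of
classic MLP trainers that also normalize a numeric class attribute);
predictions are mapped back to kcal/mol.

Training minimizes squared error by mini-batch gradient descent (batch 32,
seeded shuffling) with per-parameter adaptive moments (AMSGrad variant:
first-moment decay 0.9, second-moment decay 0.999 with a running max, step
0.01). Input-layer weights start from uniform(−0.5, 0.5)/√d so the tanh
units begin in their linear regime; the output layer starts at zero (the
scaled-target mean). Plain fixed-rate backpropagation was tried first and
rejected on evidence: a 0.3 per-sample rate diverges on this 184-column
design (the linear limit violates the step-size stability bound), and
saturated units slow convergence enough that early stopping fires long
before the signal is learned.

Early stopping holds out 15% of the rows (seeded shuffle) as a validation
set and stops after 5 consecutive epochs without a new validation-RMSE
minimum (tolerance 1e-6), returning the best-validation parameters.
Epochs are scored on a Polyak-style exponentially averaged iterate (decay
0.9), so the patience rule measures a true plateau rather than mini-batch
noise. Cross-validation partitions samples into k seeded folds
(round-robin over a permutation); each sample is predicted exactly once by
a model that never saw it, and fold seeds derive from the CV seed.

Sign convention: positive ΔΔG = destabilizing, matching the dominant
convention of curated stability datasets; the thermodynamic definition
ΔΔG = ΔG_wt − ΔΔG_mut has the opposite sign under some conventions, so the
choice is a config flag (`sign_convention`) rather than a constant.
Models serialize to a versioned JSON text format including scalers,
history and the manifest hash.

## Dataset handling and synthetic fixtures

Mutation tables are plain TSV (pdb_id, chain, position, wt, mut, ph, temp
[, ddg]); duplicate keys average their ΔΔG with a warning, and wt == mut
rows are rejected. Curation mirrors standard stability-training filters:
proline variants dropped, and variants destabilizing by more than
5 kcal/mol dropped — one-sided on the destabilizing side of the configured
sign convention, not a symmetric cut. Filters are idempotent and every
rejection is logged with its rule.

The fixture generator builds ideal-geometry structures from internal
coordinates (NeRF chain construction; bond lengths/angles at standard
values): an α-helix (φ=−57°, ψ=−47°; consecutive CA–CA ≈ 3.8 Å), a fully
extended chain (φ=ψ=180°), a flat antiparallel β-hairpin assembled
analytically so the inter-strand N···O geometry (≈2.9 Å) satisfies the
hydrogen-bond energy criterion, and an occlusion cage (one residue
enclosed by a 4 Å Fibonacci sphere of atoms) for burial tests. The
synthetic mutation dataset draws random non-proline sequences on
helix/hairpin folds (lengths 14–24), then random substitutions with pH in
[5, 9] and T in [15, 45] °C; ΔΔG targets are simulated as a linear signal
in the encoded features (spread ≈ 1.5 kcal/mol, the scale of typical
experimental ΔΔG distributions) plus Gaussian noise of 0.3 kcal/mol,
approximating experimental reproducibility. What passing tests show is
that the pipeline is self-consistent and the trainer recovers a known
signal at realistic noise; they do not show real-data accuracy, which
depends on curated experimental tables and real structures that are
deliberately not bundled.

## Thermophile scan

Homolog pairs are aligned globally (Bio.Align PairwiseAligner;
Needleman–Wunsch with BLOSUM62, gap open 10, extend 0.5 — a gap of length
L costs open + extend·(L−1)); identity is counted over the full alignment
length including gap columns. Columns aligned to a gap are excluded
entirely. Every substituted gap-free column is predicted twice: mutating
the mesophile residue to the thermophile one on the mesophile structure
under mesophile-side pH/T (MtoT), and the reverse on the thermophile
structure (TtoM). A prediction < 0 counts as a stability increase under
the positive-destabilizing convention. Exposed/buried tallies use the RSA
of the structure being mutated — either side could reasonably define
exposure, so the choice is pinned and documented here. Empty directions
report percentages as NaN, never 0.

## Problem sizes and determinism

Default test and acceptance runs use desk-scale inputs chosen as the
package's own study conditions: 1000 synthetic mutations on 20 fixture
structures for parameter recovery, 100 random graphs (≤ 30 nodes) for the
centrality oracle, 50 random short sequence pairs for the alignment
oracle, and 1000 vector pairs for the τ oracle. Every random draw flows
from an explicit seed; rerunning any command with the same seed reproduces
its outputs byte-for-byte.

## Known limitations

- Single chains only; no mmCIF; no inter-chain edges.
- The typed-edge geometry is distance-only (no angular filters), and the
  shipped potential statistics are synthetic-ensemble placeholders.
- 3-state secondary structure only (no 8-state classes).
- The evolutionary-feature formulas are package definitions; upstream
  tools may define conservation/MI/ACP differently.
- No alignment generation (PSI-BLAST etc.); the MSA is a user input.
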