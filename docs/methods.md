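# Methods

## Scope and model

`raspdplus` predicts protein–ligand binding free energies (ΔG, kcal/mol)
from pose-invariant physicochemical descriptors and screens compound
libraries by ranking predicted ΔG. The descriptor set, the nested
cross-validation protocol, the permutation importance analysis, and the
enrichment machinery are the substance of the package; the individual
regressors are standard scikit-learn estimators behind a uniform interface.

## Affinity conversion

Kd, Ki, and IC50 values (converted to molar from M/mM/uM/nM/pM inputs) are
mapped to free energies as ΔG = RT ln K with R = 1.9872×10⁻³ kcal/(mol K)
and T = 298.15 K, so sub-molar affinities give negative (favorable) ΔG —
a nanomolar binder maps to −12.28 kcal/mol. All three affinity types are
treated identically; when one complex carries several measurements the
precedence is Kd over Ki over IC50 (decreasing thermodynamic directness),
breaking ties toward the stronger value. Complexes with a metal ion within
2.1 Å of any ligand atom (plain center–center distance, boundary
exclusive-keep) are discarded: metal coordination is outside the model. The
default metal set {Li, Na, K, Mg, Ca, Mn, Fe, Co, Ni, Cu, Zn, Cd, Hg} is
configurable.

## Ligand descriptors

* **MASS** — average molecular weight, implicit hydrogens included.
* **D, A** — donor/acceptor *atom* counts (not hydrogen counts). Donors: N
  or O bearing at least one hydrogen. Acceptors: all N and O except nitro
  nitrogens and oxygens and pyrrole-type aromatic N–H (ring-delocalized
  lone pair). The rule set is fixed so every count is hand-checkable;
  e.g. acetamide: D = 1 (amide N), A = 2 (carbonyl O + amide N).
* **logP, MR** — sums of Wildman–Crippen atomic contributions, computed via
  RDKit's implementation of the published table. Tests pin hand-summed
  values (methane: one aliphatic C at 0.1441/2.503 plus four H at
  0.1230/1.057).
* **W** — Wiener index on the heavy-atom graph (hydrogen placement must not
  change a topological descriptor). Disconnected graphs sum within
  components with a warning; multi-fragment inputs (salts) are first reduced
  to the largest covalent fragment.
* **maxD** — the largest atom distance from the mass-weighted center of mass
  over all atoms present. It is not a model feature; it sizes the pocket
  spheres. SMILES inputs get a single ETKDG conformer from a fixed seed so
  maxD is reproducible; all other ligand descriptors are coordinate-free.

## Pocket descriptors

A sphere is centered on the binding site — the reference ligand's center of
mass, or a user-supplied point. Residues with mass-weighted center of mass
within maxD + 0.9 Å (inclusive) contribute Crippen logP/MR; atoms within
maxD + 3.0 Å contribute donor/acceptor counts. The aromatic residue split
uses {PHE, TRP, TYR, HIS}.

Per-residue Crippen totals are precomputed from ACE-X-NME capped dipeptides
(neutral side chains), summing RDKit per-atom contributions over the central
residue with hydrogens attributed to their heavy atom. Totals therefore
depend only on residue identity — deliberately, since residues are selected
whole by center of mass and crystal structures resolve variable atom
subsets. Protonation variants (HID/HIE/HIP, ASH/GLH, CYX, LYN) share the
parent totals.

Donor/acceptor counting uses a fixed (residue, atom-name) mapping table:
backbone N (except proline) → PD(Amide-NH); backbone O → PA(Amide-O);
side-chain assignments follow the nine chemical groups. Choices where the
grouping is genuinely ambiguous:

* Lysine NZ belongs to the positively charged donor group only, never the
  neutral amino group — no atom is counted twice within the donor family.
* Hydroxyl oxygens (Ser/Thr/Tyr) appear once among donors and once among
  acceptors; the donor and acceptor families are separate descriptor sets.
* Without hydrogens, neutral histidine is taken as the NE2–H tautomer
  (NE2 donates, ND1 accepts); HID reverses this, HIP donates from both ring
  nitrogens and accepts with neither. Protonated Asp/Glu donors require the
  explicit ASH/GLH residue names — a plain ASP/GLU is never guessed to be
  protonated.
* Unknown residue names contribute backbone donor/acceptor counts only and
  nothing to PMR/PlogP; a warning is emitted.

The thirteen residue-derived values are divided by maxD (size
normalization). PVol is not residue-derived and stays unscaled.

**Pocket volume** is a grid-probe calculation standing in for a cavity
analysis: count grid points (default spacing 0.5 Å) inside the maxD sphere
farther than (vdW radius + 1.4 Å probe) from every protein heavy atom, times
the cell volume. Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80 Å,
default 1.70). The estimate converges to analytic values as the grid is
refined: an empty sphere is reproduced within 0.5 % at 0.25 Å spacing, a
half-space wall within a few percent. Test fixtures place exclusion surfaces
*between* grid planes: a surface coinciding with a grid plane makes an
entire slab of points flip on float rounding, which is a property of any
grid estimator, not an error.

Pose invariance is a contract, not an accident: the pocket pipeline receives
only (protein, center, maxD), so two conformers with equal maxD necessarily
give identical descriptors, and the test suite asserts this end to end.

## Training protocol

Nested cross-validation: for each of 10 replicates, a random 12.5 % of rows
(`round(n × 0.125)`) is held out as the test set; the remaining pool is
split into 6 shuffled, near-equal folds. A grid search maximizes the mean
inner-validation Pearson r; ties go to the simplest candidate (fewest trees,
strongest regularization, largest k), then lexicographic order, so selection
is deterministic. The winning configuration is trained once per fold and all
six fold models are evaluated on the replicate's test rows — 60 models per
method — reporting mean ± sd. Scaling (median/IQR of the training rows;
constant columns are centered only, with a warning) is fitted inside every
fold, so no test information reaches training; a dedicated test corrupts the
held-out rows and verifies that fitted coefficients do not move.

Default hyperparameter grids (config-exposed): kNN k ∈ {1,3,5,7,11,15,21};
SVR C ∈ {0.1,1,10,100}, ε ∈ {0.01,0.1,0.5}, RBF γ ∈ {scale,0.01,0.1};
RF/eRF trees ∈ {100,200,500}, max features ∈ {all, √p}; DNN two hidden
layers with 32/64/128 units. The eRF default is 200 trees with unrestricted
leaves. The DNN is scikit-learn's MLPRegressor; it has no dropout layer, so
L2 weight decay (α ∈ {10⁻⁴,10⁻²}) plays the analogous regularization role in
its grid. The DNN is opt-in — it is the slowest learner and nothing
downstream depends on it. Protocol-level tests and the acceptance script run
the forests with single-point grids (100–200 trees): the 10 × 6 = 60 model
count and the evaluation contract are independent of grid size, and this
keeps a full protocol run on one CPU in the minutes range.

### Metrics

RMSE, Pearson r, Spearman ρ, R² (test-mean denominator), and the external
validation coefficient

Q²F3 = 1 − [Σ_test (ŷ−y)² / n_test] / [Σ_train (y−ȳ_train)² / n_train].

The training-variance denominator makes the null model score ≈ 0 and is the
default. An alternative reading — dividing by the test-set sum of squared
deviations of predictions from the training mean — is available as
`qf32_variant="test-denominator"`; the two disagree in general and the
choice is surfaced rather than silent. Constant targets yield NaN
correlations (markers, not exceptions). The null model's RMSE equals the
test-set spread around the training mean by construction; tests assert the
identity algebraically.

## Importance and ablation

Permutation importance shuffles one test-set column at a time (five seeded
shuffles), re-predicts, and records baseline-minus-shuffled Pearson r;
positive means performance drops without the feature. Shuffling happens in
the test split only and the model is never touched. Importances are not
additive and no sum-to-baseline property is asserted. Ablation retrains the
identical protocol on named subsets: MR only, MASS only, ligand only (6),
protein only (14), all (20).

## Screening and enrichment

Each library molecule is featurized independently — its own ligand
descriptors and its own maxD-sized pocket sphere at the fixed center — so a
molecule's score never depends on the rest of the library. Scores are the
mean prediction of one replicate's six fold models (replicate 0 by default,
configurable). The enrichment factor at x % selects ⌈x/100 · n⌉ best-scored
molecules (ceil keeps 1 % selections nonempty for small libraries; score
ties break stably by molecule id) and divides the active fraction of the
selection by the active fraction of the library. Union ensembles pool the
top sets of several methods and compute the EF with the union size as the
selection; presets cover all seven methods, all-but-kNN, and the
{LR, lSVR, SVR} trio. A diagnostic flag reports non-water hetero atoms
inside the residue-selection sphere (cofactor-occupied pockets are a known
failure mode); surface-site detection is out of scope.

## Synthetic data

The generators exist so every stage is testable without external downloads.

* **Toy complexes** pair a fixture ligand (ten hand-checkable molecules:
  methane through aspirin) with idealized residue templates placed at
  controlled center-of-mass distances (e.g. maxD + 0.5 Å) in seeded random
  directions. Expectation sidecars are computed by independent oracle code —
  networkx breadth-first Wiener sums, a separately hand-tabulated
  donor/acceptor map, analytic sphere volumes — never by the modules under
  test. The residue templates are geometric placeholders with correct atom
  names, not structural models.
* **Feature tables** draw twenty plausibly scaled descriptor columns
  (counts as Poisson/gamma, MASS ≈ 350 ± 70 g/mol, MR ≈ 90 ± 18, PVol in the
  hundreds of Å³) with a shared latent size factor coupling MASS/MR/W/PVol,
  mimicking the strong size correlations of real complex sets. The target is
  y = β·x + interactions + ε with known β; the default β gives ΔG in the
  −15…−6 kcal/mol range with 1 kcal/mol noise. Interaction terms act on
  z-scored columns so their coefficients are in kcal/mol per sd².
* **Screening libraries** distinguish actives from decoys by molecular size
  (hence MR), matched to models trained on MR-driven targets.

What passing these tests shows — and does not: the pipeline is internally
consistent, leak-free, deterministic under a seed, and recovers planted
signal of realistic scale. Synthetic tables cannot certify accuracy on real
protein–ligand data, where descriptor–affinity relationships are noisier and
nonlinear in ways no generator reproduces; benchmarking against curated
affinity sets remains the user's task.

## Numerical choices and limitations

* Sphere boundaries are inclusive (≤); centers of mass are mass-weighted
  over the atoms present.
* altLoc conformers resolve to highest occupancy, ties alphabetically; only
  the first MODEL of a multi-model file is read.
* LR on singular designs returns the minimum-norm least-squares solution.
* Learners that fail on a grid point are recorded and excluded from
  selection with a warning rather than aborting the search.
* Seeds: every stochastic component (splits, shuffles, embeddings, forests)
  derives from explicit integer seeds; reports are reproducible in their
  numeric content.
* Not modeled: metal coordination, cofactors and structural waters,
  protonation-state assignment, tautomer enumeration, conformer ensembles,
  covalent ligands, pocket flexibility.
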