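# Methods

## Scope and model

The package predicts hot spot residues — interface residues whose mutation
to alanine raises the binding free energy by at least a threshold
(default ΔΔG ≥ 2.0 kcal/mol, the convention of the alanine-scanning
literature; the comparison is inclusive) — from the structure of a
protein–protein complex and a user-supplied chain split. The model is a
heavy-atom model: hydrogens are neither read nor placed, so the
hydrogen-bond term operates on donor–acceptor heavy-atom distances. Only
the first MODEL of a PDB file is used; altloc `A`/blank atoms are kept;
HETATM records and waters are dropped. Insertion codes are preserved as
string suffixes on residue numbers end-to-end.

A residue is a prediction candidate when at least one of its heavy atoms
lies within the **contact cutoff** (default 5.0 Å) of a heavy atom of the
partner side, its type is not Ala/Gly/Pro, it has a Cβ, and at most two of
its side-chain heavy atoms are missing (residues failing the last two
conditions are skipped with a warning rather than imputed — rebuilding
coordinates would put model bias directly into the features).

## Energy features

For a candidate residue, three regions are built around its Cβ with the
**shell radius** (default 10.0 Å): (a) its side chain beyond Cβ, (b)
same-side shell atoms excluding the residue's own backbone+Cβ and region
(a), (c) partner-side shell atoms. Each of the four pair potentials is
summed over a×c, b×c and a×b; the b×c "environment" term therefore
excludes the mutated side chain by construction, so it measures the
interface context that survives the mutation.

Functional forms (constants live in `EnergyConfig`, one block, so a
different parameterization needs no code changes):

* **Lennard-Jones 12-6**: ε_ij = √(ε_i ε_j), r_min,ij = r_i + r_j; each
  pair is capped at +10 kcal/mol so one steric clash in an experimental
  structure cannot saturate a feature.
* **Hydrogen bond 12-10**: depth 2.0 kcal/mol at r₀ = 2.9 Å, zero outside
  2.0–3.5 Å, evaluated for both donor→acceptor orientations of a pair;
  no angular weighting (without hydrogens an angle would itself be a
  modelled quantity).
* **Coulomb**: 332.0637·q_iq_j / (ε(r)·r) with ε(r) = 4r, the standard
  cheap screening model for protein interiors.
* **Desolvation**: symmetric Gaussian solvent-exclusion
  (EEF1-style), E = −f(i,j) − f(j,i) with
  f(i,j) = ΔG_free,i /(2π^{3/2} λ_i r²)·exp(−((r − r_min,i)/λ_i)²)·V_j,
  cut off at 9.0 Å. LJ/Coulomb/H-bond terms carry no extra pair cutoff —
  the regions are already spatially bounded by the shell.

Per-atom parameters (LJ radius and depth, simplified partial charges on
polar and charged groups, EEF1-like ΔG_free/λ/volume, donor/acceptor
flags) come from a bundled whitespace-delimited table
(`src/hotspots/data/atom_params.tsv`, one row per residue/atom name;
regenerable with `scripts/make_atom_params.py`). Users can substitute any
table with the same columns. Atoms absent from the table get neutral
element-based fallback parameters with a logged warning. The charges are
deliberately coarse (integral charges spread over terminal groups):
features enter a trained classifier, so only their ranking information
matters, not absolute energies.

## Classifiers

All classifiers are soft-margin **linear SVMs** (hinge loss, L2
regularization; scikit-learn's liblinear backend with a fixed seed) over
z-scored features, with an asymmetric class cost on the positive class
because hot spots are the minority (grids: C ∈ {0.01, 0.1, 1, 10, 100},
positive-class weight ∈ {1, 2, 5}; the neutral weight 1 is in the grid, so
imbalance costing is a tunable, not an assumption). A fitted model is
exported as feature names, weights, decision threshold and the
standardization statistics — scoring is a dot product minus threshold and
never calls the training backend; serialized weight tables reproduce
backend decision values to 1e−6. The decision rule is strict: a score of
exactly 0 is a non hot spot.

The deployed ensemble routes by wild type: Glu → Glu specialist, Arg →
Arg specialist, the other 15 mutable types → general model. The general
model uses the features whose |Pearson r| with observed ΔΔG exceeds
**r_min = 0.2**. Specialist subsets are chosen by exhaustive enumeration
of all 3- and 4-feature subsets of the baseline set containing no
redundant pair (|r| > **r_max = 0.8**), for Arg additionally each subset
extended by the intra-molecular Coulomb term. Per candidate subset,
hyper-parameters are optimised by pooled inner-CV F1 over *all* mutations;
the winner maximises pooled inner-CV F1 restricted to the target amino
acid, with ties broken toward the smaller, canonically earlier subset.
Pooling inner-fold predictions (rather than averaging per-fold F1) was
chosen because per-amino-acid strata are small and per-fold F1 would often
be degenerate. If a training fold's baseline set is smaller than the
requested subset sizes, or the redundancy constraints exclude every
combination, the baseline set itself becomes the single candidate — the
search degrades gracefully instead of failing on sparse folds.

## Cross-validation

Homologous complexes share a cluster label (clustering is an input, not
computed here). `make_cluster_folds` shuffles clusters by seed and deals
them round-robin: outer folds default to leave-one-cluster-out, inner
folds to k = 3 within each outer training set. Fold plans are validated at
construction: no cluster on both sides of any fold, outer tests partition
the clusters, inner folds never contain outer-test clusters.
Standardization, the correlation filter, hyper-parameter search and
subset selection are all re-run per outer fold on training rows only;
the run records every row index touched during training, and `nested_cv`
raises if any outer-test row appears in that set. Ensemble mode with an
empty specialist list reproduces general mode exactly (verified in tests).
An optional detector (`detect_specialist_aas`) flags amino acids whose
inner-CV F1 under the general model falls below a floor (default 0.35),
but the shipped default hard-codes {Arg, Glu} as the specialist set.

Metrics use zero-denominator conventions P, R, F1, MCC := 0, chosen for
robustness in small per-amino-acid strata where a marginal can be empty.

## Synthetic data

`generate_feature_dataset` draws the 12 features from a seeded
multivariate normal (identity covariance by default; a user-supplied
covariance must be positive definite) and derives
ΔΔG = 1.5·(w*·x − b) + ε. When no offset is given, b is calibrated so
hot-spot prevalence is ≈ 22.5 %, the minority-class regime of real
alanine-scanning compilations; default ΔΔG noise is 0.5 kcal/mol and 5 %
of labels are flipped. Rows cycle round-robin through the requested
clusters (8 by default), and per-amino-acid weight overrides can plant
signal a single general classifier cannot capture — used to demonstrate
the specialist gain on Glu. What this generator does *not* emulate:
feature correlations induced by shared geometry, cluster-level feature
shifts, and the long-tailed ΔΔG distribution of real data; passing tests
on it demonstrates correctness of the machinery and recoverability of
planted signal, not real-data accuracy.

`generate_toy_complex` builds two idealized chains on parallel axes
(Cα spacing 3.8 Å, default axis separation 10 Å) with procedurally placed
backbone and side-chain atoms plus small Gaussian jitter (default
0.05 Å). "Planted" residues point their side chains across the gap so the
tip sits 5.3 Å from the partner axis — ≈3.8 Å from the facing residue's
Cβ, near the LJ minimum, guaranteeing a favorable sub-4 Å cross-side
contact; all other side chains point away. The geometry is cartoonish by
design (bond lengths along interpolated side chains are not physical);
the energy terms only require finite, contact-bearing, clash-capped
coordinates, and the generator is a pure function of its spec, emitting
byte-identical PDB text per seed.

## Problem sizes

The test suite and acceptance script use synthetic datasets of 300–500
rows over 6–8 clusters, 4–8 outer folds, and reduced hyper-parameter
grids (C ∈ {0.1, 1, 10}, class weight ∈ {1, 2}) for the subset-search
loops; these sizes give stable planted-truth recovery (weight cosine
> 0.97 across seeds) while keeping the full enumeration-inside-nested-CV
protocol intact. Brute-force energy oracles run on 200 random ≤50-atom
sets; fold-hygiene checks cover 100 seeded plans.

## Known limitations

* No side-chain repacking or relaxation after the modelled mutation; the
  features describe the wild-type environment only.
* Distance-dependent dielectric and Gaussian desolvation are coarse
  electrostatics; no PB/GB, no entropy terms.
* The bundled parameter table is simplified and not a validated force
  field; published per-complex accuracies are not reproducible without
  the original mutational compilation and curated structures.
* Homology clustering must be supplied by the user; mis-clustered inputs
  silently weaken the train/test separation guarantee.
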