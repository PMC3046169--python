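# hotspots

Structure-based prediction of **hot spot residues** at protein–protein
interfaces.

Alanine-scanning mutagenesis shows that the free energy of binding of a
protein–protein complex is dominated by a small subset of interface
residues: mutating one of these *hot spots* to alanine raises the binding
free energy by ΔΔG ≥ 2 kcal/mol and can disrupt the interaction, while most
interface mutations are nearly neutral. Locating hot spots computationally
maps the functional epitope of an interface and is a natural first step in
the rational design of protein–protein interaction inhibitors. This package
predicts hot spots from the structure of a complex alone, for structural
biologists and method developers who need a transparent, fully inspectable
linear scoring function rather than a black box.

## Model

Given a complex split into two sides by chain identifiers, every candidate
interface residue (any heavy atom within 5 Å of the partner side; Gly, Pro
and Ala excluded) is described by **12 energetic features**. Three atom
regions are defined around the mutated residue:

* **(a)** its side-chain atoms beyond Cβ (the atoms an alanine mutation removes),
* **(b)** same-side atoms within a 10 Å shell of its Cβ (excluding the residue itself),
* **(c)** partner-side atoms within that shell.

Four pairwise molecular-mechanics terms — a 12-6 Lennard-Jones potential, a
12-10 hydrogen-bond well on heavy-atom donor–acceptor distances, Coulomb
electrostatics with a distance-dependent dielectric ε(r) = 4r, and a
Gaussian solvent-exclusion desolvation term — are summed over the pairings
a×c (*side-chain inter-molecular*), b×c (*environment inter-molecular*,
which deliberately excludes the mutated side chain) and a×b (*side-chain
intra-molecular*), giving 4 × 3 = 12 features in kcal/mol.

Features are z-scored and scored by a linear SVM scoring function

```
s(x) = Σ_k w_k x_k − b,        hot spot ⇔ s > 0
```

exported as an explicit weight table, so predictions never require the
training backend. Because a single general classifier performs worst on
arginine and glutamic-acid mutations, the deployed model is an **ensemble
of three**: a general classifier built on the features whose absolute
Pearson correlation with observed ΔΔG exceeds 0.2, plus Arg and Glu
specialists. The specialists are trained on *all* mutations (there are too
few Arg/Glu examples alone) but use a small feature subset chosen by
enumerating every 3- or 4-feature combination of the baseline features that
contains no highly correlated (|r| > 0.8) pair — for Arg optionally
extended by the intra-molecular Coulomb term — and keeping the subset with
the best cross-validated F1 on the target amino acid. Predictions are
routed by wild-type residue: Glu → Glu model, Arg → Arg model, everything
else → general model.

Evaluation uses **homology-cluster-aware nested cross-validation**: related
complexes share a cluster label, outer folds are cut along cluster
boundaries (leave-one-cluster-out by default), and hyper-parameters *and*
specialist feature subsets are chosen inside inner folds only. Performance
is summarised by precision P = TP/(TP+FP), recall R = TP/(TP+FN), their
harmonic mean F1 = 2PR/(P+R), and the Matthews correlation coefficient

```
MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
```

A synthetic-data module generates toy two-chain complexes with planted
contacts and feature datasets with planted linear ground truth, so the
whole pipeline is testable without structure downloads.

## Worked example

Train the three-classifier ensemble on six toy complexes with known
planted hot spots, then score a fresh complex:

```python
from hotspots import (read_complex, build_feature_table, fit_full_ensemble,
                      predict_complex, TrainingConfig)
from hotspots.synthetic import ToyComplexSpec, demo_training_set, generate_toy_complex

# six toy complexes with known planted hot spots, one homology cluster each
complexes, mutations = demo_training_set(n_complexes=6, seed=0)
loaded = {cid: read_complex(text, {"A"}, {"B"}) for cid, text in complexes.items()}
table = build_feature_table(loaded, mutations)
config = TrainingConfig(C_grid=(0.1, 1.0, 10.0), class_weight_grid=(1.0, 2.0))
ensemble, detail = fit_full_ensemble(table, config)
print("baseline features:", detail["baseline_features"])
print("Glu specialist subset:", detail["subset_E"])

# score a fresh complex with a single planted hot spot at A/5
probe, truth = generate_toy_complex(ToyComplexSpec(
    chains={"A": "NKSWERYTQLD", "B": "LNDYKERWSTQ"},
    separation=10.0, planted={"A": {4: None}}, seed=99))
predictions = predict_complex(ensemble, read_complex(probe, {"A"}, {"B"}))
print(predictions.to_string(index=False))
print("planted hot spot:", truth["planted"])
```

Output:

```
baseline features: ('vdw_sc_inter', 'desolv_sc_inter', 'vdw_env_inter', 'desolv_env_inter', 'hbond_sc_intra', 'desolv_sc_intra')
Glu specialist subset: ('vdw_sc_inter', 'vdw_env_inter', 'desolv_env_inter')
chain resnum wt_aa     score  hotspot_call
    A      5     E  1.357652             1
    B      5     K -0.666207            -1
planted hot spot: [('A', '5', 'E')]
```

The correlation filter picked six informative features from the toy
training energies (the hydrogen-bond inter-molecular terms carry no
variance in these idealized geometries and are dropped), the Glu
specialist settled on a 3-feature subset, and on the fresh complex the
planted strong-contact residue A/5 gets a positive score (predicted hot
spot) while the weak-contact partner residue scores negative.

The same pipeline is available from the shell:

```bash
hotspots synth complex --plant A:4 --seed 99 -o probe.pdb
hotspots predict probe.pdb --side1 A --side2 B --model bundle/ -o predictions.tsv
hotspots train --mutations muts.tsv --pdb-dir pdbs/ --complexes sides.tsv -o bundle/
hotspots cv --features features.tsv --mode ensemble -o report/
```

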