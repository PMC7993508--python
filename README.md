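# ifpscore

Interpretable protein–ligand binding-affinity scoring from per-residue
interaction fingerprints and ligand fragment descriptors.

## The problem

Docking scoring functions and 3D-grid deep models predict binding
strength well but are hard to interpret: the features do not map back
onto anything a medicinal chemist recognises.  `ifpscore` takes the
opposite route.  A protein–ligand complex is encoded by *counting*
recognisable contacts and substructures:

* **IFP** — an interaction fingerprint over the 20 standard amino
  acids × 7 interaction classes (hydrophobic contact, aromatic
  face-to-face and edge-to-face stacking, H-bond accepted by the
  ligand, H-bond donated by the ligand, and ionic contacts with a
  negatively or positively charged ligand atom).  Each class fires at
  most once per residue, so the cell (ARG, H-bond) holds 2 exactly
  when two arginines H-bond the ligand.  The vector has
  20 × 7 = 140 cells.
* **Int-Dist** — for every occupied cell, the closest qualifying
  contact distance in Å (140 more entries, 280 in total).
* **Frag** — substructural molecular fragment counts of the ligand:
  simple paths of 2–6 heavy atoms (`C-C-O`, `c:c:c`, …) and augmented
  atoms (an atom with its bonded neighbours, `C(-C)(-O)`), indexed by a
  dictionary frozen over the training set.

A random forest (prediction = mean over bagged regression trees) or a
dense network (input → 400 → 200 → 100 → 1 with batch-norm, ReLU and
dropout; SGD with learning rate 0.001, decay 1e-6, momentum 0.9) maps
the features to pKd/pKi.  The network epoch is selected on a composite
validation loss

    LOSS = α·(1 − PCC) + (1 − α)·RMSE

which balances ranking ability (Pearson correlation) against absolute
error and stops training before over-fitting.  Reported metrics are
RMSE, MAE, PCC (with two-sided p-value) and Spearman ρ.

Interactions are detected geometrically from typed atoms
(distance cutoffs, ring-plane angles, donor–H–acceptor angles; all
thresholds configurable through `GeometricRules`), so every prediction
can be traced back to a per-residue contact table — the `profile`
command emits it directly.

## Worked example

Build a toy complex with planted interactions, detect them, and train a
forest on a synthetic linear dataset:

```python
import numpy as np
from ifpscore import *

spec = PlantSpec(planted=[("ARG", "IONIC_LIG_NEG", 3.0),
                          ("ARG", "HBOND_ACC_LIG", 3.1),
                          ("PHE", "AR_F2F", 3.6)], decoys=2, seed=0)
protein, ligand, expected = make_toy_complex(spec)
for r in detect_interactions(protein, ligand):
    print(f"{r.residue_name} {r.residue_id[1]:>3} "
          f"{r.interaction_class:<14} {r.distance:.2f} A")

w = np.zeros(140); w[0] = 3.0     # affinity = 3 * ALA-hydrophobic count
ds = make_synthetic_dataset(SyntheticDatasetSpec(n=500, weights=w,
                                                 noise_sigma=0.1, seed=42))
train, test = split_dataset(ds, ratio=0.8, seed=1)
results = RandomForestAffinity(train, RFConfig(n_estimators=100,
                                               random_state=1)).fit()
print(results.evaluate(test))
```

prints

```
ARG   1 IONIC_LIG_NEG  3.00 A
ARG   2 HBOND_ACC_LIG  3.10 A
PHE   3 HYDROPHOBIC    3.60 A
PHE   3 AR_F2F         3.60 A
N=100  RMSE=0.1200  MAE=0.1001  PCC=0.9992 (p=2.431e-139)  Sp=0.8929
```

The planted ionic, H-bond and stacking contacts are recovered at their
construction distances (the eclipsed aromatic stack necessarily also
yields a hydrophobic contact), and the forest recovers the linear
signal down to the noise floor (σ = 0.1 → RMSE ≈ 0.12).

The same pipeline is available from the shell:

```bash
ifpscore fixtures --seed 3 --n-complexes 12 --out fx/
ifpscore build-dict --index fx/index.csv --out frags.json
ifpscore train --index fx/index.csv --features ifp+frag \
         --dict frags.json --model-type rf --seed 1 --out model.joblib
ifpscore profile --protein fx/toy000/protein.pdb \
         --ligand fx/toy000/ligand.sdf
```

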