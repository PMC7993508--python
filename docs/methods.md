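# Methods

## Interaction model

A complex is reduced to per-residue contact events.  Atoms are typed
pharmacophorically; for protein residues the typing is a fixed table
keyed by residue and atom name (LYS NZ and the arginine guanidinium
nitrogens are cations; ASP/GLU carboxylates and C-terminal OXT are
anions; PHE/TYR/TRP/HIS carry aromatic rings; serine/threonine/tyrosine
hydroxyls, amide nitrogens, tryptophan NE1, cysteine SG and every
backbone amide are neutral donors; hydroxyls, amide oxygens, histidine
ring nitrogens, methionine SD and every backbone carbonyl are neutral
acceptors; side-chain carbons with no N/O neighbour, plus the
methionine thioether, are hydrophobic).  Ligand atoms are typed from
element, formal charge, aromaticity and neighbours: carbons bonded only
to carbon (and halogens) are hydrophobic, N/O with at least one
hydrogen are donors, oxygens and hydrogen-free nitrogens are acceptors,
and charged atoms are ions.  Two deliberate conventions:

* **Charged groups are ions only.**  A formally charged atom is
  excluded from the neutral donor/acceptor sets, so a salt bridge
  registers as a single ionic contact rather than ionic + H-bond.
  Each contact is therefore assigned its strongest class once, which
  keeps the fingerprint additive and the counts interpretable.
  Carboxylates are symmetrised: when a file localises the charge on
  one oxygen, the sibling oxygen is typed anionic as well.
* **Histidine** is aromatic always, and cationic only when both ring
  protons are present in the structure.

Seven classes are detected pairwise under geometric rules (defaults in
parentheses, all configurable and recorded with any output):
hydrophobic atom pair within cutoff (4.5 Å); aromatic face-to-face
(ring-centroid distance ≤ 4.0 Å, interplanar angle ≤ 30°) and
edge-to-face (centroid ≤ 5.5 Å, angle 60–90°); H-bonds by
donor–acceptor distance (≤ 3.5 Å) with a D–H···A angle ≥ 120° enforced
whenever the donor has an explicit hydrogen (heavy-atom-only structures
fall back to the distance criterion — ligand hydrogens are implicit, so
ligand-donated bonds are always distance-screened); ionic contacts
between opposite formal charges within 4.0 Å.  Ring planes come from an
SVD plane fit to the ring coordinates; the interplanar angle is folded
into [0°, 90°].

**Granularity.**  Each interaction class fires at most once per residue
instance, carrying the smallest qualifying contact distance.  The
fingerprint cell (amino acid, class) then counts residues, so two
arginines H-bonding the ligand give the ARG H-bond cell the value 2.
The companion distance vector stores the minimum distance per occupied
cell — the closest contact dominates the energetics and minimum is the
only aggregate that stays monotone when cutoffs shrink.  Cells are
ordered alphabetically by three-letter amino-acid code, classes in the
fixed order (hydrophobic, face-to-face, edge-to-face, H-bond accepted
by ligand, H-bond donated by ligand, ionic ligand-negative, ionic
ligand-positive), flattened row-major by amino acid.  Any fixed order
would do; this one is documented and stable.

Waters are removed during reading; the resolution filter keeps
complexes strictly below 2.5 Å (structures without a resolution, e.g.
NMR, pass only under an explicit flag) and the affinity label must be a
Kd or Ki (IC50 records are excluded from training).  Hydrogen addition
is geometric and donors-only: a bare donor receives one hydrogen 1.0 Å
along the direction away from its bonded heavy neighbours — enough for
angle screening, not a protonation model.

Not modelled: water-mediated and metal-coordination contacts, halogen
bonds, cation–π, and bond-order correction of protein files.

## Fragment descriptors

Ligand fragments are counted on the heavy-atom graph.  Sequences are
simple paths of 2–6 atoms rendered as element symbols (lower-case when
aromatic) joined by bond symbols (`-`, `=`, `#`, `:`); a path and its
reverse are one fragment, canonicalised as the lexicographic minimum of
the two renderings.  Augmented atoms are the centre symbol plus the
sorted multiset of (bond, neighbour) terms.  Counts — not binary
presence — are used, since occurrence numbers carry magnitude the
forest can exploit.  The dictionary is the lexicographically indexed
union of both families over the training molecules; it is frozen at
training time and fragments unseen at prediction are dropped (logged),
so feature columns never shift between training and scoring.  Single
atoms are covered by the augmented family, hydrogens never appear in
fragments.

## Learners

Features are used raw by the random forest.  The deep network
standardizes them to train-set mean/variance (stochastic gradient
descent does not tolerate mixed count/distance/fragment scales); the
constants are stored with the fitted model and applied at prediction.

* Random forest: scikit-learn bagged regression trees; the prediction
  is the mean over trees.  `max_features="auto"` means all features
  (the historic meaning of that option), `"sqrt"` samples √d per
  split; the tuned grid is n_estimators ∈ {100…500} × those two.
  Seeds are explicit everywhere.
* Deep network: dense 400/200/100 stack, each hidden layer followed by
  batch normalization, ReLU and inverted dropout; linear output unit.
  Implemented directly on NumPy arrays (forward and backward passes,
  BN with batch statistics in training and running statistics at
  inference, momentum SGD with the 1/(1 + decay·t) schedule, L2
  penalty on weights).  The learning-parameter audit counts dense
  weights and biases plus four parameters per hidden unit (BN scale,
  shift and the two running statistics): 159,601 / 215,601 /
  1,072,401 / 1,128,401 for input dimensions 140 / 280 / 2422 / 2562,
  and the constructed network's array sizes are checked against this
  closed form.  After each epoch the validation composite loss
  α(1−PCC) + (1−α)RMSE is evaluated; the returned model is the epoch
  minimising it (α = 0 degenerates to minimum validation RMSE, α = 1
  to maximum correlation).  Early-stopping patience is optional; by
  default all epochs run and the argmin is restored.  Non-finite
  losses abort with a diagnostic rather than returning a diverged
  model.
* The null baseline predicts the training-label mean; with constant
  predictions the correlation is undefined and reported absent rather
  than zero.

PCC p-values use the t-distribution transform, two-sided.  Batch
normalization needs at least two rows of batch statistics, so trailing
one-row minibatches are skipped.

## Synthetic data

Two generators make every component testable without external
structure databases.

**Planted complexes.**  Each requested (residue, class, distance)
triple gets a minimal ligand probe group — an apolar carbon, a
carbonyl or hydroxyl oxygen, a charged O⁻/N⁺, or a benzene ring —
hung off a chain of anchor carbons spaced 30 Å apart, with an
idealized residue template approaching from a fixed direction so that
the functional atom (or ring centroid) sits exactly at the requested
distance with compliant angles.  Decoy residues are parked beyond
every cutoff.  The ground-truth fingerprint is implied by the
construction; the one physical side effect is retained deliberately:
an aromatic stack within the stacking cutoff necessarily brings ring
carbons within the hydrophobic cutoff, so aromatic plants contribute
the corresponding hydrophobic cell whenever the constructed ring
geometry implies it.  Templates use idealized internal coordinates
(no rotamers, unrealistic linker bond lengths between probe groups) —
sufficient for exercising geometric rules and file round-trips, not
for conformational realism.  Passing these tests shows the detector
implements its stated geometry exactly; it does not validate the rule
thresholds against experimental structures.

**Synthetic datasets.**  Fingerprint counts are Poisson (rate 1.2)
over a small set of informative cells plus an equal number of
zero-weight distractor cells; distance features, when requested, are
uniform on (2.5, 4.5) Å exactly where counts are positive; labels are
weights · features + Gaussian noise.  The defaults (n = 500, 12
informative cells, unit-scale weights, σ = 0.1 pK units) model a
mid-sized curated training set with a strong linear signal: they
exercise parameter recovery and seeding, not the difficulty of real
affinity prediction, where the signal is weaker and non-linear.

## Problem sizes and numerical choices

The audit harness uses 100 random planted complexes (≤ 500 atoms each)
for detector/brute-force agreement, 50 random connected molecular
graphs (≤ 30 heavy atoms) for fragment/path-walk agreement, n = 500
synthetic rows for forest recovery, and 12 network epochs for the
α = 0 selection check — sizes at which the brute-force oracles are
exact and the whole suite runs in seconds on one CPU.  Floating-point
tie-breaks: coordinates are Å throughout, distances compared at 1e-9,
rigid-motion invariance asserted at 1e-6 Å, metric agreement with
textbook formulas at 1e-10.  Splits round n·ratio to the nearest
integer and clamp so both sides are non-empty; constant feature
columns standardize to zero rather than dividing by zero.
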