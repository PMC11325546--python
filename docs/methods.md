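# Methods

## Pipeline overview

A molecule entering the pipeline is standardized (largest covalent
fragment, proton-based neutralization, explicit hydrogens, one
deterministic 3D conformer), replaced by its most stable neutral tautomer,
scanned for protonation/deprotonation sites by two node-classification
GNNs, and finally assigned one micro-pK<sub>a</sub> per predicted site by
a paired-graph regression model. Each stage is an independent module with
its own contract; this note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Standardization (chem_io)

* Neutralization moves protons only: O/N/S atoms carrying −1 gain a
  hydrogen; N atoms carrying +1 with at least one hydrogen lose one,
  repeated until the molecule is neutral or no rule applies. Species that
  remain charged (e.g. quaternary ammonium) are passed through flagged.
* Conformers are embedded with distance geometry (ETKDG) seeded by a
  SHA-256 hash of the canonical SMILES, so the same structure always gets
  the same geometry. Species the embedder rejects fall back to flat 2D
  coordinates — still deterministic, with shape descriptors degrading
  gracefully.
* Enantiomer augmentation flips every tetrahedral tag and mirrors the
  parent conformer (x-axis negation) instead of re-embedding. This makes
  the premise "enantiomers have identical features" hold bit-for-bit, which
  the invariance tests then verify end to end. Molecules whose canonical
  SMILES is unchanged by inversion (meso forms) produce no augmentation.
* Atom indices are 0-based everywhere — files, labels, predictions — and
  refer to the explicit-hydrogen atom order of the record they accompany.
* The training-library pK<sub>a</sub> window is the closed interval
  [0, 14]; both bounds accept.

## Mock QM backend (qm)

The mock backend reproduces the *structure* of semiempirical tight-binding
descriptors with documented closed forms, not their values:

* **Partial charges** — one electronegativity-equalization sweep over the
  bond graph, `q_i = f_i − 0.16 Σ_j w_ij (χ_i − χ_j)/(χ_i + χ_j)` with
  Pauling χ and bond order w. Charges live on a dyadic grid (multiples of
  2⁻³⁰): the pairwise transfer terms cancel exactly in integer arithmetic
  and dyadic floats of this size add without rounding, so the sum of
  partial charges equals the net formal charge bit for bit.
* **Coordination number** — heavy-atom degree + 0.5 × bonded hydrogens.
* **Fukui indices** — degree/valence heuristics (f⁻ weights lone-pair-rich
  electronegative atoms, f⁺ electron-poor atoms, f⁰ low-coordination
  atoms), each normalized to sum to 1 over atoms.
* **Polarizability** — free-atom element lookup (atomic units).
* **Wiberg order** — bond order damped by electronegativity mismatch;
  always positive.
* **Total energy** (Hartree) — per-element terms + bond-order term +
  0.15·q² net-charge penalty + a jitter below 0.05 Hartree hashed from the
  *stereo-agnostic* canonical SMILES. The jitter makes distinct isomers
  rank distinctly (so tautomer selection and site energy ranking are
  non-degenerate) while enantiomers keep exactly equal energies.

The external adapter runs a GFN2-xTB executable in single-point mode with
ALPB water solvation and is constructed only when the binary exists;
pipelines treat per-molecule backend failures as skips, never aborts. The
solvation setting used for the energy is passed unchanged to the Fukui
computation. Energy comparisons for the site filter convert Hartree to eV
with 27.211386 eV/Hartree.

## Tautomer stage

Enumeration uses the stock transform-rule tautomer enumerator of the
cheminformatics toolkit (keto-enol, amide-imidic acid, lactam-lactim and
related rules; the toolkit's rule set is the reference because enumeration
differs between toolkits). The search is restricted to neutral molecules;
acids, bases and zwitterions are out of scope by design. The cap defaults
to 64 tautomers. Selection is argmin of total energy with ties broken by
lexicographically smallest canonical SMILES, which makes the selected
structure invariant to input order; partial backend failures drop the
affected tautomer unless it is the input form itself.

## Graph representation (graphs)

The node schema is locked at **61 features**: one-hots for atom type
(11), formal charge (5), degree (7), total hydrogen count (5),
hybridization (7), total valence (7), ring size (6); flags for
aromaticity, ring membership, H-bond donor/acceptor, stereocenter; scaled
mass and electronegativity; and six QM slots (partial charge, f⁺, f⁰, f⁻,
coordination number, polarizability). A stereocenter *flag* is used
instead of a chirality-direction one-hot deliberately: parity direction
would differ between enantiomers and break feature invariance. The schema
is serialized and hashed into every model artifact; inference refuses
graphs whose schema hash differs.

Edge features: bond-type one-hot, conjugation, ring membership, Wiberg
order. Each undirected bond is stored as two directed arcs with identical
features.

Molecular features are five shape/composition descriptors plus the pair
energy. From the mass-weighted gyration tensor with eigenvalues
λ₁ ≥ λ₂ ≥ λ₃:

* RadiusOfGyration = √(λ₁+λ₂+λ₃)
* Asphericity = ((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₁−λ₃)²) / (2(λ₁+λ₂+λ₃)²),
  0 for a sphere, 1 for a rod
* Eccentricity = √(λ₁²−λ₃²)/λ₁
* Spherocity = 3λ₃/(λ₁+λ₂+λ₃)

plus FractionCSP3. Degenerate inputs (fewer than three atoms, collinear
or coincident coordinates) return defined zeros, never NaN. All four
shape values are reflection-invariant. The sixth slot, the protonation
energy E(protonated) − E(deprotonated) in Hartree, is populated only when
graphs are built as a pair and is identical on both members.

## Site enumeration (sites)

Training labels are generated by a desk-scale oracle: ~25 acidic and ~25
basic SMARTS patterns (carboxylic acids, phenols, thiols, sulfonamides,
imides, azole N–H; amines, anilines, azine/azole nitrogens, amidines,
guanidines, …) select candidate atoms; each candidate is actually edited
(proton added at a lone-pair-bearing atom, or removed from an H-bearing
atom, with the formal charge adjusted) and must pass two filters:

1. **Structural-change filter** — the protonated form minus the
   transferred hydrogen must be isomorphic to the deprotonated form with
   identical elements, heavy-atom connectivity and bond orders, and with
   exactly one atom's hydrogen count differing by one. Ring openings,
   closures and any heavy-atom change fail.
2. **Energy window** — products more than 10 eV (inclusive) above the
   most stable product of the same reaction are discarded.

Product geometries are derived from the parent conformer (hydrogen row
deleted, or a new hydrogen placed 1 Å opposite the mean bond vector)
rather than re-embedded: deterministic, fast, and reflection-equivariant,
which is what makes the enantiomer-invariance guarantee survive the edit
step.

The two site models are node classifiers: a stack of message-passing
layers (choice of three families — symmetric-normalized graph
convolution, additive single-head attention, or scaled-dot-product
attention with a residual self term) followed by a two-layer dense head
producing one logit per atom. The aggregation adjacency is weighted by
the Wiberg bond order. Class imbalance (most atoms are not sites) is
handled with a positive-class weight of 4 in the binary cross-entropy;
the prediction threshold defaults to 0.5 (strict >). Datasets are split
80:10:10 *by molecule*; training uses Adam (lr 5·10⁻³), batches of 8
graphs, and early stopping on validation loss with patience 8, restoring
the best-validation weights.

## Micro-pK<sub>a</sub> model (pka)

Each labeled site becomes a PairExample: the neutral molecule paired with
its edited product. Deprotonation sites give *acidic* pairs (neutral =
protonated form); protonation sites give *basic* pairs (neutral =
deprotonated form); the orientation of the pair is what tells the model
which reaction it is scoring. Both graphs are encoded by the same GNN
(weight sharing is the default and halves the parameters while enforcing
representational symmetry; it is configurable), mean-pooled, concatenated
with both molecular feature vectors, and regressed by a dense head. Loss
is mean squared error.

Training is two-stage: pretraining on the weak-label set (80:10:10 by
molecule) and fine-tuning on the experimental-style set (80:20), starting
from the pretrained weights with a smaller learning rate (10⁻³ vs
5·10⁻³). Fine-tuning with zero epochs is an exact no-op. Both stages are
recorded in the model's provenance together with seeds and histories; all
training is bit-reproducible given the seed because the whole stack is
plain seeded numpy.

Evaluation reports RMSE, MAE and R², with R² the coefficient of
determination (not squared correlation — the convention is stated because
the two differ for biased predictors); zero-variance truth sets return
R² = NaN. Train/test overlap screening uses the maximum Tanimoto
similarity over circular fingerprints (radius 2, 2048 bits) with the
customary 0.8 threshold.

Feature attribution is integrated gradients with a midpoint Riemann sum
along the straight path from an all-zero baseline on the same topology;
attributions are exact for linear models at any step count and satisfy
completeness within 1% at 128 steps on the trained models, verified
against direct evaluation of both endpoints.

## Synthetic data (synthetic)

The generator assembles molecules from 10 templates carrying one or two
ionizable groups × ~30 inert substituents (alkyl, aryl, halogenated,
ether/thioether), deduplicated by canonical SMILES — about 7,000 unique
neutral, organic, ionizable molecules. Ground truth is the linear label
function

    pKa = base(class) − 0.55·n_halogens − 0.40·arom₂ − 0.20·n_ether + ε

with class base values: carboxylic acid 4.2, phenol 9.9, thiol 8.6,
azole N–H 12.5, primary/secondary/tertiary amine 10.6/10.8/10.1, aniline
4.6, pyridine-type N 5.2, imidazole-type N 7.0; arom₂ indicates an
aromatic atom within two bonds of the site; ε is Gaussian with
noise_sd = 0.3 pK<sub>a</sub> units by default (0 for oracle-equivalence
tests); values are clipped to [0, 14]. Base values and corrections are
plausible magnitudes for these group classes, chosen once so every label
stays inside the window. Linearity is deliberate: a least-squares probe
on the documented features recovers the coefficients to 10⁻⁶ on noiseless
data, proving the generator leaks no signal beyond its stated function.

The weak-label set mimics a macro-to-micro assignment: one acidic and one
basic label per molecule, attached to the lowest-energy labeled site of
each reaction. The experimental-style set uses the same label function
shifted by +0.75 pK<sub>a</sub> units (a systematic predicted-versus-
measured gap) plus noise, and is disjoint from the weak set by molecule.
A manifest records both specs so datasets regenerate exactly.

What the generator does *not* emulate: real electronic substituent
effects beyond the three linear corrections, tautomer-dependent acidity,
zwitterions, carbon acids, and the property distributions of a real
screening library. Passing benchmarks therefore demonstrates that the
pipeline can learn its labels and preserve its invariants — not
chemical-accuracy transferability to measured pK<sub>a</sub> data, which
requires real corpora and a real QM backend.

## Reference study conditions

The evaluation protocols in `micropka.benchmarks` fix the problem sizes
used by the tests and the acceptance script: 500 molecules for the site
classifiers (held-out per-atom accuracy ≥ 0.95 expected), 2,000 noiseless
pairs for pretraining (held-out RMSE ≤ 0.5), 200 experimental-style pairs
with five seeds for the transfer comparison (fine-tuned mean RMSE below
from-scratch mean RMSE), 50 chiral molecules for enantiomer invariance
(|ΔpKa| ≤ 10⁻⁶), and 128 integration steps for attribution completeness
(≤ 1% relative). Default model size is 3 message-passing layers of width
32 with a 2-layer head — small enough that the whole protocol retrains in
a few minutes on one CPU while leaving the benchmarks comfortable margin.

## Numerical and degenerate-case choices

* Energy-window boundary inclusive at exactly 10 eV; pK<sub>a</sub>
  window bounds inclusive at 0 and 14.
* Tautomer ties broken by smallest canonical SMILES.
* Site-probability threshold comparisons are strict (`p > t`), so
  threshold 0 marks every atom.
* Early stopping counts epochs since the best validation loss and
  restores the best weights; an improvement must exceed 10⁻⁹.
* Attention masks use additive −10⁹ on non-neighbors; self-loops are
  always present so no softmax row is empty.
* Isomorphism search in the structural filter is capped at 200 mappings
  per pair as a combinatorial guard for highly symmetric molecules.

## Known limitations

* The mock backend's descriptors are graph-derived; conformer-sensitive
  electronic effects (intramolecular H-bonds, through-space polarization)
  are invisible to it.
* Carbon acids are not represented in the oracle patterns or the grammar,
  so the site models cannot propose aliphatic C–H deprotonation.
* Macro-pK<sub>a</sub> assembly, multi-solvent prediction and uncertainty
  estimates are out of scope.
* The external GFN2-xTB adapter implements the subprocess contract but
  output parsing is not exercised in this repository's test environment;
  using it requires the external program and its output files.
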