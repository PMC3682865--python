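# Methods

## The problem and the model

Protein NMR chemical shifts δ (ppm) are exquisitely sensitive reporters of
local structure, and predicting them from coordinates underpins structure
validation, refinement and assignment.  `shiftforge` implements a *hybrid*
predictor-construction pipeline: the shift of an atom is described as a
physically motivated baseline plus a statistical model of the residual,

    δ ≈ δ_coil(residue, atom) + semi-classical terms + f(features),

where `f` is learned per *atom super class* — a named group of atom
nuclei (backbone N, CA, CB, C', amide H, then HA/HB/HD/HG and a
remaining-hydrogens class HEHZ) that shares one regression model.  The
pipeline automates the whole path from deposited data to models:

1. an initial PDB-chain ↔ shift-list mapping,
2. restriction filters — *type-1* on the mapping (protein-only entries,
   100 % sequence agreement between coordinates and shift list, homology
   culling at ≤ 10 % pairwise identity) and *type-2* on individual files
   (a structure-quality pseudo-energy with a 1000 kJ/mol cutoff),
3. fault-tolerant parsing of PDB and NMRStar files, chain matching,
   residue re-anchoring by global alignment and atom-name dialect
   translation,
4. computation of a per-atom feature table into a two-table SQLite store,
5. a random 60:40 train/test split, one 500-tree random forest per super
   class, and evaluation by RMSE and the sample-normalized Pearson
   correlation.

The evaluation metrics are

    rmse = sqrt( Σᵢ (δᵢ^exp − δᵢ^pred)² / n )
    corr = 1/(n−1) Σᵢ [(δᵢ^exp − δ̄^exp)/s_exp] [(δᵢ^pred − δ̄^pred)/s_pred]

with sample (n−1) standard deviations; `corr` is reported as undefined
for n < 2 or zero-variance vectors rather than coerced to 0.

## Semi-classical terms

All four terms use standard literature forms; r is in Å throughout.

* **Random coil** — a (residue, atom) table lookup for the backbone
  nuclei N, CA, CB (no GLY CB), C', H (no PRO H) and HA, transcribed from
  Wishart et al. (1995), *J. Biomol. NMR* 5:67.
* **Ring current** — the point-dipole form δ = Σ B·i·(1 − 3cos²θ)/r³ over
  aromatic rings, with B = 30.42 ppm·Å³ and relative intensities
  PHE 1.00, TYR 0.84, HIS 0.90, TRP 1.04/1.02 (five-/six-ring); θ is the
  angle between ring normal and centroid→atom vector.  TRP contributes
  two rings.  An atom's own residue's ring is excluded (the point-dipole
  form is invalid inside ~0.5 Å of the centroid, and ring members sit
  closer than that).  The term changes sign on the magic-angle cone
  (cos²θ = 1/3) and decays exactly as r⁻³; at 50 Å it is ~5·10⁻⁴ ppm,
  physically negligible.
* **Electric field** — the uniaxial form δ = ε·E_z with
  E_z = Σ q·cosα / r² over a minimal built-in partial-charge set
  (backbone amide/carbonyl dipole plus charged side-chain termini),
  projected on the target's single covalent bond axis, 2-bond exclusion;
  ε defaults to 1 ppm per e·Å⁻² and is configurable.
* **Hydrogen bond** — δ = a/r³ − b for the nearest N/O/S acceptor within
  3.5 Å of a donor hydrogen (a = 19.2 ppm·Å³, b = 2.3 ppm, the classic
  amide-proton distance relation), else 0.

The unavailable original parameterizations are not claimed; these are the
package's own documented choices, exposed through
`SemiClassicalParams`.

## Features

The feature-definition file (one name per line, `#` comments a feature
out) selects from a string-keyed registry: sequential descriptors
(current/previous/next residue type, sequence length, alignment score),
torsions (φ, ψ, χ₁; IUPAC sign), secondary structure from a
Kabsch–Sander-style backbone H-bond pattern (two consecutive i→i+4 turns
⇒ helix, bridge patterns ⇒ strand, else coil), explicit backbone
distances, solvent-accessible surface (Shrake–Rupley, probe 1.4 Å,
960-point deterministic sphere sampling; per-atom and summed "residue
SAS"), heavy-atom density in a 5 Å sphere, geometric hydrogen bonds
(H···A < 2.5 Å, ∠D–H–A > 120°) and disulfides (S–S ∈ [1.8, 2.5] Å), an
Amber-flavoured atom type, the nonbonded structure score, the
experimental conditions (temperature, pH, pressure, solvent,
spectrometer, shift-availability flags), and the four semi-classical
terms.  Every feature returns a value or an explicit `missing` marker —
never an absent key.

Two numerical choices matter for reproducibility.  SASA is evaluated in
a deterministic principal-axes canonical frame (axis signs fixed by
rotation-covariant statistics), making the sampled area *exactly*
invariant under proper rigid motion; the point set is antipodally
symmetric, so mirror-image neighbour configurations get exactly equal
areas.  All geometric features are pure functions of coordinates:
recomputation is bit-identical.

## Filters

* **Alignment** — Needleman–Wunsch, match +1 / mismatch 0 / gap −1;
  identity = matched columns / alignment columns × 100, so any gap breaks
  the 100 % filter.  Among co-optimal alignments the DP maximizes
  (score, matches, aligned pairs) lexicographically, which pins the
  identity uniquely and makes it symmetric in its arguments.
* **Homology culling** — greedy longest-first retention: a sequence is
  kept iff its identity to every retained sequence is ≤ the cutoff
  (default 10 %).  Deterministic; sound by construction (an all-pairs
  post-check is part of the test suite) and within one sequence of the
  exhaustive optimum on the tested set sizes.
* **Structure quality** — a pluggable scorer registry; the default
  (`"default-nb"`) is a Lennard-Jones clash term (well depth 0.4 kJ/mol,
  minimum at van der Waals contact) plus Coulomb over the built-in
  charges, with the customary 1-4 (3-bond) exclusion, in kJ/mol.  Keep
  iff score ≤ 1000 kJ/mol (≤, not <).  A scorer failure drops the entry
  as "unscorable" rather than crashing the pipeline.

## NMRStar parsing and name mapping

Deposited shift files contain stray tokens, duplicated frames and
unparseable values.  The reader tokenizes the STAR grammar line-aware
(quotes, `;` text blocks, comments), finds every loop carrying a
chemical-shift value tag (2.1 `_Chem_shift_value` or 3.1
`_Atom_chem_shift.Val`), and consumes rows with re-synchronization: a
buffer absorbs wrapped rows, and an over-full row is retried with every
single-token deletion, which recovers rows broken by one stray token
with values bit-identical to a clean parse.  Anomalies are counted per
category; only a missing shift loop or unreadable file is fatal.
Duplicate rows keep the first occurrence; an exactly duplicated loop is
skipped as a duplicated frame.  A no-op re-referencing hook
(`rereference_shifts`) marks where systematic offset correction could be
inserted; the default transform is identity.

Hydrogen nomenclature differs between dialects non-trivially: prochiral
methylenes are numbered {2,3} in the NMRStar/v3 dialect but {1,2} in
PDB v2 (CYS HB2 ↔ 1HB), while methyl and amino groups keep their digit
(ALA HB2 ↔ 2HB) and lone aromatic hydrogens are identical in both.  The
translation is an explicit per-residue bijection generated from the
hydrogen-group tables; both spellings are accepted on input and the
round-trip is exact over every standard residue's vocabulary.

If several chains tie for the best alignment score to a shift entity,
the first chain in file order is chosen; chains are re-indexed 1..k in
file order and residues 1-based in sequence order (author numbering kept
as an auxiliary column).  Only the first model of an NMR ensemble is
used.

## Model

`SuperClassRandomForest` follows the sklearn estimator protocol.  Per
class with ≥ 50 training rows (smaller classes are skipped with a
warning): categorical features are one-hot encoded with stored
categories, missing numerics are median-imputed with a parallel
missing-indicator column, and a 500-tree forest is fitted.  `mtry` (the
per-split candidate count) is tuned by the classic doubling/halving walk
around p/3 on out-of-bag error with 100-tree forests — the procedure can
reach mtry = p, reconciling "all variables sampled as candidate at each
split" with "tuned by the recommended procedures".  The split is at the
structure level (all atoms of one PDB entry on one side; round-half-up
on the structure count), stricter than an atom-level split, because
atom-level splits leak intra-protein correlation.  Impurity-based
feature importances are aggregated back to the source feature (one-hot
and indicator columns summed).  Models persist as one joblib artifact
per class plus a JSON sidecar of feature names, kinds and encodings;
prediction re-runs are byte-identical.

At prediction time experimental-condition features default to missing
unless supplied, and the alignment-score feature is fixed to 100 (no
reference sequence exists).  Output is a fixed-column CSV
(`pdb_id,chain,residue_index,residue_type,atom_name,super_class,predicted_shift_ppm`).

## The synthetic corpus: what it emulates, and what it does not

The fixture generator builds toy proteins from ideal peptide geometry
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å, standard angles, ω = 180°) by
natural-extension placement from a per-residue (φ, ψ) program, with
idealized hydrogens and PHE rings in a deterministically chosen χ₁
rotamer; a clash check rejects impossible programs.  Shifts follow the
known ground truth

    δ = δ_coil + δ_ring + 0.02 · (heavy-atom density) + N(0, σ²)

for the backbone nuclei in the random-coil table, written as NMRStar 2.1
(or 3.1) files; the same builder produces corrupted variants
(stray token, duplicated frame, non-numeric value, dialect-switched
names, one-residue index insertion).  Same spec + seed ⇒ byte-identical
files.

The study conditions are 48 structures × 16 residues over the alphabet
A/G/F (one or two PHE each; helix, extended and mixed backbone programs
with 4° jitter), σ ∈ {0, 0.3} ppm, 60:40 structure split, 500 trees.
The corpus size is chosen so that the forest's piecewise-constant
approximation of the continuous ring-current dependence is no longer the
binding error source (at 16 structures it is, ~0.1 ppm); at these
conditions the σ = 0 run reaches pooled test RMSE ≈ 0.034 ppm with every
class correlation > 0.99, and the σ = 0.3 run sits on the noise floor
(RMSE 0.30–0.32 ppm).  Homology culling is disabled for this corpus —
three-letter toy sequences are all mutually similar by construction —
and exercised on random 20-letter sequence sets instead.

What passing these tests shows: the plumbing is sound end to end —
parsing, mapping, nomenclature, feature computation and training recover
a known generating function through the entire pipeline, and the
evaluation machinery reports exactly the defined metrics.  What it does
not show: predictive accuracy on real proteins.  The toy corpus has no
side-chain heterogeneity beyond PHE, no conformational ensembles, no
referencing errors, no real measurement noise structure, and its ground
truth is, by design, expressible in the computed features.

The permutation negative control deserves a note: after shuffling
training shifts within each class, a *single* run's per-class test
correlation fluctuates with σ ≈ 0.2 — not because the pipeline leaks,
but because the structure-level split leaves only ~19 independent test
structures and shifts are correlated within a structure.  The control
therefore reports the correlation averaged over all classes and five
independent permutation replicates (≈ 0.004 under the study seed), which
estimates the expectation that should be zero.

## Known limitations

* The semi-classical parameterizations are literature-standard defaults,
  not fitted; the electric-field unit scale in particular is nominal.
* The point-dipole ring model is the only ring model shipped (the
  registry accepts alternatives); Haigh–Mallion is out of scope.
* The pseudo-energy is a quality *score*, not a force-field energy; only
  its ranking behaviour and the kJ/mol scale of its cutoff matter here.
* Strand assignment implements only the basic bridge patterns; isolated
  β-bridges and π/3₁₀ helices are labeled coil.
* The fixture builder covers ALA/GLY/PHE; other residue types exercise
  the nomenclature and feature tables through unit tests, not through
  generated structures.
* No multi-writer store support; schema evolution is limited to adding
  boolean filter columns.
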