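# Methods

## Problem setting

The design unit is a *peptide–binding-site complex*: a contiguous 6-residue
backbone fragment of one protein chain (the "peptide") posed against the
24–48 residues of the partner chain(s) whose backbone atoms lie closest to
it (the "binding site"). The task is fixed-backbone inverse design: predict
amino-acid sequences for the peptide from backbone geometry and the site's
sequence alone. Because the intended inputs are modelled or perturbed
backbones rather than crystallographic ones, training complexes carry
peptides stripped to glycine and perturbed by up to 1.07 Å RMSD from their
native pose.

## Extraction

Candidate fragments are all 6-residue windows of a ligand chain without
chain breaks (unit res_seq steps, consecutive CA–CA < 4.2 Å). The binding
site is every partner residue whose minimum backbone-atom distance to any
peptide backbone atom is at most a cutoff (default 10 Å), ranked by that
distance, truncated to the nearest 48 and restored to chain order;
candidates with fewer than 24 qualifying residues are rejected. The 10 Å /
nearest-48 rule is this package's choice — it reproduces the 24–48 band on
typical interfaces; the cutoff is configurable. Site residues may span
multiple partner chains.

A candidate enters a dataset only if (in order): at least two peptide
residues contribute > 0.5 REU to binding; at least three non-terminal
residues lie within 6 Å of the site by closest side-chain heavy atoms (on
backbone-only inputs an idealized CB — CA for glycine — is the proxy, a
logged approximation); the binding free energy is negative; and the
hot-spot set (≥ 3 REU) contains at least one non-polar residue. Resolution
curation (2.0 / 2.5 / 3.5 Å for homo-oligomeric, hetero-oligomeric and
antibody-antigen structures) is a separate metadata predicate applied only
when the PDB header provides a resolution; otherwise it is skipped with a
warning. Homo/hetero labels use ≥ 90% global-alignment sequence identity
over the shorter chain (configurable).

## Energy interface

All energy-conditioned logic goes through a two-method interface
(`binding_energy`, `per_residue_ddG`). The default backend is a surrogate,
*not* a physics force field: binding pseudo-energy is a weighted contact
count, `-(0.2 + w(aa)) * contacts` summed over peptide residues, where
contacts are site proxy atoms (backbone + ideal CB) within a 5 Å shell and
`w` mixes normalized side-chain heavy-atom count with Kyte–Doolittle
hydropathy (scale 0.25, giving REU-like magnitudes). It is additive by
construction, so the alanine-scan contribution has the closed form
`ddG_i = scale * contacts_i * (w(aa_i) − w(A))`. The sign convention is the
standard alanine-scanning one: positive `ddG_i` means the residue favours
binding (its loss destabilizes the complex). Reports carry the name of the
energy model used; external per-residue values can be supplied as a TSV.

## Perturbation

A perturbation draw composes a random rigid-body move (rotation ≤ 10° about
the centroid, translation ≤ 1 Å) with per-atom Gaussian noise (σ = 0.3 Å)
into a displacement field. Coordinate RMSD is linear in a uniform scaling
of that field, so the field is rescaled *exactly* onto a target RMSD drawn
uniformly in (0, 1.07]; no iterative search is needed. Draws that push any
consecutive CA–CA distance outside (3.2, 4.2) Å are rejected and redrawn.
RMSD is computed without superposition: the peptide's pose relative to the
site is precisely what the model must be robust to. The 1.07 Å ceiling is a
hard postcondition of every draw; the realized mean over draws (~0.45 Å at
defaults) is reported rather than targeted.

## Featurization

Five fixed-shape inputs per complex: (1) 48×6×2 intermolecular distance
maps — N(site)–N(peptide) distances stacked depth-wise with O–O distances,
site rows in chain order, zero rows past the true site size; (2, 3)
length-48 integer site sequence and 3-state secondary structure, zero
padded (amino acids 1–20 in alphabetical one-letter order, H/E/L = 1–3,
pad = 0); (4) 6×6×2 intramolecular peptide maps; (5) a 0/1 homo/hetero
label. Distances are raw Å (an inverse/capped transform exists behind a
flag but defaults off). The peptide's own identities never enter, so a
glycine-stripped backbone featurizes identically to the native one.
Secondary structure comes from a dependency-free dihedral binning — H for
φ∈(−100°,−30°), ψ∈(−80°,−5°); E for φ∈(−170°,−50°), ψ∈(90°,180°)∪
(−180°,−170°); else L — with runs of H/E shorter than 3 smoothed to L and
chain termini L.

## Models

The single-output model is an encoder–decoder. Encoder block A applies 8
3×3 convolutions over the intermolecular maps (channels 16→64, stride-2
steps shrinking the 48 site axis to 6 while preserving the 6 peptide axis)
followed by a masked mean over the site axis; block B applies 4
convolutions over the intramolecular maps; site context is the masked mean
of learned embeddings (dimension 16) of site sequence and secondary
structure plus the oligomeric bit, broadcast to all positions. The
concatenation is projected to the feature tensor `F` (depth 128 by
default) with exactly one feature vector per peptide position. The input
maps and every block-A activation are multiplied by the site-size mask, so
predictions provably depend only on real site rows (padding invariance is
asserted against junk written into the padded region).

The decoder runs forward and reverse LSTM passes over `F` (64 hidden units
per direction), concatenates their hidden states, and decodes six steps
with Bahdanau-style additive attention: at each step the previous decoder
state queries the bidirectional states, the normalized attention produces a
context vector, and an LSTM (96 units) consumes the embedded previous
residue plus context to emit a 20-way distribution. Training uses teacher
forcing; prediction is greedy argmax (no beam search).

The six-output variant copies the trained encoder with gradients blocked
(weights verified bit-identical across training) and trains its own
decoder, warm-started from the single-output decoder. Five passes are
chained by injecting each pass's final LSTM state as the next pass's
initial state; the single-output model's prediction is appended as design
six. The default loss is, per sample, the minimum over the five outputs of
the summed cross-entropy against the target plus a pairwise
probability-overlap diversity penalty (λ = 0.1); mean squared error on the
probabilities is available behind a flag. This trains multiple plausible
solutions without forcing all outputs to one target.

Channel counts, feature depth and hidden sizes are desk-scale
reconstructions chosen so the full stack (and the memorization check below)
runs in minutes on one CPU under the numpy autodiff; every dimension is
configurable through `ModelConfig`.

## Training schedules and model selection

Default schedules are staged Adam runs: 5 epochs at 1e-3, 5 at 1e-4, 2 at
2e-5 for the single-output model, and 4/4/2 at the same rates for the
six-output decoder (batch size 8). An extended schedule (60 epochs at 2e-3,
30 at 5e-4, 10 at 1e-4) exists for memorizing small planted datasets. With
`--restarts N`, independent trainings are scored by summed recovery on
designated hetero-oligomeric validation subsets and the argmax is kept
(ties: first). All randomness flows from explicit integer seeds; training
is bit-reproducible.

## Evaluation

`R_all` is the exact-identity fraction of designed residues; no
similarity-matrix credit enters it. Hot-spots are native peptide residues
with alanine-scan contributions ≥ 3 REU (inclusive boundary);
hot-spot-restricted recovery is reported as missing when a peptide has no
hot-spots, never as 0. Multi-output sets additionally report best-of-six
recovery (max over outputs, structurally ≥ the single-output entry's
recovery) and diversity (mean pairwise Hamming distance over the 15
unordered pairs). Reports include per-position and per-secondary-structure
breakdowns and the energy-model provenance tag.

## Synthetic data

The generator emulates the geometry of real peptide–pocket complexes, not
their statistics: peptides are built from canonical φ/ψ (helix −57/−47,
strand −120/130, irregular −150/60) with ideal bond geometry (N–CA 1.46 Å,
CA–C 1.52 Å, C–N 1.33 Å, C=O 1.23 Å, trans ω), and pockets are 24–48
single-residue units on a randomized arc at 4.6–7.5 Å radius wrapped around
the peptide axis — inside the 10 Å extraction cutoff and dense enough for
surrogate contacts. Site sequences and secondary-structure labels are
uniform random; optional Gaussian jitter (default 0) probes noise
robustness, with peptide draws resampled to keep the CA–CA band intact.

Targets follow a planted rule: for each peptide position, the nearest site
residue's amino-acid index plus a binned CA–CA distance (< 5.5 Å, < 7 Å,
else) modulo 20. The rule is a pure function of observable inputs, so a
non-learned rule reader recovers 100% of targets on noiseless data
(upper-bounding what a trained model can reach), and a correctly wired
model memorizes a 50-complex dataset to ≥ 95% training recovery under the
extended schedule — the package's core wiring check. What passing these
tests does *not* show: performance on real interfaces, which depends on
corpus-scale training data, real rotamer/composition statistics, and
physics-based energies, all outside this package's scope.

## Numerical choices and limitations

Ties in argmax decoding and PSSM top-k lists break toward the
alphabetically first amino acid; model selection ties keep the first
candidate. Probability rows are exact softmax outputs (row sums 1 within
1e-8). Degenerate inputs fail loudly: empty structures, chains shorter than
6, sites outside 24–48, unknown residue codes and length mismatches raise
errors rather than being coerced. The PDB path is backbone-only (no
side-chain reconstruction beyond the ideal-CB proxy, no mmCIF, no
symmetry expansion); the secondary-structure binning is a stand-in for
heavier assignment methods (a DSSP adapter would slot into
`assign_secondary_structure`); and the surrogate energy is a deliberately
simple, clearly labelled placeholder for physics-based interface scoring.
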