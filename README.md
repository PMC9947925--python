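# pepdesign

Fixed-backbone amino-acid sequence design for short peptide fragments docked
at protein binding sites.

Protein–protein interfaces are mediated by short stretches of one partner —
often a 6-residue fragment of a loop or strand — packed against a pocket of
24–48 residues on the other partner. Given only the backbone geometry of such
a fragment and the identity of the pocket, this package predicts amino-acid
sequences for the fragment that are compatible with the interface. It is
aimed at interface redesign and at *de novo* motif design workflows where the
fragment backbone is modelled rather than crystallographic, so robustness to
backbone perturbations (up to ~1 Å RMSD) is built into the data pipeline.

The package covers the full loop:

- **structure_io** — backbone-only PDB parsing/writing, 3-state secondary
  structure from backbone dihedrals, FASTA output.
- **extraction** — enumeration of 6-residue interacting fragments, selection
  of the 24–48-residue binding-site patch by backbone proximity, dataset
  filters (per-residue binding contributions, contact counts, binding-energy
  sign, hot-spot composition, resolution curation), homo/hetero-oligomeric
  labelling.
- **perturb** — bounded backbone perturbation of all-glycine peptides:
  rigid-body move + Gaussian noise rescaled to a drawn target RMSD ≤ 1.07 Å,
  computed without superposition.
- **featurize** — the five fixed-shape model inputs: intermolecular N–N/O–O
  distance maps (48×6×2), site amino-acid and secondary-structure codes
  (48 each), intramolecular peptide maps (6×6×2), and a homo/hetero label.
- **models** — an attention encoder–decoder. The encoder runs 8 convolutional
  layers over the intermolecular maps and 4 over the intramolecular maps with
  embedded site context, concatenated into a feature tensor `F` with one
  feature vector per peptide position. The decoder processes `F` with forward
  and reverse LSTM passes and emits six amino-acid distributions through
  Bahdanau-style additive attention. A six-output variant reuses the trained
  encoder frozen and chains five decoder passes through their final hidden
  states, appending the single-output prediction as the sixth design.
- **evaluation** — sequence recovery `R_all` (identity fraction),
  hot-spot-restricted recovery (alanine-scan contributions ≥ 3 REU),
  best-of-six recovery, design diversity, amino-acid composition, and a
  pluggable per-residue energy interface with a documented non-Rosetta
  surrogate.
- **fixtures** — synthetic peptide–pocket complexes with idealized geometry
  and a planted, brute-force-verifiable geometry→sequence mapping, so the
  whole stack is testable without any structure downloads.

The model core runs on a small numpy reverse-mode autodiff (`pepdesign.nn`);
training is seeded and bit-reproducible on CPU.

## Worked example

Generate 50 synthetic complexes with a planted mapping, train both model
variants, design, and score:

```bash
pepdesign simulate --n 50 --seed 7 --out sim
pepdesign train --tensors sim/tensors.h5 --schedule overfit --seed 0 \
    --multi --out model.npz
pepdesign design --model model.npz --in sim/tensors.h5 --n 1 --out d1.fasta
pepdesign evaluate --native sim/natives.fasta --designs d1.fasta \
    --complexes sim --out rep1
```

which prints

```
wrote 50 complexes to sim (targets: targets.tsv, tensors: tensors.h5)
model checkpoint written to model.npz
50 designed sequences written to d1.fasta
R_all = 1.0000 over 300 residues (50 complexes); report at rep1.json
```

`R_all = 1.0` says the single-output model has fully memorized the planted
geometry→sequence mapping of its 50 training complexes (6 residues × 50 =
300 positions) — the expected outcome for a correctly wired model on a small
deterministic dataset, and the package's core end-to-end check. The JSON
report also carries `r_hotspot` (here 1.0 over 29 surrogate-labelled
hot-spot positions) and per-position/per-secondary-structure breakdowns.
Six-sequence design and per-position probability export work the same way:

```bash
pepdesign design --model model.npz --in sim/tensors.h5 --n 6 --out d6.fasta
pepdesign export-pssm --model model.npz --in sim/tensors.h5 --out pssm.tsv
```

`d6.fasta` holds six alternative designs per complex (entry 6 is the
single-output prediction); `pssm.tsv` is the 6×20 per-position probability
table used to restrict downstream redesign alphabets (top-3/top-5/all).

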