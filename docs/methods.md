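# Methods

This note documents the models, pinned constants, numerical choices and
known limitations behind each pepkit module, and what the synthetic test
fixtures do and do not establish about real data.

## Peptide model and notation

A peptide is an ordered list of monomer codes: the 20 canonical L-amino
acids as one-letter codes, their D-counterparts as bracketed `[dX]` tokens.
Plain lowercase letters are normalised to uppercase L-residues; D-residues
must use brackets, so L/D identity is never ambiguous in a sequence string.
HELM rendering uses the simple-polymer section
(`PEPTIDE1{A.[dA].G}$$$$`); connection sections (cyclic topologies,
disulfides) are not emitted in v1. `[dG]` is accepted for table symmetry
but is chemically identical to glycine (achiral), so it cannot survive a
SMILES round trip.

All monomer-level constants live in one module (`pepkit.monomers`) so tests
can pin exact numbers and reports can cite one provenance string each:

- **masses** — average masses of the free amino acids (IUPAC atomic
  weights), used only as reference data; reported molecular weights come
  from RDKit on the built SMILES;
- **pKa** — the Lehninger side-chain set (Asp 3.65, Glu 4.25, His 6.00,
  Cys 8.18, Tyr 10.07, Lys 10.53, Arg 12.48) with termini pinned at 9.0
  (α-amino) and 2.0 (α-carboxyl). Any single published set is defensible;
  this one is pinned and recorded in report metadata as `lehninger`;
- **hydrophobicity** — Eisenberg consensus values;
- **categorical flags** — charged {D,E,K,R,H}, hydrophobic
  {A,I,L,M,F,W,V,Y}, aromatic {F,W,Y}. Histidine is categorical-charged for
  rule purposes while contributing only fractionally to the continuous net
  charge (pKa 6.0), keeping rule logic categorical and charge logic
  continuous.

## SMILES construction and sequence recovery

SMILES are built by concatenating pinned per-residue fragments from N- to
C-terminus (`N[C@@H](side)C(=O)` per residue, glycine without the
stereocenter, proline as the `N1CCC[C@H]1C(=O)` ring, a final free acid),
so atom order follows the peptide bonds — the property the conformer
writer relies on to emit residue-annotated PDB files. D-residues mirror
every stereotag in the fragment.

The decoder (`sequence_from_smiles`) walks the backbone from the free
N-terminus through successive amide bonds, identifies each residue by the
canonical, stereo-free fragment SMILES of its α-carbon plus side chain
(anchored with an atom map on CA — without the anchor, leucine and
isoleucine side chains both canonicalise to 2-methylbutane), and assigns
L/D from the CIP code of CA (L is *S*, except cysteine where L is *R*).
Reference fragment keys are generated from single-residue molecules built
by the same builder, so query and reference go through the identical RDKit
canonicalisation path; the decoder works on any atom ordering of an
equivalent molecule, not just the builder's output.

## Net charge, pI and the other sequence descriptors

Net charge at pH is the Henderson–Hasselbalch sum over ionizable side
chains plus both free termini; it is monotonically non-increasing in pH and
bracketed in sign on [0, 14] by the termini, so the isoelectric point is
found by bisection (64 iterations max, tolerance |q| < 1e-4). Bisection
rather than lookup interpolation makes `net_charge(p, pI(p)) ≈ 0` an exact,
testable self-consistency.

Hydrophobicity is the **sum** of per-residue Eisenberg values, not the
mean — the summed convention matches how the scale is used to score whole
peptides here and is additive under concatenation, which the tests exploit.
Aromaticity is the F/W/Y fraction. The instability index
(`(10/L)·Σ DIWV(xᵢ, xᵢ₊₁)`) delegates the DIWV dipeptide-weight table to
Biopython's ProtParam implementation; it is undefined below two residues
(reported as `None` in the bundle API, an error from the direct call).
SMILES-level descriptors (average MW, Crippen logP, Lipinski donor/acceptor
counts) come from RDKit; the counting convention is recorded in report
metadata as `rdkit-lipinski`. Composition-level descriptors see D-residues
as their L-parents (they are stereochemistry-blind).

## Developability rules

Three solubility rules (charged fraction > 0.45, hydrophobic fraction
> 0.45, |net charge at pH 7| > 1) and five synthesis rules (≥4 identical
consecutive residues; DG/DP aspartate-cleavage motifs; N-terminal Q/N;
hydrophobic stretch — more than 75% of the 5-residue windows contain no
charged residue, with the window shrunk to the sequence length below five
residues; ≥2 oxidation-prone M/C/W residues). All thresholds are strict
inequalities ("exceeds", "more than"), so a sequence at exactly 45% charged
passes. The synthesis set is an explicitly versioned v1 chosen from
well-known synthesis liabilities; rule evaluation is pure and
order-independent, and every rule reports evidence (the matched span or the
computed quantity).

## Gap-free alignment

Peptide comparison is defined only for equal lengths: the score is the
exact sum of symmetric substitution-matrix lookups position by position.
Unequal lengths raise an error rather than truncating — windowed or gapped
alignment models evolutionary events, the wrong prior for short synthetic
peptides, and is a deliberate non-goal. "Similar" means a strictly positive
matrix score. Matrices are read from the standard NCBI text layout;
BLOSUM62 ships with the package and is cross-checked in tests against
Biopython's published copy. The online blastp interface is a stub that
formats the short-peptide query parameters (word size 2, high expect
threshold, PAM30) and never performs network I/O.

## Conformer generation

One conformer per call: distance-geometry embedding (triangle-smoothed
bounds matrix, random distance matrix, 3D embedding — RDKit's ETKDGv3
implementation) followed by MMFF94 minimisation (static variant, recorded
in the result; up to 2000 iterations, with the convergence flag exposed).
Hydrogens are added for embedding/minimisation and stripped from output by
default. Embedding is deterministic for a fixed seed; failures retry with
deterministically derived seeds up to a budget of 10 before raising.
PDB output is v3.3 with serials 1..N, contiguous N→C residue numbering and
a TER record; D-residues are written with D-prefixed three-letter names
(e.g. `DAL`).

## Complex analysis

Parsing keeps the first model of multi-model files, drops waters and other
HETATM records, and keeps altloc A. Contacts are counted between heavy
atoms by default (crystal structures usually lack hydrogens; a flag
includes them): for each peptide residue, the number of
(peptide-atom, protein-atom) pairs with distance ≤ t (inclusive), default
t = 4.0 Å, via a k-d tree. The count is an atom-*pair* count; a
`count_atoms` flag switches to counting contacting peptide atoms instead,
since either reading of "atoms interacting" is defensible.

Secondary structure, ASA and hydrogen bonds delegate to mdtraj's C
implementations of the standard algorithms: the Kabsch–Sander
secondary-structure assignment (full DSSP alphabet, loop mapped to `-`),
Shrake–Rupley surface area, and Kabsch–Sander hydrogen-bond energies.
Relative ASA divides raw ASA by a pinned per-residue maximum (the
theoretical Tien et al. 2013 values, recorded as
`tien-2013-theoretical`) and clamps to [0, 1] — clamping matters because
maximum-ASA tables differ slightly between sources and terminal residues
can exceed them. Hydrogen bonds with energy below −0.5 kcal/mol (the
algorithm's own convention) become edges of a residue-level graph; only
bonds crossing the peptide/protein interface are kept unless intra-peptide
edges are requested; edge weight is the bond count per residue pair.
Peptide nodes are always present (isolated ones included); protein nodes
appear only with an edge. Rendering colours peptide nodes in one fixed
colour, protein nodes by chain, scales line width linearly with weight
(stored per edge as `drawn_width`), and is deterministic for a fixed layout
seed; the layout is Fruchterman–Reingold (spring) for cyclic peptides and
linear two-row otherwise.

## Libraries

Pattern expansion is the exact Cartesian product over X positions,
deduplicated and lexicographically sorted for diffable output; it refuses
more than 10⁷ sequences and points to sampling mode (a 6-X pattern already
exceeds the guard). The "uniform representation" design is the
single-position scan: every substitution at every position, base kept once.
Frequency sampling draws i.i.d. per position from rows that must sum to one
(tolerance 1e-9), seeded through NumPy's Generator for reproducibility.
Frequency matrices are per-position observed fractions over the library —
the data behind logo plots; rendering a logo is left to external tools.

## Synthetic fixtures

Structure tests run exclusively on generated PDB complexes: polyglycine
backbones built from ideal internal coordinates by NeRF placement, with
φ/ψ = (−57°, −47°) for helices and (−140°, 135°) for extended chains;
a two-chain "two_atom" fixture with exactly one inter-chain pair at 3.5 Å
(next-nearest 5.0 Å) plus interface waters that must be excluded; seeded
uniformly scattered pseudo-atom complexes for brute-force contact oracles;
and a translated two-model file for first-model-only parsing. These
fixtures establish algorithmic correctness (DSSP codes follow backbone
geometry, contact counts equal an O(N·M) double loop, hydrogen bonds sit at
i→i+4 in a helix). They do not establish behaviour on real crystal
structures — no side chains, no missing atoms, no altloc disorder beyond
the synthetic cases, no chain breaks — so parsing robustness on messy PDB
entries is only as good as Biopython's parser.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problem sizes chosen to exercise
each property densely while staying fast: 100–500 random peptides per
oracle comparison, 20 random contact fixtures × 3 thresholds, 20 embedding
seeds on a pentamer, 10⁴-draw sampling checks (CLT gives ±0.01 pooled
frequency at that n). Every stochastic path (sampling, embedding, layout)
takes an explicit seed, and derived seeds stay below 2³¹.

## Known limitations

- Cyclic peptides: the topology flag only affects graph layout and is not
  closed in SMILES or HELM connection sections.
- No non-natural monomers beyond D-amino acids; no post-translational
  modifications.
- pI/charge model ignores local electrostatic coupling between sites
  (standard Henderson–Hasselbalch independence assumption).
- Contact analysis reads PDB only (no mmCIF) and uses author numbering.
- The synthesis-rule set is empirical and versioned; it flags liabilities,
  it does not predict yields.
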