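# pepkit

Peptide analysis for drug-discovery workflows: sequence-level
physico-chemical characterization, empirical developability rules, gap-free
peptide alignment, sequence→SMILES→3D conformer construction,
protein–peptide complex interaction analysis, and combinatorial library
design — as a Python library plus a `pepkit` command.

It is aimed at people triaging peptide candidates (binders, substrates,
synthetic libraries) who need, for each sequence, the standard descriptor
roster and a quick read on whether the peptide is likely to survive
synthesis and stay in solution; and, when a complex structure is available,
a per-residue picture of how the peptide engages its target.

## What it computes

**Sequence descriptors.** Net charge at pH 7 by Henderson–Hasselbalch
summation over ionizable groups — each basic group contributes
`+1/(1+10^(pH−pKa))`, each acidic group `−1/(1+10^(pKa−pH))`, free termini
included (side-chain pKa: Lehninger table; termini pinned at 9.0/2.0);
isoelectric point as the bisection root of that charge function; summed
Eisenberg consensus hydrophobicity; ProtParam aromaticity and instability
index; and from the peptide SMILES: average molecular weight, Crippen logP
and Lipinski H-bond donor/acceptor counts (RDKit).

**Developability rules.** Solubility: charged fraction > 45%, hydrophobic
fraction > 45%, |net charge at pH 7| > 1. Synthesis: ≥4 identical
consecutive residues, DG/DP cleavage motifs, N-terminal Gln/Asn,
charge-free hydrophobic stretches, ≥2 oxidation-prone residues (M/C/W).
Each rule reports pass/fail plus the evidence span or quantity.

**Alignment.** Gap-free, position-by-position scoring of equal-length
peptides under a substitution matrix (BLOSUM62 bundled, NCBI matrix files
readable): `score = Σᵢ s(aᵢ, bᵢ)`, with per-position identity/similarity
calls.

**3D conformers.** Sequence → SMILES with backbone-ordered atoms → distance
geometry embedding → MMFF94 minimisation → residue-annotated PDB.
Deterministic for a fixed seed. D-amino acids supported via `[dX]` tokens
(and HELM notation).

**Complex analysis.** For a PDB complex with a designated peptide chain:
per-residue non-bonded contact counts (heavy-atom pairs within a threshold,
default 4.0 Å), DSSP-alphabet secondary structure and relative accessible
surface area, and a residue-level hydrogen-bond graph (Kabsch–Sander
energies below −0.5 kcal/mol) rendered with line widths proportional to
bond counts.

**Libraries.** Pattern expansion (`XRTEX` → all 400 matching pentamers),
exhaustive enumeration, single-position scans, and seeded frequency-based
sampling, with per-position frequency matrices (the data behind sequence
logos) and FASTA/HELM output.

## Worked example

```sh
pepkit -m sequence -s KLWKKFEKLA -o out/
```

prints

```
1 peptide(s) analysed, 0 failed; report: out/sequence_report.csv
  query: charge=+2.99 MW=1290.62 rules failed=3+0
```

and the CSV row carries the full roster. For this amphipathic decamer:
net charge +2.99 (four Lys and one Glu, plus termini), molecular weight
1290.62 g/mol, Crippen logP 0.22, summed Eisenberg hydrophobicity −2.00,
aromaticity 0.20, instability index 15.70 (stable, < 40), isoelectric point
10.54, 17 H-bond donors, 16 acceptors. Three solubility rules fail —
charged fraction 0.50 > 0.45, hydrophobic fraction 0.50 > 0.45, and
|+2.99| > 1 — flagging likely solubility trouble despite a clean synthesis
profile (0 rules failed). Structure mode works the same way:

```sh
pepkit -m structure -p complex.pdb -c B -t 4.0 -o out/
```

writes a per-residue table (secondary structure, relative ASA, contact
count), GraphML/DOT exports and a PNG of the hydrogen-bond graph.

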