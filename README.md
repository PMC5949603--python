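# bbpkit

Analysis toolkit for **bridged bicyclic peptides (BBPs)** — peptides whose
graph (nodes = amino acid residues, edges = peptide-bond-class linkages)
contains two degree-3 bridgehead residues joined by three bridges, giving
cyclomatic number 2. The smallest well-studied family are *norbornapeptides*,
seven-residue bicyclo[2.2.1] scaffolds, the peptide analog of norbornane.
These scaffolds are of interest in drug design because they are rigid,
serum-stable, and can present side chains the way β-turns and α-helices do.

The package is aimed at peptide chemists and structural analysts who want to
work with BBP sequences and structures computationally:

- **Notation & graphs** (`bbpkit.notation`): a plain-text sequence dialect
  (`l1 G k2 f P E1 a2`: lower case = D-residues, digit suffixes mark the two
  ring closures, `Me` prefix = backbone N-methylation) parsed into a typed
  peptide graph; closure chemistry (side-chain lactams, chloroacetyl-cysteine
  thioether) is resolved from residue identity; bicyclo[a.b.c] topology
  classification with pendant-tail handling.
- **Mass chemistry** (`bbpkit.masses`): elemental formulas from the graph
  (residue sum + H₂O, −H₂O per lactam, +C₂O per thioether, −O+N+H for a
  C-terminal amide, +CH₂ per N-methyl), monoisotopic masses, and positive-mode
  ESI adduct m/z ([M+H]⁺, [M+Na]⁺, [M+K]⁺ and the 2+ combinations).
- **Topology enumeration** (`bbpkit.topology`): all bicyclic topologies up to
  a ring size, with exact big-integer sequence-space counts, raw or corrected
  for graph automorphisms (Burnside's lemma).
- **Structure geometry** (`bbpkit.geometry`): φ/ψ/ω torsions, cis/trans
  amides, Ramachandran regions for L- *and* D-residues (mirrored regions),
  β-turn typing (I, I′, II, II′, VIa, VIb, VIII, else IV), and backbone
  N–H···O=C hydrogen-bond detection with reconstructed amide protons.
- **Helix mimicry** (`bbpkit.mimicry`): ideal α-helix construction
  (φ = −57°, ψ = −47°), exhaustive residue-triplet superposition (proper
  rotations only) and ranking by RMSD with a Gaussian atom-pair overlap score.
- **Binding** (`bbpkit.binding`): NMR amide-proton temperature-coefficient
  H-bond classification; statsmodels-style model objects for one-set-of-sites
  ITC (`OneSiteITCModel`) and 1:1 quadratic MST (`MSTBindingModel`) whose
  `fit()` returns results with estimates, standard errors, diagnostics and a
  `summary()` table; thermodynamics via ΔG = ΔH − TΔS = −RT ln K_a.
- **Synthetic data** (`bbpkit.synthetic`): a torsion-driven (NeRF-style)
  backbone builder, seeded coordinate noise, forward-simulated ITC/MST
  datasets, and packaged fixtures of the published compound tables.

## Worked example

Parse the norbornapeptide `l1 G k2 f P E1 a2` (two lactam closures: the
N-terminus onto the Glu side chain, the C-terminus onto the Lys ε-amine),
derive its formula and adduct masses, and classify its topology:

```bash
$ bbpkit mass "l1 G k2 f P E1 a2" --adducts "[M+H]+,[M+Na]+"
formula  C36H52N8O8
neutral  724.3908
[M+H]+       725.40  (725.3981)
[M+Na]+      747.38  (747.3800)
```

The formula C₃₆H₅₂N₈O₈ is the residue sum plus one water minus two waters
(one per lactam); 725.40 and 747.38 match the published calc. values for
this compound. In Python:

```python
>>> from bbpkit import parse_bbp, classify_topology
>>> t = classify_topology(parse_bbp("l1 G k2 f P E1 a2"))
>>> t.descriptor, t.ring_residues, t.topology_class
('bicyclo[2.2.1]', 7, 'bridged')
```

Fit a one-set-of-sites model to a synthetic isotherm generated at the
published titration protocol (200 μL cell, 50 μM protein, 15 × 2.5 μL
injections of 0.7 mM peptide, 25 °C) with K_D = 0.80 μM ground truth:

```python
>>> from bbpkit.binding import OneSiteITCModel, itc_model
>>> from bbpkit.synthetic import paper_itc_design
>>> e = paper_itc_design()
>>> res = OneSiteITCModel(itc_model(1.0, 1/0.80e-6, -5.0, e), e).fit()
>>> round(res.KD * 1e6, 3), round(res.dG, 2)
(0.8, -8.29)
```

ΔG = −RT ln K_a = −8.29 kcal/mol at 298.15 K for K_D = 0.80 μM, and the
identity ΔG = ΔH − TΔS holds exactly on every fit result.

Enumerate the bicyclic topology space:

```bash
$ bbpkit enumerate --max 15 --classes bridged,fused
...
topologies: 109
sequences (raw): 686135596702918560000
```

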