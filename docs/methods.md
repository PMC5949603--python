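# Methods

This note documents the models, conventions and numerical choices behind
bbpkit, and what its synthetic data do and do not emulate.

## Peptide graphs and the sequence dialect

A BBP is modeled as a graph with residues as nodes and peptide-bond-class
linkages as edges. The written chain contributes one backbone amide per
consecutive pair; each matched pair of digit labels contributes one closure
bond. Closure chemistry is inferred from residue identity rather than
notation markup, because the published sequence strings carry chemistry in
typography (bold/italics) that plain text cannot represent:

- a label pairing a `z` (the γ-thia-homoglutamate unit created by
  chloroacetyl-cysteine ligation) with the chain head is a thioether; the
  head's N-terminus is consumed by chloroacetylation;
- `E`/`e` paired with the chain head closes the Glu-side-chain-to-α-amine
  lactam; `E`/`e` paired with `K`/`k` elsewhere closes a side-chain to
  side-chain lactam;
- `K`/`k` paired with the chain tail closes the C-terminal-carboxyl-to-ε-amine
  lactam.

Pairings outside these rules (e.g. two lysines sharing a label) are
ambiguous: the parser raises instead of guessing. Acyclic tails after the
bicycle (the biotinylated probe series) are permitted; topology
classification strips them (iterated leaf removal to the 2-core), locates
the two degree-3 bridgeheads, and reports bridge sizes a ≥ b ≥ c with the
pendant residue count. A graph whose ring system has a degree-4 node
(spiro) or more/fewer than two degree-3 nodes is rejected as unsupported
for the bicyclo descriptor.

## Mass chemistry

Formula assembly: Σ residue formulas (amino acid − H₂O) + H₂O for the free
linear peptide, then per modification: C-terminal amide −O +N +H; lactam
−H₂O; thioether +2C +1O net (chloroacetylation adds C₂HO·Cl-equivalents, the
ligation expels HCl; the two carbons and the oxygen are carried by the
closure bond, not by a residue); N-methyl +CH₂. Special residue formulas:
`z` contributes a cysteine residue (C₃H₅NOS), `B` (4-benzoylphenylalanine)
C₁₆H₁₃NO₂, `K(biot)` (Nε-biotinyl-lysine) C₁₆H₂₆N₄O₃S. These rules
reproduce every self-consistent printed formula in the packaged compound
tables exactly.

Monoisotopic element masses are IUPAC values (H 1.00782503207,
C 12 exactly, N 14.0030740048, O 15.9949146196, S 31.97207100 Da); adduct
cations are electron-corrected (H⁺ 1.007276, Na⁺ 22.989218, K⁺ 38.963158 Da);
m/z = (M + Σ cation masses)/z, rounded half-up to two decimals for
comparison with journal-style calc. values. A few printed table entries are
internally inconsistent (a formula that cannot give its own printed m/z);
the fixture flags them (`formula_consistent`, `mz_consistent`) so tests can
assert against the self-consistent majority without silently "fixing" the
source. The doubly-protonated value printed for the arginine photoprobe is
one hydrogen off its own printed formula and is likewise flagged.

## Topology enumeration and chemical-space counts

Bridged topologies with ring size n correspond one-to-one with partitions
of n − 2 into exactly three positive parts (bridge sizes); fused ones with
partitions into two parts (shared-edge systems, c = 0). Counts are verified
two ways in the tests: against the partition closed form for all maxima up
to 20, and against exhaustive generation of candidate graphs deduplicated by
graph isomorphism for n ≤ 10.

Sequence-space counting is exposed as configuration, not as one number:
alphabet size per bridge node, a separate (usually smaller) alphabet for the
two bridgehead roles (diamino acids / amino diacids), raw counting versus
Burnside correction over the topology graph's automorphism group
(enumerated with VF2), and an optional orientation factor of 2 per
non-empty bridge for independently oriented C→N bridge directions. The
headline literature numbers for this compound class ("97 bicyclic graphs up
to 15 residues", "3.1 × 10¹⁹ members") derive from enumeration rules defined
in earlier cited work and not restated alongside them; under the natural
readings implemented here, bridged-only ≤ 15 gives 67 topologies and
bridged + fused gives 109, and the raw 20-letter count over both classes is
≈ 6.9 × 10²⁰. The module therefore reports counts per configuration and
makes no claim that any configuration reproduces the headline values.

## Backbone geometry

Torsions follow the IUPAC sign convention, range (−180°, 180°]; the
implementation agrees with biotite's dihedral on sign and magnitude. A
peptide bond is cis when |ω| < 90°.

The synthetic backbone builder places N/CA/C sequentially from internal
coordinates (NeRF), with standard geometry: N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, CA–CB 1.521 Å, N–H 1.01 Å; angles N-CA-C 111.2°,
CA-C-N 117.2°, C-N-CA 121.7°, CA-C=O 120.8°, N-CA-CB 110.4°. The carbonyl
oxygen is placed anti to the following amide nitrogen (torsion ψ + 180°);
CB is placed with the improper torsion C-N-CA-CB = −122.55° for L-residues
and +122.55° for D-residues, so coordinate inversion maps L structures onto
valid D structures. Torsions recomputed from built coordinates match the
input to well below 1e-6 degrees.

Ramachandran regions are deliberately coarse convex polygons approximating
the standard generic preferred/allowed contours (α_R and β preferred boxes;
wider α/β/αL allowed boxes); published contour data can be passed in via the
`polygons` argument where the approximation is too blunt. D-residue regions
are the mirror image through (φ, ψ) → (−φ, −ψ).

β-turns are typed on the (φ, ψ) of the two central window residues against
canonical values (I: −60,−30,−90,0; I′ and II′ mirrored; II: −60,120,80,0;
VIII: −60,−30,−120,120; VIa: −60,120,−90,0 and VIb: −135,135,−75,160, both
requiring a cis i+1→i+2 bond), with the community tolerance of ±30° per
angle, one angle allowed ±45°; windows matching nothing are type IV. Ties
are broken by the smallest summed angular deviation. Turn windows follow
the written chain; closure bonds are not traversed.

Hydrogen bonds are detected on amide protons reconstructed in the
C(i−1)–N(i)–CA(i) plane (N–H 1.01 Å bisecting the exterior angle), with
N···O ≤ 3.5 Å and N–H···O ≥ 120°, skipping the donor's own and preceding
residue. On an ideal α-helix this yields exactly the i+4 → i ladder.

## Helix mimicry

The ideal helix uses the textbook α-helix torsions (φ = −57°, ψ = −47°,
ω = 180°); its CA trace rises ≈ 1.5 Å per residue about the fitted axis.
All C(n,3) index triplets of both structures are compared pairwise
(35 × 35 = 1225 pairs for seven residues a side) in three atom modes (CA,
CB, or both; glycine triplets are skipped in CB modes with a notice).
Superposition is the least-squares rigid fit restricted to proper rotations
(scipy's align_vectors), so chirality is respected: a structure never
matches its mirror image at RMSD 0. Ranking uses RMSD with a Gaussian
atom-pair overlap score (mean of exp(−d²/2σ²), σ default 1.0 Å) as
tie-breaker and companion metric; residues correspond in sequence order
within a triplet, with reversed correspondence available but off by
default. Tests validate the optimum against a brute-force rotation-grid
search.

## Temperature coefficients

−Δδ/ΔT < 4.0 ppb K⁻¹ classifies an amide proton as fully H-bonded,
4.0–7.0 inclusive as partially H-bonded, > 7.0 as exposed. The boundary 4.0
is assigned to "partial" because the published thresholds write "< 4.0" for
full and "4.0–7.0" for partial. Negative coefficients are legal and
classify as full. The packaged coefficient table (9 compounds × 7 protons,
2 not determined) reproduces the published boldface partition exactly.

## ITC model and fit

One set of n identical sites with association constant K_a and molar
enthalpy ΔH. After injection i (cumulative volume dV into cell volume V₀),
effective concentrations follow the instrument-software displacement
convention M_t = M₀(1 − dV/2V₀)/(1 + dV/2V₀),
X_t = X₀(dV/V₀)/(1 + dV/2V₀); a naive-dilution alternative
(M₀V₀/(V₀+dV)) is switchable. The bound complex comes from the single-site
quadratic; cumulative heat Q_i = [MX]_i·V₀·ΔH, and injection heat
q_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2. The fit estimates
(n, log₁₀K_a, ΔH) by trust-region least squares with a small multistart
over K_a decades to avoid the flat likelihood tails at extreme c values;
results report standard errors from the Gauss–Newton covariance, the
Wiseman c value (warning outside ~1–1000), and thermodynamics with
R = 1.98 cal mol⁻¹ K⁻¹, so ΔG = ΔH − TΔS = −RT ln K_a holds identically.
Noiseless self-fits recover K_D to ≲1e-10 relative error across
K_D = 0.01–100 μM at the published protocol. A drop-first-injection flag
exists for the common first-injection anomaly but defaults off.

## MST model and fit

Fraction bound is the exact 1:1 quadratic solution at fixed labeled-protein
concentration, with the excess-ligand limit L/(L+K_D) at P = 0; the signal
interpolates linearly between free and bound plateaus (thermophoresis
physics is not modeled). The fit estimates (log₁₀K_D, S_free, S_bound);
results flag a flat series (no transition) and a fitted K_D outside the
measured concentration range as unreliable. The published dilution design
is a 15-level 2-fold series from 500 μM mixed 1:1 with labeled protein,
giving final ligand 250 μM…15.3 nM at 10 nM protein; the level count is
taken from the printed endpoints (a 2-fold series from 500 μM reaches
30.5 nM after 15 levels, not 16).

## Synthetic data: what it emulates, what it does not

The generators reproduce the published *designs* — the ITC injection
protocol, the MST dilution scheme, torsion-defined backbones with standard
geometry — under additive, seeded Gaussian noise (coordinate σ in Å; heats
and signals σ as a fraction of the maximum amplitude). Every generator is a
pure function of parameters and seed. They do not emulate instrument
baselines and drift, first-injection artifacts, heats of dilution,
fluorophore photophysics, conformational ensembles, side chains beyond CB,
or experimentally refined coordinates — so passing recovery tests
demonstrate the correctness and statistical behaviour of the estimators
under the stated designs, not robustness to real-instrument systematics.
Consequently the published turn census and the specific best-matching
helix triplets of the crystallographic/NMR structures are not asserted
anywhere: they require the deposited coordinates, which the structure
pipeline accepts as PDB input when available.

Monte-Carlo recovery at the designs used in the tests (100 seeds; ITC noise
2% of the largest heat, MST noise 5% of the plateau amplitude) gives median
K_D errors of about 10% (ITC) and 12% (MST), which the acceptance suite
checks against the 15% band.

## Problem sizes

Everything here is desk-scale: the full test suite runs in well under a
minute (mass engine over all 57 fixture compounds < 1 s; 1225-pair mimicry
rankings ~1 s; 2 × 100 Monte-Carlo fits ~7 s), chosen so the statistical
checks are comfortably reproducible on a laptop.
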