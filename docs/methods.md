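# Methods

This note records the scientific and numerical choices behind hybridfold:
what each component computes, the defaults and why, what the synthetic
generators do and do not emulate, and known limitations.

## Protein Blocks assignment

Protein Blocks are a 16-letter structural alphabet (a–p) in which each
letter is a reference vector of 8 backbone dihedrals — the
(ψ(i−2), φ(i−1), ψ(i−1), φ(i), ψ(i), φ(i+1), ψ(i+1), φ(i+2)) of a
pentapeptide window centred on the assigned residue. The canonical 16×8
reference table ships as package data
(`data/pb_reference_angles.tsv`, the values distributed with the standard
PB assignment tooling). A position is assigned the letter minimising the
RMSDA distance

RMSDA(a, b) = sqrt( (1/8) Σ_k Δ(a_k, b_k)² ),  Δ = angular difference wrapped to [0°, 180°],

with ties broken alphabetically for determinism. Positions with an
incomplete window — the two first/last residues, any window touching a
missing backbone atom or a chain break — are `Z`.

Conventions the assignment depends on (declared, configurable where noted):

- φ(i) = dihedral(C(i−1), N(i), CA(i), C(i)); ψ(i) = dihedral(N(i), CA(i),
  C(i), N(i+1)). An angle is defined when exactly the atoms it needs exist;
  e.g. losing C(j) undefines φ(j), ψ(j) and φ(j+1) but not ψ(j−1).
- Chain break: C(i)–N(i+1) distance > 2.5 Å (parameter of
  `backbone_dihedrals`). A generous covalent-bond cutoff; real peptide
  bonds sit near 1.33 Å.
- Alternate locations collapse to the highest-occupancy conformer at parse
  time; non-standard residues participate through whatever backbone atoms
  they have.

The PB→secondary-structure display map is: helix H = {m} ∪ caps
{f,k,l,n,o,p}; strand E = {d} ∪ caps {b,c,e}; coil C = {a,g,h,i,j};
Z → '-'. This is a display partition (7+4+5 letters), not a DSSP
replacement.

## Solvent accessibility

SASA uses the Shrake–Rupley method on a deterministic golden-section
lattice of n = 960 points per atom (probe 1.4 Å, element van der Waals
radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 Å, hydrogens ignored).
The fixed lattice makes results bit-reproducible and exactly
translation-invariant; under rotation the quadrature error is on the order
of 1% at 960 points (the two-sphere test bounds it at 2%). Relative
accessibility divides residue SASA by the residue-type maximum; the default
table is the Hubbard–Thornton Ala-X-Ala tripeptide set (the normalisation
NACCESS uses), with the Tien 2013 theoretical maxima selectable. Unknown
residue types fall back to the glycine maximum with a warning.

Ten SA classes are equal-width 10% bins on [0, 100] with values above 100%
(possible for extended termini) clamped into class 10. Equal-width bins are
the simplest monotone choice from buried to exposed; a quantile-based
discretisation would need a reference distribution and is intentionally not
the default.

## Profiles

Profiles live in *master coordinates*: alignment columns where the
master row is gapped are dropped, so profile length equals the ungapped
master length and search coordinates are query coordinates.

Amino-acid profile: position-based Henikoff weights (per column, a residue
type seen s times among r types contributes 1/(r·s); gaps contribute
nothing; weights normalised to sum 1), then per column

p′ = (N_eff · f_obs + β · f_pc) / (N_eff + β)

with N_eff = 1/Σ w_k² (inverse-Simpson effective sequence count),
f_pc(a) = Σ_b P(a|b) f_obs(b) the BLOSUM62 conditional-probability
pseudocount vector, and admixture β = 10 by default. The conditional matrix
is reconstructed from the published half-bit BLOSUM62 scores and
Robinson–Robinson background frequencies via q(a,b) ∝ f(a) f(b) 2^(S/2).
'X' and unknown letters contribute the background distribution. The gap
probability g_i — the weighted fraction of gap symbols in the column — is
stored beside the amino-acid simplex, which is renormalised independently.

PB and SA profiles over family members are per-column frequencies over
defined symbols with uniform smoothing weight ε = 0.05
(p ← (1−ε)p + ε/K); columns with no defined evidence are uniform. A
single-member family degenerates to near-one-hot columns.

Serialisation (`.orp`) is a versioned, tab-delimited text format with one
row per position (20 AA + gap + 16 PB + 10 SA columns); floats are written
in shortest-round-trip form, so write→read is lossless and disk-backed
searches reproduce in-memory scores exactly. Databanks are a concatenated
`.orp` stream plus a byte-offset index.

## Scoring and alignment

The column score is the sum over the three components of the co-emission
log-odds log₂(Σ_a q(a)t(a)/f(a)), each floored at S_min = −10 bits and
weighted (w_AA = 1, w_PB = 1, w_SA = 0.5). The floor bounds the damage a
single impossible column can do; the SA weight is lower because ten coarse
classes carry less information per column than the other tracks. Background
distributions: Robinson–Robinson for AA, observed PB frequencies from a
representative structure set (core helix m ≈ 0.32, core strand d ≈ 0.19)
for PB, uniform 0.1 for SA. All weights, backgrounds and gap constants are
fields of `ScoringParams` (YAML-loadable); the score function is isolated
behind `column_score_matrix` so an alternative functional form is a local
substitution.

Gap penalties are position specific: a gap opposite position *i* costs
γ_open·(1−g_i) to open and γ_ext·(1−g_i) to extend (γ_open = 3.0,
γ_ext = 0.3 bits), charged at the position consumed opposite the gap.
Columns that were always gapped in the source alignment (g = 1) are free to
gap again. The gap probability does not enter the match score itself.

The aligner is a three-state (match / query-gap / template-gap) affine DP.
Modes: `global` (both profiles consumed, terminal gaps charged), `local`
(Smith–Waterman, optimum clamped at 0), and `gloloc` (default): every
template column is consumed — matched or deleted at cost — while unaligned
query flanks are free. Transitions between the two gap states are allowed
and charged as fresh openings. Traceback tie-breaking is fixed
(match > delete > insert) so alignments are deterministic; the test suite
verifies the DP optimum exactly against exhaustive enumeration of all
gapped alignments on small profiles in all three modes.

Per-column scores S_l span the full alignment (gap columns contribute 0);
the correlation bonus S_corr = Σ_l S_l Σ_{k≤d} S_{l+k} with forward window
d = 4 rewards clustering of well-scoring columns, and enters the ranking
score as total = S_raw + w_corr·S_corr with w_corr = 0.1, small enough
that the raw score dominates but clustered conservation breaks near-ties.

Identity is computed over matched columns, coverage over the full query
length, bounds are 1-based over matched columns; an empty local alignment
reports zeros. Query lengths outside [15, 1000] warn in the library and
fail in the CLI, mirroring the intended single-domain use.

## Quality utilities

The module consumes externally computed per-residue/global pseudo-energy
scores (e.g. statistical-potential values of a model); it does not
implement a potential itself. Decoys are uniform random permutations of
the sequence positions (seeded); the z-score uses the sample (n−1)
standard deviation of ≥2 decoy scores and is undefined for constant
decoys. Bands: z ≤ −4 native-like, z ≤ −2 reliable, z ≤ −1 medium, else
poor — exact boundaries deliberately go to the better band. Local scores
are smoothed with a centred 15-residue moving mean truncated at the chain
ends (no padding), displayed against a pseudo-energy threshold of 0.

## Benchmark evaluation

Template detection is scored at the fold level: each id is weighted by the
reciprocal of its fold size so every fold contributes equally, and a
query–template pair takes the product of the two weights. The weighted ROC
sweeps the score threshold descending, collapsing tied scores into a single
step; TPR at a requested FPR (conventionally 10%) is linearly interpolated;
the area uses the trapezoid rule. With equal weights the curve reduces to
the standard ROC.

## Synthetic generators

Backbones grow in internal coordinates (NeRF placement) with ideal peptide
geometry — N–CA 1.458, CA–C 1.525, C–N 1.329 Å; N-CA-C 111.2°,
CA-C-N 116.2°, C-N-CA 121.7°; ω = 180° — plus carbonyl O and a CB
pseudo-side-chain (no CB on glycine). Prescribed (φ, ψ) are recovered on
recomputation to well under 0.5°. A requested PB string is realised by
giving each residue the central (φ, ψ) pair of its letter's reference
vector; only letters with near-homogeneous reference windows (m, d) are
exactly self-consistent under this construction, so the toy-fold generator
judges fold distinctness on the PB string the backbone *actually* realises
(pairwise Hamming separation ≥ 30% of length, drawn until satisfied).

Toy databanks (defaults: 5 folds × 2 members, 40 residues, member
sequences mutated from the fold master at rate 0.3) give every member its
own template record and emit a fold map for evaluation. Query fixtures are
held-out members: sequence freshly mutated at 0.3, an 8-row MSA generated
around it (substitutions at 0.3, deletion-only indels at 0.05 with
geometric run lengths — insertions would be dropped by master-column
profiles anyway), and PB/SA tracks computed from the member's own
structure, standing in for an external predictor. All generators are pure
functions of their seeds.

What the toys do not emulate: real side chains and packing (SASA classes on
toys reflect backbone+CB burial only), structural divergence between fold
members (members share one backbone), predictor noise on the query PB/SA
tracks, and realistic fold-space score distributions. Passing the recovery
tests therefore demonstrates the correctness and discriminative wiring of
the pipeline, not field performance on remote-homology benchmarks, which
requires real structure databanks and external MSA/PB/SA predictors.

## Problem sizes

Default verification sizes were chosen to exercise every code path while
keeping the whole suite quick on a laptop: 200 random profile pairs of
length ≤ 5 for exhaustive-enumeration agreement (enumeration cost grows
combinatorially), 5×2×40-residue databanks, 50 recovery trials, and
4 queries per fold for the ROC benchmark in the acceptance script.

## Known limitations

- No statistical significance (E-values) for hit scores; ranking uses raw
  total scores.
- mmCIF input, multi-model ensembles and PB *prediction* from sequence are
  out of scope; query PB/SA evidence comes from files or structures the
  caller supplies.
- The DP is a straightforward O(nm) Python loop — adequate for domain-sized
  profiles and small databanks, not optimised for proteome-scale scans.
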