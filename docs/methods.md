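# Methods

## Structure model and I/O

Structures are read (PDB or mmCIF, via gemmi) into a minimal
model→chain→residue→atom hierarchy. Only the first model of an
ensemble is kept. Alternate conformers collapse to the
highest-occupancy copy, ties resolved toward altloc A, so every
downstream geometry is single-conformer. Hydrogens are dropped on
read: the analyses target moderate-resolution crystal structures
(~2.5–3 Å) where hydrogens are not modelled, and every geometric
criterion in the package is defined on heavy atoms. Waters and
non-polymer heteroatoms (e.g. glycans) are retained but flagged, and
are excluded from footprints by default so buried areas describe
protein–protein burial.

Author (deposited) residue numbering is the canonical coordinate
system everywhere; translation to another receptor's mature numbering
happens only in the variant/overlap mapping layer. The immunoglobulin
domain-1 boundary used for domain-level superposition defaults to
ectodomain residues 1–101 and is a configurable range, since domain
boundaries differ slightly between depositions.

## SASA

Shrake–Rupley sphere sampling with a deterministic golden-section
spiral point set — no randomness anywhere, so areas are
bit-reproducible for fixed parameters. Defaults: probe 1.4 Å, 960
points per atom, Bondi-style radii (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å) with a 1.80 Å fallback for other elements; the table and the
fallback are overridable, and the fallback can be disabled to make an
unknown element a hard error. Occlusion candidates come from a uniform
spatial grid with cell size 2×(max radius + probe), making the sweep
effectively linear in atom count. At 960 points a single sphere is
exact to ≲0.5% and cluster totals agree with a 10,000-point evaluation
to ≲3%; tests also cross-check totals against an independent SASA
implementation (biotite) to within 5%, which is the right expectation
given that published areas from different programs differ at the few
percent level.

## Footprints and partition

Buried area is one-sided on the target: ΔSASA of the antigen alone
minus in-complex, clamped at zero per atom. This convention is chosen
because a per-binder-chain *partition* is only exactly additive on one
side: each buried target atom's loss is attributed to the binder chain
owning the nearest binder atom (KD-tree), so the chain attributions
sum to the footprint total at machine precision. Epitope membership
uses a 1.0 Å² per-residue threshold; totals always use raw ΔSASA so
they are threshold-independent.

## Contact classification

All criteria are heavy-atom based and config-exposed
(`ContactCriteria`): hydrogen bonds require a donor-capable and an
acceptor-capable atom (embedded per-residue chemistry table; backbone
N donor except proline, backbone O/OXT acceptor) within 3.5 Å, with a
heavy-atom angle proxy — every atom covalently bonded to the donor
must subtend ≥ 90° to the acceptor, which rejects acceptors tucked
behind the donor's bond without needing hydrogen positions.
Hydrophobic contacts pair apolar carbons (carbons whose bonded
neighbours are carbon/hydrogen, tabulated per residue) within 4.5 Å.
Aromatic rings (Phe/Tyr six-ring, His five-ring, both Trp rings) are
summarised by centroid and SVD plane normal; π-stacking requires
centroids within 5.5 Å and normals within 30° of parallel, cation-π
requires Lys NZ or Arg CZ within 6.0 Å of a centroid. Cutoffs follow
common practice; because published figures rarely state theirs, the
intended test surface is qualitative recovery of reported contacts,
not exact counts.

## Superposition and TM-score

CA-only Kabsch superposition (SVD, smallest singular axis negated when
the determinant is negative, so rotations are always proper). Residue
pairing is by author number or through a global pairwise alignment
(BLOSUM62, gap open 10 / extend 0.5); fewer than three or collinear
pairs are errors. The TM-score is evaluated on the *fixed* pairing
with d₀ = 1.24(L−15)^⅓ − 1.8 — no iterative fragment re-search as in
full TM-align, which is out of scope; L defaults to the number of
paired residues and can be set to a reference domain length. Scores
computed this way are comparable to TM-align on near-identical
domains but can differ when the optimal correspondence is ambiguous.

## Footprint mapping and overlap

Footprints on homologous receptors are compared at residue level:
per-residue areas are transferred through aligned columns onto one
reference numbering (source positions facing a reference gap are
dropped and reported), and overlap is Σ min(area_A, area_B) per
position. A residue-level min-area convention was chosen over
atom-level surface intersection after superposition because the two
footprints live on non-identical receptors where atom correspondence
is undefined; the atom-level alternative is documented here but not
implemented. The convention makes overlap symmetric, monotone in
per-position area, and bounded by either total.

## Variants

Variant records carry the receptor's own mature numbering; mapping to
reference numbering walks the MSA columns, and the stated reference
amino acid is checked against the receptor's sequence — a mismatch is
a hard error, which is the guard against stale numbering or
signal-peptide offset mistakes. Gap-facing positions map to
"unmapped" rather than the nearest neighbour. Epitope membership in
the report is defined by the same threshold as the footprint, so the
two modules cannot disagree.

## Kinetics

Association R(t) = Req(1 − e^(−k_obs t)), k_obs = k_on·C + k_off,
Req = R_max·C/(C + K_D); dissociation decays exponentially from the
association endpoint (curve continuity ties the dissociation amplitude
to the association phase). The global fit shares k_on, k_off and
R_max across a dilution series and fits both phases jointly — the
alternative of association-only fitting is ambiguous in common
instrument descriptions; joint fitting is strictly more constraining
and is what the simulator generates. Parameters are fitted in log
space by Levenberg–Marquardt from a 5×5 log-spaced multistart grid
(k_on ∈ [10³, 10⁷] M⁻¹s⁻¹, k_off ∈ [10⁻⁵, 10⁻¹] s⁻¹), lowest residual
sum of squares wins, ties to the smallest k_on; Langmuir fits are
multimodal on poor data and the grid makes the result deterministic.
Traces are assumed reference-subtracted (no drift term by default).

Steady-state fitting estimates each trace's equilibrium response as
the mean of the final 10% of the association window and fits
Req(C) = R_max·C/(C + K_D). When the fitted K_D exceeds the top
analyte concentration the series cannot have saturated and the fit is
flagged `non_saturating` (a warning, not an error) — the regime of the
weak-binder design, where a 1650 nM K_D is probed with a 500 nM top
concentration. On data that do reach equilibrium the steady-state and
global K_D agree within a few percent, matching the expectation that
the two estimators are near-equivalent for well-behaved binders.

## Synthetic data

The generators define the study conditions and are pure functions of
their seed.

*Toy complexes*: two ideal α-helices (φ = −57°, ψ = −47°, standard
bond internal coordinates, NeRF construction; principal axis rotated
onto z) at a configurable chain gap (default 12 Å CA–CA). Planted
contacts are realised by explicit side-chain placement along the axis
between facing CA atoms — Ser OG→Asp OD1 for hydrogen bonds (collinear
with the donor bond, so the angle proxy is exactly 180°), Lys
NZ→Trp-ring centroid for cation-π, eclipsed Phe rings for π-stacking,
Leu CD1 pairs for hydrophobic — at exactly the target distance.
Residues flanking a device become glycine so stray Cβ atoms cannot
enter a cutoff shell, making the planted set the *complete* expected
contact list. Structures are emitted as standard PDB so the reader is
exercised on its real input format. What the toy does not emulate:
packed protein cores, solvent networks, rotamer strain, or crystal
contacts — passing these tests shows the geometry and bookkeeping are
right, not that biological interfaces are simple.

*KIR-like MSA*: a seeded random 200-column gapless family alignment
(reference first, siblings diverged at ~5% of columns) plus a variant
table alternating between epitope and non-epitope positions, with the
expected intersection report emitted alongside. It emulates the
shape of a receptor-family alignment and variant cross-reference, not
real KIR allele sequences or frequencies.

*BLI datasets*: 6 two-fold dilutions from a 250 nM top concentration
(500 nM for the weak-binder design), 300 s association / 600 s
dissociation, 1 s sampling, optional Gaussian noise (the noisy-recovery
experiments use 2% of R_max); per-well CSVs plus a manifest,
byte-identical under a fixed seed. Mass-transport limitation,
baseline drift and sensor-to-sensor variability are not simulated.

## Problem sizes and numerical choices

Default test problem sizes (15–30-residue helices, 960 sphere points,
6-trace kinetics series) keep the full suite and the acceptance script
in the seconds range while leaving every algorithm on its real code
path. Tolerances used in tests reflect estimator properties, not
tuning: exact identities at machine precision (partition additivity,
Kabsch identity), discretisation bounds for SASA (0.5% sphere, 3%
convergence, 5% cross-implementation), and recovery bounds verified by
simulation for the stochastic fits (1% noise-free, 15% at 2% noise,
20% for the non-saturating steady-state design).

## Known limitations

- SASA radii are a single embedded set; reported absolute areas shift
  by a few percent under other published radii, which matters when
  comparing to areas computed by other programs.
- The hydrogen-bond angle proxy cannot distinguish donor/acceptor
  tautomers (His) or bifurcated bonds.
- TM-score on a fixed pairing understates similarity when the true
  correspondence differs from the sequence alignment.
- The overlap metric is residue-granular; two footprints touching
  different atoms of the same residue still count as overlapping.
- Kinetics models are strictly 1:1: no avidity, bivalent-analyte or
  mass-transport terms, so ELISA-style avidity-enhanced affinities are
  out of scope by design.
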