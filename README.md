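# epifoot

Structural epitope analysis for antibody–receptor complexes, built
around the lirilumab–KIR2DL3 problem: where does a therapeutic
antibody sit on a killer immunoglobulin-like receptor (KIR), does its
footprint cover the receptor's HLA binding site, which population
variants fall inside the epitope, and how strongly does the antibody
bind each variant?

The package is organised as a library (`src/epifoot/`) driven by
numbered analysis scripts (`analysis/`), with an `epifoot` command-line
interface for ad-hoc use. It is aimed at structural immunologists and
antibody engineers who have a complex structure, a family alignment
with a variant table, and biosensor data, and want the whole chain of
analyses reproducible offline.

## What it computes

**Epitope footprint.** Solvent-accessible surface area (SASA) by the
Shrake–Rupley method: per-atom area is the exposed fraction of a
deterministic golden-spiral point set times 4π(r_vdw + r_probe)².
The one-sided buried area of the antigen against a binder group is

    ΔSASA(residue) = SASA_alone(residue) − SASA_in_complex(residue), clamped at 0,

and each buried atom's loss is attributed to the binder chain owning
the nearest binder atom, so heavy-chain + light-chain attribution sums
to the epitope total exactly.

**Interface contacts.** Heavy-atom geometric classification: hydrogen
bonds (donor/acceptor chemistry table, D···A ≤ 3.5 Å, angle proxy at
the donor ≥ 90°), hydrophobic carbon–carbon contacts (≤ 4.5 Å),
π-stacking (ring centroids ≤ 5.5 Å, near-parallel normals) and
cation-π (Lys NZ / Arg CZ within 6 Å of an aromatic centroid).

**Superposition.** Kabsch least-squares CA superposition (SVD with
reflection correction), RMSD, and the TM-score on a fixed residue
pairing, TM = (1/L) Σ 1/(1 + (dᵢ/d₀)²) with d₀ = 1.24(L−15)^⅓ − 1.8.

**Footprint overlap.** Footprints measured on homologous receptors are
transferred to one reference numbering through a BLOSUM62 pairwise
alignment; overlap = Σ_p min(area_A(p), area_B(p)), plus an occlusion
fraction for domains that bury an epitope.

**Variants.** Variants recorded in any family member's mature
numbering are re-expressed in the reference receptor's numbering by
walking multiple-sequence-alignment columns (with a reference-residue
consistency guard) and intersected with the epitope.

**Binding kinetics.** 1:1 Langmuir biolayer-interferometry model,
R(t) = Req(1 − e^−(k_on·C + k_off)t) during association and exponential
decay from the association endpoint during dissociation; global fit of
(k_on, k_off, R_max) across a dilution series by multistart nonlinear
least squares, K_D = k_off/k_on, and a steady-state fit
Req(C) = R_max·C/(C + K_D) for binders too weak for kinetic fitting.

## Worked example

    python analysis/01_make_fixtures.py
    python analysis/05_binding_kinetics.py

prints

    wild_type_clean: KD 2.8 nM (kon 1e+05 /M/s, koff 0.00028 /s), truth 2.8 nM
    wild_type_2pct_noise: KD 2.79 nM (kon 1e+05 /M/s, koff 0.00028 /s), truth 2.8 nM
    weak binder (steady state): KD 1650 nM, truth 1650 nM, non-saturating flag = True

i.e. the global 1:1 fit recovers the generating affinity of the
simulated high-affinity series exactly and within ~1% under 2% noise,
while the weak binder — measured only up to 500 nM, far below its
K_D — is handled by the steady-state model and correctly flagged as a
non-saturating series. `analysis/02_epitope_footprint.py` likewise
reports the buried-area footprint of the synthetic two-helix complex
(145.9 Å² on the target side, partition identity at machine precision)
and recovers all four planted interface contacts:

    planted-contact recovery: 4/4 (exact)
      cation_pi    A/LYS11/NZ   B/TRP11/ring(...)  4.50 Å
      hbond        A/SER5/OG    B/ASP5/OD1         2.90 Å
      ...

The same functions applied to a deposited antibody–receptor complex
give the real epitope area, its heavy/light partition, contact
inventory, HLA-site overlap and variant intersection (`epifoot
footprint`, `epifoot contacts`, `epifoot overlap`, `epifoot variants`).

## Layout

    src/epifoot/      structure, sasa, interface, superpose, overlap,
                      variants, kinetics, synthetic, pipeline, cli
    analysis/         01–05: fixture generation → footprint → superposition
                      & overlap → variants → kinetics
    tests/            pytest suite (unit, property and acceptance tests)
    docs/methods.md   model assumptions, parameter choices, limitations
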