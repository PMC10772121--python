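"""Generate the synthetic study inputs.

Builds everything the downstream analyses consume, fully offline and
reproducible from one seed: a two-helix antibody/antigen-like complex
with one planted contact of each geometric class, a KIR2D-like family
alignment with a planted variant table, and simulated BLI dilution
series mirroring the two assay designs (high-affinity wild type at a
250 nM top concentration; a weak binder measured from 500 nM).

Writes results/fixtures/ and prints what was planted.
"""

import json
import sys
from pathlib import Path

from epifoot.kinetics import KineticsParams
from epifoot.synthetic import (
    PlantedContact,
    ToyComplexSpec,
    make_bli_dataset,
    make_kir_like_msa,
    make_toy_complex,
)
from epifoot.variants import write_msa

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
OUT.mkdir(parents=True, exist_ok=True)

EPITOPE = {41, 45, 46, 47, 48, 50, 65, 72, 87, 88}  # KIR2DL3-numbering epitope

# --- structures -------------------------------------------------------------
spec = ToyComplexSpec(
    planted_contacts=(
        PlantedContact("hbond", 2.9),
        PlantedContact("cation_pi", 4.5),
        PlantedContact("pi_stack", 5.0),
        PlantedContact("hydrophobic", 4.0),
    ),
    seed=SEED,
)
_, truth = make_toy_complex(spec, out_path=OUT / "toy_complex.pdb")
(OUT / "toy_complex_truth.json").write_text(json.dumps(truth, indent=2) + "\n")

make_toy_complex(
    ToyComplexSpec(inter_chain_gap=9.0, n_residues_per_chain=15, seed=SEED),
    out_path=OUT / "touching_complex.pdb",
)

# --- alignment + variants ---------------------------------------------------
msa, variants, expected = make_kir_like_msa(
    n_receptors=7, n_variants=12, epitope_positions=EPITOPE, seed=SEED
)
write_msa(msa, OUT / "kir_like.afa")
variants.to_csv(OUT / "variants.csv", index=False)
expected.to_csv(OUT / "variants_expected.csv", index=False)

# --- BLI --------------------------------------------------------------------
wt = KineticsParams(kon=1e5, koff=2.8e-4, rmax=1.0)       # KD 2.8 nM
weak = KineticsParams(kon=1e5, koff=1e5 * 1650e-9, rmax=1.0)  # KD 1650 nM
make_bli_dataset(wt, OUT / "bli_wt", top_concentration=250e-9, seed=SEED)
make_bli_dataset(wt, OUT / "bli_wt_noisy", top_concentration=250e-9,
                 noise_sd=0.02, seed=SEED)
make_bli_dataset(weak, OUT / "bli_weak", top_concentration=500e-9, seed=SEED)

print(f"fixtures written to {OUT}")
print(f"planted contacts: {[t['kind'] for t in truth]}")
print(f"variants: {len(variants)} ({int(expected['in_epitope'].sum())} inside the epitope)")
print("BLI: wild-type KD 2.8 nM (clean + 2% noise), weak binder KD 1650 nM")
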