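# Deposited structures (not shipped)

The structural integration tests and walkthrough use public PDB
depositions that are not redistributed here. To enable them, download:

    8TUI  (Fab:KIR2DL3 complex)
    1IM9  (KIR2DL1:HLA-Cw4)
    1B6U  (unbound KIR2DL3)
    6V3J  (KIR3DL1:HLA-B*57:03, optional)

from https://files.rcsb.org/download/<CODE>.pdb and place them in this
directory as lower-case `<code>.pdb` (mmCIF also accepted). The test
suite and all synthetic analyses run fully offline without them.
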