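# Deposited coordinates (user-supplied)

The acceptance checks against the published crystal structures read PDB
entries from this directory as lower-case `<id>.pdb` files:

    6vr1.pdb  wild-type p53 peptide / HLA-A2
    6vr5.pdb  p53R175H peptide / HLA-A2
    6vrm.pdb  TCR 12-6 / p53R175H / HLA-A2 complex
    6vrn.pdb  TCR 38-10 / p53R175H / HLA-A2 complex
    6vqo.pdb  TCR 1a2 / p53R175H / HLA-A2 complex (2 copies / ASU)
    6vth.pdb  unbound TCR 12-6
    6vtc.pdb  unbound TCR 1a2

Download them from https://files.rcsb.org/download/<ID>.pdb (this build
environment has no network access, so they are not bundled).  The tests
assume the conventional chain order A = MHC heavy chain, B = beta-2-
microglobulin, C = peptide, D = TCR alpha, E = TCR beta; adjust the role
maps in tests/test_acceptance.py if an entry deviates.
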