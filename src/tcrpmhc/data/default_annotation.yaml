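# Annotation config template for tcrpmhc.
#
# Loop and helix boundaries are data, not code: deposited structures keep
# author numbering, so override these defaults with the ranges appropriate to
# each structure's numbering scheme.
#
# roles: chain id -> one of mhc_heavy, b2m, peptide, tcr_alpha, tcr_beta.
# Set `peptide: auto` to auto-detect the unique 8-13 residue protein chain.
roles:
  A: mhc_heavy
  B: b2m
  C: peptide
  D: tcr_alpha
  E: tcr_beta
# peptide: auto

# IMGT-like defaults, applied to both TCR chains unless a per-chain mapping
# (chain id -> loop -> [start, end]) is given instead.
cdr_ranges:
  CDR1: [27, 38]
  CDR2: [56, 65]
  HV4: [81, 86]
  CDR3: [105, 117]

# MHC class I alpha1/alpha2 helices on the heavy chain.
helix_ranges:
  alpha1: [50, 86]
  alpha2: [138, 176]

# Conserved V-domain disulfide positions, if auto-detection is ambiguous
# (e.g. full-length chains containing the constant-domain disulfide too).
# cys_pairs:
#   D: [23, 104]
#   E: [23, 104]
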