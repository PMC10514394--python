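# Microcompartment corrections for the l-tryptophan synthesis neighbourhood
# of an iML1515-style E. coli model (direction-split ids).
#
# Tryptophan synthase is an alpha2-beta2 complex with an internal indole
# channel: the alpha partial (TRPS3) and beta partial (TRPS2) never release
# indole, so the overall reaction TRPS1 is kept and the partials are shut
# (shut them with `mdflux merge`'s companion shut list or reaction status).
# Aconitase holds cis-aconitate in its active site, so its two partials
# merge into one reversible overall reaction.
- merged_id: ACONT
  parts:
    - id: ACONTa
    - id: ACONTb
  declared_intermediates: [acon_C_c]
  reversible_pair: true
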