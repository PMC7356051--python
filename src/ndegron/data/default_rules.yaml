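# Default mammalian Arg/N-degron rule table.
#
# classes: residue tiers of the hierarchy.  cascades: ordered enzymatic
# conversions funnelling secondary/tertiary residues to N-terminal Arg
# ("C*" is oxidized Cys, i.e. Cys-sulfinate/-sulfonate).  recognin: which
# UBR substrate-binding site ultimately engages the N-terminus.
# met_excision: second-position residues permitting MetAP cleavage of the
# initiator Met.
classes:
  PRIMARY_TYPE1: [R, K, H]
  PRIMARY_TYPE2: [F, W, Y, L, I]
  SECONDARY: [D, E]
  TERTIARY: [N, Q, C]
  STABILIZING: [A, G, M, P, S, T, V]
cascades:
  N:
    - {enzyme: NTAN1, to: D}
    - {enzyme: ATE1, to: R}
  Q:
    - {enzyme: NTAQ1, to: E}
    - {enzyme: ATE1, to: R}
  C:
    - {enzyme: CYS_OXIDATION, to: "C*"}
    - {enzyme: ATE1, to: R}
  D:
    - {enzyme: ATE1, to: R}
  E:
    - {enzyme: ATE1, to: R}
recognin:
  TYPE1_SITE: [R, K, H, D, E, N, Q, C]
  TYPE2_SITE: [F, W, Y, L, I]
met_excision: [A, C, G, P, S, T, V]
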