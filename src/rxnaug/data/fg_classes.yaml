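# Equivalence classes of mutually substitutable leaving groups.
# Each member is a fragment SMILES with exactly one attachment point '*'.
# 'attach' restricts which element the attachment atom may be.
#
# Fluorine is deliberately absent from the halogen class: aryl fluorides
# are not substrates for these couplings, and the canonical example of the
# method swaps Cl for Br or I.
schema_version: 1
classes:
  halogen:
    attach: [C]
    members:
      - {name: chloro, smiles: "*Cl"}
      - {name: bromo, smiles: "*Br"}
      - {name: iodo, smiles: "*I"}
  boron:
    attach: [C]
    members:
      - {name: boronic_acid, smiles: "*B(O)O"}
      - {name: pinacol_boronate, smiles: "*B1OC(C)(C)C(C)(C)O1"}
      - {name: dioxaborinane, smiles: "*B1OCCCO1"}
  silicon:
    attach: [C]
    members:
      - {name: trimethoxysilyl, smiles: "*[Si](OC)(OC)OC"}
      - {name: triethoxysilyl, smiles: "*[Si](OCC)(OCC)OCC"}
      - {name: trichlorosilyl, smiles: "*[Si](Cl)(Cl)Cl"}
      - {name: dimethylfluorosilyl, smiles: "*[Si](C)(C)F"}
  grignard_halide:
    attach: [Mg]
    members:
      - {name: chloro, smiles: "*Cl"}
      - {name: bromo, smiles: "*Br"}
      - {name: iodo, smiles: "*I"}
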