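# Role and product rules for the five coupling classes ("template screening").
#
# Each role has a SMARTS pattern that must match exactly one reactant
# species.  'leaving_group' names how that species' product core is
# derived (delete the halide atom / the B, Si or Mg centre; 'self' = the
# species itself survives into the product, as for amine nucleophiles).
# 'augment_class' maps augmentable roles to a functional-group class from
# fg_classes.yaml.
#
# Product rules: every role core must reappear in the single product,
# elements in 'forbid_in_product' must be absent, and where
# 'require_halide_loss' is set the count of carbon-bound Cl/Br/I must
# strictly decrease from reactants to product (absence alone would reject
# legitimate spectator halides).
#
# 'precedence' resolves the rare record matching two templates.
schema_version: 1
precedence: [suzuki, hiyama, kumada, buchwald_hartwig, chan_lam]
templates:
  suzuki:
    roles:
      aryl_halide:
        pattern: "[c,$([CX3]=[CX3])][Cl,Br,I]"
        leaving_group: halide
        augment_class: halogen
      organoboron:
        pattern: "[#6][$([BX3]([OX2])[OX2]),$([B-](F)(F)F)]"
        leaving_group: boron
        augment_class: boron
    new_bond: C-C
    forbid_in_product: ["[B]"]
    require_halide_loss: true
  hiyama:
    roles:
      aryl_halide:
        pattern: "[c,$([CX3]=[CX3])][Cl,Br,I]"
        leaving_group: halide
        augment_class: halogen
      organosilicon:
        pattern: "[#6][Si]"
        leaving_group: silicon
        augment_class: silicon
    new_bond: C-C
    forbid_in_product: ["[Si]"]
    require_halide_loss: true
  kumada:
    roles:
      organyl_halide:
        # aryl, vinylic, or primary alkyl halide (alkyl allowed for Kumada only)
        pattern: "[c,$([CX3]=[CX3]),$([CX4;H2])][Cl,Br,I]"
        leaving_group: halide
        augment_class: halogen
      grignard:
        pattern: "[#6][Mg][Cl,Br,I]"
        leaving_group: grignard
        augment_class: grignard_halide
    new_bond: C-C
    forbid_in_product: ["[Mg]"]
    require_halide_loss: true
  buchwald_hartwig:
    roles:
      aryl_halide:
        pattern: "[c,$([CX3]=[CX3])][Cl,Br,I]"
        leaving_group: halide
        augment_class: halogen
      amine:
        pattern: "[NX3;H1,H2;!$(N=*);!$(N[CX3]=[O,S,N])]"
        leaving_group: self
    new_bond: C-N
    forbid_in_product: []
    require_halide_loss: true
  chan_lam:
    roles:
      organoboron:
        pattern: "[#6][$([BX3]([OX2])[OX2]),$([B-](F)(F)F)]"
        leaving_group: boron
        augment_class: boron
      n_or_o_nucleophile:
        pattern: "[$([NX3;H1,H2;!$(N=*);!$(N[CX3]=[O,S,N])]),$([OX2H][#6;!$([CX3]=O)])]"
        leaving_group: self
    new_bond: C-N/C-O
    forbid_in_product: ["[B]"]
    require_halide_loss: false
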