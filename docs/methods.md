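# Methods

## The augmentation model

The method rests on a chemical equivalence argument: within a coupling
reaction class, certain leaving groups are interchangeable without
altering the transformation. An aryl chloride, bromide and iodide all
undergo the same oxidative addition; a boronic acid and its pinacol or
1,3,2-dioxaborinane esters transmetalate to the same aryl fragment.
Replacing one member of such a class by another therefore yields a
reaction with the *same product*, the *same reaction site* and valid
valences everywhere — a plausible data point the corpus happened not to
contain. Adding these fakes to the training set densifies the sampled
chemical space without inventing new chemistry.

Two modes exist. *Single* augmentation varies one reactant role: at a
unique substitutable site it produces exactly `|members| − 1` fakes.
*Simultaneous* augmentation varies several roles at once, producing the
Cartesian product `∏ |members_r| − 1` (the original combination is
excluded). The per-class convention follows how each coupling is run in
practice: Hiyama varies halide × silicon, Suzuki halide × boron, Kumada
the organyl halide × the Mg-bound halide of the Grignard reagent;
Buchwald–Hartwig varies the halide only and Chan–Lam the boron group
only (their N/O nucleophiles have no interchangeable leaving group).

### Functional-group classes

Shipped defaults (`fg_classes.yaml`, fully user-overridable):

| class | members | attachment |
|---|---|---|
| halogen | –Cl, –Br, –I | carbon |
| boron | –B(OH)₂, –Bpin, –B(1,3,2-dioxaborinane) | carbon |
| silicon | –Si(OMe)₃, –Si(OEt)₃, –SiCl₃, –SiMe₂F | carbon |
| grignard_halide | –Cl, –Br, –I | magnesium |

Fluorine is excluded from the halogen class: aryl fluorides are not
substrates for these couplings, so a C–F "variant" would not be a
plausible reaction. The boron and silicon member lists are a deliberate
design choice — the method is the substitution engine, not any one list —
and can be replaced per run. The `grignard_halide` class is
distinguished from `halogen` purely by its attachment element (Mg), which
is how the engine avoids ever touching a carbon-bound halide when varying
a Grignard reagent and vice versa.

### Safety rules

A site is substituted only when two conditions hold:

1. **Uniqueness** — the class matches exactly once in the role's species.
   A reactant bearing both Br and Cl on the ring is ambiguous: swapping
   either could silently move the reaction site, so the species yields no
   sites at all.
2. **Leaving-group confirmation** — the matched group is absent from the
   product. A spectator chloride that survives into the product is
   demonstrably *not* the leaving group and is never substituted.

Both rules are conservative: a record failing either is skipped, never
guessed. Group matching is exact-terminal: a member's atoms may bond only
to each other and the attachment atom, so –B(OH)₂ can never half-match a
pinacol boronate ring.

Substitution itself is graph surgery (delete the matched atoms, attach
the new fragment at the same atom, re-sanitize). Any chemically invalid
result raises instead of being emitted; every emitted fake re-parses and
re-passes its parent's template.

## Template screening

The five class rules are SMARTS role patterns plus a product predicate,
shipped as editable YAML. A record passes a template when a *perfect
matching* exists: every role satisfied by a distinct reactant species.
Matching rather than strict per-role uniqueness is required because a
spectator halide on, say, the boron partner makes the halide pattern
match two species; the matching requirement resolves the assignment
without rejecting a legitimate reaction. The product predicate
operationalizes "the coupling actually happened" without atom mapping:

- each role's *core* (the species with its leaving group excised) must
  reappear as a substructure of the single product;
- B, Si or Mg (per class) must be absent from the product;
- where the class consumes a halide, the count of carbon-bound Cl/Br/I
  must strictly *decrease* from reactants to product. A decrease rather
  than absence is required so spectator halides pass; the trade-off is
  that a record whose spectator count coincidentally masks a retained
  leaving group would be missed — acceptable for a screening filter.

Records matching two templates are resolved by a fixed precedence
(suzuki > hiyama > kumada > buchwald_hartwig > chan_lam) with a warning;
multiple within-species matches of one role mark the record
ambiguous-site: it passes screening but is excluded from augmentation.
Kumada's halide pattern additionally admits primary sp³ halides, a
flagged config choice; the other classes accept aryl/vinyl halides only.

## Curation pipeline

Reactants vs. reagents on the left of `>>` are distinguished
heuristically: a species is a reactant when it (or its core after
removing a standard leaving-group motif) occurs as a substructure of the
product; Grignard species are always reactants. Small ions ([F⁻], [K⁺])
and catalysts fall through to reagent. The record identity key —
the canonical reaction string used for every dedup and leakage check —
deliberately ignores this role split and input ordering: it is a pure
function of the left-side species multiset and the product.

Splits are random with a mandatory seed: validation and test each get
⌊N·r/10⌋ records (floor, so evaluation sets never exceed nominal size)
and train takes the remainder; 10-fold CV assigns every record to exactly
one held-out fold. Augmentation runs strictly *after* splitting and only
on the training portion. Fakes colliding with raw training reactions are
deleted; fakes colliding with validation or test reactions are likewise
dropped (a leakage guard — evaluating on reactions present in training
would inflate accuracy). Merged fakes are appended in canonical-string
order, so identical inputs give byte-identical files; the pipeline
manifest records seeds, config hash and SHA-256 digests and carries no
wall-clock state, making reruns bit-reproducible. All randomness derives
from one top-level seed expanded per stage as
`(seed·1000003 + crc32(stage)) mod 2³¹`.

The tokenizer is the conventional regex scheme for SMILES seq2seq
models: bracket atoms, two-letter halogens and `%nn` ring closures are
single tokens, and joining the tokens reproduces the input exactly. The
exported training configuration (Adam β₁ = 0.9, β₂ = 0.997, ε = 1e-9,
8 heads, 256-dim embeddings, 6 layers) is the published baseline for
this task, written as YAML next to the data.

## Error taxonomy

Wrong predictions are labelled by a fixed cascade: unparsable →
`invalid_smiles`; canonical-equal → `correct`; equal after stereo
stripping → `chirality`; different carbon counts → `atom_count`; equal
molecular formula but different graph → `group_isomerism`
(constitutional isomer); else `other`. Chirality precedes the count
rules so a stereo-only miss is never masked. The carbon count (not the
full formula) keys rule 4, matching the published tabulation of "carbon
number" errors; a same-carbon different-formula miss lands in `other`.
Report percentages are computed over the wrong subset only, the
convention under which the published per-class columns sum to ~100%.

## Synthetic data

The generator emulates a screened single-class extraction from a
commercial reaction database: an n_aryl × n_partner grid of
para/meta-substituted aryl halides crossed with type-appropriate
partners (trimethoxysilanes, boronic acids, aryl Grignards, secondary
amines), with class-typical reagents ([F⁻]/[K⁺], carbonate, alkoxide,
copper). Products are built by deterministic graph surgery — join the
two role carbons, delete both leaving groups — so the expected type,
sites and fake counts are exact by construction, and each record carries
a purely textual *recipe* from which an independent string-substitution
enumerator reproduces every expected fake; the graph-surgery engine is
tested against it, not against itself. The partner vocabulary includes a
spectator chlorine deliberately, to exercise the confirmation rule.
Decoy families (esterifications, ketone reductions) provide negative
controls that fail all five templates.

What the generator does *not* emulate: the structural diversity of real
extractions (fused rings, heterocycles, multiple competing halides),
stereochemistry in substrates, yield/condition metadata, and the skewed
growth factors real corpora show when many records have ambiguous or
unconfirmed sites. Passing tests therefore demonstrate the correctness
of the machinery — counting identities, product invariance, leakage
guards, determinism — not the downstream accuracy gains on real data,
which require training a model.

## Problem sizes and numerical choices

Tests and the acceptance script use grids of 9–200 reactions per class,
N = 1000 trivial records for split arithmetic and 500 generated arenes
for the self-classification check — sizes at which every property is
exactly checkable in seconds. Canonicalization, substructure matching
and formula computation are delegated to RDKit (the backend and version
are recorded in every output's metadata; canonical strings are not
comparable across backends). Ties and orderings are everywhere resolved
by canonical-string sort. Degenerate inputs are errors, not guesses:
empty product side, multiple products, unparsable species and
too-small datasets each carry a distinct error code.

## Known limitations

- The reactant/reagent heuristic can misfile an exotic catalyst that
  shares a large substructure with the product; the identity key is
  immune, but role-dependent statistics would shift.
- Screening is deliberately strict: reactions whose roles cannot be
  assigned to distinct species (e.g. an intramolecular coupling) are
  rejected.
- The product-side substructure check cannot detect a coupling whose
  regiochemistry differs from the formal join; it verifies fragments,
  not atom-mapped bonds.
- Stereochemistry is preserved through parsing and substitution but the
  generator produces achiral substrates only; the `strip_stereo` option
  mirrors preprocessing pipelines that delete chirality.
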