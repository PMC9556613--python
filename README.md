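# rxnaug

Virtual data augmentation for coupling-reaction prediction datasets.

Sequence-to-sequence models that predict reaction products from reaction
SMILES need far more examples than most single-reaction-class corpora
contain — a few thousand Hiyama or Chan–Lam couplings are not enough to
train a transformer well. `rxnaug` implements a chemistry-aware remedy:
generate *fake* (virtual) reactions by swapping a reactant's leaving group
for an equivalent member of the same functional-group class, while keeping
the product — and therefore the reaction site and every atom valence —
unchanged. A training aryl chloride becomes a bromide and an iodide; a
boronic acid becomes its pinacol ester; a trimethoxysilane becomes a
trichlorosilane. Each swap is a chemically plausible reaction the corpus
simply did not contain.

The package is aimed at people curating reaction datasets for machine
learning. It covers the full preparation pipeline around the method:

- **chem_core** — reaction-SMILES parsing, RDKit canonicalization
  (the identity key for all deduplication), a lossless regex tokenizer,
  and export of the seq2seq training hyperparameters.
- **templates** — *template screening*: rule-based classification into the
  five coupling classes (Suzuki, Hiyama, Kumada, Buchwald–Hartwig,
  Chan–Lam) from editable SMARTS role patterns plus a product check.
- **augment** — the substitution engine: *single* augmentation varies one
  role (`|fakes| = |members| − 1` at a unique site); *simultaneous*
  augmentation takes the Cartesian product across roles
  (`∏|members| − 1`). Fakes that would touch an ambiguous site or a
  spectator group that survives into the product are never emitted.
- **dataset_builder** — 8:1:1 train/valid/test splits and 10-fold CV
  plans; augmentation applied strictly after splitting, to train only,
  with held-out reactions as a leakage guard; statistics (raw vs. virtual
  counts, growth factor); line-aligned `src`/`tgt` parallel-corpus export.
- **error_analysis** — a deterministic cascade labelling each predicted
  product against its reference: `correct`, `invalid_smiles`,
  `chirality`, `atom_count`, `group_isomerism` (constitutional isomer),
  or `other`.
- **synthetic_fixtures** — combinatorial generators of coupling datasets
  with exact ground truth, used throughout the tests.

## Worked example

```python
from rxnaug import (parse_reaction_smiles, write_reaction_smiles,
                    classify_reaction, single_augment, default_templates)

rxn = ("CC[Si](Cl)(Cl)c1ccc(C)cc1.N#Cc1ccc(Br)cc1.[F-].[K+]"
       ">>Cc1ccc(-c2ccc(C#N)cc2)cc1")
record = parse_reaction_smiles(rxn)
print(classify_reaction(record))
for fake in single_augment(record, default_templates()["hiyama"], "aryl_halide"):
    print(fake.provenance, write_reaction_smiles(fake))
```

prints

```
hiyama
fake CC[Si](Cl)(Cl)c1ccc(C)cc1.N#Cc1ccc(Cl)cc1.[F-].[K+]>>Cc1ccc(-c2ccc(C#N)cc2)cc1
fake CC[Si](Cl)(Cl)c1ccc(C)cc1.N#Cc1ccc(I)cc1.[F-].[K+]>>Cc1ccc(-c2ccc(C#N)cc2)cc1
```

The record is recognised as a Hiyama coupling (aryl silane + aryl
bromide, fluoride activation). Single augmentation of the halide role
with the halogen class {Cl, Br, I} yields exactly two fakes — the chloro
and iodo variants — each with the product copied unchanged. The silicon
role is untouched here because the dichloro(ethyl)silyl group is not a
member of the shipped silicon equivalence class; simultaneous
augmentation of a trimethoxysilane record would instead give
3 × 4 − 1 = 11 fakes.

The same flow is available from the shell:

```bash
rxnaug fixtures --type hiyama --n-aryl 10 --n-partner 10 --seed 0 -o raw.txt
rxnaug filter raw.txt --type hiyama --kept kept.txt --rejected rejected.txt
rxnaug split kept.txt --seed 0 -o splits/
rxnaug augment splits/train.txt --mode simultaneous --type hiyama \
       --role aryl_halide --role organosilicon \
       --guard splits/valid.txt --guard splits/test.txt -o train_aug.txt
rxnaug run --config pipeline.yaml -o out/   # all stages + manifest
```

Functional-group classes (`src/rxnaug/data/fg_classes.yaml`) and the
screening templates (`templates.yaml`) are ordinary YAML and can be
replaced with `--classes` / `--templates`.

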