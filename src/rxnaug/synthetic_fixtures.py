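"""Synthetic coupling datasets with exact ground truth.

Combinatorial aryl-halide x partner grids for the five coupling classes,
with products built by deterministic graph surgery (join the two role
carbons, delete both leaving groups) — so the expected reaction type,
augmentable sites and fake counts are known by construction, and every
pipeline stage is testable without any proprietary reaction corpus.

Each generated record carries a :class:`ReactionRecipe`, a purely textual
description of how its SMILES line was assembled.  The recipe powers
:func:`enumerate_fake_strings`, a string-substitution enumerator of all
expected fakes that is independent of the graph-surgery augmentation
engine and serves as its oracle.

The default partner vocabulary includes a spectator chlorine substituent,
deliberately, to exercise the leaving-group-confirmation rule.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from rdkit import Chem

from .augment import FunctionalGroupClass, default_fg_classes
from .chem_core import Molecule, ReactionRecord, parse_reaction_smiles

#: para/meta-substituted aryl cores; '{X}' is the halide, '{S}' the substituent
_ARYL_CORES = ("{X}c1ccc({S})cc1", "{X}c1cccc({S})c1")

ARYL_SUBSTITUENTS = (
    "C", "CC", "OC", "C#N", "C(C)=O", "[N+](=O)[O-]", "F", "CCC",
    "C(F)(F)F", "OCC", "C(C)C", "N(C)C", "SC", "CCCC", "OC(C)C",
    "CC(C)C", "C(=O)OC", "CCO", "C(C)(C)C", "OCCC",
)

#: the 'Cl' entry is a *spectator* halide that survives into the product
PARTNER_SUBSTITUENTS = (
    "C", "OC", "CC", "Cl", "C(F)(F)F", "CCC", "F", "OCC", "C(C)C",
    "CCCC", "N(C)C", "SC", "CC(C)C", "OCCC", "C(=O)OC", "CCO",
)

#: secondary amines (Buchwald-Hartwig and Chan-Lam nucleophiles)
AMINES = (
    "CCNCC", "CNC", "C1CCNC1", "C1CCNCC1", "C1COCCN1", "CCCCNC",
    "C1CCCNCC1", "CNc1ccccc1", "CC1CCNCC1", "CCNC",
)

#: partner member fragment (textual, no '*') and its member name, per type
_PARTNER_GROUP = {
    "suzuki": ("B(O)O", "boronic_acid"),
    "hiyama": ("[Si](OC)(OC)OC", "trimethoxysilyl"),
    "chan_lam": ("B(O)O", "boronic_acid"),
}

_REAGENTS = {
    "suzuki": ("O=C([O-])[O-]", "[K+]", "[K+]"),
    "hiyama": ("[F-]", "[K+]"),
    "kumada": (),
    "buchwald_hartwig": ("CC(C)(C)[O-]", "[Na+]"),
    "chan_lam": ("[Cu]",),
}


class FixtureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    rxn_type: str
    n_aryl: int
    n_partner: int
    seed: int = 0
    halide: str = "Br"
    grignard_halide: str = "Br"
    substituents: tuple[str, ...] = ARYL_SUBSTITUENTS
    partner_substituents: tuple[str, ...] = PARTNER_SUBSTITUENTS


@dataclass(frozen=True)
class ReactionRecipe:
    """Textual assembly instructions for one generated reaction.

    ``aryl_template`` has a ``{X}`` halide slot (empty for Chan-Lam, whose
    electrophile is the boron species).  ``partner_template`` has a ``{M}``
    slot for the partner leaving-group text (Kumada: ``{X2}`` for the
    Mg-bound halide).  The product never varies.
    """

    rxn_type: str
    aryl_template: str
    partner_template: str
    halide: str
    partner_text: str
    reagents: tuple[str, ...]
    product: str  # canonical

    def left_strings(self, x: str | None = None, m: str | None = None) -> list[str]:
        out = []
        if self.aryl_template:
            out.append(self.aryl_template.format(X=x if x is not None else self.halide))
        m = m if m is not None else self.partner_text
        out.append(self.partner_template.format(M=m, X2=m))
        out.extend(self.reagents)
        return out

    def reaction_string(self, x: str | None = None, m: str | None = None) -> str:
        return ".".join(self.left_strings(x, m)) + ">>" + self.product


# --- product construction by graph surgery --------------------------------


def _first_match(mol: Chem.Mol, smarts: str):
    q = Chem.MolFromSmarts(smarts)
    matches = mol.GetSubstructMatches(q)
    return matches[0] if matches else None


def formal_coupling(
    electrophile: Chem.Mol,
    nucleophile: Chem.Mol,
    rxn_type: str,
) -> Molecule:
    """Join the two role atoms and delete both leaving groups.

    Electrophile: C-X (X = Cl/Br/I) for halide couplings, C-B(O)O for
    Chan-Lam.  Nucleophile: the carbon bound to B/Si/Mg, or the amine N.
    No mechanistic modelling — a purely formal bond rewrite so the ground
    truth is exact by construction.
    """
    if rxn_type == "chan_lam":
        m = _first_match(electrophile, "[#6][BX3]([OX2H])[OX2H]")
        a1, e_doomed = m[0], list(m[1:])
    else:
        m = _first_match(electrophile, "[#6][Cl,Br,I]")
        a1, e_doomed = m[0], [m[1]]

    if rxn_type in ("suzuki",):
        m = _first_match(nucleophile, "[#6][BX3]([OX2H])[OX2H]")
        a2, n_doomed = m[0], list(m[1:])
    elif rxn_type == "hiyama":
        m = _first_match(nucleophile, "[#6][Si]")
        si = nucleophile.GetAtomWithIdx(m[1])
        a2 = m[0]
        # the silyl group and everything hanging off it except the aryl carbon
        n_doomed = [m[1]] + [
            nb.GetIdx() for nb in si.GetNeighbors() if nb.GetIdx() != a2
        ]
        # extend to full substituent subtrees (OMe etc.)
        n_doomed = _grow_subtree(nucleophile, n_doomed, keep=a2)
    elif rxn_type == "kumada":
        m = _first_match(nucleophile, "[#6][Mg][Cl,Br,I]")
        a2, n_doomed = m[0], [m[1], m[2]]
    elif rxn_type in ("buchwald_hartwig", "chan_lam"):
        m = _first_match(nucleophile, "[NX3;H1,H2]")
        a2, n_doomed = m[0], []
    else:
        raise FixtureConfigError(f"no product rule for {rxn_type!r}")

    combined = Chem.RWMol(Chem.CombineMols(electrophile, nucleophile))
    off = electrophile.GetNumAtoms()
    combined.AddBond(a1, a2 + off, Chem.BondType.SINGLE)
    if n_doomed == [] and rxn_type in ("buchwald_hartwig", "chan_lam"):
        atom = combined.GetAtomWithIdx(a2 + off)
        if atom.GetNumExplicitHs():
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
    for idx in sorted(e_doomed + [i + off for i in n_doomed], reverse=True):
        combined.RemoveAtom(idx)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return Molecule.from_smiles(Chem.MolToSmiles(out))


def _grow_subtree(mol: Chem.Mol, seeds: list[int], keep: int) -> list[int]:
    doomed = set(seeds)
    frontier = list(seeds)
    while frontier:
        idx = frontier.pop()
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            j = nb.GetIdx()
            if j != keep and j not in doomed:
                doomed.add(j)
                frontier.append(j)
    return sorted(doomed)


# --- dataset generation ---------------------------------------------------


def _aryl_templates(cfg: GeneratorConfig) -> list[str]:
    combos = [
        core.replace("{S}", sub)
        for core, sub in itertools.product(_ARYL_CORES, cfg.substituents)
    ]
    if cfg.n_aryl > len(combos):
        raise FixtureConfigError(
            f"vocabulary supports at most {len(combos)} aryl variants, "
            f"requested {cfg.n_aryl}"
        )
    return combos[: cfg.n_aryl]


def _partner_templates(cfg: GeneratorConfig) -> list[str]:
    t = cfg.rxn_type
    if t in ("buchwald_hartwig", "chan_lam"):
        if cfg.n_partner > len(AMINES):
            raise FixtureConfigError(
                f"vocabulary supports at most {len(AMINES)} amines, "
                f"requested {cfg.n_partner}"
            )
        return list(AMINES[: cfg.n_partner])
    # '{M}' sits after the ring closure so multi-atom member texts
    # (B(O)O, [Si](OC)(OC)OC, ...) bond to the ring carbon correctly
    combos = ["c1ccc(" + sub + ")cc1{M}" for sub in cfg.partner_substituents]
    if cfg.n_partner > len(combos):
        raise FixtureConfigError(
            f"vocabulary supports at most {len(combos)} partner variants, "
            f"requested {cfg.n_partner}"
        )
    return combos[: cfg.n_partner]


def generate_with_recipes(
    cfg: GeneratorConfig,
) -> list[tuple[ReactionRecord, ReactionRecipe]]:
    """The n_aryl x n_partner grid of coupling reactions, with recipes.

    Deterministic per seed (the seed shuffles the emission order only;
    the grid itself is fixed by the vocabulary)."""
    t = cfg.rxn_type
    if t not in _REAGENTS:
        raise FixtureConfigError(f"unknown reaction type {t!r}")
    reagents = _REAGENTS[t]
    partners = _partner_templates(cfg)

    out: list[tuple[ReactionRecord, ReactionRecipe]] = []
    if t == "chan_lam":
        # electrophile role is the boron species; build its grid from the
        # aryl substituent vocabulary with a suffix member slot
        combos = [
            core.replace("{S}", sub)
            for core, sub in itertools.product(
                ("c1ccc({S})cc1{M}", "c1cccc({S})c1{M}"), cfg.substituents
            )
        ]
        if cfg.n_aryl > len(combos):
            raise FixtureConfigError(
                f"vocabulary supports at most {len(combos)} boron variants, "
                f"requested {cfg.n_aryl}"
            )
        boron_templates = combos[: cfg.n_aryl]
        for btpl, amine in itertools.product(boron_templates, partners):
            e_mol = Chem.MolFromSmiles(btpl.format(M="B(O)O"))
            n_mol = Chem.MolFromSmiles(amine)
            product = formal_coupling(e_mol, n_mol, t)
            # the amine rides in the recipe's fixed text slots; chemically it
            # is a reactant and the parser recovers that role
            recipe = ReactionRecipe(
                rxn_type=t,
                aryl_template="",
                partner_template=btpl,
                halide="",
                partner_text="B(O)O",
                reagents=(amine,) + reagents,
                product=product.smiles,
            )
            out.append((_record_from_recipe(recipe), recipe))
    else:
        aryls = _aryl_templates(cfg)
        for atpl, ptpl in itertools.product(aryls, partners):
            if t == "buchwald_hartwig":
                partner_template, partner_text = ptpl, ""
                n_mol = Chem.MolFromSmiles(ptpl)
            elif t == "kumada":
                partner_template = ptpl.replace("{M}", "[Mg]{X2}")
                partner_text = cfg.grignard_halide
                n_mol = Chem.MolFromSmiles(
                    partner_template.format(X2=cfg.grignard_halide)
                )
            else:
                partner_template = ptpl
                partner_text = _PARTNER_GROUP[t][0]
                n_mol = Chem.MolFromSmiles(ptpl.format(M=partner_text))
            e_mol = Chem.MolFromSmiles(atpl.format(X=cfg.halide))
            product = formal_coupling(e_mol, n_mol, t)
            recipe = ReactionRecipe(
                rxn_type=t,
                aryl_template=atpl,
                partner_template=partner_template,
                halide=cfg.halide,
                partner_text=partner_text,
                reagents=reagents,
                product=product.smiles,
            )
            out.append((_record_from_recipe(recipe), recipe))

    rng = random.Random(cfg.seed)
    rng.shuffle(out)
    return out


def _record_from_recipe(recipe: ReactionRecipe) -> ReactionRecord:
    rec = parse_reaction_smiles(recipe.reaction_string())
    return rec.replace(rxn_type=recipe.rxn_type)


def generate_coupling_dataset(cfg: GeneratorConfig) -> list[ReactionRecord]:
    return [rec for rec, _ in generate_with_recipes(cfg)]


# --- independent fake enumerator (text substitution) ----------------------

#: textual alternatives per functional-group class, matching fg_classes.yaml
_TEXT_MEMBERS = {
    "halogen": ("Cl", "Br", "I"),
    "grignard_halide": ("Cl", "Br", "I"),
    "boron": ("B(O)O", "B1OC(C)(C)C(C)(C)O1", "B1OCCCO1"),
    "silicon": (
        "[Si](OC)(OC)OC",
        "[Si](OCC)(OCC)OCC",
        "[Si](Cl)(Cl)Cl",
        "[Si](C)(C)F",
    ),
}

#: which recipe slot each augmentable role varies, per reaction type
_ROLE_SLOTS = {
    "suzuki": {"aryl_halide": ("x", "halogen"), "organoboron": ("m", "boron")},
    "hiyama": {"aryl_halide": ("x", "halogen"), "organosilicon": ("m", "silicon")},
    "kumada": {
        "organyl_halide": ("x", "halogen"),
        "grignard": ("m", "grignard_halide"),
    },
    "buchwald_hartwig": {"aryl_halide": ("x", "halogen")},
    "chan_lam": {"organoboron": ("m", "boron")},
}


def enumerate_fake_strings(
    recipe: ReactionRecipe, mode: str, roles: tuple[str, ...]
) -> set[str]:
    """Expected fakes by pure string substitution on the recipe.

    Independent of the graph-surgery engine: variant reaction lines are
    assembled textually, then keyed by canonical reaction string.  Returns
    the set of canonical strings (the parent's own string excluded).
    """
    slots = _ROLE_SLOTS[recipe.rxn_type]
    chosen = {slots[r][0]: _TEXT_MEMBERS[slots[r][1]] for r in roles if r in slots}
    originals = {"x": recipe.halide, "m": recipe.partner_text}
    if mode == "single":
        (slot, members), = chosen.items()
        grids = {slot: members}
    else:
        grids = chosen
    parent = _record_from_recipe(recipe).canonical_string
    out: set[str] = set()
    slot_names = sorted(grids)
    for combo in itertools.product(*(grids[s] for s in slot_names)):
        values = dict(originals)
        values.update(dict(zip(slot_names, combo)))
        line = recipe.reaction_string(x=values["x"], m=values["m"])
        key = parse_reaction_smiles(line).canonical_string
        if key != parent:
            out.add(key)
    return out


# --- decoys ---------------------------------------------------------------

_ESTER_ACIDS = ("C", "CC", "CCC", "CC(C)", "c1ccccc1")
_ESTER_ALCOHOLS = ("OC", "OCC", "OCCC", "OC(C)C")
_KETONES = (
    ("C", "C"), ("C", "CC"), ("CC", "CC"), ("C", "CCC"),
    ("C", "c1ccccc1"), ("CC", "c1ccccc1"), ("CCC", "c1ccccc1"),
)


def generate_decoys(n: int, seed: int = 0) -> list[ReactionRecord]:
    """Reactions with no coupling motif (esterifications, ketone
    reductions); every one must fail all five templates."""
    lines: list[str] = []
    for a, alc in itertools.product(_ESTER_ACIDS, _ESTER_ALCOHOLS):
        lines.append(f"{a}C(=O)O.{alc}>>{a}C(=O){alc}")
    for r1, r2 in _KETONES:
        lines.append(f"{r1}C(=O){r2}>>{r1}C(O){r2}")
    if n > len(lines):
        raise FixtureConfigError(
            f"decoy vocabulary supports at most {len(lines)}, requested {n}"
        )
    rng = random.Random(seed)
    rng.shuffle(lines)
    return [parse_reaction_smiles(line) for line in lines[:n]]


def generate_molecule_library(n: int, seed: int = 0) -> list[str]:
    """``n`` distinct canonical SMILES of disubstituted arenes.

    A deterministic combinatorial pool (substituent x substituent x
    para/meta core) for property checks that need many valid molecules.
    """
    pool: set[str] = set()
    # ortho-, meta- and para-disubstituted benzene cores
    for core in ("c1cccc({A})c1{B}", "c1ccc({A})cc1{B}", "c1cc({A})ccc1{B}"):
        for a, b in itertools.product(ARYL_SUBSTITUENTS, PARTNER_SUBSTITUENTS):
            mol = Chem.MolFromSmiles(core.format(A=a, B=b))
            if mol is not None:
                pool.add(Chem.MolToSmiles(mol))
    if n > len(pool):
        raise FixtureConfigError(
            f"library vocabulary supports at most {len(pool)} molecules, "
            f"requested {n}"
        )
    ordered = sorted(pool)
    rng = random.Random(seed)
    rng.shuffle(ordered)
    return ordered[:n]


# --- prediction-error suite ------------------------------------------------


@dataclass(frozen=True)
class PredictionCase:
    predicted: str
    reference: str
    expected: str  # ErrorLabel value


def generate_prediction_suite() -> list[PredictionCase]:
    """Constructed (predicted, reference) pairs covering all six labels,
    patterned on the four published error categories (stereochemistry
    flips, malformed strings, wrong carbon counts, constitutional
    isomers) plus 'correct' and a catch-all 'other'."""
    return [
        # correct (including a non-canonical spelling of the same molecule)
        PredictionCase("Cc1ccccc1", "Cc1ccccc1", "correct"),
        PredictionCase("OCC", "CCO", "correct"),
        # invalid SMILES
        PredictionCase("CC((", "CCO", "invalid_smiles"),
        PredictionCase("c1ccc", "c1ccccc1", "invalid_smiles"),
        # chirality: right skeleton, wrong or dropped stereo
        PredictionCase("C[C@@H](N)C(=O)O", "C[C@H](N)C(=O)O", "chirality"),
        PredictionCase("F[C@H](Cl)Br", "F[C@@H](Cl)Br", "chirality"),
        PredictionCase(r"C/C=C\C", "C/C=C/C", "chirality"),
        # carbon-count errors
        PredictionCase("CCCc1ccccc1", "CCc1ccccc1", "atom_count"),
        PredictionCase("CCCC", "CCC", "atom_count"),
        # constitutional (group) isomers: same formula, different graph
        PredictionCase("Cc1ccccc1C", "Cc1ccc(C)cc1", "group_isomerism"),
        PredictionCase("CCOC=O", "CCC(=O)O", "group_isomerism"),
        PredictionCase("CCO", "COC", "group_isomerism"),
        # other: same carbon count, different formula
        PredictionCase("CCN", "CCO", "other"),
        PredictionCase("CCCl", "CCBr", "other"),
        PredictionCase("Oc1ccccc1", "Sc1ccccc1", "other"),
    ]
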