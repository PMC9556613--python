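"""Template screening: classify reactions into the five coupling classes.

A template is a set of role patterns (SMARTS) plus product rules.  A record
passes a template when every role pattern matches exactly one reactant
species, the roles occupy distinct species, and the product check holds:
each role's core (the species minus its leaving group) reappears in the
product, forbidden elements (B/Si/Mg) are gone, and — where required — the
number of carbon-bound halides strictly decreases.

Templates ship as an editable YAML file so the rules stay auditable.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field

import yaml
from rdkit import Chem

from .chem_core import Molecule, ReactionRecord

_HALIDE_ON_C = Chem.MolFromSmarts("[#6][Cl,Br,I]")

#: leaving-group kinds understood by the core computation
_LG_KINDS = ("halide", "boron", "silicon", "grignard", "self")


class TemplateConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RolePattern:
    name: str
    smarts: str
    leaving_group: str
    augment_class: str | None = None
    _query: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)

    @classmethod
    def build(cls, name, smarts, leaving_group, augment_class=None):
        if leaving_group not in _LG_KINDS:
            raise TemplateConfigError(f"unknown leaving_group {leaving_group!r}")
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise TemplateConfigError(f"bad SMARTS for role {name}: {smarts!r}")
        return cls(name, smarts, leaving_group, augment_class, query)

    def match_count(self, mol: Chem.Mol) -> int:
        return len(mol.GetSubstructMatches(self._query))


@dataclass(frozen=True)
class ReactionTemplate:
    name: str
    roles: tuple[RolePattern, ...]
    new_bond: str
    forbid_in_product: tuple[str, ...]
    require_halide_loss: bool

    @property
    def augmentable_roles(self) -> dict[str, str]:
        """role name -> functional-group class name"""
        return {r.name: r.augment_class for r in self.roles if r.augment_class}


@dataclass
class RoleAssignment:
    """Which reactant species plays which role, with site multiplicity."""

    role_to_species: dict[str, int]
    site_counts: dict[str, int]

    def is_ambiguous_site(self, role: str) -> bool:
        return self.site_counts.get(role, 0) > 1


@dataclass
class ScreenReport:
    template: str
    n_input: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    n_ambiguous: int = 0

    def to_dict(self) -> dict:
        return vars(self).copy()


def load_templates(path=None) -> dict[str, ReactionTemplate]:
    """Load templates from YAML (the shipped file when ``path`` is None)."""
    if path is None:
        text = (
            importlib.resources.files("rxnaug.data")
            .joinpath("templates.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "templates" not in data:
        raise TemplateConfigError("template file needs a 'templates' mapping")
    precedence = data.get("precedence") or list(data["templates"])
    out: dict[str, ReactionTemplate] = {}
    for name in precedence:
        spec = data["templates"][name]
        roles = tuple(
            RolePattern.build(
                rname,
                rspec["pattern"],
                rspec.get("leaving_group", "self"),
                rspec.get("augment_class"),
            )
            for rname, rspec in spec["roles"].items()
        )
        out[name] = ReactionTemplate(
            name=name,
            roles=roles,
            new_bond=spec.get("new_bond", ""),
            forbid_in_product=tuple(spec.get("forbid_in_product", ())),
            require_halide_loss=bool(spec.get("require_halide_loss", False)),
        )
    return out


_DEFAULT_TEMPLATES: dict[str, ReactionTemplate] | None = None


def default_templates() -> dict[str, ReactionTemplate]:
    global _DEFAULT_TEMPLATES
    if _DEFAULT_TEMPLATES is None:
        _DEFAULT_TEMPLATES = load_templates()
    return _DEFAULT_TEMPLATES


# --- core computation -----------------------------------------------------


def species_core_fragments(mol: Chem.Mol, leaving_group: str) -> list[Chem.Mol]:
    """Fragments of a role species expected to survive into the product.

    ``halide`` deletes the carbon-bound halogen atom(s); ``boron``,
    ``silicon`` and ``grignard`` excise the heteroatom centre and return
    the remaining fragments; ``self`` returns the species unchanged.
    """
    if leaving_group == "self":
        return [mol]
    rw = Chem.RWMol(mol)
    doomed: list[int] = []
    if leaving_group == "halide":
        for match in mol.GetSubstructMatches(_HALIDE_ON_C):
            doomed.append(match[1])
    else:
        symbol = {"boron": "B", "silicon": "Si", "grignard": "Mg"}[leaving_group]
        for atom in mol.GetAtoms():
            if atom.GetSymbol() == symbol:
                doomed.append(atom.GetIdx())
    if not doomed:
        return []
    for idx in sorted(set(doomed), reverse=True):
        rw.RemoveAtom(idx)
    try:
        frags = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
    except Exception:
        return []
    return list(frags)


def _count_halides(mol: Chem.Mol) -> int:
    return len(mol.GetSubstructMatches(_HALIDE_ON_C))


def product_check(
    record: ReactionRecord,
    template: ReactionTemplate,
    assignment: RoleAssignment,
) -> bool:
    """Verify the coupling happened: cores in product, leaving groups lost."""
    product = record.product.mol
    for role in template.roles:
        species = record.reactants[assignment.role_to_species[role.name]]
        # a methyl Grignard leaves a single-carbon core; everything else
        # must contribute a fragment of at least two heavy atoms
        min_atoms = 1 if role.leaving_group == "grignard" else 2
        cores = [
            f
            for f in species_core_fragments(species.mol, role.leaving_group)
            if f.GetNumHeavyAtoms() >= min_atoms
            and any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        ]
        if not cores or not any(product.HasSubstructMatch(f) for f in cores):
            return False
    for smarts in template.forbid_in_product:
        query = Chem.MolFromSmarts(smarts)
        if product.HasSubstructMatch(query):
            return False
    if template.require_halide_loss:
        before = sum(_count_halides(m.mol) for m in record.reactants)
        if _count_halides(product) >= before:
            return False
    return True


def enumerate_assignments(
    record: ReactionRecord, template: ReactionTemplate
) -> list[RoleAssignment]:
    """All ways to give each role its own distinct reactant species.

    A spectator halide on, say, the boron partner makes the halide
    pattern match two species; the perfect-matching requirement (every
    role satisfied, all on distinct species) resolves it.  Several
    pattern matches *within* one assigned species are allowed — the
    record is then "ambiguous-site" for that role and excluded from
    augmentation, but still passes screening.
    """
    per_role: list[list[tuple[int, int]]] = []
    for role in template.roles:
        hits = [
            (i, role.match_count(m.mol))
            for i, m in enumerate(record.reactants)
            if role.match_count(m.mol) > 0
        ]
        if not hits:
            return []
        per_role.append(hits)
    out: list[RoleAssignment] = []
    for combo in itertools.product(*per_role):
        indices = [idx for idx, _ in combo]
        if len(set(indices)) != len(indices):
            continue
        out.append(
            RoleAssignment(
                role_to_species={
                    role.name: idx for role, (idx, _) in zip(template.roles, combo)
                },
                site_counts={
                    role.name: n for role, (_, n) in zip(template.roles, combo)
                },
            )
        )
    return out


def match_roles(
    record: ReactionRecord, template: ReactionTemplate
) -> RoleAssignment | None:
    """The unique role assignment that also passes the product check."""
    valid = [
        a
        for a in enumerate_assignments(record, template)
        if product_check(record, template, a)
    ]
    return valid[0] if valid else None


def classify_reaction(
    record: ReactionRecord,
    templates: dict[str, ReactionTemplate] | None = None,
) -> str | None:
    """Return the unique matching coupling class, or None.

    When several templates pass, the shipped precedence order decides and
    a warning is emitted.
    """
    templates = templates or default_templates()
    passing = []
    for name, tpl in templates.items():
        if match_roles(record, tpl) is not None:
            passing.append(name)
    if not passing:
        return None
    if len(passing) > 1:
        warnings.warn(
            f"reaction matches several templates {passing}; "
            f"keeping {passing[0]} by precedence",
            stacklevel=2,
        )
    return passing[0]


def classify_with_assignment(
    record: ReactionRecord,
    templates: dict[str, ReactionTemplate] | None = None,
) -> tuple[str, ReactionTemplate, RoleAssignment] | None:
    templates = templates or default_templates()
    name = classify_reaction(record, templates)
    if name is None:
        return None
    tpl = templates[name]
    assignment = match_roles(record, tpl)
    return name, tpl, assignment


def screen_dataset(
    records: list[ReactionRecord],
    template: ReactionTemplate,
    templates: dict[str, ReactionTemplate] | None = None,
) -> tuple[list[ReactionRecord], list[ReactionRecord], ScreenReport]:
    """Keep records classified as ``template.name``; order-stable.

    Kept records come back with ``rxn_type`` set.  Rejection is data, not
    an error.
    """
    templates = templates or default_templates()
    report = ScreenReport(template=template.name, n_input=len(records))
    kept: list[ReactionRecord] = []
    rejected: list[ReactionRecord] = []
    for rec in records:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            label = classify_reaction(rec, templates)
            if caught:
                report.n_ambiguous += 1
        if label == template.name:
            kept.append(rec.replace(rxn_type=label))
            report.n_kept += 1
        else:
            rejected.append(rec)
            report.n_rejected += 1
    return kept, rejected, report
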