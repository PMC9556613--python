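"""Virtual data augmentation: fake reactions by equivalent-group substitution.

The method swaps a reactant's leaving group for another member of the same
functional-group equivalence class (Cl -> Br/I, -B(OH)2 -> -Bpin, ...)
while copying the product unchanged, so the reaction site and all atom
valences are preserved.  *Single* augmentation varies one role;
*simultaneous* augmentation takes the Cartesian product of member choices
across several roles.

Safety rules, enforced before any substitution:

* the matched member must occur exactly once in its species (a species
  bearing, say, both Br and Cl is ambiguous and is skipped);
* the matched group must be absent from the product (leaving-group
  confirmation) — a spectator halide that survives into the product is
  never substituted.

Fakes are deduplicated by canonical reaction string, never equal their
parent, and are emitted in sorted order for reproducible diffs.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import yaml
from rdkit import Chem

from .chem_core import Molecule, ReactionRecord, SmilesParseError
from .templates import ReactionTemplate, classify_with_assignment


class FGConfigError(ValueError):
    pass


class SubstitutionError(ValueError):
    """Graph surgery produced an invalid structure (never silently emitted)."""


@dataclass(frozen=True)
class FGMember:
    """One substituent pattern with a single open attachment point ('*')."""

    name: str
    smiles: str
    _frag: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)
    _query: Chem.Mol = field(compare=False, repr=False, hash=False, default=None)

    @classmethod
    def build(cls, name: str, smiles: str) -> "FGMember":
        frag = Chem.MolFromSmiles(smiles)
        if frag is None:
            raise FGConfigError(f"member {name}: bad fragment SMILES {smiles!r}")
        dummies = [a.GetIdx() for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise FGConfigError(
                f"member {name}: needs exactly one attachment point, "
                f"got {len(dummies)}"
            )
        # the attachment '*' must act as a wildcard during matching
        params = Chem.AdjustQueryParameters.NoAdjustments()
        params.makeDummiesQueries = True
        query = Chem.AdjustQueryProperties(frag, params)
        return cls(name, smiles, frag, query)

    @property
    def frag(self) -> Chem.Mol:
        return self._frag

    @property
    def query(self) -> Chem.Mol:
        return self._query

    @property
    def dummy_idx(self) -> int:
        return next(a.GetIdx() for a in self._frag.GetAtoms() if a.GetAtomicNum() == 0)

    @property
    def anchor_idx(self) -> int:
        """Index of the fragment atom bonded to the attachment point."""
        dummy = self._frag.GetAtomWithIdx(self.dummy_idx)
        return dummy.GetNeighbors()[0].GetIdx()

    def canonical_key(self) -> str:
        return Chem.MolToSmiles(self._frag)


@dataclass(frozen=True)
class FunctionalGroupClass:
    """A named set of mutually substitutable substituents."""

    name: str
    members: tuple[FGMember, ...]
    attach_elements: tuple[str, ...] = ("C",)

    def __post_init__(self):
        keys = [m.canonical_key() for m in self.members]
        if len(set(keys)) != len(keys):
            raise FGConfigError(f"class {self.name}: duplicate members")

    def member(self, name: str) -> FGMember:
        for m in self.members:
            if m.name == name:
                return m
        raise KeyError(name)


def load_fg_classes(path=None) -> dict[str, FunctionalGroupClass]:
    """Load functional-group classes (the shipped YAML when ``path`` is None)."""
    if path is None:
        text = (
            importlib.resources.files("rxnaug.data")
            .joinpath("fg_classes.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "classes" not in data:
        raise FGConfigError("class file needs a 'classes' mapping")
    out = {}
    for cname, cspec in data["classes"].items():
        members = tuple(FGMember.build(m["name"], m["smiles"]) for m in cspec["members"])
        out[cname] = FunctionalGroupClass(
            name=cname,
            members=members,
            attach_elements=tuple(cspec.get("attach", ["C"])),
        )
    return out


_DEFAULT_CLASSES: dict[str, FunctionalGroupClass] | None = None


def default_fg_classes() -> dict[str, FunctionalGroupClass]:
    global _DEFAULT_CLASSES
    if _DEFAULT_CLASSES is None:
        _DEFAULT_CLASSES = load_fg_classes()
    return _DEFAULT_CLASSES


@dataclass(frozen=True)
class AugmentedSite:
    """One substitutable occurrence of a class member within a species."""

    species_index: int
    member: FGMember
    attachment_idx: int
    group_atoms: tuple[int, ...]
    leaving_group_confirmed: bool


@dataclass(frozen=True)
class AugmentationSpec:
    """Which roles to vary and how; guards protect held-out reactions."""

    mode: str  # "single" | "simultaneous"
    roles: tuple[str, ...]
    drop_colliding_with: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.mode not in ("single", "simultaneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "single" and len(self.roles) != 1:
            raise ValueError("single mode names exactly one role")
        if self.mode == "simultaneous" and len(self.roles) < 2:
            raise ValueError("simultaneous mode names at least two roles")


# --- member matching ------------------------------------------------------


def _exact_member_matches(
    mol: Chem.Mol, member: FGMember, attach_elements: tuple[str, ...]
) -> list[tuple[int, tuple[int, ...]]]:
    """Occurrences of ``member`` as a complete terminal group.

    The dummy atom matches the attachment atom (restricted to
    ``attach_elements``); every other fragment atom may only bond to
    fragment atoms or the attachment atom, so -B(OH)2 never half-matches a
    pinacol boronate.  Returns (attachment_idx, group_atom_indices) pairs,
    deduplicated by atom set.
    """
    dummy = member.dummy_idx
    seen: set[frozenset[int]] = set()
    out: list[tuple[int, tuple[int, ...]]] = []
    for match in mol.GetSubstructMatches(member.query, uniquify=False):
        attach = match[dummy]
        group = tuple(t for q, t in enumerate(match) if q != dummy)
        key = frozenset(group)
        if key in seen:
            continue
        if mol.GetAtomWithIdx(attach).GetSymbol() not in attach_elements:
            continue
        allowed = set(group) | {attach}
        complete = all(
            nb.GetIdx() in allowed
            for g in group
            for nb in mol.GetAtomWithIdx(g).GetNeighbors()
        )
        if not complete:
            continue
        seen.add(key)
        out.append((attach, group))
    return out


def _member_in_product(product: Chem.Mol, member: FGMember, fg_class) -> bool:
    return bool(_exact_member_matches(product, member, fg_class.attach_elements))


def find_sites_in_species(
    record: ReactionRecord, species_index: int, fg_class: FunctionalGroupClass
) -> list[AugmentedSite]:
    """All class-member occurrences in one reactant species (unfiltered)."""
    mol = record.reactants[species_index].mol
    sites = []
    for member in fg_class.members:
        for attach, group in _exact_member_matches(mol, member, fg_class.attach_elements):
            confirmed = not _member_in_product(record.product.mol, member, fg_class)
            sites.append(
                AugmentedSite(species_index, member, attach, group, confirmed)
            )
    return sites


def find_augmentable_sites(
    record: ReactionRecord,
    template: ReactionTemplate,
    fg_class: FunctionalGroupClass,
    templates=None,
) -> list[AugmentedSite]:
    """Sites eligible for substitution under the safety rules.

    For each role of ``template`` whose augment class is ``fg_class``:
    the class must occur exactly once in the role's species (else the
    species is ambiguous and yields no sites) and the matched group must
    be confirmed absent from the product.
    """
    hit = classify_with_assignment(record, templates)
    if hit is None or hit[0] != template.name:
        return []
    _, tpl, assignment = hit
    out: list[AugmentedSite] = []
    for role in tpl.roles:
        if role.augment_class != fg_class.name:
            continue
        idx = assignment.role_to_species[role.name]
        sites = find_sites_in_species(record, idx, fg_class)
        if len(sites) != 1:  # zero or ambiguous
            continue
        site = sites[0]
        if site.leaving_group_confirmed:
            out.append(site)
    return out


# --- graph surgery --------------------------------------------------------


def substitute_group(
    molecule: Molecule, site: AugmentedSite, new_member: FGMember
) -> Molecule:
    """Replace the matched group with ``new_member``; identity swaps are
    rejected, and any chemically invalid result raises instead of being
    emitted."""
    if new_member.canonical_key() == site.member.canonical_key():
        raise SubstitutionError(
            f"identity replacement {site.member.name} -> {new_member.name}"
        )
    mol = molecule.mol
    combined = Chem.RWMol(Chem.CombineMols(mol, new_member.frag))
    offset = mol.GetNumAtoms()
    anchor = offset + new_member.anchor_idx
    combined.AddBond(site.attachment_idx, anchor, Chem.BondType.SINGLE)
    # delete the new fragment's dummy and the old group, highest index first
    doomed = sorted([offset + new_member.dummy_idx, *site.group_atoms], reverse=True)
    for idx in doomed:
        combined.RemoveAtom(idx)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
        smiles = Chem.MolToSmiles(out)
        return Molecule.from_smiles(smiles)
    except (SmilesParseError, Exception) as exc:
        raise SubstitutionError(
            f"substitution {site.member.name} -> {new_member.name} on "
            f"{molecule.smiles} produced an invalid structure"
        ) from exc


def _fake_from_choice(
    record: ReactionRecord,
    replacements: dict[int, tuple[AugmentedSite, FGMember]],
) -> ReactionRecord:
    reactants = list(record.reactants)
    for idx, (site, member) in replacements.items():
        reactants[idx] = substitute_group(record.reactants[idx], site, member)
    return record.replace(reactants=reactants, provenance="fake")


def _site_for_role(record, tpl, assignment, role_name, classes):
    role = next(r for r in tpl.roles if r.name == role_name)
    if role.augment_class is None:
        raise ValueError(f"role {role_name!r} is not augmentable")
    fg_class = classes[role.augment_class]
    idx = assignment.role_to_species[role_name]
    sites = find_sites_in_species(record, idx, fg_class)
    if len(sites) != 1 or not sites[0].leaving_group_confirmed:
        return None, fg_class
    return sites[0], fg_class


def single_augment(
    record: ReactionRecord,
    template: ReactionTemplate,
    role: str,
    classes: dict[str, FunctionalGroupClass] | None = None,
    templates=None,
) -> list[ReactionRecord]:
    """Fakes varying one role: one per alternative class member.

    The product is copied unchanged; output is deduplicated by canonical
    string, excludes the parent, and is sorted for determinism.  No
    eligible site means an empty result, never an error.
    """
    classes = classes or default_fg_classes()
    hit = classify_with_assignment(record, templates)
    if hit is None or hit[0] != template.name:
        return []
    _, tpl, assignment = hit
    site, fg_class = _site_for_role(record, tpl, assignment, role, classes)
    if site is None:
        return []
    idx = site.species_index
    fakes: dict[str, ReactionRecord] = {}
    for member in fg_class.members:
        if member.canonical_key() == site.member.canonical_key():
            continue
        fake = _fake_from_choice(record, {idx: (site, member)})
        if fake.canonical_string != record.canonical_string:
            fakes.setdefault(fake.canonical_string, fake)
    return [fakes[k] for k in sorted(fakes)]


def simultaneous_augment(
    record: ReactionRecord,
    template: ReactionTemplate,
    roles: tuple[str, ...],
    classes: dict[str, FunctionalGroupClass] | None = None,
    templates=None,
) -> list[ReactionRecord]:
    """Cartesian product of member choices across roles, minus the original.

    Roles without an eligible site fall back to their original member
    only, so a record with one usable site degrades gracefully to the
    single-augmentation result.
    """
    classes = classes or default_fg_classes()
    hit = classify_with_assignment(record, templates)
    if hit is None or hit[0] != template.name:
        return []
    _, tpl, assignment = hit
    per_role: list[tuple[int, AugmentedSite, list[FGMember | None]]] = []
    for role_name in roles:
        site, fg_class = _site_for_role(record, tpl, assignment, role_name, classes)
        if site is None:
            continue
        choices: list[FGMember | None] = [None]  # None = keep original member
        choices += [
            m
            for m in fg_class.members
            if m.canonical_key() != site.member.canonical_key()
        ]
        per_role.append((site.species_index, site, choices))
    if not per_role:
        return []
    fakes: dict[str, ReactionRecord] = {}
    for combo in itertools.product(*(choices for _, _, choices in per_role)):
        if all(c is None for c in combo):
            continue  # the original combination
        replacements = {
            idx: (site, member)
            for (idx, site, _), member in zip(per_role, combo)
            if member is not None
        }
        fake = _fake_from_choice(record, replacements)
        if fake.canonical_string != record.canonical_string:
            fakes.setdefault(fake.canonical_string, fake)
    return [fakes[k] for k in sorted(fakes)]


def augment_record(
    record: ReactionRecord,
    template: ReactionTemplate,
    spec: AugmentationSpec,
    classes: dict[str, FunctionalGroupClass] | None = None,
    templates=None,
) -> list[ReactionRecord]:
    if spec.mode == "single":
        fakes = single_augment(record, template, spec.roles[0], classes, templates)
    else:
        fakes = simultaneous_augment(record, template, spec.roles, classes, templates)
    if spec.drop_colliding_with:
        fakes = [f for f in fakes if f.canonical_string not in spec.drop_colliding_with]
    return fakes


def dedup_and_merge(
    raw_train: list[ReactionRecord],
    fakes: list[ReactionRecord],
    guard: frozenset[str] | set[str] = frozenset(),
) -> list[ReactionRecord]:
    """Merge fakes into the raw training list, deleting repeats.

    Fakes colliding with raw reactions or with the guard set (validation/
    test canonical strings) are dropped.  Raw order is preserved; fakes
    are appended sorted by canonical string.  Idempotent.
    """
    seen = {r.canonical_string for r in raw_train} | set(guard)
    merged = list(raw_train)
    for fake in sorted(fakes, key=lambda r: r.canonical_string):
        key = fake.canonical_string
        if key in seen:
            continue
        seen.add(key)
        merged.append(fake)
    return merged
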