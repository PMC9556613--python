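"""Molecule and reaction-SMILES substrate: parsing, canonicalization,
tokenization and serialization.

Every other module operates on the types defined here.  Canonical SMILES
(RDKit, one pinned backend per run — see :data:`BACKEND`) is the identity
key used for deduplication and cross-partition leakage checks throughout
the pipeline.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import rdkit
import yaml
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: The canonicalization backend, recorded in output metadata.  Canonical
#: strings are only comparable within a single backend/version.
BACKEND = f"rdkit-{rdkit.__version__}"

RXN_TYPES = ("hiyama", "buchwald_hartwig", "chan_lam", "kumada", "suzuki", "unknown")
PROVENANCES = ("raw", "fake")


class SmilesParseError(ValueError):
    """A SMILES string failed to parse or sanitize."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ReactionFormatError(ValueError):
    """A reaction line violates the accepted dialects.

    ``code`` is one of ``bad_separator``, ``no_product``, ``multi_product``,
    ``bad_species``.
    """

    def __init__(self, code: str, line: str, detail: str = ""):
        self.code = code
        self.line = line
        msg = f"{code}: {detail or line!r}"
        super().__init__(msg)


class TokenizationError(ValueError):
    def __init__(self, smiles: str, position: int):
        self.smiles = smiles
        self.position = position
        super().__init__(
            f"untokenizable character {smiles[position]!r} at position "
            f"{position} in {smiles!r}"
        )


def mol_from_smiles(s: str) -> Chem.Mol:
    """Parse and sanitize one species; raise :class:`SmilesParseError` on failure."""
    mol = Chem.MolFromSmiles(s, sanitize=True)
    if mol is None:
        raise SmilesParseError(s)
    return mol


def canonicalize_smiles(s: str, strip_stereo: bool = False) -> str:
    """Canonical SMILES for ``s`` (idempotent, atom-order invariant).

    Stereo annotations are preserved unless ``strip_stereo`` is set.
    """
    mol = mol_from_smiles(s)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """One chemical species: its parsed graph plus the canonical SMILES key."""

    smiles: str  # canonical form
    _mol: Chem.Mol = field(compare=False, repr=False, hash=False)

    @classmethod
    def from_smiles(cls, s: str, strip_stereo: bool = False) -> "Molecule":
        mol = mol_from_smiles(s)
        if strip_stereo:
            Chem.RemoveStereochemistry(mol)
        canonical = Chem.MolToSmiles(mol)
        # reparse from the canonical string so the stored graph and key agree
        return cls(smiles=canonical, _mol=mol_from_smiles(canonical))

    @property
    def mol(self) -> Chem.Mol:
        return self._mol

    @property
    def num_heavy_atoms(self) -> int:
        return self._mol.GetNumHeavyAtoms()

    def carbon_count(self) -> int:
        return sum(1 for a in self._mol.GetAtoms() if a.GetAtomicNum() == 6)

    def formula(self) -> str:
        from rdkit.Chem import rdMolDescriptors

        return rdMolDescriptors.CalcMolFormula(self._mol)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


@dataclass
class ReactionRecord:
    """One curated reaction: reactants, reagents, a single product.

    ``canonical_string`` is the record's identity key.  It depends only on
    the multiset of left-side species and the product, never on the
    reactant/reagent role assignment (which is heuristic) or on input
    ordering, so deduplication is stable.
    """

    reactants: list[Molecule]
    reagents: list[Molecule]
    product: Molecule
    rxn_type: str = "unknown"
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if not self.reactants:
            raise ValueError("a reaction needs at least one reactant")
        if self.rxn_type not in RXN_TYPES:
            raise ValueError(f"unknown rxn_type {self.rxn_type!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def left_species(self) -> list[Molecule]:
        return list(self.reactants) + list(self.reagents)

    @property
    def canonical_string(self) -> str:
        left = ".".join(sorted(m.smiles for m in self.left_species))
        return f"{left}>>{self.product.smiles}"

    def replace(self, **changes) -> "ReactionRecord":
        return dataclasses.replace(self, **changes)


# --- reactant vs. reagent role heuristic ---------------------------------
#
# The printed reactions put everything left of '>>'.  A left-side species
# is a *reactant* if it plausibly contributes heavy atoms to the product:
# either the species itself, or the species with a standard leaving group
# (terminal halide, boron group, silyl group, Mg-halide) removed, occurs
# as a substructure of the product.  Small ions and catalysts fall through
# to *reagent*.

_HALIDE_ON_C = Chem.MolFromSmarts("[#6][Cl,Br,I]")


def _fragment_candidates(mol: Chem.Mol) -> list[Chem.Mol]:
    """Candidate product-contributing cores of a species.

    Returns the species itself plus, for each standard leaving-group motif
    present, the carbon fragment left behind when that motif departs.
    """
    out = [mol]
    # terminal halide on carbon
    for match in mol.GetSubstructMatches(_HALIDE_ON_C):
        frag = _delete_atoms(mol, [match[1]])
        out.extend(frag)
    # B / Si / Mg centres: the carbon components that remain when the
    # heteroatom centre is excised
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("B", "Si", "Mg"):
            out.extend(_delete_atoms(mol, [atom.GetIdx()]))
    return out


def _delete_atoms(mol: Chem.Mol, indices: list[int]) -> list[Chem.Mol]:
    rw = Chem.RWMol(mol)
    for idx in sorted(indices, reverse=True):
        rw.RemoveAtom(idx)
    try:
        frags = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=True)
    except Exception:
        return []
    return list(frags)


_C_MG = Chem.MolFromSmarts("[#6][Mg]")


def _contributes_to_product(species: Chem.Mol, product: Chem.Mol) -> bool:
    if species.GetNumHeavyAtoms() < 2:
        return False
    # organometallics (Grignards) carry their organyl group into the product
    if species.HasSubstructMatch(_C_MG):
        return True
    for cand in _fragment_candidates(species):
        if cand.GetNumHeavyAtoms() >= 2 and product.HasSubstructMatch(cand):
            return True
    return False


def parse_reaction_smiles(line: str, strip_stereo: bool = False) -> ReactionRecord:
    """Parse one reaction line into a :class:`ReactionRecord`.

    Accepts both ``left>>product`` (reagents mixed into the left side) and
    ``reactants>reagents>product``.  An optional leading tab-separated ID
    column is ignored.  Species are split on ``.``, parsed and
    canonicalized; in the ``>>`` dialect, left-side species are assigned
    reactant/reagent roles by the product-contribution heuristic.
    """
    text = line.strip()
    if "\t" in text:
        # keep the field that actually contains the reaction
        fields = [f for f in text.split("\t") if ">" in f]
        if not fields:
            raise ReactionFormatError("bad_separator", line, "no '>' in any column")
        text = fields[0].strip()

    if ">>" in text:
        parts = text.split(">>")
        if len(parts) != 2:
            raise ReactionFormatError("bad_separator", line, "multiple '>>'")
        left_s, prod_s = parts
        mid_s = None
    else:
        parts = text.split(">")
        if len(parts) != 3:
            raise ReactionFormatError("bad_separator", line)
        left_s, mid_s, prod_s = parts

    def _species(chunk: str) -> list[Molecule]:
        out = []
        for s in chunk.split("."):
            s = s.strip()
            if not s:
                continue
            try:
                out.append(Molecule.from_smiles(s, strip_stereo=strip_stereo))
            except SmilesParseError as exc:
                raise ReactionFormatError("bad_species", line, str(exc)) from exc
        return out

    products = _species(prod_s)
    if len(products) == 0:
        raise ReactionFormatError("no_product", line)
    if len(products) > 1:
        raise ReactionFormatError("multi_product", line, f"{len(products)} products")
    product = products[0]

    left = _species(left_s)
    if not left:
        raise ReactionFormatError("bad_species", line, "empty left side")

    if mid_s is not None:
        reactants, reagents = left, _species(mid_s)
    else:
        reactants = [m for m in left if _contributes_to_product(m.mol, product.mol)]
        reagents = [m for m in left if m not in reactants]
        if not reactants:
            # nothing matched the heuristic; treat the whole left side as
            # reactants rather than inventing an empty reaction
            reactants, reagents = left, []
    return ReactionRecord(reactants=reactants, reagents=reagents, product=product)


def write_reaction_smiles(record: ReactionRecord) -> str:
    """Serialize to the output dialect: ``reactants.reagents>>product``."""
    left = ".".join(m.smiles for m in record.left_species)
    return f"{left}>>{record.product.smiles}"


def read_reaction_file(path, strip_stereo: bool = False) -> list[ReactionRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(parse_reaction_smiles(line, strip_stereo=strip_stereo))
    return records


def write_reaction_file(path, records: Iterable[ReactionRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(write_reaction_smiles(r) + "\n")


# --- tokenizer ------------------------------------------------------------
#
# The conventional regex tokenizer for seq2seq reaction models: bracket
# atoms, two-letter halogens, '%nn' ring closures and every structural
# character are single tokens; joining the tokens reproduces the input.

_TOKEN_RE = re.compile(
    r"\[[^\]]+\]|Br|Cl|B|C|N|O|P|S|F|I|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d"
)


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into model tokens (lossless)."""
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise TokenizationError(s, pos)
        tokens.append(m.group())
        pos = m.end()
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class TokenizedPair:
    """One seq2seq example: space-separated source and target token lines."""

    source: str
    target: str

    @classmethod
    def from_record(cls, record: ReactionRecord) -> "TokenizedPair":
        src = ".".join(m.smiles for m in record.left_species)
        tgt = record.product.smiles
        return cls(
            source=" ".join(tokenize_smiles(src)),
            target=" ".join(tokenize_smiles(tgt)),
        )


# --- training configuration ----------------------------------------------


@dataclass
class TrainingConfig:
    """Seq2seq (transformer) hyperparameters exported alongside a dataset.

    Defaults are the published baseline settings for coupling-reaction
    product prediction: Adam(beta1, beta2, epsilon), 8 attention heads,
    256-dimensional embeddings, 6 encoder/decoder layers.
    """

    beta1: float = 0.9
    beta2: float = 0.997
    epsilon: float = 1e-9
    n_heads: int = 8
    emb_dim: int = 256
    num_layers: int = 6

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def export_training_config(path, config: TrainingConfig | None = None) -> None:
    """Write the training hyperparameters as a YAML key-value file."""
    config = config or TrainingConfig()
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_training_config(path) -> TrainingConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return TrainingConfig(**data)
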