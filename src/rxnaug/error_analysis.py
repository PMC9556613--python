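"""Four-way taxonomy of wrong product predictions.

A deterministic decision cascade over a (predicted, reference) SMILES
pair:

1. predicted does not parse                       -> invalid_smiles
2. canonical strings equal                        -> correct
3. equal after stripping stereochemistry          -> chirality
4. carbon counts differ                           -> atom_count
5. molecular formulas equal, structures differ    -> group_isomerism
6. otherwise                                      -> other

Chirality precedes the count checks so a stereo-only mistake is never
masked.  ``atom_count`` is keyed on the carbon count specifically (the
published table counts carbon errors); a same-carbon different-formula
miss lands in ``other``.  ``group_isomerism`` means constitutional
isomer: identical molecular formula, different connectivity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .chem_core import Molecule, SmilesParseError


class ErrorLabel(str, enum.Enum):
    CORRECT = "correct"
    INVALID_SMILES = "invalid_smiles"
    CHIRALITY = "chirality"
    ATOM_COUNT = "atom_count"
    GROUP_ISOMERISM = "group_isomerism"
    OTHER = "other"


#: fixed order for reports
WRONG_LABELS = (
    ErrorLabel.INVALID_SMILES,
    ErrorLabel.CHIRALITY,
    ErrorLabel.ATOM_COUNT,
    ErrorLabel.GROUP_ISOMERISM,
    ErrorLabel.OTHER,
)


def classify_prediction(predicted: str, reference: str) -> ErrorLabel:
    """Label one prediction against its reference product.

    An unparsable *reference* is a caller bug and raises; an unparsable
    *prediction* is data (``invalid_smiles``).
    """
    try:
        ref = Molecule.from_smiles(reference)
    except SmilesParseError as exc:
        raise ValueError(f"invalid reference SMILES: {reference!r}") from exc
    try:
        pred = Molecule.from_smiles(predicted)
    except SmilesParseError:
        return ErrorLabel.INVALID_SMILES
    if pred.smiles == ref.smiles:
        return ErrorLabel.CORRECT
    pred_flat = Molecule.from_smiles(predicted, strip_stereo=True)
    ref_flat = Molecule.from_smiles(reference, strip_stereo=True)
    if pred_flat.smiles == ref_flat.smiles:
        return ErrorLabel.CHIRALITY
    if pred.carbon_count() != ref.carbon_count():
        return ErrorLabel.ATOM_COUNT
    if pred.formula() == ref.formula():
        return ErrorLabel.GROUP_ISOMERISM
    return ErrorLabel.OTHER


@dataclass
class ErrorReport:
    """Counts per label plus percentages over the *wrong* subset only
    (the published table's convention: its columns sum to ~100% without
    the correct predictions)."""

    counts: dict[str, int]
    n_total: int
    n_wrong: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_wrong == 0:
            return {}
        return {
            label.value: 100.0 * self.counts.get(label.value, 0) / self.n_wrong
            for label in WRONG_LABELS
        }

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_correct": self.counts.get(ErrorLabel.CORRECT.value, 0),
            "n_wrong": self.n_wrong,
            "counts": dict(self.counts),
            "percentages_of_wrong": {
                k: round(v, 2) for k, v in self.percentages.items()
            },
        }


def summarize_errors(pairs: list[tuple[str, str]]) -> ErrorReport:
    """Classify every (predicted, reference) pair and tally the labels."""
    counts: dict[str, int] = {}
    for predicted, reference in pairs:
        label = classify_prediction(predicted, reference)
        counts[label.value] = counts.get(label.value, 0) + 1
    n_total = len(pairs)
    n_wrong = n_total - counts.get(ErrorLabel.CORRECT.value, 0)
    return ErrorReport(counts=counts, n_total=n_total, n_wrong=n_wrong)
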