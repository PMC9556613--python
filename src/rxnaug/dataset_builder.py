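"""Split policy, train-only augmentation orchestration, statistics, export.

Datasets are split 8:1:1 (train/valid/test) or into 10 cross-validation
folds; augmentation is applied strictly *after* splitting and only to the
training portion, with the held-out canonical strings used as a guard so
no fake can collide with a validation or test reaction.
"""

from __future__ import annotations

import hashlib
import json
import os
import random
from dataclasses import dataclass, field

from .augment import (
    AugmentationSpec,
    FunctionalGroupClass,
    augment_record,
    dedup_and_merge,
    default_fg_classes,
)
from .chem_core import BACKEND, ReactionRecord, TokenizedPair
from .templates import ReactionTemplate


class SplitError(ValueError):
    pass


@dataclass
class SplitDataset:
    """Disjoint train/valid/test partitions; only train may hold fakes."""

    train: list[ReactionRecord]
    valid: list[ReactionRecord]
    test: list[ReactionRecord]
    seed: int = 0
    ratios: tuple[int, int, int] = (8, 1, 1)

    def check_invariants(self) -> None:
        keys = [
            {r.canonical_string for r in part}
            for part in (self.train, self.valid, self.test)
        ]
        if keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2]:
            raise SplitError("canonical reaction present in two partitions")
        for part in (self.valid, self.test):
            if any(r.provenance == "fake" for r in part):
                raise SplitError("fake record outside the training partition")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.valid), len(self.test))


@dataclass
class FoldPlan:
    k: int
    assignments: dict[str, int]  # canonical_string -> held-out fold index

    def fold_of(self, record: ReactionRecord) -> int:
        return self.assignments[record.canonical_string]


def split(
    records: list[ReactionRecord],
    ratios: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> SplitDataset:
    """Random train/valid/test partition.

    Validation and test each get ``floor(N * ratio / sum)`` records; the
    remainder goes to train, so evaluation sets are never larger than
    nominal.  Shuffling uses only ``seed``; a fixed seed gives an
    identical partition.
    """
    n = len(records)
    denom = sum(ratios)
    if any(r <= 0 for r in ratios):
        raise SplitError(f"ratios must be positive, got {ratios}")
    if n < denom:
        raise SplitError(f"need at least {denom} records for ratios {ratios}, got {n}")
    shuffled = list(records)
    random.Random(seed).shuffle(shuffled)
    n_valid = n * ratios[1] // denom
    n_test = n * ratios[2] // denom
    n_train = n - n_valid - n_test
    ds = SplitDataset(
        train=shuffled[:n_train],
        valid=shuffled[n_train : n_train + n_valid],
        test=shuffled[n_train + n_valid :],
        seed=seed,
        ratios=ratios,
    )
    ds.check_invariants()
    return ds


def augment_split(
    ds: SplitDataset,
    template: ReactionTemplate,
    spec: AugmentationSpec,
    classes: dict[str, FunctionalGroupClass] | None = None,
) -> SplitDataset:
    """Augment the training partition only.

    Train becomes ``dedup_and_merge(train, fakes-of-train)`` with the
    validation/test canonical strings as the leakage guard; valid and
    test are returned untouched (the same record objects).
    """
    classes = classes or default_fg_classes()
    guard = {r.canonical_string for r in ds.valid} | {
        r.canonical_string for r in ds.test
    }
    fakes: list[ReactionRecord] = []
    for rec in ds.train:
        fakes.extend(augment_record(rec, template, spec, classes))
    merged = dedup_and_merge(ds.train, fakes, guard=guard)
    out = SplitDataset(
        train=merged, valid=ds.valid, test=ds.test, seed=ds.seed, ratios=ds.ratios
    )
    out.check_invariants()
    return out


def kfold_plan(
    records: list[ReactionRecord], k: int = 10, seed: int = 0
) -> FoldPlan:
    """Assign every record to exactly one held-out fold (sizes differ by
    at most one)."""
    n = len(records)
    if n < k:
        raise SplitError(f"need at least k={k} records, got {n}")
    order = list(range(n))
    random.Random(seed).shuffle(order)
    assignments = {}
    for pos, idx in enumerate(order):
        assignments[records[idx].canonical_string] = pos % k
    return FoldPlan(k=k, assignments=assignments)


def fold_splits(
    records: list[ReactionRecord], plan: FoldPlan
) -> list[SplitDataset]:
    """One SplitDataset per fold: held-out fold as test, the rest as train
    (no separate validation portion in the CV protocol)."""
    out = []
    for fold in range(plan.k):
        test = [r for r in records if plan.fold_of(r) == fold]
        train = [r for r in records if plan.fold_of(r) != fold]
        out.append(SplitDataset(train=train, valid=[], test=test, ratios=(0, 0, 0)))
    return out


def dataset_stats(
    raw: list[ReactionRecord], augmented: list[ReactionRecord]
) -> dict:
    """Raw vs. virtual (augmented) counts and growth factor, plus
    provenance and per-type breakdowns — the shape of the published
    raw/virtual dataset summary table."""
    n_raw = len(raw)
    n_virtual = len(augmented)
    by_type: dict[str, int] = {}
    for r in augmented:
        by_type[r.rxn_type] = by_type.get(r.rxn_type, 0) + 1
    return {
        "raw_dataset": n_raw,
        "virtual_dataset": n_virtual,
        "growth_factor": (n_virtual / n_raw) if n_raw else float("nan"),
        "n_fake": sum(1 for r in augmented if r.provenance == "fake"),
        "n_raw_in_virtual": sum(1 for r in augmented if r.provenance == "raw"),
        "by_type": by_type,
        "backend": BACKEND,
    }


def export_pairs(ds: SplitDataset, out_dir, seed: int | None = None) -> dict:
    """Write the six parallel-corpus files (src/tgt x train/valid/test).

    Line i of ``src-<part>.txt`` is the tokenized reactants+reagents side
    of reaction i; line i of ``tgt-<part>.txt`` its tokenized product.  A
    JSON sidecar records the seed, backend and line counts.
    """
    os.makedirs(out_dir, exist_ok=True)
    counts = {}
    for part_name, part in (("train", ds.train), ("valid", ds.valid), ("test", ds.test)):
        src_path = os.path.join(out_dir, f"src-{part_name}.txt")
        tgt_path = os.path.join(out_dir, f"tgt-{part_name}.txt")
        with open(src_path, "w", encoding="utf-8") as fs, open(
            tgt_path, "w", encoding="utf-8"
        ) as ft:
            for rec in part:
                pair = TokenizedPair.from_record(rec)
                fs.write(pair.source + "\n")
                ft.write(pair.target + "\n")
        counts[part_name] = len(part)
    meta = {
        "seed": ds.seed if seed is None else seed,
        "ratios": list(ds.ratios),
        "backend": BACKEND,
        "counts": counts,
    }
    with open(os.path.join(out_dir, "pairs.meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return meta


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
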