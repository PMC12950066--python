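"""Participant-disjoint hold-out splitting.

Validity of subject-wise evaluation hinges on no participant appearing in
more than one of the train/validation/test roles; all windows from one
participant follow that participant's role assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SplitError

DEFAULT_FRACTIONS = (0.55, 0.25, 0.20)
ROLES = ("train", "val", "test")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint assignment of participant IDs to train/val/test roles."""

    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0
    repeat_index: int = 0

    def __post_init__(self) -> None:
        sets = (self.train_ids, self.val_ids, self.test_ids)
        total = sum(len(s) for s in sets)
        union = self.train_ids | self.val_ids | self.test_ids
        if len(union) != total:
            raise SplitError("role ID sets are not pairwise disjoint")
        if total >= 3 and any(len(s) == 0 for s in sets):
            raise SplitError("every role must be non-empty for >= 3 participants")

    def role_of(self, participant_id: str) -> str:
        for role, ids in zip(ROLES, (self.train_ids, self.val_ids, self.test_ids)):
            if participant_id in ids:
                return role
        raise SplitError(f"participant {participant_id!r} not in split")


def apportion(n: int, fractions) -> tuple[int, ...]:
    """Largest-remainder apportionment of n items, ties toward the first
    (training) role.  For 20 participants at (0.55, 0.25, 0.20) this gives
    (11, 5, 4)."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise SplitError("fractions must be positive and sum to 1")
    quotas = n * fractions
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    # stable sort: on tied remainders the earlier role wins
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    # every role must be populated once there are enough participants
    while n >= len(fractions) and counts.min() == 0:
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    return tuple(int(c) for c in counts)


def split_by_participant(
    ids,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
    repeat_index: int = 0,
) -> SplitSpec:
    """Randomly assign participants to train/val/test by shuffled order."""
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise SplitError("participant IDs must be unique")
    if len(ids) < 3:
        raise SplitError(f"need >= 3 participants, got {len(ids)}")
    counts = apportion(len(ids), fractions)
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
    n_tr, n_va, _ = counts
    return SplitSpec(
        train_ids=frozenset(shuffled[:n_tr]),
        val_ids=frozenset(shuffled[n_tr : n_tr + n_va]),
        test_ids=frozenset(shuffled[n_tr + n_va :]),
        fractions=tuple(float(f) for f in fractions),
        seed=seed,
        repeat_index=repeat_index,
    )


def materialize(split: SplitSpec, recordings):
    """Partition recordings into (train, val, test) lists by participant.

    Every recording ID must be assigned a role; each recording lands in
    exactly one collection.
    """
    out = {role: [] for role in ROLES}
    for rec in recordings:
        out[split.role_of(rec.participant_id)].append(rec)
    return out["train"], out["val"], out["test"]


def write_manifest(splits: list[SplitSpec], path) -> None:
    """Plain-text audit record: repeat_index, role, participant_id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("repeat_index\trole\tparticipant_id\n")
        for sp in splits:
            for role, ids in zip(ROLES, (sp.train_ids, sp.val_ids, sp.test_ids)):
                for pid in sorted(ids):
                    fh.write(f"{sp.repeat_index}\t{role}\t{pid}\n")
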