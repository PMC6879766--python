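"""Conditioned, participant-level, stratified fold construction.

Recordings can be forced into the training or validation side of every
fold (e.g. datasets with divergent annotation conventions are held out of
training entirely); the remaining recordings are split at the participant
level, stratified by the AHI >= 15 indicator plus optional disorder tags.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class FoldPlan:
    """Participant-level fold assignment for k-fold cross-validation."""

    k: int
    assignment: dict  # record_id -> "train_only" | "validation_only" | int

    def fold(self, i: int):
        """(train_ids, validation_ids) for fold ``i``."""
        if not 0 <= i < self.k:
            raise IndexError(f"fold {i} out of range for k={self.k}")
        train, val = [], []
        for rid, a in self.assignment.items():
            if a == "train_only":
                train.append(rid)
            elif a == "validation_only":
                val.append(rid)
            elif a == i:
                val.append(rid)
            else:
                train.append(rid)
        return train, val

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"k": self.k, "assignment": self.assignment}, fh,
                      indent=2)

    @staticmethod
    def from_json(path) -> "FoldPlan":
        with open(path) as fh:
            d = json.load(fh)
        return FoldPlan(k=int(d["k"]), assignment=d["assignment"])


def build_folds(metadata: Sequence[dict], k: int = 5,
                forced_train: Sequence[str] = (),
                forced_validation: Sequence[str] = (),
                seed: int = 0) -> FoldPlan:
    """Stratified participant-level fold plan.

    ``metadata`` rows need ``record_id`` and ``ahi``; an optional
    ``tags`` entry (tuple of disorder tags) refines the strata. Strata
    smaller than ``k`` are merged (with a warning) into their AHI-level
    stratum so every stratum can spread over the folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    forced_train = set(forced_train)
    forced_validation = set(forced_validation)
    assignment = {}
    free = []
    for row in metadata:
        rid = row["record_id"]
        if rid in forced_train:
            assignment[rid] = "train_only"
        elif rid in forced_validation:
            assignment[rid] = "validation_only"
        else:
            free.append(row)

    strata: dict = {}
    for row in free:
        key = (row["ahi"] >= 15.0, tuple(sorted(row.get("tags", ()))))
        strata.setdefault(key, []).append(row["record_id"])
    merged: dict = {}
    for key, ids in strata.items():
        if len(ids) < k and key[1]:
            warnings.warn(f"stratum {key} smaller than k={k}: merged",
                          stacklevel=2)
            merged.setdefault((key[0], ()), []).extend(ids)
        else:
            merged.setdefault(key, []).extend(ids)

    rng = np.random.default_rng(seed)
    fold_sizes = np.zeros(k, dtype=int)
    for key in sorted(merged, key=str):
        ids = sorted(merged[key])
        rng.shuffle(ids)
        # fill the currently smallest folds first to keep sizes level
        for rid in ids:
            i = int(np.argmin(fold_sizes))
            assignment[rid] = i
            fold_sizes[i] += 1
    return FoldPlan(k=k, assignment=assignment)
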