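"""Grouped cross-validation schemes shared by the classifier and PLSR.

Groups keep all rows sharing the listed metadata keys (within a sample type)
together: e.g. ``group_key=["replicate"]`` makes one group per (sample type,
replicate), i.e. all refills and scans of one prepared replicate; adding
``"refill"`` narrows a group to one scan triplet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, StratificationError


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout.

    kind : 'kfold_grouped' (k folds, groups kept intact, stratified by
        sample type) or 'leave_group_out' (one fold per group).
    group_key : metadata columns that define a group *within* a sample type
        (the sample-type key variety/robusta_fraction is always included).
    k : number of folds for kfold_grouped.
    seed : shuffling seed for kfold_grouped fold assignment.
    """

    kind: str = "kfold_grouped"
    group_key: tuple = ("replicate",)
    k: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("kfold_grouped", "leave_group_out"):
            raise ParameterError(f"unknown CV kind {self.kind!r}")
        if self.kind == "kfold_grouped" and self.k < 2:
            raise ParameterError("k must be >= 2")
        object.__setattr__(self, "group_key", tuple(self.group_key))


def group_ids(meta: pd.DataFrame, scheme: CVScheme) -> np.ndarray:
    """Integer group id per row: sample type x group_key columns."""
    cols = ["variety", "robusta_fraction", *scheme.group_key]
    cols = list(dict.fromkeys(c for c in cols if c in meta.columns))
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(meta[cols]))
    return codes


def build_folds(
    meta: pd.DataFrame,
    scheme: CVScheme,
    labels: np.ndarray | None = None,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Row-index folds.  For kfold_grouped with labels, folds are stratified:
    each class's groups are shuffled (seeded) and dealt round-robin, so every
    class appears in every training set; a class with fewer groups than folds
    raises :class:`StratificationError`.
    """
    gid = group_ids(meta, scheme)
    groups = pd.Series(range(len(gid))).groupby(gid).apply(lambda s: s.to_numpy())
    if scheme.kind == "leave_group_out":
        return [idx for _, idx in sorted(groups.items())]

    rng = np.random.default_rng(scheme.seed if seed is None else seed)
    fold_members: list[list] = [[] for _ in range(scheme.k)]
    if labels is not None:
        labels = np.asarray(labels)
        strata: dict = {}
        for g, idx in groups.items():
            lab = set(labels[idx])
            if len(lab) != 1:
                raise StratificationError(f"group {g} mixes class labels {sorted(map(str, lab))}")
            strata.setdefault(lab.pop(), []).append(idx)
        for lab in sorted(strata, key=str):
            member_groups = strata[lab]
            if len(member_groups) < scheme.k:
                raise StratificationError(
                    f"class {lab!r} has {len(member_groups)} group(s) but {scheme.k} folds"
                )
            order = rng.permutation(len(member_groups))
            for j, gi in enumerate(order):
                fold_members[j % scheme.k].append(member_groups[gi])
    else:
        keys = sorted(groups.keys())
        order = rng.permutation(len(keys))
        for j, gi in enumerate(order):
            fold_members[j % scheme.k].append(groups[keys[gi]])
    folds = [np.sort(np.concatenate(m)) for m in fold_members if m]
    if len(folds) < scheme.k:
        raise StratificationError("not enough groups to fill every fold")
    return folds


__all__ = ["CVScheme", "group_ids", "build_folds"]
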