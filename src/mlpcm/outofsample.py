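"""Leave-one-solvent-out and leave-one-element-out extrapolation tests.

A model that merely interpolates the training chemistry will look good
under random splits yet fail on a solvent or element it has never seen.
These experiments compare, for one group of records (all records of one
solvent, or all records whose solute contains one element), the error of
the normally-trained protocol on those records ("included") against the
error of the same protocol retrained with the group banished to the test
set ("excluded").  Both numbers are evaluated on the identical group
member records.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .mrmr import FeatureSelection
from .neural_net import NetworkConfig
from .training_protocol import (
    DEFAULT_FRACTIONS,
    SplitIndices,
    grid_search,
    post_validate,
)

__all__ = ["GroupSplitResult", "frequency_rank_groups", "leave_group_out"]


@dataclass
class GroupSplitResult:
    """Included vs excluded error of one solvent or element group."""

    group_kind: str  # solvent | element
    group_label: str
    n_samples: int
    mue_included: float
    mue_excluded: float
    included_verdict: bool
    excluded_verdict: bool


def _group_mask(dataset: Dataset, group_kind: str, group_label: str) -> np.ndarray:
    if group_kind == "solvent":
        return dataset.solvent_ids() == group_label
    if group_kind == "element":
        return np.array([group_label in es for es in dataset.element_sets()])
    raise ValueError(f"group_kind must be 'solvent' or 'element', got {group_kind!r}")


def frequency_rank_groups(
    dataset: Dataset, group_kind: str, top_n: int | None = None
) -> list[tuple[str, int]]:
    """Groups ordered by descending record count, ties broken alphabetically.

    For elements, a record whose solute contains {C, H, N} counts once
    toward each of C, H and N.
    """
    if not len(dataset):
        raise ValueError("dataset is empty")
    counts: Counter[str] = Counter()
    if group_kind == "solvent":
        counts.update(dataset.solvent_ids().tolist())
    elif group_kind == "element":
        for es in dataset.element_sets():
            counts.update(es)
    else:
        raise ValueError(f"group_kind must be 'solvent' or 'element', got {group_kind!r}")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_n is None else ranked[:top_n]


def _excluded_split_fn(dataset: Dataset, members: np.ndarray):
    """Split factory: group members are the whole test set; the remainder
    is partitioned into train and validation at the 60:15 ratio."""
    others = np.setdiff1d(np.arange(len(dataset)), members)
    f_train, f_val, _ = DEFAULT_FRACTIONS
    val_share = f_val / (f_train + f_val)

    def split_fn(seed: int) -> SplitIndices:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(others)
        n_val = int(np.floor(val_share * len(others)))
        return SplitIndices(
            train=np.sort(perm[n_val:]),
            val=np.sort(perm[:n_val]),
            test=np.sort(members.copy()),
            seed=seed,
            constraint_satisfied=True,
        )

    return split_fn


def leave_group_out(
    dataset: Dataset,
    selection: FeatureSelection,
    config: NetworkConfig,
    group_kind: str,
    group_label: str,
    seed: int = 0,
    n_splits: int = 4,
    n_inits: int = 3,
    n_postval: int = 30,
    gate: float = float("inf"),
    include_cosmors: bool = False,
) -> GroupSplitResult:
    """Run the full protocol twice and compare errors on one group.

    Included arm: ordinary constrained splits; the group MUE averages
    each member's ensemble prediction over the post-validation
    iterations in which the member sat in the test fold.  Excluded arm:
    the group is the entire test set of every split, so its records
    never enter training or validation; the group MUE uses the ensemble
    mean over all retrained models.  ``gate`` defaults to off so the
    comparison is reported even for weak candidates.
    """
    members = np.flatnonzero(_group_mask(dataset, group_kind, group_label))
    if members.size == 0:
        raise ValueError(f"no records in {group_kind} group {group_label!r}")
    if members.size == len(dataset):
        raise ValueError(f"{group_kind} group {group_label!r} is the entire dataset")
    if len(dataset) - members.size < 10:
        raise ValueError("excluding the group leaves fewer than 10 training records")

    y = dataset.dg_exp()

    # --- included arm: the standard protocol ---
    inc_candidates = grid_search(
        dataset,
        [selection],
        [config],
        n_splits=n_splits,
        n_inits=n_inits,
        gate=gate,
        master_seed=seed,
        include_cosmors=include_cosmors,
    )
    inc_report = post_validate(
        inc_candidates[0],
        dataset,
        n_iterations=n_postval,
        seed=seed + 1,
        include_cosmors=include_cosmors,
    )
    inc_pred = inc_report.test_fold_predictions[members]
    mue_included = float(np.mean(np.abs(y[members] - inc_pred)))

    # --- excluded arm: group members form the whole test set ---
    split_fn = _excluded_split_fn(dataset, members)
    exc_candidates = grid_search(
        dataset,
        [selection],
        [config],
        n_splits=n_splits,
        n_inits=n_inits,
        gate=gate,
        master_seed=seed,
        include_cosmors=include_cosmors,
        split_fn=split_fn,
    )
    exc_report = post_validate(
        exc_candidates[0],
        dataset,
        n_iterations=n_postval,
        seed=seed + 1,
        include_cosmors=include_cosmors,
        split_fn=split_fn,
    )
    exc_pred = exc_report.ensemble_predictions[members]
    mue_excluded = float(np.mean(np.abs(y[members] - exc_pred)))

    return GroupSplitResult(
        group_kind=group_kind,
        group_label=group_label,
        n_samples=int(members.size),
        mue_included=mue_included,
        mue_excluded=mue_excluded,
        included_verdict=inc_report.verdict,
        excluded_verdict=exc_report.verdict,
    )
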