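"""Threshold selection, dataset reduction and refitting.

The workflow: score the variables of an existing model, keep those at or
above a threshold on a chosen profile (total by default), rebuild the
dataset from the kept columns, refit a model with the same component layout,
and report variable counts and percent explained variation before and after.
All selections come from the *original* model's profiles — the reduction is
a single step, never sequential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .core import (
    DecomposedModel,
    MultiblockDataset,
    build_ssd_table,
)
from .importance import PROFILE_KINDS, VIOPProfiles, select_variables
from .onpls import OnPLS

__all__ = [
    "SelectionReport",
    "profile_targeted_selection",
    "reduce_dataset",
    "reduce_and_refit",
    "component_layout",
]


@dataclass
class SelectionReport:
    """Per-block summary of a reduce-and-refit run.

    ``frame`` mirrors the usual reporting layout: block, number of variables
    in the original and reduced models, and percent of total variation each
    model explains on its own data.  ``selected`` holds the kept variable
    names per block.
    """

    profile_kind: str
    threshold: float
    frame: pd.DataFrame
    selected: dict[str, list[str]]
    reduced_model: DecomposedModel
    reduced_dataset: MultiblockDataset

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return (
            f"SelectionReport(profile={self.profile_kind!r}, "
            f"threshold={self.threshold})\n{self.frame.to_string(index=False)}"
        )


def profile_targeted_selection(
    profiles: VIOPProfiles, profile_kind: str = "total", threshold: float = 1.0
) -> list[np.ndarray]:
    """Select variables per block on the requested profile.

    Blocks whose profile of that kind is empty yield empty selections (they
    are legitimate — e.g. a block with no unique components); downstream
    reduction will refuse to drop a block to zero variables.
    """
    if profile_kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {profile_kind!r}")
    out = []
    for d in range(profiles.n_blocks):
        if profiles.is_empty(d, profile_kind):
            out.append(np.array([], dtype=int))
        else:
            out.append(select_variables(profiles, d, profile_kind, threshold))
    return out


def reduce_dataset(
    dataset: MultiblockDataset, selections: list[np.ndarray]
) -> MultiblockDataset:
    """Column-subset every block to the selected variables (0-based indices)."""
    if len(selections) != dataset.n_blocks:
        raise ValueError("one selection per block is required")
    blocks, names = [], []
    for d, sel in enumerate(selections):
        sel = np.unique(np.asarray(sel, dtype=int))
        if sel.size == 0:
            raise ValueError(
                f"block {dataset.block_names[d]!r} would be reduced to zero variables"
            )
        blocks.append(dataset.blocks[d][:, sel])
        names.append([dataset.variable_names[d][k] for k in sel])
    return MultiblockDataset(
        blocks=blocks,
        block_names=list(dataset.block_names),
        variable_names=names,
        sample_ids=list(dataset.sample_ids),
    )


def component_layout(model: DecomposedModel) -> dict:
    """Extract the (n_global, local, unique) component counts of a model.

    Useful for refitting a reduced dataset with the same layout.
    """
    n_global = len(model.components_of_kind("global"))
    local_counts: dict[tuple[int, ...], int] = {}
    for c in model.components_of_kind("local"):
        key = tuple(sorted(c.member_blocks))
        local_counts[key] = local_counts.get(key, 0) + 1
    unique: dict[int, int] = {}
    for c in model.components_of_kind("unique"):
        (d,) = c.member_blocks
        unique[d] = unique.get(d, 0) + 1
    return {
        "n_global": n_global,
        "local": [(blocks, count) for blocks, count in local_counts.items()],
        "unique": unique,
    }


def _percent_explained(model: DecomposedModel, dataset: MultiblockDataset) -> list[float]:
    table = build_ssd_table(model, dataset)
    return [
        100.0 * table.ssd_cum[d] / table.ss_total[d] for d in range(dataset.n_blocks)
    ]


def reduce_and_refit(
    dataset: MultiblockDataset,
    profiles: VIOPProfiles,
    profile_kind: str = "total",
    threshold: float = 1.0,
    fit_params: dict | OnPLS | None = None,
    original_model: DecomposedModel | None = None,
) -> SelectionReport:
    """Select, reduce, refit, and compare explained variation.

    ``fit_params`` is either an :class:`OnPLS` template (cloned before use)
    or a keyword dict for one; if omitted, the layout is taken from
    ``original_model``.  ``original_model`` provides the "before" percent
    explained; if omitted, the template is fitted on the full dataset first.
    Unique-component counts that exceed what a reduced block can support are
    lowered with a warning.
    """
    if fit_params is None and original_model is None:
        raise ValueError("provide fit_params and/or original_model")
    if fit_params is None:
        fit_params = component_layout(original_model)
    template = fit_params if isinstance(fit_params, OnPLS) else OnPLS(**fit_params)

    if original_model is None:
        original_model = clone(template).fit_model(dataset)

    selections = profile_targeted_selection(profiles, profile_kind, threshold)
    reduced = reduce_dataset(dataset, selections)

    refit = clone(template)
    unique = {
        reduced.block_index(b): int(c) for b, c in dict(refit.unique or {}).items()
    }
    feasible = {}
    for d, count in unique.items():
        cap = reduced.block_sizes[d]
        if count > cap:
            warnings.warn(
                f"block {reduced.block_names[d]!r}: lowering unique components "
                f"from {count} to {cap} after reduction",
                stacklevel=2,
            )
            count = cap
        feasible[d] = count
    refit.set_params(unique=feasible)
    reduced_model = refit.fit_model(reduced)

    pct_before = _percent_explained(original_model, dataset)
    pct_after = _percent_explained(reduced_model, reduced)
    frame = pd.DataFrame(
        {
            "block": list(dataset.block_names),
            "n_original": dataset.block_sizes,
            "n_selected": [len(np.unique(s)) for s in selections],
            "percent_explained_original": pct_before,
            "percent_explained_reduced": pct_after,
        }
    )
    selected = {
        dataset.block_names[d]: [
            dataset.variable_names[d][k] for k in np.sort(np.unique(sel))
        ]
        for d, sel in enumerate(selections)
    }
    return SelectionReport(
        profile_kind=profile_kind,
        threshold=threshold,
        frame=frame,
        selected=selected,
        reduced_model=reduced_model,
        reduced_dataset=reduced,
    )
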