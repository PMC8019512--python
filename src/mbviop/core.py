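"""Core domain types and explained-variance (sum of squares) accounting.

A multiblock analysis operates on several data matrices ("blocks") that share
the same samples (rows) but measure different variables (columns), e.g. a
transcript, a protein and a metabolite block of one experiment.  A decomposed
model represents each block as a sum of rank-1 latent components
``t_a p_{a,d}^T``; every component is typed by how widely its score is shared:

* ``global`` — the score is shared by **all** blocks,
* ``local``  — shared by a strict subset (at least two, not all) of the blocks,
* ``unique`` — present in exactly one block.

The sum-of-squares bookkeeping in this module (``SSD`` per component and
block, its cumulative counterpart, and percent-explained tables) is the raw
material for the variable-importance profiles in :mod:`mbviop.importance`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "MultiblockDataset",
    "DecomposedModel",
    "SSDTable",
    "preprocess_blocks",
    "ssd_component",
    "build_ssd_table",
    "explained_variation_table",
]

KINDS = ("global", "local", "unique")


@dataclass(frozen=True)
class ComponentSpec:
    """One latent component: its identifier, type and member blocks.

    ``member_blocks`` holds 0-based block indices.  The kind is redundant
    given the member set and the total number of blocks, but carrying it
    explicitly lets a two-block model distinguish nothing (there, "global"
    is the only joint kind) and makes serialized models self-describing.
    """

    component_id: str
    kind: str
    member_blocks: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_blocks", frozenset(self.member_blocks))
        if self.kind not in KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if not self.member_blocks:
            raise ValueError(f"component {self.component_id!r} has no member blocks")

    def validate(self, n_blocks: int) -> None:
        m = len(self.member_blocks)
        if max(self.member_blocks) >= n_blocks or min(self.member_blocks) < 0:
            raise ValueError(
                f"component {self.component_id!r} references a block outside 0..{n_blocks - 1}"
            )
        if self.kind == "global" and m != n_blocks:
            raise ValueError(f"global component {self.component_id!r} must span all blocks")
        if self.kind == "local" and not (2 <= m < n_blocks):
            raise ValueError(
                f"local component {self.component_id!r} must span >=2 and < all blocks"
            )
        if self.kind == "unique" and m != 1:
            raise ValueError(f"unique component {self.component_id!r} must span one block")


def _as_matrix(block, name: str) -> np.ndarray:
    arr = np.asarray(block, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"block {name!r} is not a 2-D matrix")
    if arr.shape[1] < 1:
        raise ValueError(f"block {name!r} has no variables")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"block {name!r} contains missing or non-finite values")
    return arr


@dataclass
class MultiblockDataset:
    """An ordered set of sample-aligned data blocks.

    All blocks share the same rows (samples, ``N >= 2``); each block has its
    own variables.  Missing values are rejected — impute or drop upstream.
    """

    blocks: list[np.ndarray]
    block_names: list[str] | None = None
    variable_names: list[list[str]] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("dataset needs at least one block")
        if self.block_names is None:
            self.block_names = [f"D{i + 1}" for i in range(len(self.blocks))]
        if len(self.block_names) != len(self.blocks):
            raise ValueError("block_names length does not match number of blocks")
        if len(set(self.block_names)) != len(self.block_names):
            raise ValueError("block names must be unique")
        self.blocks = [
            _as_matrix(b, n) for b, n in zip(self.blocks, self.block_names)
        ]
        n = self.blocks[0].shape[0]
        if n < 2:
            raise ValueError("blocks must have at least 2 samples")
        for b, name in zip(self.blocks, self.block_names):
            if b.shape[0] != n:
                raise ValueError(f"block {name!r} has {b.shape[0]} rows, expected {n}")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if self.variable_names is None:
            self.variable_names = [
                [f"{name}_v{k + 1}" for k in range(b.shape[1])]
                for b, name in zip(self.blocks, self.block_names)
            ]
        for names, b, bname in zip(self.variable_names, self.blocks, self.block_names):
            if len(names) != b.shape[1]:
                raise ValueError(f"variable_names for block {bname!r} has wrong length")
            if len(set(names)) != len(names):
                raise ValueError(f"variable names within block {bname!r} must be unique")

    @property
    def n_samples(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_sizes(self) -> list[int]:
        return [b.shape[1] for b in self.blocks]

    def block_index(self, block: int | str) -> int:
        if isinstance(block, str):
            try:
                return self.block_names.index(block)
            except ValueError:
                raise KeyError(f"no block named {block!r}") from None
        return int(block)

    def copy(self) -> "MultiblockDataset":
        return MultiblockDataset(
            blocks=[b.copy() for b in self.blocks],
            block_names=list(self.block_names),
            variable_names=[list(v) for v in self.variable_names],
            sample_ids=list(self.sample_ids),
        )


def as_dataset(X) -> MultiblockDataset:
    """Coerce a :class:`MultiblockDataset` or a list of matrices to a dataset."""
    if isinstance(X, MultiblockDataset):
        return X
    return MultiblockDataset(blocks=[np.asarray(b, dtype=float) for b in X])


@dataclass
class DecomposedModel:
    """Scores, per-block normalized loadings and component typing.

    ``scores`` has one column per component (same order as ``components``);
    ``loadings`` maps ``(component_id, block_index)`` to a unit-norm loading
    vector and holds an entry exactly for the member blocks of the component.
    """

    components: list[ComponentSpec]
    scores: np.ndarray
    loadings: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.components):
            raise ValueError("scores must be N x A with one column per component")
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError("component ids must be unique")
        self.loadings = {
            k: np.asarray(v, dtype=float).ravel() for k, v in self.loadings.items()
        }

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def component_ids(self) -> list[str]:
        return [c.component_id for c in self.components]

    def component(self, component_id: str) -> ComponentSpec:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(f"no component {component_id!r}")

    def score(self, component_id: str) -> np.ndarray:
        return self.scores[:, self.component_ids.index(component_id)]

    def components_of_kind(self, kind: str) -> list[ComponentSpec]:
        return [c for c in self.components if c.kind == kind]

    def validate(
        self,
        n_blocks: int | None = None,
        block_sizes: list[int] | None = None,
        norm_tol: float = 1e-8,
        center_tol: float = 1e-8,
    ) -> None:
        """Check structural and numerical invariants of the decomposition."""
        if n_blocks is None:
            n_blocks = 1 + max(d for c in self.components for d in c.member_blocks)
        expected = {
            (c.component_id, d) for c in self.components for d in c.member_blocks
        }
        if set(self.loadings) != expected:
            missing = expected - set(self.loadings)
            extra = set(self.loadings) - expected
            raise ValueError(
                f"loadings do not match component membership "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for c in self.components:
            c.validate(n_blocks)
        for (cid, d), p in self.loadings.items():
            if block_sizes is not None and p.shape[0] != block_sizes[d]:
                raise ValueError(
                    f"loading ({cid!r}, block {d}) has length {p.shape[0]}, "
                    f"expected {block_sizes[d]}"
                )
            if abs(np.linalg.norm(p) - 1.0) > norm_tol:
                raise ValueError(f"loading ({cid!r}, block {d}) is not unit norm")
        means = np.abs(self.scores.mean(axis=0))
        if np.any(means > center_tol):
            bad = self.component_ids[int(np.argmax(means))]
            raise ValueError(f"score column {bad!r} is not mean-centered")

    def copy(self) -> "DecomposedModel":
        return DecomposedModel(
            components=list(self.components),
            scores=self.scores.copy(),
            loadings={k: v.copy() for k, v in self.loadings.items()},
        )


# ---------------------------------------------------------------------------
# Sum-of-squares accounting


@dataclass
class SSDTable:
    """Per-(component, block) explained sums of squares.

    ``ssd[(component_id, d)]`` is the SS of block ``d`` captured by the
    component's score direction; ``ssd_cum[d]`` the cumulative model-explained
    SS of the block; ``ss_total[d]`` the raw total SS of the block.
    """

    ssd: dict[tuple[str, int], float]
    ssd_cum: dict[int, float]
    ss_total: dict[int, float]

    def denominator(self, d: int, cumulative: str = "explained") -> float:
        """The SS a component's share is referred to (the ``SSD_cum`` choice).

        ``cumulative='explained'`` uses the model-explained cumulative SS
        (default); ``'total'`` uses the raw block SS instead.
        """
        if cumulative == "explained":
            value = self.ssd_cum[d]
        elif cumulative == "total":
            value = self.ss_total[d]
        else:
            raise ValueError("cumulative must be 'explained' or 'total'")
        if value <= 0.0:
            raise ValueError(f"block {d} has no explained variation to normalize by")
        return value

    def ratio(self, component_id: str, d: int, cumulative: str = "explained") -> float:
        return self.ssd[(component_id, d)] / self.denominator(d, cumulative)


def preprocess_blocks(
    dataset: MultiblockDataset,
    center: bool = True,
    equal_block_ss: bool = True,
) -> MultiblockDataset:
    """Mean-center columns and/or rescale every block to unit total SS.

    Equal-block scaling stops large blocks from dominating a joint
    decomposition; the convention here is total SS = 1 per block.  The input
    dataset is left untouched.
    """
    out = dataset.copy()
    for i, (block, name) in enumerate(zip(out.blocks, out.block_names)):
        if center:
            block = block - block.mean(axis=0, keepdims=True)
        if equal_block_ss:
            ss = float(np.sum(block**2))
            if ss <= 0.0:
                raise ValueError(f"zero-variance block: {name!r}")
            block = block / np.sqrt(ss)
        out.blocks[i] = block
    return out


def ssd_component(block: np.ndarray, score: np.ndarray) -> float:
    """SS of a block explained by one score direction.

    Computed as the squared Frobenius norm of the projection of the block
    onto the score, ``||D^T t||^2 / ||t||^2`` — equivalently the SS drop when
    the least-squares rank-1 reconstruction from ``t`` is removed.  Invariant
    to the scaling of ``t``.
    """
    block = np.asarray(block, dtype=float)
    score = np.asarray(score, dtype=float).ravel()
    if block.shape[0] != score.shape[0]:
        raise ValueError(
            f"block has {block.shape[0]} rows but score has {score.shape[0]}"
        )
    tt = float(score @ score)
    if tt == 0.0:
        raise ValueError("degenerate score")
    proj = block.T @ score
    return float(proj @ proj) / tt


def build_ssd_table(model: DecomposedModel, dataset: MultiblockDataset) -> SSDTable:
    """Evaluate per-component, cumulative, and total SS for every block."""
    if dataset.n_samples != model.scores.shape[0]:
        raise ValueError(
            f"model scores have {model.scores.shape[0]} rows, "
            f"dataset has {dataset.n_samples} samples"
        )
    for c in model.components:
        c.validate(dataset.n_blocks)
    ssd: dict[tuple[str, int], float] = {}
    for a, c in enumerate(model.components):
        t = model.scores[:, a]
        for d in sorted(c.member_blocks):
            ssd[(c.component_id, d)] = ssd_component(dataset.blocks[d], t)
    ssd_cum = {
        d: sum(v for (cid, dd), v in ssd.items() if dd == d)
        for d in range(dataset.n_blocks)
    }
    ss_total = {
        d: float(np.sum(dataset.blocks[d] ** 2)) for d in range(dataset.n_blocks)
    }
    return SSDTable(ssd=ssd, ssd_cum=ssd_cum, ss_total=ss_total)


def explained_variation_table(
    model: DecomposedModel, dataset: MultiblockDataset
) -> pd.DataFrame:
    """Percent of each block's total SS explained per component.

    Rows are blocks, columns are component ids plus a ``TOTAL`` column; cells
    for blocks a component does not touch are NaN (blank).
    """
    table = build_ssd_table(model, dataset)
    data = np.full((dataset.n_blocks, model.n_components + 1), np.nan)
    for a, c in enumerate(model.components):
        for d in c.member_blocks:
            data[d, a] = 100.0 * table.ssd[(c.component_id, d)] / table.ss_total[d]
    for d in range(dataset.n_blocks):
        data[d, -1] = 100.0 * table.ssd_cum[d] / table.ss_total[d]
    return pd.DataFrame(
        data, index=list(dataset.block_names), columns=model.component_ids + ["TOTAL"]
    )
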