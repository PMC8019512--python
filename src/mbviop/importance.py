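"""MB-VIOP: multiblock variable influence on orthogonal projections.

For every block of a decomposed multiblock model, four per-variable
importance profiles are computed — one for each type of variation the block
participates in (unique, local, global) and one for the whole model (total).
The recipe for each profile is the same: square the unit-norm loadings
(Hadamard square), weight each component's squared loading by the fraction of
explained variance it carries (an ``SSD / SSD_cum`` ratio), sum over the
relevant components and blocks, take the square root, then normalize the
vector so that its sum of squares equals the number of variables ``K`` of the
block.  Under that normalization the equal-contribution reference is exactly
1, which is also the default selection threshold: variables scoring >= 1
matter for the profile's interpretation.

The three per-kind profiles differ only in which (component, block) pairs
feed the weighting:

* **unique** — the block's own unique components and its own SS ratios;
* **local**  — the block's local components, weighted by the SS ratios of
  the *partner* blocks of each component (the block's connection to itself is
  ignored), averaged by the connectivity degree ``beta``;
* **global** — every global component, weighted by the SS ratios of all
  blocks (self included);
* **total**  — the quadratic combination of the three, renormalized.

``beta`` counts the block's (local component, partner block) connections.
Note that within one block's profile ``beta`` is a constant factor, so the
final normalization cancels it; it is computed and reported because it is
part of the method's definition and of its reporting conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin, clone

from .core import (
    DecomposedModel,
    MultiblockDataset,
    SSDTable,
    as_dataset,
    build_ssd_table,
)

__all__ = [
    "VIOPProfiles",
    "MBVIOP",
    "normalize_profile",
    "connectivity_degree",
    "viop_unique",
    "viop_local",
    "viop_global",
    "viop_total",
    "compute_profiles",
    "select_variables",
]

PROFILE_KINDS = ("unique", "local", "global", "total")


def normalize_profile(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale a raw nonnegative profile so its sum of squares equals K.

    Returns ``(sqrt(K) * v / ||v||, False)``; an all-zero input (a block with
    no components of the requested kind) is returned unchanged and flagged
    empty instead of dividing by zero.
    """
    v = np.asarray(v, dtype=float).ravel()
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return np.zeros_like(v), True
    return np.sqrt(v.size) * v / norm, False


def connectivity_degree(model: DecomposedModel, d: int) -> int:
    """Number of (local component, partner block) connections of block ``d``."""
    return sum(
        len(c.member_blocks) - 1
        for c in model.components_of_kind("local")
        if d in c.member_blocks
    )


def viop_unique(
    model: DecomposedModel,
    ssd_table: SSDTable,
    d: int,
    cumulative: str = "explained",
) -> tuple[np.ndarray, bool]:
    """Importance of block ``d``'s variables for its own unique variation."""
    comps = [c for c in model.components_of_kind("unique") if d in c.member_blocks]
    K = _block_size(model, ssd_table, d)
    raw_sq = np.zeros(K)
    for c in comps:
        p = model.loadings[(c.component_id, d)]
        raw_sq += p**2 * ssd_table.ratio(c.component_id, d, cumulative)
    return normalize_profile(np.sqrt(raw_sq))


def viop_local(
    model: DecomposedModel,
    ssd_table: SSDTable,
    d: int,
    cumulative: str = "explained",
    beta: int | None = None,
) -> tuple[np.ndarray, bool]:
    """Importance of block ``d``'s variables for its locally shared variation.

    The block's loadings are weighted by the explained-SS ratios of the
    partner blocks of each local component; the self-connection is excluded.
    ``beta`` defaults to the block's connectivity degree (its exact value is
    immaterial after normalization).
    """
    comps = [c for c in model.components_of_kind("local") if d in c.member_blocks]
    K = _block_size(model, ssd_table, d)
    if not comps:
        return normalize_profile(np.zeros(K))
    b = connectivity_degree(model, d) if beta is None else int(beta)
    if b <= 0:
        raise ValueError("connectivity degree must be positive")
    raw_sq = np.zeros(K)
    for c in comps:
        p = model.loadings[(c.component_id, d)]
        partner_weight = sum(
            ssd_table.ratio(c.component_id, d_lc, cumulative)
            for d_lc in c.member_blocks
            if d_lc != d
        )
        raw_sq += p**2 * partner_weight
    return normalize_profile(np.sqrt(raw_sq / b))


def viop_global(
    model: DecomposedModel,
    ssd_table: SSDTable,
    d: int,
    cumulative: str = "explained",
) -> tuple[np.ndarray, bool]:
    """Importance of block ``d``'s variables for the globally shared variation.

    Every global component contributes the block's squared loadings weighted
    by the explained-SS ratios of *all* blocks (block ``d`` included).
    """
    comps = model.components_of_kind("global")
    K = _block_size(model, ssd_table, d)
    raw_sq = np.zeros(K)
    for c in comps:
        p = model.loadings[(c.component_id, d)]
        weight = sum(
            ssd_table.ratio(c.component_id, d_j, cumulative)
            for d_j in sorted(c.member_blocks)
        )
        raw_sq += p**2 * weight
    return normalize_profile(np.sqrt(raw_sq))


def viop_total(
    unique: np.ndarray, local: np.ndarray, global_: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Join the three per-kind profiles quadratically and renormalize."""
    return normalize_profile(np.sqrt(unique**2 + local**2 + global_**2))


def _block_size(model: DecomposedModel, ssd_table: SSDTable, d: int) -> int:
    for c in model.components:
        if d in c.member_blocks:
            return model.loadings[(c.component_id, d)].shape[0]
    raise ValueError(f"block {d} does not participate in any component")


@dataclass
class VIOPProfiles:
    """The four MB-VIOP vectors per block, plus beta and empty-profile flags.

    Every non-empty profile satisfies ``sum(v**2) == K_d``; profiles of a
    kind the block has no components of are exact zero vectors, flagged in
    ``empty``.
    """

    block_names: list[str]
    variable_names: list[list[str]]
    values: dict[tuple[int, str], np.ndarray]
    beta: list[int]
    empty: set[tuple[int, str]] = field(default_factory=set)

    def block_index(self, block: int | str) -> int:
        if isinstance(block, str):
            return self.block_names.index(block)
        return int(block)

    def get(self, block: int | str, kind: str) -> np.ndarray:
        if kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {kind!r}")
        return self.values[(self.block_index(block), kind)]

    def is_empty(self, block: int | str, kind: str) -> bool:
        return (self.block_index(block), kind) in self.empty

    def to_frame(self, block: int | str) -> pd.DataFrame:
        """One block's profiles as a table: variable, unique, local, global, total."""
        d = self.block_index(block)
        return pd.DataFrame(
            {"variable": list(self.variable_names[d])}
            | {kind: self.values[(d, kind)] for kind in PROFILE_KINDS}
        )

    @property
    def n_blocks(self) -> int:
        return len(self.block_names)


def compute_profiles(
    model: DecomposedModel,
    dataset: MultiblockDataset,
    cumulative: str = "explained",
    beta: dict[int, int] | None = None,
) -> VIOPProfiles:
    """Run the full MB-VIOP computation for every block of a model.

    Builds the SSD table from the data and the model scores, then evaluates
    the unique, local, global and total profiles per block.  ``beta`` can
    override the connectivity degree per block index.
    """
    ssd_table = build_ssd_table(model, dataset)
    values: dict[tuple[int, str], np.ndarray] = {}
    empty: set[tuple[int, str]] = set()
    betas: list[int] = []
    for d in range(dataset.n_blocks):
        b_override = (beta or {}).get(d)
        u, u_empty = viop_unique(model, ssd_table, d, cumulative)
        l, l_empty = viop_local(model, ssd_table, d, cumulative, beta=b_override)
        g, g_empty = viop_global(model, ssd_table, d, cumulative)
        t, t_empty = viop_total(u, l, g)
        for kind, vec, flag in (
            ("unique", u, u_empty),
            ("local", l, l_empty),
            ("global", g, g_empty),
            ("total", t, t_empty),
        ):
            values[(d, kind)] = vec
            if flag:
                empty.add((d, kind))
        betas.append(
            b_override if b_override is not None else connectivity_degree(model, d)
        )
    return VIOPProfiles(
        block_names=list(dataset.block_names),
        variable_names=[list(v) for v in dataset.variable_names],
        values=values,
        beta=betas,
        empty=empty,
    )


def select_variables(
    profiles: VIOPProfiles,
    block: int | str,
    profile_kind: str = "total",
    threshold: float = 1.0,
) -> np.ndarray:
    """Variables at or above the importance threshold, most important first.

    Returns 0-based variable indices sorted by descending MB-VIOP value (ties
    by ascending index).  The default threshold 1 is the equal-contribution
    reference; lower it (e.g. to 0.5) for a more conservative selection that
    keeps a superset of variables.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = profiles.block_index(block)
    if profiles.is_empty(d, profile_kind):
        warnings.warn(
            f"block {profiles.block_names[d]!r} has an empty {profile_kind} profile; "
            "nothing to select",
            stacklevel=2,
        )
        return np.array([], dtype=int)
    v = profiles.get(d, profile_kind)
    # tiny relative slack keeps the boundary decision (v == threshold is
    # selected) stable under floating-point rounding of the normalization
    idx = np.flatnonzero(v >= threshold * (1.0 - 1e-9))
    order = np.lexsort((idx, -v[idx]))
    return idx[order]


class MBVIOP(BaseEstimator, TransformerMixin):
    """Estimator computing MB-VIOP profiles and selecting variables.

    Parameters
    ----------
    model : DecomposedModel or OnPLS estimator, optional
        The decomposition to score.  A fitted estimator contributes its
        ``model_``; an unfitted one is cloned and fitted on the data passed
        to :meth:`fit`.  Required in one of these forms.
    profile : {'unique', 'local', 'global', 'total'}
        Profile used by :meth:`transform` / :meth:`get_support`.
    threshold : float
        Selection threshold on the chosen profile (default 1.0).
    cumulative : {'explained', 'total'}
        Denominator convention of the SS ratios.
    beta : mapping block index -> int, optional
        Connectivity-degree overrides.

    Attributes (after ``fit``)
    --------------------------
    profiles_ : VIOPProfiles
    beta_ : list of int
    support_ : list of ndarray
        Selected 0-based variable indices per block (ascending).
    """

    def __init__(
        self,
        model=None,
        profile: str = "total",
        threshold: float = 1.0,
        cumulative: str = "explained",
        beta=None,
    ):
        self.model = model
        self.profile = profile
        self.threshold = threshold
        self.cumulative = cumulative
        self.beta = beta

    def _resolve_model(self, dataset: MultiblockDataset) -> DecomposedModel:
        if isinstance(self.model, DecomposedModel):
            return self.model
        if hasattr(self.model, "model_"):
            return self.model.model_
        if hasattr(self.model, "fit_model"):
            return clone(self.model).fit_model(dataset)
        raise ValueError(
            "model must be a DecomposedModel or an OnPLS estimator (fitted or not)"
        )

    def fit(self, X, y=None):
        if self.profile not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.profile!r}")
        dataset = as_dataset(X)
        model = self._resolve_model(dataset)
        beta = (
            {int(k): int(v) for k, v in self.beta.items()} if self.beta else None
        )
        self.model_ = model
        self.profiles_ = compute_profiles(
            model, dataset, cumulative=self.cumulative, beta=beta
        )
        self.beta_ = list(self.profiles_.beta)
        self.support_ = [
            np.sort(select_variables(self.profiles_, d, self.profile, self.threshold))
            if not self.profiles_.is_empty(d, self.profile)
            else np.array([], dtype=int)
            for d in range(dataset.n_blocks)
        ]
        return self

    def get_support(self, block: int | str) -> np.ndarray:
        d = self.profiles_.block_index(block)
        return self.support_[d]

    def transform(self, X):
        """Column-subset every block to its selected variables."""
        dataset = as_dataset(X)
        if dataset.n_blocks != self.profiles_.n_blocks:
            raise ValueError("dataset block count differs from the fitted profiles")
        return [b[:, idx] for b, idx in zip(dataset.blocks, self.support_)]
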