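"""Simplified OnPLS-style multiblock decomposition.

Fits a :class:`~mbviop.core.DecomposedModel` from data alone.  The fitter is
a transparent stand-in honoring the OnPLS contract — a symmetric split of
each block's variance into globally joint, locally joint and unique parts —
implemented by sequential singular-vector extraction:

1. each **global** component is the dominant left singular vector of the
   column-concatenation of all (deflated) blocks;
2. each **local** component repeats this on the concatenation of its member
   blocks' residuals, the score orthogonalized against all earlier scores;
3. each **unique** component is the dominant principal direction of one
   block's remaining residual, again orthogonalized.

After every extraction the member blocks are deflated by the rank-1
reconstruction.  Component counts are user-supplied; there is no automatic
selection.  Loadings are re-estimated by least squares against the original
(preprocessed) data and normalized to unit length.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .core import (
    ComponentSpec,
    DecomposedModel,
    MultiblockDataset,
    as_dataset,
    explained_variation_table,
)

__all__ = ["OnPLS", "normalize_loadings", "model_from_ground_truth", "fit_onpls"]

_RANK_TOL = 1e-8


def _signed_unit(v: np.ndarray) -> np.ndarray:
    """Rescale to unit norm with the largest-magnitude entry positive."""
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("zero loading vector cannot be normalized")
    v = v / norm
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    return v


def normalize_loadings(model: DecomposedModel) -> DecomposedModel:
    """Unit-norm every loading with a deterministic sign convention."""
    out = model.copy()
    out.loadings = {k: _signed_unit(p) for k, p in out.loadings.items()}
    return out


def model_from_ground_truth(
    truth: DecomposedModel, dataset: MultiblockDataset
) -> DecomposedModel:
    """Re-estimate loadings from data while keeping known scores and typing.

    Scores and component specs are taken from ``truth``; each loading is the
    least-squares regression of the block onto the score, then normalized.
    This gives a model whose loadings reflect the data actually handed in
    (noise included) rather than the noise-free design.
    """
    if truth.scores.shape[0] != dataset.n_samples:
        raise ValueError("ground-truth scores do not match dataset sample count")
    for c in truth.components:
        c.validate(dataset.n_blocks)
    loadings: dict[tuple[str, int], np.ndarray] = {}
    for a, c in enumerate(truth.components):
        t = truth.scores[:, a]
        tt = float(t @ t)
        if tt == 0.0:
            raise ValueError(f"degenerate score for component {c.component_id!r}")
        for d in c.member_blocks:
            loadings[(c.component_id, d)] = _signed_unit(dataset.blocks[d].T @ t / tt)
    return DecomposedModel(
        components=list(truth.components), scores=truth.scores.copy(), loadings=loadings
    )


class OnPLS(BaseEstimator):
    """Sequential multiblock decomposition estimator.

    Parameters
    ----------
    n_global : int
        Number of components shared by all blocks.
    local : sequence of (blocks, count)
        Local component groups; ``blocks`` is a tuple of block indices (or
        names, resolved against the fitted dataset) with 2 <= len < n_blocks.
    unique : mapping block -> count
        Number of unique components per block.

    Attributes (after ``fit``)
    --------------------------
    model_ : DecomposedModel
    explained_variation_ : pandas.DataFrame
        Percent explained per component and block, plus a TOTAL column.
    """

    def __init__(self, n_global: int = 0, local=(), unique=None,
                 refine_iter: int = 50, refine_tol: float = 1e-10):
        self.n_global = n_global
        self.local = local
        self.unique = unique
        self.refine_iter = refine_iter
        self.refine_tol = refine_tol

    def fit(self, X, y=None):
        dataset = as_dataset(X)
        n_blocks, N = dataset.n_blocks, dataset.n_samples
        unique = dict(self.unique or {})
        unique = {dataset.block_index(b): int(c) for b, c in unique.items()}
        local = [
            (tuple(sorted(dataset.block_index(b) for b in blocks)), int(count))
            for blocks, count in (self.local or ())
        ]
        total = self.n_global + sum(c for _, c in local) + sum(unique.values())
        if total == 0:
            raise ValueError("no components requested")
        if total > N - 1:
            raise ValueError(
                f"{total} components requested but only {N - 1} are feasible "
                f"with {N} samples"
            )
        for blocks, _ in local:
            if not (2 <= len(blocks) < n_blocks):
                raise ValueError(
                    f"local component group {blocks} must span >=2 and < all blocks"
                )

        residuals = [b.copy() for b in dataset.blocks]
        scores: list[np.ndarray] = []
        specs: list[ComponentSpec] = []

        def extract(members: tuple[int, ...], cid: str, kind: str) -> None:
            M = np.concatenate([residuals[d] for d in members], axis=1)
            U, s, _ = np.linalg.svd(M, full_matrices=False)
            if s[0] < _RANK_TOL:
                names = ", ".join(dataset.block_names[d] for d in members)
                raise ValueError(
                    f"rank deficiency extracting {kind} component from "
                    f"block(s) {names}: no residual variation left"
                )
            u = U[:, 0]
            t = u - u.mean()
            for s in scores:
                t = t - (s @ t) * s
            norm = np.linalg.norm(t)
            if norm < _RANK_TOL:
                names = ", ".join(dataset.block_names[d] for d in members)
                raise ValueError(
                    f"rank deficiency extracting {kind} component from block(s) {names}"
                )
            t /= norm
            for d in members:
                residuals[d] -= np.outer(t, t @ residuals[d])
            scores.append(t)
            specs.append(ComponentSpec(cid, kind, frozenset(members)))

        all_blocks = tuple(range(n_blocks))
        for g in range(self.n_global):
            extract(all_blocks, f"g{g + 1}", "global")
        li = 0
        for blocks, count in local:
            for _ in range(count):
                li += 1
                extract(blocks, f"l{li}", "local")
        ui = 0
        for d in sorted(unique):
            for _ in range(unique[d]):
                ui += 1
                extract((d,), f"u{ui}", "unique")

        T = self._refine(np.column_stack(scores), specs, dataset)
        loadings = {
            (spec.component_id, d): _signed_unit(dataset.blocks[d].T @ T[:, a])
            for a, spec in enumerate(specs)
            for d in spec.member_blocks
        }
        self.model_ = DecomposedModel(
            components=specs, scores=T, loadings=loadings
        )
        self.n_components_ = len(specs)
        self.explained_variation_ = explained_variation_table(self.model_, dataset)
        return self

    def _refine(self, T: np.ndarray, specs, dataset) -> np.ndarray:
        """Refine the greedy scores by monotone ascent on explained SS.

        Two alternating moves, both preserving centering and mutual
        orthogonality and both non-decreasing in the total member-block
        explained SS ``sum_a sum_{d in members(a)} ||D_d^T t_a||^2``:

        * coordinate update — replace one score by the best direction in the
          orthogonal complement of all other scores (top singular vector of
          the projected member concatenation);
        * Jacobi rotation — jointly rotate a pair of scores within their own
          span by the closed-form optimal angle.

        The greedy pass alone can strand a block's variance in the span of
        scores of non-member components when singular values are close; the
        pair rotations reallocate it.
        """
        N, A = T.shape
        if self.refine_iter <= 0 or A == 1:
            return T
        ones = np.full((N, 1), 1.0 / np.sqrt(N))
        concat = {
            spec.component_id: np.concatenate(
                [dataset.blocks[d] for d in sorted(spec.member_blocks)], axis=1
            )
            for spec in specs
        }

        def term(a: int, t: np.ndarray) -> float:
            M = concat[specs[a].component_id]
            return float(np.sum((M.T @ t) ** 2))

        prev = sum(term(a, T[:, a]) for a in range(A))
        for _ in range(self.refine_iter):
            for a, spec in enumerate(specs):
                others = np.delete(T, a, axis=1)
                Q = np.linalg.qr(np.hstack([others, ones]))[0]
                M = concat[spec.component_id]
                Mp = M - Q @ (Q.T @ M)
                U, s, _ = np.linalg.svd(Mp, full_matrices=False)
                if s[0] < _RANK_TOL:
                    continue
                t_new = U[:, 0]
                t_new -= Q @ (Q.T @ t_new)  # numerical re-orthogonalization
                norm = np.linalg.norm(t_new)
                if norm < _RANK_TOL:
                    continue
                t_new /= norm
                if t_new @ T[:, a] < 0:
                    t_new = -t_new
                if term(a, t_new) > term(a, T[:, a]):
                    T[:, a] = t_new
            for a in range(A):
                Ma = concat[specs[a].component_id]
                for b in range(a + 1, A):
                    Mb = concat[specs[b].component_id]
                    ta, tb = T[:, a], T[:, b]
                    pa, qa = Ma.T @ ta, Ma.T @ tb
                    pb, qb = Mb.T @ ta, Mb.T @ tb
                    # f(theta) = const + c2*cos(2 theta) + s2*sin(2 theta)
                    c2 = (pa @ pa - qa @ qa - pb @ pb + qb @ qb) / 2.0
                    s2 = float(pa @ qa) - float(pb @ qb)
                    if np.hypot(c2, s2) < 1e-15:
                        continue
                    theta = 0.5 * np.arctan2(s2, c2)
                    gain = c2 * np.cos(2 * theta) + s2 * np.sin(2 * theta) - c2
                    if gain <= 1e-14:
                        continue
                    c, s = np.cos(theta), np.sin(theta)
                    T[:, a], T[:, b] = c * ta + s * tb, -s * ta + c * tb
            cur = sum(term(a, T[:, a]) for a in range(A))
            if cur - prev <= self.refine_tol * max(1.0, abs(prev)):
                break
            prev = cur
        return T

    def fit_model(self, X) -> DecomposedModel:
        """Fit and return the decomposed model directly."""
        return self.fit(X).model_


def fit_onpls(
    dataset, n_global: int = 0, local_spec=(), unique_spec=None
) -> DecomposedModel:
    """Functional wrapper over :class:`OnPLS`."""
    return OnPLS(n_global=n_global, local=local_spec, unique=unique_spec).fit_model(
        dataset
    )
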