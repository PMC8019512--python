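import numpy as np
import pytest

from mbviop import (
    ComponentSpec,
    MultiblockDataset,
    generate,
    model_from_ground_truth,
    orthonormal_scores,
    sd16_235glu,
)
from mbviop.core import DecomposedModel
from mbviop.importance import compute_profiles


@pytest.fixture(scope="session")
def sd16():
    """The canonical four-block benchmark: (design, dataset, ground truth)."""
    design = sd16_235glu(seed=1)
    dataset, truth = generate(design)
    return design, dataset, truth


@pytest.fixture(scope="session")
def sd16_profiles(sd16):
    _, dataset, truth = sd16
    return compute_profiles(truth, dataset)


def random_instance(rng, n_blocks=None, max_components=4, max_vars=8, n_samples=10):
    """A small random dataset + valid normalized model for oracle checks.

    Blocks are random Gaussian matrices; component memberships are drawn at
    random (global always spans all blocks, locals only exist for >= 3
    blocks); scores are random orthonormal columns and loadings are the
    least-squares regressions of the blocks on them — i.e. a structurally
    valid model that need not fit the data well, which is all the importance
    equations require.
    """
    if n_blocks is None:
        n_blocks = int(rng.integers(2, 4))
    sizes = [int(rng.integers(2, max_vars + 1)) for _ in range(n_blocks)]
    blocks = [rng.standard_normal((n_samples, K)) for K in sizes]
    blocks = [b - b.mean(axis=0) for b in blocks]
    dataset = MultiblockDataset(blocks=blocks)

    n_comp = int(rng.integers(1, max_components + 1))
    components = []
    for a in range(n_comp):
        choices = ["global", "unique"] + (["local"] if n_blocks >= 3 else [])
        kind = choices[int(rng.integers(len(choices)))]
        if kind == "global":
            members = frozenset(range(n_blocks))
        elif kind == "unique":
            members = frozenset({int(rng.integers(n_blocks))})
        else:
            size = int(rng.integers(2, n_blocks))
            members = frozenset(rng.choice(n_blocks, size=size, replace=False).tolist())
        components.append(ComponentSpec(f"c{a}", kind, members))
    # every block must participate in at least one component
    covered = set().union(*(c.member_blocks for c in components))
    for d in range(n_blocks):
        if d not in covered:
            components.append(ComponentSpec(f"u_fill{d}", "unique", frozenset({d})))
    scores = orthonormal_scores(n_samples, len(components), rng)
    skeleton = DecomposedModel(
        components=components,
        scores=scores,
        loadings={
            (c.component_id, d): np.ones(sizes[d])
            for c in components
            for d in c.member_blocks
        },
    )
    model = model_from_ground_truth(skeleton, dataset)
    return dataset, model
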