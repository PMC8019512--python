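import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbviop import (
    MBVIOP,
    ComponentSpec,
    GaussianProfile,
    MultiblockDataset,
    OnPLS,
    PulseProfile,
    SyntheticDesign,
    build_ssd_table,
    compute_profiles,
    connectivity_degree,
    generate,
    normalize_profile,
    select_variables,
    viop_global,
    viop_local,
    viop_total,
    viop_unique,
)
from mbviop.core import DecomposedModel
from mbviop.importance import PROFILE_KINDS

from conftest import random_instance
from naive_reference import naive_profiles


class TestNormalizeProfile:
    def test_sum_of_squares_equals_variable_count(self):
        v, empty = normalize_profile(np.array([0.6, 0.8]))
        assert not empty
        np.testing.assert_allclose(
            v, [0.6 * np.sqrt(2), 0.8 * np.sqrt(2)], rtol=1e-12
        )
        assert np.sum(v**2) == pytest.approx(2.0)

    def test_uniform_vector_maps_to_ones(self):
        v, _ = normalize_profile(np.full(7, 0.3))
        np.testing.assert_allclose(v, 1.0)

    def test_zero_vector_flagged_empty(self):
        v, empty = normalize_profile(np.zeros(4))
        assert empty
        np.testing.assert_array_equal(v, 0.0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=20))
def test_normalization_law_property(values):
    """Any non-zero profile normalizes to sum of squares = K."""
    v, empty = normalize_profile(np.array(values))
    assert not empty
    assert np.sum(v**2) == pytest.approx(len(values), rel=1e-8)


def _single_unique_toy():
    t = np.array([1.0, -1.0]) / np.sqrt(2)
    p = np.array([0.6, 0.8])
    dataset = MultiblockDataset(blocks=[np.outer(t, p)])
    model = DecomposedModel(
        components=[ComponentSpec("u1", "unique", frozenset({0}))],
        scores=t[:, None],
        loadings={("u1", 0): p},
    )
    return dataset, model


class TestUniqueProfile:
    def test_hand_computed_rank_one_case(self):
        dataset, model = _single_unique_toy()
        table = build_ssd_table(model, dataset)
        v, empty = viop_unique(model, table, 0)
        assert not empty
        np.testing.assert_allclose(v, [0.6 * np.sqrt(2), 0.8 * np.sqrt(2)], rtol=1e-10)

    def test_block_without_unique_components_is_empty(self, sd16, sd16_profiles):
        assert sd16_profiles.is_empty("D2", "unique")
        np.testing.assert_array_equal(sd16_profiles.get("D2", "unique"), 0.0)

    def test_benchmark_overlap_variable_stands_out(self, sd16_profiles):
        v = sd16_profiles.get("D1", "unique")
        assert int(np.argmax(v)) + 1 == 13  # the variable in two unique pulses


class TestConnectivityDegree:
    def test_counts_component_partner_connections(self, sd16):
        _, _, truth = sd16
        # D1: two 2-block locals -> 2; D2: one 2-block + one 3-block -> 3
        assert connectivity_degree(truth, 0) == 2
        assert connectivity_degree(truth, 1) == 3
        assert connectivity_degree(truth, 2) == 2
        assert connectivity_degree(truth, 3) == 3

    def test_single_local_pair_gives_one(self):
        comps = [
            ComponentSpec("l1", "local", frozenset({0, 1})),
            ComponentSpec("u1", "unique", frozenset({2})),
        ]
        model = DecomposedModel(
            components=comps,
            scores=np.zeros((4, 2)),
            loadings={
                ("l1", 0): np.array([1.0]),
                ("l1", 1): np.array([1.0]),
                ("u1", 2): np.array([1.0]),
            },
        )
        assert connectivity_degree(model, 0) == 1
        assert connectivity_degree(model, 2) == 0


class TestLocalProfile:
    def test_no_local_membership_is_empty(self, sd16_profiles):
        # D3 participates in one local component, D2 in two; a block outside
        # every local component gets a flagged zero profile
        dataset, model = _single_unique_toy()
        table = build_ssd_table(model, dataset)
        v, empty = viop_local(model, table, 0)
        assert empty and not v.any()

    def test_benchmark_two_separated_peaks(self, sd16_profiles):
        v = sd16_profiles.get("D1", "local")
        flagged = np.sort(select_variables(sd16_profiles, "D1", "local")) + 1
        assert set(range(10, 19)) <= set(flagged)
        assert set(range(35, 48)) <= set(flagged)
        assert not (set(range(20, 35)) & set(flagged))  # valley between peaks

    def test_symmetric_blocks_get_identical_profiles(self):
        design = SyntheticDesign(
            n_samples=12,
            block_sizes=[6, 6, 4],
            components=[
                ComponentSpec("l1", "local", frozenset({0, 1})),
                ComponentSpec("u1", "unique", frozenset({2})),
                ComponentSpec("u2", "unique", frozenset({0})),
                ComponentSpec("u3", "unique", frozenset({1})),
            ],
            profiles={
                ("l1", 0): GaussianProfile(3, 1.0),
                ("l1", 1): GaussianProfile(3, 1.0),
                ("u1", 2): PulseProfile(1, 2),
                ("u2", 0): PulseProfile(5, 6),
                ("u3", 1): PulseProfile(5, 6),
            },
            noise_level=0.0,
            seed=3,
        )
        dataset, truth = generate(design)
        profiles = compute_profiles(truth, dataset)
        np.testing.assert_allclose(
            profiles.get(0, "local"), profiles.get(1, "local"), atol=1e-9
        )

    def test_beta_override_does_not_change_normalized_profile(self, sd16):
        _, dataset, truth = sd16
        base = compute_profiles(truth, dataset)
        overridden = compute_profiles(truth, dataset, beta={0: 7})
        np.testing.assert_allclose(
            base.get("D1", "local"), overridden.get("D1", "local"), rtol=1e-12
        )
        assert overridden.beta[0] == 7


class TestGlobalProfile:
    def test_uniform_loading_gives_all_ones(self):
        t = np.zeros(4)
        t[:2], t[2:] = 1.0, -1.0
        t /= np.linalg.norm(t)
        p = np.full(5, 1 / np.sqrt(5))
        dataset = MultiblockDataset(blocks=[np.outer(t, p)])
        model = DecomposedModel(
            components=[ComponentSpec("g1", "global", frozenset({0}))],
            scores=t[:, None],
            loadings={("g1", 0): p},
        )
        table = build_ssd_table(model, dataset)
        v, empty = viop_global(model, table, 0)
        assert not empty
        np.testing.assert_allclose(v, 1.0, rtol=1e-10)

    def test_benchmark_peaks_at_designed_global_regions(self, sd16_profiles):
        v = sd16_profiles.get("D3", "global")
        flagged = np.sort(select_variables(sd16_profiles, "D3", "global")) + 1
        assert 42 in flagged and 82 in flagged
        assert flagged.min() >= 30 and flagged.max() <= 95
        assert not (set(range(55, 75)) & set(flagged))


class TestTotalProfile:
    def test_collapses_to_single_nonempty_profile(self, sd16_profiles):
        # D2 has no unique components: with empty unique its total combines
        # local+global only; verify the quadratic join on a one-kind toy
        dataset, model = _single_unique_toy()
        profiles = compute_profiles(model, dataset)
        np.testing.assert_allclose(
            profiles.get(0, "total"), profiles.get(0, "unique"), rtol=1e-12
        )

    def test_all_uniform_inputs_stay_uniform(self):
        ones = np.ones(6)
        v, empty = viop_total(ones, ones, ones)
        assert not empty
        np.testing.assert_allclose(v, 1.0)

    def test_benchmark_overlap_variable_visible_in_total(self, sd16_profiles):
        v = sd16_profiles.get("D1", "total")
        assert v[12] > 1.0
        assert v[12] > v[11] and v[12] > v[13]  # a distinct peak at variable 13


class TestOracleEquivalence:
    @pytest.mark.parametrize("cumulative", ["explained", "total"])
    def test_matches_naive_loops_on_random_instances(self, cumulative):
        rng = np.random.default_rng(123)
        for _ in range(50):
            dataset, model = random_instance(rng)
            profiles = compute_profiles(model, dataset, cumulative=cumulative)
            expected = naive_profiles(model, dataset, cumulative=cumulative)
            for d in range(dataset.n_blocks):
                for kind in PROFILE_KINDS:
                    np.testing.assert_allclose(
                        profiles.get(d, kind),
                        expected[(d, kind)],
                        atol=1e-10,
                        err_msg=f"block {d}, {kind} profile",
                    )


class TestComputeProfiles:
    def test_sum_of_squares_law_on_benchmark(self, sd16_profiles):
        sizes = {"D1": 61, "D2": 79, "D3": 96, "D4": 96}
        for name, K in sizes.items():
            for kind in PROFILE_KINDS:
                if sd16_profiles.is_empty(name, kind):
                    continue
                v = sd16_profiles.get(name, kind)
                assert np.sum(v**2) == pytest.approx(K, rel=1e-8)
                assert (v >= 0).all()

    def test_deterministic(self, sd16):
        _, dataset, truth = sd16
        p1 = compute_profiles(truth, dataset)
        p2 = compute_profiles(truth, dataset)
        for key, v in p1.values.items():
            np.testing.assert_array_equal(v, p2.values[key])

    def test_block_rescaling_leaves_profiles_unchanged(self, sd16):
        _, dataset, truth = sd16
        base = compute_profiles(truth, dataset)
        scaled = dataset.copy()
        scaled.blocks[1] = scaled.blocks[1] * 7.5
        after = compute_profiles(truth, scaled)
        for key, v in base.values.items():
            np.testing.assert_allclose(after.values[key], v, rtol=1e-9)


class TestSelection:
    def test_threshold_boundary_inclusive(self):
        dataset, model = _single_unique_toy()
        profiles = compute_profiles(model, dataset)
        picked = select_variables(profiles, 0, "unique", threshold=1.0)
        np.testing.assert_array_equal(picked, [1])
        uniform = compute_profiles(*_uniform_case())
        all_picked = select_variables(uniform, 0, "global", threshold=1.0)
        assert len(all_picked) == 5

    def test_descending_value_order_with_index_ties(self, sd16_profiles):
        picked = select_variables(sd16_profiles, "D1", "unique")
        v = sd16_profiles.get("D1", "unique")
        values = v[picked]
        assert (np.diff(values) <= 1e-12).all()
        assert picked[0] == 12  # variable 13 first

    def test_lower_threshold_selects_superset(self, sd16_profiles):
        for name in sd16_profiles.block_names:
            strict = set(select_variables(sd16_profiles, name, "total", 1.0))
            loose = set(select_variables(sd16_profiles, name, "total", 0.5))
            assert strict <= loose

    def test_empty_profile_warns_and_returns_nothing(self, sd16_profiles):
        with pytest.warns(UserWarning, match="empty"):
            picked = select_variables(sd16_profiles, "D2", "unique")
        assert picked.size == 0

    def test_nonpositive_threshold_rejected(self, sd16_profiles):
        with pytest.raises(ValueError, match="threshold"):
            select_variables(sd16_profiles, "D1", "total", 0.0)


def _uniform_case():
    t = np.zeros(4)
    t[:2], t[2:] = 1.0, -1.0
    t /= np.linalg.norm(t)
    p = np.full(5, 1 / np.sqrt(5))
    dataset = MultiblockDataset(blocks=[np.outer(t, p)])
    model = DecomposedModel(
        components=[ComponentSpec("g1", "global", frozenset({0}))],
        scores=t[:, None],
        loadings={("g1", 0): p},
    )
    return model, dataset


@pytest.fixture(scope="module")
def two_block():
    design = SyntheticDesign(
        n_samples=16,
        block_sizes=[8, 6],
        components=[
            ComponentSpec("g1", "global", frozenset({0, 1})),
            ComponentSpec("u1", "unique", frozenset({0})),
            ComponentSpec("u2", "unique", frozenset({1})),
        ],
        profiles={
            ("g1", 0): GaussianProfile(3, 1.0),
            ("g1", 1): GaussianProfile(2, 1.0),
            ("u1", 0): PulseProfile(6, 8),
            ("u2", 1): PulseProfile(5, 6),
        },
        noise_level=0.0,
        seed=11,
    )
    dataset, truth = generate(design)
    return dataset, truth, compute_profiles(truth, dataset)


class TestTwoBlockConsistency:
    """With two blocks there is no local kind: the O2PLS situation."""

    def test_local_profiles_empty(self, two_block):
        _, _, profiles = two_block
        for d in range(2):
            assert profiles.is_empty(d, "local")
            assert profiles.beta[d] == 0

    def test_total_is_renormalized_unique_global_combination(self, two_block):
        _, _, profiles = two_block
        for d in range(2):
            u = profiles.get(d, "unique")
            g = profiles.get(d, "global")
            expected, _ = normalize_profile(np.sqrt(u**2 + g**2))
            np.testing.assert_allclose(profiles.get(d, "total"), expected, rtol=1e-10)


class TestMultiRoleVariable:
    def test_variable_in_global_and_local_supports_flagged_in_both(self):
        design = SyntheticDesign(
            n_samples=14,
            block_sizes=[6, 6, 6],
            components=[
                ComponentSpec("g1", "global", frozenset({0, 1, 2})),
                ComponentSpec("l1", "local", frozenset({0, 1})),
                ComponentSpec("u1", "unique", frozenset({2})),
            ],
            profiles={
                ("g1", 0): GaussianProfile(2, 0.7),
                ("g1", 1): GaussianProfile(2, 0.7),
                ("g1", 2): GaussianProfile(2, 0.7),
                ("l1", 0): GaussianProfile(2, 0.7),  # same support as g1 in D1
                ("l1", 1): GaussianProfile(5, 0.7),
                ("u1", 2): PulseProfile(5, 6),
            },
            noise_level=0.0,
            seed=21,
        )
        dataset, truth = generate(design)
        profiles = compute_profiles(truth, dataset)
        assert profiles.get(0, "global")[1] > 1.0
        assert profiles.get(0, "local")[1] > 1.0


class TestMBVIOPEstimator:
    def test_fit_with_decomposed_model(self, sd16):
        _, dataset, truth = sd16
        est = MBVIOP(model=truth).fit(dataset)
        assert est.beta_ == [2, 3, 2, 3]
        reduced = est.transform(dataset)
        assert [b.shape[0] for b in reduced] == [50] * 4
        for b, idx in zip(reduced, est.support_):
            assert b.shape[1] == len(idx)

    def test_fit_with_unfitted_onpls_template(self, sd16):
        _, dataset, _ = sd16
        template = OnPLS(
            n_global=2,
            local=[((0, 3), 1), ((0, 1), 1), ((1, 2, 3), 1)],
            unique={0: 3, 2: 1, 3: 1},
        )
        est = MBVIOP(model=template, profile="unique").fit(dataset)
        assert est.get_support("D2").size == 0  # no unique components in D2

    def test_rejects_missing_model(self, sd16):
        _, dataset, _ = sd16
        with pytest.raises(ValueError, match="model"):
            MBVIOP().fit(dataset)

    def test_sklearn_clone_compatible(self, sd16):
        from sklearn.base import clone

        _, _, truth = sd16
        est = MBVIOP(model=truth, threshold=0.5)
        cloned = clone(est)
        assert cloned.get_params()["threshold"] == 0.5
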