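import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petatn import (
    SUVRTable,
    cliffs_delta,
    cluster_extent_inference,
    compare_groups_atlas,
    summarize_cluster,
    voxelwise_welch_t,
)
from petatn.groupstats import delta_magnitude

from conftest import make_volume


def brute_force_delta(x, y):
    more = sum(1 for a in x for b in y if a > b)
    less = sum(1 for a in x for b in y if a < b)
    return (more - less) / (len(x) * len(y))


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "x, y, expected, mag",
        [
            ([1, 2, 3], [4, 5, 6], -1.0, "large"),
            ([1, 2, 3], [1, 2, 3], 0.0, "small"),
            ([1, 3], [2, 4], -0.5, "large"),
            ([4, 5, 6], [1, 2, 3], 1.0, "large"),
        ],
    )
    def test_known_values(self, x, y, expected, mag):
        delta, magnitude = cliffs_delta(x, y)
        assert delta == pytest.approx(expected)
        assert magnitude == mag

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(-50, 50), min_size=1, max_size=200),
        y=st.lists(st.integers(-50, 50), min_size=1, max_size=200),
    )
    def test_matches_pair_enumeration_oracle(self, x, y):
        delta, _ = cliffs_delta(x, y)
        assert delta == pytest.approx(brute_force_delta(x, y), abs=1e-15)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=20)
        assert cliffs_delta(x, y)[0] == pytest.approx(-cliffs_delta(y, x)[0])

    @pytest.mark.parametrize(
        "delta, band",
        [(0.0, "small"), (0.329, "small"), (0.33, "medium"), (0.47, "medium"),
         (0.471, "large"), (-0.8, "large")],
    )
    def test_magnitude_bands(self, delta, band):
        assert delta_magnitude(delta) == band


def suvr_table_from_values(values: dict[str, dict[str, float]], voi="cingulate"):
    records = []
    for pid, vois in values.items():
        for name, v in vois.items():
            records.append(
                {"patient_id": pid, "modality": "PBB3", "voi": name,
                 "suvr": v, "n_voxels": 100, "volume_mm3": 800.0}
            )
    return SUVRTable(pd.DataFrame.from_records(records))


@pytest.fixture(scope="module")
def table_and_groups():
    rng = np.random.default_rng(11)
    values, groups = {}, {}
    for i in range(7):
        values[f"ad{i}"] = {"cingulate": rng.normal(1.26, 0.05)}
        groups[f"ad{i}"] = "AD"
    for i in range(6):
        values[f"bn{i}"] = {"cingulate": rng.normal(0.93, 0.02)}
        groups[f"bn{i}"] = "BN"
    for i in range(10):
        values[f"sn{i}"] = {"cingulate": rng.normal(0.97, 0.10)}
        groups[f"sn{i}"] = "SNAP"
    return suvr_table_from_values(values), groups


class TestCompareGroupsAtlas:
    def test_separated_groups_significant_with_full_delta(self, table_and_groups):
        table, groups = table_and_groups
        res = compare_groups_atlas(table, groups, ["cingulate"])
        cmp_ = res.vois["cingulate"]
        ad_bn = next(c for c in cmp_.contrasts if {c.group_a, c.group_b} == {"AD", "BN"})
        assert ad_bn.delta == pytest.approx(1.0)
        assert ad_bn.p_adjusted < 0.05
        assert cmp_.omnibus_p < 0.05

    def test_adjusted_p_not_below_raw(self, table_and_groups):
        table, groups = table_and_groups
        res = compare_groups_atlas(table, groups, ["cingulate"])
        for c in res.vois["cingulate"].contrasts:
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0

    def test_patient_order_invariance(self, table_and_groups):
        table, groups = table_and_groups
        shuffled = SUVRTable(table.frame.sample(frac=1.0, random_state=3))
        a = compare_groups_atlas(table, groups, ["cingulate"]).to_frame()
        b = compare_groups_atlas(shuffled, groups, ["cingulate"]).to_frame()
        pd.testing.assert_frame_equal(
            a.sort_values("contrast").reset_index(drop=True),
            b.sort_values("contrast").reset_index(drop=True),
        )

    def test_small_group_rejected(self):
        table = suvr_table_from_values(
            {"a1": {"v": 1.0}, "a2": {"v": 1.1}, "b1": {"v": 2.0}}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups_atlas(table, {"a1": "A", "a2": "A", "b1": "B"}, ["v"])

    def test_two_group_omnibus_matches_ranksum_oracle(self, rng):
        """With two groups the Kruskal-Wallis omnibus reduces to the
        two-sided rank-sum z-test (hand-computed, no ties)."""
        xs = rng.normal(1.0, 0.15, 8)
        ys = rng.normal(1.1, 0.15, 9)
        values = {f"x{i}": {"v": v} for i, v in enumerate(xs)}
        values.update({f"y{i}": {"v": v} for i, v in enumerate(ys)})
        groups = {p: p[0] for p in values}
        res = compare_groups_atlas(suvr_table_from_values(values), groups, ["v"])
        combined = np.concatenate([xs, ys])
        ranks = stats.rankdata(combined)
        r1 = ranks[: len(xs)].sum()
        n1, n2 = len(xs), len(ys)
        big_n = n1 + n2
        z = (r1 - n1 * (big_n + 1) / 2) / np.sqrt(n1 * n2 * (big_n + 1) / 12)
        p_oracle = stats.chi2.sf(z**2, df=1)
        assert res.vois["v"].omnibus_p == pytest.approx(p_oracle, abs=1e-6)


class TestVoxelwiseWelchT:
    def test_identical_groups_give_zero(self, rng):
        vols = [make_volume(rng.random((6, 6, 6))) for _ in range(3)]
        t, df, flags = voxelwise_welch_t(vols, [v.with_data(v.data) for v in vols],
                                         np.ones((6, 6, 6), bool))
        assert np.allclose(t, 0.0)

    def test_single_voxel_matches_scalar_welch(self):
        a_vals, b_vals = [1.2, 1.3, 1.25], [0.9, 0.95, 1.0]
        a = [make_volume(np.full((1, 1, 1), v)) for v in a_vals]
        b = [make_volume(np.full((1, 1, 1), v)) for v in b_vals]
        t, df, _ = voxelwise_welch_t(a, b, np.ones((1, 1, 1), bool))
        oracle = stats.ttest_ind(a_vals, b_vals, equal_var=False)
        assert t[0, 0, 0] == pytest.approx(oracle.statistic, abs=1e-12)
        assert df[0, 0, 0] == pytest.approx(oracle.df, abs=1e-9)

    def test_swapping_groups_negates_t(self, rng):
        a = [make_volume(rng.random((5, 5, 5))) for _ in range(4)]
        b = [make_volume(rng.random((5, 5, 5))) for _ in range(3)]
        mask = np.ones((5, 5, 5), bool)
        t_ab, _, _ = voxelwise_welch_t(a, b, mask)
        t_ba, _, _ = voxelwise_welch_t(b, a, mask)
        assert np.allclose(t_ab, -t_ba, atol=1e-12)

    def test_zero_variance_voxels_flagged(self):
        a = [make_volume(np.ones((2, 2, 2))) for _ in range(3)]
        b = [make_volume(np.ones((2, 2, 2)) * 2) for _ in range(3)]
        t, _, flags = voxelwise_welch_t(a, b, np.ones((2, 2, 2), bool))
        assert flags.all()
        assert np.allclose(t, 0.0)

    def test_too_small_groups_rejected(self, rng):
        vols = [make_volume(rng.random((3, 3, 3))) for _ in range(2)]
        with pytest.raises(ValueError):
            voxelwise_welch_t(vols[:1], vols, np.ones((3, 3, 3), bool))


def effect_cohort(rng, n_a=5, n_b=5, shape=(16, 16, 16), shift=0.0, block=None):
    a = [make_volume(rng.normal(1.0, 0.1, shape)) for _ in range(n_a)]
    b = [make_volume(rng.normal(1.0, 0.1, shape)) for _ in range(n_b)]
    if block is not None and shift:
        sl = tuple(slice(*b_) for b_ in block)
        for v in a:
            v.data[sl] += shift
    return a, b


class TestClusterExtentInference:
    def test_true_effect_detected_and_overlapping(self, rng):
        a, b = effect_cohort(rng, 6, 6, shift=1.0, block=((2, 10), (2, 10), (2, 10)))
        mask = np.ones((16, 16, 16), bool)
        res = cluster_extent_inference(a, b, mask, k_min=100, n_permutations=400, seed=1)
        assert len(res.clusters) == 1
        cl = res.clusters[0]
        assert cl.size > 100 and cl.corrected_p < 0.05
        true_block = np.zeros((16, 16, 16), bool)
        true_block[2:10, 2:10, 2:10] = True
        overlap = (cl.voxels & true_block).sum() / true_block.sum()
        assert overlap > 0.8

    def test_small_effect_excluded_by_extent_rule(self, rng):
        a, b = effect_cohort(rng, 6, 6, shift=1.5, block=((2, 6), (2, 6), (2, 5)))  # 48 voxels
        mask = np.ones((16, 16, 16), bool)
        res = cluster_extent_inference(a, b, mask, k_min=100, n_permutations=400, seed=1)
        assert not res.clusters
        res2 = cluster_extent_inference(a, b, mask, k_min=10, n_permutations=400, seed=1)
        assert len(res2.clusters) >= 1

    def test_cluster_count_monotone_in_k_min(self, rng):
        a, b = effect_cohort(rng, 6, 6, shift=0.8, block=((1, 12), (1, 12), (1, 12)))
        mask = np.ones((16, 16, 16), bool)
        counts = [
            len(cluster_extent_inference(a, b, mask, k_min=k, n_permutations=400, seed=2).clusters)
            for k in (1, 100, 2000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_exhaustive_enumeration_is_deterministic(self, rng):
        a, b = effect_cohort(rng, 4, 4, shift=1.0, block=((2, 10), (2, 10), (2, 10)))
        mask = np.ones((16, 16, 16), bool)
        # C(8,4) = 70 distinct relabelings < n_permutations -> full enumeration
        r1 = cluster_extent_inference(a, b, mask, k_min=50, n_permutations=200, seed=1)
        r2 = cluster_extent_inference(a, b, mask, k_min=50, n_permutations=200, seed=999)
        assert r1.exhaustive and r2.exhaustive
        assert r1.n_permutations == 70
        assert np.array_equal(np.sort(r1.max_size_null), np.sort(r2.max_size_null))
        assert [c.corrected_p for c in r1.clusters] == [c.corrected_p for c in r2.clusters]

    def test_reported_clusters_respect_invariants(self, rng):
        a, b = effect_cohort(rng, 6, 6, shift=0.9, block=((2, 12), (2, 12), (2, 12)))
        mask = np.ones((16, 16, 16), bool)
        res = cluster_extent_inference(a, b, mask, k_min=20, n_permutations=400, seed=3)
        seen = np.zeros((16, 16, 16), bool)
        for cl in res.clusters:
            assert cl.size > 20 and cl.corrected_p < 0.05
            assert not (seen & cl.voxels).any()  # disjoint
            seen |= cl.voxels

    def test_too_few_permutations_rejected(self, rng):
        a, b = effect_cohort(rng, 4, 4)
        with pytest.raises(ValueError):
            cluster_extent_inference(a, b, np.ones((16, 16, 16), bool), n_permutations=50)


class TestSummarizeCluster:
    def test_constant_subjects_give_zero_delta(self):
        vols = {f"p{i}": make_volume(np.ones((4, 4, 4))) for i in range(6)}
        groups = {p: ("A" if i < 3 else "B") for i, p in enumerate(vols)}
        cluster = np.zeros((4, 4, 4), bool)
        cluster[:2] = True
        out = summarize_cluster(cluster, vols, groups)
        row = out.iloc[0]
        assert row["median_A"] == 1.0 and row["iqr_A"] == 0.0
        assert row["delta"] == 0.0

    def test_separated_groups_give_full_delta(self, rng):
        vols = {}
        groups = {}
        for i in range(4):
            vols[f"a{i}"] = make_volume(np.full((4, 4, 4), 1.3 + 0.01 * i))
            groups[f"a{i}"] = "A"
            vols[f"b{i}"] = make_volume(np.full((4, 4, 4), 0.9 + 0.01 * i))
            groups[f"b{i}"] = "B"
        cluster = np.ones((4, 4, 4), bool)
        out = summarize_cluster(cluster, vols, groups)
        assert out.iloc[0]["delta"] == pytest.approx(1.0)
        assert out.iloc[0]["magnitude"] == "large"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            summarize_cluster(np.zeros((2, 2, 2), bool), {}, {})
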