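from dataclasses import replace
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mirmorph.synthetic import SyntheticConfig, default_config, generate
from mirmorph.validation import (
    PercentileNormalizer,
    compare_groups,
    cross_dataset_report,
    percentile_normalize,
)
from conftest import make_matrix


def rank_oracle(flat):
    """Exhaustive midrank percentile: count comparisons cell by cell."""
    flat = np.asarray(flat, dtype=float)
    n = flat.size
    out = np.empty(n)
    for i, v in enumerate(flat):
        less = np.sum(flat < v)
        equal = np.sum(flat == v)
        out[i] = (less + (equal + 1) / 2 - 0.5) / n
    return out


class TestPercentileNormalize:
    def test_two_by_two_example(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        p = percentile_normalize(m)
        np.testing.assert_allclose(
            p.data.to_numpy(), [[0.125, 0.375], [0.625, 0.875]]
        )
        np.testing.assert_allclose(
            p.data.to_numpy().ravel(), rank_oracle([1, 2, 3, 4])
        )

    def test_all_equal_cells_are_half(self):
        p = percentile_normalize(make_matrix(np.full((3, 4), 7.0)))
        np.testing.assert_array_equal(p.data.to_numpy(), 0.5)

    def test_exhaustive_oracle_on_all_small_distinct_matrices(self):
        """Midrank percentiles match cell-by-cell rank enumeration for every
        arrangement of distinct values in every shape up to 3x3."""
        rng = np.random.default_rng(0)
        for r in (1, 2, 3):
            for c in (1, 2, 3):
                n = r * c
                if n <= 5:
                    arrangements = [np.array(p, dtype=float)
                                    for p in permutations(range(n))]
                else:
                    arrangements = [rng.permutation(n).astype(float)
                                    for _ in range(60)]
                for flat in arrangements:
                    m = make_matrix(flat.reshape(r, c))
                    got = percentile_normalize(m).data.to_numpy().ravel()
                    np.testing.assert_allclose(got, rank_oracle(flat), atol=1e-12)

    def test_strictly_increasing_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 8))
        base = percentile_normalize(make_matrix(vals)).data
        for f in (lambda x: 3 * x + 10, np.exp, lambda x: x**3):
            same = percentile_normalize(make_matrix(f(vals))).data
            np.testing.assert_allclose(same.to_numpy(), base.to_numpy(), atol=1e-12)

    def test_per_feature_pooling_ranks_within_rows(self):
        m = make_matrix([[1.0, 2.0, 3.0], [30.0, 10.0, 20.0]])
        p = percentile_normalize(m, pool="per_feature")
        expected = (np.array([[1, 2, 3], [3, 1, 2]]) - 0.5) / 3
        np.testing.assert_allclose(p.data.to_numpy(), expected)

    @given(
        st.integers(1, 6),
        st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    def test_range_mean_and_monotonicity_invariants(self, r, c, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(r, c))
        p = percentile_normalize(make_matrix(vals)).data.to_numpy()
        assert ((p > 0) & (p < 1)).all()
        assert p.mean() == pytest.approx(0.5, abs=1e-12)  # no ties
        flat_v, flat_p = vals.ravel(), p.ravel()
        order = np.argsort(flat_v)
        assert (np.diff(flat_p[order]) >= 0).all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(Exception, match="empty"):
            PercentileNormalizer().fit_transform(np.empty((0, 0)))

    def test_sklearn_transformer_interface(self):
        norm = PercentileNormalizer(pool="per_feature")
        assert norm.get_params() == {"pool": "per_feature"}
        out = norm.fit_transform(np.array([[3.0, 1.0, 2.0]]))
        np.testing.assert_allclose(out, [[5 / 6, 1 / 6, 3 / 6]])
        with pytest.raises(ValueError, match="pool"):
            PercentileNormalizer(pool="bogus").fit()


class TestCompareGroups:
    def test_identical_group_distributions_are_null(self):
        # both groups observe the exact same value multiset {1, 2, 3}
        m = make_matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        p = percentile_normalize(m)
        out = compare_groups(p, ["x", "x", "x", "y", "y", "y"], ["miR-000"])
        assert out[0].direction == "none"
        assert out[0].p == pytest.approx(1.0)

    def test_shifted_feature_is_significant_and_ranksum_agrees(self):
        rng = np.random.default_rng(7)
        n1, n2 = 48, 50
        base = rng.normal(0, 1, size=(6, n1 + n2))
        base[2, n1:] += 2.0  # +2 pooled sd shift
        m = make_matrix(base)
        p = percentile_normalize(m)
        labels = ["PGL"] * n1 + ["PANNET"] * n2
        anova = compare_groups(p, labels, ["miR-002"], test="anova")[0]
        ranksum = compare_groups(p, labels, ["miR-002"], test="ranksum")[0]
        assert anova.p < 0.01
        assert ranksum.p < 0.01  # rank-sum oracle agrees at alpha = 0.01
        assert anova.direction == ranksum.direction == "PANNET"
        u, p_mwu = stats.mannwhitneyu(
            p.data.loc["miR-002"].to_numpy()[:n1],
            p.data.loc["miR-002"].to_numpy()[n1:],
            alternative="two-sided",
        )
        assert ranksum.p == pytest.approx(p_mwu, abs=1e-12)

    def test_missing_feature_reported_not_fatal(self):
        p = percentile_normalize(make_matrix(np.random.default_rng(0).normal(size=(2, 6))))
        out = compare_groups(p, ["a"] * 3 + ["b"] * 3, ["nope", "miR-000"])
        assert out[0].missing and not out[1].missing


def gse_style_pair(seed=0):
    """Two single-cohort datasets emulating the validation series:
    48 PGL-only and 50 PANNET-only bundles with the marker profiles planted."""
    pgl = generate(
        SyntheticConfig(n_a=0, n_b=48, n_features=294, seed=seed, nonprimary={})
    )
    pannet = generate(
        SyntheticConfig(n_a=50, n_b=0, n_features=294, seed=seed + 1, nonprimary={})
    )
    return [(pgl, "pgl_series"), (pannet, "pannet_series")]


class TestCrossDatasetReport:
    def test_duplicate_dataset_gives_identical_percentiles(self, primary_bundle):
        out = cross_dataset_report(
            [(primary_bundle, "d1"), (primary_bundle, "d2")],
            ["hsa-miR-141-3p"],
        )
        per = out[0].per_dataset
        assert per["d1"] == per["d2"]

    def test_constant_shift_of_one_dataset_changes_nothing(self):
        datasets = gse_style_pair(seed=3)
        shifted_bundle = datasets[0][0]
        shifted = replace(
            shifted_bundle,
            expression=make_matrix(
                shifted_bundle.expression.values + 100.0,
                feature_ids=shifted_bundle.expression.feature_ids,
                sample_ids=shifted_bundle.expression.sample_ids,
            ),
        )
        fids = ["hsa-miR-141-3p", "hsa-miR-10b-5p"]
        base = cross_dataset_report(datasets, fids)
        moved = cross_dataset_report(
            [(shifted, "pgl_series"), (datasets[1][0], "pannet_series")], fids
        )
        for b, mv in zip(base, moved):
            assert b.p == pytest.approx(mv.p, abs=1e-12)
            assert b.group_medians == mv.group_medians

    def test_marker_directions_match_discovery(self):
        """PANNET-elevated markers show higher percentiles in the PANNET-only
        series; both miR-10b strands are higher in the PGL-only series."""
        out = cross_dataset_report(
            gse_style_pair(seed=5),
            [p.feature_id for p in default_config().planted],
        )
        by_id = {c.feature_id: c for c in out}
        for fid in ("hsa-miR-141-3p", "hsa-miR-200c-3p", "hsa-miR-192-5p",
                    "hsa-miR-194-5p"):
            assert by_id[fid].direction == "PANNET"
            assert by_id[fid].p < 0.01
        for fid in ("hsa-miR-10b-5p", "hsa-miR-10b-3p"):
            assert by_id[fid].direction == "PGL"
            assert by_id[fid].p < 0.01

    def test_mir141_elevated_in_pannet_within_each_dataset(self, primary_bundle):
        """With the marker profile planted in two mixed-cohort datasets, the
        PANNET group median percentile is higher in both."""
        d1 = primary_bundle
        d2 = generate(replace(default_config(seed=31), nonprimary={}))
        out = cross_dataset_report([(d1, "d1"), (d2, "d2")], ["hsa-miR-141-3p"])
        for did in ("d1", "d2"):
            med = out[0].per_dataset[did]
            assert med["PANNET"] > med["PGL"]

    def test_needs_two_datasets(self, primary_bundle):
        with pytest.raises(ValueError, match=">= 2"):
            cross_dataset_report([(primary_bundle, "d1")], ["hsa-miR-141-3p"])
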