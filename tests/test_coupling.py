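"""Rank-sorted sliding window and the PAGE gene-set statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import oracles
from chromcouple import (
    SimParams,
    coupling_report,
    page_statistic,
    rank_sliding_window,
    simulate_dataset,
)


def _series(values, prefix="g"):
    return pd.Series(
        values,
        index=pd.Index([f"{prefix}{i}" for i in range(len(values))],
                       name="gene_id"),
        dtype=float,
    )


class TestRankSlidingWindow:
    def test_constant_expression_gives_constant_curve(self):
        series = rank_sliding_window(
            _series(np.arange(10)), _series(np.full(10, 2.5)), window_size=4
        )
        assert np.allclose(series.window_means, 2.5)

    def test_window_equal_to_n_gives_global_mean(self):
        expr = _series([1.0, 2.0, 6.0])
        series = rank_sliding_window(_series([3, 1, 2]), expr, window_size=3)
        assert series.window_means.tolist() == [3.0]

    def test_five_genes_window_three(self):
        # after sorting by k27, expression reads 1..5 -> means 2, 3, 4
        k27 = _series([0.5, 0.1, 0.3, 0.2, 0.4])
        expr = _series([5.0, 1.0, 3.0, 2.0, 4.0])
        series = rank_sliding_window(k27, expr, window_size=3)
        assert series.window_means.tolist() == [2.0, 3.0, 4.0]
        assert list(series.gene_order) == ["g1", "g3", "g2", "g4", "g0"]

    def test_ties_broken_by_input_order(self):
        k27 = _series([0.0, 0.0, 0.0])
        series = rank_sliding_window(k27, _series([1.0, 2.0, 3.0]), window_size=2)
        assert list(series.gene_order) == ["g0", "g1", "g2"]

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="smaller window"):
            rank_sliding_window(_series([1.0]), _series([1.0]), window_size=2)

    @settings(deadline=None, max_examples=30)
    @given(
        n=hst.integers(5, 60),
        window=hst.integers(2, 10),
        step=hst.integers(1, 4),
        seed=hst.integers(0, 1000),
    )
    def test_matches_brute_force_exactly(self, n, window, step, seed):
        if window > n:
            window = n
        rng = np.random.default_rng(seed)
        k27 = rng.normal(size=n).round(2)  # rounding forces ties
        expr = rng.normal(size=n)
        series = rank_sliding_window(
            _series(k27), _series(expr), window_size=window, step=step
        )
        expected = oracles.sliding_window_means(list(k27), list(expr), window, step)
        # same numbers up to summation order of the two implementations
        np.testing.assert_allclose(series.window_means, expected, rtol=1e-12)


class TestPageStatistic:
    def test_set_mean_equal_to_parent_mean_gives_z_zero(self):
        parent = _series([1.0, 2.0, 3.0, 4.0])
        result = page_statistic(parent, ["g0", "g3"])  # mean 2.5 == parent mean
        assert result.z == 0.0
        assert result.p == 1.0

    def test_z_and_p_match_independent_formula(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=120)
        members = [f"g{i}" for i in rng.choice(120, size=25, replace=False)]
        result = page_statistic(_series(values), members)
        flags = [f"g{i}" in set(members) for i in range(120)]
        z_ref, p_ref = oracles.page_z_and_p(list(values), flags)
        assert result.z == pytest.approx(z_ref, rel=1e-12)
        assert result.p == pytest.approx(p_ref, rel=1e-9)

    def test_two_sided_p_at_z_one(self):
        # hand-built parent: mean 2, sample sd exactly 2, and a 4-gene set
        # with mean 3, so z = (3 - 2) * sqrt(4) / 2 = 1 exactly
        s5 = np.sqrt(5.0)
        parent = _series([3.0, 3.0, 3.0, 3.0, 1 + s5, 1 - s5, 1 + s5, 1 - s5])
        result = page_statistic(parent, ["g0", "g1", "g2", "g3"])
        assert result.z == pytest.approx(1.0, rel=1e-12)
        assert result.p == pytest.approx(0.31731, abs=1e-5)

    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_one_sided_tails(self, alternative):
        parent = _series(np.arange(50, dtype=float))
        high = [f"g{i}" for i in range(45, 50)]
        result = page_statistic(parent, high, alternative=alternative)
        assert result.z > 0
        assert (result.p < 0.05) == (alternative == "greater")

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            page_statistic(_series([1.0, 2.0]), [])

    def test_zero_parent_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            page_statistic(_series([3.0, 3.0, 3.0]), ["g0"])

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            page_statistic(_series([1.0, 2.0]), ["nope"])

    @settings(deadline=None, max_examples=25)
    @given(
        seed=hst.integers(0, 500),
        shift=hst.floats(-5, 5),
        scale=hst.floats(0.1, 10),
    )
    def test_affine_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=40)
        members = [f"g{i}" for i in range(8)]
        a = page_statistic(_series(values), members)
        b = page_statistic(_series(values * scale + shift), members)
        assert b.z == pytest.approx(a.z, rel=1e-9, abs=1e-9)

    def test_agrees_with_permutation_null(self):
        """Analytic p matches the empirical random-set p at moderate |z|."""
        rng = np.random.default_rng(21)
        n = 2000
        values = rng.normal(size=n)
        parent = _series(values)
        m = 40
        # pick a set with |z| around 1.5
        members = None
        for _ in range(200):
            cand = rng.choice(n, size=m, replace=False)
            z = (values[cand].mean() - values.mean()) * np.sqrt(m) / values.std(ddof=1)
            if 1.2 < abs(z) < 1.8:
                members = cand
                break
        assert members is not None
        result = page_statistic(parent, [f"g{i}" for i in members])
        n_perm = 20_000
        null_means = np.array([
            values[rng.choice(n, size=m, replace=False)].mean()
            for _ in range(n_perm)
        ])
        observed = values[members].mean()
        mu = values.mean()
        p_emp = float(np.mean(np.abs(null_means - mu) >= abs(observed - mu)))
        se = np.sqrt(p_emp * (1 - p_emp) / n_perm)
        assert result.p == pytest.approx(p_emp, abs=4 * se + 0.01)


class TestCouplingReport:
    def test_null_coupling_gives_modest_z(self):
        bundle = simulate_dataset(SimParams(seed=42, coupling_delta=0.0))
        calls, de = _calls_and_de(bundle)
        report = coupling_report(calls, de, window_size=100)
        assert abs(report.page_demethylated_set.z) < 4

    def test_planted_coupling_gives_positive_z(self, bundle, analysis):
        report = coupling_report(
            analysis["calls"], analysis["de"], window_size=100
        )
        assert report.page_demethylated_set.z > 4
        # reciprocal framing: upregulated genes sit at negative k27 log2FC
        assert report.page_upregulated_set.z < 0

    def test_median_z_monotone_in_planted_effect(self):
        """A stronger planted shift never lowers the median recovered z."""
        medians = []
        for delta in (0.0, 0.5, 1.0):
            zs = []
            for seed in range(5):
                b = simulate_dataset(
                    SimParams(seed=100 + seed, coupling_delta=delta)
                )
                calls, de = _calls_and_de(b)
                zs.append(
                    coupling_report(calls, de, window_size=100)
                    .page_demethylated_set.z
                )
            medians.append(float(np.median(zs)))
        assert medians[0] <= medians[1] <= medians[2]


def _calls_and_de(bundle):
    from chromcouple import (
        differential_genes,
        make_calls,
        normalize_library,
        promoter_signal_table,
    )

    normalized = {k: normalize_library(t) for k, t in bundle.tracks.items()}
    signal = promoter_signal_table(normalized, bundle.genes)
    calls = make_calls(
        signal["H3K4me3_minus_dox"],
        signal["H3K27me3_minus_dox"],
        signal["H3K27me3_plus_dox"],
    )
    de = differential_genes(bundle.expression, "minus_dox", "plus_dox")
    return calls, de
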