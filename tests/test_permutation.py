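"""Label reshuffling, per-edge nulls, empirical p-values, two-criterion filter."""

import numpy as np
import pandas as pd
import pytest

import netdiffcor as nd
from netdiffcor.permutation import (
    NullDistributions,
    PermutationConfig,
    build_null,
    empirical_p,
    permute_labels,
    significant_interactions,
)


class TestPermuteLabels:
    def test_group_sizes_preserved(self):
        rng = np.random.default_rng(0)
        g1, g2 = permute_labels([f"s{i}" for i in range(10)], (5, 5), rng)
        assert len(g1) == 5 and len(g2) == 5
        assert sorted(g1 + g2) == sorted(f"s{i}" for i in range(10))

    def test_same_seed_same_assignment(self):
        ids = [f"s{i}" for i in range(10)]
        a = permute_labels(ids, (5, 5), np.random.default_rng(7))
        b = permute_labels(ids, (5, 5), np.random.default_rng(7))
        assert a == b

    def test_assignments_uniform_over_many_draws(self):
        # each sample lands in group 1 with frequency 1/2 +/- binomial error
        ids = [f"s{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        hits = np.zeros(10)
        n = 10_000
        for _ in range(n):
            g1, _ = permute_labels(ids, (5, 5), rng)
            for s in g1:
                hits[ids.index(s)] += 1
        assert np.all(np.abs(hits / n - 0.5) < 0.02)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            permute_labels(["a", "b", "c"], (2, 2), np.random.default_rng(0))


class TestBuildNull:
    def test_exactly_n_perm_values_per_edge(self, null_dataset):
        cfg = PermutationConfig(n_perm=7, seed=0)
        null = build_null(null_dataset["em"], null_dataset["cm"], null_dataset["trimmed"], cfg)
        assert null.z_diff.shape == (null_dataset["trimmed"].n_edges, 7)
        assert null.r_first.shape == null.z_diff.shape
        assert null.r_second.shape == null.z_diff.shape

    def test_same_seed_bit_identical(self, null_dataset):
        args = (null_dataset["em"], null_dataset["cm"], null_dataset["trimmed"])
        n1 = build_null(*args, PermutationConfig(n_perm=50, seed=3))
        n2 = build_null(*args, PermutationConfig(n_perm=50, seed=3))
        assert np.array_equal(n1.z_diff, n2.z_diff)
        assert np.array_equal(n1.r_first, n2.r_first)

    def test_worker_count_does_not_change_results(self, null_dataset):
        args = (null_dataset["em"], null_dataset["cm"], null_dataset["trimmed"])
        serial = build_null(*args, PermutationConfig(n_perm=40, seed=5, n_workers=1))
        threaded = build_null(*args, PermutationConfig(n_perm=40, seed=5, n_workers=4))
        assert np.array_equal(serial.z_diff, threaded.z_diff)
        assert np.array_equal(serial.r_second, threaded.r_second)

    def test_null_zdiff_centered_under_exchangeability(self, null_dataset):
        cfg = PermutationConfig(n_perm=200, seed=1)
        null = build_null(null_dataset["em"], null_dataset["cm"], null_dataset["trimmed"], cfg)
        z = null.z_diff[np.isfinite(null.z_diff)]
        assert abs(z.mean()) < 3 * z.std() / np.sqrt(z.size)


class TestEmpiricalP:
    def test_direct_count(self):
        assert empirical_p(2.0, [0.5, 1.0, 1.5, 2.5]) == pytest.approx(0.25)

    def test_boundary_observed_beats_all(self):
        null = list(np.linspace(0.1, 1.0, 10))
        assert empirical_p(5.0, null, "count_over_N") == 0.0
        assert empirical_p(5.0, null, "add_one") == pytest.approx(1 / 11)

    def test_tie_counts(self):
        null = list(np.linspace(0.1, 1.0, 10))
        assert empirical_p(1.0, null, "count_over_N") == pytest.approx(0.1)

    def test_monotone_in_observed(self):
        rng = np.random.default_rng(0)
        null = rng.standard_normal(500)
        ps = [empirical_p(o, null) for o in np.linspace(0, 4, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [])


def fabricated_case(p_zdiff, p_r, n_perm=100):
    """One-edge statistics + null arrays engineered to produce the given
    empirical p-values under count_over_N (both group correlations share the
    pooled null, so they get the same p here)."""
    stats = pd.DataFrame(
        {
            "gene_a": ["a"],
            "gene_b": ["b"],
            "r_LA": [0.5],
            "r_HA": [0.5],
            "z_LA": [0.55],
            "z_HA": [0.55],
            "z_diff": [1.0],
            "valid": [True],
        }
    )
    # observed |z_diff| = 1: put exactly p_zdiff*n null values above it
    k = int(round(p_zdiff * n_perm))
    z_null = np.concatenate([np.full(k, 2.0), np.full(n_perm - k, 0.5)])
    # observed |r| = 0.5 against the 2n pooled permuted correlations
    k_r = int(round(p_r * 2 * n_perm))
    pool = np.full(2 * n_perm, 0.1)
    pool[:k_r] = 0.9
    null = NullDistributions(
        edges=[("a", "b")],
        z_diff=z_null[None, :],
        r_first=pool[None, :n_perm],
        r_second=pool[None, n_perm:],
        group_order=("LA", "HA"),
    )
    return stats, null


class TestSignificantInteractions:
    @pytest.mark.parametrize(
        "p_zdiff,p_r,expect",
        [
            (0.01, 0.01, True),   # both criteria met (one correlation enough)
            (0.20, 0.001, False), # z-difference not significant
            (0.01, 0.80, False),  # no significant correlation
        ],
    )
    def test_two_criterion_filter(self, p_zdiff, p_r, expect):
        stats, null = fabricated_case(p_zdiff, p_r)
        out = significant_interactions(stats, null, PermutationConfig(n_perm=100, seed=0))
        assert out.loc[0, "p_zdiff"] == pytest.approx(p_zdiff)
        assert bool(out.loc[0, "significant"]) is expect

    def test_flag_matches_definition_on_simulated_data(self, planted_dataset):
        d = planted_dataset
        cfg = PermutationConfig(n_perm=200, seed=0)
        stats = nd.edge_statistics(d["em"], d["cm"], d["trimmed"])
        null = build_null(d["em"], d["cm"], d["trimmed"], cfg)
        out = significant_interactions(stats, null, cfg)
        expected = (
            out["valid"]
            & (out["p_zdiff"] < cfg.alpha)
            & ((out["p_r_LA"] < cfg.alpha) | (out["p_r_HA"] < cfg.alpha))
        )
        assert (out["significant"] == expected).all()
        assert out["significant"].sum() >= 5  # planted edges detected

    def test_swapping_group_labels_keeps_significant_set(self, planted_dataset):
        d = planted_dataset
        cfg = PermutationConfig(n_perm=200, seed=0)

        def run(cm):
            em = nd.normalize_log_cpm(cm)
            stats = nd.edge_statistics(em, cm, d["trimmed"])
            null = build_null(em, cm, d["trimmed"], cfg)
            out = significant_interactions(stats, null, cfg)
            return set(
                map(tuple, out.loc[out["significant"], ["gene_a", "gene_b"]].to_numpy())
            )

        cm = d["cm"]
        swapped = nd.CountMatrix(
            counts=cm.counts, groups=cm.groups.map({"LA": "HA", "HA": "LA"})
        )
        assert run(cm) == run(swapped)

    def test_coverage_mismatch_rejected(self, null_dataset):
        d = null_dataset
        cfg = PermutationConfig(n_perm=10, seed=0)
        stats = nd.edge_statistics(d["em"], d["cm"], d["trimmed"])
        null = build_null(d["em"], d["cm"], d["trimmed"], cfg)
        with pytest.raises(ValueError, match="different edges"):
            significant_interactions(stats.iloc[1:].reset_index(drop=True), null, cfg)

    def test_null_calibration_at_alpha(self, null_dataset):
        # under a global null the fraction of edges with p_zdiff < alpha
        # should sit near alpha
        d = null_dataset
        cfg = PermutationConfig(n_perm=500, seed=0)
        stats = nd.edge_statistics(d["em"], d["cm"], d["trimmed"])
        null = build_null(d["em"], d["cm"], d["trimmed"], cfg)
        out = significant_interactions(stats, null, cfg)
        frac = (out.loc[out["valid"], "p_zdiff"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10
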