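"""Permutation null, empirical p-values and Benjamini-Hochberg FDR."""

from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trmshift import (
    PermutationConfig,
    ValidationError,
    bh_fdr,
    build_tables,
    empirical_p,
    odds_ratio_from_counts,
    permute_null,
    run_abundance_test,
    sample_labels,
)
from trmshift.simulate import SubsetProfile, GeneratorConfig


def enumerate_log_ors(subsets, groups, focal):
    """Exhaustive oracle: log OR of `focal` under every relabeling with the
    original group totals, +0.5 on all cells when any count is zero."""
    n = len(subsets)
    n_tg = sum(g == "TG" for g in groups)
    out = []
    for tg_cells in combinations(range(n), n_tg):
        tg = set(tg_cells)
        a = sum(1 for i in range(n) if i not in tg and subsets[i] == focal)
        b = sum(1 for i in range(n) if i not in tg and subsets[i] != focal)
        c = sum(1 for i in range(n) if i in tg and subsets[i] == focal)
        d = sum(1 for i in range(n) if i in tg and subsets[i] != focal)
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        out.append(log((c / d) / (a / b)))
    return np.array(out)


class TestPermuteNull:
    def test_single_subset_stratum_yields_unit_or(self):
        cells = pd.DataFrame(
            {
                "cell_id": [str(i) for i in range(8)],
                "group": ["WT"] * 4 + ["TG"] * 4,
                "compartment": "brain",
                "subset": "A",
            }
        )
        null = permute_null(cells, "brain", PermutationConfig(n_perm=50, seed=0))
        # every cell is focal: (a, 0, c, 0) is always corrected, and the
        # corrected table is identical across shuffles
        expected = log((4.5 / 0.5) / (4.5 / 0.5))
        assert np.allclose(null["A"], expected, atol=1e-9)

    def test_sampled_shuffles_match_exhaustive_frequencies(self, toy_cells):
        """20,000 sampled shuffles of the 6-cell stratum hit each of the
        C(6,3)=20 relabeling outcomes at its enumeration frequency."""
        exact = enumerate_log_ors(
            toy_cells["subset"].tolist(), toy_cells["group"].tolist(), "A"
        )
        assert exact.size == comb(6, 3) == 20
        sampled = permute_null(
            toy_cells, "brain", PermutationConfig(n_perm=20_000, seed=4)
        )["A"]
        values, exact_counts = np.unique(np.round(exact, 12), return_counts=True)
        for v, k in zip(values, exact_counts):
            p = k / exact.size
            obs = np.mean(np.abs(sampled - v) < 1e-9)
            assert abs(obs - p) < 3 * np.sqrt(p * (1 - p) / 20_000)

    def test_exhaustive_mode_reproduces_enumeration(self, toy_cells):
        null = permute_null(
            toy_cells, "brain", PermutationConfig(n_perm=1, seed=0),
            exhaustive=True,
        )
        exact = enumerate_log_ors(
            toy_cells["subset"].tolist(), toy_cells["group"].tolist(), "A"
        )
        assert np.allclose(np.sort(null["A"]), np.sort(exact), atol=1e-12)

    def test_identical_seeds_identical_nulls(self, toy_cells):
        cfg = PermutationConfig(n_perm=500, seed=99)
        a = permute_null(toy_cells, "brain", cfg)
        b = permute_null(toy_cells, "brain", cfg)
        for subset in a:
            assert np.array_equal(a[subset], b[subset])

    def test_shared_shuffle_across_subsets(self, toy_cells):
        # two-subset composition: B's counts are the complement of A's, so
        # the permuted log ORs must be exactly opposite in every iteration
        null = permute_null(toy_cells, "brain", PermutationConfig(n_perm=200, seed=1))
        assert np.allclose(null["A"], -null["B"], atol=1e-12)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValidationError):
            PermutationConfig(n_perm=0)


class TestEmpiricalP:
    def test_null_centred_observation_gives_p_one(self, rng):
        null = rng.normal(size=100)
        assert empirical_p(0.0, null) == 1.0

    def test_direct_count(self):
        assert empirical_p(0.25, np.array([0.1, -0.2, 0.3, -0.4])) == 0.5

    def test_matches_exhaustive_oracle_on_toy(self, toy_cells):
        exact_null = enumerate_log_ors(
            toy_cells["subset"].tolist(), toy_cells["group"].tolist(), "A"
        )
        obs = odds_ratio_from_counts(build_tables(toy_cells, "brain")["A"]).log_or
        exact_p = np.mean(np.abs(exact_null) >= abs(obs))
        null = permute_null(
            toy_cells, "brain", PermutationConfig(n_perm=1, seed=0),
            exhaustive=True,
        )["A"]
        assert empirical_p(obs, null) == pytest.approx(exact_p, abs=1e-12)

    @given(st.floats(0, 3), st.floats(0, 3))
    def test_p_non_increasing_in_observed_deviation(self, o1, o2):
        null = np.linspace(-2, 2, 101)
        lo, hi = sorted([o1, o2])
        assert empirical_p(hi, null) <= empirical_p(lo, null)

    def test_non_finite_null_rejected(self):
        with pytest.raises(ValidationError):
            empirical_p(0.5, np.array([0.1, np.inf]))


def brute_force_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        q[i] = best
    return np.array(q)


class TestBhFdr:
    def test_single_p_passes_through(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.array_equal(bh_fdr(p), brute_force_bh(p))

    def test_matches_scipy_reference(self, rng):
        from scipy.stats import false_discovery_control

        for _ in range(50):
            p = rng.uniform(size=20)
            assert bh_fdr(p) == pytest.approx(false_discovery_control(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestRunAbundanceTest:
    def test_report_shape_granularity_and_invariants(self, small_cells):
        cfg = PermutationConfig(n_perm=199, seed=5)
        report = run_abundance_test(small_cells, cfg)
        assert set(report.table["compartment"]) == {"brain", "meninges", "all"}
        # p values live on the k/n_perm grid
        k = report.table["p_emp"] * cfg.n_perm
        assert np.allclose(k, np.round(k), atol=1e-9)
        assert (report.table["q_fdr"] >= report.table["p_emp"] - 1e-12).all()
        assert (report.table["ci_low"] <= report.table["odds_ratio"]).all()
        assert (report.table["odds_ratio"] <= report.table["ci_high"]).all()
        sorted_idx = report.table.sort_values(["compartment", "subset"]).index
        assert list(sorted_idx) == list(report.table.index)
        assert report.n_perm == 199 and report.seed == 5

    def test_single_permutation_gives_binary_p(self, small_cells):
        report = run_abundance_test(small_cells, PermutationConfig(n_perm=1, seed=2))
        assert set(report.table["p_emp"]) <= {0.0, 1.0}

    def test_deterministic_given_seed(self, small_cells):
        cfg = PermutationConfig(n_perm=100, seed=8)
        a = run_abundance_test(small_cells, cfg)
        b = run_abundance_test(small_cells, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        pd.testing.assert_frame_equal(a.null_summary, b.null_summary)

    def test_fewer_than_two_subsets_rejected(self):
        cells = pd.DataFrame(
            {
                "cell_id": [str(i) for i in range(10)],
                "group": ["WT"] * 5 + ["TG"] * 5,
                "compartment": "brain",
                "subset": "A",
            }
        )
        with pytest.raises(ValidationError, match="2 subsets"):
            run_abundance_test(cells, PermutationConfig(n_perm=10))

    def test_global_fdr_family_single_correction(self, small_cells):
        rep = run_abundance_test(
            small_cells,
            PermutationConfig(n_perm=99, seed=3, fdr_family="global"),
        )
        assert rep.table["q_fdr"].to_numpy() == pytest.approx(
            bh_fdr(rep.table["p_emp"].to_numpy())
        )


def test_null_rejection_rate_controlled(rng):
    """Under an equal-composition null the permutation p rejects at about
    its nominal level (300 replicates, 400 cells/group, n_perm 200)."""
    strata = {("WT", "brain"): 400, ("TG", "brain"): 400}
    profiles = [
        SubsetProfile(f"S{i}", {k: 0.2 for k in strata}) for i in range(5)
    ]
    rejections = 0
    trials = 0
    for rep in range(300):
        cfg = GeneratorConfig(n_cells_per_stratum=strata, seed=int(rng.integers(2**31)))
        cells = sample_labels(profiles, cfg)
        null = permute_null(
            cells, "brain", PermutationConfig(n_perm=200, seed=int(rng.integers(2**31)))
        )
        tables = build_tables(cells, "brain")
        for subset, t in tables.items():
            p = empirical_p(odds_ratio_from_counts(t).log_or, null[subset])
            rejections += p < 0.05
            trials += 1
    # pooled over 5 subsets x 300 replicates; 3-sigma band around 0.05
    rate = rejections / trials
    assert 0.03 <= rate <= 0.07
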