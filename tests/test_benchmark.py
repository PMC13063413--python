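import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kbench
from kbench import (
    InsufficientDataError,
    InsufficientOverlapError,
    UsageError,
)

from conftest import logk_dict_to_matrix, make_matrix, random_gappy_logk
from oracles import brute_force_rem


class TestChemicalStddev:
    def test_unit_spaced_symmetric_triple(self):
        assert kbench.chemical_stddev(np.array([-1.0, 0.0, 1.0])) == pytest.approx(1.0)

    def test_constant_row_is_zero(self):
        assert kbench.chemical_stddev(np.array([0.3] * 5)) == 0.0

    def test_four_point_sample_stddev(self):
        # direct N-1 evaluation: mean 0.45, ss 0.35, sqrt(0.35/3)
        got = kbench.chemical_stddev(np.array([0.1, 0.3, 0.5, 0.9]))
        assert got == pytest.approx(0.34157, abs=5e-6)

    def test_missing_values_ignored_and_min_n_enforced(self):
        row = np.array([0.0, np.nan, 1.0, np.nan, 2.0])
        assert kbench.chemical_stddev(row) == pytest.approx(1.0)
        with pytest.raises(InsufficientDataError):
            kbench.chemical_stddev(np.array([0.0, 1.0, np.nan]))


class TestBenchmarkResiduals:
    def test_parallel_profiles_give_zero_residuals(self, parallel_pair):
        br = kbench.benchmark_residuals(parallel_pair, "A", "B")
        assert br.n_gap_filled == 0 and br.n_sites == 4
        assert all(abs(r) < 1e-12 for r in br.residuals.values())

    def test_constant_benchmark_reduces_to_own_centered_residuals(self):
        m = make_matrix({"A": [0.0, 1.0, 2.0], "B": [0.5, 0.5, 0.5]})
        br = kbench.benchmark_residuals(m, "A", "B")
        assert [br.residuals[s] for s in ["s1", "s2", "s3"]] == pytest.approx(
            [-1.0, 0.0, 1.0]
        )

    def test_gap_rule_substitutes_raw_residual(self):
        m = make_matrix({"A": [0.0, 1.0, 2.0], "B": [0.0, 1.0, None]})
        br = kbench.benchmark_residuals(m, "A", "B")
        assert br.n_gap_filled == 1 and br.n_sites == 3
        assert [br.residuals[s] for s in ["s1", "s2", "s3"]] == pytest.approx(
            [0.0, 0.0, 1.0]
        )

    def test_benchmarked_residuals_are_mean_centered(self):
        rng = np.random.default_rng(3)
        m = make_matrix(
            {"A": list(rng.normal(0, 1, 8)), "B": list(rng.normal(0, 1, 8))}
        )
        br = kbench.benchmark_residuals(m, "A", "B")
        assert abs(sum(br.residuals.values())) < 1e-9

    def test_self_benchmark_rejected(self, parallel_pair):
        with pytest.raises(UsageError):
            kbench.benchmark_residuals(parallel_pair, "A", "A")

    def test_no_overlap_rejected(self):
        m = make_matrix({"A": [0.0, 1.0, 2.0, None], "B": [None, None, None, 0.5]})
        with pytest.raises(InsufficientOverlapError):
            kbench.benchmark_residuals(m, "A", "B")


class TestRem:
    def test_perfect_benchmark_removes_all_variability(self, parallel_pair):
        sb, sa, r = kbench.rem(parallel_pair, "A", "B")
        assert sa == 0.0
        assert r == sb

    def test_constant_benchmark_changes_nothing(self):
        m = make_matrix({"A": [0.0, 1.0, 2.0], "B": [0.5, 0.5, 0.5]})
        sb, sa, r = kbench.rem(m, "A", "B")
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_anticorrelated_benchmark_hurts(self):
        m = make_matrix({"A": [0.0, 1.0, 2.0], "B": [0.0, 1.0, 0.0]})
        sb, sa, r = kbench.rem(m, "A", "B")
        assert sb == pytest.approx(1.0)
        assert sa == pytest.approx(1.1547, abs=5e-5)
        assert r == pytest.approx(-0.1547, abs=5e-5)

    def test_rem_is_stddev_difference_identity(self):
        rng = np.random.default_rng(11)
        logk = random_gappy_logk(rng, 4, 6, p_missing=0.2)
        m = logk_dict_to_matrix(logk)
        for chem in ["C0", "C1"]:
            try:
                sb, sa, r = kbench.rem(m, chem, "C3")
            except InsufficientDataError:
                continue
            assert r == pytest.approx(sb - sa, abs=1e-12)
            assert r <= sb + 1e-12  # stddev_after >= 0

    @given(shift=st.floats(-3, 3), seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to a chemical's row changes no stddev and no REM."""
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, (2, 6))
        m1 = make_matrix({"A": list(base[0]), "B": list(base[1])})
        m2 = make_matrix({"A": list(base[0] + shift), "B": list(base[1])})
        r1 = kbench.rem(m1, "A", "B")
        r2 = kbench.rem(m2, "A", "B")
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_agrees_with_brute_force_on_gappy_data(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            logk = random_gappy_logk(rng, 3, 5)
            m = logk_dict_to_matrix(logk)
            try:
                got = kbench.rem(m, "C0", "C1")
            except InsufficientDataError:
                continue
            expected = brute_force_rem(logk, "C0", "C1")
            assert got == pytest.approx(expected, abs=1e-12)


class TestMedianRemAndSelection:
    def test_single_candidate_median_is_its_rem(self, parallel_pair):
        med = kbench.median_rem(parallel_pair, "B", ["A"])
        _, _, r = kbench.rem(parallel_pair, "A", "B")
        assert med == pytest.approx(r)

    def test_even_count_midpoint_median(self):
        m = make_matrix(
            {
                "BM": [0.0, 1.0, 2.0, 3.0],
                "X": [0.0, 1.0, 2.0, 3.0],  # REM = stddev of X
                "Y": [3.0, 1.0, 0.0, 2.0],
            }
        )
        rx = kbench.rem(m, "X", "BM")[2]
        ry = kbench.rem(m, "Y", "BM")[2]
        med = kbench.median_rem(m, "BM", ["X", "Y"])
        assert med == pytest.approx((rx + ry) / 2)

    def test_candidates_with_insufficient_overlap_skipped(self):
        m = make_matrix(
            {
                "BM": [0.0, 1.0, 2.0, None],
                "X": [0.1, 1.1, 2.1, None],
                "Z": [None, None, None, 5.0],
            }
        )
        med = kbench.median_rem(m, "BM", ["X", "Z"])
        assert med == pytest.approx(kbench.rem(m, "X", "BM")[2])

    def test_symmetric_parallel_tie_broken_lexicographically(self, parallel_pair):
        winner, scores = kbench.select_benchmark(parallel_pair, ["A", "B"])
        assert winner == "A"
        assert scores["A"] == pytest.approx(scores["B"])

    def test_parallel_pair_beats_independent_noise(self):
        rng = np.random.default_rng(2)
        sites = 12
        base = rng.normal(0, 0.5, sites)
        m = make_matrix(
            {
                "A": list(base),
                "B": list(base + 0.4),
                "C": list(rng.normal(0, 0.5, sites)),
            }
        )
        winner, scores = kbench.select_benchmark(m, ["A", "B", "C"])
        assert winner in {"A", "B"}
        # exhaustive check: winner really has the largest median REM
        assert scores[winner] == max(scores.values())

    def test_pool_of_one_rejected(self, parallel_pair):
        with pytest.raises(UsageError):
            kbench.select_benchmark(parallel_pair, ["A"])


class TestRunUbm:
    def test_two_chemical_matrix_benchmarks_exactly_one(self, parallel_pair):
        result = kbench.run_ubm(parallel_pair)
        assert len(result.per_chemical) == 1
        assert result.benchmarks[0] not in result.per_chemical

    def test_mutually_parallel_chemicals_fully_reduced(self):
        base = np.array([0.0, 0.7, 0.2, 1.1, 0.5])
        m = make_matrix({c: list(base + i * 0.3) for i, c in enumerate("ABCD")})
        result = kbench.run_ubm(m)
        assert result.summary["fraction_reduced"] == 1.0
        for entry in result.per_chemical.values():
            assert entry.stddev_after == pytest.approx(0.0, abs=1e-12)
            assert entry.rem == pytest.approx(entry.stddev_before)

    def test_independent_noise_gives_negative_median_rem(self):
        """For mutually independent rows of equal variance, benchmarking adds
        variance: E[stddev'] -> sqrt(2)*sigma, so median REM ~ (1-sqrt(2))*sigma."""
        rng = np.random.default_rng(7)
        sigma = 0.4
        n_sites, n_chem, reps = 38, 6, 100
        rems = []
        for _ in range(reps):
            m = make_matrix(
                {f"C{i}": list(rng.normal(0, sigma, n_sites)) for i in range(n_chem)}
            )
            result = kbench.run_ubm(m)
            rems.append(result.summary["median_rem"])
        expected = (1 - math.sqrt(2)) * sigma
        se = np.std(rems, ddof=1) / math.sqrt(reps)
        # selection of the best benchmark biases upward slightly; allow for it
        assert np.mean(rems) < 0
        assert abs(np.mean(rems) - expected) < max(6 * se, 0.05)


class TestRunGbm:
    def test_single_group_reduces_to_ubm(self):
        rng = np.random.default_rng(9)
        m = make_matrix({f"C{i}": list(rng.normal(0, 1, 8)) for i in range(5)})
        ubm = kbench.run_ubm(m)
        grouping = kbench.GroupAssignment(
            labels={c: 1 for c in m.chemicals}, method="file", k_groups=1
        )
        gbm = kbench.run_gbm(m, grouping)
        assert gbm.benchmarks == ubm.benchmarks
        assert {c: e.rem for c, e in gbm.per_chemical.items()} == pytest.approx(
            {c: e.rem for c, e in ubm.per_chemical.items()}
        )

    def test_two_parallel_pair_groups_fully_reduced(self):
        rng = np.random.default_rng(10)
        e1, e2 = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        m = make_matrix(
            {
                "A1": list(e1),
                "A2": list(e1 + 0.5),
                "B1": list(e2),
                "B2": list(e2 - 0.3),
            }
        )
        grouping = kbench.GroupAssignment(
            labels={"A1": 1, "A2": 1, "B1": 2, "B2": 2}, method="file", k_groups=2
        )
        result = kbench.run_gbm(m, grouping)
        assert result.summary["median_rem"] > 0
        for entry in result.per_chemical.values():
            assert entry.rem == pytest.approx(entry.stddev_before)
        assert set(result.summary["group_benchmarks"]) == {"1", "2"}

    def test_singleton_group_rejected(self, parallel_pair):
        grouping = kbench.GroupAssignment(
            labels={"A": 1, "B": 2}, method="file", k_groups=2
        )
        with pytest.raises(kbench.ConfigurationError, match="2"):
            kbench.run_gbm(parallel_pair, grouping)


class TestTocAsBenchmark:
    def test_toc_normalization_equals_pseudo_benchmark_rem(self):
        rng = np.random.default_rng(12)
        m = make_matrix({"A": list(rng.normal(0, 0.5, 8))})
        toc = {s: float(10 ** rng.normal(0.3, 0.2)) for s in m.sites}
        normalized = kbench.toc_normalize(m, toc)
        sd_direct = kbench.chemical_stddev(normalized.row("A"))
        result = kbench.run_toc(m, toc)
        assert result.per_chemical["A"].stddev_after == pytest.approx(
            sd_direct, abs=1e-12
        )
        assert result.per_chemical["A"].n_gap_filled == 0


class TestFoldFactor:
    @pytest.mark.parametrize(
        "x, expected, digits",
        [(0.4, 2.5, 1), (0.0, 1.0, 10), (0.13, 1.35, 2), (0.046, 1.11, 2)],
    )
    def test_log10_stddev_to_multiplicative_factor(self, x, expected, digits):
        assert round(kbench.fold_factor(x), digits) == expected


class TestSummarize:
    def _result_with_rems(self, rems):
        result = kbench.BenchmarkResult(mode="UBM")
        for i, r in enumerate(rems):
            result.per_chemical[f"C{i}"] = kbench.ChemicalBenchmark(
                stddev_before=0.5, stddev_after=0.5 - r, rem=r, n_sites=5, n_gap_filled=0
            )
        return result

    def test_fraction_and_median(self):
        s = kbench.summarize(self._result_with_rems([0.1, -0.1, 0.3]))
        assert s["fraction_reduced"] == pytest.approx(2 / 3)
        assert s["median_rem"] == pytest.approx(0.1)

    def test_all_zero_rems(self):
        s = kbench.summarize(self._result_with_rems([0.0, 0.0]))
        assert s["fraction_reduced"] == 0.0
        assert s["median_rem"] == 0.0

    def test_single_chemical_median_is_its_rem(self):
        s = kbench.summarize(self._result_with_rems([0.2]))
        assert s["median_rem"] == pytest.approx(0.2)
        assert s["median_rem_fold_factor"] == pytest.approx(10**0.2)
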