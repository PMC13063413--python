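"""Chemical benchmarking and the REM variance-reduction statistic.

Benchmarking treats a well-characterized chemical like an internal standard:
if the ratio k_i,j / k_BM,j of chemical i to benchmark BM is constant across
site-experiments j, then the benchmark's measured rate constant at a site
captures that site's biodegradation capacity, and dividing by it removes the
site-to-site variability from chemical i. On the log10 scale the transform is
a subtraction, and its efficacy for chemical i is measured by

    REM_i = stddev_i - stddev'_i

where stddev_i is the sample standard deviation (N-1 denominator) of
log10 k_i,j over the N sites with valid values for i, and stddev'_i is the
standard deviation of the benchmarked series log10 k'_i,j = log10 k_i,j -
log10 k_BM,j. A positive REM means benchmarking reduced the spatiotemporal
variability. Because each stddev is computed about its own mean, the unknown
reference-site ratio k_i,ref/k_BM,ref drops out: mean-centering plays the
role of the reference ratio.

Gap rule: where the benchmark has no valid value at a site, the chemical's
raw mean-centered residual (log10 k_i,j minus the chemical's own mean) is
substituted for the missing benchmarked residual. The benchmarked residuals
are centered over the benchmark-valid sites only, the substituted raw
residuals over all of the chemical's valid sites, and the pooled sum of
squares is divided by N-1 with N the chemical's total valid sites.

Benchmark selection: every candidate in a pool is scored by the median REM it
achieves over the remaining pool members, and the candidate with the largest
median wins (ties broken by lexicographically smallest id). Universal
benchmarking (UBM) runs this over all chemicals; group-specific benchmarking
(GBM) runs it independently within each chemical group. Benchmark chemicals
are excluded from their own per-chemical statistics and from all summary
medians.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    InsufficientOverlapError,
    UsageError,
)
from .io import RateMatrix

logger = logging.getLogger(__name__)

#: minimum number of valid sites for any per-chemical standard deviation
DEFAULT_MIN_N = 3


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkedResiduals:
    """Mean-centered residuals of one chemical benchmarked against one benchmark."""

    chemical_id: str
    benchmark_id: str
    residuals: dict  # site_id -> residual (log10 units)
    n_sites: int
    n_gap_filled: int


@dataclass(frozen=True)
class ChemicalBenchmark:
    """Per-chemical benchmarking outcome (all values in log10 units)."""

    stddev_before: float
    stddev_after: float
    rem: float
    n_sites: int
    n_gap_filled: int


@dataclass
class BenchmarkResult:
    """Outcome of a UBM/GBM/TOC run.

    ``assignments`` maps each benchmarked chemical to its benchmark;
    ``per_chemical`` holds the stddev before/after and REM for every
    non-benchmark chemical; ``groups`` (GBM only) maps chemical -> group
    label; ``skipped`` lists chemicals that could not be benchmarked
    (insufficient data or overlap); ``summary`` is produced by
    :func:`summarize`.
    """

    mode: str  # "UBM" | "GBM" | "TOC"
    assignments: dict = field(default_factory=dict)
    per_chemical: dict = field(default_factory=dict)
    groups: dict | None = None
    benchmarks: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# core statistics (array kernels)
# ---------------------------------------------------------------------------


def _as_row(row) -> np.ndarray:
    arr = np.asarray(
        row.to_numpy(dtype=float) if hasattr(row, "to_numpy") else row, dtype=float
    )
    return arr


def chemical_stddev(row, min_n: int = DEFAULT_MIN_N) -> float:
    """Sample stddev (N-1) of a chemical's log10 k over its non-missing sites."""
    v = _as_row(row)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} valid values, got {v.size}"
        )
    return float(np.std(v, ddof=1))


def _rem_rows(
    row: np.ndarray, bm_row: np.ndarray, min_n: int
) -> tuple[float, float, float, int, int, np.ndarray, np.ndarray]:
    """REM kernel on two aligned site vectors (NaN = missing).

    Returns (stddev_before, stddev_after, rem, n_sites, n_gap_filled,
    residuals, site_index) where residuals[i] belongs to site site_index[i].
    """
    valid = np.isfinite(row)
    n = int(valid.sum())
    if n < min_n:
        raise InsufficientDataError(f"need at least {min_n} valid values, got {n}")
    vals = row[valid]
    mean_i = vals.mean()
    stddev_before = float(math.sqrt(((vals - mean_i) ** 2).sum() / (n - 1)))

    bm_valid = np.isfinite(bm_row)
    both = valid & bm_valid
    if not both.any():
        raise InsufficientOverlapError("no sites where both chemical and benchmark are valid")
    gap = valid & ~bm_valid

    diffs = row[both] - bm_row[both]
    res_bm = diffs - diffs.mean()
    res_gap = row[gap] - mean_i
    ss = float((res_bm**2).sum() + (res_gap**2).sum())
    stddev_after = math.sqrt(ss / (n - 1))

    site_index = np.concatenate([np.flatnonzero(both), np.flatnonzero(gap)])
    residuals = np.concatenate([res_bm, res_gap])
    order = np.argsort(site_index)
    return (
        stddev_before,
        stddev_after,
        stddev_before - stddev_after,
        n,
        int(gap.sum()),
        residuals[order],
        site_index[order],
    )


# ---------------------------------------------------------------------------
# public per-pair operations
# ---------------------------------------------------------------------------


def benchmark_residuals(
    matrix: RateMatrix,
    chemical: str,
    benchmark: str,
    min_n: int = DEFAULT_MIN_N,
) -> BenchmarkedResiduals:
    """Mean-centered benchmarked residuals of ``chemical`` against ``benchmark``.

    Sites where the benchmark is missing carry the gap-filled raw residual
    (see module docstring); ``n_gap_filled`` counts them.
    """
    if chemical == benchmark:
        raise UsageError("a chemical cannot be benchmarked against itself")
    row = matrix.row(chemical)
    bm_row = matrix.row(benchmark)
    _, _, _, n, n_gap, residuals, site_index = _rem_rows(row, bm_row, min_n)
    sites = matrix.sites
    return BenchmarkedResiduals(
        chemical_id=chemical,
        benchmark_id=benchmark,
        residuals={sites[i]: float(r) for i, r in zip(site_index, residuals)},
        n_sites=n,
        n_gap_filled=n_gap,
    )


def rem(
    matrix: RateMatrix,
    chemical: str,
    benchmark: str,
    min_n: int = DEFAULT_MIN_N,
) -> tuple[float, float, float]:
    """(stddev_before, stddev_after, REM) for one chemical/benchmark pair."""
    if chemical == benchmark:
        raise UsageError("a chemical cannot be benchmarked against itself")
    sb, sa, r, _, _, _, _ = _rem_rows(matrix.row(chemical), matrix.row(benchmark), min_n)
    return sb, sa, r


def fold_factor(x: float) -> float:
    """Express a log10-scale stddev or REM as a multiplicative fold factor, 10^x."""
    if not math.isfinite(x):
        raise DomainError(f"fold_factor requires a finite value, got {x!r}")
    return 10.0**x


# ---------------------------------------------------------------------------
# benchmark selection
# ---------------------------------------------------------------------------


def median_rem(
    matrix: RateMatrix,
    benchmark: str,
    candidates: Iterable[str],
    min_n: int = DEFAULT_MIN_N,
) -> float:
    """Median REM achieved by ``benchmark`` over the candidate chemicals.

    Candidates with insufficient data or no overlap with the benchmark are
    skipped (and logged); an empty effective candidate set raises
    :class:`InsufficientDataError`.
    """
    rems = []
    n_skipped = 0
    bm_row = matrix.row(benchmark)
    for cid in candidates:
        if cid == benchmark:
            raise UsageError("candidate set must exclude the benchmark")
        try:
            _, _, r, _, _, _, _ = _rem_rows(matrix.row(cid), bm_row, min_n)
        except InsufficientDataError:
            n_skipped += 1
            continue
        rems.append(r)
    if n_skipped:
        logger.debug(
            "median_rem(%s): skipped %d candidate(s) with insufficient data",
            benchmark,
            n_skipped,
        )
    if not rems:
        raise InsufficientDataError(
            f"no candidate could be benchmarked against {benchmark!r}"
        )
    return float(statistics.median(rems))


def select_benchmark(
    matrix: RateMatrix,
    pool: Sequence[str],
    min_n: int = DEFAULT_MIN_N,
) -> tuple[str, dict]:
    """Pick the pool member with the largest median REM over the rest.

    Returns (benchmark_id, {candidate: median REM or NaN if unusable});
    ties are broken by lexicographically smallest chemical id.
    """
    pool = list(pool)
    if len(pool) < 2:
        raise UsageError("benchmark selection needs a pool of at least 2 chemicals")
    scores: dict[str, float] = {}
    for cid in pool:
        others = [c for c in pool if c != cid]
        try:
            scores[cid] = median_rem(matrix, cid, others, min_n=min_n)
        except InsufficientDataError:
            scores[cid] = float("nan")
    usable = {c: s for c, s in scores.items() if math.isfinite(s)}
    if not usable:
        raise InsufficientDataError("no usable benchmark candidate in the pool")
    best_score = max(usable.values())
    winner = min(c for c, s in usable.items() if s == best_score)
    return winner, scores


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------


def _benchmark_pool(
    matrix: RateMatrix,
    pool: Sequence[str],
    result: BenchmarkResult,
    min_n: int,
) -> str:
    """Select a benchmark within ``pool`` and fill per-chemical entries."""
    benchmark, _ = select_benchmark(matrix, pool, min_n=min_n)
    result.benchmarks.append(benchmark)
    bm_row = matrix.row(benchmark)
    for cid in pool:
        if cid == benchmark:
            continue
        try:
            sb, sa, r, n, n_gap, _, _ = _rem_rows(matrix.row(cid), bm_row, min_n)
        except InsufficientDataError:
            result.skipped.append(cid)
            continue
        result.assignments[cid] = benchmark
        result.per_chemical[cid] = ChemicalBenchmark(
            stddev_before=sb, stddev_after=sa, rem=r, n_sites=n, n_gap_filled=n_gap
        )
    return benchmark


def run_ubm(matrix: RateMatrix, min_n: int = DEFAULT_MIN_N) -> BenchmarkResult:
    """Universal benchmarking: one benchmark for all chemicals."""
    counts = matrix.n_valid()
    pool = [c for c in matrix.chemicals if counts[c] >= min_n]
    if len(pool) < 2:
        raise InsufficientDataError(
            "UBM needs at least 2 chemicals with sufficient data"
        )
    result = BenchmarkResult(mode="UBM")
    _benchmark_pool(matrix, pool, result, min_n)
    result.summary = summarize(result)
    return result


def run_gbm(
    matrix: RateMatrix,
    grouping,
    min_n: int = DEFAULT_MIN_N,
) -> BenchmarkResult:
    """Group-specific benchmarking: one benchmark per chemical group.

    ``grouping`` is a :class:`~kbench.grouping.GroupAssignment` (or any object
    with a ``labels`` mapping chemical_id -> group label). Every group must
    contribute at least two chemicals present in the matrix.
    """
    labels: Mapping[str, int] = grouping.labels
    present = set(matrix.chemicals)
    by_group: dict[int, list[str]] = {}
    for cid, g in labels.items():
        if cid in present:
            by_group.setdefault(g, []).append(cid)
    if not by_group:
        raise ConfigurationError("grouping covers no chemical present in the matrix")
    for g, members in sorted(by_group.items()):
        if len(members) < 2:
            raise ConfigurationError(
                f"group {g!r} has {len(members)} chemical(s) in the matrix; "
                "group-specific benchmarking needs at least 2"
            )
    result = BenchmarkResult(mode="GBM", groups={c: g for c, g in labels.items() if c in present})
    group_benchmarks = {}
    for g, members in sorted(by_group.items()):
        group_benchmarks[g] = _benchmark_pool(matrix, sorted(members), result, min_n)
    result.summary = summarize(result)
    result.summary["group_benchmarks"] = {str(g): b for g, b in sorted(group_benchmarks.items())}
    return result


def run_toc(matrix: RateMatrix, toc_by_site: Mapping[str, float],
            min_n: int = DEFAULT_MIN_N) -> BenchmarkResult:
    """TOC normalization expressed as benchmarking against a TOC pseudo-chemical.

    The benchmark row is log10 TOC_j; since TOC is available at every site
    there are no gaps, and the per-chemical stddev_after equals the stddev of
    the TOC-normalized row.
    """
    toc_row = np.empty(len(matrix.sites))
    for j, site in enumerate(matrix.sites):
        toc = toc_by_site.get(site)
        if toc is None or not (toc > 0 and math.isfinite(toc)):
            raise DomainError(f"missing or non-positive TOC for site {site!r}")
        toc_row[j] = math.log10(toc)
    result = BenchmarkResult(mode="TOC")
    result.benchmarks.append("TOC")
    for cid in matrix.chemicals:
        try:
            sb, sa, r, n, n_gap, _, _ = _rem_rows(matrix.row(cid), toc_row, min_n)
        except InsufficientDataError:
            result.skipped.append(cid)
            continue
        result.assignments[cid] = "TOC"
        result.per_chemical[cid] = ChemicalBenchmark(
            stddev_before=sb, stddev_after=sa, rem=r, n_sites=n, n_gap_filled=n_gap
        )
    result.summary = summarize(result)
    return result


def summarize(result: BenchmarkResult) -> dict:
    """Summary statistics over the non-benchmark chemicals of a result.

    Reports the median REM, the fraction of chemicals whose stddev was
    reduced (REM > 0), per-group medians for GBM, and fold-factor versions
    (10^x) of the medians. Deterministic given the result.
    """
    rems = {c: e.rem for c, e in result.per_chemical.items()}
    summary: dict = {
        "n_chemicals": len(rems),
        "n_benchmarks": len(result.benchmarks),
        "n_skipped": len(result.skipped),
    }
    if rems:
        med = float(statistics.median(rems.values()))
        summary["median_rem"] = med
        summary["median_rem_fold_factor"] = fold_factor(med)
        summary["fraction_reduced"] = sum(1 for r in rems.values() if r > 0) / len(rems)
        summary["median_stddev_before"] = float(
            statistics.median(e.stddev_before for e in result.per_chemical.values())
        )
        summary["median_stddev_after"] = float(
            statistics.median(e.stddev_after for e in result.per_chemical.values())
        )
    else:
        summary["median_rem"] = None
        summary["median_rem_fold_factor"] = None
        summary["fraction_reduced"] = None
        summary["median_stddev_before"] = None
        summary["median_stddev_after"] = None
    if result.groups:
        per_group: dict[str, float] = {}
        by_group: dict[int, list[float]] = {}
        for cid, r in rems.items():
            by_group.setdefault(result.groups[cid], []).append(r)
        for g, vals in sorted(by_group.items()):
            per_group[str(g)] = float(statistics.median(vals))
        summary["per_group_median_rem"] = per_group
    return summary
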