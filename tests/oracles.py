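"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written in plain-python loops over dicts/lists, with
no shared code with the package, so that agreement with the vectorized
implementation is a meaningful check.
"""

from __future__ import annotations

import math


def brute_force_rem(logk: dict, chemical: str, benchmark: str):
    """Direct transcription of the variance-reduction statistic.

    ``logk`` maps chemical -> {site: log10 k or None}. Returns
    (stddev_before, stddev_after, rem). The gap rule substitutes the
    chemical's own mean-centered residual at sites where the benchmark is
    missing; benchmarked residuals are centered over benchmark-valid sites;
    the pooled sum of squares is divided by N-1 with N the chemical's total
    valid sites.
    """
    row = logk[chemical]
    bm = logk[benchmark]
    valid = [s for s in row if row[s] is not None]
    n = len(valid)
    if n < 2:
        raise ValueError("need at least 2 valid values")
    mean_i = sum(row[s] for s in valid) / n
    stddev_before = math.sqrt(sum((row[s] - mean_i) ** 2 for s in valid) / (n - 1))

    both = [s for s in valid if bm.get(s) is not None]
    gaps = [s for s in valid if bm.get(s) is None]
    if not both:
        raise ValueError("no overlap")
    diffs = {s: row[s] - bm[s] for s in both}
    dbar = sum(diffs.values()) / len(both)
    residuals = [diffs[s] - dbar for s in both]
    residuals += [row[s] - mean_i for s in gaps]
    stddev_after = math.sqrt(sum(r * r for r in residuals) / (n - 1))
    return stddev_before, stddev_after, stddev_before - stddev_after


def _ess(points) -> float:
    """Error sum of squares of a point cloud about its centroid."""
    dims = len(points[0])
    cent = [sum(p[d] for p in points) / len(points) for d in range(dims)]
    return sum(sum((p[d] - cent[d]) ** 2 for d in range(dims)) for p in points)


def brute_force_ward(X) -> list:
    """Greedy Ward agglomeration with exhaustive variance recomputation.

    ``X`` is a list of equal-length point tuples. At every step the pair of
    clusters whose merge least increases the total within-cluster error sum
    of squares is merged. Returns a list of merge events
    (frozenset(leaves of one side), frozenset(other side), height) with
    heights on the distance (Ward.D2) scale: height = sqrt(2 * delta ESS).
    """
    X = [tuple(map(float, p)) for p in X]
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pts_a = [X[i] for i in clusters[a]]
                pts_b = [X[i] for i in clusters[b]]
                increase = _ess(pts_a + pts_b) - _ess(pts_a) - _ess(pts_b)
                if best is None or increase < best[0]:
                    best = (increase, a, b)
        increase, a, b = best
        merges.append((clusters[a], clusters[b], math.sqrt(2.0 * max(increase, 0.0))))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def scipy_linkage_merges(Z, n_leaves: int) -> list:
    """Reconstruct (left leaves, right leaves, height) events from a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n_leaves)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        merges.append((members[a], members[b], float(h)))
        members[n_leaves + step] = members[a] | members[b]
    return merges
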