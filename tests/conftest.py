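"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from tbsmap import ContactMatrix


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; they recompute from first
# principles rather than reusing package code paths)
# ---------------------------------------------------------------------------


def brute_force_min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """All-pairs minimum Euclidean distance, plain loops."""
    best = float("inf")
    for a in coords_a:
        for b in coords_b:
            d = float(np.sqrt(((a - b) ** 2).sum()))
            best = min(best, d)
    return best


def set_jaccard(a, b) -> float:
    """Jaccard distance by direct set enumeration."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def greedy_agglomerate_oracle(dist, cutoff, linkage="average"):
    """Brute-force agglomeration recomputing linkage distances from scratch.

    At each step every cross-cluster linkage distance is recomputed directly
    from the original item-item matrix (mean / min / max over all item
    pairs), the closest pair merges (ties broken by ascending smallest
    members), and merging stops when the minimum exceeds the cutoff.  Shares
    no incremental state with the package implementation.
    """
    dist = np.asarray(dist, float)
    clusters = [frozenset((i,)) for i in range(dist.shape[0])]

    def linkage_distance(c1, c2):
        values = [dist[i, j] for i in c1 for j in c2]
        if linkage == "single":
            return min(values)
        if linkage == "complete":
            return max(values)
        return float(np.mean(values))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkage_distance(clusters[i], clusters[j])
                key = (d, *sorted((min(clusters[i]), min(clusters[j]))))
                if best is None or _tie_less(key, best[0]):
                    best = (key, i, j)
        (d, *_), i, j = best
        if d > cutoff + 1e-12:
            break
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(clusters, key=min)


def _tie_less(key_a, key_b, tol=1e-9):
    if key_a[0] < key_b[0] - tol:
        return True
    if key_a[0] > key_b[0] + tol:
        return False
    return key_a[1:] < key_b[1:]


@pytest.fixture
def rng():
    return np.random.default_rng(20230224)


@pytest.fixture
def small_matrix():
    """3 residues with identical supports + 2 with mutually disjoint ones."""
    frames = {
        1: [0, 1, 2, 3],
        2: [0, 1, 2, 3],
        3: [0, 1, 2, 3],
        4: [10, 11],
        5: [20, 21],
    }
    return ContactMatrix(
        substrate_id="S",
        replica_id="r01",
        n_residues=6,
        n_frames=30,
        dt_ps=2.0,
        contacts={r: np.asarray(f) for r, f in frames.items()},
    )


def random_supports(rng, n_items, universe=30, max_size=12):
    """Random non-empty frame supports for clustering tests."""
    supports = []
    for _ in range(n_items):
        size = int(rng.integers(1, max_size))
        supports.append(frozenset(rng.choice(universe, size=size, replace=False).tolist()))
    return supports
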