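"""Deterministic agglomerative clustering under the Jaccard distance.

Both clustering stages of the pipeline — residues within a replica (on frame
supports) and local clusters across replicas/substrates (on residue
membership) — use the same primitive: agglomerative clustering of finite sets
with the Jaccard distance ``1 − |A∩B| / |A∪B|``, merging while the linkage
distance stays at or below a cutoff (default 0.65).

The agglomeration is implemented here rather than delegated so that outputs
are fully deterministic: equal-height candidate merges are resolved by the
ascending smallest-original-member order of the two clusters.  Linkage updates
follow Lance–Williams (``single`` = min, ``complete`` = max, ``average`` =
size-weighted mean, i.e. unweighted pair-group averaging over the original
items).  All three linkages are monotone, so stopping at the first merge above
the cutoff is equivalent to cutting the full dendrogram at that height.
"""

from __future__ import annotations

import warnings
from typing import Collection, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["jaccard_distance", "pairwise_jaccard", "agglomerate", "LINKAGES"]

LINKAGES = ("single", "complete", "average")

#: Merges proceed while linkage distance <= cutoff + _CUT_TOL (absorbs the
#: ~1 ulp difference between incremental and direct averaging).
_CUT_TOL = 1e-12
#: Candidate merges within _TIE_TOL of the minimum are treated as tied.
_TIE_TOL = 1e-9


def jaccard_distance(a: Collection[int], b: Collection[int]) -> float:
    """Jaccard distance ``1 − |a∩b| / |a∪b|`` between two finite sets.

    Both-empty input is defined as distance 0 (with a warning); empty-support
    items are filtered out before clustering, so this should be unreachable in
    the pipeline.
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        warnings.warn(
            "jaccard_distance of two empty sets is defined as 0", stacklevel=2
        )
        return 0.0
    return 1.0 - len(sa & sb) / len(sa | sb)


def pairwise_jaccard(sets: Sequence[Collection[int]]) -> np.ndarray:
    """Square Jaccard distance matrix over a sequence of finite sets."""
    n = len(sets)
    if n == 0:
        return np.zeros((0, 0))
    universe = sorted(set().union(*map(set, sets)))
    if not universe:
        warnings.warn("all sets empty; pairwise Jaccard distances set to 0")
        return np.zeros((n, n))
    index = {v: i for i, v in enumerate(universe)}
    incidence = np.zeros((n, len(universe)), dtype=bool)
    for row, members in enumerate(sets):
        for value in members:
            incidence[row, index[value]] = True
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(incidence, metric="jaccard"))


def _pair(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def agglomerate(
    dist: np.ndarray, cutoff: float, linkage: str = "average"
) -> list[frozenset[int]]:
    """Agglomerate items given a square distance matrix, cut at ``cutoff``.

    Returns the flat partition as frozensets of 0-based item indices, ordered
    by their smallest member.  Items whose nearest linkage distance exceeds
    the cutoff remain singletons.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"dist must be square, got shape {dist.shape}")
    n = dist.shape[0]
    if n == 0:
        return []
    members: dict[int, frozenset[int]] = {i: frozenset((i,)) for i in range(n)}
    pair_d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while pair_d:
        dmin = min(pair_d.values())
        if dmin > cutoff + _CUT_TOL:
            break
        ties = [k for k, v in pair_d.items() if v <= dmin + _TIE_TOL]
        a, b = min(
            ties, key=lambda k: tuple(sorted((min(members[k[0]]), min(members[k[1]]))))
        )
        ma, mb = members.pop(a), members.pop(b)
        na, nb = len(ma), len(mb)
        merged_id = next_id
        next_id += 1
        new_edges: dict[tuple[int, int], float] = {}
        for other in members:
            dac = pair_d[_pair(a, other)]
            dbc = pair_d[_pair(b, other)]
            if linkage == "single":
                dnew = min(dac, dbc)
            elif linkage == "complete":
                dnew = max(dac, dbc)
            else:
                dnew = (na * dac + nb * dbc) / (na + nb)
            new_edges[_pair(merged_id, other)] = dnew
        pair_d = {
            k: v for k, v in pair_d.items() if a not in k and b not in k
        }
        pair_d.update(new_edges)
        members[merged_id] = ma | mb
    return sorted(members.values(), key=min)
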