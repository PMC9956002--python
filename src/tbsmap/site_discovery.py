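"""Two-stage hierarchical clustering of contact vectors into binding sites.

Stage 1 (*local clusters*): within one (substrate, replica) contact matrix,
residues with non-empty frame supports are agglomerated under the Jaccard
distance on their supports; groups with at least ``min_cluster_size`` residues
(default 3) survive.  A local cluster carries each member's interaction time
and the group occupancy time (union of member frame supports × dt), so that
frames in which several members touch the ligand simultaneously are not
double-counted.

Stage 2 (*global clusters* / binding sites): local clusters — represented by
their residue-membership sets, the only structure comparable across replicas —
are agglomerated with the same metric and cutoff.  Each resulting group is a
transient binding site: the union of member residue sets plus a per-substrate
time table (aggregated from member cluster times; median by default, sum
available for cumulative reporting).

Sites discovered separately per substrate are finally merged across substrates
by residue-set similarity, yielding one numbered site list with a
substrate-by-site time table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import agglomerate, pairwise_jaccard
from .contact_map import ContactMatrix

__all__ = [
    "LocalCluster",
    "BindingSite",
    "local_cluster",
    "global_cluster",
    "merge_sites_across_substrates",
    "site_time_table",
    "site_time_table_report",
    "render_time_table",
    "write_sites_json",
    "read_sites_json",
]

logger = logging.getLogger(__name__)

_TOL = 1e-9


def _aggregate(values: Sequence[float], aggregator: str) -> float:
    if aggregator == "median":
        return float(np.median(values))
    if aggregator == "sum":
        return float(np.sum(values))
    raise ValueError(f"aggregator must be 'median' or 'sum', got {aggregator!r}")


@dataclass(frozen=True)
class LocalCluster:
    """A >=3-residue co-interacting group within one (substrate, replica)."""

    substrate_id: str
    replica_id: str
    residues: frozenset[int]
    per_residue_time_ns: Mapping[int, float]
    cluster_time_ns: float

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("local cluster must have at least one residue")
        if set(self.per_residue_time_ns) != set(self.residues):
            raise ValueError("per_residue_time_ns keys must equal residues")
        hi = max(self.per_residue_time_ns.values())
        total = sum(self.per_residue_time_ns.values())
        if not (hi - _TOL <= self.cluster_time_ns <= total + _TOL):
            raise ValueError(
                "cluster_time_ns must lie between the largest per-residue time "
                "and the per-residue sum"
            )


@dataclass
class BindingSite:
    """A transient binding site: a global cluster of local clusters."""

    residues: frozenset[int]
    members: tuple[LocalCluster, ...]
    time_table: dict[str, float]
    site_id: int | None = None

    def __post_init__(self) -> None:
        union = frozenset().union(*(m.residues for m in self.members))
        if self.residues != union:
            raise ValueError("site residues must be the union of member residue sets")
        member_subs = {m.substrate_id for m in self.members}
        if set(self.time_table) - member_subs:
            raise ValueError("time_table lists a substrate with no member cluster")

    @property
    def total_time_ns(self) -> float:
        return float(sum(self.time_table.values()))


def local_cluster(
    m: ContactMatrix,
    jaccard_cutoff: float = 0.65,
    min_cluster_size: int = 3,
    linkage: str = "average",
) -> list[LocalCluster]:
    """Stage-1 clustering of one contact matrix into local clusters.

    Residues with empty contact vectors never enter clustering.  The flat
    partition at the distance cutoff is filtered to groups of at least
    ``min_cluster_size`` residues; an empty matrix yields an empty list.
    """
    active = m.active_residues
    if not active:
        logger.info(
            "contact matrix %s/%s has no contacts; no local clusters",
            m.substrate_id,
            m.replica_id,
        )
        return []
    supports = [m.support(r) for r in active]
    groups = agglomerate(pairwise_jaccard(supports), jaccard_cutoff, linkage)
    clusters: list[LocalCluster] = []
    for group in groups:
        residues = frozenset(active[i] for i in group)
        if len(residues) < min_cluster_size:
            continue
        clusters.append(
            LocalCluster(
                substrate_id=m.substrate_id,
                replica_id=m.replica_id,
                residues=residues,
                per_residue_time_ns={
                    r: m.interaction_time_ns(r) for r in sorted(residues)
                },
                cluster_time_ns=m.union_time_ns(residues),
            )
        )
    return sorted(clusters, key=lambda c: min(c.residues))


def global_cluster(
    local_clusters: Sequence[LocalCluster],
    jaccard_cutoff: float = 0.65,
    min_cluster_size: int = 3,
    linkage: str = "average",
    aggregator: str = "median",
) -> list[BindingSite]:
    """Stage-2 clustering of one substrate's local clusters into sites.

    Local clusters are compared by the Jaccard distance on their residue
    membership sets; each flat group becomes a :class:`BindingSite` whose
    residues are the union of its members and whose time-table entry is the
    ``aggregator`` (median or sum) of member cluster times.
    """
    if not local_clusters:
        raise ValueError("global_cluster requires at least one local cluster")
    substrates = {c.substrate_id for c in local_clusters}
    if len(substrates) > 1:
        raise ValueError(
            f"global_cluster expects one substrate, got {sorted(substrates)}"
        )
    (substrate,) = substrates
    features = [c.residues for c in local_clusters]
    groups = agglomerate(pairwise_jaccard(features), jaccard_cutoff, linkage)
    sites: list[BindingSite] = []
    for group in groups:
        members = tuple(
            sorted(
                (local_clusters[i] for i in group),
                key=lambda c: (c.replica_id, sorted(c.residues)),
            )
        )
        residues = frozenset().union(*(c.residues for c in members))
        if len(residues) < min_cluster_size:
            continue
        sites.append(
            BindingSite(
                residues=residues,
                members=members,
                time_table={
                    substrate: _aggregate(
                        [c.cluster_time_ns for c in members], aggregator
                    )
                },
            )
        )
    return sorted(sites, key=lambda s: min(s.residues))


def merge_sites_across_substrates(
    per_substrate_sites: Mapping[str, Sequence[BindingSite]],
    jaccard_cutoff: float = 0.65,
    linkage: str = "average",
    aggregator: str = "median",
) -> list[BindingSite]:
    """Unify per-substrate sites into one numbered site list.

    Sites whose residue-set Jaccard distance is within the cutoff merge under
    one ``site_id``; the merged time table keeps one entry per contributing
    substrate, re-aggregated over that substrate's member local clusters.
    Site ids are assigned in descending order of total time, ties broken by
    the smallest residue index.
    """
    flat: list[BindingSite] = [
        site for substrate in per_substrate_sites for site in per_substrate_sites[substrate]
    ]
    if not flat:
        return []
    groups = agglomerate(
        pairwise_jaccard([s.residues for s in flat]), jaccard_cutoff, linkage
    )
    merged: list[BindingSite] = []
    for group in groups:
        members = tuple(
            sorted(
                (c for i in group for c in flat[i].members),
                key=lambda c: (c.substrate_id, c.replica_id, sorted(c.residues)),
            )
        )
        residues = frozenset().union(*(c.residues for c in members))
        by_substrate: dict[str, list[float]] = {}
        for cluster in members:
            by_substrate.setdefault(cluster.substrate_id, []).append(
                cluster.cluster_time_ns
            )
        time_table = {
            sub: _aggregate(times, aggregator)
            for sub, times in sorted(by_substrate.items())
        }
        merged.append(
            BindingSite(residues=residues, members=members, time_table=time_table)
        )
    merged.sort(key=lambda s: (-s.total_time_ns, min(s.residues)))
    for rank, site in enumerate(merged, start=1):
        site.site_id = rank
    return merged


def site_time_table(
    sites: Sequence[BindingSite], substrates: Sequence[str] | None = None
) -> pd.DataFrame:
    """Site × substrate duration table (ns); NaN marks absent pairs."""
    if substrates is None:
        seen: dict[str, None] = {}
        for site in sites:
            for sub in site.time_table:
                seen.setdefault(sub)
        substrates = list(seen)
    index = [site.site_id for site in sites]
    data = {
        sub: [site.time_table.get(sub, np.nan) for site in sites]
        for sub in substrates
    }
    frame = pd.DataFrame(data, index=index, columns=list(substrates))
    frame.index.name = "site"
    return frame


def render_time_table(frame: pd.DataFrame, config_hash: str | None = None) -> str:
    """Render a site × substrate table as TSV: one decimal, '-' for absences."""
    lines = []
    if config_hash is not None:
        lines.append(f"#config_hash={config_hash}")
    lines.append("site\t" + "\t".join(str(c) for c in frame.columns))
    for site, row in frame.iterrows():
        cells = ["-" if pd.isna(v) else f"{v:.1f}" for v in row]
        lines.append(f"{site}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def site_time_table_report(
    sites: Sequence[BindingSite],
    substrates: Sequence[str] | None = None,
    config_hash: str | None = None,
) -> str:
    """TSV report of per-site per-substrate interaction times."""
    return render_time_table(site_time_table(sites, substrates), config_hash)


# ---------------------------------------------------------------------------
# Site JSON round-trip
# ---------------------------------------------------------------------------


def _site_to_dict(site: BindingSite) -> dict:
    return {
        "site_id": site.site_id,
        "residues": sorted(site.residues),
        "time_table": {k: site.time_table[k] for k in sorted(site.time_table)},
        "members": [
            {
                "substrate": c.substrate_id,
                "replica": c.replica_id,
                "residues": sorted(c.residues),
                "per_residue_time_ns": {
                    str(r): c.per_residue_time_ns[r] for r in sorted(c.residues)
                },
                "cluster_time_ns": c.cluster_time_ns,
            }
            for c in site.members
        ],
    }


def write_sites_json(
    sites: Sequence[BindingSite], path: str | Path, config_hash: str | None = None
) -> None:
    payload = {
        "config_hash": config_hash,
        "sites": [_site_to_dict(s) for s in sites],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )


def read_sites_json(path: str | Path) -> list[BindingSite]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    sites = []
    for entry in payload["sites"]:
        members = tuple(
            LocalCluster(
                substrate_id=m["substrate"],
                replica_id=m["replica"],
                residues=frozenset(m["residues"]),
                per_residue_time_ns={
                    int(r): t for r, t in m["per_residue_time_ns"].items()
                },
                cluster_time_ns=m["cluster_time_ns"],
            )
            for m in entry["members"]
        )
        sites.append(
            BindingSite(
                residues=frozenset(entry["residues"]),
                members=members,
                time_table=dict(entry["time_table"]),
                site_id=entry["site_id"],
            )
        )
    return sites
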