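"""Key-site and key-residue selection rules, and WT/mutant profile comparison.

*Key sites* for one substrate are the binding sites whose interaction time is
at least a fraction (default 0.33) of the longest binding time to the enzyme
surface, after removing sites linked to user-listed transport-pathway residues
(e.g. the entrance of the main substrate tunnel).  The longest time is taken
over *all* sites, excluded ones included — the pathway entrance is still part
of the surface.

*Key residues* are then found by pooling, over the key sites, each residue's
per-local-cluster interaction times: a residue's profile is the median of its
times across the local clusters containing it, and residues whose profile
median is greater than or equal to the median over all profiled residues are
classified as key.

For validation, :func:`compare_profiles` contrasts a mutant's per-site
interaction times with the wild type's: per-site percent change, flagged
``substantial`` above 50 % in magnitude and ``minor`` below 20 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

import numpy as np

from .site_discovery import BindingSite

__all__ = [
    "SelectionConfig",
    "ResidueProfile",
    "SiteComparison",
    "select_key_sites",
    "build_residue_profiles",
    "select_key_residues",
    "compare_profiles",
    "render_comparison_report",
    "read_exclusion_list",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the key-site rule.

    ``fraction`` — minimum time relative to the longest site time (default
    0.33; the slightly-below-one-third default admits boundary ratios such as
    32.0/96.6 = 0.331).  ``excluded_residues`` — known transport-pathway
    residues; a site overlapping them by at least ``exclusion_overlap_min``
    members is removed.  ``excluded_sites`` — direct site-id exclusion, for
    workflows starting from a published time table without residue lists.
    """

    fraction: float = 0.33
    excluded_residues: frozenset[int] = frozenset()
    excluded_sites: frozenset[int] = frozenset()
    exclusion_overlap_min: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.exclusion_overlap_min < 1:
            raise ValueError(
                f"exclusion_overlap_min must be >= 1, got {self.exclusion_overlap_min}"
            )
        object.__setattr__(self, "excluded_residues", frozenset(self.excluded_residues))
        object.__setattr__(self, "excluded_sites", frozenset(self.excluded_sites))


@dataclass(frozen=True)
class ResidueProfile:
    """A residue's interaction times across local clusters, and their median."""

    residue_index: int
    times_ns: tuple[tuple[str, str, float], ...]  # (substrate, replica, ns)
    median_time_ns: float

    def __post_init__(self) -> None:
        if not self.times_ns:
            raise ValueError("residue profile requires at least one observation")
        if any(t < 0 for _, _, t in self.times_ns):
            raise ValueError("interaction times must be non-negative")


def select_key_sites(
    time_table: Mapping[int, float],
    site_residues: Mapping[int, Collection[int]] | None,
    cfg: SelectionConfig,
) -> set[int]:
    """Apply the fraction-of-maximum rule with pathway-site exclusion.

    Parameters
    ----------
    time_table
        Site id → interaction time (ns) for one substrate.
    site_residues
        Site id → residue set, used for residue-overlap exclusion; may be
        omitted when exclusion is given directly as ``cfg.excluded_sites``.
    """
    if not time_table:
        raise ValueError("time_table must be non-empty")
    if any(t < 0 for t in time_table.values()):
        raise ValueError("interaction times must be non-negative")
    excluded = set()
    for site, time in time_table.items():
        if site in cfg.excluded_sites:
            excluded.add(site)
        elif site_residues is not None and site in site_residues:
            overlap = len(set(site_residues[site]) & cfg.excluded_residues)
            if overlap >= cfg.exclusion_overlap_min:
                excluded.add(site)
    t_max = max(time_table.values())  # over ALL sites, excluded included
    if t_max == 0:
        warnings.warn("all site times are zero; no key sites selected")
        return set()
    if excluded >= set(time_table):
        warnings.warn("all sites excluded by the pathway-residue list")
        return set()
    return {
        site
        for site, time in time_table.items()
        if site not in excluded and time / t_max >= cfg.fraction
    }


def build_residue_profiles(sites: Sequence[BindingSite]) -> list[ResidueProfile]:
    """One profile per distinct residue across the given (key) sites.

    A residue's observations are its per-residue times in every member local
    cluster that contains it; the profile median uses the standard
    mean-of-middle-two convention for even counts (``numpy.median``).
    """
    observations: dict[int, list[tuple[str, str, float]]] = {}
    for site in sites:
        for cluster in site.members:
            for residue in sorted(cluster.residues):
                observations.setdefault(residue, []).append(
                    (
                        cluster.substrate_id,
                        cluster.replica_id,
                        cluster.per_residue_time_ns[residue],
                    )
                )
    profiles = []
    for residue in sorted(observations):
        times = observations[residue]
        profiles.append(
            ResidueProfile(
                residue_index=residue,
                times_ns=tuple(times),
                median_time_ns=float(np.median([t for _, _, t in times])),
            )
        )
    return profiles


def select_key_residues(profiles: Sequence[ResidueProfile]) -> set[int]:
    """Residues whose profile median is >= the median over all profiles."""
    if not profiles:
        raise ValueError("select_key_residues requires at least one profile")
    overall = float(np.median([p.median_time_ns for p in profiles]))
    return {p.residue_index for p in profiles if p.median_time_ns >= overall}


@dataclass(frozen=True)
class SiteComparison:
    """Per-site WT-vs-mutant interaction-time change."""

    site_id: int
    wt_ns: float
    mut_ns: float
    pct_change: float | None  # None when the site is new (zero WT time)
    flag: str  # substantial | intermediate | minor | new
    is_mutated_site: bool


def compare_profiles(
    wt_site_times: Mapping[int, float],
    mut_site_times: Mapping[int, float],
    mutated_site: int,
) -> list[SiteComparison]:
    """Compare WT and mutant per-site interaction times.

    Percent change is ``100 × (mut − wt) / wt``; ``|change| > 50`` is flagged
    substantial and ``|change| < 20`` minor.  A site absent from the WT table
    (zero time) is reported as ``new`` without a percentage.  The mutated
    site must be present in both tables.
    """
    if mutated_site not in wt_site_times or mutated_site not in mut_site_times:
        raise ValueError(
            f"mutated site {mutated_site} must appear in both WT and mutant tables"
        )
    comparisons = []
    for site in sorted(set(wt_site_times) | set(mut_site_times)):
        wt = float(wt_site_times.get(site, 0.0))
        mut = float(mut_site_times.get(site, 0.0))
        if wt == 0.0 and mut > 0.0:
            pct: float | None = None
            flag = "new"
        else:
            pct = 0.0 if wt == mut else 100.0 * (mut - wt) / wt
            if abs(pct) > 50.0:
                flag = "substantial"
            elif abs(pct) < 20.0:
                flag = "minor"
            else:
                flag = "intermediate"
        comparisons.append(
            SiteComparison(
                site_id=site,
                wt_ns=wt,
                mut_ns=mut,
                pct_change=pct,
                flag=flag,
                is_mutated_site=site == mutated_site,
            )
        )
    return comparisons


def render_comparison_report(
    comparisons: Sequence[SiteComparison], config_hash: str | None = None
) -> str:
    """TSV report: site_id, wt_ns, mut_ns, pct_change, flag ('*' marks the
    mutation-carrying site)."""
    lines = []
    if config_hash is not None:
        lines.append(f"#config_hash={config_hash}")
    lines.append("site_id\twt_ns\tmut_ns\tpct_change\tflag\tmutated")
    for c in comparisons:
        pct = "-" if c.pct_change is None else f"{c.pct_change:.1f}"
        star = "*" if c.is_mutated_site else ""
        lines.append(
            f"{c.site_id}\t{c.wt_ns:.1f}\t{c.mut_ns:.1f}\t{pct}\t{c.flag}\t{star}"
        )
    return "\n".join(lines) + "\n"


def read_exclusion_list(path) -> frozenset[int]:
    """Read a residue exclusion list: one index per line, '#' comments."""
    residues = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.split("#", 1)[0].strip()
            if line:
                residues.add(int(line))
    return frozenset(residues)
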