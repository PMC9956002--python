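"""End-to-end pipeline: contacts → cluster → select → design.

A :class:`RunConfig` gathers every tunable of the workflow (distance cutoff,
Jaccard cutoff, minimum cluster size, linkage, time aggregator, key-site
fraction, ΔΔG threshold, library size, frame spacing, seed) and is
range-checked on validation.  Every output file embeds a short hash of the
configuration so runs are traceable; given the same configuration and inputs
the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .clustering import LINKAGES
from .contact_map import ContactMatrix
from .library_design import DdgTable, propose_library, render_library
from .residue_selection import (
    ResidueProfile,
    SelectionConfig,
    build_residue_profiles,
    select_key_residues,
    select_key_sites,
)
from .site_discovery import (
    BindingSite,
    global_cluster,
    local_cluster,
    merge_sites_across_substrates,
    site_time_table_report,
    write_sites_json,
)

__all__ = ["RunConfig", "PipelineResult", "config_hash", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables; see the field names for units."""

    cutoff_angstrom: float = 2.7
    heavy_atoms_only: bool = False
    dt_ps: float = 2.0
    jaccard_cutoff: float = 0.65
    min_cluster_size: int = 3
    linkage: str = "average"
    aggregator: str = "median"
    fraction: float = 0.33
    excluded_residues: tuple[int, ...] = ()
    exclusion_overlap_min: int = 1
    ddg_max_kcal_mol: float = 0.5
    max_size: int = 10
    max_variants_per_position: int = 3
    flip_ddg_sign: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.cutoff_angstrom > 0:
            raise ValueError("cutoff_angstrom must be positive")
        if not self.dt_ps > 0:
            raise ValueError("dt_ps must be positive")
        if not 0 <= self.jaccard_cutoff <= 1:
            raise ValueError("jaccard_cutoff must be in [0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")
        if self.aggregator not in ("median", "sum"):
            raise ValueError("aggregator must be 'median' or 'sum'")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.exclusion_overlap_min < 1:
            raise ValueError("exclusion_overlap_min must be >= 1")
        if self.max_size < 0 or self.max_variants_per_position < 1:
            raise ValueError("library size limits out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "excluded_residues" in kwargs:
            kwargs["excluded_residues"] = tuple(kwargs["excluded_residues"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the configuration, embedded in every output."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    sites: list[BindingSite]
    key_sites_by_substrate: dict[str, set[int]]
    profiles: list[ResidueProfile]
    key_residues: set[int]
    library: list
    config_hash: str
    outputs: dict[str, Path] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            start = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2f s", name, time.perf_counter() - start)
            return result

        return run

    return wrap


@_stage("cluster")
def _cluster_stage(
    matrices: Sequence[ContactMatrix], cfg: RunConfig
) -> list[BindingSite]:
    by_substrate: dict[str, list] = {}
    for matrix in matrices:
        locals_ = local_cluster(
            matrix, cfg.jaccard_cutoff, cfg.min_cluster_size, cfg.linkage
        )
        by_substrate.setdefault(matrix.substrate_id, []).extend(locals_)
    per_substrate_sites = {
        substrate: global_cluster(
            locals_,
            cfg.jaccard_cutoff,
            cfg.min_cluster_size,
            cfg.linkage,
            cfg.aggregator,
        )
        for substrate, locals_ in by_substrate.items()
        if locals_
    }
    return merge_sites_across_substrates(
        per_substrate_sites, cfg.jaccard_cutoff, cfg.linkage, cfg.aggregator
    )


@_stage("select")
def _select_stage(
    sites: Sequence[BindingSite], cfg: RunConfig
) -> tuple[dict[str, set[int]], list[ResidueProfile], set[int]]:
    selection = SelectionConfig(
        fraction=cfg.fraction,
        excluded_residues=frozenset(cfg.excluded_residues),
        exclusion_overlap_min=cfg.exclusion_overlap_min,
    )
    site_residues = {s.site_id: s.residues for s in sites}
    substrates = sorted({sub for s in sites for sub in s.time_table})
    key_by_substrate: dict[str, set[int]] = {}
    for substrate in substrates:
        table = {
            s.site_id: s.time_table[substrate]
            for s in sites
            if substrate in s.time_table
        }
        key_by_substrate[substrate] = select_key_sites(table, site_residues, selection)
    # Per-substrate selections are unioned before residue profiling, so a
    # residue keyed by any substrate can enter the library.
    key_ids = set().union(*key_by_substrate.values()) if key_by_substrate else set()
    key_sites = [s for s in sites if s.site_id in key_ids]
    profiles = build_residue_profiles(key_sites)
    residues = select_key_residues(profiles) if profiles else set()
    return key_by_substrate, profiles, residues


@_stage("design")
def _design_stage(
    profiles: Sequence[ResidueProfile],
    key_residues: set[int],
    ddg: DdgTable,
    cfg: RunConfig,
):
    times = {
        p.residue_index: p.median_time_ns
        for p in profiles
        if p.residue_index in key_residues
    }
    table = ddg.flipped() if cfg.flip_ddg_sign else ddg
    return propose_library(
        times,
        table,
        max_size=cfg.max_size,
        ddg_max_kcal_mol=cfg.ddg_max_kcal_mol,
        max_variants_per_position=cfg.max_variants_per_position,
    )


def run_pipeline(
    cfg: RunConfig,
    matrices: Sequence[ContactMatrix],
    outdir: str | Path,
    ddg: DdgTable | None = None,
) -> PipelineResult:
    """Run cluster → select → design on precomputed contact matrices.

    Writes ``sites.json``, ``table.tsv``, ``key_residues.json`` and (when a
    ΔΔG table is supplied) ``library.tsv`` under ``outdir``, each embedding
    the configuration hash.  Deterministic given config and inputs.
    """
    cfg.validate()
    if not matrices:
        raise StageError("stage 'cluster' failed: no contact matrices supplied")
    digest = config_hash(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sites = _cluster_stage(matrices, cfg)
    sites_path = outdir / "sites.json"
    write_sites_json(sites, sites_path, config_hash=digest)
    table_path = outdir / "table.tsv"
    table_path.write_text(
        site_time_table_report(sites, config_hash=digest), encoding="utf-8"
    )

    key_by_substrate, profiles, key_residues = _select_stage(sites, cfg)
    key_path = outdir / "key_residues.json"
    key_payload = {
        "config_hash": digest,
        "key_sites": {k: sorted(v) for k, v in sorted(key_by_substrate.items())},
        "profiles": [
            {
                "residue": p.residue_index,
                "median_time_ns": p.median_time_ns,
                "n_observations": len(p.times_ns),
            }
            for p in profiles
        ],
        "key_residues": sorted(key_residues),
    }
    key_path.write_text(json.dumps(key_payload, indent=2) + "\n", encoding="utf-8")

    outputs = {"sites": sites_path, "table": table_path, "key_residues": key_path}
    library = []
    if ddg is not None:
        library = _design_stage(profiles, key_residues, ddg, cfg)
        library_path = outdir / "library.tsv"
        library_path.write_text(
            render_library(library, config_hash=digest), encoding="utf-8"
        )
        outputs["library"] = library_path

    return PipelineResult(
        sites=sites,
        key_sites_by_substrate=key_by_substrate,
        profiles=profiles,
        key_residues=key_residues,
        library=library,
        config_hash=digest,
        outputs=outputs,
    )
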