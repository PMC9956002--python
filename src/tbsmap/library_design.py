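"""Ranked single-point mutant library from key residues and a ΔΔG table.

A FoldX-style folding free-energy table (ΔΔG per position × substitution,
kcal/mol, positive = destabilizing) is consumed as input, never computed.
Candidates at key residues are kept when their ΔΔG is at or below a
neutrality threshold (default +0.5 kcal/mol) and ranked by a deterministic
total order:

1. physicochemical-change score, descending — favouring swaps that most alter
   the chemical character of the site (aliphatic↔aromatic, charged→uncharged,
   positive↔negative, nonpolar↔polar/charged);
2. ΔΔG, ascending (more stabilizing first);
3. the residue's median ligand-interaction time, descending;
4. position ascending, then mutant letter alphabetical.

The list is truncated per position (default 3 variants) and overall (default
10 mutants, the intended smart-library size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AA_LETTERS",
    "DdgFormatError",
    "DdgTable",
    "MutationCandidate",
    "read_ddg_table",
    "write_ddg_table",
    "physchem_change_score",
    "propose_library",
    "render_library",
]

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")

ALIPHATIC = frozenset("AVLIMGP")  # aliphatic / small nonpolar
AROMATIC = frozenset("FWY")
POLAR = frozenset("STNQC")  # polar uncharged
POSITIVE = frozenset("KRH")
NEGATIVE = frozenset("DE")

_CLASS = {}
for _name, _members in (
    ("aliphatic", ALIPHATIC),
    ("aromatic", AROMATIC),
    ("polar", POLAR),
    ("positive", POSITIVE),
    ("negative", NEGATIVE),
):
    for _aa in _members:
        _CLASS[_aa] = _name


class DdgFormatError(ValueError):
    """ΔΔG table violates the TSV dialect."""


@dataclass
class DdgTable:
    """Predicted folding free-energy changes: (position, mutant) → kcal/mol."""

    entries: dict[tuple[int, str], float]
    wt_aa: dict[int, str]

    def __post_init__(self) -> None:
        for (pos, mut), _ in self.entries.items():
            wt = self.wt_aa.get(pos)
            if wt is None:
                raise DdgFormatError(f"position {pos} has entries but no WT letter")
            if mut == wt:
                raise DdgFormatError(f"entry {pos}{mut} equals the WT residue")
    @property
    def positions(self) -> list[int]:
        return sorted(self.wt_aa)

    def get(self, position: int, mut_aa: str) -> float:
        return self.entries[(position, mut_aa)]

    def mutations_at(self, position: int) -> list[str]:
        return sorted(m for (p, m) in self.entries if p == position)

    def flipped(self) -> "DdgTable":
        """Sign-flipped copy, for tables using the opposite ΔΔG orientation."""
        return DdgTable(
            entries={k: -v for k, v in self.entries.items()},
            wt_aa=dict(self.wt_aa),
        )


def _check_letter(letter: str, context: str) -> str:
    letter = str(letter).strip().upper()
    if letter not in AA_LETTERS:
        raise DdgFormatError(f"{context}: {letter!r} is not an amino-acid letter")
    return letter


def read_ddg_table(path: str | Path) -> DdgTable:
    """Read a ΔΔG TSV with columns position, wt_aa, mut_aa, ddg_kcal_mol.

    Duplicate (position, mutant) rows keep the last value with a warning; a
    row whose mutant equals its wild-type letter is a format error.
    """
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty ΔΔG table")
        return DdgTable(entries={}, wt_aa={})
    required = {"position", "wt_aa", "mut_aa", "ddg_kcal_mol"}
    if missing := required - set(frame.columns):
        raise DdgFormatError(f"{path}: missing column(s) {sorted(missing)}")
    entries: dict[tuple[int, str], float] = {}
    wt_aa: dict[int, str] = {}
    for row in frame.itertuples(index=False):
        pos = int(row.position)
        wt = _check_letter(row.wt_aa, f"{path} position {pos}")
        mut = _check_letter(row.mut_aa, f"{path} position {pos}")
        if wt == mut:
            raise DdgFormatError(
                f"{path}: position {pos} lists mutant equal to WT ({wt})"
            )
        if pos in wt_aa and wt_aa[pos] != wt:
            raise DdgFormatError(
                f"{path}: conflicting WT letters at position {pos}"
            )
        if (pos, mut) in entries:
            warnings.warn(f"{path}: duplicate row for {wt}{pos}{mut}; last wins")
        wt_aa[pos] = wt
        entries[(pos, mut)] = float(row.ddg_kcal_mol)
    return DdgTable(entries=entries, wt_aa=wt_aa)


def write_ddg_table(table: DdgTable, path: str | Path) -> None:
    lines = ["position\twt_aa\tmut_aa\tddg_kcal_mol"]
    for (pos, mut), ddg in sorted(table.entries.items()):
        lines.append(f"{pos}\t{table.wt_aa[pos]}\t{mut}\t{ddg:.4f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def physchem_change_score(wt_aa: str, mut_aa: str) -> int:
    """Score how strongly a substitution alters physicochemical character.

    2 — preferred swaps: aliphatic↔aromatic, charged→polar-uncharged,
    positive↔negative, and nonpolar↔polar/charged.
    1 — any other cross-class change (polar-uncharged → charged).
    0 — within one class.
    """
    wt = str(wt_aa).strip().upper()
    mut = str(mut_aa).strip().upper()
    for letter in (wt, mut):
        if letter not in AA_LETTERS:
            raise ValueError(f"{letter!r} is not an amino-acid letter")
    cw, cm = _CLASS[wt], _CLASS[mut]
    if cw == cm:
        return 0
    charged = {"positive", "negative"}
    nonpolar = {"aliphatic", "aromatic"}
    if {cw, cm} == nonpolar or {cw, cm} == charged:
        return 2
    if cw in charged and cm == "polar":
        return 2
    if (cw in nonpolar) != (cm in nonpolar):  # nonpolar <-> polar/charged
        return 2
    return 1  # polar-uncharged -> charged


@dataclass(frozen=True)
class MutationCandidate:
    """A ranked single-point mutation passing the stability filter."""

    position: int
    wt_aa: str
    mut_aa: str
    ddg_kcal_mol: float
    physchem_score: int
    residue_median_time_ns: float
    rank: int

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def propose_library(
    key_residues: Mapping[int, float],
    ddg: DdgTable,
    max_size: int = 10,
    ddg_max_kcal_mol: float = 0.5,
    max_variants_per_position: int = 3,
) -> list[MutationCandidate]:
    """Build the ranked mutant library.

    Parameters
    ----------
    key_residues
        Position → median ligand-interaction time (ns) of the key residues.
    ddg
        Folding free-energy table; key positions missing from it are reported
        with a warning and skipped.
    """
    if max_size < 0 or max_variants_per_position < 1:
        raise ValueError("max_size must be >= 0 and max_variants_per_position >= 1")
    pool: list[tuple] = []
    for position in sorted(key_residues):
        if position not in ddg.wt_aa:
            warnings.warn(f"key residue {position} absent from the ΔΔG table; skipped")
            continue
        wt = ddg.wt_aa[position]
        for mut in ddg.mutations_at(position):
            value = ddg.get(position, mut)
            if value <= ddg_max_kcal_mol:
                score = physchem_change_score(wt, mut)
                pool.append(
                    (
                        -score,
                        value,
                        -float(key_residues[position]),
                        position,
                        mut,
                        wt,
                    )
                )
    pool.sort()
    library: list[MutationCandidate] = []
    per_position: dict[int, int] = {}
    for neg_score, value, neg_time, position, mut, wt in pool:
        if per_position.get(position, 0) >= max_variants_per_position:
            continue
        if len(library) >= max_size:
            break
        per_position[position] = per_position.get(position, 0) + 1
        library.append(
            MutationCandidate(
                position=position,
                wt_aa=wt,
                mut_aa=mut,
                ddg_kcal_mol=value,
                physchem_score=-neg_score,
                residue_median_time_ns=-neg_time,
                rank=len(library) + 1,
            )
        )
    return library


def render_library(
    candidates: Iterable[MutationCandidate], config_hash: str | None = None
) -> str:
    """Library TSV: rank, mutation, ddg, physchem_score, median_time_ns."""
    lines = []
    if config_hash is not None:
        lines.append(f"#config_hash={config_hash}")
    lines.append("rank\tmutation\tddg_kcal_mol\tphyschem_score\tmedian_time_ns")
    for c in candidates:
        lines.append(
            f"{c.rank}\t{c.label}\t{c.ddg_kcal_mol:.2f}\t{c.physchem_score}"
            f"\t{c.residue_median_time_ns:.2f}"
        )
    return "\n".join(lines) + "\n"
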