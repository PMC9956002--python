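"""Sparse enzyme–ligand contact matrices from MD trajectories.

The elementary record of the pipeline is a binary residue × frame matrix for
one (substrate, replica) simulation: entry ``(r, f)`` is set when any atom of
protein residue ``r`` lies within a distance cutoff (default 2.7 Å, boundary
inclusive) of any atom of any free ligand copy in saved frame ``f``.
Transient surface binding is rare on the simulation time scale, so these
matrices are sparse and stored as explicit per-residue frame-index arrays,
with the frame spacing (``dt_ps``, picoseconds between saved frames, default
2 ps) carried as metadata so that contact counts convert to interaction times.

The required trajectory dialect is multi-model PDB (MODEL/ENDMDL records),
read through :func:`read_multimodel_pdb`.  Any reader that produces a
:class:`Trajectory` — a coordinate stack with per-atom residue labels — can be
plugged in instead; periodic-image minimum-distance correction is *not*
applied (a documented limitation of the plain-PDB path).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ContactMapError",
    "ConfigurationError",
    "MalformedTrajectoryError",
    "ContactTableFormatError",
    "ContactTableValidationError",
    "Trajectory",
    "ContactMatrix",
    "read_multimodel_pdb",
    "detect_contacts",
    "detect_contacts_per_copy",
    "residue_interaction_time",
    "read_contact_table",
    "write_contact_table",
]

#: Residue names accepted as protein (standard 20 plus common MD protonation
#: variants and selenomethionine).
STANDARD_AA = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HIE HID HIP CYX CYM ASH GLH LYN MSE""".split()
)


class ContactMapError(ValueError):
    """Base error for contact-map construction and I/O."""


class ConfigurationError(ContactMapError):
    """Invalid selection or parameter (e.g. empty ligand selection)."""


class MalformedTrajectoryError(ContactMapError):
    """Trajectory violates the reader contract (e.g. varying atom counts)."""


class ContactTableFormatError(ContactMapError):
    """Contact-table TSV misses required metadata or is syntactically broken."""


class ContactTableValidationError(ContactMapError):
    """Contact-table TSV carries out-of-range indices."""


@dataclass(frozen=True)
class Trajectory:
    """Coordinate stack with per-atom labels; the pluggable reader contract.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.  All frames share one
        atom ordering; readers must enforce this.
    res_name, res_id, chain_id, element
        Per-atom label arrays of length ``n_atoms``.
    """

    coords: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise MalformedTrajectoryError(
                f"coords must have shape (n_frames, n_atoms, 3), got {coords.shape}"
            )
        if coords.shape[0] == 0:
            raise MalformedTrajectoryError("trajectory has no frames")
        object.__setattr__(self, "coords", coords)
        n_atoms = coords.shape[1]
        for name in ("res_name", "res_id", "chain_id", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise MalformedTrajectoryError(
                    f"{name} has length {arr.shape}, expected ({n_atoms},)"
                )
            object.__setattr__(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB file (MODEL/ENDMDL records) into a Trajectory.

    Atom ordering must be identical across models; a mismatch raises
    :class:`MalformedTrajectoryError`.
    """
    from biotite.structure.io.pdb import PDBFile
    import biotite.structure as struc

    pdb = PDBFile.read(str(path))
    try:
        structure = pdb.get_structure()
    except Exception as exc:  # biotite raises on inconsistent models
        raise MalformedTrajectoryError(
            f"could not read {path} as a multi-model PDB trajectory: {exc}"
        ) from exc
    if isinstance(structure, struc.AtomArray):
        coords = structure.coord[None, :, :]
        atoms = structure
    else:
        coords = structure.coord
        atoms = structure[0]
    # PDB coordinates carry exactly three decimals; rounding the parser's
    # float32 values back to that precision keeps printed distances exact
    # (the boundary rule d <= cutoff is inclusive).
    coords = np.round(np.asarray(coords, dtype=float), 3)
    return Trajectory(
        coords=coords,
        res_name=np.asarray(atoms.res_name),
        res_id=np.asarray(atoms.res_id),
        chain_id=np.asarray(atoms.chain_id),
        element=np.asarray(atoms.element),
    )


@dataclass
class ContactMatrix:
    """Binary residue × frame contact record for one (substrate, replica).

    Residue indices are 1-based sequential over the protein chain as
    encountered in the structure file; frame indices are 0-based.  ``contacts``
    maps a residue index to the sorted, unique array of frames in which it
    touches the ligand.
    """

    substrate_id: str
    replica_id: str
    n_residues: int
    n_frames: int
    dt_ps: float = 2.0
    contacts: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ContactMapError(f"n_residues must be positive, got {self.n_residues}")
        if self.n_frames < 1:
            raise ContactMapError(f"n_frames must be positive, got {self.n_frames}")
        if not self.dt_ps > 0:
            raise ContactMapError(f"dt_ps must be positive, got {self.dt_ps}")
        clean: dict[int, np.ndarray] = {}
        for res, frames in self.contacts.items():
            res = int(res)
            if not 1 <= res <= self.n_residues:
                raise ContactMapError(
                    f"residue index {res} outside [1, {self.n_residues}]"
                )
            arr = np.unique(np.asarray(frames, dtype=np.int64))
            if arr.size == 0:
                continue
            if arr[0] < 0 or arr[-1] >= self.n_frames:
                raise ContactMapError(
                    f"frame index outside [0, {self.n_frames - 1}] for residue {res}"
                )
            clean[res] = arr
        self.contacts = clean

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[int, int]],
        *,
        substrate_id: str,
        replica_id: str,
        n_residues: int,
        n_frames: int,
        dt_ps: float = 2.0,
    ) -> "ContactMatrix":
        by_res: dict[int, list[int]] = {}
        for res, frame in entries:
            by_res.setdefault(int(res), []).append(int(frame))
        return cls(
            substrate_id=substrate_id,
            replica_id=replica_id,
            n_residues=n_residues,
            n_frames=n_frames,
            dt_ps=dt_ps,
            contacts={r: np.asarray(f) for r, f in by_res.items()},
        )

    @property
    def entries(self) -> set[tuple[int, int]]:
        """The contact record as a set of (residue_index, frame_index) pairs."""
        return {
            (res, int(f)) for res, frames in self.contacts.items() for f in frames
        }

    @property
    def n_entries(self) -> int:
        return sum(len(f) for f in self.contacts.values())

    @property
    def active_residues(self) -> list[int]:
        """Residues with at least one contact frame, ascending."""
        return sorted(self.contacts)

    def frames_for(self, residue_index: int) -> np.ndarray:
        self._check_residue(residue_index)
        return self.contacts.get(int(residue_index), np.empty(0, dtype=np.int64))

    def support(self, residue_index: int) -> frozenset[int]:
        """The residue's frame support as a set (the unit entering clustering)."""
        return frozenset(int(f) for f in self.frames_for(residue_index))

    def interaction_time_ns(self, residue_index: int) -> float:
        """Total ligand-contact time of one residue: #frames × dt_ps / 1000."""
        return len(self.frames_for(residue_index)) * self.dt_ps / 1000.0

    def union_time_ns(self, residues: Iterable[int]) -> float:
        """Occupancy time of a residue group: union of frame supports × dt."""
        union: set[int] = set()
        for res in residues:
            union.update(int(f) for f in self.frames_for(res))
        return len(union) * self.dt_ps / 1000.0

    def to_dense(self) -> np.ndarray:
        """Boolean (n_residues, n_frames) matrix; row r-1 is residue r."""
        dense = np.zeros((self.n_residues, self.n_frames), dtype=bool)
        for res, frames in self.contacts.items():
            dense[res - 1, frames] = True
        return dense

    def _check_residue(self, residue_index: int) -> None:
        if not 1 <= int(residue_index) <= self.n_residues:
            raise ContactMapError(
                f"residue index {residue_index} outside [1, {self.n_residues}]"
            )


def residue_interaction_time(m: ContactMatrix, residue_index: int) -> float:
    """Interaction time of one residue in ns (see ContactMatrix method)."""
    return m.interaction_time_ns(residue_index)


def _protein_residue_ordinals(
    trajectory: Trajectory, protein_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """1-based sequential residue ordinal for each protein atom."""
    ordinals = np.zeros(trajectory.n_atoms, dtype=np.int64)
    seen: dict[tuple, int] = {}
    for idx in np.flatnonzero(protein_mask):
        key = (str(trajectory.chain_id[idx]), int(trajectory.res_id[idx]))
        if key not in seen:
            seen[key] = len(seen) + 1
        ordinals[idx] = seen[key]
    return ordinals, len(seen)


def _contact_entries(
    trajectory: Trajectory,
    protein_atoms: np.ndarray,
    ligand_atoms: np.ndarray,
    ordinals: np.ndarray,
    n_residues: int,
    cutoff: float,
) -> Iterator[tuple[int, int]]:
    # Squared-distance comparison keeps the boundary case d == cutoff exact
    # for axis-aligned offsets that parse to the same double as the cutoff.
    cutoff2 = float(cutoff) ** 2
    ord0 = ordinals[protein_atoms] - 1
    for frame in range(trajectory.n_frames):
        prot_xyz = trajectory.coords[frame, protein_atoms]
        lig_xyz = trajectory.coords[frame, ligand_atoms]
        d2 = cdist(prot_xyz, lig_xyz, metric="sqeuclidean").min(axis=1)
        res_min = np.full(n_residues, np.inf)
        np.minimum.at(res_min, ord0, d2)
        for res in np.flatnonzero(res_min <= cutoff2):
            yield int(res) + 1, frame


def _selections(
    trajectory: Trajectory, ligand_selection: str, heavy_atoms_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    res_name = np.char.strip(trajectory.res_name.astype(str))
    ligand_mask = res_name == ligand_selection
    if not ligand_mask.any():
        raise ConfigurationError(
            f"ligand selection {ligand_selection!r} matches no atoms"
        )
    protein_mask = np.isin(res_name, sorted(STANDARD_AA)) & ~ligand_mask
    if not protein_mask.any():
        raise ConfigurationError("no protein residues found in trajectory")
    if heavy_atoms_only:
        heavy = np.char.strip(trajectory.element.astype(str)).astype("U2") != "H"
        ligand_mask &= heavy
        protein_mask &= heavy
        if not ligand_mask.any():
            raise ConfigurationError("ligand selection empty after removing hydrogens")
    return protein_mask, ligand_mask


def detect_contacts(
    trajectory: Trajectory,
    ligand_selection: str,
    cutoff_angstrom: float = 2.7,
    *,
    heavy_atoms_only: bool = False,
    dt_ps: float = 2.0,
    substrate_id: str = "",
    replica_id: str = "",
) -> ContactMatrix:
    """Detect per-frame enzyme–ligand contacts.

    A protein residue is in contact in a frame when the minimum distance
    between any of its atoms and any atom of *any* ligand copy is less than or
    equal to ``cutoff_angstrom`` (default 2.7 Å).  All atoms are used unless
    ``heavy_atoms_only`` drops hydrogens from both selections.

    Parameters
    ----------
    trajectory
        Frame stack with identical atom ordering in every frame.
    ligand_selection
        Residue name of the ligand copies (e.g. ``"LIG"``); must be disjoint
        from the protein selection.
    """
    if not cutoff_angstrom > 0:
        raise ConfigurationError(f"cutoff must be positive, got {cutoff_angstrom}")
    protein_mask, ligand_mask = _selections(
        trajectory, ligand_selection, heavy_atoms_only
    )
    ordinals, n_residues = _protein_residue_ordinals(trajectory, protein_mask)
    entries = _contact_entries(
        trajectory,
        np.flatnonzero(protein_mask),
        np.flatnonzero(ligand_mask),
        ordinals,
        n_residues,
        cutoff_angstrom,
    )
    return ContactMatrix.from_entries(
        entries,
        substrate_id=substrate_id,
        replica_id=replica_id,
        n_residues=n_residues,
        n_frames=trajectory.n_frames,
        dt_ps=dt_ps,
    )


def detect_contacts_per_copy(
    trajectory: Trajectory,
    ligand_selection: str,
    cutoff_angstrom: float = 2.7,
    *,
    heavy_atoms_only: bool = False,
    dt_ps: float = 2.0,
    substrate_id: str = "",
    replica_id: str = "",
) -> dict[str, ContactMatrix]:
    """Diagnostic variant: one contact matrix per individual ligand copy.

    Copies are distinguished by their (chain, residue id) in the structure
    file.  The union of the returned matrices equals :func:`detect_contacts`.
    """
    protein_mask, ligand_mask = _selections(
        trajectory, ligand_selection, heavy_atoms_only
    )
    ordinals, n_residues = _protein_residue_ordinals(trajectory, protein_mask)
    copies: dict[str, list[int]] = {}
    for idx in np.flatnonzero(ligand_mask):
        key = f"{trajectory.chain_id[idx]}:{int(trajectory.res_id[idx])}"
        copies.setdefault(key, []).append(int(idx))
    out: dict[str, ContactMatrix] = {}
    for key, atom_idx in copies.items():
        entries = _contact_entries(
            trajectory,
            np.flatnonzero(protein_mask),
            np.asarray(atom_idx),
            ordinals,
            n_residues,
            cutoff_angstrom,
        )
        out[key] = ContactMatrix.from_entries(
            entries,
            substrate_id=substrate_id,
            replica_id=f"{replica_id}/{key}",
            n_residues=n_residues,
            n_frames=trajectory.n_frames,
            dt_ps=dt_ps,
        )
    return out


# ---------------------------------------------------------------------------
# Contact-table TSV dialect:
#   #substrate=<id> / #replica=<id> / #n_residues=<int> / #n_frames=<int>
#   #dt_ps=<float>, then one "residue_index<TAB>frame_index" row per entry.
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("substrate", "replica", "n_residues", "n_frames", "dt_ps")


def write_contact_table(
    m: ContactMatrix, path: str | Path, *, config_hash: str | None = None
) -> None:
    """Write the contact-table TSV (UTF-8, LF newlines); round-trips exactly."""
    lines = []
    if config_hash is not None:
        lines.append(f"#config_hash={config_hash}")
    lines += [
        f"#substrate={m.substrate_id}",
        f"#replica={m.replica_id}",
        f"#n_residues={m.n_residues}",
        f"#n_frames={m.n_frames}",
        f"#dt_ps={m.dt_ps:g}",
    ]
    for res in m.active_residues:
        for frame in m.contacts[res]:
            lines.append(f"{res}\t{int(frame)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_contact_table(path: str | Path) -> ContactMatrix:
    """Read a contact-table TSV written by :func:`write_contact_table`."""
    meta: dict[str, str] = {}
    entries: list[tuple[int, int]] = []
    body: list[tuple[int, int, int]] = []  # (lineno, residue, frame)
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ContactTableFormatError(
                    f"{path}:{lineno}: expected 'residue<TAB>frame', got {line!r}"
                )
            try:
                body.append((lineno, int(parts[0]), int(parts[1])))
            except ValueError as exc:
                raise ContactTableFormatError(
                    f"{path}:{lineno}: non-integer index in {line!r}"
                ) from exc
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise ContactTableFormatError(
            f"{path}: missing metadata header key(s): {', '.join(missing)}"
        )
    n_residues = int(meta["n_residues"])
    n_frames = int(meta["n_frames"])
    for lineno, res, frame in body:
        if not 1 <= res <= n_residues:
            raise ContactTableValidationError(
                f"{path}:{lineno}: residue index {res} outside [1, {n_residues}]"
            )
        if not 0 <= frame < n_frames:
            raise ContactTableValidationError(
                f"{path}:{lineno}: frame index {frame} outside [0, {n_frames - 1}]"
            )
        entries.append((res, frame))
    return ContactMatrix.from_entries(
        entries,
        substrate_id=meta["substrate"],
        replica_id=meta["replica"],
        n_residues=n_residues,
        n_frames=n_frames,
        dt_ps=float(meta["dt_ps"]),
    )
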