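"""Contact detection against a brute-force distance oracle, and table I/O."""

from __future__ import annotations

import numpy as np
import pytest

from tbsmap import (
    ContactMatrix,
    Trajectory,
    detect_contacts,
    read_contact_table,
    read_multimodel_pdb,
    residue_interaction_time,
    write_contact_table,
)
from tbsmap.contact_map import (
    ConfigurationError,
    ContactMapError,
    ContactTableFormatError,
    ContactTableValidationError,
    MalformedTrajectoryError,
    detect_contacts_per_copy,
)
from tbsmap.synthetic_data import generate_toy_system

from conftest import brute_force_min_distance


def _toy_trajectory(lig_positions, n_residues=2):
    """One protein CA per residue at x=5(i-1); ligand atom per frame."""
    frames = []
    for pos in lig_positions:
        atoms = [[5.0 * i, 0.0, 0.0] for i in range(n_residues)]
        atoms.append(list(pos))
        frames.append(atoms)
    coords = np.asarray(frames, dtype=float)
    return Trajectory(
        coords=coords,
        res_name=np.asarray(["ALA"] * n_residues + ["LIG"]),
        res_id=np.asarray(list(range(1, n_residues + 1)) + [99]),
        chain_id=np.asarray(["A"] * n_residues + ["B"]),
        element=np.asarray(["C"] * n_residues + ["CL"]),
    )


class TestDetectContacts:
    def test_single_close_approach_recorded_once(self):
        # ligand 2.50 Å from residue 1 in frame 0 only
        traj = _toy_trajectory([(0.0, 0.0, 2.5), (0.0, 0.0, 30.0)])
        m = detect_contacts(traj, "LIG", 2.7)
        assert m.entries == {(1, 0)}

    def test_boundary_distance_is_inclusive(self):
        traj = _toy_trajectory([(0.0, 0.0, 2.7)])
        m = detect_contacts(traj, "LIG", 2.7)
        assert (1, 0) in m.entries

    def test_distant_ligand_yields_empty_matrix(self):
        traj = _toy_trajectory([(50.0, 50.0, 50.0)] * 3)
        m = detect_contacts(traj, "LIG", 2.7)
        assert m.entries == set()

    def test_empty_ligand_selection_is_configuration_error(self):
        traj = _toy_trajectory([(0.0, 0.0, 2.5)])
        with pytest.raises(ConfigurationError):
            detect_contacts(traj, "XYZ", 2.7)

    def test_matches_brute_force_oracle_on_random_frames(self, rng):
        """Detection equals the all-pairs distance rule on random geometry."""
        n_prot, n_lig, n_frames, cutoff = 6, 3, 100, 2.7
        coords = rng.uniform(0, 8, size=(n_frames, n_prot + n_lig, 3))
        traj = Trajectory(
            coords=coords,
            res_name=np.asarray(["ALA", "ALA", "GLY", "GLY", "LYS", "LYS"] + ["LIG"] * n_lig),
            res_id=np.asarray([1, 1, 2, 2, 3, 3] + [91, 92, 93]),
            chain_id=np.asarray(["A"] * n_prot + ["B"] * n_lig),
            element=np.asarray(["C"] * (n_prot + n_lig)),
        )
        m = detect_contacts(traj, "LIG", cutoff)
        expected = set()
        residue_atoms = {1: [0, 1], 2: [2, 3], 3: [4, 5]}
        for f in range(n_frames):
            for res, atoms in residue_atoms.items():
                d = brute_force_min_distance(
                    coords[f, atoms], coords[f, n_prot:]
                )
                if d <= cutoff:
                    expected.add((res, f))
        assert m.entries == expected

    def test_translation_invariance(self, rng):
        coords = rng.uniform(0, 6, size=(20, 3, 3))
        labels = dict(
            res_name=np.asarray(["ALA", "ALA", "LIG"]),
            res_id=np.asarray([1, 1, 9]),
            chain_id=np.asarray(["A", "A", "B"]),
            element=np.asarray(["C", "C", "CL"]),
        )
        m1 = detect_contacts(Trajectory(coords=coords, **labels), "LIG")
        shifted = coords + np.asarray([123.0, -55.0, 17.0])
        m2 = detect_contacts(Trajectory(coords=shifted, **labels), "LIG")
        assert m1.entries == m2.entries

    def test_any_ligand_copy_counts_and_per_copy_union(self, rng):
        """A residue contacts if ANY copy is close; per-copy matrices union
        to the combined one."""
        n_frames = 30
        coords = rng.uniform(0, 10, size=(n_frames, 4, 3))
        labels = dict(
            res_name=np.asarray(["ALA", "ALA", "LIG", "LIG"]),
            res_id=np.asarray([1, 2, 91, 92]),
            chain_id=np.asarray(["A", "A", "B", "B"]),
            element=np.asarray(["C", "C", "CL", "CL"]),
        )
        traj = Trajectory(coords=coords, **labels)
        combined = detect_contacts(traj, "LIG", 4.0)
        per_copy = detect_contacts_per_copy(traj, "LIG", 4.0)
        assert len(per_copy) == 2
        union = set().union(*(m.entries for m in per_copy.values()))
        assert union == combined.entries


class TestToyPdbRoundTrip:
    def test_scripted_contact_window_recovered(self, tmp_path):
        text = generate_toy_system(
            4, 50, target_residue=3, contact_frames=range(10, 20)
        )
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        traj = read_multimodel_pdb(path)
        assert traj.n_frames == 50
        m = detect_contacts(traj, "LIG", 2.7)
        assert m.entries == {(3, f) for f in range(10, 20)}

    def test_exact_270_distance_in_pdb_is_contact(self, tmp_path):
        text = generate_toy_system(
            2, 5, target_residue=1, contact_frames=[2], contact_distance=2.7
        )
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        m = detect_contacts(read_multimodel_pdb(path), "LIG", 2.7)
        assert m.entries == {(1, 2)}

    def test_empty_contact_window(self, tmp_path):
        text = generate_toy_system(2, 5, contact_frames=[])
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        m = detect_contacts(read_multimodel_pdb(path), "LIG", 2.7)
        assert m.entries == set()


class TestInteractionTime:
    def test_examples(self):
        m = ContactMatrix.from_entries(
            [(1, f) for f in range(500)],
            substrate_id="S",
            replica_id="r",
            n_residues=3,
            n_frames=50000,
            dt_ps=2.0,
        )
        assert residue_interaction_time(m, 1) == pytest.approx(1.0)
        assert residue_interaction_time(m, 2) == 0.0
        full = ContactMatrix.from_entries(
            [(1, f) for f in range(50000)],
            substrate_id="S",
            replica_id="r",
            n_residues=1,
            n_frames=50000,
            dt_ps=2.0,
        )
        assert residue_interaction_time(full, 1) == pytest.approx(100.0)

    def test_out_of_range_residue_rejected(self):
        m = ContactMatrix.from_entries(
            [(1, 0)], substrate_id="S", replica_id="r", n_residues=2, n_frames=5
        )
        with pytest.raises(ContactMapError):
            residue_interaction_time(m, 3)

    def test_sum_of_residue_times_bounds_union_time(self, rng):
        """Σ residue times >= union occupancy; equality iff no frame has two
        contacting residues."""
        for _ in range(20):
            n_res, n_frames = 5, 40
            dense = rng.random((n_res, n_frames)) < 0.2
            contacts = {
                r + 1: np.flatnonzero(dense[r]) for r in range(n_res) if dense[r].any()
            }
            if not contacts:
                continue
            m = ContactMatrix(
                substrate_id="S",
                replica_id="r",
                n_residues=n_res,
                n_frames=n_frames,
                contacts=contacts,
            )
            total = sum(m.interaction_time_ns(r) for r in range(1, n_res + 1))
            union = m.union_time_ns(range(1, n_res + 1))
            assert total >= union - 1e-12
            multi = (dense.sum(axis=0) > 1).any()
            assert (abs(total - union) < 1e-12) == (not multi)


class TestContactTableIO:
    def test_documented_example(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "#substrate=S\n#replica=r1\n#n_residues=5\n#n_frames=10\n#dt_ps=2\n"
            "3\t0\n3\t1\n"
        )
        m = read_contact_table(path)
        assert m.entries == {(3, 0), (3, 1)}
        assert m.dt_ps == 2.0

    def test_round_trip_random_matrix(self, tmp_path, rng):
        dense = rng.random((50, 1000)) < 0.01
        contacts = {
            r + 1: np.flatnonzero(dense[r]) for r in range(50) if dense[r].any()
        }
        m = ContactMatrix(
            substrate_id="SYN",
            replica_id="r07",
            n_residues=50,
            n_frames=1000,
            dt_ps=2.0,
            contacts=contacts,
        )
        path = tmp_path / "m.tsv"
        write_contact_table(m, path)
        m2 = read_contact_table(path)
        assert m2.entries == m.entries
        assert (m2.substrate_id, m2.replica_id) == ("SYN", "r07")
        assert (m2.n_residues, m2.n_frames, m2.dt_ps) == (50, 1000, 2.0)

    def test_missing_header_key_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#substrate=S\n#replica=r\n#n_residues=5\n1\t0\n")
        with pytest.raises(ContactTableFormatError, match="n_frames"):
            read_contact_table(path)

    def test_zero_residue_index_is_validation_error_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#substrate=S\n#replica=r\n#n_residues=5\n#n_frames=10\n#dt_ps=2\n"
            "0\t3\n"
        )
        with pytest.raises(ContactTableValidationError, match=":6:"):
            read_contact_table(path)


def test_mismatched_atom_counts_rejected():
    with pytest.raises(MalformedTrajectoryError):
        Trajectory(
            coords=np.zeros((2, 3, 3)),
            res_name=np.asarray(["ALA", "LIG"]),  # wrong length
            res_id=np.asarray([1, 9, 9]),
            chain_id=np.asarray(["A", "B", "B"]),
            element=np.asarray(["C", "CL", "CL"]),
        )
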