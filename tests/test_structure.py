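"""Trimer interface metrics: contacts, C-alpha statistics, SASA."""

import numpy as np
import pytest
import biotite.structure as struc

import itemfive as i5
from itemfive.structure import ContactCriteria

MINIMAL_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


def _atoms(records):
    """Build an atom array from (chain, res_id, res_name, atom, element, xyz)."""
    arr = struc.AtomArray(len(records))
    coords = np.zeros((len(records), 3))
    for i, (chain, res_id, res_name, atom, element, xyz) in enumerate(records):
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom
        arr.element[i] = element
        coords[i] = xyz
    arr.coord = coords
    return i5.StructureModel(atoms=arr)


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = i5.read_structure(p)
        assert len(model) == 2
        assert model.chains == ["A"]

    def test_synthetic_trimer_round_trip(self, tmp_path, synthetic_trimer):
        model, truth = synthetic_trimer
        path = tmp_path / "trimer.pdb"
        i5.write_structure(model, path)
        back = i5.read_structure(path)
        assert back.chains == ["A", "B", "C"]
        assert len(back) == len(model)
        stats = i5.ca_distance_stats(back)
        assert stats.total == pytest.approx(truth["ca_distance_sum"], abs=1e-2)

    def test_trimer_requirement(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = i5.read_structure(p)
        with pytest.raises(ValueError, match="3 chains"):
            i5.ca_distance_stats(model)


class TestContacts:
    def test_intercatenane_vdw_boundary(self):
        for d, expected in [(3.9, 1), (4.1, 0)]:
            model = _atoms([
                ("A", 1, "ALA", "CB", "C", (0, 0, 0)),
                ("B", 1, "ALA", "CB", "C", (d, 0, 0)),
            ])
            table = i5.classify_contacts(model, ContactCriteria(vdw_cutoff=4.0))
            counts = table.counts().get("vdW", {"inter": 0})
            assert counts["inter"] == expected, d

    def test_salt_bridge_definitional(self):
        model = _atoms([
            ("A", 5, "LYS", "NZ", "N", (0, 0, 0)),
            ("B", 9, "GLU", "OE1", "O", (3.5, 0, 0)),
        ])
        table = i5.classify_contacts(model)
        counts = table.counts()
        assert counts["salt bridge"]["inter"] == 1
        # the same N-O pair also satisfies the generic H-bond criterion
        assert counts["salt bridge"]["total"] == 1

    def test_intra_plus_inter_equals_total(self, synthetic_trimer):
        model, _ = synthetic_trimer
        for row in i5.classify_contacts(model).counts().values():
            assert row["intra"] + row["inter"] == row["total"]

    def test_brute_force_oracle(self, synthetic_trimer):
        """Contact counts equal an O(n^2) all-pairs enumeration."""
        model, _ = synthetic_trimer
        criteria = ContactCriteria()
        atoms = model.atoms
        n = atoms.array_length()
        vdw = hb = 0
        for i in range(n):
            for j in range(n):
                d = np.linalg.norm(atoms.coord[i] - atoms.coord[j])
                same_chain = atoms.chain_id[i] == atoms.chain_id[j]
                inter_ok = same_chain or d <= criteria.intercatenane_cutoff
                # vdW: unordered C-C pairs, excluding covalent/1-3 neighbours
                if j > i and atoms.element[i] == "C" == atoms.element[j]:
                    neighbour = same_chain and abs(
                        int(atoms.res_id[i]) - int(atoms.res_id[j])) <= 1
                    if d <= criteria.vdw_cutoff and not neighbour and inter_ok:
                        vdw += 1
                # H-bond: donor N -> acceptor O, directional enumeration
                if atoms.element[i] == "N" and atoms.element[j] == "O":
                    same_res = same_chain and atoms.res_id[i] == atoms.res_id[j]
                    peptide = (same_chain
                               and {atoms.atom_name[i], atoms.atom_name[j]}
                               == {"N", "O"}
                               and abs(int(atoms.res_id[i])
                                       - int(atoms.res_id[j])) == 1)
                    if d <= criteria.hbond_cutoff and not same_res \
                            and not peptide and inter_ok:
                        hb += 1
        counts = i5.classify_contacts(model, criteria).counts()
        assert counts.get("vdW", {"total": 0})["total"] == vdw
        assert counts.get("hydrogen bond", {"total": 0})["total"] == hb

    def test_invariance_under_rigid_motion_and_relabeling(self, synthetic_trimer):
        model, _ = synthetic_trimer
        base = i5.classify_contacts(model).counts()

        rotated = model.atoms.copy()
        theta = 0.7
        rot = np.array([[np.cos(theta), 0, np.sin(theta)],
                        [0, 1, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        rotated.coord = rotated.coord @ rot.T + np.array([5.0, -3.0, 2.0])
        relabel = {"A": "C", "B": "A", "C": "B"}
        rotated.chain_id = np.array([relabel[c] for c in rotated.chain_id])
        moved = i5.classify_contacts(i5.StructureModel(atoms=rotated)).counts()
        assert moved == base


class TestCaDistances:
    def test_closed_form_sum(self, synthetic_trimer):
        model, truth = synthetic_trimer
        stats = i5.ca_distance_stats(model)
        n = truth["n_residues"]
        assert len(stats.positions) == n
        assert stats.total == pytest.approx(n * 3 * truth["ca_distance"],
                                            abs=1e-9)

    def test_three_equal_distances_per_position(self, synthetic_trimer):
        model, truth = synthetic_trimer
        stats = i5.ca_distance_stats(model)
        for pos in stats.positions:
            assert stats.distances[pos] == pytest.approx(
                [truth["ca_distance"]] * 3, abs=1e-9)
            assert stats.sd[pos] == pytest.approx(0.0, abs=1e-9)

    def test_unmatched_positions_listed(self, synthetic_trimer):
        model, _ = synthetic_trimer
        atoms = model.atoms
        # drop the last residue of chain C only
        keep = ~((atoms.chain_id == "C") & (atoms.res_id == atoms.res_id.max()))
        with pytest.raises(ValueError, match="unmatched"):
            i5.ca_distance_stats(i5.StructureModel(atoms=atoms[keep]))


class TestSasa:
    def test_isolated_atom_analytic_sphere(self):
        model = _atoms([("A", 1, "GLY", "CA", "C", (0, 0, 0))])
        r = 1.7
        total, per_res = i5.sasa(model, probe_radius=1.4,
                                 n_sphere_points=2000, radii=np.array([r]))
        analytic = 4 * np.pi * (r + 1.4) ** 2
        assert total == pytest.approx(analytic, rel=0.01)
        assert per_res[("A", 1)] == pytest.approx(total)

    def test_distant_atoms_additive(self):
        model = _atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("A", 2, "GLY", "CA", "C", (100.0, 0, 0)),
        ])
        radii = np.array([1.7, 1.7])
        total, _ = i5.sasa(model, n_sphere_points=2000, radii=radii)
        single = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(2 * single, rel=0.01)

    def test_occlusion_monotonicity(self):
        far = _atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("B", 1, "GLY", "CA", "C", (10.0, 0, 0)),
        ])
        near = _atoms([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("B", 1, "GLY", "CA", "C", (2.5, 0, 0)),
        ])
        radii = np.array([1.7, 1.7])
        total_far, _ = i5.sasa(far, n_sphere_points=1000, radii=radii)
        total_near, _ = i5.sasa(near, n_sphere_points=1000, radii=radii)
        assert total_near < total_far

    def test_deterministic_for_fixed_points(self, synthetic_trimer):
        model, _ = synthetic_trimer
        radii = np.full(len(model), 1.7)
        t1, _ = i5.sasa(model, n_sphere_points=500, radii=radii)
        t2, _ = i5.sasa(model, n_sphere_points=500, radii=radii)
        assert t1 == t2
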