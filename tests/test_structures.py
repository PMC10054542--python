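import math

import numpy as np
import pytest

from implimem import (
    CorrespondenceTable,
    MembraneGeometry,
    assign_atom_types,
    builtin_scale,
    compute_sasa,
    load_pdb,
    make_fixture,
    map_coarse_grained,
    one_bead_correspondence,
    predict_transfer_energy,
    save_pdb,
)
from implimem.conformations import build_residue_template
from implimem.membrane_params import STANDARD_RESIDUES
from implimem.energy_core import Particle, ParticleSystem
from implimem.structures import (
    TypingError,
    atom_type_of,
    default_atom_params,
    _one_bead_etr,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.300  1.00  0.00           C
END
"""


class TestAtomTyping:
    @pytest.mark.parametrize(
        "residue,atom,expected",
        [
            ("ALA", "CB", "Csp3"),
            ("PHE", "CZ", "Csp2"),
            ("MET", "SD", "S"),
            ("LYS", "NZ", "N"),
            ("SER", "OG", "O"),
            ("ASP", "CG", "Csp2"),
            ("LEU", "CD1", "Csp3"),
            ("ALA", "C", "Csp2"),     # backbone carbonyl carbon
            ("LEU", "HD11", "Hnc"),   # hydrogen on carbon
            ("SER", "HG", "Hc"),      # hydroxyl hydrogen
            ("LYS", "HZ1", "Hc"),
            ("ALA", "H", "Hc"),       # backbone amide hydrogen
        ],
    )
    def test_known_assignments(self, residue, atom, expected):
        assert atom_type_of(residue, atom) == expected

    def test_typing_total_over_standard_residues(self, initial_params):
        """Every atom of every residue template resolves to a typed energy."""
        for res in STANDARD_RESIDUES:
            system = build_residue_template(res)
            assign_atom_types(system, initial_params)
            for p in system:
                assert p.type_label in {"Csp3", "Csp2", "Hnc", "Hc", "O", "N", "S"}
                assert p.etr_per_area is not None

    def test_unknown_atom_raises_with_context(self, initial_params):
        system = build_residue_template("ALA")
        system[4].type_label = "XQ"
        with pytest.raises(TypingError, match="ALA.*XQ"):
            assign_atom_types(system, initial_params)


class TestPDBIO:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINIMAL_PDB)
        s = load_pdb(path)
        assert len(s) == 3
        assert s[1].position == pytest.approx([1.458, 0.0, 0.0])
        assert not s[0].is_sidechain and s[2].is_sidechain
        assert s[0].radius == pytest.approx(1.55)  # nitrogen

    def test_multi_model_uses_first(self, tmp_path):
        body = MINIMAL_PDB.replace("END\n", "")
        shifted = body.replace("   0.000   0.000   0.000", "  99.000   0.000   0.000")
        path = tmp_path / "nmr.pdb"
        path.write_text(f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{shifted}ENDMDL\nEND\n")
        s = load_pdb(path)
        assert len(s) == 3
        assert s[0].position[0] == pytest.approx(0.0)

    def test_one_bead_pdb_detected(self, tmp_path):
        path = tmp_path / "cg.pdb"
        save_pdb(make_fixture("hydrophobic_helix", 10, seed=0), path)
        s = load_pdb(path)
        assert s.representation == "one-bead"
        assert len(s) == 10

    def test_no_atoms_errors(self, tmp_path):
        path = tmp_path / "none.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError):
            load_pdb(path)


class TestSASA:
    def test_isolated_sphere_matches_analytic_area(self):
        """A lone r=1.7 atom with a 1.4 A probe exposes 4 pi (3.1)^2 A^2."""
        s = ParticleSystem([Particle(0, [0, 0, 0], radius=1.7)])
        compute_sasa(s)
        assert s[0].sasa == pytest.approx(4 * math.pi * 3.1**2, rel=0.01)

    def test_fully_overlapping_spheres_expose_one_sphere(self):
        s = ParticleSystem(
            [Particle(0, [0, 0, 0], radius=1.7), Particle(1, [0, 0, 1e-9], radius=1.7)]
        )
        compute_sasa(s)
        total = s[0].sasa + s[1].sasa
        assert total == pytest.approx(4 * math.pi * 3.1**2, rel=0.02)

    def test_buried_particle_has_no_surface(self):
        # central atom caged by a dense shell
        shell = []
        k = 0
        golden = (1 + math.sqrt(5)) / 2
        for i in range(60):
            z = 1 - (2 * i + 1) / 60
            theta = 2 * math.pi * i / golden
            rho = math.sqrt(max(1 - z * z, 0.0))
            shell.append(
                Particle(
                    k + 1,
                    3.2 * np.array([rho * math.cos(theta), rho * math.sin(theta), z]),
                    radius=1.7,
                )
            )
            k += 1
        s = ParticleSystem([Particle(0, [0, 0, 0], radius=1.7), *shell])
        compute_sasa(s)
        assert s[0].sasa < 1.0

    def test_point_density_convergence(self):
        sys1 = build_residue_template("TRP")
        sys2 = build_residue_template("TRP")
        compute_sasa(sys1, n_points=960)
        compute_sasa(sys2, n_points=5000)
        t1 = sum(p.sasa for p in sys1)
        t2 = sum(p.sasa for p in sys2)
        assert abs(t1 - t2) / t2 < 0.005
        upper = sum(4 * math.pi * (p.radius + 1.4) ** 2 for p in sys1)
        assert 0.0 < t1 <= upper

    def test_against_independent_shrake_rupley(self, tmp_path):
        """Cross-check against Biopython's Shrake-Rupley on the same atoms."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        system = build_residue_template("LEU")
        path = tmp_path / "leu.pdb"
        save_pdb(system, path)
        compute_sasa(system)

        structure = PDBParser(QUIET=True).get_structure("leu", str(path))
        sr = ShrakeRupley(probe_radius=1.4, n_points=960)
        sr.compute(structure, level="A")
        theirs = {a.get_name(): a.sasa for a in structure.get_atoms()}
        for p in system:
            assert p.sasa == pytest.approx(theirs[p.type_label], abs=1.5)


class TestCoarseGraining:
    def test_one_bead_mapping_counts_and_centroids(self, fp_scale):
        table = one_bead_correspondence(fp_scale)
        helix_atoms = ParticleSystem(
            [
                p
                for res in range(10)
                for p in _shifted_residue("LEU", res)
            ],
        )
        cg = map_coarse_grained(helix_atoms, table)
        assert cg.representation == "one-bead"
        assert len(cg) == 10
        # bead energy-per-area times area recovers the scale value
        for bead in cg:
            assert bead.etr_per_area * bead.sasa == pytest.approx(fp_scale["LEU"])

    def test_bead_sits_at_sidechain_centroid(self, fp_scale):
        atoms = build_residue_template("LEU")
        cg = map_coarse_grained(atoms, one_bead_correspondence(fp_scale))
        sc = np.mean([p.position for p in atoms if p.is_sidechain], axis=0)
        assert cg[0].position == pytest.approx(sc)

    def test_glycine_falls_back_to_ca(self, fp_scale):
        atoms = ParticleSystem(
            [
                Particle(0, [0, 0, 0], type_label="N", residue_id=("A", "GLY", 1),
                         is_sidechain=False),
                Particle(1, [1.5, 0, 0], type_label="CA", residue_id=("A", "GLY", 1),
                         is_sidechain=False),
            ]
        )
        cg = map_coarse_grained(atoms, one_bead_correspondence(fp_scale))
        assert cg[0].position == pytest.approx([1.5, 0.0, 0.0])

    def test_uncovered_residue_errors(self, fp_scale):
        table = one_bead_correspondence(fp_scale)
        atoms = build_residue_template("LEU")
        for p in atoms:
            p.residue_id = ("A", "XYZ", 1)
        with pytest.raises(KeyError, match="XYZ"):
            map_coarse_grained(atoms, table)

    def test_correspondence_round_trip(self, tmp_path, fp_scale):
        table = one_bead_correspondence(fp_scale)
        path = tmp_path / "corr.tsv"
        table.save(path)
        back = CorrespondenceTable.load(path)
        assert back.rows.keys() == table.rows.keys()
        assert back.rows[("LEU", "B")]["energy"] == pytest.approx(fp_scale["LEU"])

    def test_units_converted_to_kcal(self):
        table = CorrespondenceTable()
        table.add("ALA", "B", "ALA", 50.0, -4.184, units="kJ/mol")
        atoms = build_residue_template("ALA")
        cg = map_coarse_grained(atoms, table)
        assert cg[0].etr_per_area * cg[0].sasa == pytest.approx(-1.0)  # kcal/mol


def _shifted_residue(res, index):
    t = build_residue_template(res)
    out = []
    for p in t:
        q = Particle(
            id=index * len(t) + p.id,
            position=p.position + np.array([0.0, 0.0, 3.0 * index]),
            radius=p.radius,
            type_label=p.type_label,
            residue_id=("A", res, index + 1),
            is_sidechain=p.is_sidechain,
        )
        out.append(q)
    return out


class TestFixtures:
    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("nope")

    def test_determinism(self):
        a = make_fixture("barrel_shell", 30, seed=7)
        b = make_fixture("barrel_shell", 30, seed=7)
        assert np.array_equal(a.positions, b.positions)
        c = make_fixture("barrel_shell", 30, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_amphipathic_faces_alternate(self, geom):
        s = make_fixture("amphipathic_helix", 18, seed=0)
        names = [p.residue_id[1] for p in s]
        assert set(names) == {"LEU", "LYS"}
        # ~3.6-residue periodicity: the face flips roughly every 1-2 residues
        flips = sum(a != b for a, b in zip(names, names[1:]))
        assert 6 <= flips <= 12
        # hydrophobic beads really carry membrane-favoring energies
        for p in s:
            if p.residue_id[1] == "LEU":
                assert p.etr_per_area < 0

    def test_helix_geometry(self):
        s = make_fixture("hydrophobic_helix", 18, seed=0)
        z = s.positions[:, 2]
        rises = np.diff(np.sort(z))
        assert np.mean(rises) == pytest.approx(1.5, abs=0.01)

    def test_barrel_extent(self):
        s = make_fixture("barrel_shell", 30, seed=0)
        z = s.positions[:, 2]
        assert z.max() - z.min() == pytest.approx(30.0, abs=0.1)

    def test_toy_residue_isolated_spheres_have_known_area(self, geom):
        s = make_fixture("toy_residue", 3, seed=0)
        compute_sasa(s)
        analytic = 4 * math.pi * (1.7 + 1.4) ** 2
        for p in s:
            if p.is_sidechain:
                assert p.sasa == pytest.approx(analytic, rel=0.01)


class TestOneBeadFidelity:
    @pytest.mark.parametrize("res", ["LEU", "SER", "ARG", "TRP", "GLY"])
    def test_transfer_energy_equals_scale_value(self, res, fp_scale, geom):
        """A single bead with the closed-form per-area energy reproduces its
        scale entry exactly at the bilayer center."""
        area = 60.0
        bead = ParticleSystem(
            [
                Particle(
                    0, [0.0, 0.0, 0.0], radius=2.3, sasa=area,
                    etr_per_area=_one_bead_etr(fp_scale[res], area, geom),
                    residue_id=("A", res, 1),
                )
            ],
            "one-bead",
        )
        assert predict_transfer_energy(bead, geom) == pytest.approx(
            fp_scale[res], abs=1e-9
        )
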