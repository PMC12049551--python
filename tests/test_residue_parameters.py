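import numpy as np
import pytest

from fluorosite import (FixtureSpec, assign_secondary_structure,
                        build_parameter_table, compute_cysteine_resemblance,
                        compute_half_sphere_exposure,
                        compute_mean_surface_distance, compute_msa_conservation,
                        compute_sasa, generate_toy_structure,
                        parse_consurf_grades, parse_dssp_file, to_three_state,
                        write_pdb)
from fluorosite.geometry import rotation_matrix
from fluorosite.residue_parameters import (DEFAULT_SELECTION, REGISTRY,
                                           REGISTRY_BY_ID, WILKE_MAX_ASA)
from fluorosite.structure_io import STANDARD_AMINO_ACIDS


class TestSasa:
    def test_exposed_residue_near_wilke_maximum(self):
        """Center of an extended Gly-Ala-Gly is almost fully exposed; a free
        residue exceeds the Wilke maximum and clips at 1.2."""
        gag = generate_toy_structure(
            FixtureSpec("coil", 3, params={"sequence": ["GLY", "ALA", "GLY"]}))
        rel = compute_sasa(gag)[gag.residues[1].residue_id][1]
        assert 0.75 <= rel <= 1.2
        free = generate_toy_structure(FixtureSpec("coil", 1))
        abs_asa, rel_free = compute_sasa(free)[free.residues[0].residue_id]
        assert abs_asa > WILKE_MAX_ASA["ALA"]
        assert rel_free == pytest.approx(1.2)

    def test_enclosed_residue_has_zero_asa(self):
        shell = generate_toy_structure(FixtureSpec("shell", 5, seed=2))
        sasa = compute_sasa(shell, n_points=240)
        for res in shell.standard_residues():
            assert sasa[res.residue_id][0] == 0.0

    def test_quadrature_convergence(self, helix):
        """Doubling the dot count changes per-residue ASA by < 2%."""
        a = compute_sasa(helix, n_points=960)
        b = compute_sasa(helix, n_points=1920)
        for rid in a:
            assert a[rid][0] == pytest.approx(b[rid][0], rel=0.02)

    def test_additivity_of_far_copies(self, helix):
        """Total ASA of two far-separated copies is twice the single-copy
        total within 1%."""
        import copy
        double = copy.deepcopy(helix)
        shifted = copy.deepcopy(helix)
        for res in shifted.residues:
            res.residue_id = ("B", res.residue_id[1], "")
            for a in res.atoms:
                a.residue_id = res.residue_id
                a.coordinates = a.coordinates + np.array([200.0, 0, 0])
        double.residues.extend(shifted.residues)
        single = sum(v[0] for v in compute_sasa(helix, n_points=480).values())
        total = sum(v[0] for v in compute_sasa(double, n_points=480).values())
        assert total == pytest.approx(2 * single, rel=0.01)


class TestHalfSphereExposure:
    def test_lone_residue(self):
        m = generate_toy_structure(FixtureSpec("coil", 1))
        assert compute_half_sphere_exposure(m)[m.residues[0].residue_id] == (0, 0)

    def test_two_residues_one_neighbor_each(self):
        m = generate_toy_structure(FixtureSpec("coil", 2))
        hse = compute_half_sphere_exposure(m, radius=10.0)
        for rid, (up, down) in hse.items():
            assert up + down == 1

    def test_matches_brute_force_on_helix(self):
        """Counts equal an independent O(n²) neighbor enumeration."""
        m = generate_toy_structure(FixtureSpec("helix", 20))
        hse = compute_half_sphere_exposure(m, radius=10.0)
        residues = m.standard_residues()
        for res in residues:
            ca = res.atom("CA").coordinates
            cb = res.atom("CB").coordinates
            u = cb - ca
            u = u / np.linalg.norm(u)
            up = down = 0
            for other in residues:
                if other is res:
                    continue
                d = other.atom("CA").coordinates - ca
                if np.linalg.norm(d) <= 10.0:
                    if np.dot(d, u) > 0:
                        up += 1
                    else:
                        down += 1
            assert hse[res.residue_id] == (up, down)


class TestMeanSurfaceDistance:
    def test_isolated_residue_is_all_surface(self):
        m = generate_toy_structure(FixtureSpec("coil", 1))
        d = compute_mean_surface_distance(m)
        assert d[m.residues[0].residue_id] < 2.0

    def test_core_exceeds_shell_residues(self, globule):
        """The innermost residue of a dense globule is farther from the
        surface than every outer-stratum residue."""
        d = compute_mean_surface_distance(globule, n_points=480)
        center = globule.atom_coordinates().mean(axis=0)
        radii = {r.residue_id: np.linalg.norm(
            r.atom("CA").coordinates - center) for r in globule.residues}
        core = min(radii, key=radii.get)
        outer = sorted(radii, key=radii.get)[-10:]
        assert all(d[core] > d[o] for o in outer)

    def test_occlusion_never_decreases_core_distance(self):
        """Enclosing a cluster in a blocking matrix pushes the surface
        outward: per-residue distances only grow."""
        inner = generate_toy_structure(FixtureSpec("globule", 5, seed=2,
                                                   params={"spacing": 5.4,
                                                           "jitter": 0.4}))
        shell = generate_toy_structure(FixtureSpec("shell", 5, seed=2))
        d_in = compute_mean_surface_distance(inner, n_points=240)
        d_sh = compute_mean_surface_distance(shell, n_points=240)
        for res in inner.standard_residues():
            assert d_sh[res.residue_id] >= d_in[res.residue_id] - 0.5


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self, helix):
        ss = assign_secondary_structure(helix)
        interior = [ss[r.residue_id] for r in helix.residues[2:-2]]
        assert all(c == "H" for c in interior)

    def test_antiparallel_sheet_interior_is_E(self):
        m = generate_toy_structure(FixtureSpec("sheet", 8))
        ss = to_three_state(assign_secondary_structure(m))
        per_chain = {}
        for r in m.residues:
            per_chain.setdefault(r.residue_id[0], []).append(ss[r.residue_id])
        for codes in per_chain.values():
            assert "E" in "".join(codes[2:-2])

    def test_extended_chain_is_coil(self):
        m = generate_toy_structure(FixtureSpec("coil", 8))
        ss = assign_secondary_structure(m)
        assert set(ss.values()) <= {"-", "S", "T"}
        assert all(to_three_state(ss)[r.residue_id] == "C" for r in m.residues)

    def test_rigid_motion_invariance(self, helix):
        import copy
        moved = copy.deepcopy(helix)
        rot = rotation_matrix(np.array([1.0, 2.0, 0.5]), 73.0)
        for res in moved.residues:
            for a in res.atoms:
                a.coordinates = rot @ a.coordinates + np.array([5.0, -3.0, 11.0])
        assert assign_secondary_structure(helix) == \
            assign_secondary_structure(moved)

    def test_agreement_with_external_dssp_oracle(self, helix, tmp_path):
        """3-state classes match mdtraj's DSSP implementation on the ideal
        helix."""
        mdtraj = pytest.importorskip("mdtraj")
        pdb = tmp_path / "helix.pdb"
        write_pdb(helix, pdb)
        traj = mdtraj.load_pdb(str(pdb))
        external = mdtraj.compute_dssp(traj, simplified=True)[0]
        ours = to_three_state(assign_secondary_structure(helix))
        agree = sum(external[i] == ours[r.residue_id]
                    for i, r in enumerate(helix.residues))
        assert agree >= len(helix.residues) - 2  # termini may differ


class TestDsspFile:
    def _dssp_text(self, rows):
        header = ("==== Secondary Structure Definition ====\n"
                  "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        lines = []
        for i, (num, chain, aa, code) in enumerate(rows, 1):
            line = list(" " * 40)
            line[0:5] = f"{i:5d}"
            line[5:10] = f"{num:5d}"
            line[11] = chain
            line[13] = aa
            line[16] = code
            lines.append("".join(line))
        return header + "\n".join(lines) + "\n"

    def test_minimal_fixture(self, tmp_path):
        p = tmp_path / "mini.dssp"
        p.write_text(self._dssp_text([(1, "A", "A", "H"), (2, "A", "G", "H"),
                                      (3, "A", "S", " ")]))
        out = parse_dssp_file(p)
        assert len(out) == 3
        assert out[("A", 1, "")] == "H"
        assert out[("A", 3, "")] == "-"

    def test_chain_break_rows_skipped(self, tmp_path):
        p = tmp_path / "brk.dssp"
        text = self._dssp_text([(1, "A", "A", "H"), (2, "A", "!", " "),
                                (3, "B", "A", "E")])
        p.write_text(text)
        out = parse_dssp_file(p)
        assert len(out) == 2

    def test_missing_header_errors(self, tmp_path):
        p = tmp_path / "bad.dssp"
        p.write_text("not a dssp file\n")
        with pytest.raises(ValueError, match="RESIDUE"):
            parse_dssp_file(p)

    def test_external_file_matches_internal_assignment(self, helix, tmp_path):
        """A DSSP-format file carrying the helix assignment parses back to
        the internal classes (3-state)."""
        internal = assign_secondary_structure(helix)
        rows = [(rid[1], rid[0], "A", code if code != "-" else " ")
                for rid, code in internal.items()]
        p = tmp_path / "helix.dssp"
        p.write_text(self._dssp_text(rows))
        parsed = parse_dssp_file(p)
        assert to_three_state(parsed) == to_three_state(internal)


CONSURF_FIXTURE = """\
 POS SEQ  3LATOM SCORE  COLOR CONFIDENCE
   1   M  MET1:A -1.200    9  -1.5,-0.9
   2   K  LYS2:A -0.300    6  -0.6,0.0
   3   E  GLU3:A  0.450    3   0.2,0.7
   4   L  LEU4:A  1.100    1   0.8,1.4
   5   C  CYS5:A -0.900    8* -1.2,-0.6
"""


class TestConsurf:
    def test_fixture_parses_as_printed(self, tmp_path):
        p = tmp_path / "grades.txt"
        p.write_text(CONSURF_FIXTURE)
        out = parse_consurf_grades(p)
        assert len(out) == 5
        assert out[("A", 1, "")] == (-1.2, 9)
        assert out[("A", 5, "")] == (-0.9, 8)

    def test_conserved_grade_has_negative_score(self, tmp_path):
        p = tmp_path / "grades.txt"
        p.write_text(CONSURF_FIXTURE)
        out = parse_consurf_grades(p)
        for (_, _, _), (score, grade) in out.items():
            if grade == 9:
                assert score < 0

    def test_structure_mismatch_errors(self, tmp_path, globule):
        p = tmp_path / "grades.txt"
        p.write_text(CONSURF_FIXTURE)
        with pytest.raises(ValueError, match="unmatched"):
            parse_consurf_grades(p, model=globule)


class TestMsaConservation:
    def _msa(self, helix):
        # 12-column alignment for the poly-ALA helix; column 0 invariant,
        # column 5 maximally variable
        seqs = []
        rng = np.random.default_rng(6)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for row in range(20):
            s = list("A" * 12)
            for col in range(1, 12):
                if col == 5:
                    s[col] = alphabet[row]
                elif rng.random() < 0.3:
                    s[col] = alphabet[rng.integers(0, 20)]
            seqs.append((f"seq{row}", "".join(s)))
        seqs[0] = ("ref", "A" * 12)
        return seqs

    def test_invariant_column_most_conserved(self, helix):
        msa = self._msa(helix)
        scores = compute_msa_conservation(helix, msa, "A")
        rid0 = helix.residues[0].residue_id
        assert scores[rid0] == min(scores.values())
        assert scores[rid0] < 0

    def test_uniform_column_near_maximum(self, helix):
        msa = self._msa(helix)
        scores = compute_msa_conservation(helix, msa, "A")
        rid5 = helix.residues[5].residue_id
        assert scores[rid5] == max(scores.values())

    def test_normalization(self, helix):
        vals = np.array(list(compute_msa_conservation(helix, self._msa(helix),
                                                      "A").values()))
        assert abs(vals.mean()) < 1e-9
        assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_ungapped_mapping_mismatch_errors(self, helix):
        with pytest.raises(ValueError, match="ungapped"):
            compute_msa_conservation(helix, [("ref", "AAA")], "A")


@pytest.mark.parametrize("aa,mass0,charge", [
    ("CYS", True, "neutral"),
    ("SER", False, "neutral"),
    ("LYS", False, "positive"),
    ("ASP", False, "negative"),
])
def test_cysteine_resemblance(aa, mass0, charge):
    from fluorosite.structure_io import ResidueRecord
    res = ResidueRecord(("A", 1, ""), aa)
    cr = compute_cysteine_resemblance(res)
    assert cr["identity"] == aa
    assert cr["charge_class"] == charge
    assert (cr["mass_delta"] == 0) == mass0
    assert (cr["volume_delta"] == 0) == mass0


class TestBuildParameterTable:
    def test_default_selection_registry(self, helix):
        registry = [REGISTRY_BY_ID[i] for i in DEFAULT_SELECTION]
        table = build_parameter_table(helix, registry=registry)
        assert len(table.frame) == len(helix.residues)
        # SS + CR + SE populated; CS missing without an annotation source
        comp = table.completeness()
        assert comp[11] == 1.0 and comp[18] == 1.0 and comp[25] == 1.0
        assert comp[13] == 0.0

    def test_full_registry_has_28_parameters(self, globule_table):
        param_cols = [d.column for d in globule_table.registry]
        assert len(param_cols) == 28
        assert all(c in globule_table.frame.columns for c in param_cols)

    def test_csv_round_trip(self, globule_table, tmp_path):
        from fluorosite.residue_parameters import ParameterTable
        p = tmp_path / "table.csv"
        globule_table.to_csv(p)
        back = ParameterTable.from_csv(p)
        assert len(back.frame) == len(globule_table.frame)
        np.testing.assert_allclose(back.column(11).to_numpy(float),
                                   globule_table.column(11).to_numpy(float))
        assert (tmp_path / "table.definitions.json").exists()
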