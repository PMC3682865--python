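"""Semi-classical terms, geometric features, and the feature registry."""

import math

import numpy as np
import pytest

from shiftforge import residues
from shiftforge.features import (
    FeatureConfigurationError,
    FeatureContext,
    compute_features,
    default_feature_definition,
    feature_registry,
    register_feature,
    resolve_features,
)
from shiftforge.features.geometry import (
    atomic_density,
    detect_hbonds_and_disulfides,
    explicit_backbone_distances,
    secondary_structure,
    solvent_accessible_surface,
    torsion_angles,
)
from shiftforge.features.semiclassical import (
    DEFAULT_PARAMS,
    MissingRandomCoilEntry,
    RANDOM_COIL_PPM,
    UnbondedTargetError,
    build_ring,
    electric_field_shift,
    hbond_effect_shift,
    random_coil_shift,
    ring_current_shift,
)
from shiftforge.fixtures import FixtureSpec, build_structure
from shiftforge.records import MISSING
from shiftforge.structure import Atom, Chain, ProteinStructure, Residue


def make_structure(atom_specs, res_name="ALA"):
    """Ad-hoc structure from (atom_name, element, xyz) triples."""
    chain = Chain(index=1, original_id="A")
    res = Residue(index=1, name=res_name, original_index=1)
    for name, element, xyz in atom_specs:
        res.atoms[name] = Atom(name, element, np.asarray(xyz, dtype=float))
    chain.residues.append(res)
    return ProteinStructure("ADHC", [chain])


class TestRegistry:
    def test_default_names_all_resolve(self):
        definition = default_feature_definition()
        reg = feature_registry()
        assert all(n in reg for n in definition)

    def test_unknown_name_is_configuration_error(self):
        with pytest.raises(FeatureConfigurationError, match="no_such"):
            resolve_features(["phi", "no_such_feature"])

    def test_user_feature_registers_and_resolves(self):
        register_feature("test_only_constant", lambda a, c: 1.0, "numeric")
        try:
            assert "test_only_constant" in feature_registry()
            resolve_features(["test_only_constant"])
            with pytest.raises(FeatureConfigurationError,
                               match="already registered"):
                register_feature("test_only_constant",
                                 lambda a, c: 2.0, "numeric")
        finally:
            from shiftforge import features

            features._REGISTRY.pop("test_only_constant", None)


class TestRandomCoil:
    def test_glycine_has_no_cb_entry(self):
        with pytest.raises(MissingRandomCoilEntry):
            random_coil_shift("GLY", "CB")

    def test_lookup_is_the_table_value(self):
        assert random_coil_shift("ALA", "CA") == RANDOM_COIL_PPM[("ALA",
                                                                  "CA")]

    def test_table_covers_backbone_nuclei(self):
        # all 20 residues for N, CA, C, HA; CB except GLY; H except PRO
        for res in residues.STANDARD_RESIDUES:
            for atom in ("N", "CA", "C", "HA"):
                assert (res, atom) in RANDOM_COIL_PPM, (res, atom)
            if res != "GLY":
                assert (res, "CB") in RANDOM_COIL_PPM
            if res != "PRO":
                assert (res, "H") in RANDOM_COIL_PPM

    def test_table_values_in_physical_ranges(self):
        for (res, atom), ppm in RANDOM_COIL_PPM.items():
            if atom in ("H", "HA"):
                assert 3.0 < ppm < 9.5
            elif atom == "N":
                assert 100.0 < ppm < 135.0
            elif atom == "C":
                assert 165.0 < ppm < 185.0
            else:
                assert 15.0 < ppm < 75.0


def unit_ring(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0),
              intensity=1.0):
    center = np.asarray(center, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    # six points of a planar hexagon perpendicular to the normal
    a = np.cross(normal, [1.0, 0.3, 0.2])
    a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    pts = np.array([center + 1.39 * (math.cos(t) * a + math.sin(t) * b)
                    for t in np.linspace(0, 2 * math.pi, 7)[:-1]])
    return build_ring("PHE", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
                      pts, intensity)


class TestRingCurrent:
    def test_zero_at_the_magic_angle(self):
        ring = unit_ring()
        r = 4.0
        cos_t = math.sqrt(1.0 / 3.0)
        pos = np.array([r * math.sqrt(1 - cos_t ** 2), 0.0, r * cos_t])
        assert ring_current_shift(pos, [ring]) == pytest.approx(0.0,
                                                                abs=1e-9)

    def test_on_axis_r_cubed_scaling(self):
        ring = unit_ring()
        v1 = ring_current_shift(np.array([0.0, 0.0, 3.0]), [ring])
        v2 = ring_current_shift(np.array([0.0, 0.0, 6.0]), [ring])
        assert v1 / v2 == pytest.approx(8.0, rel=1e-12)

    def test_sign_flips_across_the_cone(self):
        ring = unit_ring()
        above = ring_current_shift(np.array([0.0, 0.0, 4.0]), [ring])
        in_plane = ring_current_shift(np.array([4.0, 0.0, 0.0]), [ring])
        assert above * in_plane < 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(size=3) * 10
        ring = unit_ring()
        pos = np.array([1.0, 2.0, 3.0])
        moved_ring = unit_ring(center=q @ np.zeros(3) + t,
                               normal=q @ np.array([0.0, 0.0, 1.0]))
        v0 = ring_current_shift(pos, [ring])
        v1 = ring_current_shift(q @ pos + t, [moved_ring])
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_too_close_to_centroid_is_an_error(self):
        with pytest.raises(ValueError, match="implausible"):
            ring_current_shift(np.array([0.0, 0.0, 0.1]), [unit_ring()])

    def test_collinear_ring_rejected(self):
        pts = np.array([[float(i), 0.0, 0.0] for i in range(6)])
        with pytest.raises(ValueError, match="degenerate"):
            build_ring("PHE", ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
                       pts, 1.0)

    def test_far_field_vanishes(self):
        # point-dipole far field: B*2/r^3 ~ 5e-4 ppm at 50 A on-axis,
        # physically negligible and strictly r^-3-decaying
        v50 = ring_current_shift(np.array([0.0, 0.0, 50.0]), [unit_ring()])
        v500 = ring_current_shift(np.array([0.0, 0.0, 500.0]),
                                  [unit_ring()])
        assert abs(v50) < 1e-3
        assert abs(v500) < 1e-6


def efield_structure(source_xyz, charge=0.5):
    """An O-H pair (singly bonded H target) plus one charged source."""
    specs = [
        ("O", "O", (0.0, 0.0, 0.0)),
        ("H", "H", (0.96, 0.0, 0.0)),
        ("NZ", "N", source_xyz),
    ]
    st = make_structure(specs, res_name="SER")

    def charge_fn(res, name):
        return charge if name == "NZ" else 0.0

    return st, charge_fn


class TestElectricField:
    def test_axial_source_closed_form(self):
        r = 3.0
        st, qf = efield_structure((0.96 + r, 0.0, 0.0))
        h = st.chains[0].residues[0].get("H")
        v = electric_field_shift(h, st, DEFAULT_PARAMS, charge_fn=qf)
        assert v == pytest.approx(DEFAULT_PARAMS.efield_eps * 0.5 / r ** 2,
                                  rel=1e-12)

    def test_perpendicular_source_gives_zero(self):
        st, qf = efield_structure((0.96, 4.0, 0.0))
        h = st.chains[0].residues[0].get("H")
        v = electric_field_shift(h, st, DEFAULT_PARAMS, charge_fn=qf)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_doubles_axial_component(self):
        specs = [
            ("O", "O", (0.0, 0.0, 0.0)),
            ("H", "H", (0.96, 0.0, 0.0)),
            ("NZ", "N", (3.96, 2.0, 0.0)),
            ("NE", "N", (3.96, -2.0, 0.0)),
        ]
        st = make_structure(specs, res_name="SER")

        def qf(res, name):
            return 0.5 if name in ("NZ", "NE") else 0.0

        h = st.chains[0].residues[0].get("H")
        v_pair = electric_field_shift(h, st, DEFAULT_PARAMS, charge_fn=qf)
        d = np.array([3.0, 2.0, 0.0])
        r = np.linalg.norm(d)
        single_axial = 0.5 * (d[0] / r) / r ** 2
        assert v_pair == pytest.approx(2 * single_axial, rel=1e-12)

    def test_unbonded_target_is_an_error(self):
        st = make_structure([("O", "O", (0.0, 0.0, 0.0)),
                             ("NZ", "N", (9.0, 9.0, 9.0))])
        o = st.chains[0].residues[0].get("O")
        with pytest.raises(UnbondedTargetError):
            electric_field_shift(o, st)


class TestHbondEffect:
    @staticmethod
    def _donor_h_acceptor(r):
        specs = [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("H", "H", (1.0, 0.0, 0.0)),
            ("O", "O", (1.0 + r, 0.0, 0.0)),
        ]
        return make_structure(specs)

    def test_no_acceptor_within_range_gives_zero(self):
        st = self._donor_h_acceptor(5.0)
        h = st.chains[0].residues[0].get("H")
        assert hbond_effect_shift(h, st) == 0.0

    def test_root_of_the_distance_form(self):
        p = DEFAULT_PARAMS
        r0 = (p.hbond_a / p.hbond_b) ** (1.0 / 3.0)
        assert r0 < p.hbond_range
        st = self._donor_h_acceptor(r0)
        h = st.chains[0].residues[0].get("H")
        assert hbond_effect_shift(h, st) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_in_distance(self):
        values = []
        for r in (1.8, 2.2, 2.6, 3.0, 3.4):
            st = self._donor_h_acceptor(r)
            h = st.chains[0].residues[0].get("H")
            values.append(hbond_effect_shift(h, st))
        assert all(a > b for a, b in zip(values, values[1:]))


class TestTorsions:
    def test_programmed_dihedrals_recovered_exactly(self):
        program = [(-57.0, -47.0), (-139.0, 135.0), (-57.0, -47.0),
                   (-75.0, 145.0), (-57.0, -47.0)]
        spec = FixtureSpec(pdb_id="TORS", sequence="AAAAA",
                           phi_psi=program)
        st = build_structure(spec)
        ch = st.chains[0]
        for i in range(1, 4):
            t = torsion_angles(ch, i)
            assert t["phi"] == pytest.approx(program[i][0], abs=1e-6)
            assert t["psi"] == pytest.approx(program[i][1], abs=1e-6)

    def test_terminal_angles_missing(self, helix_structure):
        ch = helix_structure.chains[0]
        assert torsion_angles(ch, 0)["phi"] == MISSING
        assert torsion_angles(ch, len(ch.residues) - 1)["psi"] == MISSING

    def test_chi1_present_only_with_gamma_atom(self, helix_structure):
        ch = helix_structure.chains[0]
        by_name = {r.name: i for i, r in enumerate(ch.residues)}
        assert torsion_angles(ch, by_name["PHE"])["chi1"] != MISSING
        assert torsion_angles(ch, by_name["ALA"])["chi1"] == MISSING


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helix(self, helix_structure):
        labels = secondary_structure(helix_structure.chains[0])
        assert set(labels[3:9]) == {"helix"}

    def test_extended_chain_has_no_helix(self):
        spec = FixtureSpec(pdb_id="EXT1", sequence="AAAAAAAAAAAA",
                           phi_psi=[(-139.0, 135.0)] * 12)
        st = build_structure(spec)
        labels = secondary_structure(st.chains[0])
        assert "helix" not in labels

    def test_two_residue_peptide_is_all_coil(self):
        spec = FixtureSpec(pdb_id="TWO2", sequence="AA")
        st = build_structure(spec)
        assert secondary_structure(st.chains[0]) == ["coil", "coil"]


class TestSAS:
    def test_isolated_atom_matches_closed_form(self):
        st = make_structure([("CA", "C", (0.0, 0.0, 0.0))])
        areas, per_res = solvent_accessible_surface(st)
        rho = residues.VDW_RADII["C"] + 1.4
        assert areas[0] == pytest.approx(4 * math.pi * rho ** 2, rel=0.02)
        assert per_res[(1, 1)] == pytest.approx(areas[0])

    def test_tightly_caged_atom_is_buried(self):
        specs = [("CA", "C", (0.0, 0.0, 0.0))]
        k = 0
        for dx in (-2.2, 0.0, 2.2):
            for dy in (-2.2, 0.0, 2.2):
                for dz in (-2.2, 0.0, 2.2):
                    if dx == dy == dz == 0.0:
                        continue
                    k += 1
                    specs.append((f"C{k}", "C", (dx, dy, dz)))
        st = make_structure(specs)
        areas, _ = solvent_accessible_surface(st)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_overlapping_atoms_have_equal_areas(self):
        st = make_structure([("C1", "C", (0.0, 0.0, 0.0)),
                             ("C2", "C", (1.1, 0.7, -0.4))])
        areas, _ = solvent_accessible_surface(st)
        assert areas[0] == areas[1]  # exact: antipodal point set

    def test_unknown_element_radius_is_an_error(self):
        st = make_structure([("FE", "FE", (0.0, 0.0, 0.0))])
        with pytest.raises(KeyError, match="van der Waals"):
            solvent_accessible_surface(st)


class TestDensityAndBonds:
    def test_isolated_atom_density_zero(self):
        st = make_structure([("CA", "C", (0.0, 0.0, 0.0))])
        assert atomic_density(st, st.atoms[0]) == 0

    def test_cluster_of_three_heavy_atoms(self):
        st = make_structure([
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C1", "C", (4.0, 0.0, 0.0)),
            ("C2", "C", (0.0, 4.0, 0.0)),
            ("C3", "C", (0.0, 0.0, 4.0)),
            ("H1", "H", (0.0, 0.0, -1.0)),  # hydrogens never counted
        ])
        assert atomic_density(st, st.atoms[0]) == 3

    def test_density_rotation_invariant(self):
        st = make_structure([
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C1", "C", (4.0, 0.0, 0.0)),
            ("C2", "C", (0.0, 4.0, 0.0)),
            ("C3", "C", (0.0, 0.0, 4.0)),
        ])
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        st2 = st.transformed(q, np.array([5.0, -3.0, 2.0]))
        assert atomic_density(st2, st2.atoms[0]) == 3

    def test_constructed_hydrogen_bond_detected(self):
        # donor-H...acceptor at 1.9 A and ~165 degrees
        h = np.array([1.0, 0.0, 0.0])
        acc = h + 1.9 * np.array([math.cos(math.radians(15)),
                                  math.sin(math.radians(15)), 0.0])
        st = make_structure([
            ("N", "N", (0.0, 0.0, 0.0)),
            ("H", "H", h),
            ("O", "O", acc),
        ])
        hbonds, _ = detect_hbonds_and_disulfides(st)
        assert len(hbonds) == 1

    def test_distant_acceptor_not_detected(self):
        st = make_structure([
            ("N", "N", (0.0, 0.0, 0.0)),
            ("H", "H", (1.0, 0.0, 0.0)),
            ("O", "O", (5.0, 0.0, 0.0)),
        ])
        hbonds, _ = detect_hbonds_and_disulfides(st)
        assert hbonds == []

    def test_disulfide_detected_in_range(self):
        st = make_structure([
            ("SG", "S", (0.0, 0.0, 0.0)),
            ("SG", "S", (2.05, 0.0, 0.0)),
        ], res_name="CYS")
        # two SG in one residue dict would collide; build two residues
        chain = Chain(index=1, original_id="A")
        for i, x in enumerate((0.0, 2.05)):
            r = Residue(index=i + 1, name="CYS", original_index=i + 1)
            r.atoms["SG"] = Atom("SG", "S", np.array([x, 0.0, 0.0]))
            chain.residues.append(r)
        st = ProteinStructure("SS", [chain])
        _, disulfides = detect_hbonds_and_disulfides(st)
        assert len(disulfides) == 1


class TestBackboneDistances:
    def test_bonded_distances_match_construction(self, helix_structure):
        ch = helix_structure.chains[0]
        d = explicit_backbone_distances(ch, 3)
        assert d["d_n_ca"] == pytest.approx(1.458, abs=1e-3)
        assert d["d_ca_c"] == pytest.approx(1.525, abs=1e-3)
        assert d["d_c_n_next"] == pytest.approx(1.329, abs=1e-3)

    def test_terminal_neighbour_distances_missing(self, helix_structure):
        ch = helix_structure.chains[0]
        assert explicit_backbone_distances(ch, 0)["d_ca_ca_prev"] == MISSING
        last = len(ch.residues) - 1
        assert explicit_backbone_distances(ch, last)["d_c_n_next"] == MISSING


@pytest.fixture(scope="module")
def ctx(helix_structure):
    return FeatureContext(helix_structure)


class TestFeatureVectors:

    def test_vectors_are_complete(self, helix_structure, ctx):
        definition = default_feature_definition()
        for atom in helix_structure.atoms[:25]:
            values = compute_features(atom, ctx, definition)
            assert set(values) == set(definition.names)

    def test_first_residue_has_nter_sentinel(self, helix_structure, ctx):
        atom = helix_structure.chains[0].residues[0].get("CA")
        values = compute_features(atom, ctx, default_feature_definition())
        assert values["prev_res_type"] == "NTER"
        assert values["sequence_length"] == 12.0

    def test_conditions_missing_without_mapping_record(self,
                                                       helix_structure,
                                                       ctx):
        atom = helix_structure.chains[0].residues[1].get("CA")
        values = compute_features(atom, ctx, default_feature_definition())
        assert values["pressure"] == MISSING
        assert values["alignment_score"] == MISSING

    def test_computation_is_deterministic(self, helix_structure):
        definition = default_feature_definition()
        a = FeatureContext(helix_structure)
        b = FeatureContext(helix_structure)
        atom = helix_structure.chains[0].residues[4].get("HA")
        assert compute_features(atom, a, definition) == \
            compute_features(atom, b, definition)

    def test_geometric_features_rigid_motion_invariant(self,
                                                       helix_structure):
        """All coordinate-derived features agree to 1e-6 relative after an
        arbitrary rotation + translation of the whole structure."""
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]  # proper rotation, not a reflection
        t = rng.normal(size=3) * 20.0
        moved = helix_structure.transformed(q, t)
        definition = default_feature_definition()
        geometric = [
            "phi", "psi", "chi1", "secondary_structure",
            "d_n_ca", "d_ca_c", "d_c_o", "d_c_n_next", "d_ca_ca_prev",
            "d_ca_ca_next", "atom_sas", "residue_sas", "atomic_density",
            "hbonded", "disulfide_bonded", "structure_energy",
            "random_coil", "ring_current", "electric_field",
            "hbond_effect",
        ]
        ctx_a = FeatureContext(helix_structure)
        ctx_b = FeatureContext(moved)
        for atom_a, atom_b in zip(helix_structure.atoms[:40], moved.atoms):
            va = compute_features(atom_a, ctx_a, definition)
            vb = compute_features(atom_b, ctx_b, definition)
            for name in geometric:
                if isinstance(va[name], str) or isinstance(vb[name], str):
                    assert va[name] == vb[name], name
                else:
                    assert vb[name] == pytest.approx(
                        va[name], rel=1e-6, abs=1e-6), name
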