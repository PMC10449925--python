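"""Contact, hydration, Rg, SASA, H-bond and shear-strength metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_frame
from proteinglue.trajectory import (
    hydrogen_bond_count,
    hydrophobicity_index,
    initial_contact_time,
    radius_of_gyration,
    read_trajectory,
    sasa,
    shear_strength,
    surface_water_occupancy,
    write_trajectory,
)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        f = make_frame([[1.0, 2.0, 3.0]])
        assert radius_of_gyration(f, np.array([0])) == 0.0

    def test_two_equal_masses_one_nm_apart(self):
        f = make_frame([[0, 0, 0], [1.0, 0, 0]])
        assert radius_of_gyration(f, np.array([0, 1])) == pytest.approx(0.5)

    def test_matches_brute_force_sum(self, rng):
        xyz = rng.normal(size=(50, 3))
        m = rng.uniform(1, 20, size=50)
        f = make_frame(xyz, masses=m)
        sel = np.arange(50)
        com = np.array(
            [sum(m[i] * xyz[i, k] for i in range(50)) / m.sum() for k in range(3)]
        )
        brute = np.sqrt(
            sum(m[i] * ((xyz[i] - com) ** 2).sum() for i in range(50)) / m.sum()
        )
        assert abs(radius_of_gyration(f, sel) - brute) < 1e-12

    def test_empty_selection_rejected(self):
        f = make_frame([[0, 0, 0]])
        with pytest.raises(ValueError):
            radius_of_gyration(f, np.array([], dtype=int))

    def test_rigid_motion_invariance(self, rng):
        xyz = rng.normal(size=(30, 3))
        m = rng.uniform(1, 10, size=30)
        rot = Rotation.random(random_state=7).as_matrix()
        moved = xyz @ rot.T + np.array([3.0, -2.0, 5.0])
        a = radius_of_gyration(make_frame(xyz, masses=m), np.arange(30))
        b = radius_of_gyration(make_frame(moved, masses=m), np.arange(30))
        assert abs(a - b) / a < 1e-9


def _contact_system(res_z_by_frame):
    """One surface atom at the origin, one protein residue descending."""
    frames = []
    for i, z in enumerate(res_z_by_frame):
        frames.append(
            make_frame(
                [[0, 0, 0], [0, 0, z]],
                groups=["surface", "protein"],
                names=["SI", "CA"],
                residue_ids=[0, 1],
                residue_names=["SUR", "LEU"],
                time=float(i),
            )
        )
    return frames


class TestInitialContactTime:
    def test_immediate_contact_reports_first_frame(self):
        frames = _contact_system([0.25, 0.25, 0.25])
        assert initial_contact_time(frames, 1) == 0.0

    def test_linear_approach_reports_first_qualifying_frame(self):
        # crosses the 0.35 nm threshold between frames 3 and 4
        z = [1.0, 0.8, 0.6, 0.4, 0.3, 0.2]
        assert initial_contact_time(_contact_system(z), 1) == 4.0

    def test_never_in_contact(self):
        frames = _contact_system([1.0] * 5)
        assert initial_contact_time(frames, 1) is None

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            initial_contact_time(_contact_system([1.0]), 99)

    def test_monotone_in_threshold(self):
        z = [1.0, 0.7, 0.45, 0.3, 0.1]
        frames = _contact_system(z)
        t_small = initial_contact_time(frames, 1, threshold=0.35)
        t_large = initial_contact_time(frames, 1, threshold=0.5)
        assert t_large <= t_small


def _hydration_frame(water_heights, water_xy=None):
    surf = [[x, y, 0.0] for x in (1, 3, 5) for y in (1, 3, 5)]
    n_w = len(water_heights)
    if water_xy is None:
        water_xy = [(2.0, 2.0)] * n_w
    waters = [[water_xy[i][0], water_xy[i][1], water_heights[i]] for i in range(n_w)]
    n_s = len(surf)
    return make_frame(
        surf + waters,
        groups=["surface"] * n_s + ["water"] * n_w,
        names=["SI"] * n_s + ["OW"] * n_w,
        residue_ids=[0] * n_s + list(range(1, n_w + 1)),
        residue_names=["SUR"] * n_s + ["HOH"] * n_w,
        box=(6.0, 6.0, 6.0),
    )


class TestSurfaceWater:
    def test_fully_dry_when_all_waters_high(self):
        m = surface_water_occupancy(_hydration_frame([1.0, 1.5, 2.0]))
        assert m.total == 0

    def test_constructed_bin_counts(self):
        xy = [(0.1, 0.1), (0.1, 0.1), (3.1, 3.1)]
        m = surface_water_occupancy(
            _hydration_frame([0.2, 0.2, 0.2], xy), bin_size=1.0
        )
        assert m.total == 3
        assert m.counts[0, 0] == 2
        assert m.counts[3, 3] == 1
        assert m.counts.sum() == m.total

    def test_cutoff_at_box_height_counts_all(self):
        f = _hydration_frame([0.2, 1.0, 3.0, 5.0])
        m = surface_water_occupancy(f, height_cutoff=6.0)
        assert m.total == 4

    def test_monotone_in_cutoff(self):
        f = _hydration_frame([0.1, 0.3, 0.5, 1.0, 2.0])
        totals = [
            surface_water_occupancy(f, height_cutoff=h).total
            for h in (0.2, 0.35, 0.6, 1.5, 3.0)
        ]
        assert totals == sorted(totals)

    def test_no_water_rejected(self):
        f = make_frame([[0, 0, 0]], groups=["surface"], names=["SI"])
        with pytest.raises(ValueError):
            surface_water_occupancy(f)


class TestHydrogenBonds:
    def _frame(self, coords, names):
        return make_frame(coords, names=names)

    def test_ideal_linear_geometry_counted(self):
        # O-H...O, donor-acceptor 0.28 nm, perfectly linear
        f = self._frame([[0, 0, 0], [0.1, 0, 0], [0.28, 0, 0]], ["O", "H", "O"])
        assert hydrogen_bond_count(f, donors=[(0, 1)], acceptors=[2]) == 1

    def test_long_distance_not_counted(self):
        f = self._frame([[0, 0, 0], [0.1, 0, 0], [0.40, 0, 0]], ["O", "H", "O"])
        assert hydrogen_bond_count(f, donors=[(0, 1)], acceptors=[2]) == 0

    def test_bent_geometry_not_counted(self):
        f = self._frame([[0, 0, 0], [0.1, 0, 0], [0, 0.28, 0]], ["O", "H", "O"])
        assert hydrogen_bond_count(f, donors=[(0, 1)], acceptors=[2]) == 0

    def test_matches_all_pairs_brute_force(self, rng):
        n = 30
        xyz = rng.uniform(0, 1.2, size=(n, 3))
        f = make_frame(xyz, names=["O"] * n)
        donors = [(i, i + 1) for i in range(0, n - 1, 2)]
        acceptors = list(range(n))
        got = hydrogen_bond_count(f, donors, acceptors)
        brute = 0
        for d, h in donors:
            for a in acceptors:
                if a in (d, h):
                    continue
                dist = np.linalg.norm(xyz[a] - xyz[d])
                v1, v2 = xyz[h] - xyz[d], xyz[a] - xyz[d]
                ang = np.degrees(
                    np.arccos(
                        np.clip(
                            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                            -1,
                            1,
                        )
                    )
                )
                if dist <= 0.35 and ang <= 30.0:
                    brute += 1
        assert got == brute

    def test_invalid_hydrogen_index_rejected(self):
        f = self._frame([[0, 0, 0], [0.1, 0, 0], [0.28, 0, 0]], ["O", "H", "O"])
        with pytest.raises(ValueError):
            hydrogen_bond_count(f, donors=[(0, 99)], acceptors=[2])


class TestSasa:
    def test_lone_atom_matches_sphere_area(self):
        f = make_frame([[0, 0, 0]], names=["C"])
        got = sasa(f, np.array([0]), probe=0.14, n_points=1000)
        want = 4 * np.pi * (0.170 + 0.14) ** 2
        assert got == pytest.approx(want, rel=1e-6)

    def test_coincident_atoms_add_nothing(self):
        f1 = make_frame([[0, 0, 0]], names=["C"])
        f2 = make_frame([[0, 0, 0], [0, 0, 0 + 1e-9]], names=["C", "C"])
        a1 = sasa(f1, np.array([0]), n_points=500)
        a2 = sasa(f2, np.array([0, 1]), n_points=500)
        assert a2 == pytest.approx(a1, rel=0.02)

    def test_distant_atoms_are_additive(self):
        f = make_frame([[0, 0, 0], [5.0, 0, 0]], names=["C", "O"])
        both = sasa(f, np.array([0, 1]), n_points=500)
        each = sasa(f, np.array([0]), n_points=500) + sasa(f, np.array([1]), n_points=500)
        assert both == pytest.approx(each, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        xyz = rng.normal(scale=0.3, size=(12, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = xyz @ rot.T + 2.0
        a = sasa(make_frame(xyz, names=["C"] * 12), np.arange(12), n_points=400)
        b = sasa(make_frame(moved, names=["C"] * 12), np.arange(12), n_points=400)
        assert b == pytest.approx(a, rel=0.03)

    def test_unknown_element_rejected(self):
        f = make_frame([[0, 0, 0]], names=["Xx"])
        with pytest.raises(KeyError):
            sasa(f, np.array([0]))


class TestHydrophobicityIndex:
    def test_isoleucine_is_scale_maximum(self):
        from proteinglue import residue_scale

        assert hydrophobicity_index("ILE") == max(residue_scale().values())

    def test_arginine_is_scale_minimum(self):
        from proteinglue import residue_scale

        assert hydrophobicity_index("arginine") == min(residue_scale().values())

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            hydrophobicity_index("XYZ")


class TestShearStrength:
    def test_si_units(self):
        assert shear_strength((1.0, "N"), (1.0, "m^2")) == 1.0

    def test_zero_force(self):
        assert shear_strength((0.0, "N"), (2.0, "m^2")) == 0.0

    def test_molar_force_conversion(self):
        # 1600 kJ/mol/nm -> 2.66e-9 N; over 100 nm^2 -> ~2.66e7 Pa
        tau = shear_strength((1600.0, "kJ/mol/nm"), (100.0, "nm^2"))
        want = 1600e3 / 6.02214076e23 / 1e-9 / (100e-18)
        assert tau == pytest.approx(want, rel=1e-12)
        assert tau == pytest.approx(2.66e7, rel=0.01)

    def test_untagged_units_rejected(self):
        with pytest.raises(ValueError):
            shear_strength((1.0, "lbf"), (1.0, "m^2"))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            shear_strength((1.0, "N"), (0.0, "m^2"))


class TestTrajectoryIO:
    def test_write_read_roundtrip(self, tmp_path, rng):
        frames = [
            make_frame(
                rng.uniform(0, 5, size=(4, 3)),
                groups=["surface", "protein", "water", "water"],
                names=["SI", "CA", "OW", "OW"],
                residue_ids=[0, 1, 100, 101],
                residue_names=["SUR", "LEU", "HOH", "HOH"],
                time=float(i) * 0.5,
                box=(5, 5, 5),
            )
            for i in range(3)
        ]
        write_trajectory(frames, tmp_path / "t.xyz", tmp_path / "r.csv")
        back = read_trajectory(tmp_path / "t.xyz", tmp_path / "r.csv")
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert b.time == a.time
            np.testing.assert_allclose(b.xyz, a.xyz, atol=1e-6)
            assert list(b.groups) == list(a.groups)
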