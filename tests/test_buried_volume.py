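import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from radstab import (
    GridSpec,
    MolecularStructure,
    buried_volume,
    buried_volume_all_atoms,
    radius_scan,
)

from oracles import monte_carlo_buried


def single_atom(symbol="C"):
    return MolecularStructure(symbols=[symbol], coords=[[0.0, 0.0, 0.0]], id=symbol)


def analytic_single(r_atom, r_sphere):
    return 100.0 * (r_atom / r_sphere) ** 3


class TestSingleSphere:
    def test_carbon_matches_closed_form(self):
        res = buried_volume(single_atom("C"), 0)
        assert res.percent_buried == pytest.approx(analytic_single(1.70, 3.5), abs=0.2)

    def test_percent_consistent_with_voxel_counts(self):
        res = buried_volume(single_atom("C"), 0)
        assert res.percent_buried == 100.0 * res.occupied_voxels / res.total_voxels

    def test_atom_radius_exceeding_sphere_gives_100(self):
        res = buried_volume(single_atom("S"), 0, GridSpec(sphere_radius=1.5, spacing=0.05))
        assert res.percent_buried == 100.0

    def test_error_strictly_decreases_with_spacing(self):
        exact = analytic_single(1.70, 3.5)
        errs = [
            abs(buried_volume(single_atom("C"), 0, GridSpec(spacing=h)).percent_buried - exact)
            for h in (0.2, 0.1, 0.05)
        ]
        assert errs[0] > errs[1] > errs[2]


class TestMethyl:
    def test_at_least_13_percent(self, methyl_vbur):
        assert methyl_vbur >= 13.0

    def test_matches_monte_carlo_union_oracle(self, methyl):
        struct, _ = methyl
        grid = GridSpec()
        mc, sigma = monte_carlo_buried(struct, 0, grid)
        assert buried_volume(struct, 0, grid).percent_buried == pytest.approx(
            mc, abs=max(0.2, 3 * sigma)
        )

    def test_carbon_more_buried_than_each_hydrogen(self, methyl):
        struct, _ = methyl
        results = buried_volume_all_atoms(struct, GridSpec(spacing=0.1))
        assert len(results) == 4
        assert all(results[0].percent_buried > r.percent_buried for r in results[1:])

    def test_all_atoms_consistent_with_single_calls(self, methyl):
        struct, _ = methyl
        grid = GridSpec(spacing=0.2, sphere_radius=2.0)
        allres = buried_volume_all_atoms(struct, grid)
        for i, r in enumerate(allres):
            assert r.percent_buried == buried_volume(struct, i, grid).percent_buried


class TestInvariants:
    def test_bounds_with_center_included(self, library):
        for name, struct, _ in library:
            res = buried_volume(struct, 0, GridSpec(spacing=0.15))
            assert 0.0 < res.percent_buried <= 100.0, name

    def test_monotone_under_atom_addition(self, methyl):
        struct, _ = methyl
        grid = GridSpec(spacing=0.1)
        base = buried_volume(struct, 0, grid).percent_buried
        bigger = MolecularStructure(
            symbols=struct.symbols + ["C"],
            coords=np.vstack([struct.coords, [[0.0, 0.0, 1.5]]]),
        )
        assert buried_volume(bigger, 0, grid).percent_buried >= base

    def test_rigid_motion_jitter_below_bound(self, methyl, methyl_vbur):
        struct, _ = methyl
        rng = np.random.default_rng(20210604)
        for _ in range(4):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-2, 2, 3)
            moved = MolecularStructure(
                symbols=struct.symbols, coords=struct.coords @ rot.T + shift
            )
            jitter = abs(buried_volume(moved, 0).percent_buried - methyl_vbur)
            assert jitter <= 0.15

    def test_center_exclusion_lowers_occupancy(self, methyl):
        struct, _ = methyl
        grid = GridSpec(spacing=0.1)
        with_c = buried_volume(struct, 0, grid).percent_buried
        without = buried_volume(
            struct, 0, GridSpec(spacing=0.1, include_center_atom=False)
        ).percent_buried
        assert without < with_c

    def test_hydrogen_exclusion_matches_bare_center(self, methyl):
        struct, _ = methyl
        grid = GridSpec(spacing=0.1, include_hydrogens=False)
        res = buried_volume(struct, 0, grid)
        bare = buried_volume(single_atom("C"), 0, GridSpec(spacing=0.1))
        assert res.percent_buried == pytest.approx(bare.percent_buried)

    def test_monte_carlo_agreement_multi_sphere(self):
        # 4-sphere system with all pairwise overlaps exercised
        struct = MolecularStructure(
            symbols=["C", "N", "O", "H"],
            coords=[[0, 0, 0], [1.3, 0, 0], [0, 1.4, 0], [-0.9, -0.5, 0.4]],
        )
        grid = GridSpec()
        mc, sigma = monte_carlo_buried(struct, 0, grid)
        assert buried_volume(struct, 0, grid).percent_buried == pytest.approx(
            mc, abs=max(0.2, 3 * sigma)
        )


class TestErrors:
    def test_invalid_center_index(self, methyl):
        struct, _ = methyl
        with pytest.raises(IndexError):
            buried_volume(struct, 4)

    def test_unknown_element_radius(self):
        s = MolecularStructure(symbols=["U"], coords=[[0, 0, 0]])
        with pytest.raises(KeyError):
            buried_volume(s, 0)

    @pytest.mark.parametrize("radius,spacing", [(0.0, 0.05), (3.5, 0.5), (3.5, 0.0)])
    def test_grid_spec_validation(self, radius, spacing):
        with pytest.raises(ValueError):
            GridSpec(sphere_radius=radius, spacing=spacing)


class TestRadiusScan:
    def test_single_atom_closed_forms(self):
        scan = radius_scan(single_atom("C"), 0, [2.5, 3.5])
        assert scan[0][1] == pytest.approx(analytic_single(1.70, 2.5), abs=0.2)
        assert scan[1][1] == pytest.approx(analytic_single(1.70, 3.5), abs=0.2)
        assert scan[0][0] == 2.5 and scan[1][0] == 3.5

    def test_percent_non_increasing_once_molecule_contained(self, methyl):
        struct, _ = methyl
        # all vdW spheres lie within 1.08 + 1.2 = 2.28 Å of the center
        scan = radius_scan(struct, 0, [2.5, 3.0, 3.5, 4.0], GridSpec(spacing=0.1))
        percents = [p for _, p in scan]
        assert all(a >= b for a, b in zip(percents, percents[1:]))

    def test_empty_radii_list(self, methyl):
        struct, _ = methyl
        assert radius_scan(struct, 0, []) == []

    def test_non_ascending_radii_rejected(self, methyl):
        struct, _ = methyl
        with pytest.raises(ValueError):
            radius_scan(struct, 0, [3.5, 2.5])
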