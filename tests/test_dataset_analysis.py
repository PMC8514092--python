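import io

import numpy as np
import pytest

from radstab import (
    element_counts,
    load_dataset,
    percentile_rank,
    r_squared,
    radius_robustness,
    stable_enrichment,
    write_sdf,
)
from radstab.fixtures import dataset_to_frame, fixture_library, synthetic_dataset

TWO_MOL_CSV = """molecule_id,atom_index,element,fractional_spin,percent_buried
mol-a,0,C,0.7,30.0
mol-a,1,C,0.3,25.0
mol-a,2,H,0.0,10.0
mol-b,0,O,0.2,20.0
mol-b,1,N,0.8,45.0
"""


class TestLoadDataset:
    def test_two_molecule_fixture_recomputes_centers(self):
        records = load_dataset(io.StringIO(TWO_MOL_CSV))
        assert len(records) == 2
        a, b = records
        assert (a.center_index, a.center_element, a.max_fraction) == (0, "C", 0.7)
        assert (b.center_index, b.center_element) == (1, "N")
        assert b.percent_buried_at_center == 45.0

    def test_missing_atom_index_names_molecule(self):
        bad = TWO_MOL_CSV.replace("mol-a,1", "mol-a,3")
        with pytest.raises(ValueError, match="mol-a"):
            load_dataset(io.StringIO(bad))

    def test_missing_column_is_loud(self):
        with pytest.raises(ValueError, match="fractional_spin"):
            load_dataset(io.StringIO("molecule_id,atom_index,element,percent_buried\nm,0,C,10\n"))

    def test_stable_flagging(self):
        records = load_dataset(io.StringIO(TWO_MOL_CSV), stable_ids=["mol-b"])
        assert [r.is_known_stable for r in records] == [False, True]

    def test_sdf_join_has_no_orphans(self, library):
        structs = {name: s for name, s, _ in library}
        m = structs["methyl"]
        csv = "molecule_id,atom_index,element,fractional_spin,percent_buried\n"
        for i, el in enumerate(m.symbols):
            csv += f"methyl,{i},{el},{1.0 if i == 0 else 0.0},{20.0 + i}\n"
        records = load_dataset(io.StringIO(csv), sdf_source=write_sdf([m]))
        assert records[0].structure is not None
        assert records[0].structure.symbols == m.symbols

    def test_sdf_element_mismatch_raises(self, library):
        structs = {name: s for name, s, _ in library}
        m = structs["methyl"]
        csv = (
            "molecule_id,atom_index,element,fractional_spin,percent_buried\n"
            "methyl,0,N,1.0,20\nmethyl,1,H,0,5\nmethyl,2,H,0,5\nmethyl,3,H,0,5\n"
        )
        with pytest.raises(ValueError, match="mismatch"):
            load_dataset(io.StringIO(csv), sdf_source=write_sdf([m]))

    def test_synthetic_round_trip_through_csv(self):
        records, _ = synthetic_dataset(50, seed=9)
        frame = dataset_to_frame(records)
        reloaded = load_dataset(io.StringIO(frame.to_csv(index=False)))
        assert len(reloaded) == 50
        for orig, back in zip(records, reloaded):
            assert back.center_index == orig.center_index
            assert back.max_fraction == pytest.approx(orig.max_fraction)
            assert back.center_element == orig.center_element


class TestElementCounts:
    def test_known_composition_exact(self):
        records = load_dataset(io.StringIO(TWO_MOL_CSV))
        assert element_counts(records) == {"C": 1, "N": 1}

    def test_counts_conserve_total(self):
        records, _ = synthetic_dataset(300, seed=2)
        counts = element_counts(records)
        assert sum(counts.values()) == 300


class TestPercentileRank:
    def test_values_1_to_100(self):
        values = list(range(1, 101))
        assert percentile_rank(values, 97) == 97.0

    def test_below_minimum(self):
        assert percentile_rank([1.0, 2.0, 3.0], 0.5) == 0.0

    def test_maximum_ranks_100(self):
        assert percentile_rank([1.0, 2.0, 3.0], 3.0) == 100.0

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=500)
        for x in rng.normal(size=20):
            expected = 100.0 * np.searchsorted(np.sort(values), x, side="right") / 500
            assert percentile_rank(values, x) == pytest.approx(expected)

    def test_monotone_in_x(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=200)
        xs = np.sort(rng.normal(size=50))
        ranks = [percentile_rank(values, x) for x in xs]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank([], 1.0)


class TestStableEnrichment:
    def test_top_three_of_hundred(self):
        rng = np.random.default_rng(8)
        values = np.sort(rng.uniform(0, 100, 100))
        assert stable_enrichment(values, values[-3:]) >= 97.0

    def test_dataset_minimum_scores_low(self):
        values = np.arange(1.0, 101.0)
        assert stable_enrichment(values, [values[0]]) == 1.0

    def test_invariant_under_order_preserving_transform(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(1, 50, 200)
        stable = rng.choice(values, 5)
        base = stable_enrichment(values, stable)
        assert stable_enrichment(np.exp(values / 10), np.exp(stable / 10)) == base


class TestRSquared:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constructed_orthogonal(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert r_squared(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=50), rng.normal(size=50)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov**2 / (np.var(x) * np.var(y))
        assert r_squared(x, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def robustness_matrix(library):
    from radstab import GridSpec

    structs = [s for _, s, _ in library]
    centers = [0] * len(structs)
    return radius_robustness(
        structs, centers, radii=(2.5, 3.0, 3.5, 4.0), grid=GridSpec(spacing=0.2)
    )


class TestRadiusRobustness:
    def test_symmetric_unit_diagonal(self, robustness_matrix):
        assert np.allclose(robustness_matrix, robustness_matrix.T)
        assert np.allclose(np.diag(robustness_matrix), 1.0)

    def test_sphere_radius_choice_is_robust(self, robustness_matrix):
        # neighboring sphere radii rank the fixtures near-identically; the
        # full 2.5-4.0 Å span stays strongly correlated even though the
        # library deliberately contains a volume-saturating cage archetype
        adjacent = [robustness_matrix[i, i + 1] for i in range(3)]
        assert all(r2 > 0.9 for r2 in adjacent)
        off = robustness_matrix[~np.eye(4, dtype=bool)]
        assert np.all(off > 0.75)

    def test_identical_structures_degenerate(self, library):
        s = library[0][1]
        with pytest.raises(ValueError):
            radius_robustness([s, s, s], [0, 0, 0])

    def test_too_few_structures(self, library):
        s = library[0][1]
        with pytest.raises(ValueError, match="at least 3"):
            radius_robustness([s], [0])
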