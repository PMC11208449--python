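import numpy as np
import pytest
from shapely.geometry import Polygon

from pedfem.regions import (
    Footprint,
    RegionPartition,
    footprint_from_model,
    partition_plantar,
    partition_subtalar,
    partition_talocrural,
    stress_percentages,
)


def _rect_footprint(nx=6, ny=18, toe_rows=3):
    """Toy rectangular footprint: toe masks cover the front rows."""
    xs = np.arange(nx) + 0.5
    ys = np.arange(ny) + 0.5
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cents = np.stack([X.ravel(), Y.ravel()], axis=1)
    ids = np.arange(len(cents))
    toe_y = ny - toe_rows
    hal = Polygon([(nx / 2, toe_y), (nx, toe_y), (nx, ny), (nx / 2, ny)])
    les = Polygon([(0, toe_y), (nx / 2, toe_y), (nx / 2, ny), (0, ny)])
    return Footprint(cell_ids=ids, centroids_xy=cents, hallux_poly=hal,
                     lesser_poly=les, medial_sign=1.0)


class TestPlantar:
    def test_eight_nonoverlapping_regions_cover_footprint(self):
        fp = _rect_footprint()
        part = partition_plantar(fp)
        assert sorted(part.labels) == list(range(1, 9))
        members = part.members()
        assert len(members) == len(fp.cell_ids)
        assert len(np.unique(members)) == len(members)

    def test_equal_thirds_along_length(self):
        """Toe-excluded footprint of length 30 splits at 10 and 20."""
        fp = _rect_footprint(nx=4, ny=33, toe_rows=3)   # non-toe length 30
        part = partition_plantar(fp)
        y8 = fp.centroids_xy[np.isin(fp.cell_ids, part.labels[8]), 1]
        y67 = fp.centroids_xy[np.isin(
            fp.cell_ids, np.r_[part.labels[6], part.labels[7]]), 1]
        y345 = fp.centroids_xy[np.isin(
            fp.cell_ids, np.concatenate(
                [part.labels[3], part.labels[4], part.labels[5]])), 1]
        assert y8.max() < 10.5 and abs(y8.max() - 10) <= 0.5
        assert 10 <= y67.min() and y67.max() <= 20.5
        assert y345.min() >= 19.5

    def test_uniform_stress_symmetric_bands(self):
        fp = _rect_footprint(nx=6, ny=18, toe_rows=3)
        part = partition_plantar(fp)
        vm = np.ones(len(fp.cell_ids))
        pct = stress_percentages(vm, part)
        # medial (3) and lateral (5) forefoot bands are mirror images
        assert pct.per_region[3] == pytest.approx(pct.per_region[5])
        assert pct.per_region[6] == pytest.approx(pct.per_region[7])

    def test_empty_footprint_rejected(self):
        fp = _rect_footprint()
        fp = Footprint(cell_ids=np.empty(0, int),
                       centroids_xy=np.empty((0, 2)),
                       hallux_poly=fp.hallux_poly,
                       lesser_poly=fp.lesser_poly)
        with pytest.raises(ValueError):
            partition_plantar(fp)

    def test_model_footprint_covers_sole(self, foot_model):
        fp = footprint_from_model(foot_model)
        part = partition_plantar(fp)
        assert len(part.members()) == len(fp.cell_ids)
        assert all(len(v) > 0 for v in part.labels.values())


class TestTalocrural:
    def test_equal_counts_3x3(self):
        rng = np.random.default_rng(0)
        cents = rng.uniform(0, 10, size=(90, 3))
        part = partition_talocrural(cents)
        assert all(len(v) == 10 for v in part.labels.values())

    def test_groupings_tile_the_surface(self):
        cents = np.random.default_rng(1).uniform(size=(45, 3))
        part = partition_talocrural(cents)
        anterior = np.concatenate([part.labels[i] for i in (1, 4, 7)])
        medial = np.concatenate([part.labels[i] for i in (1, 2, 3)])
        assert len(anterior) == 15 and len(medial) == 15
        assert part.grouping_axes["anterior"] == [1, 4, 7]

    def test_numbering_medial_anterior_first(self):
        # grid of known centroids: x medial+, y anterior+
        xs, ys = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
        cents = np.stack([xs.ravel(), ys.ravel(),
                          np.zeros(9)], axis=1).astype(float)
        part = partition_talocrural(cents)
        # region 1 = most medial (x=2), most anterior (y=2)
        assert part.labels[1][0] == np.nonzero(
            (cents[:, 0] == 2) & (cents[:, 1] == 2))[0][0]

    def test_uniform_stress_equal_thirds(self):
        cents = np.random.default_rng(2).uniform(size=(90, 3))
        part = partition_talocrural(cents)
        pct = stress_percentages(np.ones(90), part)
        for g in ("medial", "middle_ml", "lateral"):
            assert pct.per_group[g] == pytest.approx(100.0 / 3.0)

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            partition_talocrural(np.zeros((5, 3)))


class TestSubtalar:
    def _facets(self, n_post=40):
        rng = np.random.default_rng(3)
        cents = rng.uniform(0, 20, size=(100, 3))
        sets = {"anterior": np.arange(0, 20), "middle": np.arange(20, 40),
                "posterior": np.arange(40, 40 + n_post)}
        return sets, cents

    def test_posterior_quadrants_equal_counts(self):
        sets, cents = self._facets(40)
        facets, quad = partition_subtalar(sets, cents)
        assert all(len(v) == 10 for v in quad.labels.values())
        assert quad.grouping_axes["medial"] == [1, 2]
        assert quad.grouping_axes["anterior"] == [1, 3]

    def test_quadrants_tile_posterior_facet(self):
        sets, cents = self._facets(40)
        _, quad = partition_subtalar(sets, cents)
        union = np.sort(quad.members())
        assert np.array_equal(union, np.sort(sets["posterior"]))

    def test_uniform_stress_proportional_to_counts(self):
        sets, cents = self._facets(40)
        facets, _ = partition_subtalar(sets, cents)
        pct = stress_percentages(np.ones(100), facets)
        assert pct.per_region["anterior"] == pytest.approx(25.0)
        assert pct.per_region["posterior"] == pytest.approx(50.0)

    def test_missing_facet_rejected(self):
        sets, cents = self._facets()
        del sets["middle"]
        with pytest.raises(ValueError, match="middle"):
            partition_subtalar(sets, cents)


class TestStressPercentages:
    def test_single_region_is_100(self):
        part = RegionPartition("one", {1: np.arange(7)})
        pct = stress_percentages(np.full(7, 3.3), part)
        assert pct.per_region[1] == pytest.approx(100.0)

    def test_scale_invariance(self):
        part = RegionPartition("two", {1: np.arange(5), 2: np.arange(5, 12)})
        v = np.random.default_rng(4).uniform(0.1, 2.0, 12)
        a = stress_percentages(v, part).per_region
        b = stress_percentages(10.0 * v, part).per_region
        assert a[1] == pytest.approx(b[1])

    def test_sums_to_100_within_1e9(self):
        rng = np.random.default_rng(5)
        labels = {i: rng.choice(1000, size=rng.integers(5, 50),
                                replace=False) for i in range(1, 9)}
        # make labels disjoint
        used = np.concatenate(list(labels.values()))
        _, idx = np.unique(used, return_index=True)
        flat = used[np.sort(idx)]
        pos = 0
        for i in labels:
            n = len(labels[i])
            labels[i] = flat[pos:pos + min(n, len(flat) - pos)]
            pos += len(labels[i])
        part = RegionPartition("rand", labels)
        pct = stress_percentages(rng.uniform(0, 1, 1000), part)
        assert sum(pct.per_region.values()) == pytest.approx(100.0,
                                                             abs=1e-9)

    def test_zero_total_rejected(self):
        part = RegionPartition("one", {1: np.arange(3)})
        with pytest.raises(ValueError):
            stress_percentages(np.zeros(3), part)
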