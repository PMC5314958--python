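import numpy as np
import pytest

import protgrad as pg
from protgrad.errors import ConfigError, DegenerateDataError
from protgrad.histograms import GLOBAL, class_layout

from conftest import make_cells


class TestFilterCells:
    def test_five_percent_threshold_is_inclusive(self, hand_cells):
        cells = hand_cells.assign(terrestrial_fraction=[0.04, 0.05, 0.9, 0.5])
        kept = pg.filter_cells(cells)
        assert sorted(kept["terrestrial_fraction"]) == [0.05, 0.5, 0.9]

    def test_identity_when_all_terrestrial(self, hand_cells):
        assert len(pg.filter_cells(hand_cells)) == len(hand_cells)

    def test_all_oceanic_raises(self, hand_cells):
        cells = hand_cells.assign(terrestrial_fraction=0.01)
        with pytest.raises(DegenerateDataError):
            pg.filter_cells(cells)


class TestClassWidth:
    def test_uniform_distribution_width(self):
        rng = np.random.default_rng(0)
        cells = make_cells(10001, rng, v=np.linspace(0, 100, 10001))
        width = pg.default_class_width(cells, "v")
        assert width == pytest.approx(4.75, rel=1e-3)

    def test_constant_variable_raises(self, hand_cells):
        cells = hand_cells.assign(v=1.0)
        with pytest.raises(DegenerateDataError):
            pg.default_class_width(cells, "v")

    def test_regions_share_the_global_layout(self):
        rng = np.random.default_rng(1)
        cells = make_cells(600, rng)
        spec = pg.VariableSpec("v", "representative")
        width = pg.default_class_width(cells, "v")
        h_global = pg.build_histogram(cells, spec, region=GLOBAL, width=width)
        h_region = pg.build_histogram(cells, spec, region="r1", width=width)
        assert [c.lower for c in h_region.classes] == [c.lower for c in h_global.classes]


class TestBuildHistogram:
    def test_hand_aggregation(self, hand_cells):
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(hand_cells, spec, width=1.0, truncation=(0.0, 1.0))
        got = [(c.lower, c.upper, c.area, c.area_prot, c.frac_prot) for c in h.classes]
        assert got == [
            (1.0, 2.0, 200.0, 40.0, 0.2),
            (2.0, 3.0, 200.0, 20.0, 0.1),
            (3.0, 4.0, 100.0, 0.0, 0.0),
        ]

    def test_zero_protection_world(self, hand_cells):
        cells = hand_cells.assign(protected_fraction=0.0)
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(cells, spec, width=1.0, truncation=(0.0, 1.0))
        assert h.total_area_prot == 0.0
        assert all(c.frac_prot == 0.0 for c in h.nonempty)

    @pytest.mark.parametrize("truncation", [(0.0, 1.0), (0.025, 0.975), (0.1, 0.9)])
    @pytest.mark.parametrize("width_scale", [0.5, 1.0, 3.0])
    def test_conservation_under_any_layout(self, truncation, width_scale):
        rng = np.random.default_rng(42)
        cells = make_cells(800, rng)
        spec = pg.VariableSpec("v", "representative")
        width = width_scale * pg.default_class_width(cells, "v", truncation=truncation)
        h = pg.build_histogram(cells, spec, width=width, truncation=truncation)
        terr = cells["cell_area_km2"] * cells["terrestrial_fraction"]
        assert h.total_area == pytest.approx(terr.sum(), rel=1e-12)
        assert h.total_area_prot == pytest.approx(
            (terr * cells["protected_fraction"]).sum(), rel=1e-12
        )
        # class-level protected fraction is a weighted mean of cell fractions
        for c in h.nonempty:
            assert 0.0 <= c.frac_prot <= 1.0

    def test_tail_pooling_bounds(self):
        rng = np.random.default_rng(3)
        cells = make_cells(2000, rng)
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(cells, spec)
        v = cells["v"]
        assert h.classes[0].lower == pytest.approx(v.min())
        assert h.classes[-1].upper == pytest.approx(v.max())
        # interior classes have the fixed width
        interior = h.classes[1:-1]
        assert all(c.upper - c.lower == pytest.approx(h.class_width) for c in interior)

    def test_unknown_region_raises(self, hand_cells):
        spec = pg.VariableSpec("v", "representative")
        with pytest.raises(ConfigError):
            pg.build_histogram(hand_cells, spec, region="nowhere", width=1.0)

    def test_empty_interior_classes_retained(self, hand_cells):
        cells = hand_cells.assign(v=[1.0, 1.1, 5.0, 5.1])
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(cells, spec, width=1.0, truncation=(0.0, 1.0))
        assert any(c.area == 0 for c in h.classes)
        assert len(h.nonempty) == 2


class TestEnsureMinClasses:
    def test_compliant_histogram_unchanged(self):
        rng = np.random.default_rng(5)
        cells = make_cells(500, rng)
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(cells, spec)
        assert pg.ensure_min_classes(h, cells, spec) is h

    def test_width_halving_reaches_minimum(self):
        rng = np.random.default_rng(6)
        cells = make_cells(400, rng)
        spec = pg.VariableSpec("v", "representative")
        wide = pg.build_histogram(cells, spec,
                                  width=10 * pg.default_class_width(cells, "v"))
        assert len(wide.nonempty) < 8
        fixed = pg.ensure_min_classes(wide, cells, spec)
        assert len(fixed.nonempty) >= 8
        assert fixed.total_area == pytest.approx(wide.total_area, rel=1e-12)

    def test_too_few_distinct_values_raises(self, hand_cells):
        cells = hand_cells.assign(v=[1.0, 1.0, 2.0, 3.0])
        spec = pg.VariableSpec("v", "representative")
        h = pg.build_histogram(cells, spec, width=1.0, truncation=(0.0, 1.0))
        with pytest.raises(DegenerateDataError, match="distinct"):
            pg.ensure_min_classes(h, cells, spec)


def test_values_on_internal_bounds_open_the_upper_class():
    layout = class_layout(np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
                         width=1.0, truncation=(0.0, 1.0))
    assert list(layout.assign(np.array([0.0, 0.9, 1.0, 3.0, 4.0]))) == [0, 0, 1, 3, 4]
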