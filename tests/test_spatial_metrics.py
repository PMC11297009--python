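"""Spatial metrics against brute-force oracles and geometric invariances."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spatsig.cell_data import PanelError, phenotype_mask
from spatsig.spatial_metrics import (DEFAULT_PAIRS, density, metrics_for_core,
                                     metrics_table, mnnd, proximity)

from conftest import make_core, random_core


def brute_mnnd(a: np.ndarray, idx_a, b: np.ndarray, idx_b) -> float:
    """O(n²) all-pairs mean of row minima, excluding self-pairs by cell id."""
    d = cdist(a, b)
    for i, ia in enumerate(idx_a):
        for j, ib in enumerate(idx_b):
            if ia == ib:
                d[i, j] = np.inf
    mins = d.min(axis=1)
    mins = mins[np.isfinite(mins)]
    return float(mins.mean())


def brute_proximity(a, idx_a, b, idx_b, r) -> float:
    d = cdist(a, b)
    total = 0
    for j, ib in enumerate(idx_b):
        count = 0
        for i, ia in enumerate(idx_a):
            if ia != ib and d[i, j] <= r:
                count += 1
        total += count
    return total / len(idx_b)


def _points(core, phen):
    mask = phenotype_mask(core.cells, phen)
    idx = np.flatnonzero(mask)
    return core.cells[["x_um", "y_um"]].to_numpy(float)[idx], idx


class TestDensity:
    def test_simple_count_per_area(self):
        core = make_core({"Tumor": [(i, i) for i in range(100)]})
        assert density(core, "Tumor").value == pytest.approx(100.0)

    def test_zero_cells_defined_zero(self):
        core = make_core({"Tumor": [(0, 0)]})
        mv = density(core, "CD8Treg")
        assert mv.value == 0.0 and mv.defined


class TestMnnd:
    def test_three_four_five(self):
        core = make_core({"CD4Treg": [(0, 0)], "Tumor": [(3, 4)]})
        assert mnnd(core, "CD4Treg", "Tumor").value == pytest.approx(5.0)

    def test_two_source_mean(self):
        core = make_core({"CD4Treg": [(0, 0), (10, 0)],
                          "Tumor": [(0, 1), (10, 3)]})
        assert mnnd(core, "CD4Treg", "Tumor").value == pytest.approx(2.0)

    def test_empty_target_undefined(self):
        core = make_core({"CD4Treg": [(0, 0)]})
        mv = mnnd(core, "CD4Treg", "Tumor")
        assert not mv.defined and np.isnan(mv.value)

    def test_sole_target_is_source_itself_undefined(self):
        core = make_core({"CD4Treg": [(0, 0)]})
        assert not mnnd(core, "CD4Treg", "CD4all").defined

    def test_self_exclusion_on_overlapping_gates(self):
        core = make_core({"CD4Treg": [(0, 0), (7, 0)], "CD4Tcon": [(100, 0)]})
        # each Treg's nearest CD4all cell other than itself is the other Treg
        assert mnnd(core, "CD4Treg", "CD4all").value == pytest.approx(7.0)

    def test_asymmetry(self):
        core = make_core({"CD4Treg": [(0, 0), (1, 0)],
                          "Tumor": [(0, 10), (500, 500)]})
        a = mnnd(core, "CD4Treg", "Tumor").value
        b = mnnd(core, "Tumor", "CD4Treg").value
        assert a != pytest.approx(b)


class TestProximity:
    def test_both_within_radius(self):
        core = make_core({"CD4Treg": [(0, 0), (0, 5)], "Tumor": [(0, 10)]})
        assert proximity(core, "CD4Treg", "Tumor", 30).value == pytest.approx(2.0)

    def test_outside_radius_zero(self):
        core = make_core({"CD4Treg": [(100, 100)], "Tumor": [(0, 0)]})
        assert proximity(core, "CD4Treg", "Tumor", 30).value == 0.0

    def test_closed_boundary(self):
        core = make_core({"CD4Treg": [(30, 0)], "Tumor": [(0, 0)]})
        assert proximity(core, "CD4Treg", "Tumor", 30).value == 1.0

    def test_invalid_radius(self):
        core = make_core({"Tumor": [(0, 0)]})
        with pytest.raises(ValueError):
            proximity(core, "CD4Treg", "Tumor", 0)

    def test_empty_target_undefined_but_empty_source_zero(self):
        core = make_core({"CD4Treg": [(0, 0)]})
        assert not proximity(core, "CD8Treg", "Tumor").defined
        assert proximity(core, "Tumor", "CD4Treg").value == 0.0

    def test_monotone_in_radius_and_bounded(self, rng):
        core = random_core(rng, n_cells=200)
        n_a = len(_points(core, "CD4all")[0])
        last = -1.0
        for r in (5, 15, 30, 60, 120):
            v = proximity(core, "CD4all", "Tumor", r).value
            assert v >= last and v <= n_a
            last = v


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        core = random_core(rng, n_cells=int(rng.integers(50, 300)),
                           core_id=f"O{seed}")
        for src, tgt in (("CD4Treg", "Tumor"), ("CD4Treg", "CD4all"),
                         ("CD8all", "CD4all")):
            a, ia = _points(core, src)
            b, ib = _points(core, tgt)
            mv = mnnd(core, src, tgt)
            pv = proximity(core, src, tgt, 30)
            if len(a) and len(b):
                expect = brute_mnnd(a, ia, b, ib)
                if np.isfinite(expect):
                    assert mv.value == pytest.approx(expect, rel=1e-12)
                assert pv.value == pytest.approx(
                    brute_proximity(a, ia, b, ib, 30), abs=0)


class TestInvariances:
    def _shift_rotate(self, core, theta, dx, dy):
        c = make_core({}, core_id="T")
        cells = core.cells.copy()
        xy = cells[["x_um", "y_um"]].to_numpy()
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = xy @ rot.T + [dx, dy]
        xy -= xy.min(axis=0) - 1.0   # keep inside an enlarged window
        cells[["x_um", "y_um"]] = xy
        c.cells = cells
        c.width_um = c.height_um = float(xy.max() + 10)
        return c

    def test_rigid_motion_invariance(self, rng):
        core = random_core(rng, n_cells=150)
        moved = self._shift_rotate(core, 0.7, 123.4, -56.7)
        for src, tgt in (("CD4Treg", "Tumor"), ("CD8all", "CD4all")):
            assert mnnd(moved, src, tgt).value == pytest.approx(
                mnnd(core, src, tgt).value, abs=1e-9)
            assert proximity(moved, src, tgt, 30).value == pytest.approx(
                proximity(core, src, tgt, 30).value, abs=0)

    def test_scaling_doubles_mnnd_and_maps_radius(self, rng):
        core = random_core(rng, n_cells=150)
        doubled = make_core({}, core_id="D")
        cells = core.cells.copy()
        cells[["x_um", "y_um"]] *= 2.0
        doubled.cells = cells
        doubled.width_um = doubled.height_um = 2000.0
        assert mnnd(doubled, "CD4all", "Tumor").value == pytest.approx(
            2 * mnnd(core, "CD4all", "Tumor").value, rel=1e-12)
        assert proximity(doubled, "CD4all", "Tumor", 60).value == pytest.approx(
            proximity(core, "CD4all", "Tumor", 30).value, abs=0)


class TestBatch:
    def test_panel1_default_plan_is_stable(self, rng):
        core = random_core(rng, n_cells=100)
        out1 = metrics_for_core(core)
        out2 = metrics_for_core(core)
        # 2 densities + 9 mNND + 9 proximity
        assert len(out1) == 2 + 2 * len(DEFAULT_PAIRS["panel1"])
        assert [(m.metric, m.source, m.target, m.value) for m in out1] == \
               [(m.metric, m.source, m.target, m.value) for m in out2]

    def test_panel2_includes_checkpoint_pair(self, rng):
        core = random_core(rng, n_cells=100, panel="panel2")
        kinds = {(m.metric, m.source, m.target) for m in metrics_for_core(core)}
        assert ("N", "PDL1pos", "PD1pos") in kinds
        assert ("P", "PDL1pos", "PD1pos") in kinds

    def test_wrong_panel_pair_raises(self, rng):
        core = random_core(rng, n_cells=50, panel="panel2")
        with pytest.raises(PanelError):
            metrics_for_core(core, pairs=[("CD4Treg", "Tumor")])

    def test_empty_core_all_undefined_except_density(self):
        core = make_core({})
        for mv in metrics_for_core(core):
            if mv.metric == "D":
                assert mv.value == 0.0 and mv.defined
            else:
                assert not mv.defined

    def test_long_table_layout(self, rng):
        cores = [random_core(rng, core_id=f"C{i}", region=reg)
                 for i, reg in enumerate(["IM", "TC"])]
        tab = metrics_table(cores)
        assert set(tab["region"]) == {"IM", "TC"}
        assert tab.groupby("core_id").size().nunique() == 1
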