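import numpy as np
import pytest

import landresist as lr
from landresist.surfaces import EO_CATEGORY, LandCover


def full_region(n, cellsize=25.0):
    """Study region covering an n x n template entirely."""
    mask = lr.Grid(values=np.ones((n, n)), xll=0, yll=0, cellsize=cellsize)
    return lr.StudyRegion(mask=mask, buffer=0.0)


class TestUniformSurface:
    def test_all_inside_cells_one(self):
        region = full_region(5)
        surf = lr.uniform_surface(region)
        assert (surf.grid.values == 1.0).all()
        assert surf.model_code == "UNIFORM"

    def test_counting_oracle_on_partial_region(self, rng):
        mask_vals = np.where(rng.uniform(size=(8, 8)) < 0.6, 1.0, np.nan)
        mask_vals[0, 0] = 1.0
        region = lr.StudyRegion(
            mask=lr.Grid(values=mask_vals, cellsize=25), buffer=0.0
        )
        surf = lr.uniform_surface(region, value=3.0)
        assert np.nansum(surf.grid.values) == 3.0 * region.n_inside

    def test_rejects_nonpositive_value(self):
        with pytest.raises(ValueError):
            lr.uniform_surface(full_region(2), value=0)


class TestGeneralizeTreeCover:
    def test_all_nontree_stays_nontree(self):
        fine = lr.Grid(values=np.zeros((10, 10)), cellsize=10)
        coarse = lr.generalize_tree_cover(fine, 25)
        assert (coarse.values[coarse.valid] == 0).all()

    def test_single_pixel_marks_containing_cell(self):
        values = np.zeros((10, 10))
        values[7, 3] = 1.0  # centre at x=35, y=25  ->  coarse cell col 1, bottom row
        fine = lr.Grid(values=values, xll=0, yll=0, cellsize=10)
        coarse = lr.generalize_tree_cover(fine, 25)
        treed = np.argwhere(coarse.values == 1.0)
        assert len(treed) == 1
        r, c = treed[0]
        assert coarse.cell_of(35.0, 25.0) == (r, c)

    def test_against_per_pixel_assignment_oracle(self, rng):
        values = (rng.uniform(size=(30, 30)) < 0.15).astype(float)
        fine = lr.Grid(values=values, xll=0, yll=0, cellsize=10)
        coarse = lr.generalize_tree_cover(fine, 25)
        oracle = np.zeros_like(coarse.values)
        for r in range(30):
            for c in range(30):
                if values[r, c] != 1.0:
                    continue
                x, y = fine.cell_center(r, c)
                rr, cc = coarse.cell_of(float(x), float(y))
                oracle[rr, cc] = 1.0
        assert np.array_equal(coarse.values, oracle)

    def test_monotone_in_tree_pixels(self, rng):
        base = (rng.uniform(size=(20, 20)) < 0.1).astype(float)
        more = base.copy()
        more[rng.uniform(size=(20, 20)) < 0.1] = 1.0
        g1 = lr.generalize_tree_cover(lr.Grid(values=base, cellsize=10), 25)
        g2 = lr.generalize_tree_cover(lr.Grid(values=more, cellsize=10), 25)
        assert (g2.values >= g1.values).all()

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError, match="binary"):
            lr.generalize_tree_cover(lr.Grid(values=np.full((2, 2), 0.5),
                                             cellsize=10), 25)


class TestScatteredTrees:
    def make(self, landcover_vals, tree_vals, cellsize=25.0):
        lc = lr.Grid(values=np.asarray(landcover_vals, float), cellsize=cellsize)
        tr = lr.Grid(values=np.asarray(tree_vals, float), cellsize=cellsize)
        return lc, tr

    def test_no_trees_unchanged(self):
        lc, tr = self.make(np.full((4, 4), float(LandCover.IMPROVED)),
                           np.zeros((4, 4)))
        out = lr.classify_scattered_trees(lc, tr)
        assert np.array_equal(out.values, lc.values)

    def test_50m_rule_exact_distances(self):
        # one tree at the centre of a 7x7 grid of 25 m cells: orthogonal
        # neighbours are 25 m away, diagonals ~35.36 m, two cells out
        # orthogonally is 50 m (included), three cells out is 75 m (not)
        n = 7
        lc_vals = np.full((n, n), float(LandCover.ARABLE))
        tree_vals = np.zeros((n, n))
        tree_vals[3, 3] = 1.0
        lc_vals[3, 3] = float(LandCover.TREE)
        lc, tr = self.make(lc_vals, tree_vals)
        out = lr.classify_scattered_trees(lc, tr, radius=50.0)
        scattered = float(LandCover.ARABLE_SCATTERED)
        for r in range(n):
            for c in range(n):
                if (r, c) == (3, 3):
                    continue
                d = 25.0 * np.hypot(r - 3, c - 3)
                assert (out.values[r, c] == scattered) == (d <= 50.0), (r, c, d)

    def test_tree_cell_never_scattered(self):
        lc_vals = np.full((3, 3), float(LandCover.UNIMPROVED))
        tree_vals = np.ones((3, 3))
        lc_vals[:, :] = float(LandCover.TREE)
        lc, tr = self.make(lc_vals, tree_vals)
        out = lr.classify_scattered_trees(lc, tr)
        assert (out.values == float(LandCover.TREE)).all()

    def test_non_agricultural_classes_unchanged(self):
        lc_vals = np.full((3, 3), float(LandCover.URBAN))
        tree_vals = np.zeros((3, 3))
        tree_vals[1, 1] = 1.0
        lc_vals[1, 1] = float(LandCover.TREE)
        lc, tr = self.make(lc_vals, tree_vals)
        out = lr.classify_scattered_trees(lc, tr)
        assert (out.values[lc.values == float(LandCover.URBAN)]
                == float(LandCover.URBAN)).all()

    def test_idempotent(self, rng):
        n = 12
        lc_vals = rng.choice(
            [float(c) for c in (LandCover.TREE, LandCover.UNIMPROVED,
                                LandCover.IMPROVED, LandCover.ARABLE,
                                LandCover.URBAN)], size=(n, n))
        tree_vals = (lc_vals == float(LandCover.TREE)).astype(float)
        lc, tr = self.make(lc_vals, tree_vals)
        once = lr.classify_scattered_trees(lc, tr)
        twice = lr.classify_scattered_trees(once, tr)
        assert np.array_equal(once.values, twice.values)

    def test_misaligned_grids_rejected(self):
        lc = lr.Grid(values=np.zeros((3, 3)), cellsize=25)
        tr = lr.Grid(values=np.zeros((3, 3)), xll=5.0, cellsize=25)
        with pytest.raises(ValueError, match="co-registered"):
            lr.classify_scattered_trees(lc, tr)


class TestTreeAndHabitatSurfaces:
    def test_tree_surface_values_and_code(self):
        region = full_region(3)
        tree = lr.Grid(values=np.eye(3), cellsize=25)
        surf = lr.tree_surface(tree, 5, region)
        assert surf.model_code == "TREE_1_5"
        assert (surf.grid.values[np.eye(3, dtype=bool)] == 1).all()
        assert (surf.grid.values[~np.eye(3, dtype=bool)] == 5).all()

    def test_all_tree_gives_uniform(self):
        region = full_region(3)
        tree = lr.Grid(values=np.ones((3, 3)), cellsize=25)
        surf = lr.tree_surface(tree, 100, region)
        assert (surf.grid.values == 1).all()

    def test_counting_oracle(self, rng):
        region = full_region(10)
        tree = lr.Grid(values=(rng.uniform(size=(10, 10)) < 0.4).astype(float),
                       cellsize=25)
        surf = lr.tree_surface(tree, 10, region)
        n_off = int((tree.values == 0).sum())
        assert int((surf.grid.values == 10).sum()) == n_off

    def test_monotone_dominance_across_off_values(self, rng):
        region = full_region(8)
        tree = lr.Grid(values=(rng.uniform(size=(8, 8)) < 0.5).astype(float),
                       cellsize=25)
        surfs = [lr.tree_surface(tree, off, region) for off in (2, 5, 10, 100)]
        for lo, hi in zip(surfs, surfs[1:]):
            assert (lo.grid.values <= hi.grid.values).all()

    def test_noncanonical_off_warns(self):
        region = full_region(2)
        tree = lr.Grid(values=np.ones((2, 2)), cellsize=25)
        with pytest.warns(UserWarning, match="canonical"):
            lr.tree_surface(tree, 7, region)
        with pytest.raises(ValueError):
            lr.tree_surface(tree, 1, region)

    def test_habitat_surface_relabelling_oracle(self, rng):
        region = full_region(6)
        hab_vals = (rng.uniform(size=(6, 6)) < 0.5).astype(float)
        hab = lr.Grid(values=hab_vals, cellsize=25)
        surf = lr.habitat_surface(hab, 2, region)
        assert surf.model_code == "HAB_1_2"
        oracle = np.where(hab_vals == 1.0, 1.0, 2.0)
        assert np.array_equal(surf.grid.values, oracle)

    def test_surface_valid_set_equals_region_inside(self, rng):
        mask_vals = np.where(rng.uniform(size=(9, 9)) < 0.7, 1.0, np.nan)
        region = lr.StudyRegion(mask=lr.Grid(values=mask_vals, cellsize=25),
                                buffer=0.0)
        tree = lr.Grid(values=(rng.uniform(size=(9, 9)) < 0.4).astype(float),
                       cellsize=25)
        surf = lr.tree_surface(tree, 10, region)
        assert np.array_equal(surf.grid.valid, region.inside)


class TestBinarizeSdm:
    def grid_from(self, values, cellsize=10.0):
        return lr.Grid(values=np.asarray(values, float), cellsize=cellsize)

    def sites_at(self, grid, cells, prefix):
        rows, cols = zip(*cells)
        xs, ys = grid.cell_center(np.array(rows), np.array(cols))
        return lr.SiteSet(ids=[f"{prefix}{i}" for i in range(len(cells))],
                          x=xs, y=ys)

    def test_perfectly_separable(self):
        sdm = self.grid_from([[0.9, 0.1], [0.9, 0.1]])
        pres = self.sites_at(sdm, [(0, 0), (1, 0)], "p")
        abs_ = self.sites_at(sdm, [(0, 1), (1, 1)], "a")
        out = lr.binarize_sdm(sdm, pres, abs_)
        assert set(np.unique(out.values)) == {0.0, 1.0}
        assert (out.values[:, 0] == 1).all() and (out.values[:, 1] == 0).all()

    def test_matches_exhaustive_threshold_scan(self, rng):
        vals = rng.uniform(size=(5, 8)).round(3)
        sdm = self.grid_from(vals)
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 5, 20), rng.integers(0, 8, 20))]
        pres_cells, abs_cells = cells[:10], cells[10:]
        pres = self.sites_at(sdm, pres_cells, "p")
        abs_ = self.sites_at(sdm, abs_cells, "a")
        out = lr.binarize_sdm(sdm, pres, abs_)

        p = np.array([vals[r, c] for r, c in pres_cells])
        a = np.array([vals[r, c] for r, c in abs_cells])
        best_t, best_j = None, -np.inf
        for t in sorted(np.unique(np.concatenate([p, a]))):
            j = np.mean(p >= t) + np.mean(a < t) - 1
            if j > best_j:
                best_t, best_j = t, j
        assert np.array_equal(out.values, (vals >= best_t).astype(float))

    def test_degenerate_scores_rejected(self):
        sdm = self.grid_from([[0.5, 0.5]])
        pres = self.sites_at(sdm, [(0, 0)], "p")
        abs_ = self.sites_at(sdm, [(0, 1)], "a")
        with pytest.raises(ValueError, match="degenerate"):
            lr.binarize_sdm(sdm, pres, abs_)


class TestLandcoverSurface:
    def test_reference_table_values(self):
        tables = lr.load_reference_tables()
        bt = tables["BT_EO_100"]
        region = full_region(2)
        lc = lr.Grid(
            values=np.array([[float(LandCover.TREE), float(LandCover.IMPROVED)],
                             [float(LandCover.TREE), float(LandCover.ARABLE)]]),
            cellsize=25,
        )
        surf = lr.landcover_surface(lc, bt, region)
        assert surf.grid.values[0, 0] == 1.0       # native tree-cover
        assert surf.grid.values[0, 1] == 2000.0    # cleared, no scattered trees
        assert surf.model_code == "BT_EO_100"

    def test_all_ones_table_gives_uniform(self):
        table = lr.ResistanceTable(
            model_code="FLAT", mapping={cat: 1.0 for cat in set(EO_CATEGORY.values())}
        )
        region = full_region(4)
        lc = lr.Grid(values=np.full((4, 4), float(LandCover.URBAN)), cellsize=25)
        surf = lr.landcover_surface(lc, table, region)
        assert (surf.grid.values == 1.0).all()

    def test_dictionary_lookup_oracle(self, rng):
        tables = lr.load_reference_tables()
        t = tables["GST_EO_5000"]
        region = full_region(10)
        codes = rng.choice([float(c) for c in LandCover], size=(10, 10))
        lc = lr.Grid(values=codes, cellsize=25)
        surf = lr.landcover_surface(lc, t, region)
        for r in range(10):
            for c in range(10):
                cat = EO_CATEGORY[LandCover(int(codes[r, c]))]
                assert surf.grid.values[r, c] == t.mapping[cat]

    def test_missing_class_named_in_error(self):
        table = lr.ResistanceTable(model_code="PARTIAL",
                                   mapping={"native_tree": 1.0})
        region = full_region(2)
        lc = lr.Grid(values=np.full((2, 2), float(LandCover.URBAN)), cellsize=25)
        with pytest.raises(KeyError, match="URBAN"):
            lr.landcover_surface(lc, table, region)

    def test_reference_tables_cover_all_models(self):
        tables = lr.load_reference_tables()
        assert {"UNIFORM", "TREE_1_2", "TREE_1_5", "TREE_1_10", "TREE_1_100",
                "HAB_1_2", "HAB_1_10"} <= set(tables)
        eo = [k for k in tables if "_EO_" in k]
        assert len(eo) == 16  # eight species at two distances
        for k in eo:
            assert all(1 <= v <= 10000 for v in tables[k].mapping.values())
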