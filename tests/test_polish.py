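import numpy as np
import pandas as pd
import pytest

from radscreen import (
    AssemblyError,
    DecompositionError,
    PlateLayout,
    ScreenCube,
    bscore_from_residuals,
    median_polish_3d,
    normalize_screen,
    scaled_mad,
)

from _oracles import polish_oracle_2d, polish_oracle_3d


def random_cube(rng, shape=(8, 12, 5), missing=0.05):
    values = rng.normal(10, 2, shape)
    mask = rng.random(shape) < missing
    values[mask] = np.nan
    return ScreenCube(values, [f"P{p}" for p in range(shape[2])])


def reconstruction_error(cube, d):
    fit = d.fitted() + d.residuals
    obs = cube.observed
    return np.nanmax(np.abs(fit[obs] - cube.values[obs]))


class TestMedianPolish:
    def test_constant_cube(self):
        cube = ScreenCube(np.full((4, 6, 3), 5.0), ["a", "b", "c"])
        d = median_polish_3d(cube)
        assert d.overall == pytest.approx(5.0)
        assert np.allclose(d.row_effects, 0)
        assert np.allclose(d.col_effects, 0)
        assert np.allclose(d.plate_effects, 0)
        assert np.allclose(d.residuals, 0)
        assert d.converged and d.n_iterations <= 2

    def test_additive_cube_recovered_exactly(self):
        a = np.array([-1.0, 0.0, 1.0])
        b = np.array([-2.0, 0.0, 2.0, 0.0, -2.0, 2.0])
        b = b - np.median(b)
        g = np.array([0.0, 0.0])
        values = 10 + a[:, None, None] + b[None, :, None] + g[None, None, :]
        d = median_polish_3d(ScreenCube(values, ["p1", "p2"]))
        assert d.overall == pytest.approx(10.0)
        assert np.allclose(d.row_effects, a, atol=1e-12)
        assert np.allclose(d.col_effects, b, atol=1e-12)
        assert np.allclose(d.plate_effects, g, atol=1e-12)
        assert np.nanmax(np.abs(d.residuals)) < 1e-12

    def test_matches_plain_loop_oracle_on_random_cubes(self, rng):
        for _ in range(10):
            cube = random_cube(rng)
            d = median_polish_3d(cube, max_iter=20, tol=1e-6)
            o_all, o_row, o_col, o_plate, o_res = polish_oracle_3d(
                cube.values, cube.observed, max_iter=20, tol=1e-6
            )
            assert d.overall == pytest.approx(o_all, abs=1e-9)
            assert np.allclose(d.row_effects, o_row, atol=1e-9)
            assert np.allclose(d.col_effects, o_col, atol=1e-9)
            assert np.allclose(d.plate_effects, o_plate, atol=1e-9)
            res = np.array(o_res)
            obs = cube.observed
            assert np.max(np.abs(d.residuals[obs] - res[obs])) < 1e-9

    def test_reconstruction_identity(self, rng):
        for _ in range(5):
            cube = random_cube(rng, missing=0.1)
            d = median_polish_3d(cube)
            assert reconstruction_error(cube, d) < 1e-8

    def test_missing_pattern_preserved_and_inert(self, rng):
        # residuals stay missing exactly where the cube was missing, and
        # masking one observed cell leaves every fully-observed row median
        # estimate finite (no NaN propagation through the sweeps)
        cube = random_cube(rng, missing=0.1)
        d = median_polish_3d(cube)
        assert np.array_equal(np.isnan(d.residuals), ~cube.observed)
        more = cube.values.copy()
        r, c, p = np.argwhere(cube.observed)[0]
        more[r, c, p] = np.nan
        d2 = median_polish_3d(ScreenCube(more, cube.plate_ids))
        assert np.isfinite(d2.row_effects).all()
        assert np.isfinite(d2.residuals[np.isfinite(more)]).all()

    def test_constant_shift_moves_only_overall(self, rng):
        cube = random_cube(rng)
        d1 = median_polish_3d(cube)
        d2 = median_polish_3d(ScreenCube(cube.values + 7.5, cube.plate_ids))
        assert d2.overall == pytest.approx(d1.overall + 7.5, abs=1e-8)
        assert np.allclose(d1.row_effects, d2.row_effects, atol=1e-8)
        obs = cube.observed
        assert np.allclose(d1.residuals[obs], d2.residuals[obs], atol=1e-8)

    def test_row_shift_absorbed_by_row_effect(self, rng):
        cube = random_cube(rng, missing=0.0)
        shifted = cube.values.copy()
        shifted[3] += 2.0
        d1 = median_polish_3d(cube, max_iter=100, tol=1e-10)
        d2 = median_polish_3d(
            ScreenCube(shifted, cube.plate_ids), max_iter=100, tol=1e-10
        )
        # the shift lands in overall + that row's effect (re-absorbing effect
        # medians into the overall term redistributes part of it)
        fit1 = d1.overall + d1.row_effects
        fit2 = d2.overall + d2.row_effects
        assert fit2[3] - fit1[3] == pytest.approx(2.0, abs=1e-8)
        others = np.delete(np.arange(len(fit1)), 3)
        assert np.allclose(fit1[others], fit2[others], atol=1e-8)
        obs = cube.observed
        assert np.max(np.abs(d1.residuals[obs] - d2.residuals[obs])) < 1e-8

    def test_identical_plates_reduce_to_2d_polish(self, rng):
        plate = rng.normal(5, 1, (6, 8))
        values = np.repeat(plate[:, :, None], 4, axis=2)
        d = median_polish_3d(ScreenCube(values, list("abcd")), max_iter=50,
                             tol=1e-9)
        assert np.allclose(d.plate_effects, 0, atol=1e-9)
        o_all, o_row, o_col, o_res = polish_oracle_2d(
            plate.tolist(), max_iter=50, tol=1e-9
        )
        assert d.overall == pytest.approx(o_all, abs=1e-8)
        assert np.allclose(d.row_effects, o_row, atol=1e-8)
        assert np.allclose(d.col_effects, o_col, atol=1e-8)
        assert np.allclose(d.residuals[:, :, 0], o_res, atol=1e-8)

    def test_all_missing_slice_raises_naming_slice(self):
        values = np.random.default_rng(0).normal(size=(4, 5, 3))
        values[:, 2, :] = np.nan
        with pytest.raises(DecompositionError, match="column slice 2"):
            median_polish_3d(ScreenCube(values, list("abc")))


class TestScaledMad:
    def test_zero_spread(self):
        assert scaled_mad([1, 1, 1]) == 0.0

    def test_hand_computed_value(self):
        # median 3, absolute deviations {2,1,0,1,2}, MAD 1
        assert scaled_mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            scaled_mad([])

    def test_normal_consistency(self):
        x = np.random.default_rng(42).standard_normal(10**6)
        assert scaled_mad(x) == pytest.approx(1.0, rel=0.01)


class TestBScores:
    def test_zero_residuals_degenerate(self):
        cube = ScreenCube(np.full((3, 4, 2), 2.0), ["a", "b"])
        d = median_polish_3d(cube)
        b = bscore_from_residuals(d)
        assert b.degenerate
        assert np.allclose(b.scores, 0.0)

    def test_scale_equivariance(self, rng):
        cube = random_cube(rng)
        b1 = bscore_from_residuals(median_polish_3d(cube))
        b2 = bscore_from_residuals(
            median_polish_3d(ScreenCube(cube.values * 2, cube.plate_ids))
        )
        obs = cube.observed
        assert np.allclose(b1.scores[obs], b2.scores[obs], atol=1e-8)

    def test_unit_scale_under_normal_residuals(self, rng):
        cube = ScreenCube(
            rng.standard_normal((16, 22, 30)), [f"p{i}" for i in range(30)]
        )
        b = bscore_from_residuals(median_polish_3d(cube))
        assert np.nanstd(b.scores) == pytest.approx(1.0, rel=0.05)


class TestNormalizeScreen:
    def test_differing_geometry_rejected(self, tiny_layout):
        other = PlateLayout("PL2", n_rows=8, n_cols=12,
                            roles={"A02": "sample"}, genes={"A02": "G1"})
        summaries = pd.DataFrame(
            {"plate": ["PL1"], "well": ["A03"], "role": ["sample"],
             "gene": ["G01"], "readout": [1.0]}
        )
        with pytest.raises(AssemblyError, match="geometry"):
            normalize_screen(summaries, {"PL1": tiny_layout, "PL2": other})

    def test_gene_scores_collapse_by_median(self, compact_sim):
        from radscreen import estimate_g1_cutoff, summarize_wells

        sim = compact_sim
        cells = sim.cells["rep1"]
        curve = estimate_g1_cutoff(cells)
        summaries = summarize_wells(cells, sim.layouts, min_cells=5,
                                    cutoff=curve.cutoff)
        res = normalize_screen(summaries, sim.layouts)
        # one score per gene; every scored gene exists in the layouts
        genes = {g for l in sim.layouts.values() for g in l.genes.values()}
        assert set(res.gene_scores.index) <= genes
        assert res.gene_scores.notna().all()
        # reconstruction identity on the assembled cube
        fit = res.decomposition.fitted() + res.decomposition.residuals
        obs = res.cube.observed
        assert np.nanmax(np.abs(fit[obs] - res.cube.values[obs])) < 1e-8

    def test_controls_masked_out_of_polish(self, compact_sim):
        from radscreen import estimate_g1_cutoff, summarize_wells

        sim = compact_sim
        cells = sim.cells["rep1"]
        curve = estimate_g1_cutoff(cells)
        summaries = summarize_wells(cells, sim.layouts, min_cells=5,
                                    cutoff=curve.cutoff)
        res = normalize_screen(summaries, sim.layouts)
        assert (res.well_scores["role"] == "sample").all()
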