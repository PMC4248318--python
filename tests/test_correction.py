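"""The 2D GC x mappability local-regression correction."""

import warnings

import numpy as np
import pytest

from shallowcn import bins, correction, counts, noise, simulate


def _grid_from_cells(x, y, z):
    return correction.MedianGrid(
        gc=np.asarray(x), mapp=np.asarray(y),
        median=np.asarray(z, dtype=float), n_bins=np.ones(len(x), dtype=np.int64),
    )


def _mesh(gc_lo=30, gc_hi=70, gc_step=2, mp_lo=50, mp_hi=100, mp_step=5):
    gx, gy = np.meshgrid(
        np.arange(gc_lo, gc_hi + 1, gc_step), np.arange(mp_lo, mp_hi + 1, mp_step)
    )
    return gx.ravel().astype(float), gy.ravel().astype(float)


class TestMedianGrid:
    def test_round_half_to_even(self, flat_annotation):
        ann = flat_annotation(3)
        ann.gc = np.array([40.5, 40.4, 41.5])
        mg = correction.median_count_grid(np.array([1.0, 2.0, 3.0]), ann)
        assert sorted(mg.gc) == [40, 42]
        cell40 = mg.median[mg.gc == 40][0]
        assert cell40 == pytest.approx(1.5)  # median of {1, 2}

    def test_median_resists_outlier(self, flat_annotation):
        ann = flat_annotation(3)
        mg = correction.median_count_grid(np.array([3.0, 5.0, 100.0]), ann)
        assert mg.n_cells == 1
        assert mg.median[0] == pytest.approx(5.0)
        assert mg.n_bins[0] == 3

    def test_no_usable_bins_rejected(self, flat_annotation):
        ann = flat_annotation(3)
        ann.usable = np.zeros(3, dtype=bool)
        with pytest.raises(ValueError):
            correction.median_count_grid(np.ones(3), ann)


class TestFitSurface:
    def test_reproduces_plane_exactly(self):
        x, y = _mesh()
        z = 2 + 0.1 * x + 0.05 * y
        for degree in (1, 2):
            s = correction.fit_surface(
                _grid_from_cells(x, y, z), family="least-squares", degree=degree
            )
            px = np.array([40.3, 55.5, 66.0, 31.0])
            py = np.array([72.1, 90.0, 51.0, 99.0])
            assert np.allclose(s.evaluate(px, py), 2 + 0.1 * px + 0.05 * py,
                               rtol=1e-10, atol=1e-9)

    def test_constant_medians_give_constant_surface(self):
        x, y = _mesh()
        s = correction.fit_surface(_grid_from_cells(x, y, np.full(len(x), 7.0)))
        assert np.allclose(s.evaluate(np.linspace(30, 70, 9), np.linspace(50, 100, 9)), 7.0)

    def test_symmetric_family_downweights_outlier(self):
        x, y = _mesh()
        z = 2 + 0.1 * x + 0.05 * y
        z_bad = z.copy()
        z_bad[len(z) // 2] *= 100.0
        s = correction.fit_surface(_grid_from_cells(x, y, z_bad), family="symmetric")
        i = len(z) // 2
        fitted = s.evaluate(x[i : i + 1], y[i : i + 1])[0]
        assert abs(fitted / z[i] - 1) < 0.01

    def test_collinear_cells_fit_along_their_line(self):
        x = np.arange(30.0, 70.0)
        y = np.full(40, 100.0)
        z = 1 + 0.2 * x
        s = correction.fit_surface(_grid_from_cells(x, y, z), family="least-squares")
        got = s.evaluate(np.array([45.3]), np.array([100.0]))[0]
        assert got == pytest.approx(1 + 0.2 * 45.3)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            correction.fit_surface(
                _grid_from_cells(np.array([40.0]), np.array([100.0]),
                                 np.array([1.0]))
            )

    def test_two_cells_degrade_to_line_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            s = correction.fit_surface(
                _grid_from_cells(np.array([40.0, 42.0]), np.array([100.0, 100.0]),
                                 np.array([1.0, 2.0])),
                family="least-squares",
            )
        assert s.evaluate(np.array([41.0]), np.array([100.0]))[0] == pytest.approx(1.5)

    def test_matches_direct_wls_oracle(self):
        """Batched local fits equal an independent per-point WLS solve."""
        rng = np.random.default_rng(6)
        x, y = _mesh(gc_step=4, mp_step=10)
        z = 5 + 0.05 * x + 0.02 * y + rng.normal(0, 0.5, len(x))
        span, degree = 0.65, 2
        s = correction.fit_surface(
            _grid_from_cells(x, y, z), span=span, family="least-squares", degree=degree
        )
        got = s.evaluate(x, y)
        import math

        q = max(int(math.ceil(span * len(x))), 7)
        for i in range(len(x)):
            d = np.hypot(x - x[i], y - y[i])
            dq = np.sort(d)[q - 1]
            w = np.clip(1 - (d / dq) ** 3, 0, None) ** 3
            dx, dy = x - x[i], y - y[i]
            X = np.column_stack([np.ones_like(dx), dx, dy, dx * dx, dx * dy, dy * dy])
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
            assert got[i] == pytest.approx(beta[0], rel=1e-8)


class TestCorrectCounts:
    def test_flat_surface_preserves_shape(self, flat_annotation):
        ann = flat_annotation(200)
        rng = np.random.default_rng(0)
        ann.gc = rng.uniform(35, 65, 200)
        adj = rng.poisson(30, 200).astype(float)
        s = correction.fit_surface(
            _grid_from_cells(*_mesh(), np.full(len(_mesh()[0]), 30.0)),
            family="least-squares",
        )
        corr = correction.correct_counts(adj, s, ann)
        assert np.allclose(corr, adj / 30.0)

    def test_unbiased_data_corrected_up_to_scale(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=2, bias="flat",
                                                     n_bins_per_chrom=400)
        mg = correction.median_count_grid(adj, ann)
        s = correction.fit_surface(mg)
        corr = correction.correct_counts(adj, s, ann)
        ok = np.isfinite(corr)
        ratio = adj[ok] / corr[ok]
        # flat truth: the fitted surface is near-constant, so the correction
        # is a near-global rescale
        assert np.nanstd(ratio) / np.nanmean(ratio) < 0.02

    def test_scale_equivariance(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=3, n_bins_per_chrom=300)
        mg1 = correction.median_count_grid(adj, ann)
        mg2 = correction.median_count_grid(adj * 10.0, ann)
        s1 = correction.fit_surface(mg1)
        s2 = correction.fit_surface(mg2)
        c1 = correction.correct_counts(adj, s1, ann)
        c2 = correction.correct_counts(adj * 10.0, s2, ann)
        ok = np.isfinite(c1)
        assert np.allclose(c1[ok], c2[ok], rtol=1e-9)


class TestResiduals:
    def test_basic_values(self, flat_annotation):
        ann = flat_annotation(3)
        x, y = _mesh()
        s = correction.fit_surface(
            _grid_from_cells(x, y, np.full(len(x), 10.0)), family="least-squares"
        )
        resid = correction.residuals(np.array([10.0, 0.0, 20.0]), s, ann)
        assert resid == pytest.approx([0.0, -1.0, 1.0])

    def test_consistent_with_correct_counts(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=5, n_bins_per_chrom=200)
        mg = correction.median_count_grid(adj, ann)
        s = correction.fit_surface(mg)
        corr = correction.correct_counts(adj, s, ann)
        resid = correction.residuals(adj, s, ann)
        ok = np.isfinite(corr)
        assert np.allclose(corr[ok], 1.0 + resid[ok])


class TestCrossValidateSpan:
    def test_smooth_bias_prefers_local_fit(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=7, bias="separable",
                                                     n_bins_per_chrom=1000)
        best, stats = correction.cross_validate_span(adj, ann, grid, [0.65, 10.0])
        assert stats[0.65] <= stats[10.0]

    def test_statistic_scale_invariant(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=8, n_bins_per_chrom=300)
        _, s1 = correction.cross_validate_span(adj, ann, grid, [0.65])
        _, s2 = correction.cross_validate_span(adj * 4.0, ann, grid, [0.65])
        assert s1[0.65] == pytest.approx(s2[0.65], rel=1e-9)

    def test_too_few_bins_rejected(self, flat_annotation):
        ann = flat_annotation(3)
        g = bins.make_bins([("1", 9)], 3)
        with pytest.raises(ValueError):
            correction.cross_validate_span(np.ones(3), ann, g, [0.65])


class TestIterativeCorrection:
    def test_unbiased_data_converges_immediately(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=9, bias="flat",
                                                     n_bins_per_chrom=300)
        surface, included, n_iter = correction.iterative_correction(
            adj, ann, resid_cutoff=5.0
        )
        assert n_iter == 1
        assert included.sum() == ann.usable.sum()

    def test_amplified_bins_excluded_and_surface_clean(self, poisson_pipeline):
        n = 8000  # cell medians need depth for a 2% surface comparison
        spec, grid, ann, raw, adj = poisson_pipeline(
            seed=9, n_bins_per_chrom=n // 2,
            copy_segments=[("1", 0, 50 * 15000, 10.0)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surface, included, n_iter = correction.iterative_correction(
                adj, ann, resid_cutoff=1.0
            )
        amplified = np.zeros(grid.n_bins, dtype=bool)
        amplified[:50] = True
        assert (~included & amplified).sum() == 50
        # shape agrees with a clean-data oracle surface after rescaling
        spec_c, grid_c, ann_c, raw_c, adj_c = poisson_pipeline(
            seed=31, n_bins_per_chrom=n // 2
        )
        oracle = correction.fit_surface(
            correction.median_count_grid(adj_c, ann_c)
        )
        qs = np.nanpercentile(ann.gc[ann.usable], [10, 90])
        gcq = np.linspace(qs[0], qs[1], 12)
        mpq = np.full(12, 100.0)
        a = surface.evaluate(gcq, mpq)
        b = oracle.evaluate(gcq, mpq)
        assert np.max(np.abs((a / a.mean()) / (b / b.mean()) - 1)) < 0.02

    def test_idempotent_at_fixed_point(self, poisson_pipeline):
        spec, grid, ann, raw, adj = poisson_pipeline(seed=10, n_bins_per_chrom=200)
        s1, inc1, _ = correction.iterative_correction(adj, ann, resid_cutoff=2.0)
        s2, inc2, n2 = correction.iterative_correction(
            adj, ann, resid_cutoff=2.0, usable=inc1
        )
        assert np.array_equal(inc1, inc2)

    def test_bad_cutoff_rejected(self, flat_annotation):
        with pytest.raises(ValueError):
            correction.iterative_correction(np.ones(5), flat_annotation(5), 0.0)


def test_post_correction_noise_reaches_counting_limit(poisson_pipeline):
    """With a smooth planted bias at N=30, the corrected profile's variance
    comes within 10% of the 1/N counting floor."""
    spec, grid, ann, raw, adj = poisson_pipeline(seed=12, bias="plane",
                                                 n_bins_per_chrom=4000)
    usable = ann.usable
    mg = correction.median_count_grid(adj, ann, usable)
    s = correction.fit_surface(mg)
    corr = correction.correct_counts(adj, s, ann, usable)
    sigma = noise.sigma_diff(np.where(usable, corr, np.nan), chrom=grid.chrom_code)
    N = raw[usable].mean()
    assert sigma**2 <= 1.1 / N
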