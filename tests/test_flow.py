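"""PIV displacement estimation, interpolation, divergence and flow
statistics, checked against literal brute-force oracles."""

import numpy as np
import pytest

from bordercell import flow as F


def brute_force_zncc(source, search):
    """Literal ZNCC of a source patch at every placement inside a search
    patch, written from the definition."""
    src = source.shape[0]
    K = search.shape[0] - src + 1
    out = np.full((K, K), -np.inf)
    s = source - source.mean()
    sn = np.sqrt((s * s).sum())
    for dy in range(K):
        for dx in range(K):
            w = search[dy : dy + src, dx : dx + src]
            wc = w - w.mean()
            denom = np.sqrt((wc * wc).sum()) * sn
            if denom > 0:
                out[dy, dx] = (wc * s).sum() / denom
    return out


def _cfg(source_px=9, search_px=17, **kw):
    # window areas chosen to convert back to the requested pixel sides at
    # 0.2 um/px: side = round_to_odd(sqrt(area)/pixel_size)
    return F.PIVConfig(
        source_area_um2=(source_px * 0.2) ** 2,
        search_area_um2=(search_px * 0.2) ** 2,
        **kw,
    )


class TestPIVConfig:
    def test_window_sides_from_default_areas(self):
        cfg = F.PIVConfig()
        assert cfg.source_side_px(0.2) == 5
        assert cfg.search_side_px(0.2) == 7

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            F.PIVConfig(corr_threshold_c0=1.5)
        with pytest.raises(ValueError):
            F.PIVConfig(source_area_um2=3.0, search_area_um2=2.0)

    def test_round_to_odd(self):
        assert [F.round_to_odd(x) for x in (0.4, 1.0, 4.2, 5.9, 7.0)] == [1, 1, 5, 5, 7]


class TestPivFramePair:
    def test_identical_frames_zero_displacement_unit_corr(self, speckle_pair):
        frame, _ = speckle_pair
        mask = np.ones_like(frame, dtype=bool)
        sp = F.piv_frame_pair(frame, frame, mask, _cfg(), 0.2, 10.0)
        assert sp.n_kept > 0
        assert np.allclose(sp.u, 0) and np.allclose(sp.v, 0)
        assert np.allclose(sp.corr, 1.0)

    def test_integer_shift_recovered_exactly(self, speckle_pair):
        frame, shifted = speckle_pair
        mask = np.ones_like(frame, dtype=bool)
        sp = F.piv_frame_pair(frame, shifted, mask, _cfg(), 0.2, 10.0)
        assert sp.n_kept == sp.n_candidates > 0
        # (3, 0) px/frame -> u = 3 * 0.2 um * 6 frames/min
        assert np.allclose(sp.u, 3 * 0.2 * 6.0)
        assert np.allclose(sp.v, 0.0)
        assert np.allclose(sp.corr, 1.0, atol=1e-12)

    def test_matches_bruteforce_oracle_everywhere(self, speckle_pair):
        frame, _ = speckle_pair
        rng = np.random.default_rng(11)
        other = frame * np.exp(rng.normal(0, 0.2, frame.shape))
        cfg = _cfg()
        mask = np.ones_like(frame, dtype=bool)
        sp = F.piv_frame_pair(frame, other, mask, cfg, 0.2, 10.0, frame_index=0)
        src, sea = 9, 17
        sh, hh = src // 2, sea // 2
        margin = hh - sh
        kept = {(x, y): (u, v, c) for x, y, u, v, c in zip(sp.x, sp.y, sp.u, sp.v, sp.corr)}
        n_checked = 0
        for cy in range(hh, 48 - hh, src):
            for cx in range(hh, 48 - hh, src):
                source = frame[cy - sh : cy + sh + 1, cx - sh : cx + sh + 1]
                search = other[cy - hh : cy + hh + 1, cx - hh : cx + hh + 1]
                corr = brute_force_zncc(source, search)
                best = corr.max()
                if not best > cfg.corr_threshold_c0:
                    assert (cx, cy) not in kept
                    continue
                ties = np.argwhere(corr == best) - margin
                order = sorted(
                    map(tuple, ties), key=lambda d: (d[0] ** 2 + d[1] ** 2, d[0], d[1])
                )
                dy, dx = order[0]
                u, v, c = kept[(cx, cy)]
                assert u == pytest.approx(dx * 0.2 * 6.0, abs=1e-12)
                assert v == pytest.approx(dy * 0.2 * 6.0, abs=1e-12)
                assert c == pytest.approx(best, abs=1e-9)
                n_checked += 1
        assert n_checked > 0

    def test_independent_noise_mostly_rejected(self):
        rng = np.random.default_rng(21)
        f0 = rng.random((64, 64))
        f1 = rng.random((64, 64))
        mask = np.ones((64, 64), dtype=bool)
        sp = F.piv_frame_pair(f0, f1, mask, _cfg(), 0.2, 10.0)
        assert sp.n_candidates >= 9
        assert sp.n_kept / sp.n_candidates < 0.10

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(F.FlowError):
            F.piv_frame_pair(
                np.ones((10, 10)), np.ones((10, 10)), np.ones((10, 10), bool),
                _cfg(), 0.2, 10.0,
            )


class TestInterpolateDense:
    def _sparse(self, xs, ys, us, vs):
        n = len(xs)
        return F.SparseFlow(
            x=np.array(xs), y=np.array(ys), u=np.array(us, float),
            v=np.array(vs, float), corr=np.ones(n), n_candidates=n,
        )

    def test_uniform_estimates_give_uniform_field(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:35, 5:35] = True
        sp = self._sparse([10, 20, 30, 15], [10, 25, 30, 30], [2.0] * 4, [1.0] * 4)
        field = F.interpolate_dense(sp, mask, F.PIVConfig(), 0.2)
        assert field.valid.any()
        assert np.allclose(field.u[field.valid], 2.0)
        assert np.allclose(field.v[field.valid], 1.0)

    def test_single_estimate_limited_to_kernel_radius(self):
        mask = np.ones((60, 60), dtype=bool)
        sp = self._sparse([30], [30], [1.5], [-0.5])
        cfg = F.PIVConfig()  # 6 um kernel -> radius 15 px at 0.2 um/px
        field = F.interpolate_dense(sp, mask, cfg, 0.2)
        ys, xs = np.nonzero(field.valid)
        r = np.hypot(xs - 30.0, ys - 30.0)
        assert r.max() <= 15.0 + 1e-9
        assert np.allclose(field.u[field.valid], 1.5)
        assert field.valid.sum() > 600  # covers most of the kernel disk

    def test_midpoint_of_two_estimates_is_arithmetic_mean(self):
        mask = np.ones((40, 40), dtype=bool)
        sp = self._sparse([14, 26], [20, 20], [1.0, 3.0], [0.0, 2.0])
        field = F.interpolate_dense(sp, mask, F.PIVConfig(), 0.2)
        assert field.u[20, 20] == pytest.approx(2.0)
        assert field.v[20, 20] == pytest.approx(1.0)

    def test_zero_estimates_all_invalid_not_error(self):
        sp = self._sparse([], [], [], [])
        field = F.interpolate_dense(sp, np.ones((20, 20), bool), F.PIVConfig(), 0.2)
        assert not field.valid.any()


class TestTemporalSmooth:
    def _field(self, value, valid=True):
        shape = (8, 8)
        return F.FlowField(
            u=np.full(shape, float(value)),
            v=np.zeros(shape),
            valid=np.full(shape, valid),
        )

    def test_constant_series_unchanged(self):
        fields = [self._field(2.0) for _ in range(5)]
        out = F.temporal_smooth(fields, F.PIVConfig(), 10.0)
        for f in out:
            assert np.allclose(f.u, 2.0)

    def test_impulse_with_invalid_neighbours_renormalizes_to_unit(self):
        fields = [self._field(0.0, valid=False) for _ in range(5)]
        fields[2] = self._field(1.0)
        out = F.temporal_smooth(fields, F.PIVConfig(), 10.0)
        # only frame 2 carries a valid sample; wherever it contributes the
        # renormalized weight must be exactly one
        assert np.allclose(out[2].u, 1.0)
        for t in (1, 3):
            assert np.allclose(out[t].u[out[t].valid], 1.0)

    def test_alternating_series_amplitude_reduced(self):
        fields = [self._field(1.0 if t % 2 == 0 else -1.0) for t in range(6)]
        out = F.temporal_smooth(fields, F.PIVConfig(), 10.0)
        inner = [np.abs(f.u).max() for f in out[1:-1]]
        assert all(a < 1.0 for a in inner)


class TestDivergence:
    def _field_from(self, u, v, valid=None):
        valid = np.ones_like(u, dtype=bool) if valid is None else valid
        return F.FlowField(u=u.astype(float), v=v.astype(float), valid=valid)

    def test_uniform_field_zero_divergence(self):
        f = self._field_from(np.full((20, 20), 3.0), np.full((20, 20), -2.0))
        d = F.divergence(f, 0.2)
        assert d.valid[1:-1, 1:-1].all()
        assert np.allclose(d.div[d.valid], 0.0)

    def test_linear_field_exact_everywhere_interior(self):
        a, b = 0.7, -0.3
        yy, xx = np.mgrid[0:30, 0:30].astype(float)
        f = self._field_from(a * xx * 0.2, b * yy * 0.2)  # u = a*x_um
        d = F.divergence(f, 0.2)
        assert np.allclose(d.div[d.valid], a + b, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        f = self._field_from(rng.random((15, 15)), rng.random((15, 15)))
        g = self._field_from(rng.random((15, 15)), rng.random((15, 15)))
        comb = self._field_from(2.0 * f.u + 3.0 * g.u, 2.0 * f.v + 3.0 * g.v)
        d = F.divergence(comb, 0.2)
        expect = 2.0 * F.divergence(f, 0.2).div + 3.0 * F.divergence(g, 0.2).div
        assert np.allclose(d.div[d.valid], expect[d.valid], atol=1e-10)

    def test_sink_truth_field_reads_minus_two_k(self, sink_movie):
        _, truth = sink_movie
        d = F.divergence(truth.flow_series[0], 0.2)
        from scipy import ndimage

        interior = ndimage.binary_erosion(truth.region_set.group_mask, iterations=2)
        assert np.allclose(d.div[d.valid & interior], -1.0)


class TestDirectionClassification:
    def test_trivial_directions(self):
        f = F.FlowField(
            u=np.array([[-1.0, 1.0, 0.0]]),
            v=np.zeros((1, 3)),
            valid=np.ones((1, 3), bool),
        )
        labels = F.classify_direction(f, (1.0, 0.0))
        assert labels.tolist() == [[F.RETROGRADE, F.ANTEROGRADE, F.UNCLASSIFIED]]

    def test_negating_motion_swaps_labels_everywhere(self):
        rng = np.random.default_rng(9)
        f = F.FlowField(
            u=rng.normal(size=(20, 20)), v=rng.normal(size=(20, 20)),
            valid=rng.random((20, 20)) > 0.2,
        )
        fwd = F.classify_direction(f, (0.6, -0.8))
        rev = F.classify_direction(f, (-0.6, 0.8))
        assert np.array_equal(rev, -fwd)

    def test_zero_motion_rejected(self):
        f = F.FlowField(u=np.ones((2, 2)), v=np.ones((2, 2)), valid=np.ones((2, 2), bool))
        with pytest.raises(F.FlowError):
            F.classify_direction(f, (0.0, 0.0))


class TestOccurrenceAndAngles:
    def _field(self, speed):
        shape = (10, 10)
        return F.FlowField(
            u=np.full(shape, float(speed)), v=np.zeros(shape),
            valid=np.ones(shape, bool),
        )

    def test_occurrence_fractions(self):
        mask = np.ones((10, 10), bool)
        fields = [self._field(2.0)] * 3
        assert F.flow_occurrence(fields, {"cables": mask}, 1.0)["cables"] == 1.0
        assert F.flow_occurrence(fields, {"cables": mask}, 5.0)["cables"] == 0.0
        half = self._field(2.0)
        half.u[:, 5:] = 0.1
        assert F.flow_occurrence([half], {"cables": mask}, 1.0)["cables"] == 0.5

    def test_empty_region_absent(self):
        out = F.flow_occurrence([self._field(1.0)], {"cables": np.zeros((10, 10), bool)}, 0.5)
        assert "cables" not in out

    def test_angle_histogram_axis_maps_to_90(self):
        axis = np.array([0.6, 0.8])
        f = F.FlowField(
            u=np.full((12, 12), axis[0]), v=np.full((12, 12), axis[1]),
            valid=np.ones((12, 12), bool),
        )
        edges, counts = F.angle_histogram(f, np.ones((12, 12), bool), axis)
        assert counts.sum() == 144
        bin90 = np.searchsorted(edges, 90.0, side="right") - 1
        assert counts[bin90] == 144

    def test_reversed_flow_maps_to_270(self):
        axis = np.array([1.0, 0.0])
        f = F.FlowField(
            u=np.full((6, 6), -2.0), v=np.zeros((6, 6)), valid=np.ones((6, 6), bool)
        )
        edges, counts = F.angle_histogram(f, np.ones((6, 6), bool), axis)
        bin270 = np.searchsorted(edges, 270.0, side="right") - 1
        assert counts[bin270] == 36

    def test_zero_field_empty_histogram(self):
        f = F.FlowField(u=np.zeros((6, 6)), v=np.zeros((6, 6)), valid=np.ones((6, 6), bool))
        _, counts = F.angle_histogram(f, np.ones((6, 6), bool), (1.0, 0.0))
        assert counts.sum() == 0


class TestSinkSignalCorrelation:
    def _div_series(self, values):
        out = []
        for v in values:
            out.append(
                F.DivergenceMap(div=np.full((8, 8), float(v)), valid=np.ones((8, 8), bool))
            )
        return out

    def test_constructed_identity_has_rho_one(self):
        rng = np.random.default_rng(4)
        divs = -rng.random(10)  # sinks of varying strength
        series = self._div_series(divs)
        myosin = np.stack([np.full((8, 8), -d) for d in divs])  # = mean(-div)
        rho, n, defined = F.sink_signal_correlation(series, myosin, np.ones((8, 8), bool))
        assert defined and n == 10
        assert rho == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(12)
        series = self._div_series(rng.normal(size=50))
        myosin = rng.normal(10.0, 1.0, size=(50, 8, 8))
        rho, n, defined = F.sink_signal_correlation(series, myosin, np.ones((8, 8), bool))
        assert defined and abs(rho) < 0.3

    def test_constant_series_flagged_undefined(self):
        series = self._div_series([-1.0] * 5)
        myosin = np.ones((5, 8, 8))
        rho, _, defined = F.sink_signal_correlation(series, myosin, np.ones((8, 8), bool))
        assert not defined and np.isnan(rho)


class TestEndToEnd:
    def test_sink_movie_pipeline_divergence(self, sink_movie):
        """PIV -> dense interpolation -> divergence on rendered frames
        must land within 25% of the analytic -2k."""
        stack, truth = sink_movie
        mask = truth.region_set.group_mask
        cfg = _cfg(source_px=9, search_px=21)
        fields = F.analyze_stack(
            stack.frames[:, 0], mask, cfg, stack.pixel_size_um, stack.frame_interval_s
        )
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, iterations=8)
        vals = np.concatenate(
            [F.divergence(f, 0.2).div[F.divergence(f, 0.2).valid & interior] for f in fields]
        )
        assert vals.size > 0
        assert abs(vals.mean() - (-1.0)) <= 0.25
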