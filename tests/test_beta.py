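"""Expression engine, beta maps, statistics, spectra and phasors."""
import numpy as np
import pytest

from spectromap import beta, masking, synth
from spectromap.errors import ConfigError, ExpressionError, SpectromapError
from spectromap.model import BetaConfig, ImageStack


def _stack(*planes):
    return ImageStack(data=np.stack([p.astype(float) for p in planes])[None, None])


class TestParser:
    def test_gp_form_parses_with_expected_identifiers(self):
        ev = beta.parse_expression("(C1-C2)/(C1+C2)")
        assert ev.identifiers == frozenset({"C1", "C2"})
        assert ev(C1=np.float64(300), C2=np.float64(100)) == pytest.approx(0.5)

    def test_syntax_error_reports_position(self):
        with pytest.raises(ExpressionError) as exc:
            beta.parse_expression("C1/")
        assert exc.value.position == 3

    def test_power_is_right_associative(self):
        ev = beta.parse_expression("2^3^2")
        assert float(ev()) == 512.0

    def test_unknown_identifier_rejected(self):
        with pytest.raises(ExpressionError):
            beta.parse_expression("C1+foo")

    def test_unary_minus_and_unicode_operators(self):
        assert float(beta.parse_expression("-2^2")()) == -4.0
        assert float(beta.parse_expression("6×2÷4")()) == 3.0

    def test_fuzz_against_reference_interpreter(self):
        """Random expression trees: rendered string must evaluate to the
        same value as direct tree evaluation."""
        rng = np.random.default_rng(42)
        ops = [("+", lambda a, b: a + b), ("-", lambda a, b: a - b),
               ("*", lambda a, b: a * b), ("/", lambda a, b: a / b)]

        def build(depth):
            if depth == 0 or rng.random() < 0.3:
                if rng.random() < 0.5:
                    v = round(float(rng.uniform(0.5, 9.5)), 3)
                    return str(v), v
                ident = f"C{rng.integers(1, 5)}"
                return ident, env[ident]
            sym, fn = ops[rng.integers(0, len(ops))]
            ls, lv = build(depth - 1)
            rs, rv = build(depth - 1)
            return f"({ls}{sym}{rs})", fn(lv, rv)

        for _ in range(300):
            env = {f"C{i}": float(rng.uniform(1, 100)) for i in range(1, 5)}
            text, expected = build(3)
            got = float(beta.parse_expression(text)(**{k: np.float64(v) for k, v in env.items()}))
            assert got == pytest.approx(expected, rel=1e-12)


class TestComputeBetaMap:
    def test_gp_arithmetic(self, gp_config):
        stack = _stack(np.full((4, 4), 300.0), np.full((4, 4), 100.0))
        bm = beta.compute_beta_map(stack, np.ones((4, 4), bool), gp_config)
        np.testing.assert_allclose(bm.values, 0.5)
        assert bm.removed_count == 0

    def test_zero_over_zero_removed_and_counted(self, gp_config):
        a = np.full((4, 4), 300.0)
        b = np.full((4, 4), 100.0)
        a[0, 0] = b[0, 0] = 0.0
        bm = beta.compute_beta_map(_stack(a, b), np.ones((4, 4), bool), gp_config)
        assert np.isnan(bm.values[0, 0])
        assert bm.removed_count == 1

    def test_two_phase_ring_yields_exact_closed_form(self, ring_scene, optimized_params, gp_config):
        _, stack, gt = ring_scene
        ms = masking.build_masks(stack, optimized_params)
        bm = beta.compute_beta_map(stack, ms.membrane_mask, gp_config)
        for phase_mask, b_true in zip(gt.pure_phase_masks[0], gt.phase_betas[0]):
            vals = bm.values[phase_mask & ms.membrane_mask]
            vals = vals[np.isfinite(vals)]
            assert vals.size > 0
            np.testing.assert_allclose(vals, b_true, atol=1e-12)

    def test_never_reads_outside_mask(self, gp_config):
        a = np.full((6, 6), 300.0)
        b = np.full((6, 6), 100.0)
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        a[~mask] = np.nan  # NaN traps outside the mask
        b[~mask] = np.nan
        bm = beta.compute_beta_map(_stack(a, b), mask, gp_config)
        assert np.isfinite(bm.values[mask]).all()
        assert bm.removed_count == 0

    def test_membrane_and_cytosol_are_independent(self, ring_scene, optimized_params):
        _, stack, _ = ring_scene
        ms = masking.build_masks(stack, optimized_params)
        cfg_m = BetaConfig(target="membrane")
        before = beta.compute_beta_map(stack, ms.membrane_mask, cfg_m).values
        # changing the cytosol computation must not touch the membrane map
        beta.compute_beta_map(
            stack, ms.cytosol_mask, BetaConfig(expression="C1/C2", target="cytosol")
        )
        after = beta.compute_beta_map(stack, ms.membrane_mask, cfg_m).values
        np.testing.assert_array_equal(before, after)

    def test_valid_range_removes_outliers(self):
        a = np.array([[4.0, 0.5]])
        b = np.array([[1.0, 1.0]])
        cfg = BetaConfig(expression="C1/C2", valid_range=[0.0, 2.0])
        bm = beta.compute_beta_map(_stack(a, b), np.ones((1, 2), bool), cfg)
        assert np.isnan(bm.values[0, 0]) and bm.values[0, 1] == 0.5
        assert bm.removed_count == 1

    def test_gp_preset_bounded_on_nonnegative_channels(self, gp_config):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 500, (32, 32))
        b = rng.uniform(0, 500, (32, 32))
        bm = beta.compute_beta_map(_stack(a, b), np.ones((32, 32), bool), gp_config)
        valid = bm.values[np.isfinite(bm.values)]
        assert (valid >= -1).all() and (valid <= 1).all()


class TestStatsAndHistogram:
    def test_median_of_three(self):
        bm = beta.BetaMap(values=np.array([[0.1, 0.2, 0.3]]), removed_count=0)
        assert beta.beta_stats(bm)["median"] == pytest.approx(0.2)

    def test_constant_map_zero_std(self):
        bm = beta.BetaMap(values=np.full((5, 5), 0.4), removed_count=0)
        assert beta.beta_stats(bm)["std"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sample_median_near_half(self):
        rng = np.random.default_rng(7)
        bm = beta.BetaMap(values=rng.uniform(0, 1, (100, 100)), removed_count=0)
        assert beta.beta_stats(bm)["median"] == pytest.approx(0.5, abs=0.02)

    def test_all_nan_raises(self):
        bm = beta.BetaMap(values=np.full((3, 3), np.nan), removed_count=9)
        with pytest.raises(SpectromapError):
            beta.beta_stats(bm)
        with pytest.raises(SpectromapError):
            beta.beta_histogram(bm)

    def test_two_phase_histogram_and_conservation(self):
        values = np.full((10, 10), np.nan)
        values.ravel()[:50] = 1 / 3
        values.ravel()[50:100] = -1 / 3
        bm = beta.BetaMap(values=values, removed_count=0)
        counts, _ = beta.beta_histogram(bm, bins=8, range=(-1, 1))
        assert sorted(counts[counts > 0]) == [50, 50]
        assert counts.sum() == np.isfinite(values).sum()


class TestSpectrumAndPhasor:
    def test_single_pixel_spectrum(self):
        stack = _stack(np.full((2, 2), 10.0), np.full((2, 2), 30.0))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        sp = beta.reconstruct_spectrum(stack, mask)
        np.testing.assert_allclose(sp.intensities, [10.0, 30.0])

    def test_two_pixel_mean(self):
        a = np.array([[10.0, 30.0]])
        b = np.array([[20.0, 40.0]])
        sp = beta.reconstruct_spectrum(_stack(a, b), np.ones((1, 2), bool))
        np.testing.assert_allclose(sp.intensities, [20.0, 30.0])

    def test_gaussian_spectrum_peak_recovered(self):
        centers = np.arange(32)
        profile = 100 * np.exp(-0.5 * ((centers - 12) / 3.0) ** 2)
        planes = [np.full((4, 4), v) for v in profile]
        sp = beta.reconstruct_spectrum(
            ImageStack(data=np.stack(planes)[None, None]), np.ones((4, 4), bool)
        )
        assert int(np.argmax(sp.intensities)) == 12

    def test_delta_and_uniform_phasor(self):
        delta = np.zeros(32)
        delta[0] = 5.0
        p = beta.phasor_transform(delta)
        assert (p.G, p.S) == (1.0, 0.0)
        p = beta.phasor_transform(np.ones(32))
        assert abs(p.G) < 1e-12 and abs(p.S) < 1e-12

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            sp = rng.uniform(0, 10, int(rng.integers(4, 64)))
            p = beta.phasor_transform(sp)
            n = len(sp)
            g = sum(sp[k] * np.cos(2 * np.pi * k / n) for k in range(n)) / sp.sum()
            s = sum(sp[k] * np.sin(2 * np.pi * k / n) for k in range(n)) / sp.sum()
            assert abs(p.G - g) < 1e-12 and abs(p.S - s) < 1e-12
            assert p.G**2 + p.S**2 <= 1 + 1e-12  # inside the unit circle

    def test_zero_spectrum_gives_nan_point(self):
        p = beta.phasor_transform(np.zeros(8))
        assert np.isnan(p.G) and np.isnan(p.S)


class TestRatioBeta:
    def test_simple_ratio(self):
        stack = _stack(np.full((2, 2), 80.0), np.full((2, 2), 40.0))
        bm = beta.ratio_beta(stack, np.ones((2, 2), bool), 0, 1)
        np.testing.assert_allclose(bm.values, 2.0)

    def test_zero_denominator_removed(self):
        stack = _stack(np.full((1, 1), 80.0), np.zeros((1, 1)))
        bm = beta.ratio_beta(stack, np.ones((1, 1), bool), 0, 1)
        assert np.isnan(bm.values[0, 0]) and bm.removed_count == 1

    def test_depolarization_scales_median_ratio(self):
        def scene(red):
            spec = synth.FixtureSpec(
                shape=(128, 128), n_channels=4, seed=1, noise_sigma=1.0, background=0.0,
                objects=[synth.RingSpec(center=(63.5, 63.5), radius=40, width=3,
                         phases=[synth.PhaseSpec(1.0, (160.0, 240.0, 0.0, 0.0))])],
            )
            return synth.make_cell_scene(spec, red_intensity=red)

        stack_c, gt_c = scene(80.0)
        stack_u, gt_u = scene(20.0)
        med_c = np.nanmedian(beta.ratio_beta(stack_c, gt_c.extras["puncta_mask"], 2, 3).values)
        med_u = np.nanmedian(beta.ratio_beta(stack_u, gt_u.extras["puncta_mask"], 2, 3).values)
        assert med_u / med_c == pytest.approx(0.25, rel=0.02)
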