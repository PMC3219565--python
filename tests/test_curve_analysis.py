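"""Tests for normalization, shifting, derivative Tm estimation and differences."""

import numpy as np
import pytest

from hrmelt.curve_analysis import (
    DegenerateBaselineError,
    FlatCurveError,
    LevelNotCrossedError,
    NoMeltError,
    DerivativeCurve,
    NormalizedCurve,
    auto_windows,
    derivative_curve,
    difference_amplitude,
    difference_curve,
    estimate_tm,
    estimate_tm_batch,
    normalize,
    temperature_shift,
    transition_width,
)
from hrmelt.melt_model import (
    HET,
    Baselines,
    DuplexSpecies,
    NoiseModel,
    RawMeltCurve,
    simulate_curve,
    species_mixture,
)


def single_species_curve(tm=85.0, width=0.35, grid=None, baselines=None, noise=None, rng=None):
    sp = DuplexSpecies(f"{tm}", tm, width, 1.0)
    return simulate_curve([sp], grid, baselines, noise, rng, sample_id="X", replicate=1)


def analytic_minus_derivative(t, mixture, baselines):
    """Closed-form -dF/dT of the noise-free signal model (oracle)."""
    u = baselines.upper(t)
    l = baselines.lower(t)
    h = np.zeros_like(t)
    dh = np.zeros_like(t)
    for sp in mixture:
        x = (t - sp.tm_c) / sp.width_c
        s = 1.0 / (1.0 + np.exp(x))
        h += sp.weight * s
        dh += sp.weight * (-s * (1.0 - s) / sp.width_c)
    du, dl = baselines.upper_slope_per_c, baselines.lower_slope_per_c
    return -(du * h + u * dh + dl * (1.0 - h) - l * dh)


class TestNormalize:
    def test_pinning_in_both_windows(self, ret, grid):
        curve = simulate_curve(species_mixture(HET, ret), grid)
        pre, post = auto_windows(curve)
        norm = normalize(curve, pre, post)
        t = norm.temperatures_c
        pre_mask = (t >= pre[0]) & (t <= pre[1])
        post_mask = (t >= post[0]) & (t <= post[1])
        assert abs(norm.values[pre_mask].mean() - 100.0) < 0.5
        assert abs(norm.values[post_mask].mean()) < 0.5

    def test_idempotent(self, grid):
        # exact idempotence needs flat baselines (with sloping baselines the
        # first normalization is a ratio of affine fits, not affine itself)
        curve = single_species_curve(grid=grid, baselines=Baselines(100.0, 0.0, 0.0, 0.0))
        pre, post = auto_windows(curve)
        once = normalize(curve, pre, post)
        twice = normalize(once, pre, post)
        assert np.max(np.abs(twice.values - once.values)) < 1e-6

    def test_pure_baseline_input_is_degenerate(self, grid):
        t = grid.temperatures()
        flatline = RawMeltCurve("F", 1, t, np.full(t.size, 50.0))
        with pytest.raises(DegenerateBaselineError):
            normalize(flatline, (66.0, 68.0), (90.0, 92.0))

    def test_window_outside_grid_rejected(self, grid):
        curve = single_species_curve(grid=grid)
        with pytest.raises(ValueError, match="window"):
            normalize(curve, (50.0, 52.0), (90.0, 92.0))


class TestAutoWindows:
    def test_windows_bracket_the_transition(self, grid):
        # derived by brute force: the derivative argmax of a Tm-85 species
        # sits at ~85, so pre lands in [65, 80] and post in [88, 95]
        curve = single_species_curve(tm=85.0, grid=grid)
        pre, post = auto_windows(curve)
        assert 65.0 <= pre[0] < pre[1] <= 80.0
        assert 88.0 <= post[0] < post[1] <= 95.0

    def test_translation_equivariance(self, grid):
        curve = single_species_curve(tm=85.0, grid=grid)
        shifted = RawMeltCurve("X", 1, curve.temperatures_c + 1.0, curve.fluorescence)
        pre0, post0 = auto_windows(curve)
        pre1, post1 = auto_windows(shifted)
        assert pre1 == pytest.approx(tuple(np.array(pre0) + 1.0))
        assert post1 == pytest.approx(tuple(np.array(post0) + 1.0))

    def test_flat_curve_rejected(self, grid):
        t = grid.temperatures()
        with pytest.raises(FlatCurveError):
            auto_windows(RawMeltCurve("F", 1, t, np.full(t.size, 3.0)))


class TestTemperatureShift:
    def test_reference_shift_is_zero(self, grid):
        curve = single_species_curve(grid=grid)
        norm = normalize(curve, *auto_windows(curve))
        (shifted,) = temperature_shift([norm], norm)
        assert shifted.shift_c == pytest.approx(0.0, abs=1e-9)

    def test_constructed_offset_recovered(self, grid):
        a = single_species_curve(tm=85.0, grid=grid)
        norm_a = normalize(a, *auto_windows(a))
        offset = NormalizedCurve(
            "B", 1, norm_a.temperatures_c + 0.5, norm_a.values.copy(),
            norm_a.pre_window, norm_a.post_window,
        )
        (shifted,) = temperature_shift([offset], norm_a)
        assert shifted.shift_c == pytest.approx(-0.5, abs=grid.spacing_c)

    def test_all_curves_cross_level_together(self, ret, grid):
        norms = []
        for genotype in ("hom_major", "het", "hom_minor"):
            c = simulate_curve(species_mixture(genotype, ret), grid)
            norms.append(normalize(c, *auto_windows(c)))
        shifted = temperature_shift(norms, norms[0], 5.0)
        crossings = []
        for s in shifted:
            below = np.nonzero(s.values < 5.0)[0]
            crossings.append(s.temperatures_c[below[0]])
        assert np.ptp(crossings) <= grid.spacing_c

    def test_values_untouched(self, grid):
        curve = single_species_curve(grid=grid)
        norm = normalize(curve, *auto_windows(curve))
        (shifted,) = temperature_shift([norm], norm)
        assert np.array_equal(shifted.values, norm.values)

    def test_level_never_reached_rejected(self, grid):
        t = grid.temperatures()
        high = NormalizedCurve(
            "H", 1, t, np.linspace(100.0, 60.0, t.size), (66.0, 68.0), (90.0, 92.0)
        )
        with pytest.raises(LevelNotCrossedError):
            temperature_shift([high], high, 5.0)


class TestDerivativeAndTm:
    def test_linear_input_constant_derivative(self, grid):
        t = grid.temperatures()
        curve = RawMeltCurve("L", 1, t, 100.0 - 2.0 * (t - 65.0))
        d = derivative_curve(curve, 25)
        interior = d.minus_df_dt[30:-30]
        assert np.max(np.abs(interior - 2.0)) < 1e-9

    def test_tm_matches_brute_force_oracle_over_random_assays(self, grid, baselines):
        # oracle: argmax of the closed-form mixture derivative on a 0.001 degC grid
        rng = np.random.default_rng(99)
        fine = np.arange(70.0, 92.0, 0.001)
        worst = 0.0
        for _ in range(100):
            tm = rng.uniform(78.0, 88.0)
            width = rng.uniform(0.2, 0.8)
            sp = DuplexSpecies("s", tm, width, 1.0)
            oracle = fine[np.argmax(analytic_minus_derivative(fine, [sp], baselines))]
            curve = simulate_curve([sp], grid, baselines)
            est = estimate_tm(derivative_curve(curve, 25))
            worst = max(worst, abs(est - oracle))
        assert worst <= 0.02

    def test_tie_breaks_toward_lower_temperature(self):
        t = np.arange(80.0, 90.0, 0.02)
        y = np.exp(-((t - 84.0) ** 2) / 0.1) + np.exp(-((t - 86.0) ** 2) / 0.1)
        d = DerivativeCurve(t, y, 1)
        assert estimate_tm(d) == pytest.approx(84.0, abs=0.02)

    def test_no_melt_rejected(self):
        t = np.arange(80.0, 90.0, 0.02)
        with pytest.raises(NoMeltError):
            estimate_tm(DerivativeCurve(t, np.full(t.size, -1.0), 1))

    def test_smoothing_reduces_derivative_variance(self, grid, rng):
        # Monte-Carlo: peak-region derivative variance shrinks vs half-width 1
        noise = NoiseModel(fluor_sd=0.5, tm_jitter_sd_c=0.0, baseline_jitter=0.0)
        rough, smooth = [], []
        for _ in range(100):
            c = single_species_curve(grid=grid, noise=noise, rng=rng)
            rough.append(derivative_curve(c, 1).minus_df_dt[1000])
            smooth.append(derivative_curve(c, 25).minus_df_dt[1000])
        assert np.var(smooth) < np.var(rough)

    def test_batch_matches_scalar_path(self, ret, grid, rng):
        noise = NoiseModel()
        curves = [
            simulate_curve(species_mixture("hom_major", ret), grid, noise=noise, rng=rng)
            for _ in range(5)
        ]
        batch = estimate_tm_batch(
            grid.temperatures(), np.vstack([c.fluorescence for c in curves])
        )
        scalar = [estimate_tm(derivative_curve(c, 25)) for c in curves]
        assert np.allclose(batch, scalar, atol=1e-12)

    def test_triplicate_tm_sd_within_observed_ceiling(self, ret, grid, rng):
        # parameter recovery of the published replicate precision:
        # estimated triplicate Tm SDs stay below 0.06 degC almost always
        ok = 0
        n_trials = 300
        temps = grid.temperatures()
        from hrmelt.melt_model import simulate_sample

        for _ in range(n_trials):
            curves = simulate_sample(ret, "hom_major", rng=rng)
            tms = estimate_tm_batch(temps, np.vstack([c.fluorescence for c in curves]))
            if np.std(tms, ddof=1) <= 0.06:
                ok += 1
        assert ok / n_trials >= 0.95


class TestDifferenceCurve:
    def _norm(self, genotype, assay, grid):
        c = simulate_curve(species_mixture(genotype, assay), grid)
        return normalize(c, *auto_windows(c))

    def test_reference_minus_itself_is_zero(self, ret, grid):
        norm = self._norm("hom_major", ret, grid)
        diff = difference_curve(norm, norm)
        assert np.max(np.abs(diff.delta_values)) < 1e-9

    def test_antisymmetry(self, ret, grid):
        a = self._norm("hom_major", ret, grid)
        b = self._norm("het", ret, grid)
        ab = difference_curve(a, b).delta_values
        ba = difference_curve(b, a).delta_values
        assert np.max(np.abs(ab + ba)) < 1e-9

    def test_het_deviates_more_from_gc_homozygote(self, assays, grid):
        # heteroduplex-driven early melt pulls the het curve further from
        # the G/G profile than from the A/A profile
        for assay in assays.values():
            het = self._norm("het", assay, grid)
            gc = self._norm(assay.gc_genotype, assay, grid)
            at = self._norm(assay.at_genotype, assay, grid)
            amp_gc = abs(difference_amplitude(difference_curve(het, gc)))
            amp_at = abs(difference_amplitude(difference_curve(het, at)))
            assert amp_gc > amp_at

    def test_disjoint_grids_rejected(self, ret, grid):
        a = self._norm("hom_major", ret, grid)
        far = type(a)("far", 1, a.temperatures_c + 100.0, a.values, a.pre_window, a.post_window)
        with pytest.raises(ValueError, match="overlap"):
            difference_curve(far, a)


class TestTransitionWidth:
    def test_logistic_closed_form(self, grid):
        # 90-10 span of one logistic species of width s is s*ln(81)
        from hrmelt.melt_model import helicity

        t = grid.temperatures()
        for s in (0.2, 0.35, 0.6):
            norm = NormalizedCurve("L", 1, t, 100.0 * helicity(t, 85.0, s), (66, 68), (92, 94))
            assert transition_width(norm) == pytest.approx(s * np.log(81.0), abs=grid.spacing_c)

    def test_width_increases_with_species_width(self, grid):
        widths = []
        for s in (0.2, 0.35, 0.6):
            curve = single_species_curve(width=s, grid=grid)
            widths.append(transition_width(normalize(curve, *auto_windows(curve))))
        assert widths[0] < widths[1] < widths[2]

    def test_het_wider_than_homozygote(self, ret, grid):
        het_c = simulate_curve(species_mixture(HET, ret), grid)
        hom_c = simulate_curve(species_mixture("hom_major", ret), grid)
        het_w = transition_width(normalize(het_c, *auto_windows(het_c)))
        hom_w = transition_width(normalize(hom_c, *auto_windows(hom_c)))
        assert het_w > hom_w

    def test_uncrossed_level_rejected(self, grid):
        t = grid.temperatures()
        curve = single_species_curve(grid=grid)
        norm = normalize(curve, *auto_windows(curve))
        with pytest.raises(LevelNotCrossedError):
            transition_width(norm, hi=150.0)
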