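"""Ligand-depletion isotherm, global shared-Kd fit, bootstrap intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftprobe import binding_isotherm, bootstrap_uncertainty, fit_global_kd
from shiftprobe.errors import UnderdeterminedError

# study design: protein 0.135 mM, ratio ladder 2..100
P0 = 0.135
RATIOS = np.array([2.0, 5.0, 10.0, 25.0, 50.0, 100.0])


def make_curves(kd, csp_max, noise=0.0, rng=None, p0=P0, ratios=RATIOS):
    """Noisy isotherm curves for a dict residue -> csp_max."""
    p = np.full(ratios.size, p0)
    l = ratios * p0
    curves = {}
    for res, amp in csp_max.items():
        y = binding_isotherm(p, l, kd, amp)
        if noise:
            y = y + rng.normal(0.0, noise, size=y.size)
        curves[res] = (p, l, np.clip(y, 0.0, None))
    return curves


class TestIsotherm:
    def test_zero_ligand_gives_zero(self):
        assert binding_isotherm(0.5, 0.0, 15.0, 0.55) == 0.0

    def test_saturation_limit(self):
        v = binding_isotherm(0.5, 1e6 * 15.0, 15.0, 0.55)
        assert v == pytest.approx(0.55, rel=1e-3)

    def test_quadratic_bound_fraction_value(self):
        # (P+L+Kd) - sqrt((P+L+Kd)^2 - 4PL)) / 2P with P=0.5, L=50, Kd=15
        assert binding_isotherm(0.5, 50.0, 15.0, 0.55) == pytest.approx(0.4223, abs=5e-5)

    def test_stoichiometric_limit_kd_to_zero(self):
        # tight binding: CSP = csp_max * min(L/P, 1)
        assert binding_isotherm(0.5, 0.5, 1e-12, 0.55) == pytest.approx(0.55, rel=1e-3)
        assert binding_isotherm(0.5, 0.25, 1e-12, 0.55) == pytest.approx(
            0.55 * 0.5, rel=1e-3
        )

    def test_no_depletion_limit(self):
        # P << Kd reduces to csp_max * L / (L + Kd)
        kd, l = 15.0, 7.0
        v = binding_isotherm(kd * 1e-4, l, kd, 0.3)
        assert v == pytest.approx(0.3 * l / (l + kd), rel=1e-3)

    def test_rejects_negative_arguments(self):
        with pytest.raises(ValueError):
            binding_isotherm(-0.5, 1.0, 15.0, 0.55)
        with pytest.raises(ValueError):
            binding_isotherm(0.5, -1.0, 15.0, 0.55)
        with pytest.raises(ValueError):
            binding_isotherm(0.5, 1.0, -15.0, 0.55)

    @given(
        kd=st.floats(0.1, 100.0),
        p=st.floats(0.01, 1.0),
        l1=st.floats(0.0, 50.0),
        dl=st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_nondecreasing_in_ligand_and_bounded(self, kd, p, l1, dl):
        v1 = binding_isotherm(p, l1, kd, 0.5)
        v2 = binding_isotherm(p, l1 + dl, kd, 0.5)
        assert 0.0 <= v1 <= 0.5 + 1e-12
        assert v2 >= v1 - 1e-12


class TestGlobalFit:
    def test_noiseless_recovery_is_exact(self):
        curves = make_curves(15.0, {81: 0.55, 83: 0.29, 96: 0.18, 125: 0.29})
        fit = fit_global_kd(curves)
        assert fit.kd == pytest.approx(15.0, rel=1e-6)
        for res, amp in {81: 0.55, 83: 0.29, 96: 0.18, 125: 0.29}.items():
            assert fit.csp_max[res] == pytest.approx(amp, rel=1e-6)
        assert fit.converged

    def test_noiseless_recovery_other_regime(self):
        curves = make_curves(0.5, {1: 0.1, 2: 0.4}, p0=0.2)
        fit = fit_global_kd(curves)
        assert fit.kd == pytest.approx(0.5, rel=1e-6)

    def test_two_points_single_residue_underdetermined(self):
        p = np.array([0.135, 0.135])
        l = np.array([0.27, 13.5])
        y = binding_isotherm(p, l, 15.0, 0.5)
        with pytest.raises(UnderdeterminedError):
            fit_global_kd({81: (p, l, y)})

    def test_fitted_ssr_never_above_truth_ssr(self):
        rng = np.random.default_rng(1)
        truth = {81: 0.55, 83: 0.29, 96: 0.18}
        curves = make_curves(15.0, truth, noise=0.01, rng=rng)
        fit = fit_global_kd(curves)
        ssr_truth = sum(
            float(np.sum((y - binding_isotherm(p, l, 15.0, truth[r])) ** 2))
            for r, (p, l, y) in curves.items()
        )
        assert fit.ssr <= ssr_truth + 1e-12

    def test_invariant_to_residue_ordering_and_weight_scale(self):
        rng = np.random.default_rng(2)
        curves = make_curves(15.0, {81: 0.55, 83: 0.29, 96: 0.18}, noise=0.01, rng=rng)
        fit1 = fit_global_kd(curves)
        reordered = {r: curves[r] for r in sorted(curves, reverse=True)}
        fit2 = fit_global_kd(reordered)
        assert fit2.kd == pytest.approx(fit1.kd, rel=1e-9)
        w1 = {r: np.ones(RATIOS.size) for r in curves}
        w5 = {r: 5.0 * np.ones(RATIOS.size) for r in curves}
        assert fit_global_kd(curves, weights=w5).kd == pytest.approx(
            fit_global_kd(curves, weights=w1).kd, rel=1e-9
        )

    def test_grid_search_oracle_agreement(self):
        """Optimizer SSR within 1% of an exhaustive 2-D log-grid search."""
        rng = np.random.default_rng(3)
        for case in range(2):
            kd_true = [3.0, 40.0][case]
            curves = make_curves(kd_true, {1: 0.4}, noise=0.01, rng=rng)
            fit = fit_global_kd(curves)
            p, l, y = curves[1]
            kd_grid = np.logspace(-2, 3, 400)
            amp_grid = np.linspace(1e-3, 1.0, 400)
            f = np.array([(p + l + k) - np.sqrt((p + l + k) ** 2 - 4 * p * l) for k in kd_grid]) / (2 * p)
            ssr_grid = ((y[None, None, :] - amp_grid[None, :, None] * f[:, None, :]) ** 2).sum(axis=2)
            assert fit.ssr <= ssr_grid.min() * 1.01

    def test_saturation_diagnostic_reported(self):
        curves = make_curves(15.0, {81: 0.55})
        fit = fit_global_kd(curves)
        # at ratio 100 (13.5 mM ligand) roughly half the protein is bound
        assert 0.3 < fit.saturation[81] < 0.6


class TestBootstrap:
    def _noisy_fit(self, seed, n_boot=50):
        rng = np.random.default_rng(seed)
        curves = make_curves(15.0, {81: 0.55, 83: 0.29}, noise=0.01, rng=rng)
        fit = fit_global_kd(curves)
        return curves, fit

    def test_same_seed_identical_intervals(self):
        curves, fit = self._noisy_fit(4)
        ci1 = bootstrap_uncertainty(curves, fit, n_boot=50, seed=1)
        ci2 = bootstrap_uncertainty(curves, fit, n_boot=50, seed=1)
        assert ci1 == ci2

    def test_interval_contains_point_estimate(self):
        curves, fit = self._noisy_fit(5)
        lo, hi, amp_ci = bootstrap_uncertainty(curves, fit, n_boot=50, seed=2)
        assert lo <= fit.kd <= hi
        for r, (alo, ahi) in amp_ci.items():
            assert alo <= fit.csp_max[r] <= ahi

    def test_noiseless_interval_width_collapses(self):
        curves = make_curves(15.0, {81: 0.55, 83: 0.29})
        fit = fit_global_kd(curves)
        lo, hi, _ = bootstrap_uncertainty(curves, fit, n_boot=50, seed=3)
        assert hi - lo < 1e-4

    def test_too_few_replicates_rejected(self):
        curves, fit = self._noisy_fit(6)
        with pytest.raises(ValueError):
            bootstrap_uncertainty(curves, fit, n_boot=5, seed=1)
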