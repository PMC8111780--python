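"""Generator determinism and closure against each analysis stage."""

import numpy as np
import pytest
from scipy import stats

from shiftprobe import (
    average_replicates,
    compare_models,
    csp_profile,
    curves_from_profile,
    fit_global_kd,
    fit_mm,
    gen_pre,
    gen_rates,
    gen_shift_table,
    gen_titration,
    gen_trace,
    intensity_ratios,
    rate_from_trace,
    secondary_shifts,
    segment_helices,
    track_peaks,
)
from shiftprobe.errors import ValidationError
from shiftprobe.synthetic_data import (
    BindingBlock,
    KineticsBlock,
    PREBlock,
    SecstructBlock,
    SyntheticSpec,
    default_depth_profile,
)


def titration_curves(spec, residues):
    series = gen_titration(spec)
    tracked = track_peaks(series, max_jump=0.3)
    profiles = {s: csp_profile(tracked, 0, s) for s in range(1, len(series))}
    return curves_from_profile(series, tracked, profiles), series


class TestTitrationClosure:
    def test_noiseless_single_residue_recovers_kd_and_amplitude(self):
        spec = SyntheticSpec(
            seed=1, binding=BindingBlock(csp_max={81: 0.55}, noise_sigma=0.0)
        )
        curves, _ = titration_curves(spec, [81])
        fit = fit_global_kd(curves, residues=[81])
        assert fit.kd == pytest.approx(15.0, rel=1e-6)
        assert fit.csp_max[81] == pytest.approx(0.55, rel=1e-6)

    def test_unperturbed_residues_only_carry_noise(self):
        spec = SyntheticSpec(seed=2, binding=BindingBlock(csp_max={}, noise_sigma=0.01))
        series = gen_titration(spec)
        tracked = track_peaks(series, max_jump=0.3)
        profile = csp_profile(tracked, 0, len(series) - 1)
        assert max(profile.values.values()) < 6 * 0.01

    def test_same_seed_identical_series(self):
        spec = SyntheticSpec(seed=3)
        s1, s2 = gen_titration(spec), gen_titration(spec)
        for p1, p2 in zip(s1.points, s2.points):
            assert p1.peaks == p2.peaks
            assert p1.ligand_conc == p2.ligand_conc

    def test_empty_ratio_list_rejected(self):
        spec = SyntheticSpec(seed=1, binding=BindingBlock(ratios=()))
        with pytest.raises(ValidationError):
            gen_titration(spec)

    def test_study_design_concentrations(self):
        series = gen_titration(SyntheticSpec(seed=0))
        assert [p.ratio for p in series.points] == [0, 2, 5, 10, 25, 50, 100]
        assert series.points[-1].ligand_conc == pytest.approx(13.5)  # 100 x 0.135


class TestPREClosure:
    def test_zero_exposure_watersoluble_ratios_near_one(self):
        depth = {i: 0.0 for i in range(1, 130)}
        spec = SyntheticSpec(seed=4, pre=PREBlock(depth=depth, noise_frac=0.0))
        probe, ref = gen_pre(spec, probe="watersoluble")
        profile = intensity_ratios(probe, ref, increase_tol=0.5)
        assert all(r == pytest.approx(1.0, abs=1e-9) for r in profile.ratios.values())

    def test_probes_are_anticorrelated(self):
        spec = SyntheticSpec(seed=5)
        pw, rw = gen_pre(spec, probe="watersoluble")
        pd_, rd = gen_pre(spec, probe="detergent")
        ratios_w = intensity_ratios(pw, rw, increase_tol=10.0).ratios
        ratios_d = intensity_ratios(pd_, rd, increase_tol=10.0).ratios
        common = sorted(ratios_w)
        rho = stats.spearmanr(
            [ratios_w[r] for r in common], [ratios_d[r] for r in common]
        ).statistic
        assert rho < -0.8

    def test_depth_outside_unit_interval_rejected(self):
        spec = SyntheticSpec(seed=6, pre=PREBlock(depth={1: 1.5}))
        with pytest.raises(ValueError):
            gen_pre(spec)

    def test_same_seed_identical_lists(self):
        spec = SyntheticSpec(seed=7)
        a1, b1 = gen_pre(spec)
        a2, b2 = gen_pre(spec)
        assert a1 == a2 and b1 == b2

    def test_default_depth_buries_the_tm_helix(self):
        spec = SyntheticSpec(seed=0)
        depth = default_depth_profile(spec)
        assert depth[60] < 0.1  # inside the transmembrane helix
        assert depth[5] > 0.8  # N-terminal loop


class TestShiftTableClosure:
    def test_noiseless_offset_recovers_segments_exactly(self):
        spec = SyntheticSpec(seed=8, secstruct=SecstructBlock(noise=0.0))
        table = gen_shift_table(spec)
        profile = secondary_shifts(table, spec.get_sequence())
        segs = segment_helices(profile)
        assert [(s.start, s.end) for s in segs] == [
            (29, 39), (48, 79), (93, 106), (112, 123),
        ]

    def test_zero_offset_gives_no_helices(self):
        spec = SyntheticSpec(seed=9, secstruct=SecstructBlock(offset=0.0, noise=0.0))
        table = gen_shift_table(spec)
        profile = secondary_shifts(table, spec.get_sequence())
        assert segment_helices(profile) == []

    def test_overlapping_segments_rejected(self):
        spec = SyntheticSpec(
            seed=10, secstruct=SecstructBlock(segments=((10, 20), (15, 30)))
        )
        with pytest.raises(ValidationError):
            gen_shift_table(spec)

    def test_noisy_boundaries_recovered_within_one_residue(self):
        hits = 0
        n_seeds = 30
        truth = [(29, 39), (48, 79), (93, 106), (112, 123)]
        for seed in range(n_seeds):
            spec = SyntheticSpec(seed=seed)
            profile = secondary_shifts(gen_shift_table(spec), spec.get_sequence())
            segs = [(s.start, s.end) for s in segment_helices(profile)]
            if len(segs) == len(truth) and all(
                abs(a - ta) <= 1 and abs(b - tb) <= 1
                for (a, b), (ta, tb) in zip(segs, truth)
            ):
                hits += 1
        assert hits / n_seeds >= 0.9


class TestRatesClosure:
    def test_noiseless_two_site_recovery(self):
        spec = SyntheticSpec(seed=11, kinetics=KineticsBlock(noise_frac=0.0))
        fit = fit_mm(average_replicates(gen_rates(spec)), n_sites=2)
        assert fit.v[0] == pytest.approx(40.0, rel=1e-6)
        assert fit.v[1] == pytest.approx(70.0, rel=1e-6)
        assert fit.km[0] == pytest.approx(1.3, rel=1e-6)
        assert fit.km[1] == pytest.approx(20.0, rel=1e-6)

    def test_noiseless_one_site_recovery(self):
        spec = SyntheticSpec(
            seed=12,
            kinetics=KineticsBlock(model="one_site", v=(208.0,), km=(8.6,), noise_frac=0.0),
        )
        fit = fit_mm(average_replicates(gen_rates(spec)), n_sites=1)
        assert fit.v[0] == pytest.approx(208.0, rel=1e-8)
        assert fit.km[0] == pytest.approx(8.6, rel=1e-8)

    def test_trace_round_trip(self):
        trace = gen_trace(rate=123.4, enzyme_conc=0.02, background_slope=-0.05)
        rate = rate_from_trace(trace, (61.0, 119.0), (1.0, 59.0), 0.02)
        assert rate == pytest.approx(123.4, abs=1e-9)

    def test_same_seed_identical_curves(self):
        spec = SyntheticSpec(seed=13)
        c1 = gen_rates(spec)
        c2 = gen_rates(spec)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.rates, b.rates)

    def test_model_selection_recovers_generating_model(self):
        spec = SyntheticSpec(
            seed=14, kinetics=KineticsBlock(model="one_site", v=(208.0,), km=(8.6,))
        )
        c = average_replicates(gen_rates(spec))
        one, two = fit_mm(c, n_sites=1), fit_mm(c, n_sites=2)
        assert compare_models(one, two, n_points=c.conc.size).preferred == "one_site"
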