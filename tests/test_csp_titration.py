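"""CSP arithmetic, concentration bookkeeping, tracking and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftprobe import (
    CSPProfile,
    Peak,
    PeakList,
    Residue,
    TitrationPoint,
    TitrationSeries,
    classify_perturbed,
    compute_csp,
    csp_profile,
    ligand_concentrations,
    track_peaks,
)
from shiftprobe.errors import (
    InfeasibleTitrationError,
    InsufficientDataError,
    ValidationError,
)

finite_shift = st.floats(-2, 2, allow_nan=False, allow_infinity=False)


class TestComputeCsp:
    @pytest.mark.parametrize(
        "dh,dn,code,expected",
        [
            (0.0, 0.0, "A", 0.0),
            (0.03, 0.5, "A", math.sqrt(0.03**2 + (0.14 * 0.5) ** 2)),  # 0.07616
            (0.03, 0.5, "G", math.sqrt(0.03**2 + (0.2 * 0.5) ** 2)),  # 0.10440
        ],
    )
    def test_worked_examples(self, dh, dn, code, expected):
        assert compute_csp(dh, dn, code) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            compute_csp(float("inf"), 0.0, "A")

    @given(dh=finite_shift, dn=finite_shift)
    @settings(max_examples=200, deadline=None)
    def test_sign_symmetric_and_nonnegative(self, dh, dn):
        v = compute_csp(dh, dn, "A")
        assert v >= 0
        assert v == compute_csp(-dh, -dn, "A")

    @given(dh=finite_shift)
    @settings(max_examples=100, deadline=None)
    def test_reduces_to_abs_dh_when_dn_zero(self, dh):
        assert compute_csp(dh, 0.0, "L") == pytest.approx(abs(dh), abs=1e-15)

    @given(dh=finite_shift, dn=st.floats(0, 2), extra=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_abs_dn(self, dh, dn, extra):
        assert compute_csp(dh, dn + extra, "A") >= compute_csp(dh, dn, "A")


class TestLigandConcentrations:
    def test_reference_only(self):
        assert ligand_concentrations([0.0], 0.135) == [(0.0, 0.135)]

    def test_highest_ratio_matches_study_concentration(self):
        # ratio 100 at 0.13 mM protein gives 13 mM ligand (no-dilution bookkeeping)
        (l, p), = ligand_concentrations([100.0], 0.13)
        assert l == pytest.approx(13.0)
        assert p == pytest.approx(0.13)

    def test_stock_dilution_mass_balance(self):
        # conservation of moles: ratio preserved, both totals diluted
        (l, p), = ligand_concentrations([100.0], 0.5, stock_conc=500.0)
        assert l / p == pytest.approx(100.0, rel=1e-12)
        assert l < 50.0 and p < 0.5
        # mole balance oracle: added volume v = n_L / stock on unit start volume
        n_p = 0.5
        n_l = l * (n_p / p)  # total volume cancels
        vol = 1.0 + n_l / 500.0
        assert p == pytest.approx(n_p / vol, rel=1e-12)
        assert l == pytest.approx(n_l / vol, rel=1e-12)

    def test_infeasible_stock_raises(self):
        with pytest.raises(InfeasibleTitrationError):
            ligand_concentrations([100.0], 0.5, stock_conc=40.0)

    def test_decreasing_ratios_rejected(self):
        with pytest.raises(ValidationError):
            ligand_concentrations([5.0, 2.0], 0.5)


def _series_from_positions(positions_per_step, codes=None):
    """positions_per_step: list of {res: (h, n)} dicts, step 0 = reference."""
    codes = codes or {}
    points = []
    for step, positions in enumerate(positions_per_step):
        peaks = PeakList()
        for res, (h, n) in positions.items():
            peaks.add(Peak(Residue(res, codes.get(res, "A")), h, n))
        ratio = float(step)
        points.append(
            TitrationPoint(
                ratio=ratio, ligand_conc=ratio * 0.1, protein_conc=0.1, peaks=peaks
            )
        )
    return TitrationSeries(points=points)


class TestTrackPeaks:
    def test_identical_lists_fully_tracked_zero_displacement(self):
        pos = {i: (7.5 + 0.02 * i, 110.0 + 0.1 * i) for i in range(1, 11)}
        series = _series_from_positions([pos, pos, pos])
        tracked = track_peaks(series)
        assert tracked.flags == {}
        profile = csp_profile(tracked, 0, 2)
        assert all(v == 0.0 for v in profile.values.values())

    def test_small_drift_is_tracked(self):
        steps = []
        for s in range(6):
            steps.append({1: (8.0 + 0.01 * s, 115.0), 2: (9.0, 125.0)})
        tracked = track_peaks(_series_from_positions(steps))
        assert 1 in tracked.tracked_residues()
        profile = csp_profile(tracked, 0, 5)
        assert profile.values[1] == pytest.approx(0.05, abs=1e-12)

    def test_swapping_peaks_are_flagged_untracked(self):
        a, b = (8.0, 110.0), (8.5, 120.0)
        steps = [{1: a, 2: b}, {1: b, 2: a}]
        tracked = track_peaks(_series_from_positions(steps))
        assert tracked.flags.get(1) == "untracked"
        assert tracked.flags.get(2) == "untracked"

    def test_tracking_is_row_order_invariant(self):
        steps = [
            {1: (8.0, 110.0), 2: (8.5, 120.0), 3: (9.0, 128.0)},
            {1: (8.01, 110.1), 2: (8.51, 120.1), 3: (9.01, 128.1)},
        ]
        t1 = track_peaks(_series_from_positions(steps))
        # same data, peaks inserted in reverse order
        rev = [dict(reversed(list(s.items()))) for s in steps]
        t2 = track_peaks(_series_from_positions(rev))
        assert t1.positions == t2.positions and t1.flags == t2.flags


class TestCspProfile:
    def test_same_step_gives_all_zero(self):
        pos = {i: (8.0 + 0.1 * i, 115.0 + i) for i in range(1, 6)}
        tracked = track_peaks(_series_from_positions([pos, pos]))
        profile = csp_profile(tracked, 1, 1)
        assert all(v == 0.0 for v in profile.values.values())

    def test_known_displacement_matches_analytic_csp(self):
        steps = [
            {1: (8.0, 115.0), 2: (9.0, 125.0)},
            {1: (8.03, 115.5), 2: (9.0, 125.0)},
        ]
        tracked = track_peaks(_series_from_positions(steps), max_jump=0.2)
        profile = csp_profile(tracked, 0, 1)
        assert profile.values[1] == pytest.approx(
            math.sqrt(0.03**2 + (0.14 * 0.5) ** 2), abs=1e-12
        )

    def test_residue_missing_at_final_step_flagged(self):
        steps = [{1: (8.0, 115.0), 2: (9.0, 125.0)}, {2: (9.0, 125.0)}]
        tracked = track_peaks(_series_from_positions(steps))
        profile = csp_profile(tracked, 0, 1)
        assert 1 not in profile.values
        assert profile.flags[1] == "untracked"

    def test_step_out_of_range(self):
        pos = {1: (8.0, 115.0), 2: (9.0, 125.0)}
        tracked = track_peaks(_series_from_positions([pos, pos]))
        with pytest.raises(ValueError):
            csp_profile(tracked, 0, 5)


class TestClassifyPerturbed:
    def test_uniform_profile_gives_empty_set(self):
        profile = CSPProfile(values={i: 0.05 for i in range(1, 11)})
        hits, threshold = classify_perturbed(profile)
        assert hits == set()

    def test_four_large_among_hundred_small(self):
        values = {i: 0.02 for i in range(1, 101)}
        values.update({200: 0.3, 201: 0.3, 202: 0.3, 203: 0.3})
        hits, threshold = classify_perturbed(CSPProfile(values=values))
        assert hits == {200, 201, 202, 203}
        # the four outliers are trimmed, so the threshold collapses onto the bulk
        assert threshold == pytest.approx(0.02, abs=1e-12)

    def test_trimming_excludes_extreme_outlier_from_threshold(self):
        # frozen hand computation: 20 each of 0.01..0.05 plus one 0.5 outlier;
        # one trim pass drops 0.5, leaving mean 0.03, sd 0.0142134
        values = {}
        idx = 1
        for v in (0.01, 0.02, 0.03, 0.04, 0.05):
            for _ in range(20):
                values[idx] = v
                idx += 1
        values[idx] = 0.5
        hits, threshold = classify_perturbed(CSPProfile(values=values))
        assert threshold == pytest.approx(0.0584268, abs=1e-6)
        assert hits == {idx}

    def test_fewer_than_five_values_raises(self):
        profile = CSPProfile(values={1: 0.1, 2: 0.1, 3: 0.1, 4: 0.1})
        with pytest.raises(InsufficientDataError):
            classify_perturbed(profile)


class TestDomainInvariants:
    def test_point_ratio_consistency_enforced(self):
        peaks = PeakList([Peak(Residue(1, "A"), 8.0, 115.0)])
        with pytest.raises(ValidationError):
            TitrationPoint(ratio=2.0, ligand_conc=1.0, protein_conc=0.1, peaks=peaks)

    def test_nonincreasing_ratios_rejected(self):
        peaks = PeakList([Peak(Residue(1, "A"), 8.0, 115.0)])
        mk = lambda r: TitrationPoint(
            ratio=r, ligand_conc=r * 0.1, protein_conc=0.1, peaks=peaks
        )
        with pytest.raises(ValidationError):
            TitrationSeries(points=[mk(0.0), mk(5.0), mk(2.0)])

    def test_negative_csp_rejected(self):
        with pytest.raises(ValidationError):
            CSPProfile(values={1: -0.1})
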