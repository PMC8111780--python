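"""Chemical-shift-perturbation (CSP) analysis of an HSQC titration series.

A titration series is an ordered set of ligand:protein molar ratios, each with
a peak list from a 2D 1H-15N correlation spectrum.  In the fast-exchange
regime each amide peak moves continuously with the bound fraction, so peaks
can be tracked from step to step by nearest neighbour in the weighted shift
space, and the perturbation between two steps is the weighted combined shift

    CSP = sqrt( (d_H)^2 + (alpha * d_N)^2 )      [ppm]

with the conventional 15N weighting alpha = 0.2 for glycine and 0.14 for all
other residues.  Residues whose CSP exceeds a robust (outlier-trimmed)
mean + k*SD threshold are classified as significantly perturbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InfeasibleTitrationError, InsufficientDataError, ValidationError
from .io_core import PeakList

#: 15N weighting factor in the CSP metric, by residue one-letter code.
ALPHA_GLY = 0.2
ALPHA_DEFAULT = 0.14

#: Default maximum step-to-step displacement (ppm, CSP metric) for tracking.
DEFAULT_MAX_JUMP = 0.05


def shift_weight(residue_code: str) -> float:
    """15N weighting factor: 0.2 for Gly, 0.14 otherwise."""
    return ALPHA_GLY if residue_code == "G" else ALPHA_DEFAULT


def compute_csp(delta_h: float, delta_n: float, residue_code: str) -> float:
    """Weighted combined 1H/15N shift change in ppm.

    Symmetric in the sign of both arguments and reduces to ``abs(delta_h)``
    when ``delta_n`` is zero.
    """
    if not (math.isfinite(delta_h) and math.isfinite(delta_n)):
        raise ValueError("shift differences must be finite")
    a = shift_weight(residue_code)
    return math.hypot(delta_h, a * delta_n)


@dataclass
class TitrationPoint:
    """One titration step: concentrations plus the peak list recorded there."""

    ratio: float  # ligand:protein molar ratio (dimensionless)
    ligand_conc: float  # total ligand, mM
    protein_conc: float  # total protein, mM
    peaks: PeakList

    def __post_init__(self):
        if self.protein_conc <= 0:
            raise ValidationError("protein concentration must be > 0")
        if self.ligand_conc < 0:
            raise ValidationError("ligand concentration must be >= 0")
        if self.ligand_conc > 0 or self.ratio > 0:
            implied = self.ligand_conc / self.protein_conc
            if abs(implied - self.ratio) > 1e-6 * max(1.0, self.ratio):
                raise ValidationError(
                    f"ratio {self.ratio} inconsistent with L/P = {implied:.6g}"
                )


@dataclass
class TitrationSeries:
    """Ordered titration points; the first is the ligand-free reference."""

    points: List[TitrationPoint]
    stock_conc: Optional[float] = None  # ligand stock, mM

    def __post_init__(self):
        if not self.points:
            raise ValidationError("titration series has zero steps")
        if self.points[0].ratio != 0:
            raise ValidationError("first titration point must be the ratio-0 reference")
        ratios = [p.ratio for p in self.points]
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValidationError(f"ratios must be strictly increasing, got {ratios}")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CSPProfile:
    """Per-residue CSPs between two steps, with per-residue tracking flags."""

    values: Dict[int, float] = field(default_factory=dict)  # residue -> ppm
    flags: Dict[int, str] = field(default_factory=dict)  # residue -> reason
    from_step: int = 0
    to_step: int = -1

    def __post_init__(self):
        if any(v < 0 for v in self.values.values()):
            raise ValidationError("CSP values must be non-negative")

    def residues(self):
        return sorted(self.values)


def ligand_concentrations(
    ratios: Sequence[float],
    protein_conc: float,
    stock_conc: Optional[float] = None,
) -> List[Tuple[float, float]]:
    """Total (ligand mM, protein mM) at each titration step.

    Without a stock concentration the bookkeeping ignores dilution:
    ``L = ratio * P0`` at constant protein.  With ``stock_conc`` the cumulative
    added stock volume dilutes both species (conservation of moles); the molar
    ratio is preserved exactly while both totals fall below their nominal
    values.
    """
    if protein_conc <= 0:
        raise ValidationError("protein concentration must be > 0")
    rs = list(ratios)
    if any(r < 0 for r in rs):
        raise ValidationError("ratios must be non-negative")
    if any(b <= a for a, b in zip(rs, rs[1:])):
        raise ValidationError("ratios must be strictly increasing")

    if stock_conc is None:
        return [(r * protein_conc, protein_conc) for r in rs]

    if stock_conc <= max(rs, default=0.0) * protein_conc:
        raise InfeasibleTitrationError(
            f"stock {stock_conc} mM cannot reach ratio {max(rs)} at "
            f"P0 = {protein_conc} mM (requires > {max(rs) * protein_conc} mM)"
        )
    # Unit start volume; the molar ratio is mole-based, so n_L = r * n_P and
    # the cumulative added stock volume is n_L / stock.
    out = []
    n_p = protein_conc * 1.0
    for r in rs:
        n_l = r * n_p
        v = 1.0 + n_l / stock_conc
        out.append((n_l / v, n_p / v))
    return out


@dataclass
class TrackedSeries:
    """A titration series with per-residue peak trajectories.

    ``positions[res]`` holds one (delta_h, delta_n) pair per step (ppm);
    residues that could not be followed are flagged with a reason.
    """

    series: TitrationSeries
    positions: Dict[int, List[Tuple[float, float]]]
    flags: Dict[int, str]
    codes: Dict[int, str]

    def tracked_residues(self):
        return sorted(r for r in self.positions if r not in self.flags)


def track_peaks(series: TitrationSeries, max_jump: float = DEFAULT_MAX_JUMP) -> TrackedSeries:
    """Follow each reference peak across titration steps.

    Matching is nearest neighbour in the weighted (CSP-metric) shift space.
    A residue is flagged ``untracked`` when its step displacement exceeds
    ``max_jump`` (ppm), or when the nearest peak carries a different residue
    label (mis-tracking onto a neighbour, e.g. two peaks swapping positions);
    two residues claiming the same peak are both flagged ``overlapped``.
    Tracking is invariant to peak-list row order.
    """
    ref = series.points[0].peaks
    codes = {p.residue.index: p.residue.one_letter for p in ref}
    positions: Dict[int, List[Tuple[float, float]]] = {
        p.residue.index: [(p.delta_h, p.delta_n)] for p in ref
    }
    flags: Dict[int, str] = {}

    for point in series.points[1:]:
        coords = [(p.residue.index, p.delta_h, p.delta_n) for p in point.peaks]
        claimed: Dict[int, List[int]] = {}
        for res in sorted(positions):
            if res in flags:
                positions[res].append(positions[res][-1])
                continue
            prev_h, prev_n = positions[res][-1]
            a = shift_weight(codes[res])
            best_j, best_d = None, math.inf
            for j, (_, h, nn) in enumerate(coords):
                d = math.hypot(h - prev_h, a * (nn - prev_n))
                if d < best_d:
                    best_j, best_d = j, d
            if best_j is None or best_d > max_jump or coords[best_j][0] != res:
                flags[res] = "untracked"
                positions[res].append(positions[res][-1])
            else:
                claimed.setdefault(best_j, []).append(res)
                positions[res].append(coords[best_j][1:])
        for j, claimants in claimed.items():
            if len(claimants) > 1:
                for res in claimants:
                    flags[res] = "overlapped"
    return TrackedSeries(series=series, positions=positions, flags=flags, codes=codes)


def csp_profile(tracked: TrackedSeries, from_step: int, to_step: int) -> CSPProfile:
    """Per-residue CSP between two titration steps of a tracked series.

    Residues flagged during tracking (or missing a position at either step)
    are carried as flags, never zero-filled.
    """
    n_steps = len(tracked.series)
    for step in (from_step, to_step):
        if not (-n_steps <= step < n_steps):
            raise ValueError(f"step index {step} out of range for {n_steps} steps")
    from_step %= n_steps
    to_step %= n_steps

    profile = CSPProfile(from_step=from_step, to_step=to_step)
    for res, traj in tracked.positions.items():
        if res in tracked.flags:
            profile.flags[res] = tracked.flags[res]
            continue
        h0, n0 = traj[from_step]
        h1, n1 = traj[to_step]
        profile.values[res] = compute_csp(h1 - h0, n1 - n0, tracked.codes[res])
    return profile


def classify_perturbed(
    profile: CSPProfile, k_sigma: float = 2.0
) -> Tuple[set, float]:
    """Residues with CSP above a robust significance threshold.

    Values more than 3 SD above the mean are trimmed iteratively until the
    retained set is stable; the threshold is then
    ``trimmed_mean + k_sigma * trimmed_SD`` and every residue above it is
    returned together with the threshold used.
    """
    vals = np.array([profile.values[r] for r in profile.residues()], dtype=float)
    if vals.size < 5:
        raise InsufficientDataError(
            f"classification needs >= 5 residues with CSP values, got {vals.size}"
        )
    kept = vals.copy()
    while True:
        mean, sd = kept.mean(), kept.std(ddof=1)
        retained = kept[kept <= mean + 3.0 * sd]
        if retained.size == kept.size or retained.size < 2:
            break
        kept = retained
    threshold = kept.mean() + k_sigma * kept.std(ddof=1)
    hits = {r for r in profile.residues() if profile.values[r] > threshold}
    return hits, float(threshold)
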