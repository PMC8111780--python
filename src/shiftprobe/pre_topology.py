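"""Paramagnetic relaxation enhancement (PRE) topology profiling.

Adding a paramagnetic probe (water-soluble or detergent-partitioning)
attenuates amide peak intensities in proportion to proximity: the per-residue
intensity ratio I/Iref between spectra with and without probe is a
qualitative distance/topology measure.  This module computes ratio profiles,
applies the standard exclusion rules (unassigned peaks, overlapped peaks,
intensity increases after probe addition), propagates a flat fractional
intensity error into ratio uncertainties, and smooths the profile with a
Gaussian sequence-weighted, inverse-variance-weighted moving average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .errors import DataError, InsufficientDataError, ValidationError
from .io_core import PeakList

#: Flat per-peak error as a fraction of the mean reference intensity.
DEFAULT_ERROR_FRAC = 0.05

#: Ratio above 1 + tol is flagged as an intensity increase (exchange effects).
DEFAULT_INCREASE_TOL = 0.2

#: Gaussian smoothing halfwidth, residues.
DEFAULT_HALFWIDTH = 3.0


@dataclass
class PREProfile:
    """Per-residue I/Iref ratios with uncertainties, flags and smoothed trace."""

    ratios: Dict[int, float] = field(default_factory=dict)
    sigmas: Dict[int, float] = field(default_factory=dict)
    flags: Dict[int, str] = field(default_factory=dict)  # exclusion reason
    smoothed: Dict[int, float] = field(default_factory=dict)
    intensities: Dict[int, float] = field(default_factory=dict)  # I
    ref_intensities: Dict[int, float] = field(default_factory=dict)  # Iref

    def residues(self):
        return sorted(set(self.ratios) | set(self.flags))

    def included(self):
        """Residues contributing to smoothing (ratio present, not excluded)."""
        return sorted(r for r in self.ratios if r not in self.flags)


def intensity_ratios(
    spec: PeakList,
    ref: PeakList,
    increase_tol: float = DEFAULT_INCREASE_TOL,
    overlapped: Iterable[int] = (),
) -> PREProfile:
    """I/Iref per residue, with exclusion flags.

    Residues present in the reference but missing (or without intensity) in
    the probe spectrum are flagged ``unassigned``.  Ratios above
    ``1 + increase_tol`` are flagged ``intensity_increase``; overlap flags are
    taken from the ``overlapped`` annotation (overlap cannot be inferred from
    centroid lists).
    """
    profile = PREProfile()
    overlapped = set(overlapped)
    for res in ref.residues():
        iref = ref[res].intensity
        if iref is None or iref <= 0:
            raise DataError(f"residue {res}: non-positive reference intensity {iref}")
        if res not in spec or spec[res].intensity is None:
            profile.flags[res] = "unassigned"
            continue
        ratio = spec[res].intensity / iref
        profile.ratios[res] = ratio
        profile.intensities[res] = spec[res].intensity
        profile.ref_intensities[res] = iref
        if res in overlapped:
            profile.flags[res] = "overlap"
        elif ratio > 1.0 + increase_tol:
            profile.flags[res] = "intensity_increase"
    return profile


def propagate_uncertainty(
    profile: PREProfile,
    ref: PeakList,
    error_frac: float = DEFAULT_ERROR_FRAC,
) -> PREProfile:
    """Attach ratio uncertainties from a flat fractional intensity error.

    Every peak is assigned the same absolute error ``error_frac`` times the
    mean reference intensity; standard first-order propagation then gives
    ``sigma_ratio = ratio * sqrt((sigma/I)^2 + (sigma/Iref)^2)``.
    """
    if error_frac <= 0:
        raise ValueError(f"error_frac must be > 0, got {error_frac}")
    ref_int = [ref[r].intensity for r in ref.residues() if ref[r].intensity is not None]
    if not ref_int:
        raise DataError("reference list has no intensities")
    sigma_peak = error_frac * float(np.mean(ref_int))
    for res, ratio in profile.ratios.items():
        i = profile.intensities[res]
        iref = profile.ref_intensities[res]
        profile.sigmas[res] = abs(ratio) * math.hypot(sigma_peak / i, sigma_peak / iref)
    return profile


def weighted_moving_average(
    profile: PREProfile,
    halfwidth: float = DEFAULT_HALFWIDTH,
    interpretation: str = "hwhm",
) -> Dict[int, float]:
    """Gaussian sequence-weighted, inverse-variance-weighted moving average.

    The weight of residue j in the average at position i is

        w_ij = exp(-d^2 / (2 sigma_g^2)) / sigma_ratio_j^2,   d = |i - j|

    over unexcluded residues j, normalized to sum 1.  ``halfwidth`` is read as
    the half-width at half-maximum by default (``sigma_g = hw / sqrt(2 ln 2)``);
    pass ``interpretation='sigma'`` to use it as sigma directly.  The window is
    truncated at ``|d| > 4 sigma_g``.  Excluded residues contribute nothing but
    still receive a smoothed value from their neighbours.
    """
    if interpretation == "hwhm":
        sigma_g = halfwidth / math.sqrt(2.0 * math.log(2.0))
    elif interpretation == "sigma":
        sigma_g = float(halfwidth)
    else:
        raise ValidationError(f"unknown halfwidth interpretation {interpretation!r}")

    contributors = profile.included()
    if not contributors:
        raise InsufficientDataError("all residues excluded; nothing to smooth")
    j = np.array(contributors, dtype=float)
    r = np.array([profile.ratios[int(x)] for x in contributors])
    inv_var = np.array(
        [1.0 / profile.sigmas[int(x)] ** 2 if int(x) in profile.sigmas else 1.0
         for x in contributors]
    )
    cutoff = 4.0 * sigma_g
    smoothed: Dict[int, float] = {}
    for i in profile.residues():
        d = np.abs(j - i)
        m = d <= cutoff
        if not np.any(m):
            continue
        w = np.exp(-(d[m] ** 2) / (2.0 * sigma_g**2)) * inv_var[m]
        smoothed[i] = float(np.sum(w * r[m]) / np.sum(w))
    profile.smoothed = smoothed
    return smoothed


def pre_profile(
    spec: PeakList,
    ref: PeakList,
    error_frac: float = DEFAULT_ERROR_FRAC,
    increase_tol: float = DEFAULT_INCREASE_TOL,
    overlapped: Iterable[int] = (),
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> PREProfile:
    """Full PRE pipeline: ratios -> exclusions -> uncertainties -> smoothing."""
    profile = intensity_ratios(spec, ref, increase_tol=increase_tol, overlapped=overlapped)
    propagate_uncertainty(profile, ref, error_frac=error_frac)
    weighted_moving_average(profile, halfwidth=halfwidth)
    return profile
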