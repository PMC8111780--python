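"""Circular-dichroism spectrum preprocessing.

Raw CD titration spectra (millidegrees vs wavelength) are background
subtracted, corrected for dilution by ligand addition, normalized to mean
residue molar ellipticity (MRE, deg cm^2 dmol^-1 per peptide bond) and
smoothed with a three-point moving average:

    MRE(lambda) = theta_mdeg(lambda) / (10 * c * l * (n_res - 1))

with c the molar protein concentration, l the path length in cm and
``n_res - 1`` the number of peptide bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import FormatError, ValidationError


@dataclass
class CDSpectrum:
    """A CD spectrum on a strictly monotonic wavelength grid.

    ``units`` is ``'mdeg'`` for raw ellipticity or ``'mre'`` after
    normalization; acquisition metadata (path length, concentration, residue
    count, dilution factor) travels with the spectrum.
    """

    wavelengths: np.ndarray  # nm
    signal: np.ndarray
    units: str = "mdeg"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.wavelengths.shape != self.signal.shape:
            raise ValidationError("wavelength and signal arrays differ in length")
        d = np.diff(self.wavelengths)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("wavelength grid must be strictly monotonic")

    def __len__(self) -> int:
        return self.wavelengths.size


def read_cd(path, **meta) -> CDSpectrum:
    """Read a two-column (wavelength nm, signal mdeg) text file."""
    try:
        data = np.loadtxt(path, comments=("#", ";"))
    except ValueError as exc:
        raise FormatError(f"{path}: not a two-column numeric file ({exc})") from None
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns, found {data.shape[1]}")
    return CDSpectrum(data[:, 0], data[:, 1], units="mdeg", meta=meta)


def write_cd(spectrum: CDSpectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths, spectrum.signal]),
        fmt="%.6g",
        header=f"wavelength_nm signal_{spectrum.units}",
    )


def preprocess_cd(
    sample: CDSpectrum,
    background: CDSpectrum,
    dilution_factor: float = 1.0,
    path_cm: Optional[float] = None,
    conc_molar: Optional[float] = None,
    n_residues: Optional[int] = None,
) -> CDSpectrum:
    """Background-subtract, dilution-correct and normalize to MRE.

    Metadata falls back to the sample spectrum's ``meta`` dict (keys
    ``path_cm``, ``conc_molar``, ``n_residues``).  Dilution factor >= 1
    rescales the subtracted signal back to the undiluted concentration.
    """
    if sample.wavelengths.shape != background.wavelengths.shape or not np.allclose(
        sample.wavelengths, background.wavelengths
    ):
        raise ValueError("sample and background wavelength grids differ")
    if dilution_factor < 1.0:
        raise ValidationError(f"dilution factor must be >= 1, got {dilution_factor}")
    path_cm = path_cm if path_cm is not None else sample.meta.get("path_cm")
    conc_molar = conc_molar if conc_molar is not None else sample.meta.get("conc_molar")
    n_residues = n_residues if n_residues is not None else sample.meta.get("n_residues")
    if not all(x is not None and x > 0 for x in (path_cm, conc_molar, n_residues)):
        raise ValidationError("path_cm, conc_molar and n_residues must all be > 0")
    if n_residues < 2:
        raise ValidationError("need at least 2 residues (1 peptide bond)")

    corrected = (sample.signal - background.signal) * dilution_factor
    mre = corrected / (10.0 * conc_molar * path_cm * (n_residues - 1))
    meta = dict(sample.meta)
    meta.update(
        path_cm=path_cm,
        conc_molar=conc_molar,
        n_residues=n_residues,
        dilution_factor=dilution_factor,
    )
    return CDSpectrum(sample.wavelengths.copy(), mre, units="mre", meta=meta)


def smooth_cd(spectrum: CDSpectrum) -> CDSpectrum:
    """Three-point moving average; endpoints average the available two points."""
    y = spectrum.signal
    if y.size < 3:
        raise ValueError(f"need >= 3 points to smooth, got {y.size}")
    out = np.empty_like(y)
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    out[0] = (y[0] + y[1]) / 2.0
    out[-1] = (y[-2] + y[-1]) / 2.0
    return replace(spectrum, wavelengths=spectrum.wavelengths.copy(), signal=out)
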