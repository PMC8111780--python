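"""Ground-truth synthetic data for every analysis stage.

Each generator emits exactly the statistical structure its partner analysis
assumes, so parameter recovery is a closure test: a fast-exchange CSP
titration with one shared Kd and per-residue amplitudes; PRE attenuation
profiles with a monotone dependence on solvent exposure for a water-soluble
probe (mirrored for a detergent-partitioning probe); Cα shift tables built
from random-coil values plus helix offsets; and one- or two-component
hyperbolic rate curves with multiplicative noise.

Defaults reproduce the study conditions: protein at 0.135 mM titrated to
ligand:protein ratios 2..100 with a shared Kd of 15 mM and maximal CSPs of
0.55/0.29/0.18/0.29 ppm on four reporter residues; four helices at
29-39, 48-79, 93-106 and 112-123 of a 129-residue membrane protein; and
two-component turnover kinetics with V = 40/70 % and Km = 1.3/20 uM.

All randomness flows from the single spec seed through one named stream per
block; the same spec always regenerates identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .activity_kinetics import ELECTRONS_PER_O2, OxygenTrace, RateCurve, mm_model
from .binding_fit import binding_isotherm
from .csp_titration import TitrationPoint, TitrationSeries, ligand_concentrations, shift_weight
from .errors import ValidationError
from .io_core import Peak, PeakList, Residue, ShiftTable
from ._random_coil import DEFAULT_TABLE, RANDOM_COIL_CA

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Per-block random streams (spawn keys off the single spec seed).
_STREAM_SEQUENCE = 0
_STREAM_PEAKS = 1
_STREAM_BINDING = 2
_STREAM_PRE = 3
_STREAM_SECSTRUCT = 4
_STREAM_KINETICS = 5


@dataclass
class BindingBlock:
    """Fast-exchange titration ground truth (concentrations mM, CSPs ppm)."""

    kd: float = 15.0
    protein_conc: float = 0.135
    ratios: Tuple[float, ...] = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0)
    csp_max: Dict[int, float] = field(
        default_factory=lambda: {81: 0.55, 83: 0.29, 96: 0.18, 125: 0.29}
    )
    noise_sigma: float = 0.01  # ppm, per dimension per step
    stock_conc: Optional[float] = None  # mM; None = no-dilution bookkeeping


@dataclass
class PREBlock:
    """Phenomenological exposure -> attenuation curve parameters."""

    depth: Optional[Dict[int, float]] = None  # residue -> exposure in [0, 1]
    gamma: float = 2.0
    r_min: float = 0.2
    noise_frac: float = 0.05  # multiplicative log-normal noise


@dataclass
class SecstructBlock:
    """Helix layout and Cα offset for the shift-table generator."""

    segments: Tuple[Tuple[int, int], ...] = ((29, 39), (48, 79), (93, 106), (112, 123))
    offset: float = 2.5  # ppm added to random coil inside helices
    noise: float = 0.2  # ppm


@dataclass
class KineticsBlock:
    """Hyperbolic rate-curve ground truth (V in %, Km in uM)."""

    model: str = "two_site"
    v: Tuple[float, ...] = (40.0, 70.0)
    km: Tuple[float, ...] = (1.3, 20.0)
    noise_frac: float = 0.03
    conc: Tuple[float, ...] = (0.25, 0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
    replicates: int = 3


@dataclass
class SyntheticSpec:
    """One seed plus per-stage ground-truth blocks."""

    seed: int = 0
    length: int = 129
    sequence: Optional[str] = None  # random composition when None
    binding: BindingBlock = field(default_factory=BindingBlock)
    pre: PREBlock = field(default_factory=PREBlock)
    secstruct: SecstructBlock = field(default_factory=SecstructBlock)
    kinetics: KineticsBlock = field(default_factory=KineticsBlock)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    def get_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence.upper()
        rng = self.rng(_STREAM_SEQUENCE)
        return "".join(rng.choice(list(_AA), size=self.length))


def _base_peaks(spec: SyntheticSpec, with_intensity: bool = False) -> PeakList:
    """Reference amide peak positions, uniform over the typical HSQC window."""
    seq = spec.get_sequence()
    rng = spec.rng(_STREAM_PEAKS)
    peaks = PeakList(label="reference")
    for i, code in enumerate(seq, start=1):
        h = rng.uniform(7.0, 9.5)
        n = rng.uniform(105.0, 130.0)
        intensity = float(rng.lognormal(mean=np.log(1e6), sigma=0.3)) if with_intensity else None
        peaks.add(Peak(Residue(i, code), h, n, intensity))
    return peaks


def gen_titration(spec: SyntheticSpec) -> TitrationSeries:
    """Synthesize a fast-exchange CSP titration series.

    Each perturbed residue's endpoint displacement follows the shared-Kd
    ligand-depletion isotherm, split into (d1H, d15N) along a fixed seeded
    direction angle so that the weighted CSP of the displacement equals the
    isotherm value.  Gaussian noise of ``noise_sigma`` ppm is added
    independently to both shift dimensions at every step; unperturbed
    residues receive noise only.
    """
    b = spec.binding
    if not b.ratios:
        raise ValidationError("ratio list is empty")
    seq = spec.get_sequence()
    for res in b.csp_max:
        if not (1 <= res <= len(seq)):
            raise ValidationError(f"perturbed residue {res} outside the sequence")
    ref = _base_peaks(spec)
    rng = spec.rng(_STREAM_BINDING)
    angles = {res: rng.uniform(0.0, 2.0 * np.pi) for res in sorted(b.csp_max)}

    concs = ligand_concentrations([0.0, *b.ratios], b.protein_conc, b.stock_conc)
    points: List[TitrationPoint] = []
    for step, (ratio, (l_tot, p_tot)) in enumerate(zip([0.0, *b.ratios], concs)):
        peaks = PeakList(label=f"ratio_{ratio:g}")
        for p in ref:
            res = p.residue.index
            dh = dn = 0.0
            if res in b.csp_max and step > 0:
                csp = binding_isotherm(p_tot, l_tot, b.kd, b.csp_max[res])
                a = shift_weight(p.residue.one_letter)
                dh = csp * np.cos(angles[res])
                dn = csp * np.sin(angles[res]) / a
            if step > 0 and b.noise_sigma > 0:
                dh += rng.normal(0.0, b.noise_sigma)
                dn += rng.normal(0.0, b.noise_sigma)
            peaks.add(Peak(p.residue, p.delta_h + dh, p.delta_n + dn, p.intensity))
        points.append(
            TitrationPoint(ratio=ratio, ligand_conc=l_tot, protein_conc=p_tot, peaks=peaks)
        )
    return TitrationSeries(points=points, stock_conc=b.stock_conc)


def default_depth_profile(spec: SyntheticSpec) -> Dict[int, float]:
    """Exposure profile implied by the helix layout.

    The transmembrane helix (the longest segment) sits in the micelle core,
    the flanking amphipathic helices at the interface, loops and termini
    fully solvent-exposed.
    """
    seq = spec.get_sequence()
    segments = sorted(spec.secstruct.segments, key=lambda s: s[0] - s[1])
    tm = segments[0] if segments else None  # longest
    depth = {}
    for i in range(1, len(seq) + 1):
        d = 0.9
        for start, end in spec.secstruct.segments:
            if start <= i <= end:
                d = 0.05 if (start, end) == tm else 0.4
                break
        depth[i] = d
    return depth


def gen_pre(spec: SyntheticSpec, probe: str = "watersoluble") -> Tuple[PeakList, PeakList]:
    """Synthesize (probe spectrum, reference spectrum) peak lists.

    A water-soluble probe attenuates exposed residues:
    ``ratio = r_min + (1 - r_min) * (1 - depth)^gamma`` with ``depth`` the
    exposure in [0, 1]; the detergent-partitioning probe uses the mirrored
    curve ``r_min + (1 - r_min) * depth^gamma``.  Multiplicative log-normal
    noise is applied to the attenuated intensities.
    """
    if probe not in ("watersoluble", "detergent"):
        raise ValidationError(f"unknown probe {probe!r}")
    p = spec.pre
    depth = p.depth if p.depth is not None else default_depth_profile(spec)
    if any(not (0.0 <= d <= 1.0) for d in depth.values()):
        raise ValueError("depth values must lie in [0, 1]")
    ref = _base_peaks(spec, with_intensity=True)
    rng = spec.rng(_STREAM_PRE if probe == "watersoluble" else _STREAM_PRE + 100)
    out = PeakList(label=f"probe_{probe}")
    for pk in ref:
        res = pk.residue.index
        d = depth.get(res, 1.0)
        x = (1.0 - d) if probe == "watersoluble" else d
        ratio = p.r_min + (1.0 - p.r_min) * x**p.gamma
        if p.noise_frac > 0:
            ratio *= float(rng.lognormal(mean=0.0, sigma=p.noise_frac))
        out.add(Peak(pk.residue, pk.delta_h, pk.delta_n, max(pk.intensity * ratio, 0.0)))
    return out, ref


def gen_shift_table(spec: SyntheticSpec) -> ShiftTable:
    """Cα shift table: random coil plus helix offset plus Gaussian noise."""
    s = spec.secstruct
    segs = sorted(s.segments)
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if b0 <= a1:
            raise ValidationError(f"overlapping helix segments {(a0, a1)} and {(b0, b1)}")
    seq = spec.get_sequence()
    if segs and (segs[0][0] < 1 or segs[-1][1] > len(seq)):
        raise ValidationError("helix segments fall outside the sequence")
    rc = RANDOM_COIL_CA[DEFAULT_TABLE]
    rng = spec.rng(_STREAM_SECSTRUCT)
    table = ShiftTable()
    for i, code in enumerate(seq, start=1):
        offset = s.offset if any(a <= i <= b for a, b in segs) else 0.0
        noise = rng.normal(0.0, s.noise) if s.noise > 0 else 0.0
        table.set(i, code, "CA", rc[code] + offset + noise)
    return table


def gen_rates(spec: SyntheticSpec) -> List[RateCurve]:
    """Synthesize replicate rate curves from the hyperbolic ground truth."""
    k = spec.kinetics
    n_sites = {"one_site": 1, "two_site": 2}.get(k.model)
    if n_sites is None:
        raise ValidationError(f"unknown kinetics model {k.model!r}")
    if len(k.v) != n_sites or len(k.km) != n_sites:
        raise ValidationError("v/km length must match the model's component count")
    c = np.asarray(k.conc, dtype=float)
    truth = mm_model(c, k.v, k.km)
    rng = spec.rng(_STREAM_KINETICS)
    curves = []
    for rep in range(k.replicates):
        noise = rng.normal(0.0, k.noise_frac, size=c.size) if k.noise_frac > 0 else 0.0
        curves.append(
            RateCurve(conc=c, rates=truth * (1.0 + noise), unit="%",
                      condition=k.model, replicate=rep)
        )
    return curves


def average_replicates(curves: Sequence[RateCurve]) -> RateCurve:
    """Mean rate curve across replicates (the form the hyperbolic fits use)."""
    if not curves:
        raise ValidationError("no replicate curves")
    conc = curves[0].conc
    stacked = np.vstack([c.rates for c in curves])
    return RateCurve(conc=conc.copy(), rates=stacked.mean(axis=0),
                     unit=curves[0].unit, condition=curves[0].condition)


def gen_trace(
    rate: float,
    enzyme_conc: float,
    background_slope: float = -0.05,
    o2_start: float = 240.0,
    dt: float = 0.5,
    t_background: float = 60.0,
    t_measure: float = 60.0,
) -> OxygenTrace:
    """Piecewise-linear oxygen-electrode trace implied by a turnover rate.

    The background segment decays at ``background_slope`` (uM O2/s, reductant
    autoxidation); after enzyme addition the slope steepens by
    ``rate * enzyme_conc / 4`` so that the background-corrected turnover
    extraction returns ``rate`` exactly.
    """
    t_bg = np.arange(0.0, t_background, dt)
    t_ms = np.arange(t_background, t_background + t_measure + dt / 2, dt)
    slope_measure = background_slope - rate * enzyme_conc / ELECTRONS_PER_O2
    o2_bg = o2_start + background_slope * t_bg
    o2_break = o2_start + background_slope * t_background
    o2_ms = o2_break + slope_measure * (t_ms - t_background)
    return OxygenTrace(
        time=np.concatenate([t_bg, t_ms]),
        o2=np.concatenate([o2_bg, o2_ms]),
        events={"enzyme_added": t_background},
    )
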